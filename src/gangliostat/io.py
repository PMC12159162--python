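"""Readers and writers for the pipeline's external formats.

CSV/TSV cell tables and label matrices, Matrix Market (MTX) expression
triplets with genes.tsv/cells.tsv sidecars (1-based on disk, 0-based in
memory), GMT gene sets, GeoJSON boundary polygons, JSON ground truth /
homology maps, and run manifests.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse
from shapely.geometry import Polygon, shape
from shapely.geometry import mapping as geom_mapping

from .consensus import HomologyMap
from .enrichment import GeneSetCollection
from .spatial import REQUIRED_CELL_COLUMNS, validate_cells

__all__ = [
    "read_cells", "write_cells",
    "read_expression", "write_expression",
    "read_gmt", "write_gmt",
    "read_polygon", "write_polygon",
    "read_labels", "read_homology_map",
    "write_manifest",
]


def read_cells(path: str | Path) -> pd.DataFrame:
    """Read a cell table CSV (cell_id, section_id, x_um, y_um, volume, cell_type)."""
    df = pd.read_csv(path)
    missing = [c for c in REQUIRED_CELL_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required column(s) {missing}")
    for col in ("x_um", "y_um", "volume"):
        try:
            df[col] = pd.to_numeric(df[col], errors="raise")
        except (ValueError, TypeError) as exc:
            raise ValueError(f"{path}: non-numeric value in column {col!r}") from exc
    df["cell_id"] = df["cell_id"].astype(str)
    df["section_id"] = df["section_id"].astype(str)
    df["cell_type"] = df["cell_type"].astype(str)
    return validate_cells(df[list(REQUIRED_CELL_COLUMNS)])


def write_cells(cells: pd.DataFrame, path: str | Path) -> None:
    validate_cells(cells)
    cells[list(REQUIRED_CELL_COLUMNS)].to_csv(path, index=False)


def read_expression(path: str | Path) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Read a genes x cells matrix, MTX + sidecars or dense CSV.

    For a ``.mtx`` path, ``genes.tsv`` and ``cells.tsv`` are expected next to
    it; cells.tsv carries the per-cell ``cluster`` and ``dataset`` columns.
    For a CSV, genes are rows (index) and cells columns, and the annotation
    frame returned is empty.  Returns (expression, cell annotation).
    """
    path = Path(path)
    if path.suffix == ".mtx":
        mat = scipy.io.mmread(path)  # 1-based on disk; scipy yields 0-based
        genes = pd.read_csv(path.parent / "genes.tsv", sep="\t")
        cells = pd.read_csv(path.parent / "cells.tsv", sep="\t")
        mat = scipy.sparse.coo_matrix(mat)
        if mat.shape != (len(genes), len(cells)):
            raise ValueError(
                f"MTX header says {mat.shape}, sidecars have "
                f"{len(genes)} genes x {len(cells)} cells"
            )
        expr = pd.DataFrame(
            mat.toarray(), index=genes.iloc[:, 0].astype(str),
            columns=cells.iloc[:, 0].astype(str),
        )
        ann = cells.set_index(cells.columns[0])
        ann.index = ann.index.astype(str)
        return expr, ann
    expr = pd.read_csv(path, index_col=0)
    return expr, pd.DataFrame(index=expr.columns)


def write_expression(
    expr: pd.DataFrame, ann: pd.DataFrame, outdir: str | Path, name: str = "matrix"
) -> Path:
    """Write genes x cells as MTX with genes.tsv / cells.tsv sidecars."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    mtx = outdir / f"{name}.mtx"
    scipy.io.mmwrite(mtx, scipy.sparse.coo_matrix(expr.to_numpy()))
    pd.DataFrame({"gene": expr.index}).to_csv(outdir / "genes.tsv", sep="\t", index=False)
    cells = ann.reindex(expr.columns)
    cells.insert(0, "cell", expr.columns)
    cells.to_csv(outdir / "cells.tsv", sep="\t", index=False)
    return mtx


def read_gmt(path: str | Path) -> GeneSetCollection:
    """Read a GMT file (set name, description, tab-separated members)."""
    sets: dict[str, set[str]] = {}
    with open(path) as fh:
        for line_no, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path}:{line_no}: GMT line needs name, description, members")
            name, members = parts[0], parts[2:]
            if name in sets:
                raise ValueError(f"{path}: duplicate set name {name!r}")
            uniq = set(members)
            if len(uniq) < len(members):
                warnings.warn(f"{path}: duplicate members collapsed in set {name!r}")
            sets[name] = uniq
    return GeneSetCollection(sets)


def write_gmt(collection: GeneSetCollection, path: str | Path) -> None:
    with open(path, "w") as fh:
        for name in collection.sets:
            members = "\t".join(sorted(collection.sets[name]))
            fh.write(f"{name}\tna\t{members}\n")


def read_polygon(path: str | Path) -> Polygon:
    """Read a boundary polygon from GeoJSON."""
    with open(path) as fh:
        gj = json.load(fh)
    if gj.get("type") == "Feature":
        gj = gj["geometry"]
    poly = shape(gj)
    if not isinstance(poly, Polygon):
        raise ValueError(f"{path}: expected a GeoJSON Polygon, got {gj.get('type')}")
    return poly


def write_polygon(poly: Polygon, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(geom_mapping(poly), fh)


def read_labels(path: str | Path) -> pd.DataFrame:
    """Read a cells x sources label matrix CSV (first column = cell id)."""
    return pd.read_csv(path, index_col=0, dtype=str)


def read_homology_map(path: str | Path) -> HomologyMap:
    """Read a homology map JSON: {"mapping": {source: {label: harmonized}},
    "exempt_families": {family: [labels]}}."""
    with open(path) as fh:
        raw = json.load(fh)
    fams = {k: set(v) for k, v in raw.get("exempt_families", {}).items()}
    return HomologyMap(mapping=raw["mapping"], exempt_families=fams)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def write_manifest(
    outdir: str | Path,
    stage: str,
    config: dict,
    seed: int | None,
    inputs: list[str | Path] = (),
    row_counts: dict[str, int] | None = None,
) -> Path:
    """Write a run manifest recording version, config hash, seed, input
    checksums and per-output row counts, for byte-reproducibility audits."""
    from . import __version__

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cfg_json = json.dumps(config, sort_keys=True, default=str)
    manifest = {
        "tool": "gangliostat",
        "version": __version__,
        "stage": stage,
        "seed": seed,
        "config_sha256": hashlib.sha256(cfg_json.encode()).hexdigest(),
        "config": json.loads(cfg_json),
        "inputs": {str(p): _sha256(Path(p)) for p in inputs},
        "row_counts": row_counts or {},
    }
    path = outdir / f"manifest_{stage}.json"
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=2)
    return path
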