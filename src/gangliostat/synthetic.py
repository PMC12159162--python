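"""Synthetic ganglion data with planted ground truth.

Four generators emulate the inputs of the analysis pipeline so that every
downstream stage can be exercised and validated without any real dataset:

* :func:`simulate_ganglion` — clustered, radially zonated point patterns of
  typed cells inside a convex tissue outline, with per-type lognormal
  volumes.  Cells of one type are placed by a parent-offspring (Thomas-type)
  cluster process; the parents' normalized depth from the tissue edge is
  Beta-distributed around a configured target quantile, so each type carries
  a planted zonation depth.
* :func:`simulate_expression` — a genes x cells matrix with planted
  co-expression modules whose per-cluster activity takes levels
  {0, 0.5, 1}, plus optional per-dataset (batch) level shifts, Gaussian
  batch offsets and noise; the matching kME table is computed from the
  realized eigengenes.
* :func:`simulate_regulons` — gene sets with exactly specified overlaps to
  planted modules (unspecified members drawn from the remaining universe).
* :func:`simulate_label_matrix` — multi-source label assignments with a
  controlled per-source concordance and bookkeeping of the fully concordant
  cell set (modulo exempt families).

All generators are deterministic in (config, seed); each draws from its own
named substream of the top-level seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import shapely
from shapely.geometry import Point, Polygon
from shapely.geometry.polygon import orient

from ._rng import substream
from .consensus import HomologyMap
from .modules import kme_table

__all__ = [
    "GanglionConfig",
    "ExpressionConfig",
    "ModuleSpec",
    "regular_polygon",
    "simulate_ganglion",
    "simulate_expression",
    "simulate_regulons",
    "simulate_label_matrix",
]


def regular_polygon(n_vertices: int, radius_um: float, center=(0.0, 0.0)) -> Polygon:
    """Regular convex n-gon used as a default tissue outline."""
    if n_vertices < 3:
        raise ValueError("a polygon needs >= 3 vertices")
    theta = 2 * np.pi * np.arange(n_vertices) / n_vertices
    xy = np.column_stack([
        center[0] + radius_um * np.cos(theta),
        center[1] + radius_um * np.sin(theta),
    ])
    return orient(Polygon(xy), sign=1.0)


@dataclass
class GanglionConfig:
    """Configuration of the zonated clustered point pattern.

    ``depth_quantile`` per type is the target *normalized edge depth* (0 =
    on the boundary, 1 = at the tissue center); parents of the cluster
    process draw their depth from Beta(c*q, c*(1-q)) with concentration
    ``depth_concentration``.  ``dispersion_um`` is the isotropic Gaussian
    SD of offspring around their parent; ``parent_intensity`` the expected
    number of cluster parents per type.
    """

    cells_per_type: list[int]
    depth_quantile: list[float]
    boundary: Polygon = field(default_factory=lambda: regular_polygon(24, 500.0))
    parent_intensity: list[float] | float = 8.0
    dispersion_um: list[float] | float = 25.0
    volume_lognormal: list[tuple[float, float]] | tuple[float, float] = (6.0, 0.3)
    depth_concentration: float = 20.0
    type_names: list[str] | None = None
    section_id: str = "S1"

    def __post_init__(self) -> None:
        n = len(self.cells_per_type)
        if len(self.depth_quantile) != n:
            raise ValueError("depth_quantile must have one entry per type")
        if any(c < 1 for c in self.cells_per_type):
            raise ValueError("all cell counts must be >= 1")
        if any(not 0.0 <= q <= 1.0 for q in self.depth_quantile):
            raise ValueError("depth_quantile must lie in [0, 1]")
        self.parent_intensity = _per_type(self.parent_intensity, n)
        self.dispersion_um = _per_type(self.dispersion_um, n)
        if any(s < 0 for s in self.dispersion_um):
            raise ValueError("dispersion sd must be >= 0")
        if isinstance(self.volume_lognormal, tuple):
            self.volume_lognormal = [self.volume_lognormal] * n
        if self.type_names is None:
            self.type_names = [f"T{i}" for i in range(n)]
        if len(self.boundary.exterior.coords) - 1 < 3:
            raise ValueError("boundary polygon needs >= 3 vertices")
        if not self.boundary.equals(self.boundary.convex_hull):
            raise ValueError("boundary polygon must be convex")


def _per_type(value, n: int) -> list:
    if np.isscalar(value):
        return [value] * n
    if len(value) != n:
        raise ValueError("per-type parameter has wrong length")
    return list(value)


def _place_parents(
    poly: Polygon, n: int, q: float, conc: float, rng: np.random.Generator
) -> np.ndarray:
    """Parents at Beta-distributed normalized depth along random rays.

    A ray from the polygon centroid at a uniform angle hits the boundary at
    r = 1; a parent at depth d sits at fraction (1 - d) of that ray, so d = 0
    lands on the boundary and d = 1 at the centroid.  Depth along a ray is
    monotone in d for a convex outline, which is all the zonation ordering
    needs.
    """
    cx, cy = poly.centroid.x, poly.centroid.y
    theta = rng.uniform(0, 2 * np.pi, size=n)
    a = max(q * conc, 1e-6)
    b = max((1 - q) * conc, 1e-6)
    depth = rng.beta(a, b, size=n)
    # boundary hit of each ray: intersect with a segment past the outline
    far = 2.0 * poly.exterior.distance(Point(cx, cy)) + 2.0 * _circumradius(poly)
    out = np.empty((n, 2))
    for i in range(n):
        ray = shapely.LineString([
            (cx, cy),
            (cx + far * np.cos(theta[i]), cy + far * np.sin(theta[i])),
        ])
        hit = ray.intersection(poly.exterior)
        if hit.is_empty:
            raise RuntimeError("ray from centroid failed to reach the boundary")
        if hit.geom_type != "Point":
            # vertex/edge grazing: take the boundary point nearest the centroid
            pts_on_ring = [
                (c[0], c[1])
                for geom in getattr(hit, "geoms", [hit])
                for c in np.atleast_2d(np.asarray(geom.coords))
            ]
            bx, by = min(pts_on_ring, key=lambda c: (c[0] - cx) ** 2 + (c[1] - cy) ** 2)
        else:
            bx, by = hit.x, hit.y
        r = 1.0 - depth[i]
        out[i] = (cx + r * (bx - cx), cy + r * (by - cy))
    return out


def _circumradius(poly: Polygon) -> float:
    cx, cy = poly.centroid.x, poly.centroid.y
    xy = np.asarray(poly.exterior.coords)
    return float(np.sqrt(((xy - [cx, cy]) ** 2).sum(axis=1)).max())


def simulate_ganglion(
    cfg: GanglionConfig, seed: int = 0
) -> tuple[pd.DataFrame, Polygon, dict]:
    """Simulate the cell table of one ganglion section.

    Returns (cell table, boundary polygon, ground truth).  The ground truth
    records each type's target depth quantile and the planted depth ordering
    (most superficial type first).  All centroids lie inside or on the
    boundary; identical (cfg, seed) reproduce the table exactly.
    """
    rng = substream(seed, "ganglion")
    poly = cfg.boundary
    rows = []
    for t, n_cells in enumerate(cfg.cells_per_type):
        n_parents = max(1, int(rng.poisson(cfg.parent_intensity[t])))
        parents = _place_parents(
            poly, n_parents, cfg.depth_quantile[t], cfg.depth_concentration, rng
        )
        assign = rng.integers(0, n_parents, size=n_cells)
        sd = cfg.dispersion_um[t]
        if sd == 0:
            pts = parents[assign].copy()
        else:
            # vectorized rejection: redraw offspring that left the tissue
            pts = parents[assign] + rng.normal(0.0, sd, size=(n_cells, 2))
            bad = ~shapely.intersects_xy(poly, pts[:, 0], pts[:, 1])
            for _ in range(200):
                if not bad.any():
                    break
                pts[bad] = parents[assign[bad]] + rng.normal(0.0, sd, size=(int(bad.sum()), 2))
                bad = ~shapely.intersects_xy(poly, pts[:, 0], pts[:, 1])
            else:
                pts[bad] = parents[assign[bad]]  # give up: collapse onto parent
        meanlog, sdlog = cfg.volume_lognormal[t]
        vol = rng.lognormal(meanlog, sdlog, size=n_cells)
        for i in range(n_cells):
            rows.append({
                "cell_id": f"{cfg.type_names[t]}_{i}",
                "section_id": cfg.section_id,
                "x_um": pts[i, 0],
                "y_um": pts[i, 1],
                "volume": vol[i],
                "cell_type": cfg.type_names[t],
            })
    cells = pd.DataFrame(rows)
    order = np.argsort(cfg.depth_quantile, kind="stable")
    truth = {
        "depth_quantile": dict(zip(cfg.type_names, cfg.depth_quantile)),
        "depth_order_peripheral_first": [cfg.type_names[i] for i in order],
    }
    return cells, poly, truth


@dataclass
class ModuleSpec:
    """One planted co-expression module.

    ``cluster_levels`` maps every cluster to an activity level in
    {0, 0.5, 1}; ``dataset_levels`` (optional) plants a per-dataset level
    instead of / on top of the cluster signal, producing a batch-driven
    module.  ``loading_scale`` multiplies the per-gene loadings (drawn
    uniformly in [0.8, 1.2]).
    """

    n_genes: int
    cluster_levels: list[float]
    loading_scale: float = 1.0
    dataset_levels: list[float] | None = None

    def __post_init__(self) -> None:
        allowed = {0.0, 0.5, 1.0}
        if not set(self.cluster_levels) <= allowed:
            raise ValueError("planted cluster levels must be in {0, 0.5, 1}")
        if self.dataset_levels is not None and not set(self.dataset_levels) <= allowed:
            raise ValueError("planted dataset levels must be in {0, 0.5, 1}")


@dataclass
class ExpressionConfig:
    """Configuration of the planted-module expression matrix."""

    n_genes: int
    n_cells: int
    n_clusters: int
    n_datasets: int
    modules: list[ModuleSpec]
    noise_sd: float = 0.2
    batch_shift_sd: float = 0.0

    def __post_init__(self) -> None:
        total = sum(m.n_genes for m in self.modules)
        if total > self.n_genes:
            raise ValueError(
                f"module genes ({total}) exceed n_genes ({self.n_genes})"
            )
        for m in self.modules:
            if len(m.cluster_levels) != self.n_clusters:
                raise ValueError("cluster_levels must have one entry per cluster")
            if m.dataset_levels is not None and len(m.dataset_levels) != self.n_datasets:
                raise ValueError("dataset_levels must have one entry per dataset")


def simulate_expression(
    cfg: ExpressionConfig, seed: int = 0
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame, dict]:
    """Simulate expression with planted modules; derive the kME table.

    Returns (expression genes x cells, cell annotation with ``cluster`` and
    ``dataset`` columns, kME table, ground truth).  Module gene g in cell i:

        x[g, i] = loading_g * (level[cluster(i)] + dataset_level[dataset(i)])
                  + batch_shift[dataset(i), g] + noise

    Non-module genes are pure noise.  Cells are split evenly over clusters
    and cyclically over datasets so every (cluster, dataset) combination is
    populated.  The kME table is the Pearson correlation of every gene with
    each planted module's realized eigengene.
    """
    rng = substream(seed, "expression")
    genes = [f"G{i:04d}" for i in range(cfg.n_genes)]
    cells = [f"C{i:05d}" for i in range(cfg.n_cells)]
    clusters = np.repeat(
        np.arange(cfg.n_clusters), int(np.ceil(cfg.n_cells / cfg.n_clusters))
    )[: cfg.n_cells]
    datasets = np.arange(cfg.n_cells) % cfg.n_datasets
    ann = pd.DataFrame(
        {
            "cluster": [f"K{c}" for c in clusters],
            "dataset": [f"D{d}" for d in datasets],
        },
        index=cells,
    )
    x = rng.normal(0.0, cfg.noise_sd, size=(cfg.n_genes, cfg.n_cells)) if cfg.noise_sd > 0 \
        else np.zeros((cfg.n_genes, cfg.n_cells))
    module_genes: dict[str, list[str]] = {}
    levels: dict[str, list[float]] = {}
    start = 0
    for mi, spec in enumerate(cfg.modules):
        name = f"M{mi}"
        rows = slice(start, start + spec.n_genes)
        module_genes[name] = genes[rows]
        levels[name] = list(spec.cluster_levels)
        start += spec.n_genes
        loading = spec.loading_scale * rng.uniform(0.8, 1.2, size=spec.n_genes)
        sig_c = np.asarray(spec.cluster_levels, dtype=float)[clusters]
        sig_d = (
            np.asarray(spec.dataset_levels, dtype=float)[datasets]
            if spec.dataset_levels is not None
            else 0.0
        )
        x[rows] += loading[:, None] * (sig_c + sig_d)[None, :]
    if cfg.batch_shift_sd > 0:
        shift = rng.normal(0.0, cfg.batch_shift_sd, size=(cfg.n_genes, cfg.n_datasets))
        x += shift[:, datasets]
    expr = pd.DataFrame(x, index=genes, columns=cells)
    kme = kme_table(expr, module_genes)
    truth = {
        "module_genes": module_genes,
        "cluster_levels": levels,
        "clusters": [f"K{c}" for c in range(cfg.n_clusters)],
        "batch_driven": [
            f"M{mi}" for mi, s in enumerate(cfg.modules) if s.dataset_levels is not None
        ],
    }
    return expr, ann, kme, truth


def simulate_regulons(
    module_genes: dict[str, list[str]],
    universe: list[str],
    regulon_sizes: dict[str, int],
    overlaps: dict[tuple[str, str], int],
    seed: int = 0,
) -> tuple[dict[str, set[str]], dict]:
    """Gene sets with exactly specified overlaps to planted modules.

    ``overlaps[(module, regulon)] = k`` forces |module ∩ regulon| = k by
    drawing k members from the module and the remainder of the regulon from
    the universe minus *all* modules with a specified pair for that regulon.
    Pairs without a specification get whatever overlap chance produces.
    """
    rng = substream(seed, "regulons")
    universe = list(universe)
    mods = {m: set(g) for m, g in module_genes.items()}
    for (m, r), k in overlaps.items():
        if m not in mods:
            raise ValueError(f"unknown module {m!r} in overlap spec")
        if r not in regulon_sizes:
            raise ValueError(f"unknown regulon {r!r} in overlap spec")
        if k > min(len(mods[m]), regulon_sizes[r]):
            raise ValueError(
                f"requested overlap {k} for ({m}, {r}) exceeds min set size"
            )
    regulons: dict[str, set[str]] = {}
    for r in sorted(regulon_sizes):
        size = regulon_sizes[r]
        specified = {m: k for (m, rr), k in overlaps.items() if rr == r}
        members: set[str] = set()
        blocked: set[str] = set()
        for m in sorted(specified):
            blocked |= mods[m]
        for m in sorted(specified):
            pool = sorted(mods[m] - members)
            take = specified[m] - len(members & mods[m])
            if take > 0:
                members |= set(rng.choice(pool, size=take, replace=False))
        free_pool = sorted(set(universe) - blocked - members)
        n_free = size - len(members)
        if n_free < 0 or n_free > len(free_pool):
            raise ValueError(f"regulon {r!r}: cannot reach size {size} given the spec")
        members |= set(rng.choice(free_pool, size=n_free, replace=False))
        regulons[r] = members
    enriched = sorted((m, r) for (m, r), k in overlaps.items() if k > 0)
    truth = {"specified_overlaps": {f"{m}|{r}": k for (m, r), k in overlaps.items()},
             "enriched_pairs": enriched}
    return regulons, truth


def simulate_label_matrix(
    n_cells: int,
    sources: list[str],
    labels: list[str],
    concordance: float,
    exempt_families: dict[str, set[str]] | None = None,
    seed: int = 0,
) -> tuple[pd.DataFrame, dict]:
    """Multi-source label assignments with controlled concordance.

    Each cell gets a uniformly drawn true label; each source independently
    reports it with probability *concordance*, otherwise a uniformly random
    *other* label.  The ground truth records the true labels and the exact
    set of cells every source agrees on — counting agreement at the family
    level inside declared exempt families — which is what the consensus
    filter must recover.
    """
    if not 0.0 <= concordance <= 1.0:
        raise ValueError("concordance must lie in [0, 1]")
    if len(sources) < 2:
        raise ValueError("need >= 2 sources")
    rng = substream(seed, "labels")
    labels = list(labels)
    hmap = HomologyMap(mapping={}, exempt_families=exempt_families or {})
    true_idx = rng.integers(0, len(labels), size=n_cells)
    matrix = np.empty((n_cells, len(sources)), dtype=object)
    for j in range(len(sources)):
        agree = rng.random(n_cells) < concordance
        alt = rng.integers(0, len(labels) - 1, size=n_cells)
        for i in range(n_cells):
            if agree[i]:
                matrix[i, j] = labels[true_idx[i]]
            else:
                a = alt[i]
                matrix[i, j] = labels[a if a < true_idx[i] else a + 1]
    cell_ids = [f"c{i:05d}" for i in range(n_cells)]
    lm = pd.DataFrame(matrix, index=cell_ids, columns=sources)
    concordant = []
    for i in range(n_cells):
        vals = set(matrix[i])
        if len(vals) == 1:
            concordant.append(cell_ids[i])
        else:
            fams = {hmap.family_of(v) for v in vals}
            if len(fams) == 1 and None not in fams:
                concordant.append(cell_ids[i])
    truth = {
        "true_label": dict(zip(cell_ids, (labels[t] for t in true_idx))),
        "concordant_cells": concordant,
    }
    return lm, truth
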