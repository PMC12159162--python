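"""Pairwise cell-type proximity statistics for in-situ transcriptomics.

Given a table of segmented cells (centroid, volume, type label, section), the
functions here compute the volume-normalized pairwise distance matrix, its
aggregation into a cell-type x cell-type mean-distance matrix, a [0, 1]
neighbor score, and an average-linkage ordering of the type matrix.

The volume normalization divides each centroid-to-centroid Euclidean distance
d_ij by the mean of the two cell volumes, avg_volume_ij = (v_i + v_j) / 2, so
that large somata (which force their centroids apart) are not spuriously
scored as distant.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform
from sklearn.neighbors import NearestNeighbors

__all__ = [
    "pairwise_euclidean",
    "volume_normalize",
    "aggregate_type_distance",
    "type_distance_matrix",
    "neighbor_score",
    "knn_neighbor_score",
    "cluster_type_matrix",
    "TypeDendrogram",
]

REQUIRED_CELL_COLUMNS = ("cell_id", "section_id", "x_um", "y_um", "volume", "cell_type")


def validate_cells(cells: pd.DataFrame) -> pd.DataFrame:
    """Check the cell-table contract: required columns, finite coordinates,
    positive volumes, cell ids unique within each section."""
    missing = [c for c in REQUIRED_CELL_COLUMNS if c not in cells.columns]
    if missing:
        raise ValueError(f"cell table is missing required column(s): {missing}")
    xy = cells[["x_um", "y_um"]].to_numpy(dtype=float)
    bad = ~np.isfinite(xy).all(axis=1)
    if bad.any():
        offenders = cells.loc[bad, "cell_id"].tolist()[:5]
        raise ValueError(f"non-finite coordinates for cell_id(s) {offenders}")
    vol = cells["volume"].to_numpy(dtype=float)
    if not np.isfinite(vol).all() or (vol <= 0).any():
        offenders = cells.loc[~(np.isfinite(vol) & (vol > 0)), "cell_id"].tolist()[:5]
        raise ValueError(f"volume must be finite and > 0; offending cell_id(s) {offenders}")
    dup = cells.duplicated(subset=["section_id", "cell_id"])
    if dup.any():
        offenders = cells.loc[dup, "cell_id"].tolist()[:5]
        raise ValueError(f"duplicate cell_id within section: {offenders}")
    return cells


def pairwise_euclidean(cells: pd.DataFrame) -> np.ndarray:
    """Dense matrix of centroid-to-centroid Euclidean distances (um).

    Symmetric with an exactly-zero diagonal; entry (i, j) is
    sqrt((x_i - x_j)^2 + (y_i - y_j)^2) in the row order of *cells*.
    """
    validate_cells(cells)
    if len(cells) < 2:
        raise ValueError("need at least 2 cells to form pairwise distances")
    xy = cells[["x_um", "y_um"]].to_numpy(dtype=float)
    diff = xy[:, None, :] - xy[None, :, :]
    d = np.sqrt((diff**2).sum(axis=-1))
    np.fill_diagonal(d, 0.0)
    return d


def volume_normalize(distances: np.ndarray, volumes: np.ndarray) -> np.ndarray:
    """Divide each pairwise distance by the mean volume of the two cells.

    d_norm(i, j) = d(i, j) / ((v_i + v_j) / 2).  The diagonal stays zero.
    """
    volumes = np.asarray(volumes, dtype=float)
    if (volumes <= 0).any() or not np.isfinite(volumes).all():
        raise ValueError("all volumes must be finite and > 0")
    avg = (volumes[:, None] + volumes[None, :]) / 2.0
    out = np.asarray(distances, dtype=float) / avg
    np.fill_diagonal(out, 0.0)
    return out


def aggregate_type_distance(norm: np.ndarray, labels: pd.Series | np.ndarray) -> pd.DataFrame:
    """Collapse a per-cell normalized distance matrix to a type x type matrix.

    Off-diagonal (A, B): mean of d_norm over all ordered pairs i in A, j in B.
    Diagonal (A, A): mean over distinct within-type pairs, self-pairs excluded
    (a zero self-distance would deflate the within-type mean).  A type with a
    single cell has no within-type pair and gets NaN on its diagonal.
    """
    labels = pd.Series(np.asarray(labels), name="cell_type")
    if len(labels) != norm.shape[0]:
        raise ValueError("label vector length does not match distance matrix")
    types = sorted(labels.unique())
    idx = {t: np.flatnonzero(labels.to_numpy() == t) for t in types}
    out = pd.DataFrame(np.nan, index=types, columns=types, dtype=float)
    for a in types:
        ia = idx[a]
        for b in types:
            ib = idx[b]
            block = norm[np.ix_(ia, ib)]
            if a == b:
                n = len(ia)
                if n < 2:
                    continue  # flagged missing: no within-type pair
                # unordered distinct pairs = upper triangle
                out.loc[a, b] = block[np.triu_indices(n, k=1)].mean()
            else:
                out.loc[a, b] = block.mean()
    return out


def type_distance_matrix(
    cells: pd.DataFrame, per_section: bool = True
) -> pd.DataFrame:
    """Volume-normalized mean type-distance matrix for a cell table.

    With ``per_section=True`` (default) the matrix is computed within each
    section and pooled by unweighted mean across sections; otherwise all cells
    are treated as one section.
    """
    validate_cells(cells)
    groups = cells.groupby("section_id") if per_section else [(None, cells)]
    mats = []
    for _, sec in groups:
        if len(sec) < 2:
            continue
        d = pairwise_euclidean(sec)
        dn = volume_normalize(d, sec["volume"].to_numpy())
        mats.append(aggregate_type_distance(dn, sec["cell_type"]))
    if not mats:
        raise ValueError("no section with >= 2 cells")
    types = sorted(set().union(*(m.index for m in mats)))
    aligned = [m.reindex(index=types, columns=types) for m in mats]
    pooled = pd.concat(aligned).groupby(level=0).mean()
    return pooled.reindex(index=types, columns=types)


def neighbor_score(tdm: pd.DataFrame) -> pd.DataFrame:
    """Min-max-inverted type distance: 1 = closest pair, 0 = farthest pair.

    score = 1 - (d - min) / (max - min), over all finite entries of the type
    distance matrix; invariant to affine rescaling of the distances.
    """
    vals = tdm.to_numpy(dtype=float)
    finite = vals[np.isfinite(vals)]
    if finite.size < 2:
        raise ValueError("need >= 2 finite entries in the type distance matrix")
    lo, hi = finite.min(), finite.max()
    if hi == lo:
        raise ValueError(
            "degenerate type distance matrix: all entries equal, "
            "neighbor score undefined (max == min)"
        )
    return 1.0 - (tdm - lo) / (hi - lo)


def knn_neighbor_score(cells: pd.DataFrame, k: int = 10) -> pd.DataFrame:
    """Alternative neighbor score from k-nearest-neighbor composition.

    score(A, B) = mean over cells of type A of the fraction of their k
    nearest neighbors (within the same section) that are of type B,
    symmetrized by averaging with score(B, A).  Bounded in [0, 1].
    """
    validate_cells(cells)
    types = sorted(cells["cell_type"].unique())
    counts = pd.DataFrame(0.0, index=types, columns=types)
    n_cells = pd.Series(0, index=types, dtype=float)
    for _, sec in cells.groupby("section_id"):
        if len(sec) <= k:
            warnings.warn(f"section with {len(sec)} cells <= k={k}; skipped")
            continue
        xy = sec[["x_um", "y_um"]].to_numpy(dtype=float)
        lab = sec["cell_type"].to_numpy()
        nn = NearestNeighbors(n_neighbors=k + 1).fit(xy)
        _, ind = nn.kneighbors(xy)
        neigh = lab[ind[:, 1:]]  # drop self
        for a in types:
            rows = neigh[lab == a]
            if rows.size == 0:
                continue
            n_cells[a] += rows.shape[0]
            for b in types:
                counts.loc[a, b] += (rows == b).sum() / k
    frac = counts.div(n_cells.replace(0, np.nan), axis=0)
    return (frac + frac.T) / 2.0


@dataclass
class TypeDendrogram:
    """Average-linkage dendrogram of the type distance matrix."""

    linkage: np.ndarray
    labels: list[str]
    leaf_order: list[str] = field(init=False)

    def __post_init__(self) -> None:
        leaves = hierarchy.leaves_list(self.linkage)
        self.leaf_order = [self.labels[i] for i in leaves]

    def to_newick(self) -> str:
        tree = hierarchy.to_tree(self.linkage)

        def rec(node, parent_dist: float) -> str:
            length = parent_dist - node.dist
            if node.is_leaf():
                return f"{self.labels[node.id]}:{length:g}"
            left = rec(node.left, node.dist)
            right = rec(node.right, node.dist)
            return f"({left},{right}):{length:g}"

        body = rec(tree, tree.dist)
        return body + ";"


def cluster_type_matrix(tdm: pd.DataFrame, method: str = "average") -> TypeDendrogram:
    """Agglomerative clustering of cell types on their mean-distance matrix.

    The matrix entries are treated directly as dissimilarities; ties are
    broken deterministically by presenting types in lexicographic order.
    """
    if tdm.isna().to_numpy().any():
        raise ValueError("type distance matrix contains NaN entries")
    order = sorted(tdm.index)
    tdm = tdm.loc[order, order]
    vals = tdm.to_numpy(dtype=float)
    sym = (vals + vals.T) / 2.0
    np.fill_diagonal(sym, 0.0)
    condensed = squareform(sym, checks=False)
    Z = hierarchy.linkage(condensed, method=method)
    return TypeDendrogram(linkage=Z, labels=list(order))
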