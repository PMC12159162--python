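"""Cross-dataset consensus labeling and probabilistic type similarity.

An integrated atlas built from several independently annotated datasets needs
three ingredients implemented here:

* *harmonization* — each source dataset uses its own cluster nomenclature; a
  homology map translates every source label into a shared vocabulary;
* *consensus filtering* — a cell is kept only when every source classifier
  assigns it to the same harmonized cluster, except for declared exempt
  label families (e.g. the A-LTMR group, whose per-dataset assignments are
  known to be unreliable at the subtype level) where agreement at the family
  level suffices;
* *probabilistic scoring* — a classifier trained on one reference dataset
  scores every cell of every other dataset against the reference types;
  concatenated score profiles are embedded with PCA, a k-nearest-neighbor
  graph gates which type pairs are comparable, and the gated Pearson
  correlation of type-mean PC profiles — power-transformed and column
  z-scored — is the cross-dataset type similarity matrix.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA
from sklearn.linear_model import LogisticRegression
from sklearn.neighbors import NearestNeighbors

UNASSIGNED = "unassigned"

__all__ = [
    "UNASSIGNED",
    "HomologyMap",
    "harmonize",
    "consensus_filter",
    "rank_markers",
    "train_and_score",
    "cross_similarity",
]


@dataclass
class HomologyMap:
    """Per-source label translation plus exempt label families.

    ``mapping[source][label]`` gives the harmonized label; every family in
    ``exempt_families`` is a set of harmonized labels treated as one group
    during consensus filtering.  Families must be disjoint.
    """

    mapping: dict[str, dict[str, str]]
    exempt_families: dict[str, set[str]] | None = None

    def __post_init__(self) -> None:
        self.exempt_families = self.exempt_families or {}
        seen: set[str] = set()
        for name, fam in self.exempt_families.items():
            if seen & fam:
                raise ValueError(f"exempt families overlap at {sorted(seen & fam)}")
            seen |= fam

    def family_of(self, label: str) -> str | None:
        for name, fam in self.exempt_families.items():
            if label in fam:
                return name
        return None


def harmonize(labels: pd.DataFrame, hmap: HomologyMap) -> pd.DataFrame:
    """Translate every source's labels into the harmonized vocabulary.

    *labels* is cells x sources.  ``unassigned`` passes through untouched;
    any other label missing from the source's map is an error.
    """
    out = {}
    for source in labels.columns:
        src_map = hmap.mapping.get(source)
        if src_map is None:
            raise ValueError(f"homology map has no entry for source {source!r}")
        col = labels[source]
        unmapped = set(col.unique()) - set(src_map) - {UNASSIGNED}
        if unmapped:
            raise ValueError(
                f"source {source!r} has unmapped label(s): {sorted(unmapped)[:10]}"
            )
        out[source] = col.map(lambda v: v if v == UNASSIGNED else src_map[v])
    return pd.DataFrame(out, index=labels.index)


def consensus_filter(
    harmonized: pd.DataFrame, hmap: HomologyMap | None = None
) -> tuple[pd.Index, pd.DataFrame]:
    """Keep cells on which all sources agree, honoring exempt families.

    A cell is kept iff every source assigns the same harmonized label, or all
    its source labels fall inside a single exempt family.  ``unassigned``
    always counts as disagreement.  Returns (kept cell index, per-cell report
    with a ``reason`` code in {concordant, exempt_family, unassigned,
    discordant} and the consensus label where one exists).
    """
    hmap = hmap or HomologyMap(mapping={})
    reasons = []
    consensus = []
    kept_flags = []
    for _, row in harmonized.iterrows():
        vals = list(row)
        if UNASSIGNED in vals:
            reasons.append("unassigned")
            consensus.append(None)
            kept_flags.append(False)
        elif len(set(vals)) == 1:
            reasons.append("concordant")
            consensus.append(vals[0])
            kept_flags.append(True)
        else:
            fams = {hmap.family_of(v) for v in vals}
            if len(fams) == 1 and None not in fams:
                reasons.append("exempt_family")
                consensus.append(fams.pop())
                kept_flags.append(True)
            else:
                reasons.append("discordant")
                consensus.append(None)
                kept_flags.append(False)
    report = pd.DataFrame(
        {"kept": kept_flags, "reason": reasons, "consensus_label": consensus},
        index=harmonized.index,
    )
    return harmonized.index[report["kept"]], report


def rank_markers(
    expr: pd.DataFrame,
    labels: pd.Series,
    top_k: int = 20,
    n_hvg: int = 0,
) -> tuple[dict[str, list[str]], list[str]]:
    """Rank marker genes per type by fold change and expressing-fraction gap.

    For every gene and type: log2 fold change of (type mean + 1) over
    (rest mean + 1), and the difference in the fraction of cells with
    non-zero expression.  A gene's final rank within a type is its best rank
    under either heuristic.  Returns ({type: top_k ranked genes}, feature
    list = union of all top markers with the *n_hvg* most variable genes).
    """
    labels = pd.Series(np.asarray(labels), index=expr.columns)
    types = sorted(labels.unique())
    if len(types) < 2:
        raise ValueError("need >= 2 cell types to rank markers")
    x = expr.to_numpy(dtype=float)
    markers: dict[str, list[str]] = {}
    for t in types:
        mask = (labels == t).to_numpy()
        if mask.sum() < 2:
            warnings.warn(f"type {t!r} has < 2 cells; skipped")
            continue
        in_mean = x[:, mask].mean(axis=1)
        out_mean = x[:, ~mask].mean(axis=1)
        # pseudocounted fold change; negative means (scaled data) clip to 0
        lfc = np.log2(np.clip(in_mean, 0, None) + 1) - np.log2(np.clip(out_mean, 0, None) + 1)
        frac_gap = (x[:, mask] > 0).mean(axis=1) - (x[:, ~mask] > 0).mean(axis=1)
        # rank 0 = best; final rank = best of the two heuristics
        r1 = np.empty(len(lfc), dtype=int)
        r1[np.argsort(-lfc, kind="stable")] = np.arange(len(lfc))
        r2 = np.empty(len(frac_gap), dtype=int)
        r2[np.argsort(-frac_gap, kind="stable")] = np.arange(len(frac_gap))
        best = np.minimum(r1, r2)
        order = np.lexsort((np.arange(len(best)), best))
        markers[t] = [expr.index[i] for i in order[:top_k]]
    features = sorted(set().union(*markers.values()))
    if n_hvg > 0:
        var = expr.var(axis=1)
        hvg = var.sort_values(ascending=False).index[:n_hvg]
        features = sorted(set(features) | set(hvg))
    return markers, features


def _minmax_fit(ref: pd.DataFrame) -> tuple[pd.Series, pd.Series]:
    lo = ref.min(axis=1)
    hi = ref.max(axis=1)
    return lo, hi


def _minmax_apply(expr: pd.DataFrame, lo: pd.Series, hi: pd.Series) -> np.ndarray:
    rng = (hi - lo).replace(0, 1.0)
    scaled = expr.sub(lo, axis=0).div(rng, axis=0).clip(0.0, 1.0)
    return scaled.to_numpy(dtype=float).T  # cells x genes


def train_and_score(
    ref_expr: pd.DataFrame,
    ref_labels: pd.Series,
    query_expr: pd.DataFrame,
    cutoff: float = 0.55,
    features: list[str] | None = None,
    classifier=None,
    exclude_genes: list[str] | None = None,
) -> tuple[pd.DataFrame, pd.Series]:
    """Train a probabilistic classifier on a reference; score a query.

    Expression is min-max scaled per gene on the shared feature set (scaling
    fitted on the reference).  The default classifier is a regularized
    multinomial linear model whose normalized-exponential outputs are the
    per-class probabilistic scores; any object with ``fit``/``predict_proba``
    and a ``classes_`` attribute can be plugged in.  A query cell's hard
    label is the argmax class when its score reaches *cutoff*, otherwise
    ``unassigned``.  Genes in *exclude_genes* (e.g. cell-cycle genes) are
    removed before training.
    """
    shared = ref_expr.index.intersection(query_expr.index)
    if features is not None:
        shared = shared.intersection(pd.Index(features))
    if exclude_genes:
        shared = shared.difference(pd.Index(exclude_genes))
    if len(shared) == 0:
        raise ValueError("no shared feature genes between reference and query")
    ref = ref_expr.loc[shared]
    qry = query_expr.loc[shared]
    lo, hi = _minmax_fit(ref)
    x_ref = _minmax_apply(ref, lo, hi)
    x_qry = _minmax_apply(qry, lo, hi)
    clf = classifier if classifier is not None else LogisticRegression(max_iter=2000)
    clf.fit(x_ref, np.asarray(ref_labels))
    proba = clf.predict_proba(x_qry)
    scores = pd.DataFrame(proba, index=query_expr.columns, columns=clf.classes_)
    argmax = scores.idxmax(axis=1)
    top = scores.max(axis=1)
    hard = argmax.where(top >= cutoff, UNASSIGNED)
    hard.name = "label"
    return scores, hard


def cross_similarity(
    profiles: list[pd.DataFrame],
    type_labels: list[pd.Series],
    dataset_names: list[str],
    n_pcs: int = 15,
    k: int = 100,
    power: float = 1.25,
) -> pd.DataFrame:
    """Cross-dataset cell-type similarity from probabilistic score profiles.

    All datasets' score profiles (cells x reference classes, shared columns)
    are concatenated and embedded with PCA (top *n_pcs*).  A k-nearest-
    neighbor graph over the PC space gates comparability: a pair of
    (dataset, type) groups gets the Pearson correlation of their type-mean PC
    profiles only if at least one neighbor edge connects cells of the two
    groups across datasets (within-dataset pairs are gated by any edge);
    ungated pairs are floored to the matrix minimum.  The matrix is then
    transformed elementwise by the sign-preserving power |s|^power * sign(s)
    and each column is z-scored to mean 0, SD 1.

    Rows/columns are indexed ``dataset|type``.
    """
    if len(profiles) < 2:
        raise ValueError("need score profiles from >= 2 datasets")
    cols = profiles[0].columns
    blocks, groups = [], []
    for prof, lab, name in zip(profiles, type_labels, dataset_names):
        if not prof.columns.equals(cols):
            raise ValueError("all score profiles must share the same reference classes")
        blocks.append(prof.to_numpy(dtype=float))
        groups.extend(f"{name}|{t}" for t in np.asarray(lab))
    x = np.vstack(blocks)
    groups = np.asarray(groups)
    n_cells = x.shape[0]
    if k >= n_cells:
        raise ValueError(f"k={k} must be smaller than the {n_cells} pooled cells")
    n_pcs = min(n_pcs, x.shape[1], n_cells)
    pcs = PCA(n_components=n_pcs, random_state=0).fit_transform(x)

    nn = NearestNeighbors(n_neighbors=k + 1).fit(pcs)
    _, ind = nn.kneighbors(pcs)
    ind = ind[:, 1:]

    names = sorted(set(groups))
    gidx = {g: i for i, g in enumerate(names)}
    connected = np.zeros((len(names), len(names)), dtype=bool)
    src = np.repeat(np.arange(n_cells), k)
    dst = ind.ravel()
    gi = np.fromiter((gidx[g] for g in groups[src]), int, len(src))
    gj = np.fromiter((gidx[g] for g in groups[dst]), int, len(dst))
    connected[gi, gj] = True
    connected |= connected.T
    np.fill_diagonal(connected, True)

    means = np.vstack([pcs[groups == g].mean(axis=0) for g in names])
    corr = np.corrcoef(means)
    # ungated pairs are floored to the most-dissimilar value observed anywhere
    sim = np.where(connected, corr, corr.min())

    sim = np.sign(sim) * np.abs(sim) ** power
    mu = sim.mean(axis=0, keepdims=True)
    sd = sim.std(axis=0, ddof=0, keepdims=True)
    if (sd == 0).any():
        warnings.warn("constant similarity column(s); left at 0 after centering")
        sd = np.where(sd == 0, 1.0, sd)
    sim = (sim - mu) / sd
    return pd.DataFrame(sim, index=names, columns=names)
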