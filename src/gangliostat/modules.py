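"""Co-expression module architecture metrics.

Post-processing of a WGCNA-style kME table (gene x module eigengene
correlations) and of module eigengenes computed on an expression matrix:

* redundant gene-to-module assignment — each gene joins its best-correlated
  module plus every module within 95% of that best correlation, subject to a
  floor of 0.3;
* eigengene summaries per cluster and per dataset, the module *magnitude*
  (max minus min of per-cluster eigengene means) and *relative magnitude*
  (magnitude divided by the mean per-group eigengene SD);
* module selection by cluster-driven (vs dataset/batch-driven) variation;
* digitization of per-cluster eigengene means into levels {0, 0.5, 1} by
  thirds of the min-max range, with derived *signal width* (sum of levels)
  and *uniqueness* (w_max minus width);
* bar decomposition of cluster identity (assigned gene count x level);
* per-cell gene-set scores with expression-bin-matched control genes;
* regulator dot scores (scaled TF expression x scaled region-set score).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._rng import substream

__all__ = [
    "assign_genes",
    "compute_eigengene",
    "summarize_and_magnitude",
    "select_modules",
    "digitize",
    "width_uniqueness",
    "bar_decomposition",
    "module_score",
    "eregulon_dot",
    "EigengeneSummary",
]


def assign_genes(kme: pd.DataFrame, r_min: float = 0.3, frac: float = 0.95) -> pd.DataFrame:
    """Redundant gene-to-module assignment from a kME table.

    A gene with row maximum R_max < *r_min* stays unassigned.  Otherwise it is
    assigned to its argmax module and to every module m with
    kME(g, m) >= frac * R_max (and >= r_min).  The comparison is closed (>=)
    so the argmax always satisfies its own rule and exact-boundary ties are
    included.

    Returns a frame indexed by gene with columns ``modules`` (tuple of module
    names, possibly empty, in kME-descending order) and ``r_max``.
    """
    if kme.empty:
        raise ValueError("empty kME table")
    vals = kme.to_numpy(dtype=float)
    if not np.isfinite(vals).all():
        raise ValueError("kME table contains non-finite values")
    cols = np.asarray(kme.columns)
    r_max = vals.max(axis=1)
    records = []
    for g in range(vals.shape[0]):
        if r_max[g] < r_min:
            records.append(())
            continue
        ok = (vals[g] >= frac * r_max[g]) & (vals[g] >= r_min)
        order = np.argsort(-vals[g], kind="stable")
        records.append(tuple(cols[i] for i in order if ok[i]))
    return pd.DataFrame({"modules": records, "r_max": r_max}, index=kme.index)


def assignment_counts(assignment: pd.DataFrame) -> pd.Series:
    """Number of genes assigned to each module (redundant counts)."""
    counts: dict[str, int] = {}
    for mods in assignment["modules"]:
        for m in mods:
            counts[m] = counts.get(m, 0) + 1
    return pd.Series(counts, dtype=int).sort_index()


def compute_eigengene(expr: pd.DataFrame, module_genes: list[str]) -> pd.Series:
    """Module eigengene: first principal component of the module's genes.

    *expr* is genes x cells.  Member genes are standardized across cells, the
    leading left singular direction gives a per-cell score, which is scaled to
    unit variance and sign-fixed so that its correlation with the module mean
    expression profile is non-negative.
    """
    present = [g for g in module_genes if g in expr.index]
    if not present:
        raise ValueError("no module gene present in the expression matrix")
    sub = expr.loc[present].to_numpy(dtype=float)
    mu = sub.mean(axis=1, keepdims=True)
    sd = sub.std(axis=1, ddof=0, keepdims=True)
    zero_var = sd[:, 0] == 0
    if zero_var.any():
        offenders = [present[i] for i in np.flatnonzero(zero_var)]
        raise ValueError(f"zero-variance module gene(s): {offenders}")
    z = (sub - mu) / sd
    # leading right singular vector of the gene x cell z-matrix = per-cell PC1
    _, _, vt = np.linalg.svd(z, full_matrices=False)
    pc = vt[0]
    pc = pc / pc.std(ddof=0)
    mean_profile = sub.mean(axis=0)
    if np.std(mean_profile) > 0 and np.corrcoef(pc, mean_profile)[0, 1] < 0:
        pc = -pc
    return pd.Series(pc, index=expr.columns, name="eigengene")


def kme_table(expr: pd.DataFrame, module_genes: dict[str, list[str]]) -> pd.DataFrame:
    """Pearson correlation of every gene with every module eigengene."""
    eig = {m: compute_eigengene(expr, genes) for m, genes in module_genes.items()}
    x = expr.to_numpy(dtype=float)
    xc = x - x.mean(axis=1, keepdims=True)
    xs = xc.std(axis=1, ddof=0)
    out = {}
    for m, e in eig.items():
        ev = e.to_numpy()
        ec = ev - ev.mean()
        denom = xs * ec.std(ddof=0) * x.shape[1]
        with np.errstate(invalid="ignore", divide="ignore"):
            out[m] = np.where(denom > 0, (xc @ ec) / denom, 0.0)
    return pd.DataFrame(out, index=expr.index)


@dataclass
class EigengeneSummary:
    """Per-module eigengene group summaries and magnitude statistics.

    ``magnitude`` is max - min of the per-cluster eigengene means; the
    *relative* magnitudes divide by the mean of the per-group SDs (groups
    with a single cell have no SD and are excluded from that mean).
    A zero mean SD leaves the relative magnitude undefined (NaN, flagged).
    """

    module: str
    cluster_means: pd.Series
    cluster_sds: pd.Series
    dataset_means: pd.Series
    dataset_sds: pd.Series
    magnitude: float = field(init=False)
    relative_magnitude_clusters: float = field(init=False)
    dataset_magnitude: float = field(init=False)
    relative_magnitude_datasets: float = field(init=False)

    def __post_init__(self) -> None:
        self.magnitude = float(self.cluster_means.max() - self.cluster_means.min())
        self.dataset_magnitude = float(self.dataset_means.max() - self.dataset_means.min())
        self.relative_magnitude_clusters = _relative(self.magnitude, self.cluster_sds)
        self.relative_magnitude_datasets = _relative(self.dataset_magnitude, self.dataset_sds)


def _relative(magnitude: float, sds: pd.Series) -> float:
    valid = sds.dropna()
    if len(valid) < len(sds):
        warnings.warn("group(s) with a single cell: SD missing, excluded from the SD mean")
    mean_sd = valid.mean()
    if not np.isfinite(mean_sd) or mean_sd == 0:
        if magnitude == 0:
            return 0.0
        warnings.warn("mean group SD is 0; relative magnitude undefined")
        return float("nan")
    return float(magnitude / mean_sd)


def summarize_and_magnitude(
    eigengene: pd.Series,
    clusters: pd.Series | np.ndarray,
    datasets: pd.Series | np.ndarray,
    module: str = "module",
) -> EigengeneSummary:
    """Group the eigengene by cluster and by dataset; derive magnitudes."""
    df = pd.DataFrame({
        "e": np.asarray(eigengene, dtype=float),
        "cluster": np.asarray(clusters),
        "dataset": np.asarray(datasets),
    })
    cm = df.groupby("cluster")["e"].mean()
    cs = df.groupby("cluster")["e"].std(ddof=1)
    dm = df.groupby("dataset")["e"].mean()
    ds = df.groupby("dataset")["e"].std(ddof=1)
    return EigengeneSummary(module, cm, cs, dm, ds)


def select_modules(
    summaries: list[EigengeneSummary], cluster_rm_min: float = 3.7
) -> pd.DataFrame:
    """Keep modules whose variation is cluster-driven, not dataset-driven.

    A module is kept iff its relative magnitude across clusters is
    >= *cluster_rm_min* AND exceeds its relative magnitude across datasets.
    Both criteria are reported per module so users can re-filter.
    """
    rows = []
    for s in summaries:
        rm_c = s.relative_magnitude_clusters
        rm_d = s.relative_magnitude_datasets
        passes_rm = bool(np.isfinite(rm_c) and rm_c >= cluster_rm_min)
        cluster_dominant = bool(np.isfinite(rm_c) and (not np.isfinite(rm_d) or rm_c > rm_d))
        rows.append({
            "module": s.module,
            "relative_magnitude_clusters": rm_c,
            "relative_magnitude_datasets": rm_d,
            "passes_rm_threshold": passes_rm,
            "cluster_dominant": cluster_dominant,
            "kept": passes_rm and cluster_dominant,
        })
    return pd.DataFrame(rows).set_index("module")


def digitize(summary: EigengeneSummary, tol: float = 1e-9) -> pd.Series:
    """Digitize per-cluster eigengene means into levels {0, 0.5, 1}.

    Each cluster mean is placed on the min-max range of the module:
    p_c = (mean_c - min) / magnitude.  Level 0 below 1/3, 0.5 in the closed
    middle third [1/3, 2/3], 1 above 2/3.  A magnitude below *tol* is
    degenerate: every level is 0 (flagged via the series ``.attrs``).
    """
    means = summary.cluster_means
    if summary.magnitude < tol:
        out = pd.Series(0.0, index=means.index, name=summary.module)
        out.attrs["degenerate"] = True
        return out
    p = (means - means.min()) / summary.magnitude
    levels = pd.Series(np.where(p < 1 / 3, 0.0, np.where(p <= 2 / 3, 0.5, 1.0)),
                       index=means.index, name=summary.module)
    levels.attrs["degenerate"] = False
    return levels


def width_uniqueness(profile: pd.DataFrame, w_max: float | None = None) -> pd.DataFrame:
    """Signal width and uniqueness per module.

    *profile* is modules x clusters with levels in {0, 0.5, 1}.  Width is the
    row sum of levels (how many clusters the module is active in, half-active
    counting one half); uniqueness = w_max - width.  w_max defaults to the
    observed maximum width; pass a constant (e.g. 10) to pin the scale.
    """
    bad = ~profile.isin([0.0, 0.5, 1.0]).to_numpy()
    if bad.any():
        raise ValueError("digitized profile may only contain levels 0, 0.5, 1")
    width = profile.sum(axis=1)
    if w_max is None:
        w_max = float(width.max())
    return pd.DataFrame({"signal_width": width, "uniqueness": w_max - width})


def bar_decomposition(assignment: pd.DataFrame, profile: pd.DataFrame) -> pd.DataFrame:
    """Identity bar segments: assigned gene count times digitized level.

    Returns a long frame (cluster, module, segment) where
    segment = |genes assigned to module| * level(module, cluster); level-0
    segments are omitted (the module does not appear in that cluster's bar).
    The per-cluster total of segments counts the cluster's "efficient genes".
    """
    counts = assignment_counts(assignment)
    prof_mods = set(profile.index)
    cnt_mods = set(counts.index)
    if prof_mods != cnt_mods:
        raise ValueError(
            f"module sets differ between assignment and profile: "
            f"only-in-assignment={sorted(cnt_mods - prof_mods)}, "
            f"only-in-profile={sorted(prof_mods - cnt_mods)}"
        )
    rows = []
    for cluster in profile.columns:
        for module in profile.index:
            level = profile.loc[module, cluster]
            if level == 0:
                continue
            rows.append({
                "cluster": cluster,
                "module": module,
                "level": level,
                "n_genes": int(counts[module]),
                "segment": counts[module] * level,
            })
    return pd.DataFrame(rows, columns=["cluster", "module", "level", "n_genes", "segment"])


def module_score(
    expr: pd.DataFrame,
    gene_set: list[str],
    n_bins: int = 24,
    n_ctrl: int = 100,
    seed: int = 0,
) -> pd.Series:
    """Per-cell gene-set score against expression-bin-matched controls.

    All genes are binned into *n_bins* bins of average expression; for each
    set gene, *n_ctrl* control genes are drawn with replacement from its bin.
    score(cell) = mean expression of the set genes - mean expression of the
    pooled control draw.  Deterministic given *seed*.
    """
    present = [g for g in gene_set if g in expr.index]
    if not present:
        raise ValueError("no gene of the set is present in the expression matrix")
    if n_bins > expr.shape[0]:
        raise ValueError(f"n_bins={n_bins} exceeds the {expr.shape[0]} genes available")
    rng = substream(seed, "module_score")
    avg = expr.mean(axis=1)
    # rank-based cut => near-equal occupancy even with tied averages
    ranks = avg.rank(method="first")
    bins = pd.cut(ranks, bins=n_bins, labels=False)
    bin_members = {b: expr.index[bins == b].to_numpy() for b in range(n_bins)}
    ctrl_genes: list[str] = []
    for g in sorted(present):
        pool = bin_members[int(bins[g])]
        ctrl_genes.extend(rng.choice(pool, size=n_ctrl, replace=True))
    set_mean = expr.loc[present].mean(axis=0)
    ctrl_mean = expr.loc[ctrl_genes].mean(axis=0)
    out = set_mean - ctrl_mean
    out.name = "module_score"
    return out


def _minmax(v: pd.Series, name: str) -> pd.Series:
    lo, hi = v.min(), v.max()
    if hi == lo:
        warnings.warn(f"{name} is constant across types; scaled to all zeros")
        return pd.Series(0.0, index=v.index)
    return (v - lo) / (hi - lo)


def eregulon_dot(
    tf_stat: pd.Series, region_score: pd.Series, gene_score: pd.Series
) -> pd.DataFrame:
    """Dot-plot scores for one regulator across cell types.

    Each input vector (TF expression statistic, region-set accessibility
    score, target-gene-set score; one value per cell type) is min-max scaled
    to [0, 1] across types.  Dot size = scaled TF stat x scaled region score;
    dot color = scaled gene score.
    """
    idx = tf_stat.index
    if len(idx) < 2:
        raise ValueError("need >= 2 cell types")
    if not (idx.equals(region_score.index) and idx.equals(gene_score.index)):
        raise ValueError("tf_stat, region_score and gene_score must share one type index")
    tf = _minmax(tf_stat.astype(float), "tf_stat")
    rg = _minmax(region_score.astype(float), "region_score")
    gn = _minmax(gene_score.astype(float), "gene_score")
    return pd.DataFrame({"size": tf * rg, "color": gn}, index=idx)
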