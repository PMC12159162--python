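"""Module x regulon gene-set overlap enrichment.

Overlap counts between two gene-set collections over a declared universe,
one-sided Fisher exact (hypergeometric tail) p-values for enrichment,
Benjamini-Hochberg adjustment across the whole grid, and the per-module
"any significant overlap" summary.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

__all__ = [
    "GeneSetCollection",
    "overlap_counts",
    "fisher_enrichment",
    "adjust_and_summarize",
    "enrichment_grid",
]


@dataclass
class GeneSetCollection:
    """Named gene sets over a declared universe."""

    sets: dict[str, set[str]]
    universe: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        if not self.universe:
            self.universe = set().union(*self.sets.values()) if self.sets else set()
        for name, members in self.sets.items():
            extra = members - self.universe
            if extra:
                raise ValueError(
                    f"set {name!r} has member(s) outside the universe: {sorted(extra)[:5]}"
                )

    def restrict(self, universe: set[str]) -> "GeneSetCollection":
        return GeneSetCollection(
            {n: s & universe for n, s in self.sets.items()}, set(universe)
        )


def overlap_counts(
    modules: GeneSetCollection,
    regulons: GeneSetCollection,
    universe: set[str] | None = None,
    on_outside: str = "error",
) -> pd.DataFrame:
    """|module ∩ regulon| count matrix after restriction to the universe.

    The default universe is the union of all module and all regulon genes.
    Genes outside an explicit universe raise (``on_outside='error'``) or are
    dropped with a warning (``'drop'``).
    """
    if universe is None:
        universe = modules.universe | regulons.universe
    else:
        universe = set(universe)
        outside_members = set().union(*modules.sets.values(), *regulons.sets.values()) - universe
        if outside_members:
            if on_outside == "error":
                raise ValueError(
                    f"gene(s) outside the declared universe: {sorted(outside_members)[:10]}"
                )
            warnings.warn(f"dropping {len(outside_members)} gene(s) outside the universe")
    mod = {n: s & universe for n, s in modules.sets.items()}
    reg = {n: s & universe for n, s in regulons.sets.items()}
    out = pd.DataFrame(
        {rn: {mn: len(ms & rs) for mn, ms in mod.items()} for rn, rs in reg.items()},
        dtype=int,
    ).reindex(index=list(mod), columns=list(reg))
    out.attrs["universe_size"] = len(universe)
    out.attrs["module_sizes"] = {n: len(s) for n, s in mod.items()}
    out.attrs["regulon_sizes"] = {n: len(s) for n, s in reg.items()}
    return out


def fisher_enrichment(
    counts: pd.DataFrame,
    module_sizes: dict[str, int],
    regulon_sizes: dict[str, int],
    universe_size: int,
    alternative: str = "greater",
) -> pd.DataFrame:
    """One-sided Fisher exact p-values for over-representation.

    For observed overlap k with module size K, regulon size n and universe
    size N: p = P(X >= k), X ~ Hypergeometric(N, K, n).  An overlap of 0
    therefore gives p = 1 exactly.  ``alternative='two-sided'`` uses the
    two-sided Fisher exact test instead.
    """
    p = pd.DataFrame(np.nan, index=counts.index, columns=counts.columns)
    for mn in counts.index:
        K = module_sizes[mn]
        for rn in counts.columns:
            n = regulon_sizes[rn]
            k = int(counts.loc[mn, rn])
            if k > min(K, n) or K > universe_size or n > universe_size:
                raise ValueError(
                    f"inconsistent table for ({mn}, {rn}): overlap {k}, sizes {K}/{n}, N={universe_size}"
                )
            if alternative == "greater":
                p.loc[mn, rn] = hypergeom.sf(k - 1, universe_size, K, n)
            else:
                from scipy.stats import fisher_exact

                table = [[k, K - k], [n - k, universe_size - K - n + k]]
                p.loc[mn, rn] = fisher_exact(table, alternative="two-sided")[1]
    return p


def adjust_and_summarize(
    p: pd.DataFrame, method: str = "fdr_bh", alpha: float = 0.05
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Benjamini-Hochberg adjustment across all grid cells jointly.

    Returns (adjusted p matrix, per-module summary).  The summary flags for
    every module whether it has at least one adjusted p <= alpha; modules
    without any significant overlap are the grayed-out rows of the overlap
    heatmap.
    """
    flat = p.to_numpy(dtype=float).ravel()
    if np.any((flat <= 0) | (flat > 1) | ~np.isfinite(flat)):
        raise ValueError("p-values must lie in (0, 1]")
    adj = multipletests(flat, method=method)[1].reshape(p.shape)
    adj = pd.DataFrame(adj, index=p.index, columns=p.columns)
    sig = adj <= alpha
    summary = pd.DataFrame({
        "n_significant": sig.sum(axis=1).astype(int),
        "any_significant": sig.any(axis=1),
    })
    return adj, summary


def enrichment_grid(
    modules: GeneSetCollection,
    regulons: GeneSetCollection,
    universe: set[str] | None = None,
    alpha: float = 0.05,
    alternative: str = "greater",
) -> pd.DataFrame:
    """Long-format overlap grid: counts, sizes, p, adjusted p, log10(adj p)."""
    counts = overlap_counts(modules, regulons, universe)
    N = counts.attrs["universe_size"]
    msz, rsz = counts.attrs["module_sizes"], counts.attrs["regulon_sizes"]
    p = fisher_enrichment(counts, msz, rsz, N, alternative=alternative)
    adj, _ = adjust_and_summarize(p, alpha=alpha)
    rows = []
    for mn in counts.index:
        for rn in counts.columns:
            rows.append({
                "module": mn,
                "regulon": rn,
                "overlap": int(counts.loc[mn, rn]),
                "module_size": msz[mn],
                "regulon_size": rsz[rn],
                "universe_size": N,
                "p": p.loc[mn, rn],
                "p_adj": adj.loc[mn, rn],
                "log10_p_adj": np.log10(adj.loc[mn, rn]),
                "significant": bool(adj.loc[mn, rn] <= alpha),
            })
    return pd.DataFrame(rows)
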