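"""kME assignment, eigengene magnitudes, digitization, scores."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from gangliostat.modules import (
    assign_genes,
    bar_decomposition,
    compute_eigengene,
    digitize,
    eregulon_dot,
    module_score,
    select_modules,
    summarize_and_magnitude,
    width_uniqueness,
)
from gangliostat.synthetic import ExpressionConfig, ModuleSpec, simulate_expression


def brute_force_assign(kme: pd.DataFrame, r_min=0.3, frac=0.95) -> dict[str, set[str]]:
    """Independent two-pass re-implementation of the redundant assignment."""
    out = {}
    for g in kme.index:
        row = kme.loc[g]
        best = row.max()
        if best < r_min:
            out[g] = set()
            continue
        members = {row.idxmax()}
        for m in kme.columns:
            if row[m] >= frac * best and row[m] >= r_min:
                members.add(m)
        out[g] = members
    return out


class TestAssignGenes:
    def test_worked_example(self):
        kme = pd.DataFrame([[0.8, 0.77, 0.5]], index=["g"], columns=["M1", "M2", "M3"])
        got = assign_genes(kme)
        assert set(got.loc["g", "modules"]) == {"M1", "M2"}  # 0.77 >= 0.76, 0.5 < 0.76
        assert got.loc["g", "r_max"] == 0.8

    def test_floor_threshold(self):
        kme = pd.DataFrame([[0.29, 0.2, 0.1]], index=["g"], columns=["A", "B", "C"])
        assert assign_genes(kme).loc["g", "modules"] == ()

    def test_matches_brute_force(self):
        rng = np.random.default_rng(3)
        kme = pd.DataFrame(
            rng.uniform(-1, 1, (500, 10)),
            index=[f"g{i}" for i in range(500)],
            columns=[f"M{j}" for j in range(10)],
        )
        got = assign_genes(kme)
        want = brute_force_assign(kme)
        for g in kme.index:
            assert set(got.loc[g, "modules"]) == want[g]

    def test_column_order_invariance_and_argmax_membership(self):
        rng = np.random.default_rng(4)
        kme = pd.DataFrame(rng.uniform(0, 1, (50, 5)),
                           index=[f"g{i}" for i in range(50)],
                           columns=list("ABCDE"))
        a1 = assign_genes(kme)
        a2 = assign_genes(kme[list("EDCBA")])
        for g in kme.index:
            assert set(a1.loc[g, "modules"]) == set(a2.loc[g, "modules"])
            if a1.loc[g, "modules"]:
                assert kme.loc[g].idxmax() in a1.loc[g, "modules"]

    def test_empty_table_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            assign_genes(pd.DataFrame())


class TestComputeEigengene:
    def test_single_gene_module(self):
        rng = np.random.default_rng(5)
        expr = pd.DataFrame(rng.normal(0, 1, (3, 40)),
                            index=["a", "b", "c"],
                            columns=[f"c{i}" for i in range(40)])
        eig = compute_eigengene(expr, ["a"])
        z = (expr.loc["a"] - expr.loc["a"].mean()) / expr.loc["a"].std(ddof=0)
        assert abs(np.corrcoef(eig, z)[0, 1]) > 1 - 1e-12

    def test_perfectly_correlated_pair(self):
        base = np.linspace(0, 1, 30)
        expr = pd.DataFrame([base, 2 * base + 1],
                            index=["a", "b"], columns=[f"c{i}" for i in range(30)])
        eig = compute_eigengene(expr, ["a", "b"])
        assert np.corrcoef(eig, base)[0, 1] == pytest.approx(1.0, abs=1e-12)

    def test_unit_variance_and_sign_convention(self):
        rng = np.random.default_rng(6)
        signal = rng.normal(0, 1, 60)
        expr = pd.DataFrame(signal + rng.normal(0, 0.3, (8, 60)),
                            index=[f"g{i}" for i in range(8)],
                            columns=[f"c{i}" for i in range(60)])
        eig = compute_eigengene(expr, list(expr.index))
        assert eig.std(ddof=0) == pytest.approx(1.0, abs=1e-9)
        assert np.corrcoef(eig, expr.mean(axis=0))[0, 1] >= 0

    def test_zero_variance_gene_reported(self):
        expr = pd.DataFrame([[1.0, 1.0, 1.0], [0.0, 1.0, 2.0]],
                            index=["flat", "ok"], columns=list("xyz"))
        with pytest.raises(ValueError, match="flat"):
            compute_eigengene(expr, ["flat", "ok"])


class TestSummaryAndSelection:
    def _summary(self, values, clusters, datasets):
        return summarize_and_magnitude(pd.Series(values), clusters, datasets)

    def test_magnitude_formula(self):
        # three clusters with means 0, 1, 2 and common SD 0.5
        rng = np.random.default_rng(0)
        vals, clus = [], []
        for c, mu in enumerate([0.0, 1.0, 2.0]):
            draws = rng.normal(0, 1, 200)
            draws = (draws - draws.mean()) / draws.std(ddof=1) * 0.5 + mu
            vals.extend(draws)
            clus.extend([f"K{c}"] * 200)
        s = self._summary(vals, clus, ["D0"] * len(vals))
        assert s.magnitude == pytest.approx(2.0, abs=1e-12)
        assert s.relative_magnitude_clusters == pytest.approx(4.0, abs=1e-9)

    def test_constant_eigengene(self):
        s = self._summary([1.0] * 9, ["a", "b", "c"] * 3, ["d"] * 9)
        assert s.magnitude == 0.0
        assert s.relative_magnitude_clusters == 0.0

    def test_matches_groupby_oracle(self):
        rng = np.random.default_rng(7)
        vals = rng.normal(0, 1, 120)
        clus = rng.choice(["K0", "K1", "K2"], 120)
        ds = rng.choice(["D0", "D1"], 120)
        s = self._summary(vals, clus, ds)
        for k in ["K0", "K1", "K2"]:
            sel = vals[clus == k]
            assert s.cluster_means[k] == pytest.approx(sel.mean(), abs=1e-12)
            assert s.cluster_sds[k] == pytest.approx(sel.std(ddof=1), abs=1e-12)
        want_mag = max(s.cluster_means) - min(s.cluster_means)
        assert s.magnitude == pytest.approx(want_mag, abs=1e-12)
        assert s.relative_magnitude_clusters == pytest.approx(
            want_mag / s.cluster_sds.mean(), abs=1e-9)

    def test_singleton_group_warns(self):
        with pytest.warns(UserWarning, match="single cell"):
            self._summary([0.0, 1.0, 2.0], ["a", "a", "b"], ["d"] * 3)

    def test_selection_rules(self):
        rng = np.random.default_rng(8)
        vals = rng.normal(0, 1, 60)
        s_keep = self._summary(vals, ["a", "b"] * 30, ["d", "e"] * 30)
        s_keep.relative_magnitude_clusters = 5.0
        s_keep.relative_magnitude_datasets = 1.0
        s_keep.module = "keep"
        s_low = self._summary(vals, ["a", "b"] * 30, ["d", "e"] * 30)
        s_low.relative_magnitude_clusters = 2.0
        s_low.relative_magnitude_datasets = 0.1
        s_low.module = "low"
        s_batch = self._summary(vals, ["a", "b"] * 30, ["d", "e"] * 30)
        s_batch.relative_magnitude_clusters = 4.0
        s_batch.relative_magnitude_datasets = 8.0
        s_batch.module = "batch"
        sel = select_modules([s_keep, s_low, s_batch])
        assert sel.loc["keep", "kept"]
        assert not sel.loc["low", "kept"]      # below the 3.7 threshold
        assert not sel.loc["batch", "kept"]    # dataset-dominated


class TestDigitize:
    def _summary_with_means(self, means):
        rng = np.random.default_rng(1)
        vals, clus = [], []
        for c, mu in enumerate(means):
            vals.extend(rng.normal(mu, 0.01, 30))
            clus.extend([f"K{c}"] * 30)
        return summarize_and_magnitude(pd.Series(vals), clus, ["D0"] * len(vals))

    def test_levels_for_spread_means(self):
        s = self._summary_with_means([0.0, 1.0, 2.0])
        lv = digitize(s)
        assert lv.tolist() == [0.0, 0.5, 1.0]

    def test_boundary_one_third_is_half(self):
        s = self._summary_with_means([0.0, 3.0])
        s.cluster_means = pd.Series({"K0": 0.0, "K1": 1.0, "K2": 3.0})
        s.magnitude = 3.0
        lv = digitize(s)
        assert lv["K1"] == 0.5  # exactly 1/3 of the range: closed middle bin

    def test_degenerate_magnitude_flags_all_zero(self):
        s = self._summary_with_means([0.0, 1.0])
        s.cluster_means = pd.Series({"K0": 1.0, "K1": 1.0})
        s.magnitude = 0.0
        lv = digitize(s)
        assert (lv == 0).all() and lv.attrs["degenerate"]

    @given(st.floats(0.1, 10.0), st.floats(-5.0, 5.0))
    def test_affine_invariance(self, a, b):
        s = self._summary_with_means([0.0, 0.4, 1.0])
        lv = digitize(s)
        s.cluster_means = a * s.cluster_means + b
        s.magnitude = a * s.magnitude
        assert digitize(s).tolist() == lv.tolist()


class TestWidthUniqueness:
    def test_width_sum(self):
        prof = pd.DataFrame([[1.0, 0.5, 0.0, 0.0]], index=["M"],
                            columns=["K0", "K1", "K2", "K3"])
        wu = width_uniqueness(prof)
        assert wu.loc["M", "signal_width"] == 1.5

    def test_fixed_wmax_convention(self):
        prof = pd.DataFrame([[1.0, 0.5, 0.0, 0.0]], index=["M"],
                            columns=["K0", "K1", "K2", "K3"])
        wu = width_uniqueness(prof, w_max=10.0)
        assert wu.loc["M", "uniqueness"] == 8.5

    def test_all_zero_module(self):
        prof = pd.DataFrame([[0.0] * 4, [1.0, 1.0, 0.0, 0.0]],
                            index=["Z", "M"], columns=["K0", "K1", "K2", "K3"])
        wu = width_uniqueness(prof)
        assert wu.loc["Z", "signal_width"] == 0.0
        assert wu.loc["Z", "uniqueness"] == 2.0  # observed max width

    def test_width_monotone_uniqueness_antimonotone(self):
        prof = pd.DataFrame([[1.0, 0.5, 1.0]], index=["M"], columns=["a", "b", "c"])
        lower = prof.copy()
        lower.loc["M", "c"] = 0.5
        w0 = width_uniqueness(prof, w_max=10.0)
        w1 = width_uniqueness(lower, w_max=10.0)
        assert w1.loc["M", "signal_width"] < w0.loc["M", "signal_width"]
        assert w1.loc["M", "uniqueness"] > w0.loc["M", "uniqueness"]

    def test_invalid_levels_rejected(self):
        prof = pd.DataFrame([[0.7]], index=["M"], columns=["K0"])
        with pytest.raises(ValueError, match="levels"):
            width_uniqueness(prof)


class TestBarDecomposition:
    def _assignment(self, counts: dict[str, int]) -> pd.DataFrame:
        rows, genes = [], []
        for m, n in counts.items():
            for i in range(n):
                genes.append(f"{m}_g{i}")
                rows.append({"modules": (m,), "r_max": 0.9})
        return pd.DataFrame(rows, index=genes)

    def test_segment_value(self):
        assignment = self._assignment({"M": 40})
        prof = pd.DataFrame([[0.5]], index=["M"], columns=["K0"])
        bars = bar_decomposition(assignment, prof)
        assert bars.loc[0, "segment"] == 20.0

    def test_level_zero_omitted(self):
        assignment = self._assignment({"M": 10})
        prof = pd.DataFrame([[0.0]], index=["M"], columns=["K0"])
        assert bar_decomposition(assignment, prof).empty

    def test_module_mismatch_rejected(self):
        assignment = self._assignment({"M": 5})
        prof = pd.DataFrame([[1.0]], index=["OTHER"], columns=["K0"])
        with pytest.raises(ValueError, match="differ"):
            bar_decomposition(assignment, prof)

    def test_matches_product_oracle(self):
        rng = np.random.default_rng(9)
        counts = {f"M{i}": int(rng.integers(1, 30)) for i in range(5)}
        assignment = self._assignment(counts)
        prof = pd.DataFrame(
            rng.choice([0.0, 0.5, 1.0], (5, 4)),
            index=list(counts), columns=[f"K{j}" for j in range(4)],
        )
        bars = bar_decomposition(assignment, prof)
        for _, r in bars.iterrows():
            assert r["segment"] == counts[r["module"]] * prof.loc[r["module"], r["cluster"]]
        # per-cluster totals equal the oracle sum over modules
        for k in prof.columns:
            want = sum(counts[m] * prof.loc[m, k] for m in counts)
            got = bars[bars.cluster == k]["segment"].sum()
            assert got == want


class TestModuleScore:
    def test_constant_matrix_scores_zero(self):
        expr = pd.DataFrame(3.14, index=[f"g{i}" for i in range(60)],
                            columns=[f"c{i}" for i in range(10)])
        s = module_score(expr, ["g0", "g1"], n_bins=6, seed=0)
        assert np.abs(s).max() == pytest.approx(0.0, abs=1e-12)

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(10)
        expr = pd.DataFrame(rng.lognormal(0, 1, (80, 20)),
                            index=[f"g{i}" for i in range(80)],
                            columns=[f"c{i}" for i in range(20)])
        s1 = module_score(expr, ["g3", "g5", "g7"], n_bins=8, seed=42)
        s2 = module_score(expr, ["g3", "g5", "g7"], n_bins=8, seed=42)
        pd.testing.assert_series_equal(s1, s2)
        s3 = module_score(expr, ["g3", "g5", "g7"], n_bins=8, seed=43)
        assert not np.allclose(s1, s3)

    def test_planted_module_peaks_in_active_cluster(self):
        hits = 0
        for seed in range(5):
            cfg = ExpressionConfig(
                n_genes=150, n_cells=200, n_clusters=4, n_datasets=1,
                modules=[ModuleSpec(20, [1.0, 0.0, 0.0, 0.0])], noise_sd=0.3)
            expr, ann, _, truth = simulate_expression(cfg, seed=seed)
            s = module_score(expr, truth["module_genes"]["M0"], n_bins=10, seed=seed)
            by_cluster = s.groupby(ann["cluster"]).mean()
            hits += by_cluster.idxmax() == "K0"
        assert hits == 5

    def test_absent_set_rejected(self):
        expr = pd.DataFrame(np.ones((30, 3)), index=[f"g{i}" for i in range(30)],
                            columns=list("abc"))
        with pytest.raises(ValueError, match="present"):
            module_score(expr, ["nope"], n_bins=5)


class TestEregulonDot:
    def _vectors(self):
        idx = ["NP1", "PEP1", "LTMR"]
        return (pd.Series([0.1, 0.9, 0.5], index=idx),
                pd.Series([2.0, 8.0, 5.0], index=idx),
                pd.Series([0.0, 1.0, 0.3], index=idx))

    def test_max_everywhere_scores_one(self):
        tf, rg, gn = self._vectors()
        dot = eregulon_dot(tf, rg, gn)
        assert dot.loc["PEP1", "size"] == 1.0

    def test_min_tf_kills_size(self):
        tf, rg, gn = self._vectors()
        dot = eregulon_dot(tf, rg, gn)
        assert dot.loc["NP1", "size"] == 0.0

    def test_matches_elementwise_oracle(self):
        rng = np.random.default_rng(11)
        idx = [f"t{i}" for i in range(7)]
        tf = pd.Series(rng.uniform(0, 5, 7), index=idx)
        rg = pd.Series(rng.uniform(0, 5, 7), index=idx)
        gn = pd.Series(rng.uniform(0, 5, 7), index=idx)
        dot = eregulon_dot(tf, rg, gn)
        mm = lambda v: (v - v.min()) / (v.max() - v.min())
        assert np.abs(dot["size"] - mm(tf) * mm(rg)).max() < 1e-12
        assert np.abs(dot["color"] - mm(gn)).max() < 1e-12

    def test_constant_vector_warns_and_zeroes(self):
        idx = ["a", "b"]
        with pytest.warns(UserWarning, match="constant"):
            dot = eregulon_dot(pd.Series([1.0, 1.0], index=idx),
                               pd.Series([0.0, 1.0], index=idx),
                               pd.Series([0.0, 1.0], index=idx))
        assert (dot["size"] == 0.0).all()
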