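"""Normalization, dispersion, NB Wald test, BH adjustment and DEG calling."""

import numpy as np
import pandas as pd
import pytest

from conftest import make_counts
from wdnafld import diffexpr, synth
from wdnafld.design import make_design
from wdnafld.diffexpr import (
    bh_adjust,
    call_degs,
    estimate_dispersion,
    nb_wald_test,
    run_comparison_plan,
    size_factors,
)


def brute_force_bh(p):
    """Independent BH oracle: p_(i) * m / i with cumulative min from the right."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    scaled = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(scaled[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


class TestSizeFactors:
    def test_hand_example(self):
        # two genes (2,8) each: geometric mean 4, ratios (0.5, 2) per column
        cm = make_counts([[2, 8], [2, 8]])
        assert size_factors(cm) == pytest.approx([0.5, 2.0])

    def test_identical_columns_give_unit_factors(self):
        cm = make_counts(np.tile([[5], [9], [20]], (1, 4)))
        assert size_factors(cm) == pytest.approx([1, 1, 1, 1])

    def test_scaling_one_column_scales_its_factor(self):
        rng = np.random.default_rng(0)
        vals = rng.integers(1, 100, size=(20, 4))
        base = size_factors(make_counts(vals))
        scaled = vals.copy()
        scaled[:, 2] *= 3
        new = size_factors(make_counts(scaled))
        # factors are defined up to the geometric-mean reference, which itself
        # absorbs 3^(1/4); relative to the other samples the factor triples
        rel = new / base
        assert rel[2] / rel[0] == pytest.approx(3.0)
        assert rel[[0, 1, 3]] / rel[0] == pytest.approx([1.0, 1.0, 1.0])

    def test_no_allpositive_gene_is_an_error(self):
        cm = make_counts([[0, 5], [5, 0]])
        with pytest.raises(ValueError, match="pseudo-count"):
            size_factors(cm)


class TestDispersion:
    def test_poisson_counts_estimate_near_zero(self):
        rng = np.random.default_rng(1)
        vals = rng.poisson(100, size=(500, 10))
        cm = make_counts(vals)
        phi = estimate_dispersion(cm, np.ones(10), ["a"] * 5 + ["b"] * 5)
        assert np.median(phi) < 0.01

    def test_nb_dispersion_recovered(self):
        rng = np.random.default_rng(2)
        mu, phi0 = 200.0, 0.2
        r = 1 / phi0
        vals = rng.negative_binomial(r, r / (r + mu), size=(500, 20))
        cm = make_counts(vals)
        est = estimate_dispersion(cm, np.ones(20), ["a"] * 10 + ["b"] * 10)
        assert 0.1 <= np.median(est) <= 0.3

    def test_constant_gene_floored(self):
        vals = np.vstack([np.full(6, 50), np.arange(6) + 10])
        phi = estimate_dispersion(make_counts(vals), np.ones(6), ["a"] * 3 + ["b"] * 3)
        assert phi[0] == pytest.approx(1e-8)

    def test_single_replicate_everywhere_is_an_error(self):
        cm = make_counts([[1, 2], [3, 4]])
        with pytest.raises(ValueError, match="replicates"):
            estimate_dispersion(cm, np.ones(2), ["a", "b"])


class TestNbWald:
    def test_identical_groups_give_zero_lfc(self):
        vals = np.tile([[10, 20, 30, 10, 20, 30]], (3, 1))
        cm = make_counts(vals)
        res = nb_wald_test(cm, np.ones(6), np.full(3, 0.1),
                           ["s0", "s1", "s2"], ["s3", "s4", "s5"])
        assert res.table["log2fc"].to_numpy() == pytest.approx(0.0, abs=1e-6)

    def test_swapping_groups_negates_lfc_keeps_p(self):
        rng = np.random.default_rng(3)
        vals = rng.poisson([[50], [500]], size=(2, 8))
        cm = make_counts(vals)
        a, b = [f"s{j}" for j in range(4)], [f"s{j}" for j in range(4, 8)]
        phi = np.full(2, 0.05)
        r1 = nb_wald_test(cm, np.ones(8), phi, a, b).table
        r2 = nb_wald_test(cm, np.ones(8), phi, b, a).table
        assert r2["log2fc"].to_numpy() == pytest.approx(-r1["log2fc"].to_numpy(), abs=1e-6)
        assert r2["p"].to_numpy() == pytest.approx(r1["p"].to_numpy(), abs=1e-9)

    def test_planted_fourfold_recovered(self):
        rng = np.random.default_rng(4)
        mu, phi0, n = 200.0, 0.05, 5
        r = 1 / phi0
        a = rng.negative_binomial(r, r / (r + mu), size=(300, n))
        b = rng.negative_binomial(r, r / (r + 4 * mu), size=(300, n))
        cm = make_counts(np.hstack([a, b]))
        res = nb_wald_test(cm, np.ones(2 * n), np.full(300, phi0),
                           [f"s{j}" for j in range(n)], [f"s{j}" for j in range(n, 2 * n)])
        assert abs(res.table["log2fc"].median() - 2.0) <= 0.3

    def test_null_type_i_error_calibrated(self):
        rng = np.random.default_rng(5)
        mu, phi0 = 100.0, 0.1
        r = 1 / phi0
        vals = rng.negative_binomial(r, r / (r + mu), size=(2000, 20))
        cm = make_counts(vals)
        sf = size_factors(cm)
        groups = ["a"] * 10 + ["b"] * 10
        phi = estimate_dispersion(cm, sf, groups)
        res = nb_wald_test(cm, sf, phi, [f"s{j}" for j in range(10)],
                           [f"s{j}" for j in range(10, 20)])
        rate = (res.table["p"] <= 0.05).mean()
        assert 0.03 <= rate <= 0.07
        # BH keeps the null discovery fraction below alpha + 2 SE
        frac = (res.table["fdr"] <= 0.05).mean()
        assert frac <= 0.05 + 2 * np.sqrt(0.05 * 0.95 / 2000)

    def test_all_zero_gene_flagged_untestable(self):
        vals = np.vstack([np.zeros(6, dtype=int), np.full(6, 30)])
        cm = make_counts(vals)
        res = nb_wald_test(cm, np.ones(6), np.full(2, 0.1),
                           ["s0", "s1", "s2"], ["s3", "s4", "s5"])
        row = res.table.iloc[0]
        assert row["untestable"] and row["p"] == 1.0 and row["log2fc"] == 0.0

    def test_empty_or_overlapping_groups_rejected(self):
        cm = make_counts([[1, 2, 3, 4]])
        with pytest.raises(ValueError):
            nb_wald_test(cm, np.ones(4), np.ones(1), [], ["s0"])
        with pytest.raises(ValueError):
            nb_wald_test(cm, np.ones(4), np.ones(1), ["s0"], ["s0", "s1"])


class TestBhAdjust:
    def test_hand_example(self):
        assert bh_adjust([0.01, 0.02, 0.03, 0.04]) == pytest.approx([0.04] * 4)

    def test_single_p(self):
        assert bh_adjust([0.3]) == pytest.approx([0.3])

    def test_matches_brute_force_on_random_vectors(self):
        rng = np.random.default_rng(6)
        for _ in range(1000):
            p = rng.uniform(size=rng.integers(1, 60))
            assert np.allclose(bh_adjust(p), brute_force_bh(p), atol=0.0)

    def test_permutation_invariance_of_multiset(self):
        rng = np.random.default_rng(7)
        p = rng.uniform(size=30)
        q1 = np.sort(bh_adjust(p))
        q2 = np.sort(bh_adjust(p[::-1]))
        assert np.allclose(q1, q2)

    def test_nan_propagated_and_excluded(self):
        q = bh_adjust([0.01, np.nan, 0.02])
        assert np.isnan(q[1])
        assert np.allclose(q[[0, 2]], brute_force_bh([0.01, 0.02]))

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([1.5])


class TestCallDegs:
    @staticmethod
    def _result(lfc, fdr):
        table = pd.DataFrame(
            {"mean_a": 1.0, "mean_b": 1.0, "log2fc": lfc, "se": 0.1,
             "p": fdr, "fdr": fdr, "untestable": False},
            index=[f"g{i}" for i in range(len(lfc))],
        )
        return diffexpr.DEResult("toy", table)

    def test_threshold_boundaries(self):
        res = self._result([0.60, 0.0, -0.70], [5e-4, 5e-4, 5e-4])
        degs = call_degs(res, 1.5, 0.001)
        assert "g0" in degs.up        # 0.60 >= log2(1.5) ~ 0.585
        assert "g1" not in degs.up and "g1" not in degs.down
        assert "g2" in degs.down

    def test_matches_brute_force_filter(self):
        rng = np.random.default_rng(8)
        lfc = rng.normal(0, 1, size=50)
        fdr = rng.uniform(size=50)
        res = self._result(lfc, fdr)
        degs = call_degs(res, 1.5, 0.05)
        thr = np.log2(1.5)
        want_up = {f"g{i}" for i in range(50) if lfc[i] >= thr and fdr[i] <= 0.05}
        want_down = {f"g{i}" for i in range(50) if lfc[i] <= -thr and fdr[i] <= 0.05}
        assert set(degs.up) == want_up and set(degs.down) == want_down

    def test_nonpositive_thresholds_rejected(self):
        res = self._result([0.0], [1.0])
        with pytest.raises(ValueError):
            call_degs(res, 0.0, 0.01)


class TestComparisonPlan:
    def test_default_design_yields_20_comparisons(self, small_design):
        spec = synth.GeneSpec(n_null=40)
        counts, _ = synth.simulate_counts(small_design, spec, seed=0)
        plan = run_comparison_plan(counts, small_design)
        assert plan.n_comparisons == 9 + 5 + 6
        assert len(plan.families["wd_vs_sd3"]) == 9
        assert len(plan.families["sd_vs_sd3"]) == 5
        assert len(plan.families["wd_vs_sd_same_week"]) == 6
        assert set(plan.sd_overlap) == {6, 30, 36, 42, 48}

    def test_minimal_design_single_comparison(self):
        d = make_design(wd_weeks={3}, sd_weeks={3}, replicates_per_level=3)
        counts, _ = synth.simulate_counts(d, synth.GeneSpec(n_null=40), seed=0)
        plan = run_comparison_plan(counts, d)
        assert list(plan.deg_sets) == ["WD3 vs SD3"]

    def test_planted_deg_recall(self):
        # 4-fold step genes from WD6 pass the 1.5-fold/0.001 filter with recall >= 0.9
        d = make_design(replicates_per_level=5)
        spec = synth.GeneSpec(n_null=500, n_rjg_up=60, log2fc=2.0, dispersion=0.05,
                              baseline_mean=(100.0, 1000.0), rjg_jump_level="WD6")
        counts, truths = synth.simulate_counts(d, spec, seed=11)
        plan = run_comparison_plan(counts, d)
        planted = {t.gene_id for t in truths if t.archetype == "rjg_up"}
        recalled = planted & set(plan.deg_sets["WD18 vs SD3"].up)
        assert len(recalled) / len(planted) >= 0.9

    def test_global_rescaling_leaves_calls_unchanged(self):
        d = make_design(wd_weeks={3, 6, 12}, sd_weeks={3}, replicates_per_level=3)
        spec = synth.GeneSpec(n_null=100, n_rjg_up=20, log2fc=2.5,
                              baseline_mean=(100.0, 500.0), rjg_jump_level="WD6",
                              dispersion=0.05)
        counts, _ = synth.simulate_counts(d, spec, seed=12)
        plan1 = run_comparison_plan(counts, d)
        doubled = diffexpr.CountMatrix(counts.values * 2, counts.gene_ids, counts.sample_ids)
        plan2 = run_comparison_plan(doubled, d)
        for label, ds1 in plan1.deg_sets.items():
            ds2 = plan2.deg_sets[label]
            # fold estimates compensate exactly through the size factors;
            # calls may flip only for genes sitting on the FDR boundary
            t1, t2 = plan1.results[label].table, plan2.results[label].table
            assert np.allclose(t1["log2fc"], t2["log2fc"], atol=0.02)
            flips = (set(ds1.up) ^ set(ds2.up)) | (set(ds1.down) ^ set(ds2.down))
            for g in flips:
                assert min(t1.loc[g, "fdr"], t2.loc[g, "fdr"]) <= 0.001 * 5

    def test_missing_reference_level_rejected(self):
        d = make_design(wd_weeks={3, 6, 12}, sd_weeks={6}, replicates_per_level=3)
        counts, _ = synth.simulate_counts(d, synth.GeneSpec(n_null=20), seed=0)
        with pytest.raises(ValueError, match="SD3"):
            run_comparison_plan(counts, d)
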