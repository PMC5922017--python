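import warnings

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import chi2

from mirlag import de
from mirlag.io_model import TIMEPOINTS, CountMatrix

from conftest import group_mean_counts, make_samples, unit_normalized


def brute_force_bh(pvals):
    """Step-up definition: adj_(k) = min_{j >= k} min(1, m p_(j) / j)."""
    p = np.asarray(pvals, dtype=float)
    m = p.size
    order = np.argsort(p, kind="mergesort")
    sorted_p = p[order]
    adj = np.empty(m)
    for k in range(m):
        adj[k] = min(min(1.0, m * sorted_p[j] / (j + 1)) for j in range(k, m))
    out = np.empty(m)
    out[order] = adj
    return out


class TestUpperQuartile:
    def test_hand_computed_factors(self, full_design_samples):
        samples = full_design_samples[:2]
        counts = CountMatrix(["a", "b", "c", "d"], samples,
                             np.array([[10, 20], [20, 40], [30, 60], [40, 80]]))
        norm = de.upper_quartile_normalize(counts)
        # 75th percentiles are 32.5 and 65 -> factor ratio exactly 2
        assert norm.scale_factors[1] / norm.scale_factors[0] == pytest.approx(2.0)
        assert np.exp(np.mean(np.log(norm.scale_factors))) == pytest.approx(1.0)
        uq = np.percentile(norm.normalized, 75, axis=0)
        assert uq[0] == pytest.approx(uq[1])

    def test_scaled_sample_gives_identical_columns(self, full_design_samples):
        samples = full_design_samples[:2]
        rng = np.random.default_rng(0)
        col = rng.integers(1, 100, size=20)
        counts = CountMatrix([f"e{i}" for i in range(20)], samples,
                             np.column_stack([col, 2 * col]))
        norm = de.upper_quartile_normalize(counts)
        assert np.allclose(norm.normalized[:, 0], norm.normalized[:, 1])

    def test_single_column(self, full_design_samples):
        counts = CountMatrix(["a", "b"], full_design_samples[:1],
                             np.array([[4], [8]]))
        norm = de.upper_quartile_normalize(counts)
        assert norm.scale_factors[0] == pytest.approx(1.0)
        assert np.allclose(norm.normalized, counts.counts)

    def test_zero_upper_quartile_error(self, full_design_samples):
        samples = full_design_samples[:2]
        counts = CountMatrix(["a", "b", "c", "d"], samples,
                             np.array([[0, 5], [0, 5], [0, 5], [0, 5]]))
        with pytest.raises(ValueError, match="upper quartile"):
            de.upper_quartile_normalize(counts)

    def test_column_scaling_invariance(self, full_design_samples):
        # multiplying any sample's column by c > 0 leaves the normalized
        # matrix unchanged up to one global scalar (the geomean-1 factor
        # constraint makes strict elementwise invariance unattainable; the
        # scalar cancels in every downstream contrast)
        samples = full_design_samples[:4]
        rng = np.random.default_rng(1)
        base = rng.integers(1, 200, size=(30, 4))
        norm1 = de.upper_quartile_normalize(
            CountMatrix([f"e{i}" for i in range(30)], samples, base))
        scaled = base.copy()
        scaled[:, 2] *= 3
        norm2 = de.upper_quartile_normalize(
            CountMatrix([f"e{i}" for i in range(30)], samples, scaled))
        ratio = norm2.normalized / norm1.normalized
        assert np.allclose(ratio, ratio.flat[0])
        # per-column upper quartiles stay equal across samples
        uq = np.percentile(norm2.normalized, 75, axis=0)
        assert np.allclose(uq, uq[0])


class TestBenjaminiHochberg:
    def test_hand_computed(self):
        assert np.allclose(de.benjamini_hochberg([0.01, 0.02, 0.03, 0.04]),
                           [0.04, 0.04, 0.04, 0.04])

    def test_single_value_identity(self):
        assert de.benjamini_hochberg([0.5]) == pytest.approx([0.5])

    def test_monotone(self):
        p = np.sort(np.random.default_rng(2).uniform(size=50))
        adj = de.benjamini_hochberg(p)
        assert np.all(np.diff(adj) >= -1e-15)

    def test_output_bounds(self):
        p = np.random.default_rng(3).uniform(size=100)
        adj = de.benjamini_hochberg(p)
        assert np.all(adj >= p - 1e-15)
        assert np.all(adj <= 1.0)

    def test_invalid_input(self):
        with pytest.raises(ValueError):
            de.benjamini_hochberg([0.5, 1.2])
        with pytest.raises(ValueError):
            de.benjamini_hochberg([-0.1])

    @given(st.lists(st.sampled_from([0.0, 0.001, 0.01, 0.04, 0.05, 0.2,
                                     0.5, 0.8, 1.0]),
                    min_size=1, max_size=6))
    @settings(max_examples=300, deadline=None)
    def test_matches_brute_force_definition(self, pvals):
        assert np.allclose(de.benjamini_hochberg(pvals),
                           brute_force_bh(pvals), atol=1e-12)


class TestDispersionEstimation:
    def test_poisson_counts_near_zero(self, full_design_samples):
        rng = np.random.default_rng(0)
        n = 2000
        base = np.exp(rng.normal(4.5, 1.0, n))
        y = rng.poisson(np.tile(base[:, None], (1, 60)))
        norm = unit_normalized(y, full_design_samples)
        disp = de.estimate_dispersions(norm)
        assert np.median(disp) <= 0.05

    def test_nb_phi_04_recovered(self, full_design_samples):
        rng = np.random.default_rng(1)
        n = 2000
        phi = 0.4
        base = np.exp(rng.normal(4.5, 1.0, n))
        lam = rng.gamma(1 / phi, np.tile(base[:, None] * phi, (1, 60)))
        y = rng.poisson(lam)
        norm = unit_normalized(y, full_design_samples)
        disp = de.estimate_dispersions(norm)
        assert 0.2 <= disp.mean() <= 0.6

    def test_constant_counts_raw_zero(self, full_design_samples):
        y = np.array([[5] * 60, [7] * 60, [11] * 60])
        norm = unit_normalized(y, full_design_samples)
        raw = de.estimate_dispersions(norm, trend_weight=0.0)
        assert np.allclose(raw, 0.0)

    def test_small_group_error(self):
        samples = make_samples(n_per_group=1)
        norm = unit_normalized(np.ones((3, 10), dtype=int), samples)
        with pytest.raises(ValueError, match="fewer than 2"):
            de.estimate_dispersions(norm)


def statsmodels_lrt_pvalues(y, samples, scale_factors, alpha):
    """Independent oracle: per-time-point LRT via statsmodels GLM."""
    import pandas as pd
    import statsmodels.api as sm

    cell = [f"{s.treatment}:{s.time_h}" for s in samples]
    offset = np.log(scale_factors)
    if alpha < 1e-8:
        fam = sm.families.Poisson()
    else:
        fam = sm.families.NegativeBinomial(alpha=alpha)
    X = pd.get_dummies(pd.Series(cell)).astype(float).to_numpy()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        full = sm.GLM(y, X, family=fam, offset=offset).fit()
        pvals = {}
        for t in TIMEPOINTS:
            merged = ["merged" if c in (f"treated:{t}", f"control:{t}") else c
                      for c in cell]
            X0 = pd.get_dummies(pd.Series(merged)).astype(float).to_numpy()
            red = sm.GLM(y, X0, family=fam, offset=offset).fit()
            pvals[t] = chi2.sf(max(2 * (full.llf - red.llf), 0.0), df=1)
    return pvals


class TestDifferentialExpression:
    def test_poisson_limit_matches_statsmodels(self, full_design_samples):
        rng = np.random.default_rng(1)
        y = rng.poisson(50, size=60)
        norm = unit_normalized(y.reshape(1, -1), full_design_samples)
        res = de.test_differential_expression(norm, dispersions=np.array([0.0]))
        oracle = statsmodels_lrt_pvalues(y, full_design_samples,
                                         np.ones(60), 0.0)
        for t in TIMEPOINTS:
            assert res[f"p_{t}"].iloc[0] == pytest.approx(oracle[t], abs=1e-6)

    def test_nb_matches_statsmodels(self, full_design_samples):
        rng = np.random.default_rng(2)
        alpha = 0.3
        lam = rng.gamma(1 / alpha, 60 * alpha, size=60)
        y = rng.poisson(lam)
        norm = unit_normalized(y.reshape(1, -1), full_design_samples)
        res = de.test_differential_expression(norm, dispersions=np.array([alpha]))
        oracle = statsmodels_lrt_pvalues(y, full_design_samples,
                                         np.ones(60), alpha)
        for t in TIMEPOINTS:
            assert res[f"p_{t}"].iloc[0] == pytest.approx(oracle[t], abs=1e-6)

    def test_planted_fold_change_detected(self, full_design_samples):
        rng = np.random.default_rng(3)
        phi = 0.1
        treated = [100, 1000, 100, 100, 100]   # 10-fold at t = 3 h
        control = [100, 100, 100, 100, 100]
        y = group_mean_counts(full_design_samples, treated, control,
                              n_entities=50, rng=rng, phi=phi)
        norm = unit_normalized(y, full_design_samples)
        res = de.test_differential_expression(
            norm, dispersions=np.full(50, phi))
        assert (res["fdr_3"] <= 0.05).all()
        # single-entity spec tolerance is 0.5; across 50 replicate entities
        # the mean should be well inside it
        assert abs(res["log2fc_3"].mean() - np.log2(10)) <= 0.15
        assert res["log2fc_3"].iloc[0] == pytest.approx(np.log2(10), abs=0.5)

    def test_null_type_I_error(self, full_design_samples):
        rng = np.random.default_rng(4)
        n = 2000
        phi = 0.15
        base = np.exp(rng.normal(4.5, 1.0, n))
        lam = rng.gamma(1 / phi, np.tile(base[:, None] * phi, (1, 60)))
        y = rng.poisson(lam)
        norm = unit_normalized(y, full_design_samples)
        res = de.test_differential_expression(norm)
        for t in TIMEPOINTS:
            assert 0.03 <= (res[f"p_{t}"] <= 0.05).mean() <= 0.07

    def test_fdr_geq_p_and_significance_rule(self, full_design_samples):
        rng = np.random.default_rng(5)
        y = rng.poisson(40, size=(100, 60))
        norm = unit_normalized(y, full_design_samples)
        res = de.test_differential_expression(norm)
        for t in TIMEPOINTS:
            assert (res[f"fdr_{t}"] >= res[f"p_{t}"] - 1e-12).all()
        min_fdr = res[[f"fdr_{t}" for t in TIMEPOINTS]].min(axis=1)
        assert res["significant"].equals(min_fdr <= 0.05)

    def test_all_zero_group_reported_na(self, full_design_samples):
        y = group_mean_counts(full_design_samples, [0, 50, 50, 50, 50],
                              [0, 50, 50, 50, 50])
        y = np.vstack([y, np.full((1, 60), 30)])
        norm = unit_normalized(y, full_design_samples)
        res = de.test_differential_expression(norm)
        assert np.isnan(res["log2fc_1"].iloc[0])
        assert res["p_1"].iloc[0] == 1.0
        assert not np.isnan(res["log2fc_1"].iloc[1])

    def test_rin_covariate_shrinks_null_fold_changes(self):
        # planted count-RIN degradation bias + treatment-linked RIN shift
        from mirlag.simulate import SimConfig, generate_dataset

        cfg = SimConfig(seed=4, n_mirna=200, n_mrna=50, frac_de=0.0,
                        n_true_pairs=0, n_decoy_pairs=0, frac_rin_biased=0.5,
                        degradation_gamma=(1.0, 2.0), rin_sd=0.5,
                        rin_treated_late_shift=1.2, dispersion=0.03)
        ds = generate_dataset(cfg)
        norm = de.upper_quartile_normalize(ds.mirna_counts)
        disp = de.estimate_dispersions(norm)
        res0 = de.test_differential_expression(norm, use_rin=False,
                                               dispersions=disp)
        res1 = de.test_differential_expression(norm, use_rin=True,
                                               dispersions=disp)
        fc_cols = [f"log2fc_{t}" for t in TIMEPOINTS]
        a0 = np.nanmean(np.abs(res0[fc_cols].to_numpy()))
        a1 = np.nanmean(np.abs(res1[fc_cols].to_numpy()))
        assert a1 < a0

    def test_significance_p_mode(self, full_design_samples):
        rng = np.random.default_rng(6)
        y = rng.poisson(40, size=(50, 60))
        norm = unit_normalized(y, full_design_samples)
        res_p = de.test_differential_expression(norm, significance="p")
        min_p = res_p[[f"p_{t}" for t in TIMEPOINTS]].min(axis=1)
        assert res_p["significant"].equals(min_p <= 0.05)
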