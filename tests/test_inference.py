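import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

import hurdleda as h
from hurdleda.abundance import fit_abundance
from hurdleda.inference import (
    assemble_results,
    bh_fdr,
    combine_pvalues,
    contrast_test,
    decide_significance,
    feature_specific_design,
    omnibus_test,
    ordered_contrasts,
)
from hurdleda.model import ModelSpec, build_design
from hurdleda.preprocess import FeatureTable, split_and_transform
from hurdleda.prevalence import fit_prevalence
from hurdleda.abundance import CoefficientEstimate


class TestCombinePvalues:
    def test_closed_form(self):
        assert combine_pvalues(0.05, 0.9) == pytest.approx(0.0975)
        assert combine_pvalues(1.0, 1.0) == pytest.approx(1.0)
        assert combine_pvalues(0.0, 0.7) == pytest.approx(0.0)

    @given(st.floats(0, 1), st.floats(0, 1))
    @settings(max_examples=50, derandomize=True)
    def test_matches_beta12_cdf_and_monotone(self, pa, pb):
        joint = combine_pvalues(pa, pb)
        m = min(pa, pb)
        assert joint == pytest.approx(1 - (1 - m) ** 2)
        assert joint == pytest.approx(stats.beta.cdf(m, 1, 2))
        # monotone in each argument
        assert combine_pvalues(min(pa + 0.05, 1.0), pb) >= joint - 1e-12

    def test_null_joint_uniform(self):
        rng = np.random.default_rng(0)
        pa, pb = rng.random(10000), rng.random(10000)
        joint = np.array([combine_pvalues(a, b) for a, b in zip(pa, pb)])
        assert stats.kstest(joint, "uniform").pvalue > 0.01

    def test_out_of_range_errors(self):
        with pytest.raises(ValueError):
            combine_pvalues(1.5, 0.2)


def bh_bruteforce(p):
    """Step-up definition: q_(i) = min_{j>=i} m * p_(j) / j."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p)
    q_sorted = np.minimum.accumulate(
        (m * p[order] / (np.arange(m) + 1))[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


class TestBhFdr:
    def test_spec_example(self):
        np.testing.assert_allclose(bh_fdr([0.01, 0.02, 0.03]),
                                   [0.03, 0.03, 0.03])

    def test_single_p(self):
        np.testing.assert_allclose(bh_fdr([0.42]), [0.42])

    @given(st.lists(st.floats(0, 1), min_size=1, max_size=1000))
    @settings(max_examples=30, derandomize=True)
    def test_matches_bruteforce_oracle(self, pvals):
        np.testing.assert_allclose(bh_fdr(pvals), bh_bruteforce(pvals),
                                   atol=1e-12)

    def test_nan_passthrough(self):
        q = bh_fdr([0.01, np.nan, 0.04])
        assert np.isnan(q[1])
        np.testing.assert_allclose(q[[0, 2]], bh_bruteforce([0.01, 0.04]))


def _categorical_fit(n=300, shift=0.0, seed=0, model="abundance", levels=3):
    """One feature regressed on a categorical covariate; returns
    (FeatureFit, DesignInfo)."""
    rng = np.random.default_rng(seed)
    groups = rng.integers(0, levels, n)
    metadata = pd.DataFrame(
        {"grp": pd.Categorical([f"g{v}" for v in groups])},
        index=[f"s{i}" for i in range(n)])
    spec = ModelSpec(fixed_terms=["grp"])
    design = build_design(metadata, spec)
    if model == "abundance":
        y = rng.standard_normal(n) + shift * (groups == levels - 1)
        values = pd.DataFrame({"f": np.exp2(y)}, index=metadata.index)
        fits = {}
        fit_abundance(split_and_transform(
            FeatureTable(values, scale="absolute")),
            metadata, spec, design=design, collect_fits=fits)
    else:
        p = 1 / (1 + np.exp(-(0.2 + shift * (groups == levels - 1))))
        presence = pd.DataFrame({"f": rng.binomial(1, p)},
                                index=metadata.index)
        values = presence.astype(float) * 0.5
        fits = {}
        fit_prevalence(split_and_transform(
            FeatureTable(values, scale="absolute")),
            metadata, spec, design=design, collect_fits=fits)
    return fits["f"], design


class TestOmnibus:
    def test_null_uniformity(self):
        pvals = []
        for seed in range(60):
            fit, design = _categorical_fit(n=120, shift=0.0, seed=seed)
            p, err = omnibus_test(fit, "grp", design)
            assert err is None
            pvals.append(p)
        assert stats.kstest(pvals, "uniform").pvalue > 0.01

    @pytest.mark.parametrize("model", ["abundance", "prevalence"])
    def test_power_with_shifted_group(self, model):
        fit, design = _categorical_fit(n=300, shift=3.0, seed=1, model=model)
        p, err = omnibus_test(fit, "grp", design)
        assert err is None
        assert p < 1e-4

    def test_two_levels_reduces_to_marginal(self):
        fit, design = _categorical_fit(n=200, shift=1.0, seed=2, levels=2)
        p_omni, _ = omnibus_test(fit, "grp", design)
        coef = [c for c in fit.params.index if c.startswith("grp[")][0]
        t = fit.params[coef] / np.sqrt(fit.cov.loc[coef, coef])
        p_marginal = 2 * stats.t.sf(abs(t), fit.df_resid)
        assert p_omni == pytest.approx(p_marginal, rel=1e-6)


class TestContrasts:
    def test_single_coefficient_equals_marginal(self):
        fit, design = _categorical_fit(n=200, shift=2.0, seed=3)
        coef = "grp[g2]"
        C = pd.DataFrame([{coef: 1.0}]).fillna(0.0)
        ((est, se, p),) = contrast_test(fit, C, [0.0])
        t = fit.params[coef] / np.sqrt(fit.cov.loc[coef, coef])
        assert est == pytest.approx(fit.params[coef])
        assert p == pytest.approx(2 * stats.t.sf(abs(t), fit.df_resid))

    def test_rhs_at_estimate_gives_p_one(self):
        fit, design = _categorical_fit(n=200, shift=2.0, seed=4)
        C = pd.DataFrame([{"grp[g1]": 1.0, "grp[g2]": -1.0}])
        est = fit.params["grp[g1]"] - fit.params["grp[g2]"]
        ((_, _, p),) = contrast_test(fit, C, [est])
        assert p == pytest.approx(1.0)

    def test_equal_coefficients_null(self):
        # g1 and g2 share the same true mean: the difference contrast is null
        pvals = []
        for seed in range(40):
            fit, _ = _categorical_fit(n=150, shift=0.0, seed=100 + seed)
            C = pd.DataFrame([{"grp[g1]": 1.0, "grp[g2]": -1.0}])
            pvals.append(contrast_test(fit, C, [0.0])[0][2])
        assert stats.kstest(pvals, "uniform").pvalue > 0.01

    def test_name_mismatch_errors(self):
        fit, _ = _categorical_fit(n=100, seed=5)
        with pytest.raises(KeyError, match="nonexistent"):
            contrast_test(fit, pd.DataFrame([{"nonexistent": 1.0}]), [0.0])


class TestOrderedContrasts:
    def _ordered_fits(self, effects, n=400, seed=0):
        rng = np.random.default_rng(seed)
        levels = rng.integers(1, len(effects) + 1, n)
        metadata = pd.DataFrame({"stage": levels},
                                index=[f"s{i}" for i in range(n)])
        spec = ModelSpec(fixed_terms=["stage"],
                         covariate_types={"stage": "ordered"},
                         ordered_levels={"stage": list(range(1, len(effects) + 1))})
        design = build_design(metadata, spec)
        cum = np.asarray(effects)
        y = cum[levels - 1] + rng.standard_normal(n) * 0.5
        values = pd.DataFrame({"f": np.exp2(y)}, index=metadata.index)
        fits = {}
        fit_abundance(split_and_transform(
            FeatureTable(values, scale="absolute")),
            metadata, spec, design=design, collect_fits=fits)
        return fits, design

    def test_number_of_tests_is_levels_minus_one(self):
        fits, design = self._ordered_fits([0.0, 1.0, 1.0, 2.0])
        rows = ordered_contrasts(fits, "stage", design)
        assert len(rows) == 3

    def test_planted_monotone_effect_recovered(self):
        fits, design = self._ordered_fits([0.0, 2.0, 2.0, 4.0], n=500, seed=1)
        rows = {r.coefficient: r for r in
                ordered_contrasts(fits, "stage", design)}
        assert rows["stage[2 vs 1]"].beta == pytest.approx(2.0, abs=0.3)
        assert rows["stage[2 vs 1]"].p_raw < 1e-6
        assert rows["stage[3 vs 2]"].p_raw > 0.01
        assert rows["stage[4 vs 3]"].p_raw < 1e-6

    def test_unordered_covariate_errors(self):
        fits, design = self._ordered_fits([0.0, 1.0, 2.0])
        with pytest.raises(ValueError):
            ordered_contrasts(fits, "nope", design)


class TestFeatureSpecificDesign:
    def test_design_width(self):
        design = pd.DataFrame(np.ones((5, 4)),
                              columns=["(Intercept)", "a", "b", "c"],
                              index=[f"s{i}" for i in range(5)])
        fsc = pd.DataFrame({"f1": np.arange(5.0)}, index=design.index)
        out = feature_specific_design(design, fsc, "f1")
        assert out.shape == (5, 5)

    def test_constant_column_errors(self):
        design = pd.DataFrame(np.ones((5, 2)),
                              columns=["(Intercept)", "a"],
                              index=[f"s{i}" for i in range(5)])
        fsc = pd.DataFrame({"f1": np.ones(5)}, index=design.index)
        with pytest.raises(ValueError, match="constant"):
            feature_specific_design(design, fsc, "f1")

    def test_rna_dna_recovery(self):
        """RNA = DNA + transcriptional effect: controlling the DNA
        covariate isolates the planted expression effect."""
        rng = np.random.default_rng(6)
        n = 300
        x = rng.standard_normal(n)
        log_dna = rng.standard_normal(n) * 2.0 - 8.0
        log_rna = log_dna + 1.5 * x + rng.standard_normal(n) * 0.3
        idx = [f"s{i}" for i in range(n)]
        rna = pd.DataFrame({"g1": np.exp2(log_rna)}, index=idx)
        fsc = pd.DataFrame({"g1": log_dna}, index=idx)
        metadata = pd.DataFrame({"x": x}, index=idx)
        spec = ModelSpec(fixed_terms=["x"], feature_specific_covariate=fsc,
                         feature_specific_name="dna")
        ests = fit_abundance(split_and_transform(
            FeatureTable(rna, scale="absolute")), metadata, spec)
        by_coef = {e.coefficient: e for e in ests}
        assert by_coef["x"].beta == pytest.approx(1.5, abs=0.1)
        assert by_coef["dna"].beta == pytest.approx(1.0, abs=0.05)


def _fake_estimate(feature, p, model="abundance", beta=2.0, error=None):
    return CoefficientEstimate(feature=feature, coefficient="x",
                               variable="x", model=model, beta=beta, se=0.3,
                               df=40, p_raw=p, error=error)


class TestAssembleResults:
    def test_error_record_never_significant(self):
        spec = ModelSpec(fixed_terms=["x"])
        recs = assemble_results(
            [_fake_estimate("f1", 1e-8, error="fit failed: boom")],
            [_fake_estimate("f1", 1e-8, model="prevalence")],
            None, spec)
        ab = next(r for r in recs if r.model == "abundance")
        assert not ab.significant
        assert "partial" in ab.flags

    def test_coef_threshold_rule(self):
        spec = ModelSpec(fixed_terms=["x"], coef_threshold=1.0)
        recs = assemble_results(
            [_fake_estimate("f1", 1e-8, beta=0.5)],
            [_fake_estimate("f1", 1e-8, model="prevalence", beta=0.5)],
            None, spec)
        assert not any(r.significant for r in recs)

    def test_joint_p_is_combined(self):
        spec = ModelSpec(fixed_terms=["x"])
        recs = assemble_results(
            [_fake_estimate("f1", 0.05)],
            [_fake_estimate("f1", 0.9, model="prevalence")],
            None, spec)
        for r in recs:
            assert r.p_joint == pytest.approx(0.0975)

    def test_screened_prevalence_not_significant(self):
        from hurdleda.prevalence import PrevalenceFlag
        spec = ModelSpec(fixed_terms=["x"])
        flags = [PrevalenceFlag("f1", "x", True, "induced")]
        recs = assemble_results(
            [_fake_estimate("f1", 1e-8)],
            [_fake_estimate("f1", 1e-8, model="prevalence")],
            flags, spec)
        prev = next(r for r in recs if r.model == "prevalence")
        ab = next(r for r in recs if r.model == "abundance")
        assert not prev.significant and ab.significant
        assert "abundance_induced" in prev.flags

    def test_decide_significance_switches_pool(self):
        spec = ModelSpec(fixed_terms=["x"])
        recs = assemble_results(
            [_fake_estimate("f1", 0.5), _fake_estimate("f2", 1e-4)],
            [_fake_estimate("f1", 1e-4, model="prevalence"),
             _fake_estimate("f2", 0.5, model="prevalence")],
            None, spec)
        joint = decide_significance(recs, use_joint=True)
        individual = decide_significance(recs, use_joint=False)
        sig_joint = {(r.feature, r.model) for r in joint if r.significant}
        sig_ind = {(r.feature, r.model) for r in individual if r.significant}
        # joint significance marks both components of a pair; individual
        # only the component that is itself small
        assert ("f1", "abundance") in sig_joint
        assert ("f1", "abundance") not in sig_ind
        assert ("f1", "prevalence") in sig_ind


class TestFdrControlNull:
    def test_all_null_fdp_controlled(self):
        """With no planted effects the joint-q discoveries stay rare."""
        n_disc = 0
        n_tests = 0
        for seed in range(3):
            ds = h.simulate_dataset(n=50, m=60, g=3, assoc_fraction=0.0,
                                    seed=seed)
            recs = h.analyze_dataset(ds, seed=seed)
            pairs = {(r.feature, r.variable) for r in recs if r.significant}
            n_disc += len(pairs)
            n_tests += 180
        assert n_disc / n_tests < 0.02
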