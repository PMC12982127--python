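import numpy as np
import pandas as pd
import pytest

import hurdleda as h
from hurdleda.simulate import (
    SimulationTruth,
    add_spike_in,
    make_metadata,
    make_ordered_covariate,
    make_template,
    make_truth,
    repeated_sampling,
    shuffle_metadata,
    simulate_ancombc,
    simulate_counts,
    simulate_dataset,
)


class TestMakeMetadata:
    def test_binary_continuous_split(self):
        md = make_metadata(100, 5, seed=0)
        binary = [c for c in md.columns if set(md[c].unique()) <= {0.0, 1.0}]
        assert len(binary) == 3  # ceil(5/2)
        assert md.shape == (100, 5)

    def test_continuous_moments(self):
        md = make_metadata(10000, 4, seed=1)
        cont = md.iloc[:, 2:]  # last two columns are continuous
        np.testing.assert_allclose(cont.mean(), 0.0, atol=0.05)
        np.testing.assert_allclose(cont.var(), 1.0, atol=0.06)


class TestMakeTruth:
    def test_forced_arithmetic(self):
        truth = make_truth(100, 5, assoc_fraction=0.1, seed=0)
        t = truth.table
        assert len(t) == 50
        assert (t.type == "abundance").sum() == 25
        assert (t.effect > 0).sum() == 25
        assert t[["feature", "metadatum"]].drop_duplicates().shape[0] == 50
        assert t.effect.abs().between(2.5, 5.0).all()

    def test_zero_fraction_empty(self):
        assert len(make_truth(100, 5, assoc_fraction=0.0, seed=0)) == 0

    def test_positive_fraction_mode(self):
        truth = make_truth(100, 5, assoc_fraction=1.0, seed=0,
                           positive_fraction=0.9)
        assert (truth.table.effect > 0).sum() == 450
        assert len(truth.table) == 500


class TestSimulateCounts:
    def test_count_row_sums_equal_depths(self, standard_dataset):
        sums = standard_dataset.counts.values.sum(axis=1)
        np.testing.assert_array_equal(sums.to_numpy(),
                                      standard_dataset.depths.to_numpy())

    def test_seeded_determinism(self):
        a = simulate_dataset(n=30, m=40, g=3, seed=123)
        b = simulate_dataset(n=30, m=40, g=3, seed=123)
        pd.testing.assert_frame_equal(a.counts.values, b.counts.values)
        pd.testing.assert_frame_equal(a.metadata, b.metadata)
        pd.testing.assert_frame_equal(a.truth.table, b.truth.table)

    def test_depth_mean(self):
        ds = simulate_dataset(n=400, m=30, g=2, assoc_fraction=0.0, seed=3)
        assert ds.depths.mean() == pytest.approx(50_000, rel=0.1)

    def test_zero_modes_sparsity_direction(self):
        zi = simulate_dataset(n=80, zero_mode="zero_inflated", seed=5)
        seq = simulate_dataset(n=80, zero_mode="sequencing_only", seed=5)
        f_zi = (zi.counts.values.values == 0).mean()
        f_seq = (seq.counts.values.values == 0).mean()
        assert f_zi > f_seq + 0.1

    def test_planted_abundance_effect_visible(self):
        """A binary covariate with a +4 log2 abundance effect separates
        group means of log2 relative abundance by roughly 4 after
        removing the compositional offset (shared by null features)."""
        rng = np.random.default_rng(0)
        template = make_template(60, rng)
        md = make_metadata(800, 1, rng)  # single binary covariate
        truth = SimulationTruth(pd.DataFrame([
            {"feature": "feature_1", "metadatum": "covariate_1",
             "type": "abundance", "effect": 4.0}]))
        # dense data isolate the abundance effect from detection effects
        ds = simulate_counts(template, md, truth, zero_mode="sequencing_only",
                             depth_mean=10_000_000, seed=rng)
        rel = h.tss_normalize(ds.counts)
        logrel = np.log2(rel.values.where(rel.values > 0))
        x = md["covariate_1"].to_numpy()
        diffs = (logrel[x == 1].mean() - logrel[x == 0].mean())
        offset = diffs.drop("feature_1").median()
        assert diffs["feature_1"] - offset == pytest.approx(4.0, abs=0.6)

    def test_truth_bookkeeping(self, standard_dataset):
        t = standard_dataset.truth.table
        assert set(t.feature) <= set(standard_dataset.counts.feature_ids)
        assert set(t.metadatum) <= set(standard_dataset.metadata.columns)
        assert not t.duplicated(["feature", "metadatum", "type"]).any()


class TestSpikeIn:
    def test_fraction_range_and_exclusion(self):
        ds = simulate_dataset(n=40, m=50, g=3, spike_in=True, seed=7)
        name, spike = ds.spike_in
        pre_total = ds.absolute.drop(columns=[name]).sum(axis=1)
        frac = spike / pre_total
        assert ((frac >= 0.01) & (frac <= 0.10)).all()
        assert name not in set(ds.truth.table.feature)

    def test_roundtrip_recovery(self):
        """Spike-in scaling of the sampled reads recovers the true
        absolute abundances up to multinomial noise."""
        ds = simulate_dataset(n=30, m=40, g=2, assoc_fraction=0.0,
                              depth_mean=500_000, spike_in=True, seed=9)
        name, spike = ds.spike_in
        rel = h.tss_normalize(ds.counts)
        est = h.scale_spike_in(rel, name, spike)
        # compare on well-sampled features only (enough reads for accuracy)
        common = est.values.columns.drop(name)
        true = ds.absolute.loc[est.values.index, common]
        got = est.values[common]
        mask = (ds.counts.values.loc[est.values.index, common] > 50)
        ratios = (got / true)[mask].stack()
        assert np.median(np.abs(np.log2(ratios))) < 0.2


class TestOrderedCovariate:
    def test_partition_sums_to_total(self):
        levels, cum = make_ordered_covariate(200, 4, (2.5, 5.0), seed=0)
        assert cum[0] == 0.0
        assert 2.5 <= cum[-1] <= 5.0
        assert len(cum) == 4
        assert set(levels.unique()) <= {1, 2, 3, 4}

    def test_zero_collapse_creates_ties(self):
        # over many draws, some consecutive cumulative coefficients tie
        ties = 0
        for seed in range(20):
            _, cum = make_ordered_covariate(10, 5, (2.5, 5.0), seed=seed)
            ties += int(np.any(np.diff(cum) == 0.0))
        assert ties > 0

    def test_monotone_cumulative(self):
        for seed in range(10):
            _, cum = make_ordered_covariate(10, 4, (2.5, 5.0), seed=seed)
            assert np.all(np.diff(cum) >= 0)


class TestAncombcGenerator:
    def test_structural_zeros(self):
        ds = simulate_ancombc(m=100, n_per_group=20, seed=1)
        group = ds.metadata["group"].to_numpy()
        t = ds.truth.table
        sz = t[~np.isfinite(t.effect)]
        assert len(sz) == 40  # 20% per group x 2 groups
        for row in sz.itertuples():
            grp_samples = group == (0 if row.effect > 0 else 1)
            col = ds.counts.values[row.feature].to_numpy()
            assert (col[grp_samples] == 0).all()

    def test_null_mode_groups_equal(self):
        ds = simulate_ancombc(m=50, n_per_group=100,
                              structural_zero_fraction=0.0,
                              da_fraction=0.0, seed=2)
        assert len(ds.truth.table) == 0
        rel = h.tss_normalize(ds.counts)
        g = ds.metadata["group"].to_numpy()
        m0 = rel.values[g == 0].mean()
        m1 = rel.values[g == 1].mean()
        assert np.abs(m0 - m1).max() < 0.02


class TestRepeatedSampling:
    def test_shapes_and_ids(self):
        rng = np.random.default_rng(0)
        template = make_template(30, rng)
        md = make_metadata(20, 3, rng)
        truth = h.SimulationTruth.empty()
        ds = repeated_sampling(template, md, truth,
                               samples_per_individual=10, seed=1)
        assert ds.counts.values.shape[0] == 200
        assert ds.individual_ids.nunique() == 20
        # metadata constant within individual
        joined = ds.metadata.assign(ind=ds.individual_ids)
        assert (joined.groupby("ind").nunique() <= 1).all().all()

    def test_single_sample_reduces_to_cross_sectional(self):
        rng = np.random.default_rng(3)
        template = make_template(30, rng)
        md = make_metadata(25, 3, np.random.default_rng(5))
        truth = h.SimulationTruth.empty()
        a = repeated_sampling(template, md, truth,
                              samples_per_individual=1, seed=42)
        b = simulate_counts(template, md, truth, seed=42)
        pd.testing.assert_frame_equal(a.counts.values, b.counts.values)

    def test_intraclass_correlation(self):
        """Per-individual intercepts induce higher within-individual than
        between-individual similarity of log2 abundances."""
        rng = np.random.default_rng(4)
        template = make_template(40, rng)
        md = make_metadata(30, 2, rng)
        ds = repeated_sampling(template, md, h.SimulationTruth.empty(),
                               samples_per_individual=6, intercept_sd=2.0,
                               zero_mode="sequencing_only", seed=6)
        rel = h.tss_normalize(ds.counts)
        logrel = np.log2(rel.values.where(rel.values > 0))
        ind = ds.individual_ids
        icc_num, icc_den = [], []
        for col in logrel.columns[:20]:
            y = logrel[col].dropna()
            if len(y) < 50:
                continue
            grp = ind.loc[y.index]
            grand = y.var()
            within = y.groupby(grp).var().mean()
            icc_num.append(grand - within)
            icc_den.append(grand)
        assert sum(icc_num) / sum(icc_den) > 0.15


class TestShuffleMetadata:
    def test_marginal_preserved_counts_untouched(self, standard_dataset):
        sh = shuffle_metadata(standard_dataset, "covariate_1", seed=0)
        assert sorted(sh.metadata["covariate_1"]) == sorted(
            standard_dataset.metadata["covariate_1"])
        pd.testing.assert_frame_equal(sh.counts.values,
                                      standard_dataset.counts.values)
        assert len(sh.truth.table) == 0

    def test_seed_reproducibility(self, standard_dataset):
        a = shuffle_metadata(standard_dataset, "covariate_1", seed=5)
        b = shuffle_metadata(standard_dataset, "covariate_1", seed=5)
        pd.testing.assert_frame_equal(a.metadata, b.metadata)
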