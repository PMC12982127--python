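"""Synthetic zero-inflated log-normal communities with known ground truth.

Features follow a zero-inflated log-normal null: each feature i has a
baseline prevalence pi_i, a log2-scale mean mu_i and standard deviation
sigma_i on the absolute-abundance scale. Planted prevalence effects act
additively on the logit of pi_i, and abundance effects act additively
on the log2 absolute abundance, so the ground truth is known on the
absolute scale while the observable data — multinomial reads at a
log-normal depth — are compositional, mirroring how sequencing hides
total load. A two-group generator with multiplicative mean shifts and
structural zeros, a spike-in extension, ordered (thermometer-generated)
covariates, repeated sampling with per-individual intercepts, and a
metadata-shuffle null are also provided.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .preprocess import FeatureTable


@dataclass
class Template:
    """Per-feature null distribution parameters (log2 scale)."""

    log2_mean: np.ndarray
    log2_sd: np.ndarray
    prevalence: np.ndarray
    feature_ids: list[str] = field(default=None)

    def __post_init__(self) -> None:
        self.log2_mean = np.asarray(self.log2_mean, dtype=float)
        self.log2_sd = np.asarray(self.log2_sd, dtype=float)
        self.prevalence = np.asarray(self.prevalence, dtype=float)
        if not (len(self.log2_mean) == len(self.log2_sd) == len(self.prevalence)):
            raise ValueError("template arrays must have equal length")
        if (self.log2_sd <= 0).any():
            raise ValueError("log2_sd must be positive")
        if ((self.prevalence <= 0) | (self.prevalence > 1)).any():
            raise ValueError("prevalence must be in (0, 1]")
        if self.feature_ids is None:
            self.feature_ids = [f"feature_{i+1}" for i in range(len(self.log2_mean))]

    @property
    def n_features(self) -> int:
        return len(self.log2_mean)


@dataclass
class SimulationTruth:
    """Planted effects: rows of (feature, metadatum, type, effect).

    Abundance effects are log2 units per covariate unit on the absolute
    scale; prevalence effects are log-odds units. Structural zeros are
    recorded with infinite effect magnitude (complete loss).
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"feature", "metadatum", "type", "effect"}
        if not required.issubset(self.table.columns):
            raise ValueError(f"truth table needs columns {sorted(required)}")

    @classmethod
    def empty(cls) -> "SimulationTruth":
        return cls(pd.DataFrame(columns=["feature", "metadatum", "type", "effect"]))

    def __len__(self) -> int:
        return len(self.table)


@dataclass
class SyntheticDataset:
    """Counts, metadata and ground truth for one simulated study."""

    counts: FeatureTable
    metadata: pd.DataFrame
    truth: SimulationTruth
    depths: pd.Series
    spike_in: tuple[str, pd.Series] | None = None
    individual_ids: pd.Series | None = None
    absolute: pd.DataFrame | None = None   # retained pre-sampling abundances


def make_template(
    m: int,
    rng: np.random.Generator,
    log2_mean_loc: float = -13.0,
    log2_mean_scale: float = 5.0,
    log2_sd_range: tuple[float, float] = (1.0, 3.0),
    prevalence_beta: tuple[float, float] = (1.0, 2.5),
) -> Template:
    """Draw a null community template.

    Defaults give heavy-tailed feature abundances spanning several
    orders of magnitude and mostly-rare features, emulating stool-like
    taxonomic profiles: at the default 50,000-read depth a 100-feature
    community yields roughly three-quarters zeros in the zero-inflated
    mode and roughly 40% sampling zeros in the sequencing-only mode.
    Only the spread of ``log2_mean`` matters after normalization; the
    location is compositionally irrelevant.
    """
    return Template(
        log2_mean=rng.normal(log2_mean_loc, log2_mean_scale, m),
        log2_sd=rng.uniform(*log2_sd_range, m),
        prevalence=np.clip(rng.beta(*prevalence_beta, m), 1e-4, 1.0),
    )


def make_metadata(n: int, g: int, seed: int | np.random.Generator) -> pd.DataFrame:
    """n samples x g covariates: ceil(g/2) binarized at 0, rest standard
    normal, drawn from an identity-covariance multivariate normal."""
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    X = rng.standard_normal((n, g))
    n_binary = int(np.ceil(g / 2))
    X[:, :n_binary] = (X[:, :n_binary] > 0).astype(float)
    cols = [f"covariate_{j+1}" for j in range(g)]
    return pd.DataFrame(X, columns=cols,
                        index=[f"sample_{k+1}" for k in range(n)])


def _split_count(total: int, fraction: float, rng: np.random.Generator) -> int:
    """floor(total*fraction), plus a seeded coin for the fractional part."""
    exact = total * fraction
    base = int(np.floor(exact))
    if exact - base > 1e-12 and rng.random() < (exact - base):
        base += 1
    return min(base, total)


def make_truth(
    m: int,
    g: int,
    assoc_fraction: float = 0.1,
    effect_range: tuple[float, float] = (2.5, 5.0),
    seed: int | np.random.Generator = 0,
    positive_fraction: float = 0.5,
    abundance_fraction: float = 0.5,
    feature_ids: list[str] | None = None,
    metadata_cols: list[str] | None = None,
) -> SimulationTruth:
    """Plant round(m*g*fraction) associations on distinct pairs.

    Effect magnitudes are uniform on ``effect_range``; types
    (abundance/prevalence) and signs split per the given fractions,
    with fractional counts resolved by a seeded coin.
    """
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    if not 0.0 <= assoc_fraction <= 1.0:
        raise ValueError("assoc_fraction must be in [0, 1]")
    feature_ids = feature_ids or [f"feature_{i+1}" for i in range(m)]
    metadata_cols = metadata_cols or [f"covariate_{j+1}" for j in range(g)]
    n_pairs = int(round(m * g * assoc_fraction))
    if n_pairs == 0:
        return SimulationTruth.empty()
    all_pairs = [(f, c) for f in feature_ids for c in metadata_cols]
    chosen = rng.choice(len(all_pairs), size=n_pairs, replace=False)
    n_abund = _split_count(n_pairs, abundance_fraction, rng)
    types = np.array(["abundance"] * n_abund
                     + ["prevalence"] * (n_pairs - n_abund))
    rng.shuffle(types)
    n_pos = _split_count(n_pairs, positive_fraction, rng)
    signs = np.concatenate([np.ones(n_pos), -np.ones(n_pairs - n_pos)])
    rng.shuffle(signs)
    magnitudes = rng.uniform(*effect_range, n_pairs)
    rows = [{"feature": all_pairs[i][0], "metadatum": all_pairs[i][1],
             "type": t, "effect": s * mag}
            for i, t, s, mag in zip(chosen, types, signs, magnitudes)]
    return SimulationTruth(pd.DataFrame(rows))


def _effect_matrices(truth: SimulationTruth, feature_ids, metadata_cols):
    m, g = len(feature_ids), len(metadata_cols)
    fidx = {f: i for i, f in enumerate(feature_ids)}
    cidx = {c: j for j, c in enumerate(metadata_cols)}
    E_ab = np.zeros((m, g))
    E_prev = np.zeros((m, g))
    for _, row in truth.table.iterrows():
        if row.feature not in fidx or row.metadatum not in cidx:
            raise ValueError(f"truth row references unknown ids: {row.feature}, {row.metadatum}")
        if not np.isfinite(row.effect):
            continue  # structural zeros are imposed directly, not via logits
        tgt = E_ab if row.type == "abundance" else E_prev
        tgt[fidx[row.feature], cidx[row.metadatum]] += row.effect
    return E_ab, E_prev


def _draw_depths(n: int, depth_mean: float, rng: np.random.Generator,
                 sigma: float = 0.5) -> np.ndarray:
    """Log-normal depths with the requested arithmetic mean."""
    meanlog = np.log(depth_mean) - sigma ** 2 / 2.0
    return np.maximum(rng.lognormal(meanlog, sigma, n).round().astype(int), 1)


def _sample_counts(absolute: np.ndarray, depths: np.ndarray,
                   rng: np.random.Generator) -> np.ndarray:
    counts = np.zeros_like(absolute, dtype=int)
    for k in range(absolute.shape[0]):
        total = absolute[k].sum()
        if total <= 0:
            continue
        counts[k] = rng.multinomial(depths[k], absolute[k] / total)
    return counts


def _absolute_abundances(template, X, E_ab, E_prev, zero_mode, rng,
                         ab_offset=None, prev_offset=None):
    """Draw the n x m absolute-abundance matrix (zeros = true absences)."""
    n = X.shape[0]
    m = template.n_features
    logit_pi = np.log(template.prevalence) - np.log1p(-np.clip(template.prevalence, None, 1 - 1e-12))
    logits = logit_pi[None, :] + X @ E_prev.T
    if prev_offset is not None:
        logits = logits + prev_offset
    if zero_mode == "sequencing_only":
        present = np.ones((n, m), dtype=bool)
    elif zero_mode == "zero_inflated":
        present = rng.random((n, m)) < 1.0 / (1.0 + np.exp(-logits))
    else:
        raise ValueError(f"unknown zero_mode {zero_mode!r}")
    log2A = (template.log2_mean[None, :] + X @ E_ab.T
             + rng.standard_normal((n, m)) * template.log2_sd[None, :])
    if ab_offset is not None:
        log2A = log2A + ab_offset
    A = np.exp2(log2A) * present
    # a sample with every feature absent cannot be sequenced; keep the
    # most prevalent feature present (vanishingly rare at realistic m)
    dead = ~present.any(axis=1)
    if dead.any():
        top = int(np.argmax(template.prevalence))
        A[dead, top] = np.exp2(log2A[dead, top])
    return A


def simulate_counts(
    template: Template,
    metadata: pd.DataFrame,
    truth: SimulationTruth,
    depth_mean: float = 50_000,
    zero_mode: str = "zero_inflated",
    seed: int | np.random.Generator = 0,
    _ab_offset: np.ndarray | None = None,
    _prev_offset: np.ndarray | None = None,
    _individual_ids: pd.Series | None = None,
) -> SyntheticDataset:
    """Simulate reads from a community with planted absolute-scale effects.

    Per sample: presence ~ Bernoulli(logistic(logit pi + prevalence
    effects . x)); nonzero absolute abundance = 2^(mu + abundance
    effects . x + Normal(0, sigma^2)); counts ~ Multinomial(depth,
    relative abundances) with log-normal depths. ``sequencing_only``
    forces all features present so every zero is a sampling zero.
    """
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    X = metadata.to_numpy(dtype=float)
    E_ab, E_prev = _effect_matrices(truth, template.feature_ids,
                                    list(metadata.columns))
    A = _absolute_abundances(template, X, E_ab, E_prev, zero_mode, rng,
                             _ab_offset, _prev_offset)
    depths = _draw_depths(len(metadata), depth_mean, rng)
    counts = _sample_counts(A, depths, rng)
    counts_df = pd.DataFrame(counts, index=metadata.index,
                             columns=template.feature_ids)
    return SyntheticDataset(
        counts=FeatureTable(counts_df, scale="counts"),
        metadata=metadata.copy(),
        truth=truth,
        depths=pd.Series(depths, index=metadata.index, name="depth"),
        individual_ids=_individual_ids,
        absolute=pd.DataFrame(A, index=metadata.index,
                              columns=template.feature_ids),
    )


def add_spike_in(dataset: SyntheticDataset, seed: int | np.random.Generator = 0,
                 name: str = "spike_in") -> SyntheticDataset:
    """Append a spike-in reference feature and resample the reads.

    The reference's absolute abundance is drawn uniformly from 1%-10%
    of each sample's pre-spike total, stored as the known spike-in
    quantity, and included before read sampling, so downstream spike-in
    scaling can recover true absolute abundances up to read noise. The
    spike feature is never part of the truth.
    """
    if dataset.absolute is None:
        raise ValueError("dataset lacks retained absolute abundances")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    A = dataset.absolute.to_numpy(dtype=float)
    totals = A.sum(axis=1)
    spike = rng.uniform(0.01, 0.10, len(totals)) * totals
    A_new = np.hstack([A, spike[:, None]])
    depths = dataset.depths.to_numpy()
    counts = _sample_counts(A_new, depths, rng)
    cols = list(dataset.absolute.columns) + [name]
    counts_df = pd.DataFrame(counts, index=dataset.metadata.index, columns=cols)
    spike_series = pd.Series(spike, index=dataset.metadata.index, name=name)
    return replace(
        dataset,
        counts=FeatureTable(counts_df, scale="counts"),
        spike_in=(name, spike_series),
        absolute=pd.DataFrame(A_new, index=dataset.metadata.index, columns=cols),
    )


def make_ordered_covariate(
    n: int,
    n_levels: int,
    effect_total_range: tuple[float, float] = (2.5, 5.0),
    seed: int | np.random.Generator = 0,
) -> tuple[pd.Series, np.ndarray]:
    """Ordered covariate with a Dirichlet-partitioned cumulative effect.

    Internally the levels are thermometer encoded (level j sets the
    first j of P indicators); the total baseline-to-top difference is
    drawn from ``effect_total_range`` and divided among the level steps
    by a Dirichlet(1) draw. Each step is then, with probability 1/2,
    zeroed and folded into the next step, creating runs of equal
    levels. Returns the per-sample levels (1..P) and the cumulative
    per-level coefficients (baseline 0).
    """
    if n_levels < 3:
        raise ValueError("ordered covariates need at least 3 levels")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    total = rng.uniform(*effect_total_range)
    incr = rng.dirichlet(np.ones(n_levels - 1)) * total
    for j in range(n_levels - 2):
        if rng.random() < 0.5:
            incr[j + 1] += incr[j]
            incr[j] = 0.0
    cumulative = np.concatenate([[0.0], np.cumsum(incr)])
    levels = pd.Series(rng.integers(1, n_levels + 1, n),
                       index=[f"sample_{k+1}" for k in range(n)],
                       name="ordered_covariate")
    return levels, cumulative


def simulate_ancombc(
    m: int,
    n_per_group: int,
    structural_zero_fraction: float = 0.2,
    effect_range: tuple[float, float] = (2.5, 5.0),
    da_fraction: float = 0.1,
    depth_mean: float = 50_000,
    seed: int | np.random.Generator = 0,
) -> SyntheticDataset:
    """Two-group generator with multiplicative shifts and structural zeros.

    Group-2 mean absolute abundances of a random ``da_fraction`` of
    features are multiplied by effects uniform on ``effect_range``
    (deliberately unbalancing the microbial load); a random
    ``structural_zero_fraction`` of features is hard-zeroed in each
    group. Reads are drawn by multinomial sampling of the normalized
    profiles at log-normal depths (a close stand-in for rarefaction at
    depth >> m). Structural zeros enter the truth as prevalence rows
    with infinite effect magnitude.
    """
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    n = 2 * n_per_group
    feature_ids = [f"feature_{i+1}" for i in range(m)]
    sample_ids = [f"sample_{k+1}" for k in range(n)]
    group = np.repeat([0.0, 1.0], n_per_group)
    # null per-feature mean absolute abundances, heavy tailed
    base_mean = np.exp(rng.normal(0.0, 2.0, m))
    mult = np.ones(m)
    n_da = int(round(m * da_fraction))
    da_features = rng.choice(m, size=n_da, replace=False)
    mult[da_features] = rng.uniform(*effect_range, n_da)
    log2A = (np.log2(base_mean)[None, :]
             + group[:, None] * np.log2(mult)[None, :]
             + rng.standard_normal((n, m)))
    A = np.exp2(log2A)
    n_sz = int(round(m * structural_zero_fraction))
    sz = {0: rng.choice(m, size=n_sz, replace=False),
          1: rng.choice(m, size=n_sz, replace=False)}
    A[np.ix_(group == 0, sz[0])] = 0.0
    A[np.ix_(group == 1, sz[1])] = 0.0
    depths = _draw_depths(n, depth_mean, rng)
    counts = _sample_counts(A, depths, rng)

    rows = [{"feature": feature_ids[i], "metadatum": "group",
             "type": "abundance", "effect": float(np.log2(mult[i]))}
            for i in da_features]
    for grp, feats in sz.items():
        sign = 1.0 if grp == 0 else -1.0  # zeroed in group 0 => present with group=1
        for i in feats:
            rows.append({"feature": feature_ids[i], "metadatum": "group",
                         "type": "prevalence", "effect": sign * np.inf})
    truth = (SimulationTruth(pd.DataFrame(rows)) if rows
             else SimulationTruth.empty())
    metadata = pd.DataFrame({"group": group}, index=sample_ids)
    return SyntheticDataset(
        counts=FeatureTable(
            pd.DataFrame(counts, index=sample_ids, columns=feature_ids),
            scale="counts"),
        metadata=metadata, truth=truth,
        depths=pd.Series(depths, index=sample_ids, name="depth"),
        absolute=pd.DataFrame(A, index=sample_ids, columns=feature_ids),
    )


def repeated_sampling(
    template: Template,
    individual_metadata: pd.DataFrame,
    truth: SimulationTruth,
    samples_per_individual: int = 10,
    intercept_sd: float = 1.0,
    depth_mean: float = 50_000,
    zero_mode: str = "zero_inflated",
    seed: int | np.random.Generator = 0,
) -> SyntheticDataset:
    """Longitudinal extension: each individual contributes several samples.

    Metadata are constant within an individual. Per (feature,
    individual) random intercepts ~ Normal(0, intercept_sd^2) are added
    to the log2 abundances and to the prevalence logits, inducing
    intra-individual correlation. With one sample per individual this
    reduces exactly to the cross-sectional generator.
    """
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    if samples_per_individual < 1:
        raise ValueError("samples_per_individual must be >= 1")
    if samples_per_individual == 1:
        ds = simulate_counts(template, individual_metadata, truth,
                             depth_mean=depth_mean, zero_mode=zero_mode,
                             seed=rng)
        return replace(ds, individual_ids=pd.Series(
            individual_metadata.index, index=individual_metadata.index,
            name="individual"))
    n_ind = len(individual_metadata)
    m = template.n_features
    sample_index = []
    ind_of_sample = []
    for ind_i, ind in enumerate(individual_metadata.index):
        for s in range(samples_per_individual):
            sample_index.append(f"{ind}_s{s+1}")
            ind_of_sample.append(ind_i)
    ind_of_sample = np.array(ind_of_sample)
    metadata = individual_metadata.iloc[ind_of_sample].copy()
    metadata.index = sample_index
    ab_int = rng.standard_normal((n_ind, m)) * intercept_sd
    prev_int = rng.standard_normal((n_ind, m)) * intercept_sd
    ds = simulate_counts(
        template, metadata, truth, depth_mean=depth_mean,
        zero_mode=zero_mode, seed=rng,
        _ab_offset=ab_int[ind_of_sample],
        _prev_offset=prev_int[ind_of_sample],
        _individual_ids=pd.Series(
            [individual_metadata.index[i] for i in ind_of_sample],
            index=sample_index, name="individual"),
    )
    return ds


def shuffle_metadata(
    dataset: SyntheticDataset,
    covariate: str,
    seed: int | np.random.Generator = 0,
) -> SyntheticDataset:
    """Permute one metadata column across samples (counts untouched).

    The permutation destroys every feature-covariate association in
    expectation, so the returned dataset carries an empty truth table:
    any discovery against the shuffled covariate is a false positive.
    """
    if covariate not in dataset.metadata.columns:
        raise KeyError(f"covariate {covariate!r} not in metadata")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    metadata = dataset.metadata.copy()
    metadata[covariate] = rng.permutation(metadata[covariate].to_numpy())
    return replace(dataset, metadata=metadata, truth=SimulationTruth.empty())


def simulate_dataset(
    n: int = 50,
    m: int = 100,
    g: int = 5,
    assoc_fraction: float = 0.1,
    effect_range: tuple[float, float] = (2.5, 5.0),
    positive_fraction: float = 0.5,
    depth_mean: float = 50_000,
    zero_mode: str = "zero_inflated",
    samples_per_individual: int = 1,
    intercept_sd: float = 1.0,
    spike_in: bool = False,
    seed: int = 0,
) -> SyntheticDataset:
    """One-call standard study: template + metadata + truth + reads.

    ``n`` is the number of individuals; with ``samples_per_individual
    > 1`` the dataset has ``n * samples_per_individual`` rows and
    per-individual random intercepts.
    """
    rng = np.random.default_rng(seed)
    template = make_template(m, rng)
    metadata = make_metadata(n, g, rng)
    truth = make_truth(m, g, assoc_fraction, effect_range, rng,
                       positive_fraction=positive_fraction,
                       feature_ids=template.feature_ids,
                       metadata_cols=list(metadata.columns))
    if samples_per_individual > 1:
        ds = repeated_sampling(template, metadata, truth,
                               samples_per_individual=samples_per_individual,
                               intercept_sd=intercept_sd,
                               depth_mean=depth_mean, zero_mode=zero_mode,
                               seed=rng)
    else:
        ds = simulate_counts(template, metadata, truth,
                             depth_mean=depth_mean, zero_mode=zero_mode,
                             seed=rng)
    if spike_in:
        ds = add_spike_in(ds, seed=rng)
    return ds
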