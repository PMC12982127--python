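"""Normalization, filtering, and splitting of feature abundance tables.

Tables are oriented samples-in-rows, features-in-columns. Zeros are
treated as true feature absence throughout: no pseudo-counts are added
anywhere in the pipeline. The abundance table is split into a binary
presence/absence mask and a log2-transformed table of the nonzero
values, which downstream logistic and linear models consume separately.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

_SCALES = ("counts", "relative", "absolute")


@dataclass
class FeatureTable:
    """A samples x features table of non-negative abundances.

    Parameters
    ----------
    values : pandas.DataFrame
        Non-negative, finite abundances; index = sample ids,
        columns = feature ids, both unique.
    scale : str
        One of ``counts``, ``relative``, ``absolute``. For ``relative``
        every non-degenerate sample row must sum to 1 (tolerance 1e-9);
        all-zero rows are permitted but flagged.
    """

    values: pd.DataFrame
    scale: str = "counts"

    def __post_init__(self) -> None:
        if self.scale not in _SCALES:
            raise ValueError(f"scale must be one of {_SCALES}, got {self.scale!r}")
        vals = np.asarray(self.values.values, dtype=float)
        if not np.all(np.isfinite(vals)):
            raise ValueError("abundance table contains non-finite values")
        if (vals < 0).any():
            raise ValueError("abundance table contains negative values")
        if self.values.index.has_duplicates:
            raise ValueError("duplicate sample ids")
        if self.values.columns.has_duplicates:
            raise ValueError("duplicate feature ids")
        if self.scale == "relative":
            # filtered tables are subcompositions, so sums below 1 are
            # legitimate; sums above 1 are not relative abundances
            sums = vals.sum(axis=1)
            if (sums > 1.0 + 1e-6).any():
                bad = sums > 1.0 + 1e-6
                raise ValueError(
                    "relative-scale rows must sum to at most 1; offending "
                    f"samples: {list(self.values.index[bad])[:5]}"
                )

    @property
    def sample_ids(self) -> list:
        return list(self.values.index)

    @property
    def feature_ids(self) -> list:
        return list(self.values.columns)

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    def all_zero_samples(self) -> list:
        mask = self.values.sum(axis=1) == 0
        return list(self.values.index[mask])


@dataclass
class SplitData:
    """Presence mask and log2 nonzero abundances for hurdle modeling.

    ``log_abundance`` is NaN exactly where ``presence`` is 0;
    ``n_present`` is the per-feature count of present samples.
    """

    presence: pd.DataFrame
    log_abundance: pd.DataFrame
    n_present: pd.Series = field(default=None)

    def __post_init__(self) -> None:
        if self.n_present is None:
            self.n_present = self.presence.sum(axis=0).astype(int)


@dataclass
class FilterSpec:
    """Feature retention thresholds.

    The default rule retains any feature present with nonidentical
    abundance in at least two samples; features whose nonzero values are
    all equal carry no abundance information.
    """

    min_prevalence: float = 0.0
    min_abundance: float = 0.0
    require_nonidentical_nonzero: bool = True

    def __post_init__(self) -> None:
        if not 0.0 <= self.min_prevalence <= 1.0:
            raise ValueError("min_prevalence must be in [0, 1]")
        if self.min_abundance < 0:
            raise ValueError("min_abundance must be non-negative")


def tss_normalize(table: FeatureTable) -> FeatureTable:
    """Total-sum scale each sample to relative abundances.

    All-zero samples are left as zeros and reported with a warning;
    they should normally be dropped before modeling.
    """
    if table.scale == "relative":
        return table
    vals = table.values.to_numpy(dtype=float)
    sums = vals.sum(axis=1, keepdims=True)
    zero_rows = sums[:, 0] == 0
    if zero_rows.any():
        logger.warning(
            "%d all-zero sample(s) left unnormalized: %s",
            int(zero_rows.sum()),
            list(table.values.index[zero_rows])[:5],
        )
    safe = np.where(sums == 0, 1.0, sums)
    rel = vals / safe
    out = pd.DataFrame(rel, index=table.values.index, columns=table.values.columns)
    return FeatureTable(out, scale="relative")


def filter_features(table: FeatureTable, spec: FilterSpec | None = None) -> FeatureTable:
    """Drop features failing the prevalence/abundance/variation thresholds."""
    if spec is None:
        spec = FilterSpec()
    vals = table.values
    nonzero = vals > 0
    prevalence = nonzero.mean(axis=0)
    keep = prevalence >= spec.min_prevalence
    if spec.min_abundance > 0:
        max_abund = vals.max(axis=0)
        keep &= max_abund >= spec.min_abundance
    if spec.require_nonidentical_nonzero:
        def _informative(col: pd.Series) -> bool:
            nz = col[col > 0]
            return len(nz) >= 2 and nz.nunique() > 1

        keep &= vals.apply(_informative, axis=0)
    dropped = int((~keep).sum())
    if dropped:
        logger.info("filtered out %d of %d features", dropped, vals.shape[1])
    if keep.sum() == 0:
        logger.warning("all features filtered out")
    return FeatureTable(vals.loc[:, keep], scale=table.scale)


def split_and_transform(table: FeatureTable) -> SplitData:
    """Split into presence/absence and log2 nonzero abundance tables.

    Exact zeros define absence; log2 is applied only to nonzero entries
    so no pseudo-count is ever introduced.
    """
    vals = table.values.to_numpy(dtype=float)
    presence = (vals > 0).astype(int)
    with np.errstate(divide="ignore"):
        log_ab = np.where(vals > 0, np.log2(np.where(vals > 0, vals, 1.0)), np.nan)
    idx, cols = table.values.index, table.values.columns
    return SplitData(
        presence=pd.DataFrame(presence, index=idx, columns=cols),
        log_abundance=pd.DataFrame(log_ab, index=idx, columns=cols),
    )


def scale_spike_in(
    rel: FeatureTable,
    ref_feature: str,
    ref_abs: pd.Series,
) -> FeatureTable:
    """Rescale relative abundances to absolute using a spike-in reference.

    For a reference feature with known absolute abundance ``A_ref,k``
    and observed relative abundance ``P_ref,k``, each feature's absolute
    abundance is estimated as ``A_ik = A_ref,k * P_ik / P_ref,k`` —
    within-sample abundance ratios are preserved. Samples where the
    reference feature was not observed cannot be rescaled and are
    dropped with a warning. The reference feature itself is retained in
    the output (with its estimated abundance equal to ``ref_abs``) but
    should be excluded from downstream testing.
    """
    if rel.scale != "relative":
        raise ValueError("spike-in scaling expects a relative-abundance table")
    if ref_feature not in rel.values.columns:
        raise ValueError(f"reference feature {ref_feature!r} not in table")
    ref_abs = pd.Series(ref_abs).reindex(rel.values.index)
    if ref_abs.isna().any():
        raise ValueError("spike-in absolute abundances missing for some samples")
    if (ref_abs <= 0).any():
        raise ValueError("spike-in absolute abundances must be positive")
    p_ref = rel.values[ref_feature]
    usable = p_ref > 0
    if not usable.all():
        logger.warning(
            "dropping %d sample(s) with zero spike-in reference abundance",
            int((~usable).sum()),
        )
    sub = rel.values.loc[usable]
    factor = (ref_abs[usable] / p_ref[usable]).to_numpy()[:, None]
    abs_vals = sub.to_numpy(dtype=float) * factor
    out = pd.DataFrame(abs_vals, index=sub.index, columns=sub.columns)
    return FeatureTable(out, scale="absolute")


def scale_total(rel: FeatureTable, totals: pd.Series) -> FeatureTable:
    """Rescale relative abundances by per-sample total-load estimates.

    ``A_ik = P_ik * T_k``; per-sample sums of the output equal the
    supplied totals.
    """
    if rel.scale != "relative":
        raise ValueError("total-load scaling expects a relative-abundance table")
    totals = pd.Series(totals).reindex(rel.values.index)
    if totals.isna().any():
        raise ValueError("total abundance estimates missing for some samples")
    if (totals <= 0).any():
        raise ValueError("total abundance estimates must be positive")
    abs_vals = rel.values.to_numpy(dtype=float) * totals.to_numpy()[:, None]
    out = pd.DataFrame(abs_vals, index=rel.values.index, columns=rel.values.columns)
    return FeatureTable(out, scale="absolute")


def rna_dna_pair(
    rna: FeatureTable, dna: FeatureTable
) -> tuple[FeatureTable, pd.DataFrame]:
    """Pair metatranscriptomic (RNA) and metagenomic (DNA) tables.

    Returns the RNA table (unchanged values) plus a feature-specific
    covariate table of log2 DNA abundances to control for gene copy
    number, built per feature per sample as:

    1. DNA nonzero — use log2 of the DNA relative abundance as-is;
    2. RNA nonzero but DNA zero — DNA assumed below the detection
       limit; the covariate is set to log2 of half the dataset-wide
       minimum nonzero DNA relative abundance;
    3. both zero — no expression information; the observation is
       excluded (covariate NaN, and the RNA zero already marks absence).
    """
    if rna.values.shape != dna.values.shape or not (
        rna.values.index.equals(dna.values.index)
        and rna.values.columns.equals(dna.values.columns)
    ):
        raise ValueError("RNA and DNA tables must share sample and feature ids")
    dna_vals = dna.values.to_numpy(dtype=float)
    rna_vals = rna.values.to_numpy(dtype=float)
    nonzero_dna = dna_vals[dna_vals > 0]
    if nonzero_dna.size == 0:
        raise ValueError("DNA table has no nonzero entries")
    sentinel = np.log2(nonzero_dna.min() / 2.0)
    with np.errstate(divide="ignore"):
        log_dna = np.where(dna_vals > 0, np.log2(np.where(dna_vals > 0, dna_vals, 1.0)), np.nan)
    covariate = np.where(
        dna_vals > 0,
        log_dna,
        np.where(rna_vals > 0, sentinel, np.nan),
    )
    fsc = pd.DataFrame(covariate, index=rna.values.index, columns=rna.values.columns)
    return rna, fsc
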