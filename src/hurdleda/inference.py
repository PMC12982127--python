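"""Combining prevalence and abundance results into association calls.

Each (feature, covariate) pair gets an individual q-value per model
component (Benjamini-Hochberg over the pooled abundance and prevalence
p-values) and a joint p-value formed by evaluating the Beta(1, 2) CDF
at the minimum of the two component p-values — the exact null
distribution of the minimum of two independent uniforms, which the two
components are under the null because the abundance model sees only
the nonzero values and the prevalence model only the mask. Extended
tests (omnibus, ordered consecutive-level contrasts, arbitrary
contrasts, feature-specific covariates) join the individual FDR pool.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats

from .abundance import (
    CoefficientEstimate,
    FeatureFit,
    MedianSummary,
    fit_abundance,
    median_bootstrap_variance,
    median_test,
    subtract_median,
)
from .model import INTERCEPT, DesignInfo, ModelSpec, build_design
from .preprocess import (
    FeatureTable,
    FilterSpec,
    filter_features,
    scale_spike_in,
    scale_total,
    split_and_transform,
    tss_normalize,
)
from .prevalence import PrevalenceFlag, fit_prevalence, screen_abundance_induced

logger = logging.getLogger(__name__)


@dataclass
class AssociationRecord:
    """One (feature, coefficient, model) row of the association table."""

    feature: str
    coefficient: str
    variable: str
    model: str                      # "abundance" | "prevalence"
    beta: float = np.nan
    se: float = np.nan
    p_individual: float = np.nan
    q_individual: float = np.nan
    p_joint: float = np.nan
    q_joint: float = np.nan
    flags: set = field(default_factory=set)
    error: str | None = None
    significant: bool = False


def combine_pvalues(p_abund: float, p_prev: float) -> float:
    """Beta(1, 2) CDF at the smaller of the two component p-values:
    1 - (1 - min)^2, uniform under the joint null."""
    for p in (p_abund, p_prev):
        if not (np.isnan(p) or 0.0 <= p <= 1.0):
            raise ValueError(f"p-value outside [0, 1]: {p}")
    if np.isnan(p_abund) and np.isnan(p_prev):
        return np.nan
    if np.isnan(p_abund):
        return p_prev
    if np.isnan(p_prev):
        return p_abund
    m = min(p_abund, p_prev)
    return 2.0 * m - m * m


def bh_fdr(pvals: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values (NaNs pass through)."""
    from statsmodels.stats.multitest import multipletests

    p = np.asarray(pvals, dtype=float)
    q = np.full_like(p, np.nan)
    ok = ~np.isnan(p)
    if ok.sum():
        q[ok] = multipletests(p[ok], method="fdr_bh")[1]
    return q


# ---------------------------------------------------------------------------
# extended tests


def omnibus_test(fit: FeatureFit, variable: str, design: DesignInfo):
    """Single p-value for H0: all level coefficients of ``variable`` are 0.

    Linear models use a Wald F-test on the residual degrees of freedom
    (equivalent to the ANOVA F for OLS); logistic models use a
    likelihood-ratio test with the augmentation rows and weights
    retained in both nested fits. Mixed fits use a Wald chi-square.
    """
    coefs = [c for c, v in design.coef_to_var.items()
             if v == variable and c != INTERCEPT and c in fit.params.index]
    if not coefs:
        return np.nan, "no coefficients for variable"
    r = len(coefs)
    est = fit.params[coefs].to_numpy()
    if fit.model == "abundance":
        sub = fit.cov.loc[coefs, coefs].to_numpy()
        try:
            stat = float(est @ np.linalg.solve(sub, est)) / r
        except np.linalg.LinAlgError:
            return np.nan, "singular covariance"
        if fit.df_resid is not None:
            return float(stats.f.sf(stat, r, fit.df_resid)), None
        return float(stats.chi2.sf(stat * r, r)), None
    # logistic: LRT against the model without the variable's columns
    if fit.y is None or fit.X is None:
        return np.nan, "fit context not retained"
    keep = [c for c in fit.X.columns if c not in coefs]
    from .prevalence import _weighted_logistic
    try:
        if fit.groups is not None:
            sub = fit.cov.loc[coefs, coefs].to_numpy()
            stat = float(est @ np.linalg.solve(sub, est))
            return float(stats.chi2.sf(stat, r)), None
        *_, ll0 = _weighted_logistic(fit.y, fit.X[keep].to_numpy(),
                                     fit.weights)
    except (ValueError, np.linalg.LinAlgError) as exc:
        return np.nan, f"reduced fit failed: {exc}"
    lr = 2.0 * (fit.loglik - ll0)
    return float(stats.chi2.sf(max(lr, 0.0), r)), None


def contrast_test(fit: FeatureFit, C: pd.DataFrame, rhs: np.ndarray):
    """Wald tests of C beta = rhs, one p-value per contrast row.

    ``C`` columns must name fitted coefficients; a name mismatch raises
    with the unmatched columns listed.
    """
    missing = [c for c in C.columns if c not in fit.params.index]
    if missing:
        raise KeyError(f"contrast names not in fitted coefficients: {missing}")
    rhs = np.atleast_1d(np.asarray(rhs, dtype=float))
    out = []
    for row_i in range(C.shape[0]):
        c = np.zeros(len(fit.params))
        for name, val in C.iloc[row_i].items():
            c[fit.params.index.get_loc(name)] = val
        est = float(c @ fit.params.to_numpy())
        var = float(c @ fit.cov.to_numpy() @ c)
        if var <= 0:
            out.append((est, np.nan, np.nan))
            continue
        z = (est - rhs[row_i]) / np.sqrt(var)
        if fit.model == "abundance" and fit.df_resid is not None:
            p = 2 * stats.t.sf(abs(z), fit.df_resid)
        else:
            p = 2 * stats.norm.sf(abs(z))
        out.append((est, np.sqrt(var), float(p)))
    return out


def ordered_contrasts(
    fits: dict[str, FeatureFit],
    variable: str,
    design: DesignInfo,
    rhs: str = "zero",
    rng: np.random.Generator | None = None,
    n_boot: int = 1000,
) -> list[CoefficientEstimate]:
    """Consecutive-level difference tests for an ordered covariate.

    For levels l1 < ... < lP (treatment coded against l1) the tested
    quantities are beta[l2], beta[l3]-beta[l2], ..., beta[lP]-beta[lP-1]
    — P-1 tests. ``rhs='median'`` subtracts the across-feature median
    of each difference, with the same bootstrap variance machinery as
    the abundance median test. No monotone ordering is imposed.
    """
    if variable not in design.var_levels:
        raise ValueError(f"{variable!r} is not an ordered/categorical covariate")
    levels = design.var_levels[variable]
    pairs = list(zip(levels[:-1], levels[1:]))
    rows: list[CoefficientEstimate] = []
    per_pair: dict[tuple, list] = {p: [] for p in pairs}
    for feature, fit in fits.items():
        for lo, hi in pairs:
            name_hi = f"{variable}[{hi}]"
            name_lo = f"{variable}[{lo}]"
            c = pd.Series(0.0, index=fit.params.index)
            if name_hi in c.index:
                c[name_hi] = 1.0
            if name_lo in c.index:
                c[name_lo] = -1.0
            cv = c.to_numpy()
            est = float(cv @ fit.params.to_numpy())
            var = float(cv @ fit.cov.to_numpy() @ cv)
            per_pair[(lo, hi)].append((feature, fit, est, var))
    for (lo, hi), entries in per_pair.items():
        ests = np.array([e[2] for e in entries])
        ses = np.sqrt(np.array([max(e[3], 0.0) for e in entries]))
        if rhs == "median" and len(entries) >= 2:
            med = float(np.median(ests))
            var_med = median_bootstrap_variance(
                ests, ses, rng or np.random.default_rng(0), n_boot)
        else:
            med, var_med = 0.0, 0.0
        for (feature, fit, est, var), se in zip(entries, ses):
            denom = np.sqrt(max(var, 0.0) + var_med)
            if denom == 0:
                p = 1.0 if est == med else np.nan
            else:
                z = (est - med) / denom
                if fit.model == "abundance" and fit.df_resid is not None and rhs == "zero":
                    p = 2 * stats.t.sf(abs(z), fit.df_resid)
                else:
                    p = 2 * stats.norm.sf(abs(z))
            rows.append(CoefficientEstimate(
                feature=feature, coefficient=f"{variable}[{hi} vs {lo}]",
                variable=variable, model=fit.model, beta=est, se=float(se),
                p_raw=float(p), n_obs=fit.n_obs,
            ))
    return rows


def feature_specific_design(
    design: pd.DataFrame, fsc_table: pd.DataFrame, feature: str,
    name: str = "fsc",
) -> pd.DataFrame:
    """Append feature ``i``'s column of the feature-specific covariate
    table to the design, widening it from g+1 to g+2 columns."""
    if feature not in fsc_table.columns:
        raise KeyError(f"feature {feature!r} missing from feature-specific table")
    col = fsc_table[feature].reindex(design.index)
    out = design.assign(**{name: col.to_numpy(dtype=float)})
    if out[name].nunique(dropna=True) <= 1:
        raise ValueError("feature-specific covariate constant (collinear with intercept)")
    return out


# ---------------------------------------------------------------------------
# assembly


def assemble_results(
    abundance_estimates: list[CoefficientEstimate],
    prevalence_estimates: list[CoefficientEstimate],
    flags: list[PrevalenceFlag] | None,
    spec: ModelSpec,
    adjusted_abundance_p: dict[tuple, float] | None = None,
    extra_estimates: list[CoefficientEstimate] | None = None,
) -> list[AssociationRecord]:
    """Merge component fits into the final association table.

    ``adjusted_abundance_p`` maps (feature, coefficient) to the
    median-comparison p-value; when present it replaces the raw
    abundance p in both FDR pools. Individual q pools abundance and
    prevalence (and any extended-test) p-values together; joint p per
    (feature, coefficient) combines the two component p-values, with a
    "partial" flag when one component errored; joint q pools the joint
    p-values. A record is significant when its joint q is below the FDR
    level, it carries no error, its |coefficient| clears the post hoc
    threshold (if set), and — for prevalence records under screening —
    it was not flagged abundance-induced.
    """
    adjusted_abundance_p = adjusted_abundance_p or {}
    flag_map = {(f.feature, f.coefficient): f for f in (flags or [])}

    records: list[AssociationRecord] = []
    for e in abundance_estimates:
        p_ind = adjusted_abundance_p.get((e.feature, e.coefficient), e.p_raw)
        records.append(AssociationRecord(
            feature=e.feature, coefficient=e.coefficient, variable=e.variable,
            model="abundance", beta=e.beta, se=e.se,
            p_individual=p_ind, error=e.error,
        ))
    for e in prevalence_estimates:
        rec = AssociationRecord(
            feature=e.feature, coefficient=e.coefficient, variable=e.variable,
            model="prevalence", beta=e.beta, se=e.se,
            p_individual=e.p_raw, error=e.error,
        )
        f = flag_map.get((e.feature, e.coefficient))
        if f is not None and f.abundance_induced:
            rec.flags.add("abundance_induced")
        records.append(rec)
    for e in (extra_estimates or []):
        records.append(AssociationRecord(
            feature=e.feature, coefficient=e.coefficient, variable=e.variable,
            model=e.model, beta=e.beta, se=e.se,
            p_individual=e.p_raw, error=e.error,
        ))

    # individual q over the pooled error-free p-values
    pool_idx = [i for i, r in enumerate(records)
                if r.error is None and not np.isnan(r.p_individual)]
    qvals = bh_fdr(np.array([records[i].p_individual for i in pool_idx]))
    for i, q in zip(pool_idx, qvals):
        records[i].q_individual = float(q)

    # joint p per (feature, coefficient) over the two hurdle components
    by_key: dict[tuple, dict[str, AssociationRecord]] = {}
    for r in records:
        if r.model in ("abundance", "prevalence"):
            by_key.setdefault((r.feature, r.coefficient), {})[r.model] = r
    joint_p: dict[tuple, float] = {}
    for key, comps in by_key.items():
        pa = comps.get("abundance")
        pp = comps.get("prevalence")
        p_a = pa.p_individual if (pa is not None and pa.error is None) else np.nan
        p_p = pp.p_individual if (pp is not None and pp.error is None) else np.nan
        if np.isnan(p_a) and np.isnan(p_p):
            continue
        pj = combine_pvalues(p_a, p_p)
        if np.isnan(p_a) or np.isnan(p_p):
            for r in comps.values():
                r.flags.add("partial")
        joint_p[key] = pj
    keys = list(joint_p)
    joint_q = dict(zip(keys, bh_fdr(np.array([joint_p[k] for k in keys]))))
    for key, comps in by_key.items():
        if key not in joint_p:
            continue
        for r in comps.values():
            r.p_joint = joint_p[key]
            r.q_joint = float(joint_q[key])

    decide_significance(records, spec.fdr_level, spec.coef_threshold,
                        use_joint=True,
                        apply_screen=spec.screen_prevalence, inplace=True)
    return records


def decide_significance(
    records: list[AssociationRecord],
    fdr_level: float = 0.1,
    coef_threshold: float = 0.0,
    use_joint: bool = True,
    apply_screen: bool = True,
    inplace: bool = False,
) -> list[AssociationRecord]:
    """(Re)compute the per-record significance calls.

    ``use_joint`` selects the joint q (default, for overall calls) or
    the individual q (for type-resolved evaluation). The q-values
    themselves are fixed at assembly; only the call changes.
    """
    out = records if inplace else [replace(r, flags=set(r.flags)) for r in records]
    for r in out:
        q = r.q_joint if use_joint else r.q_individual
        sig = (
            r.error is None
            and not np.isnan(q)
            and q < fdr_level
            and (coef_threshold <= 0 or abs(r.beta) > coef_threshold)
        )
        if apply_screen and r.model == "prevalence" and "abundance_induced" in r.flags:
            sig = False
        r.significant = bool(sig)
    return out


def records_to_frame(records: list[AssociationRecord]) -> pd.DataFrame:
    """Association records as a tidy DataFrame (TSV-ready)."""
    return pd.DataFrame([{
        "feature": r.feature,
        "coefficient": r.coefficient,
        "variable": r.variable,
        "model": r.model,
        "beta": r.beta,
        "se": r.se,
        "p_individual": r.p_individual,
        "q_individual": r.q_individual,
        "p_joint": r.p_joint,
        "q_joint": r.q_joint,
        "flags": ";".join(sorted(r.flags)),
        "error": r.error or "",
        "significant": r.significant,
    } for r in records])


# ---------------------------------------------------------------------------
# full pipeline


def fit_hurdle(
    table: FeatureTable,
    metadata: pd.DataFrame,
    spec: ModelSpec,
    spike_in: tuple[str, pd.Series] | None = None,
    totals: pd.Series | None = None,
    filter_spec: FilterSpec | None = None,
    seed: int = 0,
) -> list[AssociationRecord]:
    """Run the full hurdle pipeline on one dataset.

    Steps: TSS-normalize (counts input), complete-case subset on the
    model variables, feature filtering, optional absolute-abundance
    scaling (spike-in or total load, which turns the median comparison
    off since the data are then on the absolute scale), split into
    presence/absence and log2 nonzero abundance, fit both model
    components, median-compare abundance coefficients, screen
    abundance-induced prevalence effects, and assemble the association
    table. Per-feature failures become error records, never crashes.
    """
    rng = np.random.default_rng(seed)

    common = table.values.index.intersection(metadata.index)
    n_drop = max(len(table.values.index), len(metadata.index)) - len(common)
    if n_drop:
        logger.info("inner join on sample ids dropped %d sample(s)", n_drop)
    table = FeatureTable(table.values.loc[common], scale=table.scale)
    metadata = metadata.loc[common]

    zero_samples = table.all_zero_samples()
    if zero_samples:
        logger.warning("dropping %d all-zero sample(s)", len(zero_samples))
        keep = ~table.values.index.isin(zero_samples)
        table = FeatureTable(table.values.loc[keep], scale=table.scale)
        metadata = metadata.loc[table.values.index]

    model_vars = {p for t in spec.fixed_terms for p in t.split(":")}
    model_vars |= set(spec.random_intercept_groups)
    missing_cols = model_vars - set(metadata.columns)
    if missing_cols:
        raise KeyError(f"metadata columns not found: {sorted(missing_cols)}")
    cc = metadata[sorted(model_vars)].notna().all(axis=1)
    if not cc.all():
        logger.info("dropping %d sample(s) with missing model variables",
                    int((~cc).sum()))
        metadata = metadata.loc[cc]
        table = FeatureTable(table.values.loc[metadata.index], scale=table.scale)

    rel = tss_normalize(table) if table.scale == "counts" else table
    rel = filter_features(rel, filter_spec)

    median_comparison = spec.median_comparison
    ref_feature = None
    if spike_in is not None:
        ref_feature, ref_abs = spike_in
        abund_table = scale_spike_in(rel, ref_feature, pd.Series(ref_abs))
        if median_comparison:
            logger.info("spike-in scaling supplied: median comparison disabled")
            median_comparison = False
        # samples without the reference observed were dropped
        metadata = metadata.loc[abund_table.values.index]
        rel = FeatureTable(rel.values.loc[abund_table.values.index],
                           scale="relative")
        abund_table = FeatureTable(
            abund_table.values.drop(columns=[ref_feature]), scale="absolute")
        # reference feature is excluded from testing; rows no longer sum
        # to 1 so the container is tagged counts (values stay relative)
        rel = FeatureTable(rel.values.drop(columns=[ref_feature]),
                           scale="counts")
    elif totals is not None:
        abund_table = scale_total(rel, pd.Series(totals))
        if median_comparison:
            logger.info("total-load scaling supplied: median comparison disabled")
            median_comparison = False
    elif table.scale == "absolute":
        abund_table = rel
        if median_comparison:
            logger.info("absolute-scale input: median comparison disabled")
            median_comparison = False
    else:
        abund_table = rel

    design = build_design(metadata, spec)
    split_abund = split_and_transform(abund_table)
    split_rel = split_and_transform(rel)

    abund_fits: dict[str, FeatureFit] = {}
    abund_ests = fit_abundance(split_abund, metadata, spec, design=design,
                               collect_fits=abund_fits)
    raw_abund_ests = abund_ests  # against-zero fits, pre median subtraction
    prev_fits: dict[str, FeatureFit] = {}
    prev_ests = fit_prevalence(split_rel, metadata, spec, design=design,
                               collect_fits=prev_fits)

    coef_names = [c for c in design.coef_names if c != INTERCEPT]

    adjusted_p: dict[tuple, float] = {}
    if median_comparison:
        for coef in coef_names:
            summary, pmap = median_test(abund_ests, coef, rng)
            for feature, p in pmap.items():
                adjusted_p[(feature, coef)] = p
            if summary is not None and spec.subtract_median:
                abund_ests = subtract_median(abund_ests, summary)

    flags = None
    if spec.screen_prevalence:
        if abund_table.scale == "relative":
            screen_ests = raw_abund_ests
        else:
            # screening is defined on the relative scale
            screen_ests = fit_abundance(split_rel, metadata, spec,
                                        design=design)
        flags = screen_abundance_induced(prev_ests, screen_ests,
                                         fdr_level=spec.fdr_level)

    extra: list[CoefficientEstimate] = []
    for var in spec.omnibus_vars:
        for fits in (abund_fits, prev_fits):
            for feature, fit in fits.items():
                p, err = omnibus_test(fit, var, design)
                extra.append(CoefficientEstimate(
                    feature=feature, coefficient=f"{var}[omnibus]",
                    variable=var, model=fit.model, p_raw=p,
                    n_obs=fit.n_obs, error=err))
    for var in spec.ordered_vars:
        for fits in (abund_fits, prev_fits):
            extra.extend(ordered_contrasts(fits, var, design, rhs="zero",
                                           rng=rng))
    if spec.contrasts:
        for C, rhs in spec.contrasts:
            C = pd.DataFrame(C)
            for fits in (abund_fits, prev_fits):
                for feature, fit in fits.items():
                    try:
                        results = contrast_test(fit, C, rhs)
                    except KeyError as exc:
                        extra.append(CoefficientEstimate(
                            feature=feature, coefficient="contrast",
                            variable="contrast", model=fit.model,
                            error=str(exc)))
                        continue
                    for row_i, (est, se, p) in enumerate(results):
                        extra.append(CoefficientEstimate(
                            feature=feature,
                            coefficient=f"contrast[{row_i}]",
                            variable="contrast", model=fit.model,
                            beta=est, se=se, p_raw=p, n_obs=fit.n_obs))

    return assemble_results(abund_ests, prev_ests, flags, spec,
                            adjusted_abundance_p=adjusted_p,
                            extra_estimates=extra)
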