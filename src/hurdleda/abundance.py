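"""Per-feature log-linear abundance models and the median-comparison test.

Each feature's log2 nonzero abundances are regressed on the covariates
by OLS (or a restricted-maximum-likelihood random-intercept fit).
Because sequencing data are compositional, a coefficient fitted on
relative abundances estimates the absolute-scale effect only up to a
per-covariate additive shift shared by all features. When fewer than
half the community's features truly change, that shift is consistently
estimated by the across-feature median of the fitted coefficients, so
testing each coefficient against the median recovers absolute-scale
inference from relative data. The median-comparison test is a z-test
whose denominator carries both the coefficient's standard error and a
parametric-bootstrap estimate of the median's sampling variance.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import stats

from .model import INTERCEPT, ModelSpec, DesignInfo, build_design
from .preprocess import SplitData

logger = logging.getLogger(__name__)


@dataclass
class CoefficientEstimate:
    """One fitted (feature, coefficient) slope from one model component."""

    feature: str
    coefficient: str
    variable: str
    model: str            # "abundance" or "prevalence"
    beta: float = np.nan
    se: float = np.nan
    df: float = np.nan
    p_raw: float = np.nan
    n_obs: int = 0
    error: str | None = None


@dataclass
class MedianSummary:
    """Across-feature median of a coefficient and its bootstrap variance."""

    coefficient: str
    median: float
    median_var: float
    n_features_used: int


@dataclass
class FeatureFit:
    """Full fit context for one feature, kept for extended tests."""

    feature: str
    model: str
    params: pd.Series
    cov: pd.DataFrame
    df_resid: float | None
    n_obs: int
    loglik: float | None = None
    # retained inputs so nested models can be refit (logistic LRT)
    y: np.ndarray | None = None
    X: pd.DataFrame | None = None
    weights: np.ndarray | None = None
    groups: np.ndarray | None = None


def _error_estimates(feature, design: DesignInfo, model, msg, fsc_name=None):
    out = []
    for coef in design.coef_names:
        if coef == INTERCEPT:
            continue
        out.append(CoefficientEstimate(
            feature=feature, coefficient=coef,
            variable=design.coef_to_var[coef], model=model, error=msg,
        ))
    if fsc_name is not None:
        out.append(CoefficientEstimate(
            feature=feature, coefficient=fsc_name, variable=fsc_name,
            model=model, error=msg,
        ))
    return out


def _feature_design(design: DesignInfo, spec: ModelSpec, feature: str,
                    row_index: pd.Index):
    """Subset the design to given rows, appending any feature-specific
    covariate column. Returns (X frame, fsc_name or None, error or None)."""
    X = design.matrix.loc[row_index]
    fsc_name = None
    if spec.feature_specific_covariate is not None:
        fsc = spec.feature_specific_covariate
        if feature not in fsc.columns:
            return None, None, f"feature missing from feature-specific covariate table"
        col = fsc[feature].reindex(row_index)
        keep = col.notna()
        X = X.loc[keep]
        col = col.loc[keep]
        fsc_name = spec.feature_specific_name
        X = X.assign(**{fsc_name: col.to_numpy(dtype=float)})
        if X[fsc_name].nunique() <= 1:
            return None, None, "feature-specific covariate constant (collinear with intercept)"
    return X, fsc_name, None


def _ols_fit(y: np.ndarray, X: pd.DataFrame):
    """Plain OLS with t-based inference; returns FeatureFit pieces."""
    n, k = X.shape
    Xv = X.to_numpy(dtype=float)
    beta, _, rank, _ = np.linalg.lstsq(Xv, y, rcond=None)
    if rank < k:
        raise np.linalg.LinAlgError("rank-deficient design")
    resid = y - Xv @ beta
    df_resid = n - k
    sigma2 = float(resid @ resid) / df_resid
    XtX_inv = np.linalg.inv(Xv.T @ Xv)
    cov = sigma2 * XtX_inv
    se = np.sqrt(np.diag(cov))
    tvals = beta / se
    pvals = 2 * stats.t.sf(np.abs(tvals), df_resid)
    return beta, se, cov, df_resid, pvals


def fit_abundance(
    split: SplitData,
    metadata: pd.DataFrame,
    spec: ModelSpec,
    design: DesignInfo | None = None,
    collect_fits: dict | None = None,
) -> list[CoefficientEstimate]:
    """Fit the abundance model one feature at a time.

    Only samples where the feature is present contribute. Features with
    too few nonzero observations for the design, rank-deficient
    subsets, or non-convergent mixed fits yield error-tagged records
    rather than estimates. Intercept coefficients are not reported.
    """
    if design is None:
        design = build_design(metadata, spec)
    mixed = bool(spec.random_intercept_groups)
    group_col = spec.random_intercept_groups[0] if mixed else None
    estimates: list[CoefficientEstimate] = []

    for feature in split.log_abundance.columns:
        y_all = split.log_abundance[feature]
        present = y_all.notna()
        row_index = y_all.index[present]
        X, fsc_name, err = _feature_design(design, spec, feature, row_index)
        if err is not None:
            estimates.extend(_error_estimates(
                feature, design, "abundance", err,
                fsc_name=spec.feature_specific_name
                if spec.feature_specific_covariate is not None else None))
            continue
        y = y_all.loc[X.index].to_numpy(dtype=float)
        n, k = X.shape
        if n <= k:
            estimates.extend(_error_estimates(
                feature, design, "abundance",
                "insufficient nonzero observations", fsc_name=fsc_name))
            continue
        try:
            if mixed:
                beta, se, cov, df_resid, pvals, ll = _fit_linear_mixed(
                    y, X, metadata.loc[X.index, group_col].to_numpy())
            else:
                beta, se, cov, df_resid, pvals = _ols_fit(y, X)
                ll = None
        except (np.linalg.LinAlgError, ValueError) as exc:
            estimates.extend(_error_estimates(
                feature, design, "abundance", f"fit failed: {exc}",
                fsc_name=fsc_name))
            continue
        names = list(X.columns)
        if collect_fits is not None:
            collect_fits[feature] = FeatureFit(
                feature=feature, model="abundance",
                params=pd.Series(beta, index=names),
                cov=pd.DataFrame(cov, index=names, columns=names),
                df_resid=df_resid, n_obs=n, loglik=ll,
                y=y, X=X,
            )
        for i, coef in enumerate(names):
            if coef == INTERCEPT:
                continue
            variable = design.coef_to_var.get(coef, coef)
            estimates.append(CoefficientEstimate(
                feature=feature, coefficient=coef, variable=variable,
                model="abundance", beta=float(beta[i]), se=float(se[i]),
                df=float(df_resid) if df_resid is not None else np.nan,
                p_raw=float(pvals[i]), n_obs=n,
            ))
    return estimates


def _fit_linear_mixed(y, X, groups):
    """REML random-intercept linear model via statsmodels MixedLM."""
    from statsmodels.regression.mixed_linear_model import MixedLM

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = MixedLM(y, X.to_numpy(dtype=float), groups=groups)
        res = model.fit(reml=True, method="lbfgs", maxiter=200)
        if not res.converged:
            raise ValueError("mixed model did not converge")
        k = X.shape[1]
        beta = np.asarray(res.fe_params)
        se = np.asarray(res.bse_fe)
        cov = np.asarray(res.cov_params())[:k, :k]
    if not np.all(np.isfinite(se)):
        raise ValueError("mixed model covariance not positive definite")
    # many-groups normal approximation for fixed effects
    z = beta / se
    pvals = 2 * stats.norm.sf(np.abs(z))
    return beta, se, cov, None, pvals, float(res.llf)


def median_bootstrap_variance(
    betas: np.ndarray, ses: np.ndarray, rng: np.random.Generator, n_boot: int = 1000
) -> float:
    """Parametric-bootstrap variance of the across-feature median.

    Draws beta* ~ Normal(beta_hat_i, se_i^2) independently per feature,
    takes the median across features in each draw, and returns the
    variance of those medians.
    """
    draws = rng.standard_normal((n_boot, len(betas))) * ses[None, :] + betas[None, :]
    return float(np.var(np.median(draws, axis=1), ddof=1))


def median_test(
    estimates: list[CoefficientEstimate],
    coefficient: str,
    rng: np.random.Generator,
    n_boot: int = 1000,
) -> tuple[MedianSummary | None, dict[str, float]]:
    """Test each feature's coefficient against the across-feature median.

    The statistic is ``(beta_i - M) / sqrt(se_i^2 + var(M))``, where
    ``var(M)`` comes from a seeded parametric bootstrap so both sources
    of variability are counted. The two-sided reference is the
    feature's own residual-df t distribution (normal when the fit
    reports no residual df, e.g. mixed models): near-saturated fits —
    few nonzero observations, many coefficients — can produce tiny,
    unreliable standard errors, and a normal reference would turn those
    into spuriously extreme p-values. With fewer than two usable fits
    the raw against-zero p-values are kept and a warning is logged.
    """
    usable = [e for e in estimates
              if e.coefficient == coefficient and e.error is None]
    if len(usable) < 2:
        logger.warning(
            "median comparison for %r skipped: <2 usable fits", coefficient)
        return None, {e.feature: e.p_raw for e in usable}
    betas = np.array([e.beta for e in usable])
    ses = np.array([e.se for e in usable])
    dfs = np.array([e.df for e in usable])
    med = float(np.median(betas))
    var_med = median_bootstrap_variance(betas, ses, rng, n_boot)
    z = (betas - med) / np.sqrt(ses ** 2 + var_med)
    have_df = np.isfinite(dfs) & (dfs > 0)
    pvals = np.where(
        have_df,
        2 * stats.t.sf(np.abs(z), np.where(have_df, dfs, 1.0)),
        2 * stats.norm.sf(np.abs(z)),
    )
    summary = MedianSummary(
        coefficient=coefficient, median=med, median_var=var_med,
        n_features_used=len(usable),
    )
    return summary, {e.feature: float(p) for e, p in zip(usable, pvals)}


def subtract_median(
    estimates: list[CoefficientEstimate], summary: MedianSummary
) -> list[CoefficientEstimate]:
    """Report median-subtracted coefficients (standard errors unchanged).

    Off by default: the raw relative-scale coefficients are usually
    easier to interpret, but the subtracted versions estimate the
    absolute-scale effects under the median assumption.
    """
    out = []
    for e in estimates:
        if e.coefficient == summary.coefficient and e.error is None:
            out.append(replace(e, beta=e.beta - summary.median))
        else:
            out.append(e)
    return out
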