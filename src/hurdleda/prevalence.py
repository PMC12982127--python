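"""Weighted-augmented logistic prevalence models.

Presence/absence of each feature is regressed on the covariates by
weighted maximum-likelihood logistic regression. To guard against
linear separability — common when a feature is present in only a few
samples — every original observation is augmented with one artificial
presence and one artificial absence carrying identical covariates and
a small weight, so the total augmented weight equals the number of
covariate columns g. This is equivalent to a Diaconis-Ylvisaker
conjugate prior centered at prevalence 1/2 and keeps all estimates
finite while extending naturally to random-intercept models.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from ._glmm import fit_weighted_logistic_mixed
from .abundance import CoefficientEstimate, FeatureFit, _error_estimates, _feature_design
from .model import INTERCEPT, ModelSpec, DesignInfo, build_design
from .preprocess import SplitData

logger = logging.getLogger(__name__)


@dataclass
class AugmentedDesign:
    """The 3n-row augmented response/design/weights triple."""

    response: np.ndarray   # length 3n: [B; 1; 0]
    design: np.ndarray     # 3n x (g+1): [X; X; X]
    weights: np.ndarray    # [1]*n + [g/(2n)]*2n
    groups: np.ndarray | None = None


@dataclass
class PrevalenceFlag:
    """Per-association marker for likely abundance-induced prevalence."""

    feature: str
    coefficient: str
    abundance_induced: bool
    reason: str


def augment(
    presence_column: np.ndarray,
    design: np.ndarray,
    groups: np.ndarray | None = None,
    g: int | None = None,
) -> AugmentedDesign:
    """Stack one artificial presence and one artificial absence per sample.

    ``g`` is the number of fixed-effect covariate columns excluding the
    intercept (inferred from the design width when not given). The 2n
    augmented rows each get weight ``g/(2n)`` so their total weight is
    equivalent to g extra samples.
    """
    B = np.asarray(presence_column, dtype=float)
    X = np.asarray(design, dtype=float)
    n = len(B)
    if n < 1:
        raise ValueError("empty presence vector")
    if g is None:
        g = max(X.shape[1] - 1, 1)
    response = np.concatenate([B, np.ones(n), np.zeros(n)])
    design3 = np.vstack([X, X, X])
    weights = np.concatenate([np.ones(n), np.full(2 * n, g / (2.0 * n))])
    groups3 = np.concatenate([groups] * 3) if groups is not None else None
    return AugmentedDesign(response=response, design=design3,
                           weights=weights, groups=groups3)


def _weighted_logistic(y, X, w, tol=1e-8, maxiter=200):
    """Weighted logistic MLE via statsmodels GLM; Wald inference."""
    import statsmodels.api as sm

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = sm.GLM(y, X, family=sm.families.Binomial(), freq_weights=w)
        res = model.fit(maxiter=maxiter, tol=tol)
    if not getattr(res, "converged", True):
        raise ValueError("logistic model did not converge")
    beta = np.asarray(res.params)
    se = np.asarray(res.bse)
    cov = np.asarray(res.cov_params())
    pvals = 2 * stats.norm.sf(np.abs(beta / se))
    return beta, se, cov, pvals, float(res.llf)


def fit_prevalence(
    split: SplitData,
    metadata: pd.DataFrame,
    spec: ModelSpec,
    design: DesignInfo | None = None,
    collect_fits: dict | None = None,
) -> list[CoefficientEstimate]:
    """Fit the augmented logistic model one feature at a time.

    Features present in every sample or absent from every sample carry
    no prevalence information and yield error records. Random
    intercepts are fitted by Gauss-Hermite marginal likelihood with the
    augmentation rows and weights retained.
    """
    if design is None:
        design = build_design(metadata, spec)
    mixed = bool(spec.random_intercept_groups)
    group_col = spec.random_intercept_groups[0] if mixed else None
    estimates: list[CoefficientEstimate] = []

    for feature in split.presence.columns:
        pres_all = split.presence[feature]
        X, fsc_name, err = _feature_design(design, spec, feature, pres_all.index)
        if err is not None:
            estimates.extend(_error_estimates(
                feature, design, "prevalence", err,
                fsc_name=spec.feature_specific_name
                if spec.feature_specific_covariate is not None else None))
            continue
        B = pres_all.loc[X.index].to_numpy(dtype=float)
        n = len(B)
        if B.sum() == n:
            estimates.extend(_error_estimates(
                feature, design, "prevalence", "no absence variation",
                fsc_name=fsc_name))
            continue
        if B.sum() == 0:
            estimates.extend(_error_estimates(
                feature, design, "prevalence", "no presence variation",
                fsc_name=fsc_name))
            continue
        groups = metadata.loc[X.index, group_col].to_numpy() if mixed else None
        g = design.n_covariate_columns + (1 if fsc_name else 0)
        if spec.augment:
            aug = augment(B, X.to_numpy(dtype=float), groups=groups, g=g)
            y, Xv, w, grp = aug.response, aug.design, aug.weights, aug.groups
        else:
            y, Xv, w, grp = B, X.to_numpy(dtype=float), np.ones(n), groups
        try:
            if np.linalg.matrix_rank(Xv) < Xv.shape[1]:
                raise np.linalg.LinAlgError("rank-deficient design")
            if mixed:
                fitres = fit_weighted_logistic_mixed(y, Xv, w, grp)
                if not fitres["converged"]:
                    raise ValueError("mixed logistic model did not converge")
                beta, se, cov = fitres["beta"], fitres["se"], fitres["cov"]
                pvals = 2 * stats.norm.sf(np.abs(beta / se))
                ll = fitres["loglik"]
            else:
                beta, se, cov, pvals, ll = _weighted_logistic(y, Xv, w)
        except (np.linalg.LinAlgError, ValueError) as exc:
            estimates.extend(_error_estimates(
                feature, design, "prevalence", f"fit failed: {exc}",
                fsc_name=fsc_name))
            continue
        names = list(X.columns)
        if collect_fits is not None:
            collect_fits[feature] = FeatureFit(
                feature=feature, model="prevalence",
                params=pd.Series(beta, index=names),
                cov=pd.DataFrame(cov[:len(names), :len(names)],
                                 index=names, columns=names),
                df_resid=None, n_obs=n, loglik=ll,
                y=y, X=pd.DataFrame(Xv, columns=names),
                weights=w, groups=grp,
            )
        for i, coef in enumerate(names):
            if coef == INTERCEPT:
                continue
            estimates.append(CoefficientEstimate(
                feature=feature, coefficient=coef,
                variable=design.coef_to_var.get(coef, coef),
                model="prevalence", beta=float(beta[i]), se=float(se[i]),
                df=np.nan, p_raw=float(pvals[i]), n_obs=n,
            ))
    return estimates


def screen_abundance_induced(
    prevalence_estimates: list[CoefficientEstimate],
    abundance_vs_zero: list[CoefficientEstimate],
    fdr_level: float = 0.1,
) -> list[PrevalenceFlag]:
    """Flag prevalence effects likely induced by abundance changes.

    With finite read depth, a genuine decrease in a feature's abundance
    pushes it below the detection limit more often, masquerading as a
    prevalence effect. A prevalence association is flagged when, in a
    plain linear fit of the log2 relative abundances tested against
    zero (not the median): (1) the abundance q-value is significant,
    (2) the abundance and prevalence coefficients share a sign, and
    (3) the abundance coefficient has the larger magnitude. The q-pool
    is all features x coefficients of the screening fit.
    """
    from .inference import bh_fdr

    ab = {(e.feature, e.coefficient): e for e in abundance_vs_zero
          if e.error is None}
    keys = list(ab)
    qvals = bh_fdr(np.array([ab[k].p_raw for k in keys])) if keys else np.array([])
    qmap = dict(zip(keys, qvals))
    flags = []
    for e in prevalence_estimates:
        key = (e.feature, e.coefficient)
        if e.error is not None:
            flags.append(PrevalenceFlag(e.feature, e.coefficient, False,
                                        "prevalence fit errored"))
            continue
        if key not in ab:
            flags.append(PrevalenceFlag(e.feature, e.coefficient, False,
                                        "no abundance fit"))
            continue
        a = ab[key]
        cond1 = qmap[key] < fdr_level
        cond2 = np.sign(a.beta) == np.sign(e.beta)
        cond3 = abs(a.beta) > abs(e.beta)
        flagged = bool(cond1 and cond2 and cond3)
        reason = ("abundance q={:.3g}, sign match, larger magnitude"
                  .format(qmap[key]) if flagged else "")
        flags.append(PrevalenceFlag(e.feature, e.coefficient, flagged, reason))
    return flags


def inclusion_logodds(r: float, n: float) -> float:
    """Exact log odds that a feature with relative abundance r yields
    at least one read at depth n, under Binomial(n, r) sampling.

    log((1 - (1-r)^n) / (1-r)^n); approximately n*r for small r with
    n > 2/r, which is why untransformed read depth is the natural
    covariate when depth correlates with the metadata of interest.
    """
    if not 0.0 < r < 1.0:
        raise ValueError("relative abundance must be strictly in (0, 1)")
    if n < 1:
        raise ValueError("read depth must be >= 1")
    log_miss = n * np.log1p(-r)            # log (1-r)^n
    # log(1 - exp(log_miss)) computed stably
    if log_miss > -1e-10:
        log_hit = np.log(-log_miss)        # ~log(x) as 1-e^{-x} -> x
    else:
        log_hit = np.log1p(-np.exp(log_miss))
    return float(log_hit - log_miss)
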