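"""Scoring discovered associations against simulation ground truth.

Two matching rules are supported. ``any_type`` credits a discovery that
names the right feature and metadatum regardless of whether it was
called as an abundance or prevalence association (the fair rule when
comparing against tools that do not report a type). ``type_matched``
additionally requires the association type to agree, isolating how
well the hurdle components attribute effects.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .inference import AssociationRecord, decide_significance, fit_hurdle
from .model import ModelSpec
from .simulate import SimulationTruth, SyntheticDataset, simulate_dataset

logger = logging.getLogger(__name__)


@dataclass
class EvaluationReport:
    """Precision/recall/F1 plus effect-size recovery metrics.

    ``precision`` is None when nothing was discovered (undefined, and
    excluded from cell averages rather than coerced to 0 or 1).
    ``shrinkage_error`` is mean((|fit| - |true|)/|true|) over
    significant type-matched true positives; ``effect_correlation`` is
    the per-metadatum Spearman correlation of fitted versus true
    coefficients (true 0 where nothing was planted), averaged over
    metadata.
    """

    precision: float | None
    recall: float
    f1: float | None
    shrinkage_error: float | None
    effect_correlation: float | None
    n_tp: int
    n_fp: int
    n_fn: int
    matching_mode: str


def _truth_keys(truth: SimulationTruth, typed: bool) -> set:
    if typed:
        return set(zip(truth.table["feature"], truth.table["metadatum"],
                       truth.table["type"]))
    return set(zip(truth.table["feature"], truth.table["metadatum"]))


def _discovered_keys(records: list[AssociationRecord], typed: bool) -> set:
    keys = set()
    for r in records:
        if not r.significant or r.model not in ("abundance", "prevalence"):
            continue
        keys.add((r.feature, r.variable, r.model) if typed
                 else (r.feature, r.variable))
    return keys


def match_associations(
    records: list[AssociationRecord],
    truth: SimulationTruth,
    mode: str = "any_type",
) -> tuple[set, set, set]:
    """True-positive, false-positive and false-negative key sets.

    Keys are (feature, metadatum) in ``any_type`` mode (duplicate
    discoveries of one pair count once) and (feature, metadatum, type)
    in ``type_matched`` mode.
    """
    if mode not in ("any_type", "type_matched"):
        raise ValueError(f"unknown matching mode {mode!r}")
    typed = mode == "type_matched"
    truth_keys = _truth_keys(truth, typed)
    found = _discovered_keys(records, typed)
    tp = found & truth_keys
    fp = found - truth_keys
    fn = truth_keys - found
    return tp, fp, fn


def shrinkage_error(
    records: list[AssociationRecord], truth: SimulationTruth
) -> float | None:
    """Relative coefficient shrinkage over significant true positives.

    mean((|beta_hat| - |beta|) / |beta|) over significant records whose
    (feature, metadatum, type) matches a finite-effect truth row; 0 is
    optimal, negative means shrinkage toward zero.
    """
    true_map = {(r.feature, r.metadatum, r.type): r.effect
                for r in truth.table.itertuples()
                if np.isfinite(r.effect)}
    vals = []
    for r in records:
        if not r.significant:
            continue
        key = (r.feature, r.variable, r.model)
        if key in true_map:
            b = true_map[key]
            vals.append((abs(r.beta) - abs(b)) / abs(b))
    if not vals:
        return None
    return float(np.mean(vals))


def effect_correlation(
    records: list[AssociationRecord], truth: SimulationTruth
) -> float | None:
    """Per-metadatum Spearman correlation of fitted vs true coefficients.

    For every (feature, metadatum) the true coefficient is the planted
    effect (0 when nothing was planted; infinite-effect rows skipped)
    and the fitted coefficient comes from the model component matching
    the truth type, defaulting to the abundance component for null
    pairs. Constant vectors are skipped with a warning; the returned
    value averages the per-metadatum correlations.
    """
    fitted = {(r.feature, r.variable, r.model): r.beta for r in records
              if r.error is None and r.model in ("abundance", "prevalence")}
    true_map = {}
    for r in truth.table.itertuples():
        if np.isfinite(r.effect):
            true_map[(r.feature, r.metadatum)] = (r.type, r.effect)
    metadata_vars = sorted({r.variable for r in records
                            if r.model in ("abundance", "prevalence")})
    features = sorted({r.feature for r in records})
    corrs = []
    for var in metadata_vars:
        xs, ys = [], []
        for f in features:
            typ, eff = true_map.get((f, var), ("abundance", 0.0))
            beta = fitted.get((f, var, typ))
            if beta is None or not np.isfinite(beta):
                continue
            xs.append(eff)
            ys.append(beta)
        if len(xs) < 3 or len(set(xs)) < 2 or len(set(ys)) < 2:
            logger.warning("metadatum %r skipped in effect correlation", var)
            continue
        rho = sps.spearmanr(xs, ys).statistic
        corrs.append(rho)
    if not corrs:
        return None
    return float(np.mean(corrs))


def evaluate_run(
    records: list[AssociationRecord],
    truth: SimulationTruth,
    mode: str = "any_type",
) -> EvaluationReport:
    """Score one analyzed dataset against its ground truth."""
    tp, fp, fn = match_associations(records, truth, mode)
    n_tp, n_fp, n_fn = len(tp), len(fp), len(fn)
    precision = n_tp / (n_tp + n_fp) if (n_tp + n_fp) else None
    recall = n_tp / (n_tp + n_fn) if (n_tp + n_fn) else 0.0
    if precision is None or precision + recall == 0:
        f1 = None
    else:
        f1 = 2 * precision * recall / (precision + recall)
    return EvaluationReport(
        precision=precision, recall=recall, f1=f1,
        shrinkage_error=shrinkage_error(records, truth),
        effect_correlation=effect_correlation(records, truth),
        n_tp=n_tp, n_fp=n_fp, n_fn=n_fn, matching_mode=mode,
    )


def fp_small_prevalence_fraction(
    records: list[AssociationRecord],
    truth: SimulationTruth,
    cutoff: float = 1.0,
) -> tuple[int, int]:
    """Among any-type false discoveries, how many have a prevalence
    coefficient with magnitude below ``cutoff``.

    Returns (n_small, n_false_discoveries_with_prevalence_coefficient).
    """
    _, fp, _ = match_associations(records, truth, "any_type")
    prev_beta = {(r.feature, r.variable): r.beta for r in records
                 if r.model == "prevalence" and r.error is None}
    n_small = n_tot = 0
    for key in fp:
        if key in prev_beta and np.isfinite(prev_beta[key]):
            n_tot += 1
            if abs(prev_beta[key]) < cutoff:
                n_small += 1
    return n_small, n_tot


def _default_spec(metadata: pd.DataFrame, dataset: SyntheticDataset) -> ModelSpec:
    spec = ModelSpec(
        fixed_terms=list(metadata.columns),
        median_comparison=True,
        subtract_median=True,   # report absolute-scale estimates in benchmarks
        augment=True,
        screen_prevalence=True,
        fdr_level=0.1,
    )
    if dataset.individual_ids is not None:
        spec.random_intercept_groups = ["individual"]
    return spec


def analyze_dataset(
    dataset: SyntheticDataset,
    spec: ModelSpec | None = None,
    use_spike_in: bool = False,
    seed: int = 0,
) -> list[AssociationRecord]:
    """Run the full pipeline on one simulated dataset."""
    metadata = dataset.metadata.copy()
    if dataset.individual_ids is not None:
        metadata["individual"] = dataset.individual_ids
    if spec is None:
        spec = _default_spec(dataset.metadata, dataset)
    spike = dataset.spike_in if use_spike_in else None
    return fit_hurdle(dataset.counts, metadata, spec, spike_in=spike,
                      seed=seed)


def run_benchmark(
    sample_sizes: list[int],
    replicates: int = 20,
    mode: str = "zero_inflated",
    m: int = 100,
    g: int = 5,
    assoc_fraction: float = 0.1,
    effect_range: tuple[float, float] = (2.5, 5.0),
    depth_mean: float = 50_000,
    samples_per_individual: int = 1,
    matching_mode: str = "any_type",
    seed: int = 0,
) -> pd.DataFrame:
    """Simulate -> fit -> evaluate over a grid of sample sizes.

    Returns a long-format table with one row per (sample size,
    replicate); replicate failures are logged and omitted from the
    table so cell means are computed over survivors. Child seeds are
    derived deterministically from the master seed, so a fixed seed
    reproduces the table exactly.
    """
    rows = []
    for si, n in enumerate(sample_sizes):
        for rep in range(replicates):
            child = np.random.SeedSequence([seed, si, rep]).generate_state(1)[0] % (2**31)
            try:
                if mode == "ancombc":
                    ds = simulate_ancombc_wrapper(n, m, depth_mean, child)
                else:
                    ds = simulate_dataset(
                        n=n, m=m, g=g, assoc_fraction=assoc_fraction,
                        effect_range=effect_range, depth_mean=depth_mean,
                        zero_mode=mode if mode in ("zero_inflated",
                                                   "sequencing_only")
                        else "zero_inflated",
                        samples_per_individual=samples_per_individual,
                        seed=int(child),
                    )
                records = analyze_dataset(ds, seed=int(child))
                report = evaluate_run(records, ds.truth, matching_mode)
            except Exception:
                logger.exception("replicate n=%d rep=%d failed", n, rep)
                continue
            rows.append({
                "mode": mode, "n_samples": n, "replicate": rep,
                "precision": report.precision, "recall": report.recall,
                "f1": report.f1, "shrinkage_error": report.shrinkage_error,
                "effect_correlation": report.effect_correlation,
                "n_tp": report.n_tp, "n_fp": report.n_fp, "n_fn": report.n_fn,
            })
    return pd.DataFrame(rows)


def simulate_ancombc_wrapper(n: int, m: int, depth_mean: float, seed: int):
    from .simulate import simulate_ancombc

    return simulate_ancombc(m=m, n_per_group=n // 2, depth_mean=depth_mean,
                            seed=int(seed))


def summarize_benchmark(results: pd.DataFrame) -> pd.DataFrame:
    """Cell means and standard deviations over replicates."""
    metrics = ["precision", "recall", "f1", "shrinkage_error",
               "effect_correlation"]
    return (results.groupby(["mode", "n_samples"])[metrics]
            .agg(["mean", "std"]).reset_index())
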