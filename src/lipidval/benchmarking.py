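"""Alternative validation strategies for separating case-mix from drift.

A drop in external performance can reflect (a) a less favourable case-mix in
the new population, (b) genuinely shifted predictor effects, or (c) limits of
the predictors themselves. Three complementary strategies triangulate:

* **Case-mix reference values** — bootstrap the validation cohort and, in
  each replicate, simulate outcomes from the model's own predicted
  probabilities (complete transferability of coefficients). The resulting
  AuROC distribution shows what discrimination the case-mix alone supports,
  and slope/CITL centre on 1/0 by construction; percentile intervals come
  from the replicate distribution. The benchmark depends only on predictors,
  never on the observed outcomes.
* **Refitting** — re-estimate all coefficients on the validation data
  (case-mix plus coefficient shift absorbed).
* **Imputed metabolic age** — replace the device-measured metabolic age by
  its linear proxy from age, BMI and gender before scoring, to check that
  model performance survives indirect measurement.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from . import models, performance, update
from .exceptions import DegenerateInputError, EstimationError, ParameterError

STRATEGIES = ("temporal", "casemix_reference", "refit", "imputed_metage")
STAGES = ("before_update", "after_recalibration")


@dataclass(frozen=True)
class BenchmarkResult:
    strategy: str
    stage: str
    auroc: performance.MetricEstimate
    c_slope: performance.MetricEstimate
    citl: performance.MetricEstimate
    replications: int = 1
    skipped: int = 0
    seed: int | None = None


def _percentile_estimate(draws: np.ndarray, method: str) -> performance.MetricEstimate:
    lo, hi = np.percentile(draws, [2.5, 97.5])
    return performance.MetricEstimate(
        float(np.mean(draws)), float(np.std(draws, ddof=1)) if draws.size > 1 else 0.0,
        float(min(lo, np.mean(draws))), float(max(hi, np.mean(draws))), method,
    )


def casemix_reference(cohort: pd.DataFrame, model: models.LogisticModel,
                      B: int = 1000, seed: int = 0,
                      require_ci: bool = True) -> BenchmarkResult:
    """Case-mix-adjusted reference performance by outcome simulation.

    Each of ``B`` replications resamples ``n`` participants with replacement,
    draws outcomes from the model's predicted probabilities, and recomputes
    AuROC, C-slope and CITL. Replications where the simulated outcome is
    single-class (or the fit separates) are skipped and counted; more than
    10% skips aborts.
    """
    if B < 1:
        raise ParameterError("B must be >= 1")
    if require_ci and B < 100:
        raise ParameterError("need B >= 100 for percentile CIs")
    p = np.asarray(models.predicted_probability(model, cohort), dtype=float)
    lp = np.asarray(models.linear_predictor(model, cohort), dtype=float)
    n = p.size
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    aucs, slopes, citls = [], [], []
    skipped = 0
    for _ in range(B):
        idx = rng.integers(0, n, size=n)
        y = (rng.random(n) < p[idx]).astype(int)
        try:
            a, b = performance.recalibration_fit(y, lp[idx])
            c = performance.citl(y, lp[idx]).value
            auc = performance.auroc(y, p[idx]).value
        except (DegenerateInputError, EstimationError):
            skipped += 1
            continue
        aucs.append(auc)
        slopes.append(b)
        citls.append(c)
    if skipped > 0.1 * B:
        raise EstimationError(
            f"{skipped}/{B} case-mix replications degenerate; cohort too "
            "small or risk distribution too extreme"
        )
    method = "bootstrap-percentile"
    return BenchmarkResult(
        strategy="casemix_reference", stage="before_update",
        auroc=_percentile_estimate(np.array(aucs), method),
        c_slope=_percentile_estimate(np.array(slopes), method),
        citl=_percentile_estimate(np.array(citls), method),
        replications=B, skipped=skipped, seed=seed,
    )


def _from_report(rep: performance.ValidationReport, strategy: str,
                 stage: str) -> BenchmarkResult:
    return BenchmarkResult(strategy=strategy, stage=stage, auroc=rep.auroc,
                           c_slope=rep.c_slope, citl=rep.citl)


def with_imputed_metage(cohort: pd.DataFrame) -> pd.DataFrame:
    """Copy of the cohort with metabolic age replaced by its linear proxy."""
    for col in ("age", "bmi", "male"):
        if col not in cohort.columns:
            raise ParameterError(f"cohort has no column {col!r} needed for imputation")
    out = cohort.copy()
    out["metabolic_age"] = models.impute_metabolic_age(
        cohort["age"], cohort["bmi"], cohort["male"]
    )
    return out


def strategy_matrix(cohort: pd.DataFrame, model: models.LogisticModel,
                    endpoint: str | None = None, B: int = 1000,
                    seed: int = 0,
                    casemix_lp: str = "original") -> list[BenchmarkResult]:
    """Run all validation strategies; returns one result row per cell.

    ``casemix_lp`` selects whether the after-update case-mix benchmark
    simulates outcomes from the original or the recalibrated model's
    predictions ("original" or "updated").
    """
    if casemix_lp not in ("original", "updated"):
        raise ParameterError(f"casemix_lp {casemix_lp!r} not recognised")
    endpoint = endpoint or model.endpoint
    recal = update.recalibrate(model, cohort, endpoint)
    results = [
        _from_report(recal.pre_metrics, "temporal", "before_update"),
        _from_report(recal.post_metrics, "temporal", "after_recalibration"),
    ]

    cm_before = casemix_reference(cohort, model, B=B, seed=seed)
    results.append(cm_before)
    after_model = model if casemix_lp == "original" else recal.updated_model
    cm_after = casemix_reference(cohort, after_model, B=B, seed=seed + 1)
    results.append(BenchmarkResult(
        strategy="casemix_reference", stage="after_recalibration",
        auroc=cm_after.auroc, c_slope=cm_after.c_slope, citl=cm_after.citl,
        replications=cm_after.replications, skipped=cm_after.skipped,
        seed=cm_after.seed,
    ))

    refitted = update.refit(cohort, list(model.terms), endpoint)
    results.append(_from_report(
        performance.validate(cohort, refitted, endpoint),
        "refit", "after_recalibration",
    ))

    imputed = with_imputed_metage(cohort)
    results.append(_from_report(
        performance.validate(imputed, model, endpoint),
        "imputed_metage", "before_update",
    ))
    imput_recal = update.recalibrate(model, imputed, endpoint)
    results.append(_from_report(
        imput_recal.post_metrics, "imputed_metage", "after_recalibration",
    ))
    return results


def matrix_to_frame(results: list[BenchmarkResult]) -> pd.DataFrame:
    """Strategy-by-stage table of the three headline metrics."""
    rows = []
    for r in results:
        rows.append({
            "strategy": r.strategy,
            "stage": r.stage,
            "auroc": r.auroc.value, "auroc_lo": r.auroc.ci_low,
            "auroc_hi": r.auroc.ci_high,
            "c_slope": r.c_slope.value, "c_slope_lo": r.c_slope.ci_low,
            "c_slope_hi": r.c_slope.ci_high,
            "citl": r.citl.value, "citl_lo": r.citl.ci_low,
            "citl_hi": r.citl.ci_high,
            "replications": r.replications, "skipped": r.skipped,
        })
    return pd.DataFrame(rows)


def evaluate_imputation(cohort: pd.DataFrame) -> dict:
    """Linear calibration of observed on proxy-imputed metabolic age.

    Returns R-squared, linear CITL (mean residual, observed minus imputed)
    and the OLS slope of observed on imputed metabolic age.
    """
    if "metabolic_age" not in cohort.columns:
        raise ParameterError("cohort has no column 'metabolic_age'")
    observed = cohort["metabolic_age"].to_numpy(dtype=float)
    imputed = np.asarray(models.impute_metabolic_age(
        cohort["age"], cohort["bmi"], cohort["male"]
    ), dtype=float)
    if np.ptp(imputed) == 0:
        raise DegenerateInputError("imputed metabolic age has zero variance")
    fit = stats.linregress(imputed, observed)
    slope, r = fit.slope, fit.rvalue
    return {
        "n": int(observed.size),
        "r_squared": float(r ** 2),
        "citl": float(np.mean(observed - imputed)),
        "c_slope": float(slope),
    }
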