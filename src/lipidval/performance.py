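"""Discrimination and calibration of a risk model on a labelled cohort.

Discrimination is the area under the non-parametric ROC curve (AuROC), i.e.
the Mann-Whitney concordance probability with ties counted one half, with a
DeLong variance estimator for the confidence interval. Calibration is
summarised by three standard quantities on the linear-predictor (LP) scale:

* calibration-in-the-large (CITL): maximum-likelihood intercept ``a`` of
  ``logit P(y=1) = a + LP`` with the LP as a fixed offset — 0 means overall
  risk is neither over- nor under-estimated;
* calibration slope (C-slope): slope ``b`` of ``logit P(y=1) = a + b*LP``
  with the intercept re-estimated jointly — values below 1 mean predictions
  are too extreme (risk overestimated at the high end);
* E:O ratio: mean predicted risk over observed event rate, with a log-normal
  interval based on SE(ln E:O) = sqrt((1-phi)/(n*phi)).

A calibration curve (quantile bins with exact binomial intervals, or a local
smoother) supports plotting observed against predicted risk.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from statsmodels.tools.sm_exceptions import (PerfectSeparationError,
                                             PerfectSeparationWarning)

from . import cohort as cohort_mod
from . import models
from .exceptions import DegenerateInputError, EstimationError, ParameterError

Z95 = stats.norm.ppf(0.975)

#: Probabilities are clipped here before any logit to avoid infinities.
P_EPS = 1e-12


@dataclass(frozen=True)
class MetricEstimate:
    """Point estimate with standard error and 95% confidence interval."""

    value: float
    se: float
    ci_low: float
    ci_high: float
    method: str

    def __post_init__(self) -> None:
        if np.isnan(self.value):
            return  # null placeholder for flagged (degenerate) rows
        if self.se < 0:
            raise ParameterError("se must be >= 0")
        if not self.ci_low <= self.value <= self.ci_high:
            raise ParameterError("CI must bracket the point estimate")

    def covers(self, value: float) -> bool:
        return self.ci_low <= value <= self.ci_high


@dataclass(frozen=True)
class CalibrationCurve:
    """Observed event proportion against predicted risk."""

    points: pd.DataFrame  # columns: predicted, observed, ci_low, ci_high
    smoother: str
    bin_count: int | None = None


@dataclass(frozen=True)
class ValidationReport:
    """Full performance summary of one model on one cohort."""

    n: int
    events: int
    prevalence: float
    auroc: MetricEstimate
    c_slope: MetricEstimate
    citl: MetricEstimate
    eo_ratio: MetricEstimate
    curve: CalibrationCurve
    discrimination_label: str


def _as_binary(y) -> np.ndarray:
    y = np.asarray(y)
    if y.ndim != 1 or y.size == 0:
        raise ParameterError("y must be a non-empty 1-d vector")
    vals = np.unique(y)
    if not np.all(np.isin(vals, (0, 1))):
        raise ParameterError("y must be coded 0/1")
    return y.astype(int)


def _require_both_classes(y: np.ndarray) -> None:
    if y.min() == y.max():
        raise DegenerateInputError("both outcome classes must be present")


def _midrank(x: np.ndarray) -> np.ndarray:
    return stats.rankdata(x, method="average")


def auroc(y, p) -> MetricEstimate:
    """Mann-Whitney concordance with a DeLong-variance 95% CI."""
    y = _as_binary(y)
    p = np.asarray(p, dtype=float)
    if p.shape != y.shape:
        raise ParameterError("y and p must have equal length")
    _require_both_classes(y)

    pos, neg = p[y == 1], p[y == 0]
    m, n = pos.size, neg.size
    tz = _midrank(np.concatenate([pos, neg]))
    tx = _midrank(pos)
    ty = _midrank(neg)
    auc = (tz[:m].sum() - m * (m + 1) / 2) / (m * n)
    # DeLong structural components
    v10 = (tz[:m] - tx) / n
    v01 = 1.0 - (tz[m:] - ty) / m
    s10 = v10.var(ddof=1) if m > 1 else 0.0
    s01 = v01.var(ddof=1) if n > 1 else 0.0
    se = float(np.sqrt(s10 / m + s01 / n))
    lo = max(0.0, auc - Z95 * se)
    hi = min(1.0, auc + Z95 * se)
    return MetricEstimate(float(auc), se, lo, hi, "mann-whitney/delong")


def _glm_fit(y: np.ndarray, X: np.ndarray, offset=None):
    """Binomial GLM fit that converts failure modes into package errors."""
    try:
        with warnings.catch_warnings():
            # separation is detected and raised as EstimationError below
            warnings.simplefilter("ignore", PerfectSeparationWarning)
            res = sm.GLM(y, X, family=sm.families.Binomial(), offset=offset).fit()
    except PerfectSeparationError as exc:
        raise EstimationError(f"perfect separation: {exc}") from exc
    except (np.linalg.LinAlgError, ValueError) as exc:
        raise EstimationError(f"logistic fit failed: {exc}") from exc
    if not np.all(np.isfinite(res.params)) or not np.all(np.isfinite(res.bse)):
        raise EstimationError(
            f"logistic fit did not identify finite estimates (params={res.params})"
        )
    # (quasi-)separation drives the deviance to zero / coefficients to
    # infinity without IRLS failing; report it instead of a huge estimate
    if res.deviance < 1e-7 or np.abs(res.params).max() > 1e2:
        raise EstimationError(
            "perfect or quasi-complete separation: slope estimate diverges"
        )
    return res


def citl(y, lp) -> MetricEstimate:
    """Calibration-in-the-large: MLE intercept with the LP as offset."""
    y = _as_binary(y)
    lp = np.asarray(lp, dtype=float)
    _require_both_classes(y)
    res = _glm_fit(y, np.ones((y.size, 1)), offset=lp)
    a, se = float(res.params[0]), float(res.bse[0])
    return MetricEstimate(a, se, a - Z95 * se, a + Z95 * se, "glm-offset/wald")


def calibration_slope(y, lp) -> MetricEstimate:
    """Calibration slope from logit = a + b*LP (intercept refit jointly)."""
    y = _as_binary(y)
    lp = np.asarray(lp, dtype=float)
    _require_both_classes(y)
    if np.ptp(lp) == 0:
        raise DegenerateInputError("LP is constant; slope is unidentifiable")
    X = np.column_stack([np.ones_like(lp), lp])
    res = _glm_fit(y, X)
    b, se = float(res.params[1]), float(res.bse[1])
    return MetricEstimate(b, se, b - Z95 * se, b + Z95 * se, "glm-joint/wald")


def recalibration_fit(y, lp) -> tuple[float, float]:
    """Joint MLE (intercept, slope) of the recalibration model; shared with
    :mod:`lipidval.update` and :mod:`lipidval.fairness`."""
    y = _as_binary(y)
    lp = np.asarray(lp, dtype=float)
    _require_both_classes(y)
    if np.ptp(lp) == 0:
        raise DegenerateInputError("LP is constant; slope is unidentifiable")
    res = _glm_fit(y, np.column_stack([np.ones_like(lp), lp]))
    return float(res.params[0]), float(res.params[1])


def eo_ratio(y, p) -> MetricEstimate:
    """Expected-to-observed ratio with a log-normal 95% interval."""
    y = _as_binary(y)
    p = np.asarray(p, dtype=float)
    if p.shape != y.shape:
        raise ParameterError("y and p must have equal length")
    phi = y.mean()
    if phi == 0:
        raise DegenerateInputError("E:O undefined with zero events")
    ratio = float(p.mean() / phi)
    se_log = float(np.sqrt((1 - phi) / (y.size * phi)))
    lo = ratio * np.exp(-Z95 * se_log)
    hi = ratio * np.exp(Z95 * se_log)
    # delta-method SE on the ratio scale for reporting
    return MetricEstimate(ratio, ratio * se_log, lo, hi, "lognormal")


def calibration_curve(y, p, smoother: str = "quantile_bins",
                      bins: int = 10, span: float = 0.75) -> CalibrationCurve:
    """Calibration-plot points: quantile bins or a local (lowess) smoother."""
    y = _as_binary(y)
    p = np.clip(np.asarray(p, dtype=float), P_EPS, 1 - P_EPS)
    if smoother == "quantile_bins":
        if y.size < 10 * bins:
            raise ParameterError(
                f"need at least {10 * bins} records for {bins} bins, got {y.size}"
            )
        if np.ptp(p) == 0:
            # constant risk: one effective point
            k, n = int(y.sum()), int(y.size)
            ci = stats.binomtest(k, n).proportion_ci(0.95, method="exact")
            pts = pd.DataFrame(
                [(p[0], k / n, ci.low, ci.high)],
                columns=["predicted", "observed", "ci_low", "ci_high"],
            )
            return CalibrationCurve(pts, "quantile_bins", bins)
        grp = pd.qcut(p, bins, labels=False, duplicates="drop")
        rows = []
        for g in np.unique(grp):
            sel = grp == g
            k, n = int(y[sel].sum()), int(sel.sum())
            ci = stats.binomtest(k, n).proportion_ci(0.95, method="exact")
            rows.append((p[sel].mean(), k / n, ci.low, ci.high))
        pts = pd.DataFrame(rows, columns=["predicted", "observed", "ci_low", "ci_high"])
        pts = pts.sort_values("predicted", ignore_index=True)
        return CalibrationCurve(pts, "quantile_bins", bins)
    if smoother == "loess":
        sm_xy = sm.nonparametric.lowess(y, p, frac=span)
        pts = pd.DataFrame(sm_xy, columns=["predicted", "observed"])
        pts["observed"] = pts["observed"].clip(0.0, 1.0)
        pts["ci_low"] = np.nan
        pts["ci_high"] = np.nan
        return CalibrationCurve(pts, "loess", None)
    raise ParameterError(f"smoother {smoother!r} not recognised")


def discrimination_label(auc: float) -> str:
    """Hosmer-Lemeshow wording for an AuROC value."""
    if auc <= 0.5:
        return "no discrimination"
    if auc <= 0.7:
        return "poor"
    if auc <= 0.8:
        return "acceptable"
    if auc <= 0.9:
        return "excellent"
    return "outstanding"


def validate(cohort: pd.DataFrame, model: models.LogisticModel,
             endpoint: str | None = None, smoother: str = "quantile_bins",
             bins: int = 10) -> ValidationReport:
    """Score a labelled cohort with ``model`` and assemble the full report."""
    endpoint = endpoint or model.endpoint
    ycol = cohort_mod.event_column(endpoint)
    if ycol not in cohort.columns:
        raise ParameterError(f"cohort has no outcome column {ycol!r}")
    y = _as_binary(cohort[ycol].to_numpy())
    lp = models.linear_predictor(model, cohort)
    p = models.predicted_probability(model, cohort)
    auc = auroc(y, p)
    return ValidationReport(
        n=int(y.size),
        events=int(y.sum()),
        prevalence=float(y.mean()),
        auroc=auc,
        c_slope=calibration_slope(y, lp),
        citl=citl(y, lp),
        eo_ratio=eo_ratio(y, p),
        curve=calibration_curve(y, p, smoother=smoother, bins=bins),
        discrimination_label=discrimination_label(auc.value),
    )


def report_to_dict(report: ValidationReport) -> dict:
    """JSON-friendly rendering of a ValidationReport (curve excluded)."""
    def m(est: MetricEstimate) -> dict:
        return {"value": est.value, "se": est.se,
                "ci_low": est.ci_low, "ci_high": est.ci_high, "method": est.method}

    return {
        "n": report.n,
        "events": report.events,
        "prevalence": report.prevalence,
        "auroc": m(report.auroc),
        "c_slope": m(report.c_slope),
        "citl": m(report.citl),
        "eo_ratio": m(report.eo_ratio),
        "discrimination_label": report.discrimination_label,
    }
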