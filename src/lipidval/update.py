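"""Model updating: logistic recalibration and full refitting.

Recalibration follows the standard two-parameter logistic framework: fit
``logit P(y=1) = alpha + beta * LP`` on the validation data and fold the
estimates back into the equation (coefficients scaled by beta, intercept
alpha + beta * original intercept). By joint maximum likelihood the updated
model is, by construction, perfectly calibrated on the data used to update
it (slope 1, CITL 0 up to solver tolerance).

A ``sequential`` variant estimates the intercept correction from the
slope-fixed-at-one offset model (the CITL) and the slope from the joint fit,
then applies both. Unlike the joint update this does not exactly zero out
same-data miscalibration, which can leave a post-update slope slightly off
one — offered for sensitivity analysis because published updates are not
always explicit about which variant was used.

Refitting re-estimates every coefficient from scratch on the validation data
and therefore absorbs both case-mix differences and genuine shifts in
predictor effects.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from . import cohort as cohort_mod
from . import models, performance
from .exceptions import DegenerateInputError, ParameterError


@dataclass(frozen=True)
class RecalibrationResult:
    alpha: float
    beta: float
    method: str
    updated_model: models.LogisticModel
    pre_metrics: performance.ValidationReport
    post_metrics: performance.ValidationReport


def _outcome(cohort: pd.DataFrame, endpoint: str) -> np.ndarray:
    ycol = cohort_mod.event_column(endpoint)
    if ycol not in cohort.columns:
        raise ParameterError(f"cohort has no outcome column {ycol!r}")
    return cohort[ycol].to_numpy()


def recalibrate(model: models.LogisticModel, cohort: pd.DataFrame,
                endpoint: str | None = None,
                method: str = "joint") -> RecalibrationResult:
    """Intercept/slope update of ``model`` on a labelled cohort."""
    endpoint = endpoint or model.endpoint
    y = _outcome(cohort, endpoint)
    lp = models.linear_predictor(model, cohort)
    if method == "joint":
        alpha, beta = performance.recalibration_fit(y, lp)
    elif method == "sequential":
        alpha = performance.citl(y, lp).value
        _, beta = performance.recalibration_fit(y, lp)
    else:
        raise ParameterError(f"method {method!r} not recognised")
    updated = model.scaled(alpha, beta)
    return RecalibrationResult(
        alpha=alpha,
        beta=beta,
        method=method,
        updated_model=updated,
        pre_metrics=performance.validate(cohort, model, endpoint),
        post_metrics=performance.validate(cohort, updated, endpoint),
    )


def refit(cohort: pd.DataFrame, terms: Sequence[str],
          endpoint: str, name: str | None = None) -> models.LogisticModel:
    """Full maximum-likelihood refit of a logistic model with ``terms``."""
    terms = list(terms)
    if not terms:
        raise ParameterError("term list must be non-empty")
    y = _outcome(cohort, endpoint)
    if len(cohort) <= 10 * len(terms):
        raise ParameterError(
            f"refit needs n > {10 * len(terms)} for {len(terms)} terms, "
            f"got n={len(cohort)}"
        )
    cols = []
    for t in terms:
        if t not in cohort.columns:
            raise ParameterError(f"cohort has no column {t!r}")
        x = cohort[t].to_numpy(dtype=float)
        if np.ptp(x) == 0:
            raise DegenerateInputError(f"term {t!r} has zero variance")
        cols.append(x)
    X = np.column_stack([np.ones(len(cohort))] + cols)
    res = performance._glm_fit(np.asarray(y, dtype=int), X)
    return models.LogisticModel(
        name=name or f"refit_{endpoint}",
        terms=dict(zip(terms, map(float, res.params[1:]))),
        intercept=float(res.params[0]),
        endpoint=endpoint,
        provenance="user_supplied",
    )


def log_likelihood(model: models.LogisticModel, cohort: pd.DataFrame,
                   endpoint: str | None = None) -> float:
    """Bernoulli log-likelihood of a model on a labelled cohort."""
    endpoint = endpoint or model.endpoint
    y = np.asarray(_outcome(cohort, endpoint), dtype=float)
    p = np.clip(models.predicted_probability(model, cohort),
                performance.P_EPS, 1 - performance.P_EPS)
    return float(np.sum(y * np.log(p) + (1 - y) * np.log1p(-p)))


def _fmt(x: float) -> str:
    """Signed 4-decimal coefficient, unicode minus as in the printed style."""
    s = f"{x:+.4f}"
    return s.replace("-", "−")


def emit_equation(model: models.LogisticModel) -> str:
    """Render a model as text in the published-equation style."""
    body = "".join(f"{_fmt(c)}*({name})" for name, c in model.terms.items())
    body = body.lstrip("+")
    lp = f"{body}{_fmt(model.intercept)}"
    return (
        f"Predicted probability [{model.name}, endpoint {model.endpoint}]\n"
        f"  = exp({lp}) / (1 + exp({lp}))\n"
    )
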