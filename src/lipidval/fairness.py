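"""Subgroup heterogeneity ("fairness") assessment of model performance.

Discrimination and calibration are recomputed within participant subgroups
(gender, ISCO occupation group, tertiles of continuous characteristics, or
user-supplied cuts). Subgroup AuROC is the covariate-conditional ROC area,
computed within each subgroup independently. Subgroup calibration comes from
a binomial GLM with full effect modification of intercept and slope by the
subgroup,

    logit P(y=1) = sum_g 1[g] * (a_g + b_g * LP),

whose saturated-interaction estimates coincide with independent per-group
recalibration fits; those per-group fits are what is computed.

Small subgroups (below 20 participants or 5 events) and single-class or
separated subgroups are reported as flagged rows with null estimates rather
than silently dropped, so the table always partitions the cohort.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from . import cohort as cohort_mod
from . import models, performance
from .exceptions import DegenerateInputError, EstimationError, ParameterError

#: Reporting floor: subgroups below this are flagged as unstable.
MIN_GROUP_N = 20
MIN_GROUP_EVENTS = 5


@dataclass(frozen=True)
class SubgroupDefinition:
    """How one covariate is cut into subgroups."""

    covariate: str
    scheme: str = "tertiles"           # categories | tertiles | custom_cuts
    cuts: Sequence[float] | None = None
    labels: Sequence[str] | None = None

    def __post_init__(self) -> None:
        if self.scheme not in ("categories", "tertiles", "custom_cuts"):
            raise ParameterError(f"scheme {self.scheme!r} not recognised")
        if self.scheme == "custom_cuts" and not self.cuts:
            raise ParameterError("custom_cuts scheme requires cut points")


def assign_groups(cohort: pd.DataFrame, definition: SubgroupDefinition) -> pd.Series:
    """Label each participant; the labels partition the cohort."""
    cov = definition.covariate
    if cov not in cohort.columns:
        raise ParameterError(f"cohort has no column {cov!r}")
    x = cohort[cov]
    if definition.scheme == "categories":
        return x.astype(str).rename("group")
    if definition.scheme == "tertiles":
        try:
            groups = pd.qcut(x.astype(float), 3, duplicates="drop")
        except ValueError as exc:
            raise ParameterError(f"cannot form tertiles of {cov!r}: {exc}") from exc
    else:
        edges = [-np.inf, *definition.cuts, np.inf]
        groups = pd.cut(x.astype(float), edges)
    out = groups.astype(str).rename("group")
    if definition.labels is not None:
        cats = list(pd.unique(out))
        if len(definition.labels) != len(cats):
            raise ParameterError(
                f"{len(cats)} groups formed but {len(definition.labels)} labels given"
            )
        out = out.map(dict(zip(cats, definition.labels)))
    return out


def _null_metric(note: str) -> performance.MetricEstimate:
    return performance.MetricEstimate(np.nan, 0.0, np.nan, np.nan, note)


def subgroup_auroc(y, p, groups) -> pd.DataFrame:
    """AuROC within each subgroup independently (conditioning, not pooling)."""
    y = np.asarray(y)
    p = np.asarray(p, dtype=float)
    groups = pd.Series(groups).reset_index(drop=True)
    rows = []
    for g in groups.unique():
        sel = (groups == g).to_numpy()
        try:
            est = performance.auroc(y[sel], p[sel])
            flag = ""
        except DegenerateInputError:
            est, flag = _null_metric("single-class"), "single-class"
        rows.append({"group": g, "n": int(sel.sum()), "events": int(y[sel].sum()),
                     "auroc": est.value, "auroc_lo": est.ci_low,
                     "auroc_hi": est.ci_high, "flag": flag})
    return pd.DataFrame(rows)


def subgroup_calibration(y, lp, groups) -> pd.DataFrame:
    """Per-group calibration slope and CITL (saturated effect modification)."""
    y = np.asarray(y)
    lp = np.asarray(lp, dtype=float)
    groups = pd.Series(groups).reset_index(drop=True)
    rows = []
    for g in groups.unique():
        sel = (groups == g).to_numpy()
        flag = ""
        try:
            slope = performance.calibration_slope(y[sel], lp[sel])
            c = performance.citl(y[sel], lp[sel])
        except (DegenerateInputError, EstimationError) as exc:
            slope = c = _null_metric(type(exc).__name__)
            flag = str(exc)
        rows.append({
            "group": g, "n": int(sel.sum()), "events": int(y[sel].sum()),
            "c_slope": slope.value, "c_slope_lo": slope.ci_low,
            "c_slope_hi": slope.ci_high,
            "citl": c.value, "citl_lo": c.ci_low, "citl_hi": c.ci_high,
            "flag": flag,
        })
    return pd.DataFrame(rows)


#: Derived covariates computable from richer record schemas when present.
DERIVED_COVARIATES = {
    "waist_to_height": ("waist_cm", "height_cm"),
    "fat_percentage": ("fat_mass_kg", "weight_kg"),
    "muscle_percentage": ("muscle_mass_kg", "weight_kg"),
}


def _with_derived(cohort: pd.DataFrame, covariate: str) -> pd.DataFrame | None:
    if covariate in cohort.columns:
        return cohort
    if covariate in DERIVED_COVARIATES:
        num, den = DERIVED_COVARIATES[covariate]
        if num in cohort.columns and den in cohort.columns:
            out = cohort.copy()
            out[covariate] = out[num] / out[den] * (
                100.0 if covariate.endswith("percentage") else 1.0
            )
            return out
    return None


def fairness_report(cohort: pd.DataFrame, model: models.LogisticModel,
                    definitions: Sequence[SubgroupDefinition],
                    endpoint: str | None = None) -> pd.DataFrame:
    """Subgroup AuROC/C-slope/CITL table over all requested covariates.

    Covariates absent from the cohort (including underivable derived ones)
    are omitted with a warning row; small subgroups are flagged.
    """
    endpoint = endpoint or model.endpoint
    ycol = cohort_mod.event_column(endpoint)
    if ycol not in cohort.columns:
        raise ParameterError(f"cohort has no outcome column {ycol!r}")
    frames = []
    for definition in definitions:
        data = _with_derived(cohort, definition.covariate)
        if data is None:
            frames.append(pd.DataFrame([{
                "covariate": definition.covariate, "group": "(unavailable)",
                "n": 0, "events": 0, "flag": "covariate not in cohort",
            }]))
            continue
        y = data[ycol].to_numpy()
        p = models.predicted_probability(model, data)
        lp = models.linear_predictor(model, data)
        groups = assign_groups(data, definition)
        disc = subgroup_auroc(y, p, groups)
        cal = subgroup_calibration(y, lp, groups).drop(columns=["n", "events"])
        tab = disc.merge(cal, on="group", suffixes=("", "_cal"))
        tab["flag"] = tab[["flag", "flag_cal"]].apply(
            lambda r: "; ".join(v for v in r if v), axis=1
        )
        tab = tab.drop(columns=["flag_cal"])
        small = (tab["n"] < MIN_GROUP_N) | (tab["events"] < MIN_GROUP_EVENTS)
        tab.loc[small, "flag"] = (
            tab.loc[small, "flag"].where(tab.loc[small, "flag"] != "", "")
            + " small-subgroup"
        ).str.strip()
        tab.insert(0, "covariate", definition.covariate)
        frames.append(tab)
    return pd.concat(frames, ignore_index=True)


def default_definitions(cohort: pd.DataFrame) -> list[SubgroupDefinition]:
    """Study covariate set: gender and ISCO as categories, the rest tertiles."""
    defs = [
        SubgroupDefinition("male", scheme="categories"),
        SubgroupDefinition("isco_code", scheme="categories"),
    ]
    for cov in ("bmi", "age", "fat_percentage", "muscle_percentage",
                "waist_to_height", "metabolic_age", "dbp"):
        defs.append(SubgroupDefinition(cov, scheme="tertiles"))
    return defs
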