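"""Published risk equations and the metabolic-age proxy.

Two diagnostic logistic models screen young adults (20-40 y) for elevated
serum cholesterol (>= 160 mg/dL):

* LDL-C model:     logit(p) = -2.6091 + 0.5542*male + 0.0155*metabolic_age
* non-HDL-C model: logit(p) = -3.1255 + 0.9008*male + 0.0294*metabolic_age
                              + 0.0100*dbp

``metabolic_age`` is a bioelectrical-impedance body-composition summary in
years; where the device output is unavailable it can be proxied by a linear
function of chronological age, BMI and gender (``impute_metabolic_age``).

Gender is coded male=1, female=0 throughout; loaders reject anything else.
Models are data (JSON/YAML files with keys ``name``, ``endpoint``,
``intercept``, ``terms``), so user-supplied coefficient sets (for example
the pre-recalibration development-cohort equations) plug into every
downstream stage unchanged.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from importlib import resources
from typing import Mapping

import numpy as np
import pandas as pd
import yaml
from scipy.special import expit

from .exceptions import ParameterError, SchemaError

#: Predictors any shipped model may reference.
KNOWN_PREDICTORS = ("male", "metabolic_age", "dbp")

VALID_ENDPOINTS = ("ldl", "nonhdl")
VALID_PROVENANCE = ("updated_eq1", "updated_eq2", "user_supplied")


@dataclass(frozen=True)
class LogisticModel:
    """A named logistic risk equation: intercept + sum(coef * predictor)."""

    name: str
    terms: Mapping[str, float]
    intercept: float
    endpoint: str
    provenance: str = "user_supplied"

    def __post_init__(self) -> None:
        if self.endpoint not in VALID_ENDPOINTS:
            raise ParameterError(
                f"endpoint must be one of {VALID_ENDPOINTS}, got {self.endpoint!r}"
            )
        if self.provenance not in VALID_PROVENANCE:
            raise ParameterError(f"provenance {self.provenance!r} not recognised")
        if not math.isfinite(self.intercept):
            raise ParameterError("intercept must be finite")
        for k, v in self.terms.items():
            if not math.isfinite(v):
                raise ParameterError(f"coefficient for {k!r} must be finite")
        object.__setattr__(self, "terms", dict(self.terms))

    @property
    def predictors(self) -> tuple[str, ...]:
        return tuple(self.terms)

    def scaled(self, alpha: float, beta: float, name: str | None = None) -> "LogisticModel":
        """Recalibrated copy: coefficients *= beta, intercept = alpha + beta*b0."""
        return replace(
            self,
            name=name or f"{self.name}_recalibrated",
            terms={k: beta * v for k, v in self.terms.items()},
            intercept=alpha + beta * self.intercept,
            provenance="user_supplied",
        )


# Shipped defaults: the updated (post-recalibration) screening equations.
LDL_MODEL = LogisticModel(
    name="elevated_ldl",
    terms={"male": 0.5542, "metabolic_age": 0.0155},
    intercept=-2.6091,
    endpoint="ldl",
    provenance="updated_eq1",
)

NONHDL_MODEL = LogisticModel(
    name="elevated_nonhdl",
    terms={"male": 0.9008, "metabolic_age": 0.0294, "dbp": 0.0100},
    intercept=-3.1255,
    endpoint="nonhdl",
    provenance="updated_eq2",
)


@dataclass(frozen=True)
class MetAgeProxyModel:
    """Linear proxy for device-measured metabolic age (years)."""

    coef_age: float = 0.541
    coef_bmi: float = 2.394
    coef_male: float = -7.326
    intercept: float = -39.156


METAGE_PROXY = MetAgeProxyModel()


def _extract(data, name: str):
    """Pull one predictor column/value, raising a named SchemaError."""
    try:
        if isinstance(data, pd.DataFrame):
            return data[name].to_numpy(dtype=float)
        return float(data[name])
    except (KeyError, TypeError) as exc:
        raise SchemaError(f"record is missing predictor {name!r}") from exc


def linear_predictor(model: LogisticModel, data):
    """Log-odds score: intercept + sum of coefficient*value.

    ``data`` is a DataFrame (vectorised; returns an ndarray) or any mapping
    for a single participant (returns a float). A score of 0 corresponds to
    a predicted probability of 0.5.
    """
    lp = model.intercept
    for name, coef in model.terms.items():
        lp = lp + coef * _extract(data, name)
    return lp


def predicted_probability(model: LogisticModel, data):
    """Risk probability: inverse-logit of the linear predictor, in (0, 1)."""
    return expit(linear_predictor(model, data))


def impute_metabolic_age(age, bmi, male, proxy: MetAgeProxyModel = METAGE_PROXY):
    """Estimate metabolic age (years) from age, BMI and gender.

    The proxy is a plain linear combination and is intentionally not clamped:
    extreme inputs can yield implausible (even negative) years, which callers
    should treat as a signal that the subject is outside the supported range.
    """
    age = np.asarray(age, dtype=float)
    bmi = np.asarray(bmi, dtype=float)
    if np.any(age <= 0):
        raise ParameterError("age must be positive")
    if np.any(bmi <= 0):
        raise ParameterError("bmi must be positive")
    male = np.asarray(male, dtype=float)
    if not np.all(np.isin(male, (0.0, 1.0))):
        raise ParameterError("male must be coded 0 (female) / 1 (male)")
    out = (
        proxy.intercept
        + proxy.coef_age * age
        + proxy.coef_bmi * bmi
        + proxy.coef_male * male
    )
    return out if out.ndim else float(out)


# ---------------------------------------------------------------------------
# Model files
# ---------------------------------------------------------------------------

_REQUIRED_KEYS = {"name", "endpoint", "intercept", "terms"}


def model_from_dict(doc: dict) -> LogisticModel:
    if not isinstance(doc, dict):
        raise SchemaError("model file must contain a mapping")
    missing = _REQUIRED_KEYS - set(doc)
    if missing:
        raise SchemaError(f"model file missing keys: {sorted(missing)}")
    extra = set(doc) - _REQUIRED_KEYS - {"provenance"}
    if extra:
        raise SchemaError(f"model file has unrecognised keys: {sorted(extra)}")
    terms = doc["terms"]
    if not isinstance(terms, dict) or not terms:
        raise SchemaError("'terms' must be a non-empty mapping")
    for k in terms:
        if k not in KNOWN_PREDICTORS:
            raise SchemaError(
                f"unknown predictor {k!r}; expected one of {KNOWN_PREDICTORS}"
            )
    return LogisticModel(
        name=str(doc["name"]),
        terms={k: float(v) for k, v in terms.items()},
        intercept=float(doc["intercept"]),
        endpoint=str(doc["endpoint"]),
        provenance=str(doc.get("provenance", "user_supplied")),
    )


def model_to_dict(model: LogisticModel) -> dict:
    return {
        "name": model.name,
        "endpoint": model.endpoint,
        "intercept": model.intercept,
        "terms": dict(model.terms),
        "provenance": model.provenance,
    }


def load_model(path) -> LogisticModel:
    """Read a model from a JSON or YAML file (by extension)."""
    text = open(path, "r", encoding="utf-8").read()
    if str(path).endswith((".yml", ".yaml")):
        doc = yaml.safe_load(text)
    else:
        doc = json.loads(text)
    return model_from_dict(doc)


def save_model(model: LogisticModel, path) -> None:
    doc = model_to_dict(model)
    with open(path, "w", encoding="utf-8") as fh:
        if str(path).endswith((".yml", ".yaml")):
            yaml.safe_dump(doc, fh, sort_keys=False)
        else:
            json.dump(doc, fh, indent=2)
            fh.write("\n")


def load_shipped(name: str) -> LogisticModel:
    """Load one of the bundled model files ('ldl' or 'nonhdl')."""
    fname = {"ldl": "elevated_ldl.json", "nonhdl": "elevated_nonhdl.json"}.get(name)
    if fname is None:
        raise ParameterError(f"no shipped model named {name!r}")
    text = resources.files("lipidval").joinpath("model_files", fname).read_text()
    return model_from_dict(json.loads(text))
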