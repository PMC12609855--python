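"""Decision-curve analysis: clinical net benefit across threshold probabilities.

At a threshold probability ``t`` a participant is referred for confirmatory
testing when predicted risk ``p >= t`` (ties count as positive). Net benefit
is true positives minus odds(t)-weighted false positives per participant,

    NB(t) = (TP - FP * t/(1-t)) / n,

benchmarked against the treat-all policy NB_all(t) = phi - (1-phi)*t/(1-t)
and treat-none (identically 0). The net reduction in investigations per 100
participants, (NB - NB_all) / (t/(1-t)) * 100, converts the difference into
confirmatory tests avoided relative to testing everyone, without missing
additional cases. Curves are reported unsmoothed on a fixed threshold grid.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .exceptions import ParameterError


@dataclass(frozen=True)
class DecisionCurve:
    thresholds: np.ndarray
    nb_model: np.ndarray
    nb_all: np.ndarray
    nb_none: np.ndarray
    avoided_per100: np.ndarray
    prevalence: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "threshold": self.thresholds,
            "nb_model": self.nb_model,
            "nb_all": self.nb_all,
            "nb_none": self.nb_none,
            "avoided_per100": self.avoided_per100,
        })


def default_grid(start: float = 0.01, stop: float = 0.60,
                 step: float = 0.01) -> np.ndarray:
    """Threshold grid 0.01..0.60 by 0.01 (covers the 10-50% range of
    practical interest with margin)."""
    n = int(round((stop - start) / step)) + 1
    return np.round(np.linspace(start, stop, n), 10)


def _check_t(t: float) -> None:
    if not 0.0 < t < 1.0:
        raise ParameterError(f"threshold must lie strictly in (0, 1), got {t}")


def _check_inputs(y, p) -> tuple[np.ndarray, np.ndarray]:
    y = np.asarray(y)
    p = np.asarray(p, dtype=float)
    if y.shape != p.shape or y.ndim != 1 or y.size == 0:
        raise ParameterError("y and p must be equal-length non-empty vectors")
    if not np.all(np.isin(np.unique(y), (0, 1))):
        raise ParameterError("y must be coded 0/1")
    return y.astype(int), p


def net_benefit(y, p, t: float) -> float:
    """Net benefit of the model policy (refer iff p >= t) at threshold t."""
    y, p = _check_inputs(y, p)
    _check_t(t)
    positive = p >= t
    tp = int(np.sum(positive & (y == 1)))
    fp = int(np.sum(positive & (y == 0)))
    return (tp - fp * t / (1 - t)) / y.size


def net_benefit_treat_all(prevalence: float, t: float) -> float:
    """Net benefit of referring everyone; crosses zero at t = prevalence."""
    _check_t(t)
    if not 0.0 <= prevalence <= 1.0:
        raise ParameterError(f"prevalence must be in [0, 1], got {prevalence}")
    return prevalence - (1 - prevalence) * t / (1 - t)


def net_reduction_per100(y, p, t: float) -> float:
    """Confirmatory investigations avoided per 100 participants vs treat-all."""
    y, p = _check_inputs(y, p)
    _check_t(t)
    nb = net_benefit(y, p, t)
    nb_all = net_benefit_treat_all(float(np.mean(y)), t)
    return (nb - nb_all) / (t / (1 - t)) * 100.0


def decision_curve(y, p, grid=None) -> DecisionCurve:
    """Evaluate the three policies over a threshold grid."""
    y, p = _check_inputs(y, p)
    grid = default_grid() if grid is None else np.asarray(grid, dtype=float)
    if grid.size == 0:
        raise ParameterError("threshold grid must be non-empty")
    if np.any(grid <= 0) or np.any(grid >= 1):
        raise ParameterError("grid thresholds must lie strictly in (0, 1)")
    if np.any(np.diff(grid) <= 0):
        raise ParameterError("grid must be sorted strictly ascending")
    phi = float(np.mean(y))
    nb_model = np.array([net_benefit(y, p, t) for t in grid])
    nb_all = np.array([net_benefit_treat_all(phi, t) for t in grid])
    odds = grid / (1 - grid)
    return DecisionCurve(
        thresholds=grid,
        nb_model=nb_model,
        nb_all=nb_all,
        nb_none=np.zeros_like(grid),
        avoided_per100=(nb_model - nb_all) / odds * 100.0,
        prevalence=phi,
    )
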