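"""Minimum sample size for externally validating a risk model.

Implements the three precision criteria of the Riley-style validation
sample-size framework: the smallest n at which the anticipated 95%
confidence interval is no wider than a target for

1. the C-statistic, using a Newcombe-type variance
   ``C(1-C) * [1 + (n/2-1)(1-C)/(2-C) + (n/2-1) C/(1+C)] / (n^2 phi (1-phi))``;
2. the calibration slope, from the Fisher information of the two-parameter
   logistic recalibration model ``logit = a + b*LP`` evaluated under an
   assumed normal linear-predictor distribution LP ~ N(mu, sigma^2) — the
   per-subject information is integrated with fixed 200-node Gauss-Hermite
   quadrature, so the result is deterministic (tools that integrate by
   simulating a large LP sample agree to ~0.3%);
3. the O/E (observed/expected) ratio, with SE(ln O/E) = sqrt((1-phi)/(n phi)).

The O/E target width is interpreted on the ratio scale with the asymmetric
exponential interval, solving ``2*sinh(z * SE) = width`` (default); the
simpler symmetric log-scale convention ``SE = width / (2z)`` is available via
``oe_convention="log_delta"``. The O/E criterion is sensitive at the +/-5
participant level to whether the prevalence is a rounded proportion or an
exact event fraction, so :class:`SampleSizeSpec` carries an optional
``oe_prevalence`` separate from the headline prevalence.

The required validation size is the maximum of the three criteria.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from math import asinh, ceil, sqrt

import numpy as np
from scipy import stats
from scipy.special import expit

from .exceptions import ParameterError

Z95 = stats.norm.ppf(0.975)

#: Fixed quadrature rule for the slope criterion.
GH_NODES = 200


@dataclass(frozen=True)
class SampleSizeSpec:
    """Anticipated performance and target precisions for one model."""

    prevalence: float
    c_statistic: float
    lp_mean: float
    lp_sd: float
    width_c: float = 0.1
    width_slope: float = 0.25
    width_oe: float = 0.25
    anticipated_slope: float = 1.0
    anticipated_oe: float = 1.0
    oe_prevalence: float | None = None   # exact event fraction, if distinct
    confidence: float = 0.95
    oe_convention: str = "asymmetric_exp"

    def __post_init__(self) -> None:
        if not 0.0 < self.prevalence < 1.0:
            raise ParameterError(f"prevalence must be in (0,1), got {self.prevalence}")
        if self.oe_prevalence is not None and not 0.0 < self.oe_prevalence < 1.0:
            raise ParameterError("oe_prevalence must be in (0,1)")
        if not 0.5 <= self.c_statistic < 1.0:
            raise ParameterError(
                f"c_statistic must be in [0.5, 1), got {self.c_statistic}"
            )
        for name in ("width_c", "width_slope", "width_oe"):
            if not getattr(self, name) > 0:
                raise ParameterError(f"{name} must be > 0")
        if not self.lp_sd > 0:
            raise ParameterError(f"lp_sd must be > 0, got {self.lp_sd}")
        if not 0.0 < self.confidence < 1.0:
            raise ParameterError("confidence must be in (0,1)")
        if self.oe_convention not in ("asymmetric_exp", "log_delta"):
            raise ParameterError(f"oe_convention {self.oe_convention!r} not recognised")

    @property
    def z(self) -> float:
        return float(stats.norm.ppf(0.5 + self.confidence / 2))


@dataclass(frozen=True)
class SampleSizeResult:
    n_cstat: int
    n_slope: int
    n_oe: int
    diagnostics: dict = field(default_factory=dict)

    @property
    def n_required(self) -> int:
        return max(self.n_cstat, self.n_slope, self.n_oe)


def _cstat_width(n: float, C: float, phi: float, z: float) -> float:
    var = (C * (1 - C)
           * (1 + (n / 2 - 1) * (1 - C) / (2 - C) + (n / 2 - 1) * C / (1 + C))
           / (n ** 2 * phi * (1 - phi)))
    return 2 * z * sqrt(var)


def n_for_cstat(spec: SampleSizeSpec) -> int:
    """Smallest n whose anticipated C-statistic CI is narrow enough."""
    C, phi, z, target = spec.c_statistic, spec.prevalence, spec.z, spec.width_c
    # width ~ k/sqrt(n): bracket by doubling, then bisect to the exact
    # integer boundary so that n-1 fails and n passes.
    n = 4
    while _cstat_width(n, C, phi, z) > target:
        n *= 2
        if n > 10 ** 9:
            raise ParameterError("width_c is infeasibly small")
    lo, hi = n // 2, n
    while hi - lo > 1:
        mid = (lo + hi) // 2
        if _cstat_width(mid, C, phi, z) > target:
            lo = mid
        else:
            hi = mid
    return hi


def slope_unit_variance(lp_mean: float, lp_sd: float,
                        intercept: float = 0.0, slope: float = 1.0,
                        nodes: int = GH_NODES) -> float:
    """Per-subject asymptotic variance of the recalibration-slope MLE.

    Integrates the 2x2 Fisher information of ``logit = a + b*LP`` over
    LP ~ N(lp_mean, lp_sd^2) at the anticipated (a, b) and returns the (b, b)
    element of its inverse.
    """
    x, w = np.polynomial.hermite_e.hermegauss(nodes)  # probabilists' rule
    w = w / w.sum()
    lp = lp_mean + lp_sd * x
    v = expit(intercept + slope * lp)
    v = v * (1 - v)
    i_aa = float(np.sum(w * v))
    i_ab = float(np.sum(w * v * lp))
    i_bb = float(np.sum(w * v * lp * lp))
    det = i_aa * i_bb - i_ab ** 2
    if det <= 0:
        raise ParameterError("Fisher information is singular for this LP spread")
    return i_aa / det


def n_for_slope(spec: SampleSizeSpec) -> int:
    """Smallest n whose anticipated calibration-slope CI is narrow enough."""
    unit_var = slope_unit_variance(
        spec.lp_mean, spec.lp_sd, slope=spec.anticipated_slope
    )
    se_target = spec.width_slope / (2 * spec.z)
    return ceil(unit_var / se_target ** 2)


def n_for_oe(spec: SampleSizeSpec) -> int:
    """Smallest n whose anticipated O/E-ratio CI is narrow enough."""
    phi = spec.oe_prevalence if spec.oe_prevalence is not None else spec.prevalence
    oe = spec.anticipated_oe
    if spec.oe_convention == "asymmetric_exp":
        # interval [oe*exp(-z se), oe*exp(z se)] has width 2*oe*sinh(z se)
        se_target = asinh(spec.width_oe / (2 * oe)) / spec.z
    else:
        se_target = spec.width_oe / (2 * spec.z * oe)
    n = (1 - phi) / (phi * se_target ** 2)
    if n > 10 ** 9:
        raise ParameterError("width_oe is infeasibly small at this prevalence")
    return ceil(n)


def validation_sample_size(spec: SampleSizeSpec) -> SampleSizeResult:
    """All three criteria plus per-criterion anticipated SEs at the chosen n."""
    n_c = n_for_cstat(spec)
    n_s = n_for_slope(spec)
    n_o = n_for_oe(spec)
    phi_oe = spec.oe_prevalence if spec.oe_prevalence is not None else spec.prevalence
    unit_var = slope_unit_variance(spec.lp_mean, spec.lp_sd,
                                   slope=spec.anticipated_slope)
    diagnostics = {
        "se_cstat_at_n": _cstat_width(n_c, spec.c_statistic, spec.prevalence,
                                      spec.z) / (2 * spec.z),
        "se_slope_at_n": sqrt(unit_var / n_s),
        "se_ln_oe_at_n": sqrt((1 - phi_oe) / (n_o * phi_oe)),
    }
    return SampleSizeResult(n_cstat=n_c, n_slope=n_s, n_oe=n_o,
                            diagnostics=diagnostics)


# Reproduction inputs for the two shipped models. Headline prevalences are
# the rounded published proportions (used by the C-statistic criterion);
# the O/E criterion uses the exact development-cohort event fractions, to
# which it is sensitive at the +/-5 participant level.
LDL_SIZING = SampleSizeSpec(
    prevalence=0.136, c_statistic=0.639, lp_mean=-2.04, lp_sd=0.41,
    oe_prevalence=303 / 2222,
)

NONHDL_SIZING = SampleSizeSpec(
    prevalence=0.197, c_statistic=0.721, lp_mean=-1.41, lp_sd=0.81,
    oe_prevalence=1013 / 5149,
)
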