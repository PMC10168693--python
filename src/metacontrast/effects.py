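"""Standardized mean differences (Cohen's d, Hedges' g) from two-arm
summary statistics.

d = (mean_t - mean_c) / s_pooled with the usual pooled SD, and
var(d) = (n_t + n_c) / (n_t * n_c) + d^2 / (2 (n_t + n_c)).  Hedges' g
applies the small-sample correction J = 1 - 3 / (4 df - 1), df =
n_t + n_c - 2, giving g = J d and var(g) = J^2 var(d).  Confidence
intervals are normal (z = 1.96) as is conventional in inverse-variance
meta-analysis.  ``orient`` maps raw effects onto a benefit-positive
scale so that outcomes with opposite polarity (infarct volume vs.
cognitive score) are comparable.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, replace

from .core import ArmSummary, Direction, ValidationError

Z_95 = 1.959963984540054  # normal 97.5% quantile


class Metric(str, enum.Enum):
    d = "d"
    g = "g"


class EffectSizeError(ValueError):
    """Raised when an SMD is undefined for the given arms."""


@dataclass(frozen=True)
class EffectEstimate:
    """A standardized mean difference with its variance and 95% CI."""

    point: float
    variance: float
    ci_low: float
    ci_high: float
    metric: Metric
    n_treat: int
    n_control: int
    degenerate_variance: bool = False

    @property
    def se(self) -> float:
        return math.sqrt(self.variance)


def pooled_sd(sd_t: float, n_t: int, sd_c: float, n_c: int) -> float:
    """Pooled standard deviation of two arms.

    sqrt(((n_t-1) sd_t^2 + (n_c-1) sd_c^2) / (n_t + n_c - 2)); requires
    at least 2 per arm.
    """
    if n_t < 2 or n_c < 2:
        raise EffectSizeError(
            f"degrees of freedom exhausted: need n >= 2 per arm, "
            f"got n_t={n_t}, n_c={n_c}"
        )
    if sd_t < 0 or sd_c < 0:
        raise ValidationError("SDs must be nonnegative")
    return math.sqrt(
        ((n_t - 1) * sd_t**2 + (n_c - 1) * sd_c**2) / (n_t + n_c - 2)
    )


def hedges_j(n_t: int, n_c: int) -> float:
    """Small-sample correction factor J = 1 - 3/(4 df - 1), df = n_t+n_c-2."""
    df = n_t + n_c - 2
    if df < 1:
        raise EffectSizeError("degrees of freedom exhausted")
    return 1.0 - 3.0 / (4.0 * df - 1.0)


def smd(
    treat: ArmSummary, control: ArmSummary, metric: Metric = Metric.g
) -> EffectEstimate:
    """Standardized mean difference between a treatment and a control arm.

    With a zero pooled SD the SMD is undefined unless the means are also
    equal, in which case the point is 0 with an error-flagged variance.
    """
    metric = Metric(metric)
    n_t, n_c = treat.n, control.n
    sp = pooled_sd(treat.sd, n_t, control.sd, n_c)
    diff = treat.mean - control.mean
    if sp == 0.0:
        if diff != 0.0:
            raise EffectSizeError(
                "undefined SMD: zero pooled SD with unequal means"
            )
        point, var, flagged = 0.0, 0.0, True
    else:
        d = diff / sp
        var_d = (n_t + n_c) / (n_t * n_c) + d**2 / (2.0 * (n_t + n_c))
        if metric is Metric.g:
            j = hedges_j(n_t, n_c)
            point, var = j * d, j**2 * var_d
        else:
            point, var = d, var_d
        flagged = False
    se = math.sqrt(var)
    return EffectEstimate(
        point=point,
        variance=var,
        ci_low=point - Z_95 * se,
        ci_high=point + Z_95 * se,
        metric=metric,
        n_treat=n_t,
        n_control=n_c,
        degenerate_variance=flagged,
    )


def orient(e: EffectEstimate, direction: Direction) -> EffectEstimate:
    """Flip the sign for lower-is-better outcomes.

    After orientation a positive point always favours treatment. The CI
    bounds are swapped along with the sign; the variance is unchanged.
    """
    if Direction(direction) is Direction.higher_is_better:
        return e
    return replace(e, point=-e.point, ci_low=-e.ci_high, ci_high=-e.ci_low)
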