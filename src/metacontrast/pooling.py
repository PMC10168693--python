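"""Fixed- and random-effects inverse-variance pooling.

The between-study variance tau^2 is estimated by DerSimonian-Laird from
Cochran's Q:

    Q = sum w_i (x_i - x_FE)^2,  w_i = 1/v_i
    C = sum w_i - sum w_i^2 / sum w_i
    tau^2 = max(0, (Q - (k - 1)) / C)

Random-effects weights are w*_i = 1/(v_i + tau^2); confidence intervals
are plain z intervals (no Knapp-Hartung adjustment). Pooling a single
estimate returns that estimate with tau^2 = 0, so a comparison with one
multilaboratory study flows through the same code path.
"""

from __future__ import annotations

import enum
import logging
import math
from dataclasses import dataclass
from typing import Sequence, Union

import numpy as np
from scipy import stats

from .effects import EffectEstimate, Z_95

logger = logging.getLogger("metacontrast")


class PoolModel(str, enum.Enum):
    fixed = "fixed"
    random = "random"


class PoolingError(ValueError):
    pass


@dataclass(frozen=True)
class PooledEstimate:
    """Inverse-variance pooled effect with heterogeneity statistics."""

    point: float
    se: float
    ci_low: float
    ci_high: float
    tau2: float
    q: float
    df: int
    k: int
    model: PoolModel

    @property
    def variance(self) -> float:
        return self.se**2

    @property
    def p_value(self) -> float:
        """Two-sided z test of point = 0."""
        if self.se == 0:
            return 0.0 if self.point != 0 else 1.0
        z = self.point / self.se
        return 2.0 * stats.norm.sf(abs(z))


def _points_vars(
    estimates: Sequence[Union[EffectEstimate, PooledEstimate]],
) -> tuple[np.ndarray, np.ndarray]:
    if not estimates:
        raise PoolingError("cannot pool an empty list of estimates")
    pts = np.array([e.point for e in estimates], dtype=float)
    vs = np.array([e.variance for e in estimates], dtype=float)
    if (vs <= 0).any():
        raise PoolingError("all estimate variances must be positive")
    return pts, vs


def _q_statistic(pts: np.ndarray, vs: np.ndarray) -> float:
    w = 1.0 / vs
    x_fe = float(np.sum(w * pts) / np.sum(w))
    return float(np.sum(w * (pts - x_fe) ** 2))


def fixed_pool(
    estimates: Sequence[Union[EffectEstimate, PooledEstimate]],
) -> PooledEstimate:
    """Fixed-effect inverse-variance pool: weights 1/v_i."""
    pts, vs = _points_vars(estimates)
    w = 1.0 / vs
    sw = float(np.sum(w))
    point = float(np.sum(w * pts) / sw)
    se = math.sqrt(1.0 / sw)
    k = len(pts)
    q = _q_statistic(pts, vs) if k > 1 else 0.0
    return PooledEstimate(
        point=point,
        se=se,
        ci_low=point - Z_95 * se,
        ci_high=point + Z_95 * se,
        tau2=0.0,
        q=q,
        df=k - 1,
        k=k,
        model=PoolModel.fixed,
    )


def dl_tau2(
    estimates: Sequence[Union[EffectEstimate, PooledEstimate]],
) -> float:
    """DerSimonian-Laird moment estimate of tau^2, truncated at zero."""
    pts, vs = _points_vars(estimates)
    k = len(pts)
    if k < 2:
        logger.info("tau^2 requires k >= 2 estimates; defining tau^2 = 0")
        return 0.0
    w = 1.0 / vs
    q = _q_statistic(pts, vs)
    c = float(np.sum(w) - np.sum(w**2) / np.sum(w))
    if c <= 0:
        return 0.0
    return max(0.0, (q - (k - 1)) / c)


def random_pool(
    estimates: Sequence[Union[EffectEstimate, PooledEstimate]],
) -> PooledEstimate:
    """DerSimonian-Laird random-effects pool: weights 1/(v_i + tau^2)."""
    pts, vs = _points_vars(estimates)
    k = len(pts)
    tau2 = dl_tau2(estimates) if k > 1 else 0.0
    q = _q_statistic(pts, vs) if k > 1 else 0.0
    w = 1.0 / (vs + tau2)
    sw = float(np.sum(w))
    point = float(np.sum(w * pts) / sw)
    se = math.sqrt(1.0 / sw)
    return PooledEstimate(
        point=point,
        se=se,
        ci_low=point - Z_95 * se,
        ci_high=point + Z_95 * se,
        tau2=tau2,
        q=q,
        df=k - 1,
        k=k,
        model=PoolModel.random,
    )


def pool(
    estimates: Sequence[Union[EffectEstimate, PooledEstimate]],
    model: PoolModel = PoolModel.random,
) -> PooledEstimate:
    model = PoolModel(model)
    return fixed_pool(estimates) if model is PoolModel.fixed else random_pool(estimates)
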