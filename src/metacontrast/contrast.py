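"""Design contrasts between multilaboratory and single-lab studies.

Two per-comparison statistics quantify how effect estimates differ by
design:

* DSMD_i = d(single-lab pool)_i - d(multilab)_i, with standard error
  sqrt(se_s^2 + se_m^2) treating the two designs as independent; a
  positive DSMD means single-lab studies showed the larger effect.
* ESR_i = ES(single-lab pool)_i / ES(multilab)_i; an ESR of 1 means no
  difference, above 1 a larger single-lab effect.

Per-comparison DSMDs are combined across comparisons by random-effects
inverse-variance pooling (an equal-weight and a fixed-effect variant are
available); ESRs are summarised by their median and range. Direction
counts use the strict inequality DSMD > 0, with ties reported
separately, and a multilab confidence interval is counted as "outside"
the single-lab pooled interval only when the two intervals are disjoint.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .core import ComparisonSet, StudyRecord, ValidationError
from .effects import EffectEstimate, Metric, Z_95, orient, smd
from .pooling import PooledEstimate, PoolModel, pool, random_pool

logger = logging.getLogger("metacontrast")

#: Pooled multilab effects closer to zero than this (SMD scale) make the
#: effect-size ratio numerically meaningless; such comparisons are flagged
#: degenerate and excluded from the median.
ESR_TOLERANCE = 1e-8


@dataclass(frozen=True)
class DsmdResult:
    comparison_id: str
    dsmd: float
    se: float
    ci_low: float
    ci_high: float
    d_single: PooledEstimate
    d_multi: PooledEstimate

    @property
    def variance(self) -> float:
        return self.se**2

    @property
    def point(self) -> float:  # lets DsmdResult flow through the pooling engine
        return self.dsmd


@dataclass(frozen=True)
class EsrResult:
    comparison_id: str
    esr: Optional[float]
    es_single: float
    es_multi: float
    degenerate: bool = False


@dataclass
class ContrastReport:
    pooled_dsmd: PooledEstimate
    median_esr: float
    esr_range: tuple[float, float]
    n_comparisons: int
    n_single_larger: int
    n_dsmd_ties: int
    n_esr_gt_1: int
    n_ci_nonoverlap: int
    per_comparison_dsmd: list[DsmdResult] = field(default_factory=list)
    per_comparison_esr: list[EsrResult] = field(default_factory=list)


def study_effect(record: StudyRecord, metric: Metric = Metric.g) -> EffectEstimate:
    """Oriented (benefit-positive) effect estimate for one study.

    A multilaboratory study reported per center is reduced to one
    estimate by random-effects pooling of the per-center SMDs; otherwise
    the aggregate arms are used directly.
    """
    if record.strata:
        per_center = [smd(t, c, metric) for t, c in record.strata]
        pooled = random_pool(per_center)
        est = EffectEstimate(
            point=pooled.point,
            variance=pooled.variance,
            ci_low=pooled.ci_low,
            ci_high=pooled.ci_high,
            metric=Metric(metric),
            n_treat=sum(t.n for t, _ in record.strata),
            n_control=sum(c.n for _, c in record.strata),
        )
    else:
        est = smd(record.treatment_arm, record.control_arm, metric)
    return orient(est, record.direction)


def comparison_pools(
    comparison: ComparisonSet, metric: Metric = Metric.g
) -> tuple[PooledEstimate, PooledEstimate]:
    """(single-lab pool, multilab estimate) for one comparison, oriented."""
    singles = [study_effect(s, metric) for s in comparison.singles]
    multi = study_effect(comparison.multilab, metric)
    return random_pool(singles), random_pool([multi])


def dsmd(
    comparison: ComparisonSet,
    metric: Metric = Metric.g,
    pools: Optional[tuple[PooledEstimate, PooledEstimate]] = None,
) -> DsmdResult:
    """Per-comparison difference in standardized mean differences."""
    try:
        d_s, d_m = pools if pools is not None else comparison_pools(comparison, metric)
    except Exception as exc:
        raise ValidationError(
            f"comparison {comparison.comparison_id}: {exc}"
        ) from exc
    delta = d_s.point - d_m.point
    se = math.sqrt(d_s.se**2 + d_m.se**2)
    return DsmdResult(
        comparison_id=comparison.comparison_id,
        dsmd=delta,
        se=se,
        ci_low=delta - Z_95 * se,
        ci_high=delta + Z_95 * se,
        d_single=d_s,
        d_multi=d_m,
    )


def esr(
    comparison: ComparisonSet,
    metric: Metric = Metric.g,
    tolerance: float = ESR_TOLERANCE,
    pools: Optional[tuple[PooledEstimate, PooledEstimate]] = None,
) -> EsrResult:
    """Per-comparison effect size ratio of the oriented pooled points."""
    d_s, d_m = pools if pools is not None else comparison_pools(comparison, metric)
    if abs(d_m.point) < tolerance:
        logger.warning(
            "comparison %s: multilab effect %.3g below tolerance; "
            "ESR flagged degenerate",
            comparison.comparison_id,
            d_m.point,
        )
        return EsrResult(
            comparison.comparison_id, None, d_s.point, d_m.point, degenerate=True
        )
    return EsrResult(
        comparison.comparison_id, d_s.point / d_m.point, d_s.point, d_m.point
    )


def pool_dsmd(
    results: Sequence[DsmdResult],
    model: PoolModel = PoolModel.random,
    weighting: str = "inverse_variance",
) -> PooledEstimate:
    """Combined DSMD across comparisons.

    Default: random-effects inverse-variance pooling of the per-comparison
    DSMDs using their variances (se_s^2 + se_m^2). ``weighting="equal"``
    gives every comparison unit weight instead.
    """
    if not results:
        raise ValidationError("no DSMD results to pool")
    if weighting == "equal":
        # unweighted mean of independent estimates; se from their variances
        pts = np.array([r.dsmd for r in results])
        vs = np.array([r.variance for r in results])
        k = len(pts)
        point = float(pts.mean())
        se = math.sqrt(float(vs.sum()) / k**2)
        return PooledEstimate(
            point=point,
            se=se,
            ci_low=point - Z_95 * se,
            ci_high=point + Z_95 * se,
            tau2=0.0,
            q=float("nan"),
            df=k - 1,
            k=k,
            model=PoolModel(model),
        )
    return pool(list(results), model)


def median_esr(results: Sequence[EsrResult]) -> tuple[float, tuple[float, float]]:
    """Median and (min, max) ESR over non-degenerate comparisons."""
    vals = [r.esr for r in results if not r.degenerate]
    if not vals:
        raise ValidationError("no non-degenerate ESR results")
    arr = np.array(vals, dtype=float)
    return float(np.median(arr)), (float(arr.min()), float(arr.max()))


def direction_count(results: Sequence[DsmdResult]) -> tuple[int, int]:
    """(number with DSMD strictly > 0, number of exact ties at 0)."""
    if not results:
        raise ValidationError("no DSMD results")
    positive = sum(1 for r in results if r.dsmd > 0)
    ties = sum(1 for r in results if r.dsmd == 0)
    return positive, ties


def _disjoint(a: tuple[float, float], b: tuple[float, float]) -> bool:
    return a[1] < b[0] or b[1] < a[0]


def ci_nonoverlap_count(results: Sequence[DsmdResult]) -> int:
    """Comparisons whose multilab CI is disjoint from the single-lab
    pooled CI."""
    count = 0
    for r in results:
        multi_ci = (r.d_multi.ci_low, r.d_multi.ci_high)
        single_ci = (r.d_single.ci_low, r.d_single.ci_high)
        outside = _disjoint(multi_ci, single_ci)
        logger.debug(
            "comparison %s: multilab CI (%.3f, %.3f) vs single CI "
            "(%.3f, %.3f) -> %s",
            r.comparison_id, *multi_ci, *single_ci,
            "disjoint" if outside else "overlapping",
        )
        count += outside
    return count


def contrast_report(
    comparisons: Sequence[ComparisonSet],
    metric: Metric = Metric.g,
    model: PoolModel = PoolModel.random,
    weighting: str = "inverse_variance",
    esr_tolerance: float = ESR_TOLERANCE,
) -> ContrastReport:
    """Full design contrast over a corpus of matched comparisons."""
    dsmd_results: list[DsmdResult] = []
    esr_results: list[EsrResult] = []
    for comp in comparisons:
        pools = comparison_pools(comp, metric)
        dsmd_results.append(dsmd(comp, metric, pools=pools))
        esr_results.append(esr(comp, metric, tolerance=esr_tolerance, pools=pools))
    med, rng = median_esr(esr_results)
    n_pos, n_ties = direction_count(dsmd_results)
    return ContrastReport(
        pooled_dsmd=pool_dsmd(dsmd_results, model, weighting),
        median_esr=med,
        esr_range=rng,
        n_comparisons=len(dsmd_results),
        n_single_larger=n_pos,
        n_dsmd_ties=n_ties,
        n_esr_gt_1=sum(
            1 for r in esr_results if not r.degenerate and r.esr > 1
        ),
        n_ci_nonoverlap=ci_nonoverlap_count(dsmd_results),
        per_comparison_dsmd=dsmd_results,
        per_comparison_esr=esr_results,
    )
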