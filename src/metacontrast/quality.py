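"""Methodological-quality scoring and between-design comparison.

Each study is scored 0-5 as the count of five bias-reducing practices it
reported (randomization, low-risk randomization method, personnel
blinding, outcome-assessor blinding, complete outcome data). Score
distributions of multilaboratory vs single-lab studies are compared with
a two-sided Mann-Whitney U test: exact when the product of group sizes
is small and there are no ties, otherwise the tie-corrected normal
approximation with continuity correction. Per-practice adherence rates
are reported descriptively only, without per-item tests.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from .core import QualityFlags, ValidationError

#: Below this product of group sizes (and with no ties) the exact null
#: distribution of U is enumerated; above it the normal approximation is used.
EXACT_THRESHOLD = 400


def total_score(flags: QualityFlags) -> int:
    """Sum of the five binary practice flags (0-5)."""
    return sum(flags.as_tuple())


def mann_whitney(a: Sequence[int], b: Sequence[int]) -> tuple[float, float]:
    """Two-sided Mann-Whitney U test.

    Returns (U of the first group, two-sided p). U_a is computed from
    midranks, so U_a + U_b = n_a * n_b holds under ties.
    """
    if len(a) == 0 or len(b) == 0:
        raise ValidationError("Mann-Whitney groups must be nonempty")
    a_arr, b_arr = np.asarray(a, float), np.asarray(b, float)
    has_ties = len(np.unique(np.concatenate([a_arr, b_arr]))) < len(a_arr) + len(b_arr)
    if not has_ties and len(a_arr) * len(b_arr) <= EXACT_THRESHOLD:
        method = "exact"
        res = stats.mannwhitneyu(a_arr, b_arr, alternative="two-sided", method=method)
    else:
        res = stats.mannwhitneyu(
            a_arr,
            b_arr,
            alternative="two-sided",
            method="asymptotic",
            use_continuity=True,
        )
    return float(res.statistic), float(res.pvalue)


def proportion_at_least(scores: Sequence[int], threshold: int = 3) -> float:
    """Fraction of scores at or above the threshold."""
    if len(scores) == 0:
        raise ValidationError("no scores supplied")
    arr = np.asarray(scores)
    if arr.min() < 0 or arr.max() > 5:
        raise ValidationError("quality scores must lie in 0-5")
    return float(np.mean(arr >= threshold))


@dataclass
class QualityComparison:
    """Between-design comparison of total quality scores."""

    scores_multi: list[int]
    scores_single: list[int]
    median_multi: float
    range_multi: tuple[int, int]
    median_single: float
    range_single: tuple[int, int]
    u_statistic: float
    p_value: float
    prop_ge3_multi: float
    prop_ge3_single: float
    practice_rates_multi: dict[str, float]
    practice_rates_single: dict[str, float]


def _practice_rates(flag_sets: Sequence[QualityFlags]) -> dict[str, float]:
    mat = np.array([f.as_tuple() for f in flag_sets])
    return {
        name: float(mat[:, i].mean())
        for i, name in enumerate(QualityFlags.FIELDS)
    }


def compare_quality(
    multi_flags: Sequence[QualityFlags],
    single_flags: Sequence[QualityFlags],
) -> QualityComparison:
    """Score both designs and test the score distributions."""
    if not multi_flags or not single_flags:
        raise ValidationError("both design groups need at least one study")
    s_m = [total_score(f) for f in multi_flags]
    s_s = [total_score(f) for f in single_flags]
    u, p = mann_whitney(s_m, s_s)
    return QualityComparison(
        scores_multi=s_m,
        scores_single=s_s,
        median_multi=float(np.median(s_m)),
        range_multi=(min(s_m), max(s_m)),
        median_single=float(np.median(s_s)),
        range_single=(min(s_s), max(s_s)),
        u_statistic=u,
        p_value=p,
        prop_ge3_multi=proportion_at_least(s_m),
        prop_ge3_single=proportion_at_least(s_s),
        practice_rates_multi=_practice_rates(multi_flags),
        practice_rates_single=_practice_rates(single_flags),
    )
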