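"""Domain types shared by all pipeline stages, plus descriptive synthesis
of study characteristics (sample sizes, species, centers).

The central objects are :class:`StudyRecord` (one two-arm animal study,
either multilaboratory or single-lab) and :class:`ComparisonSet` (one
multilaboratory study matched to its set of single-lab studies on a shared
outcome). Descriptive operations reproduce the kind of characteristics
table systematic reviews print: median and range of sample size, total
animal count, rodent share, and the number of participating centers.
"""

from __future__ import annotations

import enum
import logging
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence, Union

import numpy as np

logger = logging.getLogger("metacontrast")

#: Species counted as lab rodents for the rodent-share descriptive.
RODENT_SPECIES = frozenset({"mouse", "rat"})

#: Sentinel for "not reported" counts in input tables.
NR = "NR"


class Design(str, enum.Enum):
    multilab = "multilab"
    single = "single"


class DispersionKind(str, enum.Enum):
    SD = "SD"
    SE = "SE"


class Direction(str, enum.Enum):
    higher_is_better = "higher_is_better"
    lower_is_better = "lower_is_better"


class Sex(str, enum.Enum):
    M = "M"
    F = "F"
    both = "both"
    NR = "NR"


class ValidationError(ValueError):
    """Raised when an input record violates a domain invariant."""


@dataclass(frozen=True)
class ArmSummary:
    """Summary statistics for one experimental arm.

    ``dispersion`` is either a standard deviation or a standard error,
    disambiguated by ``dispersion_kind``; the SD is recoverable from an SE
    as SE * sqrt(n).
    """

    mean: float
    dispersion: float
    n: int
    dispersion_kind: DispersionKind = DispersionKind.SD

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValidationError(f"arm sample size must be >= 1, got {self.n}")
        if self.dispersion < 0:
            raise ValidationError(
                f"arm dispersion must be >= 0, got {self.dispersion}"
            )

    @property
    def sd(self) -> float:
        """Standard deviation, converting SE -> SD as SE * sqrt(n)."""
        if self.dispersion_kind is DispersionKind.SE:
            return self.dispersion * np.sqrt(self.n)
        return self.dispersion


@dataclass(frozen=True)
class QualityFlags:
    """Five binary bias-reducing practices scored 0/1 each.

    The practices: randomization to treatment groups, a low-risk method of
    randomization, blinding of personnel, blinding of the outcome
    assessor, and complete outcome data. The total score is their sum,
    0-5.
    """

    randomized: int
    low_rob_randomization_method: int
    blinded_personnel: int
    blinded_outcome_assessor: int
    complete_outcome_data: int

    FIELDS = (
        "randomized",
        "low_rob_randomization_method",
        "blinded_personnel",
        "blinded_outcome_assessor",
        "complete_outcome_data",
    )

    def __post_init__(self) -> None:
        for name in self.FIELDS:
            v = getattr(self, name)
            if v not in (0, 1):
                raise ValidationError(f"quality flag {name} must be 0/1, got {v!r}")

    def as_tuple(self) -> tuple[int, ...]:
        return tuple(getattr(self, name) for name in self.FIELDS)


@dataclass
class StudyRecord:
    """One two-arm study with its arm summaries and metadata.

    A multilaboratory study reported per center carries its per-center
    arm pairs in ``strata``; ``treatment_arm``/``control_arm`` then hold
    the aggregate arms (or the only stratum).
    """

    study_id: str
    design: Design
    comparison_id: str
    treatment_arm: ArmSummary
    control_arm: ArmSummary
    outcome_label: str = ""
    direction: Direction = Direction.higher_is_better
    species: str = ""
    sex: Sex = Sex.NR
    year: Optional[int] = None
    quality_flags: Optional[QualityFlags] = None
    centers_experimental: Optional[int] = None
    centers_nonexperimental: Optional[int] = None
    dual_role_centers: int = 0
    total_animals: Optional[int] = None
    strata: list[tuple[ArmSummary, ArmSummary]] = field(default_factory=list)
    #: free-form numeric features used by the study matcher
    #: (intervention_timing, dose, measurement_time)
    extras: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.design = Design(self.design)
        self.direction = Direction(self.direction)
        self.sex = Sex(self.sex)
        for attr in ("centers_experimental", "centers_nonexperimental"):
            v = getattr(self, attr)
            if v is not None and v < 0:
                raise ValidationError(f"{self.study_id}: {attr} must be >= 0")

    @property
    def centers_total(self) -> Optional[int]:
        """Distinct centers: experimental + non-experimental, a center
        holding both roles counted once."""
        if self.centers_experimental is None:
            return None
        non_exp = self.centers_nonexperimental or 0
        return self.centers_experimental + non_exp - self.dual_role_centers


@dataclass
class ComparisonSet:
    """One multilaboratory study and its matched single-lab studies."""

    comparison_id: str
    multilab: StudyRecord
    singles: list[StudyRecord]
    outcome_label: str = ""

    MAX_SINGLES = 10

    def __post_init__(self) -> None:
        if self.multilab.design is not Design.multilab:
            raise ValidationError(
                f"comparison {self.comparison_id}: reference study "
                f"{self.multilab.study_id} is not a multilab study"
            )
        if not self.singles:
            raise ValidationError(
                f"comparison {self.comparison_id}: no single-lab studies"
            )
        if len(self.singles) > self.MAX_SINGLES:
            raise ValidationError(
                f"comparison {self.comparison_id}: {len(self.singles)} "
                f"single-lab studies exceed the maximum of {self.MAX_SINGLES}"
            )
        for s in self.singles:
            if s.design is not Design.single:
                raise ValidationError(
                    f"comparison {self.comparison_id}: {s.study_id} is not "
                    "a single-lab study"
                )


@dataclass(frozen=True)
class CohortEntry:
    """One species cohort of a study: its animal count (or NR) and species.

    Studies using several species contribute one entry per species cohort,
    so that the sample-size range reflects each cohort.
    """

    study_id: str
    n: Union[int, str]  # integer or the NR sentinel
    species: str = ""
    sex: str = Sex.NR.value

    @property
    def is_nr(self) -> bool:
        return isinstance(self.n, str)


@dataclass
class CharacteristicsSummary:
    median_n: float
    n_range: tuple[int, int]
    total_animals: int
    pct_rodent: float  # unrounded; round for report display
    species_counts: dict[str, int]
    sex_counts_per_cohort: dict[str, int]
    sex_counts_per_study: dict[str, int]
    n_entries: int
    n_excluded_nr: int

    @property
    def pct_rodent_display(self) -> int:
        return int(round(self.pct_rodent))


def _as_cohort_entries(
    records: Sequence[Union[StudyRecord, CohortEntry]],
) -> list[CohortEntry]:
    out: list[CohortEntry] = []
    for r in records:
        if isinstance(r, CohortEntry):
            out.append(r)
        else:
            n = r.total_animals if r.total_animals is not None else NR
            out.append(CohortEntry(r.study_id, n, r.species, r.sex.value))
    return out


def summarize_characteristics(
    records: Sequence[Union[StudyRecord, CohortEntry]],
) -> CharacteristicsSummary:
    """Median/range/total of animal counts and the rodent share.

    NR (not reported) counts are excluded from the median, range and
    total; the rodent share is the fraction of counted animals in mouse
    or rat cohorts. Raises if no entry has a usable sample size or any
    count is negative.
    """
    entries = _as_cohort_entries(records)
    if not entries:
        raise ValidationError("no entries supplied")
    usable = [e for e in entries if not e.is_nr]
    excluded = [e for e in entries if e.is_nr]
    for e in excluded:
        logger.info("excluding NR sample size for study %s", e.study_id)
    if not usable:
        raise ValidationError("no usable sample sizes")
    ns = np.array([int(e.n) for e in usable])
    if (ns < 0).any():
        bad = [e.study_id for e in usable if int(e.n) < 0]
        raise ValidationError(f"negative sample size for: {', '.join(bad)}")

    total = int(ns.sum())
    rodent = sum(
        int(e.n) for e in usable if e.species.lower() in RODENT_SPECIES
    )
    species_counts: dict[str, int] = {}
    sex_cohort: dict[str, int] = {}
    for e in entries:
        if e.species:
            species_counts[e.species] = species_counts.get(e.species, 0) + 1
        sex_cohort[e.sex] = sex_cohort.get(e.sex, 0) + 1
    # per-study sex tally collapses multi-cohort studies to one entry
    by_study: dict[str, str] = {}
    for e in entries:
        prev = by_study.get(e.study_id)
        if prev is not None and prev != e.sex:
            by_study[e.study_id] = Sex.both.value
        else:
            by_study[e.study_id] = e.sex
    sex_study: dict[str, int] = {}
    for s in by_study.values():
        sex_study[s] = sex_study.get(s, 0) + 1

    return CharacteristicsSummary(
        median_n=float(np.median(ns)),
        n_range=(int(ns.min()), int(ns.max())),
        total_animals=total,
        pct_rodent=100.0 * rodent / total,
        species_counts=species_counts,
        sex_counts_per_cohort=sex_cohort,
        sex_counts_per_study=sex_study,
        n_entries=len(entries),
        n_excluded_nr=len(excluded),
    )


def summarize_centers(
    records: Sequence[StudyRecord],
) -> tuple[float, tuple[int, int], float, tuple[int, int]]:
    """Median and range of total and experimental center counts.

    Total centers count each distinct center once even when it serves
    both an experimental and a coordinating role. Every record must
    carry an experimental-center count.
    """
    missing = [r.study_id for r in records if r.centers_experimental is None]
    if missing:
        raise ValidationError(
            f"missing center counts for: {', '.join(missing)}"
        )
    if not records:
        raise ValidationError("no studies supplied")
    totals = np.array([r.centers_total for r in records])
    exps = np.array([r.centers_experimental for r in records])
    return (
        float(np.median(totals)),
        (int(totals.min()), int(totals.max())),
        float(np.median(exps)),
        (int(exps.min()), int(exps.max())),
    )
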