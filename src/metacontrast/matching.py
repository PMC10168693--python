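"""Similarity-based selection of single-lab studies for a comparison.

Candidates are ranked against the reference multilaboratory study by a
transparent weighted sum of per-feature similarities — binary match for
species and sex, 1/(1+|delta|) proximity for intervention timing, dose,
measurement time and publication year — and the top k (default 10) are
selected. Ties at the selection boundary are broken by a seeded uniform
draw so the selection is reproducible, and per-feature contributions are
retained for audit.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .core import StudyRecord, ValidationError

#: Features scored when ranking candidates. Binary features match
#: exactly; proximity features decay as 1/(1+|difference|).
BINARY_FEATURES = ("species", "sex")
PROXIMITY_FEATURES = (
    "intervention_timing",
    "dose",
    "measurement_time",
    "year",
)


@dataclass
class SimilarityConfig:
    """Feature weights, selection size and tie-break seed."""

    weights: dict[str, float] = field(
        default_factory=lambda: {
            f: 1.0 for f in BINARY_FEATURES + PROXIMITY_FEATURES
        }
    )
    k: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if self.k < 1:
            raise ValidationError("selection size k must be >= 1")
        if any(w < 0 for w in self.weights.values()):
            raise ValidationError("feature weights must be >= 0")


def _feature(record: StudyRecord, name: str):
    if name == "species":
        return record.species or None
    if name == "sex":
        return record.sex.value if record.sex.value != "NR" else None
    if name == "year":
        return record.year
    # timing/dose/measurement-time live in an extras mapping when present
    extras = getattr(record, "extras", None)
    if extras:
        return extras.get(name)
    return None


def feature_similarities(
    candidate: StudyRecord, reference: StudyRecord
) -> dict[str, float]:
    """Per-feature similarity in [0, 1]; a missing feature contributes 0."""
    sims: dict[str, float] = {}
    for name in BINARY_FEATURES:
        c, r = _feature(candidate, name), _feature(reference, name)
        sims[name] = float(c is not None and r is not None and c == r)
    for name in PROXIMITY_FEATURES:
        c, r = _feature(candidate, name), _feature(reference, name)
        if c is None or r is None:
            sims[name] = 0.0
        else:
            sims[name] = 1.0 / (1.0 + abs(float(c) - float(r)))
    return sims


def similarity_score(
    candidate: StudyRecord,
    reference: StudyRecord,
    cfg: Optional[SimilarityConfig] = None,
) -> float:
    """Weighted sum of per-feature similarities (>= 0)."""
    cfg = cfg or SimilarityConfig()
    sims = feature_similarities(candidate, reference)
    return float(sum(cfg.weights.get(f, 0.0) * s for f, s in sims.items()))


def select_top_k(
    candidates: Sequence[StudyRecord],
    reference: StudyRecord,
    cfg: Optional[SimilarityConfig] = None,
) -> list[StudyRecord]:
    """Top-k candidates by similarity, seeded random draw within the
    boundary tie band.

    Sorting is by descending score with the study id as a stable,
    order-independent secondary key; when more candidates tie at the
    k-th score than fit, the required number is drawn uniformly from
    the tie band with the configured seed.
    """
    cfg = cfg or SimilarityConfig()
    if not candidates:
        raise ValidationError("no candidate studies supplied")
    if len(candidates) <= cfg.k:
        return list(candidates)

    scored = sorted(
        ((similarity_score(c, reference, cfg), c) for c in candidates),
        key=lambda t: (-t[0], t[1].study_id),
    )
    boundary_score = scored[cfg.k - 1][0]
    above = [c for s, c in scored if s > boundary_score]
    tied = [c for s, c in scored if s == boundary_score]
    n_needed = cfg.k - len(above)
    if len(tied) > n_needed:
        rng = np.random.default_rng(cfg.seed)
        tied_sorted = sorted(tied, key=lambda c: c.study_id)
        idx = rng.choice(len(tied_sorted), size=n_needed, replace=False)
        tied = [tied_sorted[i] for i in sorted(idx)]
    return above + tied
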