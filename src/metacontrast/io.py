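"""CSV interchange, pipeline composition, plots and output manifests.

The single tabular interchange format is UTF-8 CSV with a header row and
the sentinel "NR" for not-reported counts. A study occupies one row, or
several rows sharing a ``study_id`` when a multilaboratory study is
reported per center (the ``center`` column labels the stratum); the
per-center rows become strata and the aggregate arms are reconstructed
exactly from the stratum summaries. Row-level validation problems are
aggregated and reported together with their row numbers.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd

from .contrast import ContrastReport, ESR_TOLERANCE, contrast_report
from .core import (
    ArmSummary,
    CohortEntry,
    ComparisonSet,
    CharacteristicsSummary,
    Design,
    DispersionKind,
    Direction,
    NR,
    QualityFlags,
    Sex,
    StudyRecord,
    ValidationError,
    summarize_characteristics,
    summarize_centers,
)
from .effects import Metric
from .pooling import PoolModel
from .quality import QualityComparison, compare_quality

logger = logging.getLogger("metacontrast")

REQUIRED_COLUMNS = [
    "study_id", "design", "comparison_id", "outcome_label", "direction",
    "mean_treat", "dispersion_treat", "n_treat",
    "mean_control", "dispersion_control", "n_control", "dispersion_kind",
]
OPTIONAL_COLUMNS = [
    "center", "species", "sex", "year",
    "randomized", "low_rob_randomization_method", "blinded_personnel",
    "blinded_outcome_assessor", "complete_outcome_data",
    "centers_experimental", "centers_nonexperimental", "dual_role_centers",
    "total_animals", "intervention_timing", "dose", "measurement_time",
]


def _is_nr(value) -> bool:
    return (
        value is None
        or (isinstance(value, float) and np.isnan(value))
        or (isinstance(value, str) and value.strip().upper() in ("", NR, "NA"))
    )


def _opt_int(value) -> Optional[int]:
    return None if _is_nr(value) else int(value)


def combine_arms(arms: Sequence[ArmSummary]) -> ArmSummary:
    """Exact aggregate mean/SD of several strata of the same arm."""
    ns = np.array([a.n for a in arms])
    means = np.array([a.mean for a in arms])
    sds = np.array([a.sd for a in arms])
    n = int(ns.sum())
    mean = float(np.sum(ns * means) / n)
    # pooled sum of squares about the grand mean
    ss = np.sum((ns - 1) * sds**2) + np.sum(ns * (means - mean) ** 2)
    sd = float(np.sqrt(ss / (n - 1))) if n > 1 else 0.0
    return ArmSummary(mean=mean, dispersion=sd, n=n)


def _row_arms(row: pd.Series) -> tuple[ArmSummary, ArmSummary]:
    kind = DispersionKind(str(row["dispersion_kind"]).upper())
    treat = ArmSummary(
        float(row["mean_treat"]), float(row["dispersion_treat"]),
        int(row["n_treat"]), kind,
    )
    control = ArmSummary(
        float(row["mean_control"]), float(row["dispersion_control"]),
        int(row["n_control"]), kind,
    )
    if kind is DispersionKind.SE:
        logger.info(
            "row %s: dispersions given as SE; SD reconstructed as SE*sqrt(n)",
            row["study_id"],
        )
    return treat, control


def _row_flags(row: pd.Series) -> Optional[QualityFlags]:
    vals = [row.get(f) for f in QualityFlags.FIELDS]
    if any(_is_nr(v) for v in vals):
        return None
    return QualityFlags(*[int(v) for v in vals])


def _row_extras(row: pd.Series) -> dict:
    extras = {}
    for name in ("intervention_timing", "dose", "measurement_time"):
        v = row.get(name)
        if not _is_nr(v):
            extras[name] = float(v)
    return extras


def read_studies(path: Union[str, Path]) -> list[StudyRecord]:
    """Read and validate the study-level CSV into StudyRecords.

    Rows sharing a study_id (with distinct ``center`` labels) are merged
    into one multilaboratory record with per-center strata.
    """
    df = pd.read_csv(path, dtype={"study_id": str, "comparison_id": str})
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"missing required columns: {', '.join(missing)}")
    for c in OPTIONAL_COLUMNS:
        if c not in df.columns:
            df[c] = None

    errors: list[str] = []
    records: list[StudyRecord] = []
    for study_id, group in df.groupby("study_id", sort=False):
        try:
            first = group.iloc[0]
            strata = []
            if len(group) > 1 or not _is_nr(first.get("center")):
                for _, row in group.iterrows():
                    strata.append(_row_arms(row))
            if strata:
                treat = combine_arms([t for t, _ in strata])
                control = combine_arms([c for _, c in strata])
            else:
                treat, control = _row_arms(first)
            records.append(
                StudyRecord(
                    study_id=str(study_id),
                    design=Design(str(first["design"])),
                    comparison_id=str(first["comparison_id"]),
                    treatment_arm=treat,
                    control_arm=control,
                    outcome_label=str(first["outcome_label"]),
                    direction=Direction(str(first["direction"])),
                    species="" if _is_nr(first.get("species")) else str(first["species"]),
                    sex=Sex(str(first["sex"])) if not _is_nr(first.get("sex")) else Sex.NR,
                    year=_opt_int(first.get("year")),
                    quality_flags=_row_flags(first),
                    centers_experimental=_opt_int(first.get("centers_experimental")),
                    centers_nonexperimental=_opt_int(first.get("centers_nonexperimental")),
                    dual_role_centers=_opt_int(first.get("dual_role_centers")) or 0,
                    total_animals=_opt_int(first.get("total_animals")),
                    strata=strata if len(strata) > 1 else [],
                    extras=_row_extras(first),
                )
            )
        except (ValidationError, ValueError, KeyError) as exc:
            rows = ", ".join(str(i + 2) for i in group.index)  # 1-based + header
            errors.append(f"study {study_id} (rows {rows}): {exc}")
    center_key = df["center"].map(lambda v: "" if _is_nr(v) else str(v))
    counts = df.assign(_center=center_key).groupby(["study_id", "_center"]).size()
    for (sid, ctr), cnt in counts.items():
        if cnt > 1:
            where = f"center {ctr}" if ctr else "no center label"
            errors.append(f"study {sid}: {cnt} duplicate rows ({where})")
    if errors:
        raise ValidationError("invalid study table:\n  " + "\n  ".join(errors))
    return records


def write_studies(records: Sequence[StudyRecord], path: Union[str, Path]) -> None:
    """Write StudyRecords back to the interchange CSV (round-trips
    read_studies for aggregate rows; strata are written per center)."""
    rows = []
    for r in records:
        pairs = r.strata if r.strata else [(r.treatment_arm, r.control_arm)]
        for i, (t, c) in enumerate(pairs):
            row = {
                "study_id": r.study_id,
                "design": r.design.value,
                "comparison_id": r.comparison_id,
                "outcome_label": r.outcome_label,
                "direction": r.direction.value,
                "center": f"center{i + 1}" if r.strata else None,
                "mean_treat": t.mean,
                "dispersion_treat": t.dispersion,
                "n_treat": t.n,
                "mean_control": c.mean,
                "dispersion_control": c.dispersion,
                "n_control": c.n,
                "dispersion_kind": t.dispersion_kind.value,
                "species": r.species or None,
                "sex": r.sex.value,
                "year": r.year,
                "centers_experimental": r.centers_experimental,
                "centers_nonexperimental": r.centers_nonexperimental,
                "dual_role_centers": r.dual_role_centers or None,
                "total_animals": r.total_animals,
            }
            if r.quality_flags is not None:
                row.update(dict(zip(QualityFlags.FIELDS, r.quality_flags.as_tuple())))
            row.update(r.extras)
            rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)


def build_comparisons(records: Sequence[StudyRecord]) -> list[ComparisonSet]:
    """Group studies by comparison_id into validated ComparisonSets."""
    groups: dict[str, list[StudyRecord]] = {}
    for r in records:
        groups.setdefault(r.comparison_id, []).append(r)
    errors, out = [], []
    for cid, members in groups.items():
        multis = [m for m in members if m.design is Design.multilab]
        singles = [m for m in members if m.design is Design.single]
        if len(multis) != 1:
            errors.append(
                f"comparison {cid}: expected exactly 1 multilab study, "
                f"found {len(multis)}"
            )
            continue
        try:
            out.append(
                ComparisonSet(
                    comparison_id=cid,
                    multilab=multis[0],
                    singles=singles,
                    outcome_label=multis[0].outcome_label,
                )
            )
        except ValidationError as exc:
            errors.append(str(exc))
    if errors:
        raise ValidationError("invalid comparison map:\n  " + "\n  ".join(errors))
    return out


def read_comparisons(path: Union[str, Path]) -> list[ComparisonSet]:
    """Read the study CSV and group it into comparisons."""
    return build_comparisons(read_studies(path))


def read_characteristics(path: Union[str, Path]) -> tuple[list[CohortEntry], list[StudyRecord]]:
    """Read a study-characteristics table (one row per species cohort).

    Columns: study_id, design, species, sex, year, n (integer or "NR"),
    centers_experimental, centers_nonexperimental, dual_role_centers.
    Returns the cohort entries for sample-size descriptives and skeleton
    records (one per study) for center descriptives.
    """
    df = pd.read_csv(path, dtype={"study_id": str})
    entries: list[CohortEntry] = []
    errors: list[str] = []
    for i, row in df.iterrows():
        n = NR if _is_nr(row["n"]) else int(row["n"])
        if isinstance(n, int) and n < 0:
            errors.append(f"row {i + 2}: negative n for study {row['study_id']}")
        if n == NR:
            logger.info("row %d: NR sample size (study %s)", i + 2, row["study_id"])
        entries.append(
            CohortEntry(
                study_id=str(row["study_id"]),
                n=n,
                species=str(row.get("species", "") or ""),
                sex=str(row["sex"]) if not _is_nr(row.get("sex")) else Sex.NR.value,
            )
        )
    if errors:
        raise ValidationError("invalid characteristics table:\n  " + "\n  ".join(errors))
    dummy = ArmSummary(0.0, 1.0, 2)
    studies: list[StudyRecord] = []
    for sid, group in df.groupby("study_id", sort=False):
        first = group.iloc[0]
        studies.append(
            StudyRecord(
                study_id=str(sid),
                design=Design(str(first.get("design", "multilab"))),
                comparison_id=str(sid),
                treatment_arm=dummy,
                control_arm=dummy,
                species=str(first.get("species", "") or ""),
                sex=Sex(str(first["sex"])) if not _is_nr(first.get("sex")) else Sex.NR,
                year=_opt_int(first.get("year")),
                centers_experimental=_opt_int(first.get("centers_experimental")),
                centers_nonexperimental=_opt_int(first.get("centers_nonexperimental")),
                dual_role_centers=_opt_int(first.get("dual_role_centers")) or 0,
            )
        )
    return entries, studies


# ---------------------------------------------------------------------------
# pipeline

@dataclass
class PipelineConfig:
    studies_path: Union[str, Path]
    out_dir: Union[str, Path]
    characteristics_path: Optional[Union[str, Path]] = None
    metric: Metric = Metric.g
    model: PoolModel = PoolModel.random
    weighting: str = "inverse_variance"
    esr_tolerance: float = ESR_TOLERANCE
    seed: int = 0
    make_plots: bool = True


@dataclass
class PipelineResult:
    contrast: ContrastReport
    quality: Optional[QualityComparison]
    characteristics: Optional[CharacteristicsSummary]
    centers: Optional[tuple] = None
    manifest: dict = field(default_factory=dict)


def _config_hash(cfg: PipelineConfig) -> str:
    # analytic settings only; where outputs land must not change the hash
    fields = {
        k: str(v) for k, v in asdict(cfg).items()
        if k not in ("out_dir", "make_plots")
    }
    payload = json.dumps(fields, sort_keys=True)
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _pooled_to_dict(p) -> dict:
    return {
        "point": p.point, "se": p.se, "ci_low": p.ci_low, "ci_high": p.ci_high,
        "tau2": p.tau2, "q": p.q, "k": p.k, "p_value": p.p_value,
        "model": p.model.value,
    }


def contrast_to_dict(report: ContrastReport) -> dict:
    return {
        "pooled_dsmd": _pooled_to_dict(report.pooled_dsmd),
        "median_esr": report.median_esr,
        "esr_range": list(report.esr_range),
        "n_comparisons": report.n_comparisons,
        "n_single_larger": report.n_single_larger,
        "n_dsmd_ties": report.n_dsmd_ties,
        "n_esr_gt_1": report.n_esr_gt_1,
        "n_ci_nonoverlap": report.n_ci_nonoverlap,
        "per_comparison": [
            {
                "comparison_id": d.comparison_id,
                "dsmd": d.dsmd, "se": d.se,
                "ci_low": d.ci_low, "ci_high": d.ci_high,
                "d_single": _pooled_to_dict(d.d_single),
                "d_multi": _pooled_to_dict(d.d_multi),
                "esr": e.esr, "esr_degenerate": e.degenerate,
            }
            for d, e in zip(report.per_comparison_dsmd, report.per_comparison_esr)
        ],
    }


def forest_plot_dsmd(report: ContrastReport, path: Union[str, Path]) -> None:
    """One row per comparison plus the pooled diamond."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    rows = report.per_comparison_dsmd
    fig, ax = plt.subplots(figsize=(6, 0.4 * len(rows) + 1.5))
    ys = np.arange(len(rows), 0, -1)
    for y, r in zip(ys, rows):
        ax.plot([r.ci_low, r.ci_high], [y, y], color="k", lw=1)
        ax.plot(r.dsmd, y, "ks", ms=4)
    p = report.pooled_dsmd
    ax.fill(
        [p.ci_low, p.point, p.ci_high, p.point],
        [0, 0.25, 0, -0.25],
        color="0.3",
    )
    ax.axvline(0.0, color="0.6", ls="--", lw=0.8)
    ax.set_yticks(list(ys) + [0])
    ax.set_yticklabels([r.comparison_id for r in rows] + ["pooled"])
    ax.set_xlabel("DSMD (single-lab pool minus multilab)")
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)


def forest_plot_comparisons(
    comparisons: Sequence[ComparisonSet],
    report: ContrastReport,
    path: Union[str, Path],
) -> None:
    """Per-comparison panels: single-lab studies, their pool, the multilab
    estimate."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    from .contrast import study_effect

    n = len(comparisons)
    ncols = min(3, n)
    nrows = int(np.ceil(n / ncols))
    fig, axes = plt.subplots(
        nrows, ncols, figsize=(4 * ncols, 2.5 * nrows), squeeze=False
    )
    for ax in axes.ravel()[n:]:
        ax.axis("off")
    for ax, comp, d in zip(
        axes.ravel(), comparisons, report.per_comparison_dsmd
    ):
        effects = [study_effect(s) for s in comp.singles]
        ys = np.arange(len(effects), 0, -1)
        for y, e in zip(ys, effects):
            ax.plot([e.ci_low, e.ci_high], [y, y], color="0.5", lw=1)
            ax.plot(e.point, y, "o", color="0.5", ms=3)
        ax.plot(
            [d.d_single.ci_low, d.d_single.ci_high], [0, 0], color="k", lw=2
        )
        ax.plot(d.d_single.point, 0, "kD", ms=5)
        ax.plot(
            [d.d_multi.ci_low, d.d_multi.ci_high], [-1, -1], color="b", lw=2
        )
        ax.plot(d.d_multi.point, -1, "bD", ms=5)
        ax.axvline(0.0, color="0.8", ls="--", lw=0.8)
        ax.set_title(comp.comparison_id, fontsize=8)
        ax.set_yticks([])
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)


def run_pipeline(cfg: PipelineConfig) -> PipelineResult:
    """End-to-end run: read studies, contrast designs, compare quality,
    summarize characteristics, write outputs and a manifest."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    records = read_studies(cfg.studies_path)
    comparisons = build_comparisons(records)
    report = contrast_report(
        comparisons,
        metric=cfg.metric,
        model=cfg.model,
        weighting=cfg.weighting,
        esr_tolerance=cfg.esr_tolerance,
    )

    multi_flags = [
        r.quality_flags for r in records
        if r.design is Design.multilab and r.quality_flags is not None
    ]
    single_flags = [
        r.quality_flags for r in records
        if r.design is Design.single and r.quality_flags is not None
    ]
    quality = (
        compare_quality(multi_flags, single_flags)
        if multi_flags and single_flags
        else None
    )

    characteristics = centers = None
    if cfg.characteristics_path is not None:
        entries, studies = read_characteristics(cfg.characteristics_path)
        characteristics = summarize_characteristics(entries)
        centers = summarize_centers(studies)

    manifest = {
        "config_hash": _config_hash(cfg),
        "seed": cfg.seed,
        "n_studies": len(records),
        "n_comparisons": len(comparisons),
    }
    payload = {"manifest": manifest, "contrast": contrast_to_dict(report)}
    if quality is not None:
        payload["quality"] = {
            "median_multi": quality.median_multi,
            "range_multi": list(quality.range_multi),
            "median_single": quality.median_single,
            "range_single": list(quality.range_single),
            "u_statistic": quality.u_statistic,
            "p_value": quality.p_value,
            "prop_ge3_multi": quality.prop_ge3_multi,
            "prop_ge3_single": quality.prop_ge3_single,
            "practice_rates_multi": quality.practice_rates_multi,
            "practice_rates_single": quality.practice_rates_single,
        }
    if characteristics is not None:
        payload["characteristics"] = {
            "median_n": characteristics.median_n,
            "n_range": list(characteristics.n_range),
            "total_animals": characteristics.total_animals,
            "pct_rodent": characteristics.pct_rodent,
            "pct_rodent_display": characteristics.pct_rodent_display,
        }
        payload["centers"] = {
            "median_total": centers[0], "range_total": list(centers[1]),
            "median_experimental": centers[2],
            "range_experimental": list(centers[3]),
        }
    (out / "report.json").write_text(json.dumps(payload, indent=2, sort_keys=True))

    per_comp = pd.DataFrame(
        [
            {
                "comparison_id": d.comparison_id,
                "dsmd": d.dsmd, "se": d.se,
                "ci_low": d.ci_low, "ci_high": d.ci_high,
                "d_single": d.d_single.point, "d_multi": d.d_multi.point,
                "esr": e.esr,
            }
            for d, e in zip(report.per_comparison_dsmd, report.per_comparison_esr)
        ]
    )
    per_comp.to_csv(out / "contrast.csv", index=False)
    if cfg.make_plots:
        forest_plot_dsmd(report, out / "forest_dsmd.svg")
        forest_plot_comparisons(comparisons, report, out / "forest_comparisons.svg")
    return PipelineResult(
        contrast=report,
        quality=quality,
        characteristics=characteristics,
        centers=centers,
        manifest=manifest,
    )
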