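"""metacontrast: meta-epidemiological comparison of multilaboratory and
single-laboratory preclinical study effect sizes.

Computes standardized mean differences from two-arm summary statistics,
pools them with DerSimonian-Laird random-effects meta-analysis, and
contrasts study designs through the difference in standardized mean
differences (DSMD) and the effect size ratio (ESR), alongside a
Mann-Whitney comparison of methodological-quality scores and a
ground-truth synthetic-data generator for validation.
"""

from importlib.resources import files as _files

from .core import (
    ArmSummary,
    CohortEntry,
    ComparisonSet,
    CharacteristicsSummary,
    Design,
    Direction,
    DispersionKind,
    QualityFlags,
    Sex,
    StudyRecord,
    ValidationError,
    summarize_centers,
    summarize_characteristics,
)
from .effects import (
    EffectEstimate,
    EffectSizeError,
    Metric,
    hedges_j,
    orient,
    pooled_sd,
    smd,
)
from .pooling import (
    PooledEstimate,
    PoolModel,
    PoolingError,
    dl_tau2,
    fixed_pool,
    pool,
    random_pool,
)
from .contrast import (
    ContrastReport,
    DsmdResult,
    EsrResult,
    ci_nonoverlap_count,
    contrast_report,
    direction_count,
    dsmd,
    esr,
    median_esr,
    pool_dsmd,
    study_effect,
)
from .quality import (
    QualityComparison,
    compare_quality,
    mann_whitney,
    proportion_at_least,
    total_score,
)
from .matching import SimilarityConfig, select_top_k, similarity_score
from .simulate import (
    RecoveryReport,
    SimConfig,
    recovery_experiment,
    simulate_comparison,
    simulate_corpus,
)
from .io import (
    PipelineConfig,
    PipelineResult,
    build_comparisons,
    read_characteristics,
    read_comparisons,
    read_studies,
    run_pipeline,
    write_studies,
)

__version__ = "0.1.0"


def multilab_characteristics_path():
    """Path to the bundled characteristics table of the 16 published
    preclinical multilaboratory studies (one row per species cohort)."""
    return _files("metacontrast").joinpath("data/multilab_characteristics.csv")
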