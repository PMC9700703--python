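"""mwascreen: medication-wide association screening for pregnancy outcomes.

A tested pipeline from EHR-style event tables (patients, deliveries,
medication orders, diagnoses) to per-medication adjusted odds ratios for
cesarean section, preterm birth and stillbirth, with Bonferroni
family-wise control, a candidate-drug exclusion rule engine, privacy-
aware reporting, and a synthetic obstetric-EHR generator for validation.
"""

from importlib.resources import files as _files

__version__ = "0.1.0"


def data_path(name: str) -> str:
    """Path to a packaged fixture file (toy vocabulary, drug map, ...)."""
    return str(_files("mwascreen").joinpath("data", name))


from .codesets import CodeSet, IcdCode, Vocabulary, load_vocabulary, matches, normalize_code
from .cohort import build_cohort, summarize_cohort
from .covariates import build_covariates, in_lookback
from .errors import (
    AlignmentError,
    ConfigError,
    DegenerateDataError,
    MwasError,
    ValidationError,
)
from .exposure import (
    DrugMap,
    ExposureMatrix,
    apply_min_patient_filter,
    build_exposures,
    in_exposure_window,
)
from .reporting import export_forest, render_summary, run_pipeline, suppress_small_cells
from .screen import (
    AssociationResult,
    MedicationScreen,
    MedicationScreenResults,
    ScreenSpec,
    compare_goodness_of_fit,
    fit_single,
    run_screen,
)
from .simulate import (
    SimConfig,
    SimulatedCohort,
    default_config,
    exact_margins_fixture,
    simulate,
    simulate_analysis_matrix,
)
from .trials import CandidateDrug, apply_exclusions, load_candidates

__all__ = [
    "__version__",
    "data_path",
    # codesets
    "IcdCode", "CodeSet", "Vocabulary", "normalize_code", "matches", "load_vocabulary",
    # simulate
    "SimConfig", "SimulatedCohort", "default_config", "simulate",
    "simulate_analysis_matrix", "exact_margins_fixture",
    # cohort & covariates
    "build_cohort", "summarize_cohort", "build_covariates", "in_lookback",
    # exposure
    "DrugMap", "ExposureMatrix", "in_exposure_window", "build_exposures",
    "apply_min_patient_filter",
    # screen
    "MedicationScreen", "MedicationScreenResults", "AssociationResult",
    "ScreenSpec", "fit_single", "run_screen", "compare_goodness_of_fit",
    # trials & reporting
    "CandidateDrug", "apply_exclusions", "load_candidates",
    "suppress_small_cells", "render_summary", "export_forest", "run_pipeline",
    # errors
    "MwasError", "ValidationError", "ConfigError", "DegenerateDataError", "AlignmentError",
]
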