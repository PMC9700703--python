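"""Privacy-aware rendering, forest export, and the pipeline driver.

Every user-facing table passes through small-cell suppression: any
reported count of patients or deliveries below 10 is replaced by a mask
token, and percentages derived from masked counts are masked too, since
a percentage at a known denominator reveals the count.
"""

from __future__ import annotations

import json
import logging
import shutil
from dataclasses import dataclass
from datetime import date
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import MwasError, ValidationError

__all__ = [
    "MASK_TOKEN",
    "SUPPRESSION_THRESHOLD",
    "suppress_small_cells",
    "render_summary",
    "render_association_table",
    "ForestRow",
    "export_forest",
    "run_pipeline",
]

logger = logging.getLogger(__name__)

MASK_TOKEN = "*"
SUPPRESSION_THRESHOLD = 10


def suppress_small_cells(count: int, threshold: int = SUPPRESSION_THRESHOLD) -> str:
    """Render a count: masked below the threshold, else with thousands
    separators.

    >>> suppress_small_cells(9)
    '*'
    >>> suppress_small_cells(5071)
    '5,071'
    """
    if count < 0:
        raise ValidationError(f"negative count: {count}")
    if count < threshold:
        return MASK_TOKEN
    return f"{int(count):,}"


def _render_pair(n, pct, threshold) -> tuple[str, str]:
    n = int(n)
    if n < threshold:
        return MASK_TOKEN, MASK_TOKEN
    return f"{n:,}", f"{pct:.2f}"


def render_summary(summary: pd.DataFrame, threshold: int = SUPPRESSION_THRESHOLD) -> pd.DataFrame:
    """String-render a cohort summary with small-cell suppression.

    Count cells below the threshold and their percentages become the
    mask token.  The mean-age row passes through unmasked (it is a mean,
    not a count).
    """
    out = []
    for _, row in summary.iterrows():
        if row["section"] == "maternal_age":
            out.append(
                {
                    "section": row["section"],
                    "row": row["row"],
                    "unexposed": f"{row['unexposed_n']:.2f} ± {row['unexposed_pct']:.2f}",
                    "exposed": f"{row['exposed_n']:.2f} ± {row['exposed_pct']:.2f}",
                    "total": f"{row['total_n']:.2f} ± {row['total_pct']:.2f}",
                }
            )
            continue
        cells = {}
        for stratum in ("unexposed", "exposed", "total"):
            n, pct = _render_pair(row[f"{stratum}_n"], row[f"{stratum}_pct"], threshold)
            cells[stratum] = MASK_TOKEN if n == MASK_TOKEN else f"{n} ({pct}%)"
        out.append({"section": row["section"], "row": row["row"], **cells})
    return pd.DataFrame(out)


def render_association_table(results, threshold: int = SUPPRESSION_THRESHOLD) -> pd.DataFrame:
    """Suppress small exposure counts in the wide association table."""
    table = results.association_table().copy()
    table["n_exposed"] = table["n_exposed"].map(
        lambda n: suppress_small_cells(int(n), threshold)
    )
    return table


@dataclass(frozen=True)
class ForestRow:
    """One interval in a forest-plot panel."""

    label: str
    estimate: float
    ci_low: float
    ci_high: float
    group: str  # "medication" | "covariate"
    outcome: str


def export_forest(results, alpha: float = 0.05) -> pd.DataFrame:
    """Forest-plot data: nominally significant medications and covariates.

    One panel per (outcome, group); within a panel rows are ordered by
    estimate.  Medication rows use the screen's adjusted ORs; covariate
    rows use the per-outcome covariate reference model.  Empty input
    yields an empty frame with the right columns.
    """
    rows: list[ForestRow] = []
    for r in results.results:
        if r.converged and np.isfinite(r.p_nominal) and r.p_nominal <= alpha:
            rows.append(
                ForestRow(r.medication, r.or_estimate, r.ci_low, r.ci_high,
                          "medication", r.outcome)
            )
    for outcome, ref in results.covariate_models.items():
        for term, rec in ref.iterrows():
            if np.isfinite(rec["p"]) and rec["p"] <= alpha:
                rows.append(
                    ForestRow(str(term), float(rec["or"]), float(rec["ci_low"]),
                              float(rec["ci_high"]), "covariate", outcome)
                )
    frame = pd.DataFrame(
        [r.__dict__ for r in rows],
        columns=["label", "estimate", "ci_low", "ci_high", "group", "outcome"],
    )
    return frame.sort_values(
        ["outcome", "group", "estimate", "label"], kind="stable"
    ).reset_index(drop=True)


# ---------------------------------------------------------------------
# end-to-end driver
# ---------------------------------------------------------------------

def _load_config(config) -> dict:
    if isinstance(config, dict):
        return config
    import yaml

    with open(config) as fh:
        return yaml.safe_load(fh)


def run_pipeline(config, out_dir: str | Path) -> dict:
    """Run every stage end to end and write the artifact bundle.

    ``config`` is a dict or a YAML path with keys:

    - ``simulate``: keyword overrides for the synthetic generator
      (alternatively ``tables``: a directory of pre-existing
      patients/deliveries/orders/diagnoses CSVs);
    - ``vocabulary``, ``drug_map``, ``candidates``: file paths
      (defaults: the packaged toy fixtures);
    - ``min_patients``, ``alpha``, ``bonferroni_m``, ``cutoff_year``.

    Writes: the candidate exclusion report, the cohort summary (masked),
    the association table (masked), the forest export, and a manifest
    with seeds, versions, per-stage record counts and the Bonferroni
    family size.  On failure, partial outputs are removed and the
    failing stage is named.
    """
    from . import __version__, data_path
    from .cohort import build_cohort, summarize_cohort
    from .covariates import build_covariates
    from .codesets import load_vocabulary
    from .exposure import DrugMap, apply_min_patient_filter, build_exposures
    from .screen import MedicationScreen
    from .simulate import default_config, simulate
    from .trials import apply_exclusions, exclusion_report, load_candidates

    cfg = _load_config(config)
    out = Path(out_dir)
    created = not out.exists()
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"stages": {}, "version": __version__}
    stage = "setup"
    try:
        vocab = load_vocabulary(cfg.get("vocabulary", data_path("toy_vocabulary.csv")))
        drug_map = DrugMap.read_csv(cfg.get("drug_map", data_path("drug_map.csv")))

        stage = "trial_filter"
        candidates = load_candidates(cfg.get("candidates", data_path("candidate_drugs.csv")))
        kept, excluded = apply_exclusions(candidates, cutoff_year=cfg.get("cutoff_year", 2017))
        exclusion_report(excluded).to_csv(out / "exclusion_report.csv", index=False)
        manifest["stages"]["trial_filter"] = {
            "candidates": len(candidates), "kept": len(kept), "excluded": len(excluded),
        }
        kept_names = {d.name.lower() for d in kept}

        stage = "simulate"
        if "tables" in cfg:
            tdir = Path(cfg["tables"])
            patients = pd.read_csv(tdir / "patients.csv", parse_dates=["birth_date"])
            deliveries = pd.read_csv(tdir / "deliveries.csv", parse_dates=["delivery_date"])
            orders = pd.read_csv(tdir / "orders.csv", parse_dates=["order_date"])
            diagnoses = pd.read_csv(tdir / "diagnoses.csv", parse_dates=["date"])
            manifest["stages"]["input"] = {"tables_dir": str(tdir)}
        else:
            sim_cfg = default_config(**cfg.get("simulate", {}))
            cohort_sim = simulate(sim_cfg)
            patients, deliveries = cohort_sim.patients, cohort_sim.deliveries
            orders, diagnoses = cohort_sim.orders, cohort_sim.diagnoses
            manifest["stages"]["simulate"] = {
                "seed": sim_cfg.seed,
                "n_patients": int(len(patients)),
                "n_deliveries": int(len(deliveries)),
                "n_orders": int(len(orders)),
                "n_diagnoses": int(len(diagnoses)),
            }

        stage = "cohort_outcomes"
        cohort = build_cohort(deliveries, diagnoses, vocab, patients=patients)
        manifest["stages"]["cohort_outcomes"] = {"deliveries": int(len(cohort))}

        stage = "exposure"
        # restrict the screen to medication variables whose ingredient
        # survived the candidate-drug exclusions, when kept names overlap
        expo_all = build_exposures(orders, cohort, drug_map)
        candidate_vars = [v for v in expo_all.variables if v.lower() in kept_names]
        if candidate_vars:
            expo_all = type(expo_all)(
                expo_all.data[candidate_vars],
                expo_all.patient_counts[candidate_vars],
                expo_all.delivery_counts[candidate_vars],
            )
        expo = apply_min_patient_filter(expo_all, threshold=cfg.get("min_patients", 10))
        manifest["stages"]["exposure"] = {
            "variables_before_filter": len(expo_all.variables),
            "variables_screened": len(expo.variables),
        }

        stage = "covariates"
        covs = build_covariates(cohort, diagnoses, vocab, patients)
        manifest["stages"]["covariates"] = {"columns": int(covs.shape[1])}

        stage = "screen"
        model = MedicationScreen(
            cohort.set_index("delivery_id")[["cesarean", "preterm", "stillbirth"]],
            expo, covs,
            alpha=cfg.get("alpha", 0.05), bonferroni_m=cfg.get("bonferroni_m"),
        )
        results = model.fit()
        manifest["stages"]["screen"] = {
            "tests": len(results.results),
            "bonferroni_m": results.bonferroni_m,
            "outcomes": len(model.spec.outcomes),
            "medications_screened": len(model.spec.medications),
            "alpha": model.spec.alpha,
        }

        stage = "report"
        summary = summarize_cohort(cohort, expo.any_exposure().values, covariates=covs)
        render_summary(summary).to_csv(out / "cohort_summary.csv", index=False)
        render_association_table(results).to_csv(out / "association_table.csv", index=False)
        results.forest_rows().to_csv(out / "forest_export.csv", index=False)
        (out / "screen_summary.txt").write_text(results.summary() + "\n")
        manifest["run_date"] = date.today().isoformat()
        manifest["config"] = {k: v for k, v in cfg.items() if k != "tables"}
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
        return manifest
    except MwasError:
        if created:
            shutil.rmtree(out, ignore_errors=True)
        else:
            for f in ("exclusion_report.csv", "cohort_summary.csv",
                      "association_table.csv", "forest_export.csv",
                      "screen_summary.txt", "manifest.json"):
                (out / f).unlink(missing_ok=True)
        logger.error("pipeline failed in stage %s", stage)
        raise
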