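import json
import re

import numpy as np
import pandas as pd
import pytest

import mwascreen as mw
from mwascreen.cohort import summarize_cohort
from mwascreen.reporting import (
    MASK_TOKEN,
    export_forest,
    render_summary,
    run_pipeline,
    suppress_small_cells,
)


class TestSuppression:
    @pytest.mark.parametrize(
        "count, rendered",
        [(0, MASK_TOKEN), (9, MASK_TOKEN), (10, "10"), (5071, "5,071"), (63334, "63,334")],
    )
    def test_boundaries_and_formatting(self, count, rendered):
        assert suppress_small_cells(count) == rendered

    def test_negative_count_rejected(self):
        with pytest.raises(mw.ValidationError):
            suppress_small_cells(-1)

    def test_rendered_summary_masks_counts_and_their_percentages(self):
        cohort = pd.DataFrame(
            {
                "patient_id": [f"P{i}" for i in range(40)],
                "delivery_id": [f"D{i}" for i in range(40)],
                "cesarean": [1] * 9 + [0] * 31,
                "preterm": [1] * 12 + [0] * 28,
                "stillbirth": [0] * 40,
            }
        )
        s = summarize_cohort(cohort, np.zeros(40, bool))
        rendered = render_summary(s).set_index("row")
        assert rendered.loc["cesarean", "total"] == MASK_TOKEN  # 9 -> masked, pct too
        assert rendered.loc["preterm", "total"] == "12 (30.00%)"


def _fitted_results(planted=None, n=8000, seed=2, null_covariates=False):
    overrides = dict(
        medication_base_exposure_prob={"drugA": 0.10, "drugB": 0.08},
        covariate_exposure_log_odds={},
        planted_log_or=planted or {},
        seed=seed,
        drug_name_synonyms={"drugA": ["drugA"], "drugB": ["drugB"]},
    )
    if null_covariates:
        overrides["covariate_outcome_log_odds"] = {}
    cfg = mw.default_config(**overrides)
    m = mw.simulate_analysis_matrix(cfg, n_deliveries=n)
    outcomes = m[["cesarean", "preterm", "stillbirth"]]
    expo = m[["rx_drugA", "rx_drugB"]].rename(columns=lambda c: c.removeprefix("rx_"))
    covs = m[cfg.covariates + ["maternal_age"]]
    return mw.MedicationScreen(outcomes, expo, covs).fit()


class TestForestExport:
    def test_empty_results_empty_export(self):
        res = _fitted_results(seed=4, null_covariates=True)
        out = export_forest(res, alpha=1e-12)  # nothing this significant under the null
        assert len(out) == 0
        assert list(out.columns) == ["label", "estimate", "ci_low", "ci_high", "group", "outcome"]

    def test_planted_strong_effect_appears_in_its_panel(self):
        res = _fitted_results(planted={("drugA", "cesarean"): np.log(3.0)})
        out = export_forest(res, alpha=0.05)
        meds = out[(out.group == "medication") & (out.outcome == "cesarean")]
        assert "drugA" in set(meds.label)

    def test_only_significant_rows_and_ordering(self):
        res = _fitted_results(planted={("drugA", "cesarean"): np.log(3.0)})
        out = export_forest(res, alpha=0.05)
        for (_, _), grp in out.groupby(["outcome", "group"]):
            assert grp["estimate"].is_monotonic_increasing
        assert (out["ci_low"] <= out["estimate"]).all()
        assert (out["estimate"] <= out["ci_high"]).all()


PIPELINE_CFG = {
    "simulate": {"n_patients": 1200, "seed": 77},
    "min_patients": 5,
}


class TestPipeline:
    def test_end_to_end_artifacts_and_manifest(self, tmp_path):
        manifest = run_pipeline(PIPELINE_CFG, tmp_path / "run")
        for f in ("exclusion_report.csv", "cohort_summary.csv", "association_table.csv",
                  "forest_export.csv", "screen_summary.txt", "manifest.json"):
            assert (tmp_path / "run" / f).exists()
        assert manifest["stages"]["screen"]["outcomes"] == 3
        assert manifest["stages"]["screen"]["medications_screened"] >= 1
        on_disk = json.loads((tmp_path / "run" / "manifest.json").read_text())
        assert on_disk["stages"]["simulate"]["seed"] == 77

    def test_same_seed_byte_identical_association_tables(self, tmp_path):
        run_pipeline(PIPELINE_CFG, tmp_path / "a")
        run_pipeline(PIPELINE_CFG, tmp_path / "b")
        assert (tmp_path / "a" / "association_table.csv").read_bytes() == (
            tmp_path / "b" / "association_table.csv"
        ).read_bytes()

    def test_no_unmasked_small_count_in_user_facing_tables(self, tmp_path):
        run_pipeline(PIPELINE_CFG, tmp_path / "run")
        summary = pd.read_csv(tmp_path / "run" / "cohort_summary.csv")
        for cell in summary[["unexposed", "exposed", "total"]].values.ravel():
            m = re.match(r"^([\d,]+)(?: \()", str(cell))
            if m:
                assert int(m.group(1).replace(",", "")) >= 10
        assoc = pd.read_csv(tmp_path / "run" / "association_table.csv")
        for cell in assoc["n_exposed"]:
            if str(cell) != MASK_TOKEN:
                assert int(str(cell).replace(",", "")) >= 10

    def test_failure_removes_partial_outputs(self, tmp_path):
        bad = {"simulate": {"n_patients": -5}}
        with pytest.raises(mw.MwasError):
            run_pipeline(bad, tmp_path / "bad")
        assert not (tmp_path / "bad").exists()


class TestCli:
    def test_simulate_then_screen_roundtrip(self, tmp_path):
        from click.testing import CliRunner

        from mwascreen.cli import main

        runner = CliRunner()
        r = runner.invoke(
            main, ["simulate", "--n-patients", "800", "--seed", "5", "--out-dir", str(tmp_path / "t")]
        )
        assert r.exit_code == 0, r.output
        r = runner.invoke(
            main,
            ["screen", "--tables", str(tmp_path / "t"), "--min-patients", "5",
             "--out", str(tmp_path / "results.csv")],
        )
        assert r.exit_code == 0, r.output
        frame = pd.read_csv(tmp_path / "results.csv")
        assert {"medication", "outcome", "or_estimate", "p_bonferroni"} <= set(frame.columns)

    def test_filter_trials_command(self, tmp_path):
        from click.testing import CliRunner

        from mwascreen.cli import main

        r = CliRunner().invoke(main, ["filter-trials", "--out", str(tmp_path / "kept.csv")])
        assert r.exit_code == 0, r.output
        kept = pd.read_csv(tmp_path / "kept.csv")
        assert "hydroxychloroquine" in set(kept["name"])
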