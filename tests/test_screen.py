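import numpy as np
import pandas as pd
import pytest

import mwascreen as mw
from mwascreen.errors import AlignmentError, DegenerateDataError
from mwascreen.screen import (
    MedicationScreen,
    ScreenSpec,
    compare_goodness_of_fit,
    fit_single,
    run_screen,
)


def _two_by_two(a, b, c, d):
    """Exposed: a events / b non-events; unexposed: c events / d non-events."""
    y = np.r_[np.ones(a), np.zeros(b), np.ones(c), np.zeros(d)]
    x = np.r_[np.ones(a + b), np.zeros(c + d)]
    return y, x


class TestFitSingle:
    def test_covariate_free_or_equals_cross_product_ratio(self):
        y, x = _two_by_two(30, 70, 90, 810)
        r = fit_single(y, x)
        oracle = (30 * 810) / (70 * 90)
        assert abs(r.or_estimate - oracle) / oracle < 1e-6
        assert r.ci_low < r.or_estimate < r.ci_high

    def test_random_tables_match_oracle(self):
        rng = np.random.default_rng(42)
        for _ in range(25):
            a, b, c, d = rng.integers(5, 200, size=4)
            y, x = _two_by_two(a, b, c, d)
            r = fit_single(y, x)
            oracle = (a * d) / (b * c)
            assert abs(r.or_estimate - oracle) / oracle < 1e-6

    def test_degenerate_outcome_and_exposure(self):
        with pytest.raises(DegenerateDataError, match="outcome"):
            fit_single(np.zeros(50), np.r_[np.ones(25), np.zeros(25)])
        with pytest.raises(DegenerateDataError, match="exposure"):
            fit_single(np.r_[np.ones(25), np.zeros(25)], np.ones(50))

    def test_perfect_separation_flagged_not_estimated(self):
        y = np.r_[np.ones(12), np.zeros(12)]
        r = fit_single(y, y.copy())
        assert r.separation_flag
        assert not r.converged
        assert np.isnan(r.or_estimate)

    def test_rare_covariate_without_events_does_not_break_fit(self):
        # a comorbidity whose only carriers have no events has an
        # infinite nuisance MLE; the exposure estimate must still come out
        rng = np.random.default_rng(0)
        n = 2000
        y = rng.binomial(1, 0.3, n)
        x = rng.binomial(1, 0.1, n)
        cov = np.zeros(n)
        cov[np.where(y == 0)[0][:3]] = 1
        r = fit_single(y, x, cov[:, None])
        assert r.converged

    def test_alignment_errors(self):
        y = np.r_[np.ones(5), np.zeros(5)]
        with pytest.raises(AlignmentError):
            fit_single(y, np.r_[np.ones(3), np.zeros(4)])


class TestGoodnessOfFit:
    def _fits(self, seed=1, beta_cov=1.0):
        rng = np.random.default_rng(seed)
        n = 3000
        c = rng.binomial(1, 0.3, n)
        x = rng.binomial(1, 0.2, n)
        p = 1 / (1 + np.exp(-(-1 + beta_cov * c)))
        y = rng.binomial(1, p)
        adj = fit_single(y, x, c[:, None].astype(float))
        unadj = fit_single(y, x)
        return adj, unadj

    def test_lr_statistic_nonnegative_and_df(self):
        adj, unadj = self._fits()
        g = compare_goodness_of_fit(adj, unadj)
        assert g.lr_stat >= 0
        assert g.df == 1
        assert g.p_value < 0.05  # the covariate truly matters here

    def test_identical_models_lr_zero(self):
        _, unadj = self._fits()
        g = compare_goodness_of_fit(unadj, unadj)
        assert g.lr_stat == 0
        assert g.df == 0

    def test_mismatched_rows_rejected(self):
        adj, _ = self._fits(seed=1)
        other = fit_single(
            np.r_[np.ones(10), np.zeros(10)], np.r_[np.ones(5), np.zeros(5), np.ones(5), np.zeros(5)]
        )
        with pytest.raises(AlignmentError):
            compare_goodness_of_fit(adj, other)


def _screen_inputs(n=4000, seed=0, planted=None):
    cfg = mw.default_config(
        medication_base_exposure_prob={"drugA": 0.08, "drugB": 0.05},
        covariate_exposure_log_odds={},
        planted_log_or=planted or {},
        seed=seed,
        drug_name_synonyms={"drugA": ["drugA"], "drugB": ["drugB"]},
    )
    m = mw.simulate_analysis_matrix(cfg, n_deliveries=n)
    outcomes = m[["cesarean", "preterm", "stillbirth"]]
    expo = m[[c for c in m.columns if c.startswith("rx_")]].rename(
        columns=lambda c: c.removeprefix("rx_")
    )
    covs = m[cfg.covariates + ["maternal_age"]]
    return outcomes, expo, covs


class TestScreen:
    def test_bonferroni_arithmetic_and_flags(self):
        outcomes, expo, covs = _screen_inputs()
        model = MedicationScreen(outcomes, expo, covs)
        res = model.fit()
        m = res.bonferroni_m
        assert m == len(expo.columns) * 3
        for r in res.results:
            if np.isfinite(r.p_nominal):
                assert r.p_bonferroni == min(1.0, r.p_nominal * m)
                assert r.p_bonferroni >= r.p_nominal
                assert r.sig_nominal == (r.p_nominal <= 0.05)
                assert r.sig_bonferroni == int(r.sig_nominal and r.p_bonferroni <= 0.05)

    def test_results_deterministically_ordered(self):
        outcomes, expo, covs = _screen_inputs()
        res = MedicationScreen(outcomes, expo, covs).fit()
        keys = [(r.medication, r.outcome) for r in res.results]
        assert keys == sorted(keys)

    def test_row_permutation_changes_nothing(self):
        outcomes, expo, covs = _screen_inputs()
        res_a = MedicationScreen(outcomes, expo, covs).fit()
        perm = np.random.default_rng(7).permutation(len(outcomes))
        res_b = MedicationScreen(
            outcomes.iloc[perm], expo.iloc[perm], covs.iloc[perm]
        ).fit()
        a, b = res_a.frame, res_b.frame
        pd.testing.assert_frame_equal(a, b)

    def test_degenerate_pair_yields_flagged_row_screen_continues(self):
        outcomes, expo, covs = _screen_inputs()
        expo = expo.copy()
        expo["drugB"] = 0  # constant exposure: degenerate
        res = MedicationScreen(outcomes, expo, covs).fit()
        bad = [r for r in res.results if r.medication == "drugB"]
        good = [r for r in res.results if r.medication == "drugA"]
        assert all(not r.converged and r.error for r in bad)
        assert any(r.converged for r in good)

    def test_planted_effect_recovered(self):
        outcomes, expo, covs = _screen_inputs(
            n=30_000, seed=3, planted={("drugA", "cesarean"): np.log(2.0)}
        )
        res = MedicationScreen(outcomes, expo, covs).fit()
        r = res[("drugA", "cesarean")]
        assert r.ci_low < 2.0 < r.ci_high
        assert r.sig_nominal == 1

    def test_misaligned_matrices_rejected(self):
        outcomes, expo, covs = _screen_inputs()
        with pytest.raises(AlignmentError):
            MedicationScreen(outcomes.iloc[:-1], expo, covs)

    def test_cluster_robust_option_runs(self):
        outcomes, expo, covs = _screen_inputs(n=2000)
        groups = np.arange(len(outcomes)) // 2
        res = MedicationScreen(outcomes, expo, covs, cluster_groups=groups).fit()
        assert any(r.converged for r in res.results)

    def test_run_screen_wrapper_matches_model(self):
        outcomes, expo, covs = _screen_inputs()
        cohort = outcomes.reset_index().rename(columns={"index": "delivery_id"})
        spec = ScreenSpec(medications=sorted(expo.columns),
                          covariate_names=list(covs.columns))
        results = run_screen(spec, expo, covs, outcomes)
        direct = MedicationScreen(outcomes, expo, covs).fit().results
        assert [(r.medication, r.outcome, r.or_estimate) for r in results] == [
            (r.medication, r.outcome, r.or_estimate) for r in direct
        ]

    def test_summary_header_states_family_size(self):
        outcomes, expo, covs = _screen_inputs()
        res = MedicationScreen(outcomes, expo, covs).fit()
        text = res.summary()
        assert f"Bonferroni m = {res.bonferroni_m}" in text
        assert "family" in text
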