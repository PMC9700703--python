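"""The medication-wide association screen.

For every retained medication variable and every delivery outcome, a
separate maximum-likelihood logistic regression is fit:

    logit P(outcome) = b0 + b1*exposure + b2*maternal_age + b'*covariates

The reported association is the adjusted odds ratio ``exp(b1)`` with a
Wald 95% confidence interval ``exp(b1 +/- 1.959964*SE)`` and a two-sided
Wald p-value.  Family-wise error across the screen is controlled by
Bonferroni: ``p_bonf = min(1, m * p)``, with ``m`` defaulting to
(number of medications) x (number of outcomes).  Whether the family is
the full screen or one outcome's medications is a genuine modelling
choice; the default and the ``m`` actually used are stated in every
report header.

Deliveries are treated as independent observations even when one
patient contributes several; a patient-clustered sandwich variance is
available as an extension (``cluster_groups``).  Perfect separation is
flagged and the estimate withheld rather than penalized: the screen is
a plain-MLE screen, and a diverging coefficient (|b1| > 10 on the log
odds scale) is evidence the data cannot support the model, not an
estimate.

The public surface is modelled on statsmodels: construct a
:class:`MedicationScreen` from aligned matrices (or straight from the
four event tables via :meth:`MedicationScreen.from_tables`), call
``fit()``, and read estimates, intervals and diagnostics off the
returned :class:`MedicationScreenResults`.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
import statsmodels.api as sm
from statsmodels.tools.sm_exceptions import PerfectSeparationError

from .errors import AlignmentError, DegenerateDataError, ValidationError
from .exposure import ExposureMatrix
from .simulate import OUTCOMES

__all__ = [
    "WALD_Z",
    "AssociationResult",
    "ScreenSpec",
    "GoodnessOfFit",
    "fit_single",
    "run_screen",
    "compare_goodness_of_fit",
    "MedicationScreen",
    "MedicationScreenResults",
]

WALD_Z = 1.959964  # two-sided 95% normal quantile
SEPARATION_COEF = 10.0  # |log OR| beyond this is treated as separation


@dataclass
class AssociationResult:
    """One medication x outcome association from the screen."""

    medication: str
    outcome: str
    n_exposed: int
    or_estimate: float = np.nan
    ci_low: float = np.nan
    ci_high: float = np.nan
    p_nominal: float = np.nan
    p_bonferroni: float = np.nan
    sig_nominal: int = 0
    sig_bonferroni: int = 0
    converged: bool = False
    separation_flag: bool = False
    error: str | None = None
    # fit diagnostics (populated when the fit succeeds)
    llf: float = np.nan
    aic: float = np.nan
    df_model: int = 0
    n_obs: int = 0

    @property
    def log_or(self) -> float:
        return float(np.log(self.or_estimate)) if np.isfinite(self.or_estimate) else np.nan


@dataclass
class ScreenSpec:
    """What the screen runs over and how significance is declared."""

    outcomes: list[str] = field(default_factory=lambda: list(OUTCOMES))
    medications: list[str] = field(default_factory=list)
    covariate_names: list[str] = field(default_factory=list)
    alpha: float = 0.05
    bonferroni_m: int | None = None  # default: |medications| * |outcomes|

    def resolved_m(self) -> int:
        m = self.bonferroni_m
        if m is None:
            m = len(self.medications) * len(self.outcomes)
        if m < len(self.medications) * len(self.outcomes):
            raise ValidationError(
                "bonferroni_m smaller than the number of reported tests"
            )
        return max(m, 1)


@dataclass
class GoodnessOfFit:
    """Adjusted vs unadjusted model comparison (nested by construction)."""

    llf_adjusted: float
    llf_unadjusted: float
    aic_adjusted: float
    aic_unadjusted: float
    lr_stat: float
    df: int
    p_value: float


def _prune_adjustment(cm: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Boolean mask of adjustment columns that can enter the likelihood.

    Dropped: constant columns, and binary columns whose carriers show no
    outcome variation (their MLE is infinite -- quasi-separation in a
    nuisance covariate -- which stalls Newton without informing the
    exposure coefficient).  Continuous columns are only screened for
    constancy.
    """
    keep = cm.std(axis=0) > 0
    for j in np.nonzero(keep)[0]:
        col = cm[:, j]
        uniq = np.unique(col)
        if uniq.size == 2 and np.isin(uniq, [0.0, 1.0]).all():
            carriers = col == 1.0
            if y[carriers].min() == y[carriers].max():
                keep[j] = False
    return keep


def _check_binary(vec: np.ndarray, kind: str) -> np.ndarray:
    vec = np.asarray(vec)
    uniq = np.unique(vec)
    if not np.isin(uniq, [0, 1]).all():
        raise ValidationError(f"{kind} vector is not binary 0/1")
    if uniq.size < 2:
        raise DegenerateDataError(kind)
    return vec.astype(float)


def fit_single(
    outcome_vec,
    exposure_vec,
    covariate_matrix: pd.DataFrame | np.ndarray | None = None,
    alpha: float = 0.05,
    cluster_groups=None,
) -> AssociationResult:
    """Adjusted logistic fit of one outcome on one exposure.

    ``covariate_matrix`` columns (typically maternal age plus the 16
    comorbidity flags) enter as main effects alongside an intercept.
    Returns an :class:`AssociationResult` without the Bonferroni fields
    (the screen fills those in, since they depend on the family size).

    Raises
    ------
    DegenerateDataError
        If the outcome or exposure vector is constant.
    """
    y = _check_binary(outcome_vec, "outcome")
    x = _check_binary(exposure_vec, "exposure")
    if y.shape[0] != x.shape[0]:
        raise AlignmentError("outcome and exposure vectors differ in length")
    cols = [np.ones_like(x), x]
    if covariate_matrix is not None:
        cm = np.asarray(covariate_matrix, dtype=float)
        if cm.ndim == 1:
            cm = cm[:, None]
        if cm.shape[0] != y.shape[0]:
            raise AlignmentError("covariate matrix row count differs from outcome")
        cols.append(cm[:, _prune_adjustment(cm, y)])
    X = np.column_stack(cols)

    res = AssociationResult(
        medication="", outcome="", n_exposed=int(x.sum()),
        df_model=X.shape[1] - 1, n_obs=int(y.shape[0]),
    )
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model = sm.Logit(y, X)
            if cluster_groups is not None:
                fit = model.fit(
                    disp=0, maxiter=100, method="newton",
                    cov_type="cluster", cov_kwds={"groups": np.asarray(cluster_groups)},
                )
            else:
                fit = model.fit(disp=0, maxiter=100, method="newton")
    except (PerfectSeparationError, np.linalg.LinAlgError) as exc:
        res.separation_flag = True
        res.error = f"{type(exc).__name__}: {exc}"
        return res

    coef, se = float(fit.params[1]), float(fit.bse[1])
    converged = bool(fit.mle_retvals.get("converged", False))
    diverged = abs(coef) > SEPARATION_COEF or not np.isfinite(se) or se == 0
    if not converged or diverged:
        res.separation_flag = diverged
        res.converged = False
        res.error = "separation" if diverged else "non-convergence"
        return res

    res.converged = True
    res.or_estimate = float(np.exp(coef))
    res.ci_low = float(np.exp(coef - WALD_Z * se))
    res.ci_high = float(np.exp(coef + WALD_Z * se))
    res.p_nominal = float(fit.pvalues[1])
    res.sig_nominal = int(res.p_nominal <= alpha)
    res.llf = float(fit.llf)
    res.aic = float(fit.aic)
    return res


def compare_goodness_of_fit(adjusted: AssociationResult, unadjusted: AssociationResult) -> GoodnessOfFit:
    """Likelihood-ratio comparison of the adjusted over unadjusted fit.

    Both fits must be on identical rows; the unadjusted model (intercept
    + exposure) is nested in the adjusted one, so the LR statistic is
    nonnegative with df = number of adjustment columns.
    """
    from scipy.stats import chi2

    if adjusted.n_obs != unadjusted.n_obs:
        raise AlignmentError("models were not fit on identical rows")
    if not (adjusted.converged and unadjusted.converged):
        raise ValidationError("both fits must have converged for a GoF comparison")
    df = adjusted.df_model - unadjusted.df_model
    if df < 0:
        raise ValidationError("adjusted model has fewer parameters than unadjusted")
    lr = max(0.0, 2.0 * (adjusted.llf - unadjusted.llf))
    p = float(chi2.sf(lr, df)) if df > 0 else 1.0
    return GoodnessOfFit(
        llf_adjusted=adjusted.llf,
        llf_unadjusted=unadjusted.llf,
        aic_adjusted=adjusted.aic,
        aic_unadjusted=unadjusted.aic,
        lr_stat=lr,
        df=df,
        p_value=p,
    )


def _apply_bonferroni(results: list[AssociationResult], m: int, alpha: float) -> None:
    for r in results:
        if np.isfinite(r.p_nominal):
            r.p_bonferroni = min(1.0, r.p_nominal * m)
            r.sig_nominal = int(r.p_nominal <= alpha)
            # the stricter flag additionally requires nominal significance
            r.sig_bonferroni = int(r.sig_nominal and r.p_bonferroni <= alpha)


class MedicationScreen:
    """Model object: the full medication x outcome screen.

    Parameters
    ----------
    outcomes : DataFrame, one binary column per outcome, indexed like
        the exposure matrix (delivery-level).
    exposures : :class:`ExposureMatrix` or a binary DataFrame.
    covariates : DataFrame of adjustment columns (the comorbidity flags
        plus ``maternal_age``), same index.
    alpha, bonferroni_m : significance level and Bonferroni family size
        (default family: every medication x outcome pair in the screen).
    cluster_groups : optional per-delivery patient identifiers; switches
        the exposure-coefficient variance to a patient-clustered
        sandwich estimate (an extension beyond the plain screen).
    """

    def __init__(
        self,
        outcomes: pd.DataFrame,
        exposures: ExposureMatrix | pd.DataFrame,
        covariates: pd.DataFrame,
        alpha: float = 0.05,
        bonferroni_m: int | None = None,
        cluster_groups=None,
    ):
        if isinstance(exposures, ExposureMatrix):
            self.exposure_matrix = exposures
            exp_df = exposures.data
        else:
            exp_df = exposures
            self.exposure_matrix = None
        if not (len(outcomes) == len(exp_df) == len(covariates)):
            raise AlignmentError("outcomes, exposures and covariates differ in length")
        if not (outcomes.index.equals(exp_df.index) and outcomes.index.equals(covariates.index)):
            raise AlignmentError("outcomes, exposures and covariates must share an index")
        self.outcomes = outcomes
        self.exposures = exp_df
        self.covariates = covariates
        self.cluster_groups = np.asarray(cluster_groups) if cluster_groups is not None else None
        self.spec = ScreenSpec(
            outcomes=sorted(outcomes.columns),
            medications=sorted(exp_df.columns),
            covariate_names=list(covariates.columns),
            alpha=alpha,
            bonferroni_m=bonferroni_m,
        )

    # -- construction from raw event tables -------------------------
    @classmethod
    def from_tables(
        cls,
        patients: pd.DataFrame,
        deliveries: pd.DataFrame,
        orders: pd.DataFrame,
        diagnoses: pd.DataFrame,
        vocab,
        drug_map,
        min_patients: int = 10,
        covariate_names=None,
        outcome_names: tuple[str, ...] = OUTCOMES,
        alpha: float = 0.05,
        bonferroni_m: int | None = None,
        cluster: bool = False,
    ) -> "MedicationScreen":
        """Run the upstream stages and assemble an aligned screen.

        Applies outcome ascertainment, exposure-window construction with
        brand/generic merging, the minimum-patient inclusion filter, and
        the covariate lookback, then aligns everything on delivery_id.
        """
        from .cohort import build_cohort
        from .covariates import build_covariates
        from .exposure import apply_min_patient_filter, build_exposures

        cohort = build_cohort(deliveries, diagnoses, vocab, patients=patients,
                              outcomes=outcome_names)
        expo = apply_min_patient_filter(
            build_exposures(orders, cohort, drug_map), threshold=min_patients
        )
        covs = build_covariates(cohort, diagnoses, vocab, patients,
                                covariate_names=covariate_names)
        outcomes_df = cohort.set_index("delivery_id")[list(outcome_names)]
        screen = cls(
            outcomes_df, expo, covs, alpha=alpha, bonferroni_m=bonferroni_m,
            cluster_groups=cohort["patient_id"].values if cluster else None,
        )
        screen.cohort = cohort
        return screen

    # -- fitting -----------------------------------------------------
    def fit(self, gof: bool = False) -> "MedicationScreenResults":
        """Fit every medication x outcome pair and the per-outcome
        covariate reference models.

        A degenerate or separated pair yields a flagged result row; the
        screen never aborts wholesale.  ``gof=True`` additionally fits
        the unadjusted (intercept + exposure) model per pair and stores
        likelihood-ratio comparisons.
        """
        spec = self.spec
        m = spec.resolved_m()
        cov_arr = self.covariates.to_numpy(float)
        results: list[AssociationResult] = []
        gofs: dict[tuple[str, str], GoodnessOfFit] = {}
        for med in spec.medications:
            x = self.exposures[med].to_numpy()
            for out in spec.outcomes:
                y = self.outcomes[out].to_numpy()
                try:
                    r = fit_single(y, x, cov_arr, alpha=spec.alpha,
                                   cluster_groups=self.cluster_groups)
                except DegenerateDataError as exc:
                    r = AssociationResult(
                        medication=med, outcome=out, n_exposed=int(np.sum(x)),
                        error=str(exc), converged=False,
                    )
                r.medication, r.outcome = med, out
                results.append(r)
                if gof and r.converged:
                    try:
                        unadj = fit_single(y, x, None, alpha=spec.alpha)
                        gofs[(med, out)] = compare_goodness_of_fit(r, unadj)
                    except (DegenerateDataError, ValidationError):
                        pass
        _apply_bonferroni(results, m, spec.alpha)

        covariate_models = {}
        for out in spec.outcomes:
            covariate_models[out] = self._fit_covariate_reference(out)
        return MedicationScreenResults(self, results, covariate_models, gofs, m)

    def _fit_covariate_reference(self, outcome: str) -> pd.DataFrame:
        """Adjusted model of one outcome on the covariates alone.

        Supplies the covariate panel of the forest export: the
        covariate odds ratios shown alongside the medications come from
        this medication-free reference fit, so they do not depend on
        which medication's model one looks at.
        """
        y = self.outcomes[outcome].to_numpy(float)
        cm = self.covariates.to_numpy(float)
        keep = _prune_adjustment(cm, y)
        X = np.column_stack([np.ones(len(y)), cm[:, keep]])
        names = [c for c, k in zip(self.covariates.columns, keep) if k]
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                fit = sm.Logit(y, X).fit(disp=0, maxiter=100, method="newton")
            if not fit.mle_retvals.get("converged", False):
                raise PerfectSeparationError("no convergence")
        except (PerfectSeparationError, np.linalg.LinAlgError):
            return pd.DataFrame(
                columns=["term", "or", "ci_low", "ci_high", "p"]
            ).set_index("term")
        coefs, ses, ps = fit.params[1:], fit.bse[1:], fit.pvalues[1:]
        return pd.DataFrame(
            {
                "or": np.exp(coefs),
                "ci_low": np.exp(coefs - WALD_Z * ses),
                "ci_high": np.exp(coefs + WALD_Z * ses),
                "p": ps,
            },
            index=pd.Index(names, name="term"),
        )


class MedicationScreenResults:
    """Estimates, intervals and diagnostics from a fitted screen."""

    def __init__(self, model: MedicationScreen, results, covariate_models, gofs, bonferroni_m):
        self.model = model
        self.results: list[AssociationResult] = sorted(
            results, key=lambda r: (r.medication, r.outcome)
        )
        self.covariate_models: dict[str, pd.DataFrame] = covariate_models
        self.goodness_of_fit: dict[tuple[str, str], GoodnessOfFit] = gofs
        self.bonferroni_m = bonferroni_m
        self.alpha = model.spec.alpha

    @property
    def frame(self) -> pd.DataFrame:
        """All association results as a tidy DataFrame."""
        return pd.DataFrame([asdict(r) for r in self.results])

    def __getitem__(self, key: tuple[str, str]) -> AssociationResult:
        med, out = key
        for r in self.results:
            if r.medication == med and r.outcome == out:
                return r
        raise KeyError(key)

    def summary(self) -> str:
        """Plain-text report of the screen.

        The header states alpha and the Bonferroni family size used,
        including how the family was defined, since the correction's
        meaning depends on that choice.
        """
        spec = self.model.spec
        lines = [
            "Medication-wide association screen",
            "=" * 70,
            f"deliveries: {len(self.model.outcomes):,}   medications: {len(spec.medications)}   outcomes: {len(spec.outcomes)}",
            f"adjustment columns: {len(spec.covariate_names)}",
            f"alpha = {spec.alpha}; Bonferroni m = {self.bonferroni_m} "
            f"(family = all medication x outcome tests in this screen; "
            f"per-outcome families are a configuration option)",
            "-" * 70,
        ]
        lines.append(f"{'medication':<28}{'outcome':<12}{'n_exp':>6}  OR (95% CI)           p        flags")
        for r in self.results:
            if r.converged:
                est = f"{r.or_estimate:6.2f} ({r.ci_low:.2f}-{r.ci_high:.2f})"
                p = f"{r.p_nominal:8.2e}"
            else:
                est, p = "   --", "    --"
            flags = ("**" if r.sig_bonferroni else "*" if r.sig_nominal else "") + (
                " SEP" if r.separation_flag else ""
            )
            lines.append(f"{r.medication:<28}{r.outcome:<12}{r.n_exposed:>6}  {est:<22}{p:>8}  {flags}")
        return "\n".join(lines)

    def association_table(self) -> pd.DataFrame:
        """Wide per-medication table: one OR (95% CI) column per outcome.

        Significance markers: ``*`` nominal p <= alpha, ``**`` nominal
        and Bonferroni-adjusted p <= alpha.  Small exposure counts are
        masked by the rendering layer, not here.
        """
        spec = self.model.spec
        rows = {}
        for r in self.results:
            row = rows.setdefault(r.medication, {"medication": r.medication, "n_exposed": r.n_exposed})
            if r.converged:
                mark = "**" if r.sig_bonferroni else ("*" if r.sig_nominal else "")
                row[r.outcome] = f"{r.or_estimate:.2f} ({r.ci_low:.2f}-{r.ci_high:.2f}){mark}"
            else:
                row[r.outcome] = "not estimable"
        return pd.DataFrame(
            [rows[m] for m in spec.medications],
            columns=["medication", "n_exposed", *spec.outcomes],
        )

    def forest_rows(self, alpha: float | None = None) -> pd.DataFrame:
        """Forest-plot export: nominally significant rows only.

        Medication rows come from the screen fits, covariate rows from
        the per-outcome covariate reference models; within each
        (outcome, group) panel rows are ordered by estimate.
        """
        from .reporting import export_forest

        return export_forest(self, alpha if alpha is not None else self.alpha)


def run_screen(
    spec: ScreenSpec,
    exposures: ExposureMatrix | pd.DataFrame,
    covariates: pd.DataFrame,
    cohort: pd.DataFrame,
) -> list[AssociationResult]:
    """Functional wrapper over :class:`MedicationScreen` for scripts.

    ``cohort`` must carry the binary outcome columns named in ``spec``
    plus a delivery_id column or index aligned with the matrices.
    """
    outcomes_df = (
        cohort.set_index("delivery_id")[spec.outcomes]
        if "delivery_id" in cohort.columns
        else cohort[spec.outcomes]
    )
    exp_df = exposures.data if isinstance(exposures, ExposureMatrix) else exposures
    if spec.medications:
        exp_df = exp_df[spec.medications]
    model = MedicationScreen(
        outcomes_df, exp_df, covariates[spec.covariate_names] if spec.covariate_names else covariates,
        alpha=spec.alpha, bonferroni_m=spec.bonferroni_m,
    )
    return model.fit().results
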