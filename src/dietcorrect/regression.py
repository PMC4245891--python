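"""Regression correction of self-reported energy intake.

A multiple linear regression predicts percent energy misreporting,
``pct = 100*(EE - EI_claimed)/EE``, from five easily measured covariates:

    sex code (1 = male, 2 = female), age (years), weight (kg),
    log(EI_claimed), and IndEI_claimed = EI_claimed / RMR.

Inverting the energy-balance definition of misreporting under the
homeostasis assumption (true EI = EE) converts a predicted percentage into
a corrected intake:  ``EI_corrected = EI_claimed / (1 - pct/100)``.

The published coefficient vector fitted on the OPEN doubly-labeled-water
study is available via :func:`default_open_model`.  The base of the
published log term is not stated, and the printed intercept does not
satisfy the least-squares identity (intercept + slopes·covariate-means =
mean outcome) on the published summary moments under either base, so
:func:`calibrate` both selects a log convention and recentres the
intercept against a reference population before the model is applied to
new data.  :func:`fit_misreport_model` refits the model from scratch on
any training table that carries measured EE.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, asdict, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import scipy.stats
import statsmodels.api as sm

from . import metrics
from .metrics import schofield_rmr, sex_code

__all__ = [
    "MisreportModel",
    "default_open_model",
    "predict_pct_misreport",
    "correct_ei",
    "MisreportRegression",
    "MisreportRegressionResults",
    "fit_misreport_model",
    "backward_eliminate",
    "normality_diagnostic",
    "QQDiagnostic",
    "recenter_intercept",
    "calibrate",
    "CalibrationReport",
    "OPEN_MEAN_PCT_MISREPORT",
]

#: Observed mean percent misreporting in the OPEN training study, computed
#: from the published summary means: 100*(2627 - 2346)/2627.
OPEN_MEAN_PCT_MISREPORT = 100.0 * (2627.0 - 2346.0) / 2627.0

#: Canonical design columns, in the published order.
CANONICAL_COVARIATES = ("sex", "age_years", "weight_kg", "log_ei_claimed", "ind_ei_claimed")


@dataclass(frozen=True)
class MisreportModel:
    """A linear model of percent misreporting (constant or refitted).

    Coefficients are on the percent scale; ``log_convention`` records the
    base used for the log-intake term so corrections are reproducible.
    """

    intercept: float
    beta_sex: float
    beta_age: float
    beta_weight: float
    beta_log_ei: float
    beta_ind_ei: float
    log_convention: str = "natural"
    r_squared: Optional[float] = None
    source: str = "refit"
    rmr_equation: str = "weight_only"

    def __post_init__(self):
        for name, v in asdict(self).items():
            if name in ("log_convention", "source", "r_squared", "rmr_equation"):
                continue
            if not np.isfinite(v):
                raise ValueError(f"coefficient {name} must be finite")
        if self.log_convention not in ("natural", "base10"):
            raise ValueError("log_convention must be 'natural' or 'base10'")
        if self.rmr_equation not in ("weight_only", "weight_height"):
            raise ValueError("rmr_equation must be 'weight_only' or 'weight_height'")
        if self.r_squared is not None and not (0.0 <= self.r_squared <= 1.0):
            raise ValueError("r_squared must lie in [0, 1]")

    @property
    def slopes(self) -> np.ndarray:
        return np.array([self.beta_sex, self.beta_age, self.beta_weight,
                         self.beta_log_ei, self.beta_ind_ei])

    def _log(self, x):
        return np.log(x) if self.log_convention == "natural" else np.log10(x)

    def predict(self, sex, age_years, weight_kg, ei_claimed_kcal, rmr_kcal):
        """Predicted percent misreporting for the given covariates."""
        ei = np.asarray(ei_claimed_kcal, dtype=float)
        rmr = np.asarray(rmr_kcal, dtype=float)
        if np.any(ei <= 0.0):
            raise ValueError("ei_claimed_kcal must be positive (log term undefined at 0)")
        if np.any(rmr <= 0.0):
            raise ValueError("rmr_kcal must be positive")
        sexes = sex_code(sex)
        out = (self.intercept
               + self.beta_sex * np.asarray(sexes, dtype=float)
               + self.beta_age * np.asarray(age_years, dtype=float)
               + self.beta_weight * np.asarray(weight_kg, dtype=float)
               + self.beta_log_ei * self._log(ei)
               + self.beta_ind_ei * ei / rmr)
        return float(out) if np.ndim(out) == 0 else out

    def to_json(self, path=None) -> str:
        doc = json.dumps(asdict(self), indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(doc + "\n")
        return doc

    @classmethod
    def from_json(cls, source) -> "MisreportModel":
        if isinstance(source, (str, bytes)) and str(source).lstrip().startswith("{"):
            doc = json.loads(source)
        else:
            with open(source) as fh:
                doc = json.load(fh)
        return cls(**doc)


def default_open_model() -> MisreportModel:
    """The published OPEN coefficient vector for percent misreporting.

    Fitted on the 423 non-Black OPEN participants; R^2 = 0.84.  The sex
    coefficient was reported non-significant but is retained as printed in
    the final model table.
    """
    return MisreportModel(
        intercept=298.19,
        beta_sex=-2.30,
        beta_age=-0.36,
        beta_weight=0.21,
        beta_log_ei=-35.84,
        beta_ind_ei=-30.47,
        log_convention="natural",
        r_squared=0.84,
        source="paper_table2",
    )


def predict_pct_misreport(model: MisreportModel, person, rmr_kcal=None):
    """Predicted percent misreporting for a Person or person table.

    ``rmr_kcal`` may be supplied; otherwise it is computed with the
    weight-only Schofield equations.
    """
    if isinstance(person, pd.DataFrame):
        sexes = sex_code(person["sex"].to_numpy())
        age = person["age_years"].to_numpy(dtype=float)
        weight = person["weight_kg"].to_numpy(dtype=float)
        ei = person["ei_claimed_kcal"].to_numpy(dtype=float)
        if rmr_kcal is None:
            height = person["height_cm"].to_numpy(dtype=float) if "height_cm" in person else None
            rmr_kcal = schofield_rmr(sexes, age, weight,
                                     equation=model.rmr_equation, height_cm=height)
        return model.predict(sexes, age, weight, ei, rmr_kcal)
    if rmr_kcal is None:
        rmr_kcal = schofield_rmr(person.sex, person.age_years, person.weight_kg,
                                 equation=model.rmr_equation, height_cm=person.height_cm)
    return model.predict(person.sex, person.age_years, person.weight_kg,
                         person.ei_claimed_kcal, rmr_kcal)


def correct_ei(ei_claimed_kcal, pct, cap: float = 99.0):
    """Invert a predicted misreporting percentage into a corrected intake.

    ``EI_corrected = EI_claimed / (1 - pct/100)`` with ``pct`` first clamped
    to ``[-cap, +cap]`` so that covariate extremes cannot drive the
    denominator to zero.
    """
    ei = np.asarray(ei_claimed_kcal, dtype=float)
    if np.any(ei < 0.0):
        raise ValueError("ei_claimed_kcal must be non-negative")
    if not (0.0 < cap < 100.0):
        raise ValueError("cap must lie in (0, 100)")
    p = np.clip(np.asarray(pct, dtype=float), -cap, cap)
    if np.any(p >= 100.0):
        raise ValueError("pct must be < 100 after capping")
    out = ei / (1.0 - p / 100.0)
    return float(out) if out.ndim == 0 else out


def _design_frame(df: pd.DataFrame, log_convention: str, *, equation="weight_only",
                  extra: Sequence[str] = ()) -> pd.DataFrame:
    """Build the regression design (and outcome when EE is present)."""
    sexes = sex_code(df["sex"].to_numpy())
    age = df["age_years"].to_numpy(dtype=float)
    weight = df["weight_kg"].to_numpy(dtype=float)
    ei = df["ei_claimed_kcal"].to_numpy(dtype=float)
    if np.any(ei <= 0.0):
        raise ValueError("training rows must have ei_claimed_kcal > 0")
    height = df["height_cm"].to_numpy(dtype=float) if "height_cm" in df else None
    rmr = schofield_rmr(sexes, age, weight, equation=equation, height_cm=height)
    log = np.log if log_convention == "natural" else np.log10
    X = pd.DataFrame({
        "sex": sexes.astype(float),
        "age_years": age,
        "weight_kg": weight,
        "log_ei_claimed": log(ei),
        "ind_ei_claimed": ei / rmr,
    }, index=df.index)
    for name in extra:
        X[name] = df[name].to_numpy(dtype=float)
    if "ee_kcal" in df and df["ee_kcal"].notna().all():
        ee = df["ee_kcal"].to_numpy(dtype=float)
        if np.any(ee <= 0.0):
            raise ValueError("training rows must have ee_kcal > 0")
        X.attrs["pct_misreport"] = 100.0 * (ee - ei) / ee
    return X


def _check_collinearity(X: pd.DataFrame):
    """Raise naming the dependent columns if the design is rank deficient."""
    mat = np.column_stack([np.ones(len(X)), X.to_numpy(dtype=float)])
    rank = np.linalg.matrix_rank(mat)
    if rank < mat.shape[1]:
        culprits = []
        cols = list(X.columns)
        for j, name in enumerate(cols):
            others = np.delete(mat, j + 1, axis=1)
            if np.linalg.matrix_rank(others) == rank:
                culprits.append(name)
        raise ValueError(
            "design matrix is rank deficient; collinear terms: " + ", ".join(culprits)
        )


class MisreportRegression:
    """OLS model of percent misreporting built from a training table.

    Parameters
    ----------
    data : DataFrame
        Person table with measured ``ee_kcal`` (training data) and positive
        ``ei_claimed_kcal``.
    log_convention : {"natural", "base10"}
        Base of the log-intake covariate.
    equation : {"weight_only", "weight_height"}
        Schofield variant used to derive RMR for the IndEI covariate.
    extra_covariates : sequence of str
        Additional numeric columns of ``data`` to include as candidates.
    include_black : bool
        By default rows with ``race_group == "black"`` are excluded from
        fitting, mirroring the training-study modelling population.
    """

    def __init__(self, data: pd.DataFrame, *, log_convention="natural",
                 equation="weight_only", extra_covariates: Sequence[str] = (),
                 include_black: bool = False):
        if log_convention not in ("natural", "base10"):
            raise ValueError("log_convention must be 'natural' or 'base10'")
        if not include_black and "race_group" in data:
            data = data[data["race_group"] != "black"]
        if len(data) < 20:
            raise ValueError("at least 20 training rows are required")
        if "ee_kcal" not in data or data["ee_kcal"].isna().any():
            raise ValueError("training data must carry measured ee_kcal on every row")
        self.data = data.reset_index(drop=True)
        self.log_convention = log_convention
        self.equation = equation
        self.extra_covariates = tuple(extra_covariates)
        self.exog = _design_frame(self.data, log_convention, equation=equation,
                                  extra=self.extra_covariates)
        self.endog = self.exog.attrs["pct_misreport"]

    @classmethod
    def from_dataframe(cls, data: pd.DataFrame, **kwargs) -> "MisreportRegression":
        return cls(data, **kwargs)

    def _ols(self, columns: Sequence[str]):
        X = self.exog[list(columns)]
        _check_collinearity(X)
        return sm.OLS(self.endog, sm.add_constant(X, has_constant="add")).fit()

    def fit(self, *, selection: Optional[str] = None, alpha: float = 0.05
            ) -> "MisreportRegressionResults":
        """Fit by OLS; ``selection="backward"`` prunes covariates with p > alpha.

        Backward elimination removes one covariate at a time — the one with
        the largest two-sided coefficient p-value above ``alpha`` (ties
        broken toward the later-listed candidate) — and refits until every
        remaining covariate is significant.  The intercept is never removed.
        """
        columns = list(self.exog.columns)
        eliminated: list[str] = []
        res = self._ols(columns)
        if selection == "backward":
            if not (0.0 < alpha < 1.0):
                raise ValueError("alpha must lie in (0, 1)")
            while columns:
                pvals = res.pvalues.drop("const")
                worst_p = pvals.max()
                if worst_p <= alpha:
                    break
                # ties: drop the covariate listed later in the candidate order
                at_max = [c for c in columns if math.isclose(pvals[c], worst_p, rel_tol=0, abs_tol=0) or pvals[c] == worst_p]
                drop = at_max[-1]
                columns.remove(drop)
                eliminated.append(drop)
                if not columns:
                    break
                res = self._ols(columns)
        elif selection is not None:
            raise ValueError(f"unknown selection strategy {selection!r}")
        return MisreportRegressionResults(self, res, columns, eliminated)


class MisreportRegressionResults:
    """Fitted misreporting regression: estimates, uncertainty, diagnostics."""

    def __init__(self, model: MisreportRegression, sm_results, retained, eliminated):
        self.model = model
        self.sm_results = sm_results
        self.retained = tuple(retained)
        self.eliminated = tuple(eliminated)

    @property
    def params(self) -> pd.Series:
        return self.sm_results.params

    @property
    def bse(self) -> pd.Series:
        return self.sm_results.bse

    @property
    def pvalues(self) -> pd.Series:
        return self.sm_results.pvalues

    @property
    def rsquared(self) -> float:
        return float(self.sm_results.rsquared)

    def summary(self):
        return self.sm_results.summary()

    def as_misreport_model(self) -> MisreportModel:
        """Export as a constant coefficient vector (dropped terms get 0).

        Only the five canonical covariates can be represented; retained
        extra covariates raise.
        """
        non_canonical = [c for c in self.retained if c not in CANONICAL_COVARIATES]
        if non_canonical:
            raise ValueError(
                "cannot express non-canonical covariates as a MisreportModel: "
                + ", ".join(non_canonical)
            )
        coef = {c: float(self.params.get(c, 0.0)) for c in CANONICAL_COVARIATES}
        return MisreportModel(
            intercept=float(self.params["const"]),
            beta_sex=coef["sex"],
            beta_age=coef["age_years"],
            beta_weight=coef["weight_kg"],
            beta_log_ei=coef["log_ei_claimed"],
            beta_ind_ei=coef["ind_ei_claimed"],
            log_convention=self.model.log_convention,
            r_squared=self.rsquared,
            source="refit",
        )

    def predict(self, df: pd.DataFrame):
        return predict_pct_misreport(self.as_misreport_model(), df)

    def correct(self, df: pd.DataFrame, cap: float = 99.0) -> pd.DataFrame:
        """Return ``df`` with added ``pct_predicted`` and ``ei_corrected`` columns."""
        out = df.copy()
        pct = self.predict(df)
        out["pct_predicted"] = pct
        out["ei_corrected"] = correct_ei(df["ei_claimed_kcal"].to_numpy(dtype=float), pct, cap)
        return out


def fit_misreport_model(training: pd.DataFrame, log_convention="natural",
                        **kwargs) -> MisreportModel:
    """OLS fit of percent misreporting on the five canonical covariates."""
    return (MisreportRegression(training, log_convention=log_convention, **kwargs)
            .fit().as_misreport_model())


def backward_eliminate(training: pd.DataFrame, candidates: Sequence[str] = (),
                       alpha: float = 0.05, log_convention="natural",
                       **kwargs) -> MisreportRegressionResults:
    """Backward stepwise selection starting from the canonical covariates.

    ``candidates`` names additional numeric columns of ``training`` to add
    to the candidate set before pruning.
    """
    model = MisreportRegression(training, log_convention=log_convention,
                                extra_covariates=candidates, **kwargs)
    return model.fit(selection="backward", alpha=alpha)


@dataclass
class QQDiagnostic:
    """Quantile–quantile pairs against the standard normal, plus the QQ line."""

    theoretical: np.ndarray
    observed: np.ndarray
    slope: float
    intercept: float


def normality_diagnostic(values) -> QQDiagnostic:
    """Normal QQ diagnostic for an outcome sample (e.g. percent misreporting).

    Returns sorted observed values paired with standard-normal plotting
    quantiles and the least-squares line through the pairs; a slope close
    to the sample SD indicates approximate normality.
    """
    x = np.asarray(values, dtype=float)
    if x.size < 3:
        raise ValueError("at least 3 values are required for a QQ diagnostic")
    (osm, osr), (slope, intercept, _r) = scipy.stats.probplot(x, dist="norm", fit=True)
    return QQDiagnostic(theoretical=osm, observed=osr,
                        slope=float(slope), intercept=float(intercept))


def recenter_intercept(model: MisreportModel, reference: pd.DataFrame,
                       target_mean_pct: Optional[float] = None,
                       *, equation=None) -> MisreportModel:
    """Recentre the intercept so the model is mean-unbiased on a reference table.

    Any least-squares fit satisfies "mean prediction = mean outcome" on its
    own training sample; a constant coefficient vector transported from the
    literature can be restored to that state by shifting the intercept so
    that the mean predicted misreporting over ``reference`` equals
    ``target_mean_pct`` (default: the reference's own observed mean when it
    carries measured EE, else the published OPEN mean of ~10.7%).
    """
    if equation is None:
        equation = model.rmr_equation
    if target_mean_pct is None:
        if "ee_kcal" in reference and reference["ee_kcal"].notna().all():
            ee = reference["ee_kcal"].to_numpy(dtype=float)
            ei = reference["ei_claimed_kcal"].to_numpy(dtype=float)
            target_mean_pct = float(np.mean(100.0 * (ee - ei) / ee))
        else:
            target_mean_pct = OPEN_MEAN_PCT_MISREPORT
    X = _design_frame(reference, model.log_convention, equation=equation)
    mean_linpred = float(model.slopes @ X.to_numpy(dtype=float).mean(axis=0))
    return replace(model, intercept=target_mean_pct - mean_linpred,
                   source="recalibrated")


@dataclass
class CalibrationReport:
    """Outcome of the log-convention / Schofield-variant calibration."""

    table: pd.DataFrame
    log_convention: str
    equation: str
    model: MisreportModel
    target_mean_pct: float


def calibrate(reference: pd.DataFrame, model: Optional[MisreportModel] = None,
              target_mean_pct: Optional[float] = None) -> CalibrationReport:
    """Choose the log convention and Schofield variant, and recentre the intercept.

    Evaluates {natural, base10} x {weight_only, weight_height} (the latter
    only when heights are available), scoring each combination by the gap
    between the population-mean predicted misreporting on ``reference`` and
    the target mean; returns the winning combination together with an
    intercept-recentred model ready for application.
    """
    if model is None:
        model = default_open_model()
    if target_mean_pct is None:
        if "ee_kcal" in reference and reference["ee_kcal"].notna().all():
            ee = reference["ee_kcal"].to_numpy(dtype=float)
            ei = reference["ei_claimed_kcal"].to_numpy(dtype=float)
            target_mean_pct = float(np.mean(100.0 * (ee - ei) / ee))
        else:
            target_mean_pct = OPEN_MEAN_PCT_MISREPORT
    equations = ["weight_only"]
    if "height_cm" in reference and reference["height_cm"].notna().all():
        equations.append("weight_height")
    rows = []
    for conv in ("natural", "base10"):
        for eq in equations:
            cand = replace(model, log_convention=conv)
            X = _design_frame(reference, conv, equation=eq)
            mean_pred = cand.intercept + float(
                cand.slopes @ X.to_numpy(dtype=float).mean(axis=0))
            rows.append({"log_convention": conv, "equation": eq,
                         "mean_predicted_pct": mean_pred,
                         "gap": abs(mean_pred - target_mean_pct)})
    table = pd.DataFrame(rows).sort_values("gap").reset_index(drop=True)
    best = table.iloc[0]
    chosen = replace(model, log_convention=best["log_convention"],
                     rmr_equation=best["equation"])
    chosen = recenter_intercept(chosen, reference, target_mean_pct)
    return CalibrationReport(table=table, log_convention=best["log_convention"],
                             equation=best["equation"], model=chosen,
                             target_mean_pct=target_mean_pct)
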