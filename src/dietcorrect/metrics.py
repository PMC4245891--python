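"""Energy-balance metrics and physiological plausibility checks.

The quantities defined here underpin both correction methods:

* **RMR** — resting metabolic rate (kcal/day), predicted from sex, age and
  weight with the adult Schofield equations.
* **PAL** — physical activity level, EE/RMR.  Total energy expenditure (EE)
  cannot be below resting expenditure, so PAL >= 1 for any living subject.
* **IndEI** — index of energy intake, EI/RMR.  Under energy homeostasis
  (stable body weight) intake equals expenditure, so IndEI should equal PAL
  and inherits its physiological range.
* **Percent misreporting** — ``100*(EE - EI_claimed)/EE``; positive values
  are under-reporting, negative values over-reporting.

Reported intakes whose IndEI falls outside sex-specific plausibility bounds
(< 1, or > 2.8 for women / 3.5 for men — extremely active but not
expedition-level) are classified as implausible.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

__all__ = [
    "MALE",
    "FEMALE",
    "sex_code",
    "schofield_rmr",
    "pct_misreport",
    "classify_plausibility",
    "weight_status",
    "PlausibilityBounds",
    "goldberg_bounds",
    "Person",
    "EnergyProfile",
    "derive_profile",
    "derive_profiles",
]

MALE = 1
FEMALE = 2

_SEX_ALIASES = {
    "1": MALE, "2": FEMALE,
    "m": MALE, "f": FEMALE,
    "male": MALE, "female": FEMALE,
}

# Adult Schofield equations, kcal/day, weight-only form:
# RMR = a * weight_kg + b, selected by sex and age band.
# Age bands: [18, 30), [30, 60], (60, inf) — age 30 and 60 both fall in the
# middle band (closed upper edge).
SCHOFIELD_WEIGHT_ONLY = {
    MALE: ((15.3, 679.0), (11.6, 879.0), (13.5, 487.0)),
    FEMALE: ((14.7, 496.0), (8.7, 829.0), (10.5, 596.0)),
}

# Weight + height form: RMR = a * weight_kg + h * height_m + b.
SCHOFIELD_WEIGHT_HEIGHT = {
    MALE: ((15.4, -27.0, 717.0), (11.3, 16.0, 901.0), (8.8, 1128.0, -1071.0)),
    FEMALE: ((13.3, 334.0, 35.0), (8.7, -25.0, 865.0), (9.2, 637.0, -302.0)),
}


def sex_code(sex):
    """Map sex encodings {1, 2, M, F, male, female} to the canonical 1/2 coding.

    The numeric coding (1 = male, 2 = female) is fixed so that published
    regression coefficients keyed to it are directly usable.
    """
    arr = np.asarray(sex)
    scalar = arr.ndim == 0
    flat = np.atleast_1d(arr)
    out = np.empty(flat.shape, dtype=np.int64)
    for i, v in enumerate(flat):
        if isinstance(v, (int, np.integer, float, np.floating)) and not isinstance(v, bool):
            iv = int(v)
            if iv not in (MALE, FEMALE) or iv != v:
                raise ValueError(f"unrecognised sex code {v!r} (expected 1=male, 2=female)")
            out[i] = iv
        else:
            key = str(v).strip().lower()
            if key not in _SEX_ALIASES:
                raise ValueError(f"unrecognised sex code {v!r}")
            out[i] = _SEX_ALIASES[key]
    return int(out[0]) if scalar else out


def _age_band(age_years):
    """0 for [18, 30), 1 for [30, 60], 2 for (60, inf)."""
    age = np.asarray(age_years, dtype=float)
    return np.where(age < 30.0, 0, np.where(age <= 60.0, 1, 2))


def schofield_rmr(sex, age_years, weight_kg, *, equation="weight_only", height_cm=None):
    """Predicted resting metabolic rate (kcal/day) from the adult Schofield equations.

    Parameters
    ----------
    sex : int, str or array-like
        1/male or 2/female.
    age_years : float or array-like
        Age in years, must be >= 18 (the methods are defined for adults).
    weight_kg : float or array-like
        Body weight in kilograms, must be positive.
    equation : {"weight_only", "weight_height"}
        Which published adult form to use.  The weight-only form is the
        default; the weight+height form requires ``height_cm``.
    height_cm : float or array-like, optional
        Standing height in centimetres (weight+height form only).

    Returns
    -------
    float or ndarray
        RMR in kcal/day, piecewise linear and strictly increasing in weight
        within each sex/age band.
    """
    sexes = np.atleast_1d(sex_code(sex))
    age = np.asarray(age_years, dtype=float)
    weight = np.asarray(weight_kg, dtype=float)
    scalar = age.ndim == 0 and weight.ndim == 0 and np.asarray(sex).ndim == 0
    age, weight, sexes = np.broadcast_arrays(np.atleast_1d(age), np.atleast_1d(weight), sexes)

    if np.any(~np.isfinite(age)) or np.any(age < 18.0):
        raise ValueError("schofield_rmr is defined for adults: age_years must be >= 18")
    if np.any(~np.isfinite(weight)) or np.any(weight <= 0.0):
        raise ValueError("weight_kg must be positive and finite")

    band = _age_band(age)
    rmr = np.empty(age.shape, dtype=float)
    if equation == "weight_only":
        for s, table in SCHOFIELD_WEIGHT_ONLY.items():
            for b, (a_coef, const) in enumerate(table):
                m = (sexes == s) & (band == b)
                rmr[m] = a_coef * weight[m] + const
    elif equation == "weight_height":
        if height_cm is None:
            raise ValueError("height_cm is required for the weight_height equations")
        height_m = np.broadcast_to(np.atleast_1d(np.asarray(height_cm, dtype=float)) / 100.0, age.shape)
        if np.any(~np.isfinite(height_m)) or np.any(height_m <= 0.0):
            raise ValueError("height_cm must be positive and finite")
        for s, table in SCHOFIELD_WEIGHT_HEIGHT.items():
            for b, (a_coef, h_coef, const) in enumerate(table):
                m = (sexes == s) & (band == b)
                rmr[m] = a_coef * weight[m] + h_coef * height_m[m] + const
    else:
        raise ValueError(f"unknown Schofield equation set {equation!r}")
    return float(rmr[0]) if scalar else rmr


def pct_misreport(ee_kcal, ei_claimed_kcal):
    """Percent energy misreporting, ``100*(EE - EI_claimed)/EE``.

    Positive values are under-reporting, negative values over-reporting.
    Assumes energy homeostasis so that true intake equals expenditure.
    """
    ee = np.asarray(ee_kcal, dtype=float)
    ei = np.asarray(ei_claimed_kcal, dtype=float)
    if np.any(~np.isfinite(ee)) or np.any(ee <= 0.0):
        raise ValueError("ee_kcal must be positive and finite")
    if np.any(~np.isfinite(ei)) or np.any(ei < 0.0):
        raise ValueError("ei_claimed_kcal must be non-negative and finite")
    out = 100.0 * (ee - ei) / ee
    return float(out) if out.ndim == 0 else out


@dataclass(frozen=True)
class PlausibilityBounds:
    """Sex-specific plausibility range for IndEI (= PAL under homeostasis).

    The lower bound of 1 follows from EE >= RMR; the defaults of 2.8 (women)
    and 3.5 (men) correspond to extremely active individuals short of
    sustained athletic feats.  Values exactly on a bound are plausible.
    """

    min_indei: float = 1.0
    max_indei_female: float = 2.8
    max_indei_male: float = 3.5

    def __post_init__(self):
        if not (0.0 < self.min_indei < self.max_indei_female <= self.max_indei_male):
            raise ValueError(
                "bounds must satisfy 0 < min_indei < max_indei_female <= max_indei_male"
            )

    def max_for(self, sex):
        sexes = np.atleast_1d(sex_code(sex))
        out = np.where(sexes == FEMALE, self.max_indei_female, self.max_indei_male)
        return float(out[0]) if np.asarray(sex).ndim == 0 else out


def goldberg_bounds() -> PlausibilityBounds:
    """Alternative bounds with the Goldberg lower cut-off of 1.35.

    Not the default: whole-body calorimetry has recorded PAL as low as 1.16,
    and predicted (rather than measured) RMR argues for the permissive lower
    bound of 1.
    """
    return PlausibilityBounds(min_indei=1.35)


def classify_plausibility(ind_ei, sex, bounds: PlausibilityBounds = PlausibilityBounds()):
    """Classify IndEI values as plausible / implausible_low / implausible_high.

    Boundary values count as plausible (the failure conditions are strict
    inequalities: < min, or > the sex-specific max).
    """
    x = np.asarray(ind_ei, dtype=float)
    scalar = x.ndim == 0 and np.asarray(sex).ndim == 0
    x1 = np.atleast_1d(x)
    if np.any(~np.isfinite(x1)) or np.any(x1 < 0.0):
        raise ValueError("ind_ei must be finite and non-negative")
    sexes = np.atleast_1d(sex_code(sex))
    hi = np.broadcast_to(np.where(sexes == FEMALE, bounds.max_indei_female,
                                  bounds.max_indei_male), x1.shape)
    labels = np.where(x1 < bounds.min_indei, "implausible_low",
                      np.where(x1 > hi, "implausible_high", "plausible"))
    return str(labels[0]) if scalar else labels


def weight_status(weight_kg, height_cm):
    """CDC/WHO weight-status category from BMI (kg/m^2).

    underweight: BMI < 18.5; normal: [18.5, 25]; overweight: (25, 30];
    obese: > 30.
    """
    w = np.asarray(weight_kg, dtype=float)
    h = np.asarray(height_cm, dtype=float)
    scalar = w.ndim == 0 and h.ndim == 0
    w1, h1 = np.broadcast_arrays(np.atleast_1d(w), np.atleast_1d(h))
    if np.any(w1 <= 0.0) or np.any(h1 <= 0.0) or np.any(~np.isfinite(w1)) or np.any(~np.isfinite(h1)):
        raise ValueError("weight_kg and height_cm must be positive and finite")
    bmi = w1 / (h1 / 100.0) ** 2
    labels = np.where(bmi < 18.5, "underweight",
                      np.where(bmi <= 25.0, "normal",
                               np.where(bmi <= 30.0, "overweight", "obese")))
    return str(labels[0]) if scalar else labels


@dataclass
class Person:
    """One survey respondent's anthropometrics and reported intake.

    ``ee_kcal`` (measured total energy expenditure, doubly labeled water) is
    present only in training data.
    """

    id: object
    sex: int
    age_years: float
    weight_kg: float
    ei_claimed_kcal: float
    height_cm: Optional[float] = None
    ee_kcal: Optional[float] = None
    special_diet: bool = False
    atypical_day: bool = False
    nonreporter: bool = False
    race_group: str = "unknown"

    def __post_init__(self):
        self.sex = sex_code(self.sex)
        if not np.isfinite(self.age_years) or self.age_years < 18:
            raise ValueError("age_years must be finite and >= 18")
        if not np.isfinite(self.weight_kg) or self.weight_kg <= 0:
            raise ValueError("weight_kg must be positive")
        if not np.isfinite(self.ei_claimed_kcal) or self.ei_claimed_kcal < 0:
            raise ValueError("ei_claimed_kcal must be finite and non-negative")
        if self.ee_kcal is not None and (not np.isfinite(self.ee_kcal) or self.ee_kcal <= 0):
            raise ValueError("ee_kcal must be positive when present")
        if self.race_group not in ("black", "nonblack", "unknown"):
            raise ValueError(f"unknown race_group {self.race_group!r}")


@dataclass
class EnergyProfile:
    """Derived energy quantities for a single person.

    ``pal`` and ``pct_misreport`` are present iff measured EE is available.
    """

    rmr_kcal: float
    ind_ei_claimed: float
    pal: Optional[float] = None
    pct_misreport: Optional[float] = None
    plausibility: str = "plausible"


def derive_profile(person: Person, bounds: PlausibilityBounds = PlausibilityBounds(),
                   *, equation="weight_only") -> EnergyProfile:
    """Fill in RMR, IndEI, and (when EE is measured) PAL and percent misreporting."""
    rmr = schofield_rmr(person.sex, person.age_years, person.weight_kg,
                        equation=equation, height_cm=person.height_cm)
    if rmr <= 0:
        raise RuntimeError("internal error: non-positive RMR")
    ind_ei = person.ei_claimed_kcal / rmr
    pal = pm = None
    if person.ee_kcal is not None:
        pal = person.ee_kcal / rmr
        pm = pct_misreport(person.ee_kcal, person.ei_claimed_kcal)
    label = classify_plausibility(ind_ei, person.sex, bounds)
    return EnergyProfile(rmr_kcal=rmr, ind_ei_claimed=ind_ei, pal=pal,
                         pct_misreport=pm, plausibility=label)


def derive_profiles(df: pd.DataFrame, bounds: PlausibilityBounds = PlausibilityBounds(),
                    *, equation="weight_only") -> pd.DataFrame:
    """Vectorised :func:`derive_profile` over a person table.

    Returns a copy of ``df`` with added columns ``rmr_kcal``,
    ``ind_ei_claimed``, ``plausibility`` and, when ``ee_kcal`` is present,
    ``pal`` and ``pct_misreport``.
    """
    out = df.copy()
    sexes = sex_code(out["sex"].to_numpy())
    height = out["height_cm"].to_numpy(dtype=float) if "height_cm" in out else None
    rmr = schofield_rmr(sexes, out["age_years"].to_numpy(dtype=float),
                        out["weight_kg"].to_numpy(dtype=float),
                        equation=equation, height_cm=height)
    out["rmr_kcal"] = rmr
    out["ind_ei_claimed"] = out["ei_claimed_kcal"].to_numpy(dtype=float) / rmr
    if "ee_kcal" in out.columns and out["ee_kcal"].notna().any():
        ee = out["ee_kcal"].to_numpy(dtype=float)
        out["pal"] = ee / rmr
        out["pct_misreport"] = 100.0 * (ee - out["ei_claimed_kcal"].to_numpy(dtype=float)) / ee
    out["plausibility"] = classify_plausibility(out["ind_ei_claimed"].to_numpy(), sexes, bounds)
    return out
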