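"""Synthetic survey populations for testing the correction methods.

Two generators stand in for datasets that cannot be redistributed:

* :func:`generate_open_like` — a doubly-labeled-water *training* study:
  adults 40–69 with reported intake and measured expenditure, whose
  misreporting follows a known linear model in the five regression
  covariates.  The true coefficient vector is attached to the output so
  parameter-recovery tests have an exact target.
* :func:`generate_nhanes_like` — a national-survey *test* population with
  age–sex strata calibrated to published summary moments, optionally tuned
  so a chosen fraction of reported intakes is physiologically implausible.

Construction of the training set.  The misreporting model's covariates
include ``log(EI_claimed)`` and ``IndEI_claimed``, which depend on the very
intake the model generates, so "draw expenditure, then solve for intake"
is a per-person fixed point.  With the steep published slopes that fixed
point is unstable or multi-rooted for a sizeable share of realistic
activity levels, and noise placed inside it becomes amplified and
correlated with the covariates — which would make ordinary least squares
inconsistent and the generator useless for recovery testing.  The
generator therefore draws the *claimed* quantities first (intake
log-normal on published moments), evaluates percent misreporting from the
linear model plus exogenous Gaussian noise, and derives measured
expenditure as ``EE = EI/(1 - pct/100)``; the noise is thereby attributed
to the expenditure measurement (doubly labeled water carries a few percent
error in practice).  PAL = EE/RMR is then a derived quantity, guarded to a
physiologic band.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, Optional, Tuple

import numpy as np
import pandas as pd
import scipy.optimize
import scipy.stats

from .metrics import FEMALE, MALE, PlausibilityBounds, schofield_rmr
from .regression import MisreportModel, OPEN_MEAN_PCT_MISREPORT, default_open_model
from .shift import PALDistribution, default_pal_distributions
from .simulate import DEFAULT_AGE_BIN_EDGES, StratumTable, build_strata

__all__ = [
    "OpenLikeConfig",
    "generate_open_like",
    "NhanesLikeConfig",
    "generate_nhanes_like",
    "default_agesex_weights",
    "NHANES_FLAVORS",
]

# Synthetic-only guard band for derived PAL; a generator-level safeguard,
# not a method assumption.
_PAL_GUARD = (1.05, 4.5)

_HEIGHT_BY_SEX = {MALE: (176.0, 7.5), FEMALE: (162.0, 7.0)}  # cm, synthetic


def _truncnorm(rng, mean, sd, lower, size):
    a = (lower - mean) / sd
    return scipy.stats.truncnorm.rvs(a, np.inf, loc=mean, scale=sd,
                                     size=size, random_state=rng)


def _lognormal_params(mean, sd):
    """(mu, sigma) of a log-normal with the given arithmetic mean and SD."""
    cv2 = (sd / mean) ** 2
    sigma2 = math.log1p(cv2)
    return math.log(mean) - sigma2 / 2.0, math.sqrt(sigma2)


@dataclass
class OpenLikeConfig:
    """Conditions of the synthetic training study (doubly-labeled-water cohort).

    Defaults reproduce the published training-study summary: 45.7% women,
    ages 40–69, weight 81.0 (17.6) kg, reported intake 2346 (808) kcal, and
    mean misreporting of ~10.7%.  ``misreport_model`` supplies the slope
    vector (published values by default); its intercept is recentred on the
    generated sample so the mean misreporting matches ``target_mean_pct``
    (the printed intercept is not mean-consistent with the published
    summary moments under any log base — see the methods note).
    """

    n: int = 423
    sex_fraction_female: float = 0.457
    age_range: Tuple[float, float] = (40.0, 69.0)
    weight_mean_kg: float = 81.0
    weight_sd_kg: float = 17.6
    ei_mean_kcal: float = 2346.0
    ei_sd_kcal: float = 808.0
    pal_params: Dict[int, PALDistribution] = field(default_factory=default_pal_distributions)
    misreport_model: MisreportModel = field(default_factory=default_open_model)
    target_mean_pct: float = OPEN_MEAN_PCT_MISREPORT
    noise_sd: float = 5.0
    black_fraction: float = 0.0
    black_model: Optional[MisreportModel] = None
    seed: int = 0

    def __post_init__(self):
        if self.n < 1:
            raise ValueError("n must be >= 1")
        if not (0.0 <= self.sex_fraction_female <= 1.0):
            raise ValueError("sex_fraction_female must lie in [0, 1]")
        if not (0.0 <= self.black_fraction <= 1.0):
            raise ValueError("black_fraction must lie in [0, 1]")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if self.age_range[0] < 18 or self.age_range[1] < self.age_range[0]:
            raise ValueError("age_range must be an adult interval")
        if min(self.weight_mean_kg, self.weight_sd_kg,
               self.ei_mean_kcal, self.ei_sd_kcal) <= 0:
            raise ValueError("weight and intake moments must be positive")


def generate_open_like(config: OpenLikeConfig = OpenLikeConfig()) -> pd.DataFrame:
    """Generate a training table with measured ``ee_kcal``.

    The true coefficient vector actually used (published slopes, recentred
    intercept) is attached as ``df.attrs["true_model"]``.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n
    sex = np.where(rng.random(n) < config.sex_fraction_female, FEMALE, MALE)
    age = rng.uniform(config.age_range[0], config.age_range[1], size=n)
    weight = _truncnorm(rng, config.weight_mean_kg, config.weight_sd_kg, 35.0, n)
    height = np.empty(n)
    for s, (hm, hs) in _HEIGHT_BY_SEX.items():
        m = sex == s
        height[m] = rng.normal(hm, hs, size=int(m.sum()))
    rmr = schofield_rmr(sex, age, weight)

    mu, sigma = _lognormal_params(config.ei_mean_kcal, config.ei_sd_kcal)
    ei = rng.lognormal(mu, sigma, size=n)
    log = np.log if config.misreport_model.log_convention == "natural" else np.log10
    X = np.column_stack([sex.astype(float), age, weight, log(ei), ei / rmr])

    slopes = config.misreport_model.slopes
    intercept = config.target_mean_pct - float(slopes @ X.mean(axis=0))
    pct = intercept + X @ slopes

    race = np.full(n, "nonblack", dtype=object)
    if config.black_fraction > 0:
        black = rng.random(n) < config.black_fraction
        race[black] = "black"
        bm = config.black_model
        if bm is not None:
            b_int = config.target_mean_pct - float(bm.slopes @ X[black].mean(axis=0)) \
                if math.isnan(bm.intercept) else bm.intercept
            pct[black] = b_int + X[black] @ bm.slopes

    if config.noise_sd > 0:
        pct = pct + rng.normal(0.0, config.noise_sd, size=n)
    # guard: keep derived PAL = IndEI/(1 - pct/100) inside the physiologic band
    ind_ei = ei / rmr
    lo = 100.0 * (1.0 - ind_ei / _PAL_GUARD[0])
    hi = 100.0 * (1.0 - ind_ei / _PAL_GUARD[1])
    pct = np.clip(pct, lo, hi)
    ee = ei / (1.0 - pct / 100.0)

    df = pd.DataFrame({
        "id": np.arange(n),
        "sex": sex,
        "age_years": age,
        "weight_kg": weight,
        "height_cm": height,
        "ei_claimed_kcal": ei,
        "ee_kcal": ee,
        "special_diet": False,
        "atypical_day": False,
        "nonreporter": False,
        "race_group": race,
    })
    df.attrs["true_model"] = MisreportModel(
        intercept=intercept, beta_sex=float(slopes[0]), beta_age=float(slopes[1]),
        beta_weight=float(slopes[2]), beta_log_ei=float(slopes[3]),
        beta_ind_ei=float(slopes[4]),
        log_convention=config.misreport_model.log_convention,
        source="synthetic_truth")
    return df


#: Published summary moments the two survey flavors are calibrated to.
NHANES_FLAVORS = {
    "1971": {"weight_mean": 69.2, "weight_sd": 15.3,
             "ei_mean": 1876.0, "ei_sd": 884.0, "age_max": 74.0},
    "2007": {"weight_mean": 80.0, "weight_sd": 20.7,
             "ei_mean": 2120.0, "ei_sd": 1050.0, "age_max": 79.0},
}


@dataclass
class NhanesLikeConfig:
    """Conditions of the synthetic national-survey test population.

    Reported intake is log-normal with the flavor's overall mean/SD, split
    by sex with a female/male reported-intake ratio of 0.70 (overall mean
    preserved).  When ``implausible_fraction_target`` is set, a common
    location shift of the per-sex log-intake means is solved so that the
    expected fraction of IndEI values outside the default bounds equals the
    target.
    """

    n: int = 10_000
    flavor: str = "2007"
    sex_fraction_female: float = 0.51
    ei_female_male_ratio: float = 0.70
    implausible_fraction_target: Optional[float] = None
    age_bin_edges: Tuple[float, ...] = DEFAULT_AGE_BIN_EDGES
    bounds: PlausibilityBounds = field(default_factory=PlausibilityBounds)
    black_fraction: float = 0.15
    seed: int = 0

    def __post_init__(self):
        if self.n < 1:
            raise ValueError("n must be >= 1")
        if self.flavor not in NHANES_FLAVORS:
            raise ValueError(f"unknown flavor {self.flavor!r}; known: {sorted(NHANES_FLAVORS)}")
        if self.implausible_fraction_target is not None and not (
                0.0 < self.implausible_fraction_target < 1.0):
            raise ValueError("implausible_fraction_target must lie in (0, 1)")
        if not (0.0 <= self.sex_fraction_female <= 1.0):
            raise ValueError("sex_fraction_female must lie in [0, 1]")
        if self.ei_female_male_ratio <= 0:
            raise ValueError("ei_female_male_ratio must be positive")


def _sex_ei_means(config: NhanesLikeConfig) -> Dict[int, float]:
    """Per-sex intake means preserving the flavor's overall mean."""
    m = NHANES_FLAVORS[config.flavor]["ei_mean"]
    wf = config.sex_fraction_female
    r = config.ei_female_male_ratio
    male_mean = m / ((1.0 - wf) + r * wf)
    return {MALE: male_mean, FEMALE: r * male_mean}


def _expected_fail_fraction(delta, mu_by_sex, sigma, rmr, sex, bounds):
    """Expected out-of-bounds fraction under log-normal intake shifted by delta."""
    total = 0.0
    n = len(rmr)
    for s, mu in mu_by_sex.items():
        m = sex == s
        if not m.any():
            continue
        hi = bounds.max_indei_female if s == FEMALE else bounds.max_indei_male
        z_lo = (np.log(bounds.min_indei * rmr[m]) - mu - delta) / sigma
        z_hi = (np.log(hi * rmr[m]) - mu - delta) / sigma
        p = scipy.stats.norm.cdf(z_lo) + scipy.stats.norm.sf(z_hi)
        total += float(p.sum())
    return total / n


def generate_nhanes_like(config: NhanesLikeConfig = NhanesLikeConfig()
                         ) -> Tuple[pd.DataFrame, StratumTable]:
    """Generate a survey person table and its sex x age stratification."""
    rng = np.random.default_rng(config.seed)
    n = config.n
    flavor = NHANES_FLAVORS[config.flavor]
    sex = np.where(rng.random(n) < config.sex_fraction_female, FEMALE, MALE)
    age = rng.uniform(18.0, flavor["age_max"], size=n)
    weight = _truncnorm(rng, flavor["weight_mean"], flavor["weight_sd"], 35.0, n)
    height = np.empty(n)
    for s, (hm, hs) in _HEIGHT_BY_SEX.items():
        m = sex == s
        height[m] = rng.normal(hm, hs, size=int(m.sum()))
    rmr = schofield_rmr(sex, age, weight)

    cv = flavor["ei_sd"] / flavor["ei_mean"]
    sigma = math.sqrt(math.log1p(cv * cv))
    mu_by_sex = {s: math.log(m_s) - sigma * sigma / 2.0
                 for s, m_s in _sex_ei_means(config).items()}

    delta = 0.0
    if config.implausible_fraction_target is not None:
        target = config.implausible_fraction_target

        def f(d):
            return _expected_fail_fraction(d, mu_by_sex, sigma, rmr, sex,
                                           config.bounds) - target

        grid = np.linspace(-2.0, 2.0, 81)
        vals = np.array([f(d) for d in grid])
        i_min = int(np.argmin(vals))
        if vals[i_min] > 0:
            raise ValueError(
                "implausible_fraction_target is below the achievable minimum "
                f"({vals[i_min] + target:.3f}) for this population")
        # under-reporting branch: lowest-mean solution at or left of the minimum
        left = grid[: i_min + 1][vals[: i_min + 1] > 0]
        lo = left[-1] if left.size else -5.0
        delta = scipy.optimize.brentq(f, lo, grid[i_min])

    ei = np.empty(n)
    for s, mu in mu_by_sex.items():
        m = sex == s
        ei[m] = rng.lognormal(mu + delta, sigma, size=int(m.sum()))

    race = np.where(rng.random(n) < config.black_fraction, "black", "nonblack")
    df = pd.DataFrame({
        "id": np.arange(n),
        "sex": sex,
        "age_years": age,
        "weight_kg": weight,
        "height_cm": height,
        "ei_claimed_kcal": ei,
        "ee_kcal": np.nan,
        "special_diet": False,
        "atypical_day": False,
        "nonreporter": False,
        "race_group": race,
    })
    df.attrs["log_ei_shift"] = delta
    return df, build_strata(df, config.age_bin_edges)


def default_agesex_weights(flavor: str = "2007",
                           age_bin_edges=DEFAULT_AGE_BIN_EDGES
                           ) -> Dict[Tuple[int, int], float]:
    """Bundled synthetic census-style age–sex weights.

    Uniform across age bins with a 0.49/0.51 male/female split; a
    self-contained stand-in for real census distributions, which must be
    supplied externally to emulate a specific survey year.
    """
    if flavor not in NHANES_FLAVORS:
        raise ValueError(f"unknown flavor {flavor!r}; known: {sorted(NHANES_FLAVORS)}")
    n_bins = len(age_bin_edges)
    weights = {}
    for b in range(n_bins):
        weights[(MALE, b)] = 0.49 / n_bins
        weights[(FEMALE, b)] = 0.51 / n_bins
    return weights
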