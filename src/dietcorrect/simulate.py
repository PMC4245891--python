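"""Monte-Carlo simulation of survey populations and correction failure rates.

A survey person table is partitioned into sex x age-bin strata.  Each
replicate draws a synthetic population: every individual first receives a
(sex, age-bin) cell from a census-style weight table, then a complete
record (height, weight, reported intake drawn jointly, preserving their
correlation) uniformly with replacement from the matching stratum.  A
correction method — none, the misreporting regression, or the intake shift
— is applied and the *failure rate* recorded: the percent of individuals
whose (corrected) IndEI falls outside the plausibility bounds.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from typing import Dict, Optional, Tuple

import numpy as np
import pandas as pd

from . import metrics
from .metrics import FEMALE, MALE, PlausibilityBounds, classify_plausibility, schofield_rmr, sex_code
from .regression import MisreportModel, correct_ei
from .shift import PALDistribution, compute_shift, apply_shift

__all__ = [
    "DEFAULT_AGE_BIN_EDGES",
    "apply_exclusions",
    "filter_population",
    "StratumTable",
    "build_strata",
    "sample_population",
    "SimulationConfig",
    "SimulationResult",
    "run_simulation",
    "PopulationSimulation",
]

#: Default 10-year age bands: 18–29, 30–39, ..., 60–69, 70+.
DEFAULT_AGE_BIN_EDGES = (18.0, 30.0, 40.0, 50.0, 60.0, 70.0)

_RECORD_COLUMNS = ("height_cm", "weight_kg", "ei_claimed_kcal")


def apply_exclusions(raw: pd.DataFrame) -> Tuple[pd.DataFrame, Dict[str, int]]:
    """Drop records unusable under the homeostasis assumption.

    Excluded, in order: respondents on a special diet, those who ate
    atypically that day, non-reporters (flag set or missing/zero intake),
    and minors (age < 18).  Missing flag columns are treated as all-false.
    Returns the filtered table and the count removed by each rule.
    """
    df = raw.copy()
    counts: Dict[str, int] = {}

    def flag(name):
        if name in df:
            col = df[name]
            if col.dtype == object:
                col = col.map(_parse_bool)
            return col.fillna(False).astype(bool).to_numpy()
        return np.zeros(len(df), dtype=bool)

    drop = flag("special_diet")
    counts["special_diet"] = int(drop.sum())
    df = df[~drop]

    drop = flag("atypical_day")
    counts["atypical_day"] = int(drop.sum())
    df = df[~drop]

    nonrep = flag("nonreporter")
    if "ei_claimed_kcal" in df:
        ei = pd.to_numeric(df["ei_claimed_kcal"], errors="coerce")
        nonrep = nonrep | ei.isna().to_numpy() | (ei.to_numpy() <= 0.0)
    counts["nonreporter"] = int(nonrep.sum())
    df = df[~nonrep]

    underage = pd.to_numeric(df["age_years"], errors="coerce").to_numpy() < 18.0
    counts["under_18"] = int(underage.sum())
    df = df[~underage]

    return df.reset_index(drop=True), counts


def _parse_bool(v):
    if isinstance(v, str):
        return v.strip().lower() in ("1", "true", "t", "yes", "y")
    return bool(v) if pd.notna(v) else False


def filter_population(df: pd.DataFrame, which: str) -> pd.DataFrame:
    """Sub-population filters mirroring the sensitivity analysis groups."""
    if which == "all_adults":
        return df
    if which == "nonblack":
        return df[df.get("race_group", pd.Series("unknown", index=df.index)) != "black"]
    if which == "nonblack_40_69":
        out = df[df.get("race_group", pd.Series("unknown", index=df.index)) != "black"]
        age = out["age_years"].to_numpy(dtype=float)
        return out[(age >= 40.0) & (age <= 69.0)]
    raise ValueError(f"unknown population filter {which!r}")


@dataclass
class StratumTable:
    """Records partitioned into sex x half-open age bins.

    ``strata`` maps ``(sex_code, bin_index)`` to an array of records with
    columns (height_cm, weight_kg, ei_claimed_kcal); ``age_bin_edges`` are
    the left edges, the last bin extending upward without limit.
    """

    strata: Dict[Tuple[int, int], np.ndarray]
    age_bin_edges: Tuple[float, ...]

    @property
    def n_bins(self) -> int:
        return len(self.age_bin_edges)

    def age_bin_range(self, idx: int) -> Tuple[float, float]:
        lo = self.age_bin_edges[idx]
        hi = (self.age_bin_edges[idx + 1] if idx + 1 < len(self.age_bin_edges)
              else lo + 10.0)
        return lo, hi


def build_strata(persons: pd.DataFrame,
                 age_bin_edges=DEFAULT_AGE_BIN_EDGES) -> StratumTable:
    """Partition a person table by sex and half-open age bins [lo, hi).

    Ages at an interior edge go to the upper bin; ages above the last edge
    go to the final bin.  Ages below the first edge are rejected.
    """
    if len(persons) == 0:
        raise ValueError("cannot build strata from an empty table")
    edges = tuple(float(e) for e in age_bin_edges)
    if list(edges) != sorted(set(edges)):
        raise ValueError("age_bin_edges must be strictly increasing")
    age = persons["age_years"].to_numpy(dtype=float)
    if np.any(age < edges[0]):
        raise ValueError(f"ages below the first edge {edges[0]} are not binnable")
    sexes = sex_code(persons["sex"].to_numpy())
    bins = np.searchsorted(edges, age, side="right") - 1
    strata: Dict[Tuple[int, int], np.ndarray] = {}
    height = (persons["height_cm"].to_numpy(dtype=float) if "height_cm" in persons
              else np.full(len(persons), np.nan))
    records = np.column_stack([
        height,
        persons["weight_kg"].to_numpy(dtype=float),
        persons["ei_claimed_kcal"].to_numpy(dtype=float),
    ])
    for s in (MALE, FEMALE):
        for b in range(len(edges)):
            m = (sexes == s) & (bins == b)
            if m.any():
                strata[(s, b)] = records[m]
    return StratumTable(strata=strata, age_bin_edges=edges)


def sample_population(strata: StratumTable, agesex_weights: Dict[Tuple[int, int], float],
                      n: int, rng) -> pd.DataFrame:
    """Draw a synthetic population of ``n`` individuals.

    Each individual's (sex, age-bin) cell follows ``agesex_weights`` (must
    sum to 1); their full record is then drawn uniformly with replacement
    from that stratum, and an age uniformly within the bin.  Deterministic
    given the generator state.
    """
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(rng)
    cells = sorted(agesex_weights)
    w = np.array([agesex_weights[c] for c in cells], dtype=float)
    if abs(w.sum() - 1.0) > 1e-9:
        raise ValueError("agesex_weights must sum to 1")
    if np.any(w < 0):
        raise ValueError("agesex_weights must be non-negative")
    for c, wc in zip(cells, w):
        if wc > 0 and c not in strata.strata:
            raise ValueError(f"positively weighted stratum {c} has no records")
    counts = rng.multinomial(int(n), w)
    parts = []
    for cell, k in zip(cells, counts):
        if k == 0:
            continue
        s, b = cell
        recs = strata.strata[cell]
        idx = rng.integers(0, len(recs), size=k)
        lo, hi = strata.age_bin_range(b)
        age = rng.uniform(lo, hi, size=k)
        parts.append(pd.DataFrame({
            "sex": np.full(k, s, dtype=int),
            "age_years": age,
            "height_cm": recs[idx, 0],
            "weight_kg": recs[idx, 1],
            "ei_claimed_kcal": recs[idx, 2],
        }))
    out = pd.concat(parts, ignore_index=True)
    out.insert(0, "id", np.arange(len(out)))
    return out


@dataclass
class SimulationConfig:
    """Configuration of one Monte-Carlo experiment."""

    n_individuals: int = 10_000
    n_replicates: int = 1_000
    seed: int = 0
    population_filter: str = "all_adults"
    method: str = "none"
    bounds: PlausibilityBounds = field(default_factory=PlausibilityBounds)
    cap_pct: float = 99.0

    def __post_init__(self):
        if self.n_individuals < 1 or self.n_replicates < 1:
            raise ValueError("n_individuals and n_replicates must be >= 1")
        if self.method not in ("none", "regression", "intake_shift"):
            raise ValueError(f"unknown method {self.method!r}")
        if self.population_filter not in ("all_adults", "nonblack", "nonblack_40_69"):
            raise ValueError(f"unknown population_filter {self.population_filter!r}")


@dataclass
class SimulationResult:
    """Failure rates per replicate plus method-specific aggregates."""

    method: str
    n_individuals: int
    n_replicates: int
    seed: int
    failure_rate_per_replicate: np.ndarray
    failure_rate_mean: float
    shift_kcal_by_sex: Optional[Dict[int, float]] = None
    shift_kcal_by_sex_per_replicate: Optional[Dict[int, np.ndarray]] = None
    delta_ei_quantiles: Optional[Dict[str, float]] = None

    def __post_init__(self):
        rates = np.asarray(self.failure_rate_per_replicate, dtype=float)
        if np.any((rates < 0) | (rates > 100)):
            raise ValueError("failure rates must lie in [0, 100]")
        if rates.size and not np.isclose(self.failure_rate_mean, rates.mean(),
                                         rtol=1e-12, atol=1e-9):
            raise ValueError("failure_rate_mean must be the mean of per-replicate rates")

    def summary(self) -> str:
        lines = [
            f"method: {self.method}",
            f"replicates: {self.n_replicates} x {self.n_individuals} individuals (seed {self.seed})",
            f"failure rate: mean {self.failure_rate_mean:.2f}% "
            f"(sd {np.std(self.failure_rate_per_replicate, ddof=1) if self.n_replicates > 1 else 0.0:.3f})",
        ]
        if self.shift_kcal_by_sex:
            names = {MALE: "men", FEMALE: "women"}
            for s, v in sorted(self.shift_kcal_by_sex.items()):
                lines.append(f"intake shift ({names[s]}): {v:+.0f} kcal")
        if self.delta_ei_quantiles:
            lines.append(
                "regression EI delta quantiles: "
                f"p25 {self.delta_ei_quantiles['p25']:+.0f} kcal, "
                f"p75 {self.delta_ei_quantiles['p75']:+.0f} kcal")
        return "\n".join(lines)

    def to_dict(self) -> dict:
        d = {
            "method": self.method,
            "n_individuals": self.n_individuals,
            "n_replicates": self.n_replicates,
            "seed": self.seed,
            "failure_rate_mean": self.failure_rate_mean,
            "failure_rate_per_replicate": np.asarray(
                self.failure_rate_per_replicate, dtype=float).tolist(),
        }
        if self.shift_kcal_by_sex is not None:
            d["shift_kcal_by_sex"] = {str(k): v for k, v in self.shift_kcal_by_sex.items()}
        if self.delta_ei_quantiles is not None:
            d["delta_ei_quantiles"] = dict(self.delta_ei_quantiles)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationResult":
        rates = np.asarray(d["failure_rate_per_replicate"], dtype=float)
        return cls(
            method=d["method"], n_individuals=d["n_individuals"],
            n_replicates=d["n_replicates"], seed=d["seed"],
            failure_rate_per_replicate=rates,
            failure_rate_mean=float(d["failure_rate_mean"]),
            shift_kcal_by_sex=({int(k): float(v) for k, v in d["shift_kcal_by_sex"].items()}
                               if "shift_kcal_by_sex" in d else None),
            delta_ei_quantiles=(dict(d["delta_ei_quantiles"])
                                if "delta_ei_quantiles" in d else None),
        )


def _replicate_failure(pop: pd.DataFrame, config: SimulationConfig,
                       model: Optional[MisreportModel],
                       pal_dists: Optional[Dict[int, PALDistribution]]):
    """Failure rate (%) for one sampled population, plus method extras."""
    sexes = sex_code(pop["sex"].to_numpy())
    rmr = schofield_rmr(sexes, pop["age_years"].to_numpy(dtype=float),
                        pop["weight_kg"].to_numpy(dtype=float))
    ei = pop["ei_claimed_kcal"].to_numpy(dtype=float)
    ind_ei = ei / rmr
    extras: dict = {}
    if config.method == "none":
        evaluated = ind_ei
    elif config.method == "regression":
        rmr_m = rmr
        if model.rmr_equation != "weight_only":
            rmr_m = schofield_rmr(sexes, pop["age_years"].to_numpy(dtype=float),
                                  pop["weight_kg"].to_numpy(dtype=float),
                                  equation=model.rmr_equation,
                                  height_cm=pop["height_cm"].to_numpy(dtype=float))
        pct = model.predict(sexes, pop["age_years"].to_numpy(dtype=float),
                            pop["weight_kg"].to_numpy(dtype=float), ei, rmr_m)
        ei_corr = correct_ei(ei, pct, cap=config.cap_pct)
        evaluated = ei_corr / rmr_m
        extras["delta_ei"] = ei_corr - ei
    else:  # intake_shift
        evaluated = ind_ei.copy()
        shifts = {}
        for s, dist in pal_dists.items():
            m = sexes == s
            if not m.any():
                continue
            res = compute_shift(ind_ei[m], rmr[m], dist, sex=s)
            shifts[s] = res.shift_kcal
            evaluated[m] = apply_shift(ei[m], res.shift_kcal) / rmr[m]
        extras["shifts"] = shifts
    labels = classify_plausibility(evaluated, sexes, config.bounds)
    rate = 100.0 * float(np.mean(labels != "plausible"))
    return rate, extras


def run_simulation(config: SimulationConfig, strata: StratumTable,
                   agesex_weights: Dict[Tuple[int, int], float],
                   model: Optional[MisreportModel] = None,
                   pal_dists: Optional[Dict[int, PALDistribution]] = None
                   ) -> SimulationResult:
    """Run the configured number of replicates and aggregate failure rates.

    Each replicate uses an independent RNG stream derived from
    ``(config.seed, replicate_index)``, so results are reproducible and
    individual replicates can be regenerated in isolation.
    """
    if config.method == "regression" and model is None:
        raise ValueError("method='regression' requires a MisreportModel")
    if config.method == "intake_shift" and not pal_dists:
        raise ValueError("method='intake_shift' requires per-sex PALDistributions")
    rates = np.empty(config.n_replicates)
    deltas = [] if config.method == "regression" else None
    shift_streams: Dict[int, list] = {}
    for r in range(config.n_replicates):
        rng = np.random.default_rng([config.seed, r])
        pop = sample_population(strata, agesex_weights, config.n_individuals, rng)
        rates[r], extras = _replicate_failure(pop, config, model, pal_dists)
        if deltas is not None:
            deltas.append(extras["delta_ei"])
        if "shifts" in extras:
            for s, v in extras["shifts"].items():
                shift_streams.setdefault(s, []).append(v)
    result = SimulationResult(
        method=config.method, n_individuals=config.n_individuals,
        n_replicates=config.n_replicates, seed=config.seed,
        failure_rate_per_replicate=rates, failure_rate_mean=float(rates.mean()),
    )
    if deltas is not None:
        pooled = np.concatenate(deltas)
        result.delta_ei_quantiles = {
            "p25": float(np.percentile(pooled, 25)),
            "p75": float(np.percentile(pooled, 75)),
        }
    if shift_streams:
        result.shift_kcal_by_sex_per_replicate = {
            s: np.asarray(v) for s, v in shift_streams.items()}
        result.shift_kcal_by_sex = {
            s: float(np.mean(v)) for s, v in shift_streams.items()}
    return result


class PopulationSimulation:
    """Model-object wrapper: build from a raw person table, then ``run()``.

    Applies the standard exclusions and the configured population filter,
    builds sex x age strata, and runs the Monte-Carlo experiment.
    """

    def __init__(self, config: SimulationConfig, persons: pd.DataFrame,
                 agesex_weights: Optional[Dict[Tuple[int, int], float]] = None,
                 model: Optional[MisreportModel] = None,
                 pal_dists: Optional[Dict[int, PALDistribution]] = None,
                 age_bin_edges=DEFAULT_AGE_BIN_EDGES):
        self.config = config
        filtered, self.exclusion_counts = apply_exclusions(persons)
        filtered = filter_population(filtered, config.population_filter)
        self.persons = filtered
        self.strata = build_strata(filtered, age_bin_edges)
        if agesex_weights is None:
            present = sorted(self.strata.strata)
            agesex_weights = {c: 1.0 / len(present) for c in present}
        self.agesex_weights = agesex_weights
        self.model = model
        self.pal_dists = pal_dists

    @classmethod
    def from_dataframe(cls, persons: pd.DataFrame, config: SimulationConfig,
                       **kwargs) -> "PopulationSimulation":
        return cls(config, persons, **kwargs)

    def run(self) -> SimulationResult:
        return run_simulation(self.config, self.strata, self.agesex_weights,
                              model=self.model, pal_dists=self.pal_dists)
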