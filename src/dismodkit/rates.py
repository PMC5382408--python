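"""Observed incidence/prevalence rates, direct standardization, cross-network
summaries, and the period life-table check on registry mortality."""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .registry_io import (
    AGE_CAP,
    EPISODE_OF_CARE,
    EPISODE_OF_DISEASE,
    AgeBand,
    RegistryCounts,
    RegistryTable,
    StandardPopulation,
)

RATE_KINDS = ("incidence", "prevalence", "mortality")


@dataclass(frozen=True)
class RateSchedule:
    """Stratum-indexed rates: per person-year for incidence/mortality,
    proportion in [0, 1] for prevalence."""

    values: Mapping[tuple[str, AgeBand], float]
    kind: str

    def __post_init__(self):
        if self.kind not in RATE_KINDS:
            raise ValueError(f"kind must be one of {RATE_KINDS}")
        for key, v in self.values.items():
            if v < 0:
                raise ValueError(f"negative rate at {key}")
            if self.kind == "prevalence" and v > 1:
                raise ValueError(f"prevalence above 1 at {key}")

    def to_single_year(self, sex: str) -> np.ndarray:
        """Expand band values onto the 0..99 grid by constant interpolation."""
        out = np.full(AGE_CAP, np.nan)
        for (s, band), v in self.values.items():
            if s == sex:
                out[band.lower:band.upper] = v
        return out


@dataclass(frozen=True)
class StandardizedRate:
    """Age-sex standardized rate per 1,000 with optional percentile CI."""

    value: float
    ci_lo: float | None = None
    ci_hi: float | None = None
    se_log: float | None = None

    def __post_init__(self):
        if self.ci_lo is not None and self.ci_hi is not None:
            if not (self.ci_lo <= self.value + 1e-12 and self.value <= self.ci_hi + 1e-12):
                raise ValueError("CI must bracket the point estimate")


def round_half_up(x: float, ndigits: int = 0) -> float:
    """Presentation rounding with ties away from zero (half-up)."""
    factor = 10.0 ** ndigits
    return math.floor(abs(x) * factor + 0.5) / factor * (1 if x >= 0 else -1)


# ---------------------------------------------------------------------------
# per-stratum observed measures


def person_years_at_risk(c: RegistryCounts) -> float:
    """Disease-free person-years under the half-period convention.

    Prevalent cases contribute no disease-free time, incident cases half a
    year, and deaths/institutionalizations among the diseased return half a
    year each; floored at zero.
    """
    py = (c.person_years - c.prev_count - 0.5 * c.inc_count
          + 0.5 * (c.deaths_with_disease + c.inst_with_disease))
    return max(py, 0.0)


def observed_incidence(c: RegistryCounts) -> float:
    """Incidence density: new cases per person-year free of disease."""
    py_free = person_years_at_risk(c)
    if py_free <= 0:
        raise ValueError("no disease-free exposure")
    return c.inc_count / py_free


def observed_prevalence(c: RegistryCounts, registry_type: str) -> float:
    """Point prevalence on 1 January.

    Disease-based registries count open disease episodes directly; care-based
    registries count patients seen for the disease in the lookback window,
    minus those first seen in the index year.
    """
    if c.n_registered <= 0:
        raise ValueError("n_registered must be positive")
    if registry_type == EPISODE_OF_DISEASE:
        return c.prev_count / c.n_registered
    if registry_type == EPISODE_OF_CARE:
        if c.seen_in_window is None:
            raise ValueError("care-based prevalence requires seen_in_window")
        if c.seen_in_window < c.inc_count:
            raise ValueError(
                f"seen_in_window ({c.seen_in_window}) below inc_count ({c.inc_count})")
        return (c.seen_in_window - c.inc_count) / c.n_registered
    raise ValueError(f"unknown registry_type {registry_type!r}")


def incidence_schedule(table: RegistryTable, network: str, disease: str) -> RateSchedule:
    """Observed incidence rates for one network x disease, keyed by (sex, band)."""
    values = {}
    for key, c in table.subset(network=network, disease=disease).rows.items():
        py_free = person_years_at_risk(c)
        values[(key.sex, key.age_band)] = c.inc_count / py_free if py_free > 0 else 0.0
    return RateSchedule(values=values, kind="incidence")


def prevalence_schedule(table: RegistryTable, network: str, disease: str) -> RateSchedule:
    """Observed prevalence per (sex, band); strata with nobody registered
    carry no information and are reported as 0."""
    values = {}
    for key, c in table.subset(network=network, disease=disease).rows.items():
        if c.n_registered <= 0:
            values[(key.sex, key.age_band)] = 0.0
        else:
            values[(key.sex, key.age_band)] = observed_prevalence(c, table.registry_type)
    return RateSchedule(values=values, kind="prevalence")


# ---------------------------------------------------------------------------
# standardization and summaries


def direct_standardize(r: RateSchedule, w: StandardPopulation) -> StandardizedRate:
    """Directly standardized rate per 1,000: 1000 * sum_s w_s * r_s."""
    missing = sorted(set(w.weights) - set(r.values), key=str)
    if missing:
        raise ValueError(f"rate schedule missing strata: {missing}")
    value = 1000.0 * sum(wt * r.values[key] for key, wt in w.weights.items())
    return StandardizedRate(value=value)


def simple_mean(rates: Sequence[StandardizedRate]) -> StandardizedRate:
    """Unweighted arithmetic mean over networks; no CI is attached."""
    if not rates:
        raise ValueError("simple_mean of empty list")
    return StandardizedRate(value=float(np.mean([r.value for r in rates])))


def max_min_ratio(rates: Sequence[StandardizedRate]) -> float:
    """Spread of network estimates: highest over lowest."""
    if not rates:
        raise ValueError("max_min_ratio of empty list")
    values = [r.value for r in rates]
    lo = min(values)
    if lo <= 0:
        raise ValueError("max_min_ratio undefined when the minimum is zero")
    return max(values) / lo


# ---------------------------------------------------------------------------
# life-table check


def life_expectancy(q, from_age: int = 0) -> float:
    """Period life expectancy from annual death probabilities.

    ``q`` maps single-year ages to death probabilities; it may be a full
    0..99 array or any sequence covering ``from_age``..99.  Half-year
    convention: survivors of a year add a full year, deaths in a year add
    half a year.  The table is truncated at age 99 where everyone alive
    dies (documented cap).
    """
    q = np.asarray(q, dtype=float)
    if q.ndim != 1:
        raise ValueError("q must be one-dimensional")
    if not (0 <= from_age < AGE_CAP):
        raise ValueError(f"from_age must be in [0, {AGE_CAP})")
    if q.shape[0] == AGE_CAP:
        q = q[from_age:]
    elif q.shape[0] != AGE_CAP - from_age:
        raise ValueError(
            f"q must cover ages {from_age}..{AGE_CAP - 1} "
            f"(length {AGE_CAP - from_age} or full {AGE_CAP})")
    if np.any((q < 0) | (q > 1)) or np.any(~np.isfinite(q)):
        raise ValueError("death probabilities must lie in [0, 1]")
    q = q.copy()
    q[-1] = 1.0  # terminal cap: everyone alive at 99 dies that year
    alive = np.concatenate([[1.0], np.cumprod(1.0 - q)[:-1]])
    return float(np.sum(alive * (1.0 - q)) + 0.5 * np.sum(alive * q))
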