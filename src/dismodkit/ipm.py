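"""Discrete-time illness-death cohort projection.

A hypothetical birth cohort is pushed through annual transitions driven by
incidence (inflow to the diseased state) and mortality/institutionalization
(outflow), yielding the prevalence that would be observed were the rates
stationary.  All flows are computed from the start-of-year state (explicit
forward scheme); this discrete recursion is the normative definition used
throughout the package.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np

from .registry_io import AGE_CAP, AgeBand
from .rates import RateSchedule


def _as_grid(x, name: str) -> np.ndarray:
    arr = np.asarray(x, dtype=float)
    if arr.ndim == 0:
        arr = np.full(AGE_CAP, float(arr))
    if arr.shape != (AGE_CAP,):
        raise ValueError(f"{name} must be scalar or length-{AGE_CAP}, got shape {arr.shape}")
    return arr


@dataclass(frozen=True)
class DiseaseSchedules:
    """Age-indexed annual transition probabilities for one sex.

    i: incidence; m: general (disease-free) mortality; f: excess mortality of
    the diseased; r: institutionalization of the diseased.
    """

    i: np.ndarray
    m: np.ndarray
    f: np.ndarray
    r: np.ndarray

    def __post_init__(self):
        for name in ("i", "m", "f", "r"):
            object.__setattr__(self, name, _as_grid(getattr(self, name), name))
        self.validate()

    def validate(self) -> None:
        for name in ("i", "m", "f", "r"):
            v = getattr(self, name)
            if np.any((v < 0) | (v > 1)) or np.any(~np.isfinite(v)):
                raise ValueError(f"{name} must lie in [0, 1]")
        if np.any(self.i + self.m > 1 + 1e-12):
            raise ValueError("i(a) + m(a) must not exceed 1")
        if np.any(self.m + self.f + self.r > 1 + 1e-12):
            raise ValueError("m(a) + f(a) + r(a) must not exceed 1")

    def with_incidence(self, i) -> "DiseaseSchedules":
        return DiseaseSchedules(i=i, m=self.m, f=self.f, r=self.r)


@dataclass(frozen=True)
class CohortState:
    """Start-of-year occupancies by age for a unit birth cohort.

    S: disease-free; C: diseased; dead and inst accumulate the outflows so
    that S + C + dead + inst == 1 at every age.
    """

    S: np.ndarray
    C: np.ndarray
    dead: np.ndarray
    inst: np.ndarray

    @property
    def alive(self) -> np.ndarray:
        return self.S + self.C


def project_cohort(s: DiseaseSchedules) -> CohortState:
    """Run the annual illness-death recursion over ages 0..99.

    S(a+1) = S(a) (1 - i(a) - m(a));
    C(a+1) = C(a) (1 - m(a) - f(a) - r(a)) + S(a) i(a).
    New cases are not exposed to diseased outflow in their onset year.
    """
    s.validate()
    S = np.empty(AGE_CAP)
    C = np.empty(AGE_CAP)
    dead = np.empty(AGE_CAP)
    inst = np.empty(AGE_CAP)
    S[0], C[0], dead[0], inst[0] = 1.0, 0.0, 0.0, 0.0
    for a in range(AGE_CAP - 1):
        S[a + 1] = S[a] * (1.0 - s.i[a] - s.m[a])
        C[a + 1] = C[a] * (1.0 - s.m[a] - s.f[a] - s.r[a]) + S[a] * s.i[a]
        dead[a + 1] = dead[a] + S[a] * s.m[a] + C[a] * (s.m[a] + s.f[a])
        inst[a + 1] = inst[a] + C[a] * s.r[a]
    return CohortState(S=S, C=C, dead=dead, inst=inst)


def prevalence_by_age(c: CohortState) -> np.ndarray:
    """Single-year prevalence p(a) = C/(S+C); NaN where the cohort is extinct."""
    alive = c.alive
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(alive > 0, c.C / np.where(alive > 0, alive, 1.0), np.nan)
    return p


def projected_prevalence(c: CohortState, bands=None, sex: str = "f") -> RateSchedule:
    """Band prevalence schedule (occupancy-weighted within bands) for one
    sex's projected cohort; extinct bands are reported as missing strata."""
    from .registry_io import default_bands

    bands = list(bands) if bands is not None else default_bands()
    values = {(sex, band): v for band, v in band_prevalence(c, bands).items()}
    return RateSchedule(values=values, kind="prevalence")


def band_prevalence(c: CohortState, bands) -> dict[AgeBand, float]:
    """Occupancy-weighted band prevalence; extinct bands are dropped."""
    p = prevalence_by_age(c)
    out: dict[AgeBand, float] = {}
    for band in bands:
        occ = c.alive[band.lower:band.upper]
        total = occ.sum()
        if total <= 0:
            continue  # extinct: value undefined, reported as missing
        out[band] = float(np.nansum(p[band.lower:band.upper] * occ) / total)
    return out


def projected_prevalence_for_sex(states: Mapping[str, CohortState], bands) -> RateSchedule:
    """Assemble a (sex, band)-keyed prevalence schedule from per-sex cohorts."""
    values = {}
    for sex, state in states.items():
        for band, v in band_prevalence(state, bands).items():
            values[(sex, band)] = v
    return RateSchedule(values=values, kind="prevalence")


@dataclass(frozen=True)
class ConsistencyReport:
    """Observed vs projected prevalence per stratum plus a summary."""

    strata: tuple[tuple[str, AgeBand], ...]
    observed: tuple[float, ...]
    projected: tuple[float, ...]
    difference: tuple[float, ...]
    ratio: tuple[float | None, ...]
    mean_abs_difference: float

    def to_records(self) -> list[dict]:
        recs = []
        for (sex, band), obs, proj, diff, ratio in zip(
                self.strata, self.observed, self.projected, self.difference, self.ratio):
            recs.append({
                "sex": sex, "age_lo": band.lower, "age_hi": band.upper,
                "observed": obs, "projected": proj,
                "difference": diff, "ratio": ratio,
            })
        return recs


SCHEDULE_COLUMNS = ["sex", "age_lo", "age_hi", "incidence", "mortality",
                    "excess_mortality", "institutionalization"]


def read_schedules(path) -> dict[str, DiseaseSchedules]:
    """Read per-sex transition schedules from a banded CSV, expanding band
    values to the single-year grid by constant interpolation."""
    import pandas as pd

    frame = pd.read_csv(path, dtype={"sex": str})
    missing = [c for c in SCHEDULE_COLUMNS if c not in frame.columns]
    if missing:
        raise ValueError(f"missing column(s) {missing} in {path}")
    out: dict[str, DiseaseSchedules] = {}
    for sex, grp in frame.groupby("sex"):
        grids = {name: np.full(AGE_CAP, np.nan) for name in ("i", "m", "f", "r")}
        for _, rec in grp.iterrows():
            band = AgeBand(int(rec["age_lo"]), int(rec["age_hi"]))
            grids["i"][band.lower:band.upper] = rec["incidence"]
            grids["m"][band.lower:band.upper] = rec["mortality"]
            grids["f"][band.lower:band.upper] = rec["excess_mortality"]
            grids["r"][band.lower:band.upper] = rec["institutionalization"]
        for name, grid in grids.items():
            if np.any(np.isnan(grid)):
                raise ValueError(f"schedule '{name}' for sex {sex!r} does not cover ages 0-99")
        out[str(sex)] = DiseaseSchedules(**grids)
    return out


def write_schedules(by_sex: Mapping[str, DiseaseSchedules], path, band_width: int = 5) -> None:
    """Write per-sex schedules banded by simple within-band means."""
    import pandas as pd

    records = []
    for sex in sorted(by_sex):
        s = by_sex[sex]
        for lo in range(0, AGE_CAP, band_width):
            sl = slice(lo, lo + band_width)
            records.append({
                "sex": sex, "age_lo": lo, "age_hi": lo + band_width,
                "incidence": float(s.i[sl].mean()),
                "mortality": float(s.m[sl].mean()),
                "excess_mortality": float(s.f[sl].mean()),
                "institutionalization": float(s.r[sl].mean()),
            })
    pd.DataFrame.from_records(records, columns=SCHEDULE_COLUMNS).to_csv(
        path, index=False, float_format="%.10g")


def consistency_report(observed: RateSchedule, projected: RateSchedule) -> ConsistencyReport:
    """Per-stratum (projected - observed) differences and ratios with the
    mean absolute difference as summary."""
    if set(observed.values) != set(projected.values):
        only_obs = sorted(set(observed.values) - set(projected.values), key=str)
        only_proj = sorted(set(projected.values) - set(observed.values), key=str)
        raise ValueError(f"stratum mismatch: observed-only {only_obs}, projected-only {only_proj}")
    strata = sorted(observed.values, key=lambda k: (k[0], k[1]))
    obs = [observed.values[k] for k in strata]
    proj = [projected.values[k] for k in strata]
    diff = [p - o for p, o in zip(proj, obs)]
    ratio = [p / o if o != 0 else None for p, o in zip(proj, obs)]
    mad = float(np.mean(np.abs(diff))) if diff else 0.0
    return ConsistencyReport(
        strata=tuple(strata), observed=tuple(obs), projected=tuple(proj),
        difference=tuple(diff), ratio=tuple(ratio), mean_abs_difference=mad,
    )
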