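"""Synthetic GP-registry generator.

Simulates a closed population through a stationary illness-death process
(year steps, flows from start-of-year state, matching the projection
recursion), overlays a care-seeking contact process, and extracts
aggregated registry tables the way an episode-of-disease or
episode-of-care registration would: disease-based registries read the
true state on 1 January; care-based registries classify from contacts in
a lookback window, so long-standing cases who happen to contact only in
the index year are misclassified as incident, and cases with no contact
in the whole window are missed entirely.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Mapping, NamedTuple

import numpy as np

from .ipm import DiseaseSchedules
from .registry_io import (
    AGE_CAP,
    EPISODE_OF_CARE,
    EPISODE_OF_DISEASE,
    AgeBand,
    RegistryCounts,
    RegistryTable,
    StratumKey,
    default_bands,
)

_SEXES = ("f", "m")


@dataclass(frozen=True)
class TruthConfig:
    """True disease process: per-sex transition schedules plus population."""

    disease: str
    schedules: Mapping[str, DiseaseSchedules]
    population: int
    age_weights: np.ndarray | None = None  # shared across sexes; uniform default
    p_female: float = 0.5
    index_year: int = 2010

    def __post_init__(self):
        if self.population <= 0:
            raise ValueError("population must be positive")
        if set(self.schedules) != set(_SEXES):
            raise ValueError("schedules must be keyed by 'f' and 'm'")
        w = self.age_weights
        if w is None:
            w = np.full(AGE_CAP, 1.0 / AGE_CAP)
        else:
            w = np.asarray(w, dtype=float)
            if w.shape != (AGE_CAP,) or np.any(w < 0) or w.sum() <= 0:
                raise ValueError("age_weights must be a non-negative length-100 vector")
            w = w / w.sum()
        object.__setattr__(self, "age_weights", w)


@dataclass(frozen=True)
class ObservationConfig:
    """How the true process is observed by a registry."""

    registry_type: str = EPISODE_OF_DISEASE
    contact_prob: float = 1.0
    lookback_years: int = 0
    mortality_underreport: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if not (0.0 < self.contact_prob <= 1.0):
            raise ValueError("contact_prob must lie in (0, 1]")
        if self.lookback_years < 0:
            raise ValueError("lookback_years must be >= 0")
        if not (0.0 <= self.mortality_underreport < 1.0):
            raise ValueError("mortality_underreport must lie in [0, 1)")


@dataclass
class PatientHistories:
    """Columnar patient-level histories; -1 encodes 'never'."""

    index_year: int
    sex: np.ndarray          # uint8: 0 = f, 1 = m
    birth_year: np.ndarray
    onset_year: np.ndarray
    death_year: np.ndarray
    inst_year: np.ndarray

    @property
    def n(self) -> int:
        return self.sex.shape[0]

    def last_observed_year(self) -> np.ndarray:
        """Last calendar year each patient is present in the practice."""
        last = np.full(self.n, self.index_year)
        has_death = self.death_year >= 0
        last[has_death] = np.minimum(last[has_death], self.death_year[has_death])
        has_inst = self.inst_year >= 0
        last[has_inst] = np.minimum(last[has_inst], self.inst_year[has_inst])
        return last


@dataclass(frozen=True)
class ContactRecord:
    """Boolean patient x calendar-year contact matrix from ``year0`` on."""

    year0: int
    matrix: np.ndarray

    def in_year(self, year: int) -> np.ndarray:
        col = year - self.year0
        if col < 0 or col >= self.matrix.shape[1]:
            return np.zeros(self.matrix.shape[0], dtype=bool)
        return self.matrix[:, col]


class Misclassification(NamedTuple):
    kappa: float
    missed: float


# ---------------------------------------------------------------------------
# simulation


def simulate_truth(t: TruthConfig, seed: int) -> PatientHistories:
    """Year-by-year simulation of onset, death and institutionalization.

    Flows use start-of-year state: a disease-free patient either acquires
    the disease (prob i(a)) or dies (prob m(a)) in a year; a diseased
    patient dies (m(a)+f(a)) or is institutionalized (r(a)).  New cases are
    not exposed to diseased outflow in their onset year, mirroring the
    projection recursion.
    """
    rng = np.random.default_rng(seed)
    n = t.population
    sex = (rng.random(n) >= t.p_female).astype(np.uint8)  # 0 = f, 1 = m
    age_at_index = rng.choice(AGE_CAP, size=n, p=t.age_weights)
    birth = t.index_year - age_at_index

    grids = {name: np.stack([getattr(t.schedules["f"], name),
                             getattr(t.schedules["m"], name)])
             for name in ("i", "m", "f", "r")}

    onset = np.full(n, -1, dtype=np.int64)
    death = np.full(n, -1, dtype=np.int64)
    inst = np.full(n, -1, dtype=np.int64)

    for year in range(int(birth.min()), t.index_year + 1):
        idx = np.nonzero((birth <= year) & (death < 0) & (inst < 0))[0]
        if idx.size == 0:
            continue
        a = year - birth[idx]
        s = sex[idx]
        u = rng.random(idx.size)
        iv = grids["i"][s, a]
        mv = grids["m"][s, a]
        fv = grids["f"][s, a]
        rv = grids["r"][s, a]
        free = onset[idx] < 0
        new_onset = free & (u < iv)
        die_free = free & (u >= iv) & (u < iv + mv)
        die_dis = ~free & (u < mv + fv)
        inst_dis = ~free & (u >= mv + fv) & (u < mv + fv + rv)
        onset[idx[new_onset]] = year
        death[idx[die_free | die_dis]] = year
        inst[idx[inst_dis]] = year

    return PatientHistories(index_year=t.index_year, sex=sex, birth_year=birth,
                            onset_year=onset, death_year=death, inst_year=inst)


def add_contacts(h: PatientHistories, o: ObservationConfig) -> ContactRecord:
    """Bernoulli(contact_prob) disease-coded contact per post-onset
    patient-year; the onset year always has a contact (diagnosis = visit)."""
    rng = np.random.default_rng(o.seed)
    onsets = h.onset_year[h.onset_year >= 0]
    year0 = int(onsets.min()) if onsets.size else h.index_year
    years = range(year0, h.index_year + 1)
    matrix = np.zeros((h.n, len(years)), dtype=bool)
    last = h.last_observed_year()
    for j, year in enumerate(years):
        eligible = (h.onset_year >= 0) & (h.onset_year <= year) & (year <= last)
        contact = eligible & (rng.random(h.n) < o.contact_prob)
        contact |= eligible & (h.onset_year == year)
        matrix[:, j] = contact
    return ContactRecord(year0=year0, matrix=matrix)


# ---------------------------------------------------------------------------
# extraction


def _aggregate(h: PatientHistories, registered: np.ndarray,
               prev_mask: np.ndarray, inc_mask: np.ndarray,
               seen_mask: np.ndarray | None,
               o: ObservationConfig, network: str, disease: str,
               registry_type: str, lookback_years: int) -> RegistryTable:
    index = h.index_year
    bands = default_bands()
    n_bands = len(bands)
    age = index - h.birth_year
    band_idx = np.clip(age // 5, 0, n_bands - 1)
    stratum = h.sex.astype(np.int64) * n_bands + band_idx

    diseased_before_or_in = (h.onset_year >= 0) & (h.onset_year <= index)
    died_index = h.death_year == index
    inst_index = h.inst_year == index
    died_dis = registered & diseased_before_or_in & died_index
    inst_dis = registered & diseased_before_or_in & inst_index

    # under-registration of mortality: thin recorded disease deaths /
    # institutionalizations (the true outflow still shapes person-years)
    rng = np.random.default_rng(o.seed + 1_000_003)
    keep = rng.random(h.n) < (1.0 - o.mortality_underreport)
    died_dis_rec = died_dis & keep
    inst_dis_rec = inst_dis & keep

    size = 2 * n_bands

    def count(mask: np.ndarray) -> np.ndarray:
        return np.bincount(stratum[mask], minlength=size)

    n_reg = count(registered)
    prev = count(registered & prev_mask)
    inc = count(registered & inc_mask)
    deaths = count(died_dis_rec)
    insts = count(inst_dis_rec)
    leavers = count(registered & (died_index | inst_index))
    person_years = n_reg - 0.5 * leavers  # half-period convention
    seen = count(registered & seen_mask) if seen_mask is not None else None

    rows: dict[StratumKey, RegistryCounts] = {}
    for s_code, sex in enumerate(_SEXES):
        for b, band in enumerate(bands):
            j = s_code * n_bands + b
            rows[StratumKey(network, disease, sex, band)] = RegistryCounts(
                person_years=float(person_years[j]),
                n_registered=int(n_reg[j]),
                prev_count=int(prev[j]),
                inc_count=int(inc[j]),
                deaths_with_disease=int(min(deaths[j], prev[j] + inc[j])),
                inst_with_disease=int(min(insts[j], max(prev[j] + inc[j] - deaths[j], 0))),
                seen_in_window=int(seen[j]) if seen is not None else None,
            )
    return RegistryTable(registry_type=registry_type, lookback_years=lookback_years,
                         rows=rows)


def _registered_mask(h: PatientHistories) -> np.ndarray:
    index = h.index_year
    return ((h.birth_year <= index)
            & ((h.death_year < 0) | (h.death_year >= index))
            & ((h.inst_year < 0) | (h.inst_year >= index)))


def extract_disease_based(h: PatientHistories, o: ObservationConfig,
                          network: str = "net", disease: str = "disease") -> RegistryTable:
    """Episode-of-disease extraction: the true state on 1 January is read
    directly — prevalent if onset before the index year, incident if onset
    during it."""
    index = h.index_year
    registered = _registered_mask(h)
    prev_mask = (h.onset_year >= 0) & (h.onset_year < index)
    inc_mask = h.onset_year == index
    return _aggregate(h, registered, prev_mask, inc_mask, None, o, network, disease,
                      EPISODE_OF_DISEASE, 0)


def extract_care_based(h: PatientHistories, contacts: ContactRecord,
                       o: ObservationConfig,
                       network: str = "net", disease: str = "disease") -> RegistryTable:
    """Episode-of-care extraction with a lookback window of L years.

    A patient is *seen* with >= 1 disease-coded contact in the L+1 window
    years; counted incident when the first window contact falls in the
    index year; prevalent otherwise.  Truly prevalent cases with no window
    contact are absent from the counts entirely.
    """
    index = h.index_year
    L = o.lookback_years
    if index - L < int(h.birth_year.min()):
        raise ValueError(f"lookback {L} exceeds the simulated history span")
    registered = _registered_mask(h)
    seen = np.zeros(h.n, dtype=bool)
    prior = np.zeros(h.n, dtype=bool)
    for year in range(index - L, index):
        prior |= contacts.in_year(year)
    seen = prior | contacts.in_year(index)
    inc_mask = contacts.in_year(index) & ~prior
    prev_mask = seen & ~inc_mask
    return _aggregate(h, registered, prev_mask, inc_mask, seen, o, network, disease,
                      EPISODE_OF_CARE, L)


def implied_misclassification(contact_prob: float, lookback_years: int) -> Misclassification:
    """Analytic failure rates of the window classification for a
    long-standing prevalent case: misclassified-as-incident with
    probability rho (1-rho)^L, missed entirely with (1-rho)^(L+1)."""
    if not (0.0 < contact_prob <= 1.0):
        raise ValueError("contact_prob must lie in (0, 1]")
    if lookback_years < 0:
        raise ValueError("lookback_years must be >= 0")
    rho, L = contact_prob, lookback_years
    return Misclassification(kappa=rho * (1.0 - rho) ** L,
                             missed=(1.0 - rho) ** (L + 1))


def simulate_registry(t: TruthConfig, o: ObservationConfig, seed: int,
                      network: str = "net") -> RegistryTable:
    """End-to-end convenience: truth -> contacts (if needed) -> extraction."""
    h = simulate_truth(t, seed)
    o = replace(o, seed=seed if o.seed == 0 else o.seed)
    if o.registry_type == EPISODE_OF_CARE:
        contacts = add_contacts(h, o)
        return extract_care_based(h, contacts, o, network=network, disease=t.disease)
    return extract_disease_based(h, o, network=network, disease=t.disease)


# ---------------------------------------------------------------------------
# presets


def _gompertz(scale: float, rate: float) -> np.ndarray:
    ages = np.arange(AGE_CAP, dtype=float)
    return np.clip(scale * np.exp(rate * ages), 0.0, 0.6)


def _schedules(i_scale: float, i_rate: float, f_frac: float,
               f_const: float = 0.0, r_const: float = 0.001) -> dict[str, DiseaseSchedules]:
    """Exp-in-age incidence (exactly log-polynomial, so the fitted curve can
    represent the truth), Gompertz general mortality, proportional excess."""
    m = _gompertz(5e-5, 0.085)
    i = _gompertz(i_scale, i_rate)
    f = np.clip(f_frac * m + f_const, 0.0, 0.4)
    r = np.where(np.arange(AGE_CAP) >= 65, r_const, 0.0)
    # male mortality slightly above female, as in most populations
    out = {}
    for sex, m_mult in (("f", 1.0), ("m", 1.25)):
        m_sex = np.clip(m * m_mult, 0.0, 0.6)
        out[sex] = DiseaseSchedules(i=i, m=m_sex,
                                    f=np.clip(f * m_mult, 0.0, 0.4), r=r)
    return out


@dataclass(frozen=True)
class Scenario:
    name: str
    truth: TruthConfig
    obs: ObservationConfig


def preset_scenarios(population: int = 50_000) -> list[Scenario]:
    """Named presets spanning high/low contact probability and care/disease
    registration; magnitudes loosely echo four common chronic diseases."""
    presets = [
        Scenario(
            "diabetes_like",
            TruthConfig("diabetes", _schedules(1.2e-4, 0.050, 0.4), population),
            ObservationConfig(EPISODE_OF_DISEASE, contact_prob=0.95, lookback_years=0),
        ),
        Scenario(
            "copd_like",
            TruthConfig("copd", _schedules(4e-5, 0.062, 0.6), population),
            ObservationConfig(EPISODE_OF_CARE, contact_prob=0.7, lookback_years=2),
        ),
        Scenario(
            "heart_failure_like",
            TruthConfig("heart_failure", _schedules(6e-6, 0.105, 1.0, f_const=0.02),
                        population),
            ObservationConfig(EPISODE_OF_DISEASE, contact_prob=0.85, lookback_years=0),
        ),
        Scenario(
            "knee_oa_like",
            TruthConfig("knee_oa", _schedules(2.5e-5, 0.068, 0.05), population),
            ObservationConfig(EPISODE_OF_CARE, contact_prob=0.3, lookback_years=2,
                              mortality_underreport=0.2),
        ),
    ]
    return presets


def get_preset(name: str, population: int | None = None) -> Scenario:
    for sc in preset_scenarios(population or 50_000):
        if sc.name == name:
            return sc
    raise KeyError(f"unknown preset {name!r}")


# five networks echoing the published size range (14k-270k person-years)
FIVE_NETWORKS: tuple[tuple[str, int, str], ...] = (
    ("N1", 270_000, EPISODE_OF_CARE),
    ("N2", 14_000, EPISODE_OF_DISEASE),
    ("N3", 44_000, EPISODE_OF_DISEASE),
    ("N4", 14_000, EPISODE_OF_CARE),
    ("N5", 88_000, EPISODE_OF_DISEASE),
)


def five_network_bundle(preset: str = "diabetes_like",
                        scale: float = 1.0) -> list[Scenario]:
    """Five networks sharing one true disease process but differing in size
    and registration type, mirroring the published network contrast."""
    base = get_preset(preset)
    out = []
    for name, size, rtype in FIVE_NETWORKS:
        truth = replace(base.truth, population=max(int(size * scale), 1000))
        lookback = 2 if rtype == EPISODE_OF_CARE else 0
        obs = replace(base.obs, registry_type=rtype, lookback_years=lookback)
        out.append(Scenario(name=name, truth=truth, obs=obs))
    return out
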