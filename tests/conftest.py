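from __future__ import annotations

import numpy as np
import pytest

from dismodkit.registry_io import (
    AgeBand,
    RegistryCounts,
    RegistryTable,
    StandardPopulation,
    StratumKey,
    default_bands,
)


def make_counts(person_years=1000.0, n_registered=None, prev=0, inc=0,
                deaths=0, inst=0, seen=None) -> RegistryCounts:
    return RegistryCounts(
        person_years=person_years,
        n_registered=int(round(person_years)) if n_registered is None else n_registered,
        prev_count=prev,
        inc_count=inc,
        deaths_with_disease=deaths,
        inst_with_disease=inst,
        seen_in_window=seen,
    )


def make_table(strata, registry_type="episode_of_disease", lookback=0) -> RegistryTable:
    """strata: iterable of (network, disease, sex, (lo, hi), RegistryCounts)."""
    rows = {}
    for network, disease, sex, (lo, hi), counts in strata:
        rows[StratumKey(network, disease, sex, AgeBand(lo, hi))] = counts
    return RegistryTable(registry_type=registry_type, lookback_years=lookback, rows=rows)


@pytest.fixture
def two_band_table() -> RegistryTable:
    return make_table([
        ("n1", "d", "f", (0, 50), make_counts(1000, prev=100, inc=10, deaths=4, inst=2)),
        ("n1", "d", "f", (50, 100), make_counts(500, prev=80, inc=8, deaths=6, inst=1)),
    ])


@pytest.fixture
def uniform_stdpop() -> StandardPopulation:
    bands = default_bands()
    n = 2 * len(bands)
    return StandardPopulation({(s, b): 1.0 / n for s in ("f", "m") for b in bands})


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20100101)
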