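"""Reading, validation and writing of aggregated registry tables.

The exchange format is a flat CSV with one row per stratum
(network x disease x sex x age band) carrying person-years and the
count columns every downstream stage consumes.  Ages are half-open
integer bands partitioning [0, 100); sexes are coded ``f``/``m``.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import pandas as pd

logger = logging.getLogger(__name__)

AGE_CAP = 100

REGISTRY_COLUMNS = [
    "network",
    "disease",
    "sex",
    "age_lo",
    "age_hi",
    "person_years",
    "n_registered",
    "prev_count",
    "inc_count",
    "deaths_with_disease",
    "inst_with_disease",
    "seen_in_window",
]

STDPOP_COLUMNS = ["sex", "age_lo", "age_hi", "weight"]

SEXES = ("f", "m")

EPISODE_OF_CARE = "episode_of_care"
EPISODE_OF_DISEASE = "episode_of_disease"


class RegistryParseError(ValueError):
    """Structured parse failure naming the offending row and column."""

    def __init__(self, message: str, row: int | None = None, column: str | None = None):
        self.row = row
        self.column = column
        where = []
        if row is not None:
            where.append(f"row {row}")
        if column is not None:
            where.append(f"column '{column}'")
        suffix = f" ({', '.join(where)})" if where else ""
        super().__init__(message + suffix)


@dataclass(frozen=True, order=True)
class AgeBand:
    """Half-open integer age band [lower, upper)."""

    lower: int
    upper: int

    def __post_init__(self):
        if not (0 <= self.lower < self.upper <= AGE_CAP):
            raise ValueError(f"invalid age band [{self.lower}, {self.upper})")

    @property
    def width(self) -> int:
        return self.upper - self.lower

    def ages(self) -> range:
        return range(self.lower, self.upper)

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"[{self.lower},{self.upper})"


def default_bands(width: int = 5) -> list[AgeBand]:
    """Canonical partition of [0, 100) into equal-width bands."""
    return [AgeBand(lo, lo + width) for lo in range(0, AGE_CAP, width)]


@dataclass(frozen=True, order=True)
class StratumKey:
    network: str
    disease: str
    sex: str
    age_band: AgeBand

    def __post_init__(self):
        if self.sex not in SEXES:
            raise ValueError(f"sex must be one of {SEXES}, got {self.sex!r}")


@dataclass(frozen=True)
class RegistryCounts:
    person_years: float
    n_registered: int
    prev_count: int
    inc_count: int
    deaths_with_disease: int
    inst_with_disease: int
    seen_in_window: int | None = None


@dataclass
class RegistryTable:
    registry_type: str
    lookback_years: int
    rows: dict[StratumKey, RegistryCounts] = field(default_factory=dict)

    def __post_init__(self):
        if self.registry_type not in (EPISODE_OF_CARE, EPISODE_OF_DISEASE):
            raise ValueError(f"unknown registry_type {self.registry_type!r}")
        if self.lookback_years < 0:
            raise ValueError("lookback_years must be >= 0")

    def networks(self) -> list[str]:
        return sorted({k.network for k in self.rows})

    def diseases(self) -> list[str]:
        return sorted({k.disease for k in self.rows})

    def subset(self, network: str | None = None, disease: str | None = None,
               sex: str | None = None) -> "RegistryTable":
        rows = {
            k: v
            for k, v in self.rows.items()
            if (network is None or k.network == network)
            and (disease is None or k.disease == disease)
            and (sex is None or k.sex == sex)
        }
        return RegistryTable(self.registry_type, self.lookback_years, rows)

    def to_frame(self) -> pd.DataFrame:
        records = []
        for key in sorted(self.rows):
            c = self.rows[key]
            records.append(
                {
                    "network": key.network,
                    "disease": key.disease,
                    "sex": key.sex,
                    "age_lo": key.age_band.lower,
                    "age_hi": key.age_band.upper,
                    "person_years": c.person_years,
                    "n_registered": c.n_registered,
                    "prev_count": c.prev_count,
                    "inc_count": c.inc_count,
                    "deaths_with_disease": c.deaths_with_disease,
                    "inst_with_disease": c.inst_with_disease,
                    "seen_in_window": c.seen_in_window,
                }
            )
        return pd.DataFrame.from_records(records, columns=REGISTRY_COLUMNS)

    def __eq__(self, other) -> bool:
        if not isinstance(other, RegistryTable):
            return NotImplemented
        if (self.registry_type, self.lookback_years) != (other.registry_type, other.lookback_years):
            return False
        if set(self.rows) != set(other.rows):
            return False
        for k, a in self.rows.items():
            b = other.rows[k]
            if (a.n_registered, a.prev_count, a.inc_count, a.deaths_with_disease,
                    a.inst_with_disease, a.seen_in_window) != (
                    b.n_registered, b.prev_count, b.inc_count, b.deaths_with_disease,
                    b.inst_with_disease, b.seen_in_window):
                return False
            if not math.isclose(a.person_years, b.person_years, rel_tol=0.0, abs_tol=1e-12 * max(1.0, abs(a.person_years))):
                return False
        return True


@dataclass(frozen=True)
class StandardPopulation:
    """Normalized direct-standardization weights keyed by (sex, AgeBand)."""

    weights: Mapping[tuple[str, AgeBand], float]

    def __post_init__(self):
        total = sum(self.weights.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"standard population weights sum to {total}, expected 1")
        if any(w < 0 for w in self.weights.values()):
            raise ValueError("standard population weights must be non-negative")


@dataclass(frozen=True)
class Violation:
    """A single data-quality finding; violations are data, not exceptions."""

    stratum: str
    field: str
    rule: str

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"{self.stratum}: {self.field}: {self.rule}"


# ---------------------------------------------------------------------------
# reading / writing


def _parse_int(value, row: int, column: str, allow_missing: bool = False) -> int | None:
    if value is None or (isinstance(value, float) and math.isnan(value)) or value == "":
        if allow_missing:
            return None
        raise RegistryParseError("missing value", row=row, column=column)
    try:
        f = float(value)
    except (TypeError, ValueError):
        raise RegistryParseError(f"non-numeric cell {value!r}", row=row, column=column) from None
    if abs(f - round(f)) > 1e-9:
        raise RegistryParseError(f"expected integer, got {value!r}", row=row, column=column)
    return int(round(f))


def _parse_float(value, row: int, column: str) -> float:
    if value is None or (isinstance(value, float) and math.isnan(value)) or value == "":
        raise RegistryParseError("missing value", row=row, column=column)
    try:
        return float(value)
    except (TypeError, ValueError):
        raise RegistryParseError(f"non-numeric cell {value!r}", row=row, column=column) from None


def read_registry_table(path, registry_type: str = EPISODE_OF_DISEASE,
                        lookback_years: int = 0) -> RegistryTable:
    """Read and validate a registry CSV.

    ``registry_type`` and ``lookback_years`` are observation metadata not
    carried in the flat CSV; they default to a disease-based registry.

    Raises
    ------
    RegistryParseError
        On schema problems or invariant violations, naming row and column.
    """
    try:
        frame = pd.read_csv(path, dtype={"network": str, "disease": str, "sex": str})
    except FileNotFoundError:
        raise
    except Exception as exc:  # malformed CSV
        raise RegistryParseError(f"cannot parse CSV {path}: {exc}") from exc
    missing = [c for c in REGISTRY_COLUMNS if c not in frame.columns]
    if missing:
        raise RegistryParseError(f"missing column(s) {missing} in {path}")
    table = table_from_frame(frame, registry_type=registry_type, lookback_years=lookback_years)
    violations = validate_table(table)
    if violations:
        v = violations[0]
        raise RegistryParseError(
            f"invalid registry table ({len(violations)} violation(s)); first: "
            f"{v.stratum}: {v.field}: {v.rule}"
        )
    return table


def table_from_frame(frame: pd.DataFrame, registry_type: str = EPISODE_OF_DISEASE,
                     lookback_years: int = 0) -> RegistryTable:
    rows: dict[StratumKey, RegistryCounts] = {}
    for idx, rec in frame.iterrows():
        rownum = int(idx) + 2  # 1-based with header line
        sex = str(rec["sex"]).strip()
        if sex not in SEXES:
            raise RegistryParseError(f"sex must be 'f' or 'm', got {sex!r}", row=rownum, column="sex")
        lo = _parse_int(rec["age_lo"], rownum, "age_lo")
        hi = _parse_int(rec["age_hi"], rownum, "age_hi")
        try:
            band = AgeBand(lo, hi)
        except ValueError as exc:
            raise RegistryParseError(str(exc), row=rownum, column="age_lo") from None
        key = StratumKey(str(rec["network"]), str(rec["disease"]), sex, band)
        if key in rows:
            raise RegistryParseError(f"duplicate stratum {key}", row=rownum, column="age_lo")
        person_years = _parse_float(rec["person_years"], rownum, "person_years")
        n_registered = _parse_int(rec["n_registered"], rownum, "n_registered", allow_missing=True)
        if n_registered is None:
            # stable-population fallback: registered head count taken to
            # equal the person-years of observation
            n_registered = int(round(person_years))
            logger.info("row %d: n_registered missing; assuming stable population (%d)",
                        rownum, n_registered)
        counts = RegistryCounts(
            person_years=person_years,
            n_registered=n_registered,
            prev_count=_parse_int(rec["prev_count"], rownum, "prev_count"),
            inc_count=_parse_int(rec["inc_count"], rownum, "inc_count"),
            deaths_with_disease=_parse_int(rec["deaths_with_disease"], rownum, "deaths_with_disease"),
            inst_with_disease=_parse_int(rec["inst_with_disease"], rownum, "inst_with_disease"),
            seen_in_window=_parse_int(rec["seen_in_window"], rownum, "seen_in_window",
                                      allow_missing=True),
        )
        rows[key] = counts
    return RegistryTable(registry_type=registry_type, lookback_years=lookback_years, rows=rows)


def write_registry_table(table: RegistryTable, path) -> None:
    frame = table.to_frame()
    frame.to_csv(path, index=False, float_format="%.6f")


def validate_table(table: RegistryTable) -> list[Violation]:
    """Check every type invariant; total on syntactically valid input."""
    out: list[Violation] = []
    for key, c in table.rows.items():
        name = f"{key.network}/{key.disease}/{key.sex}/{key.age_band}"
        if c.person_years < 0:
            out.append(Violation(name, "person_years", "must be non-negative"))
        for fieldname in ("n_registered", "prev_count", "inc_count",
                          "deaths_with_disease", "inst_with_disease"):
            if getattr(c, fieldname) < 0:
                out.append(Violation(name, fieldname, "must be non-negative"))
        if c.seen_in_window is not None and c.seen_in_window < 0:
            out.append(Violation(name, "seen_in_window", "must be non-negative"))
        if c.prev_count > c.n_registered:
            out.append(Violation(name, "prev_count",
                                 f"prev_count ({c.prev_count}) exceeds n_registered ({c.n_registered})"))
        if c.deaths_with_disease + c.inst_with_disease > c.prev_count + c.inc_count:
            out.append(Violation(
                name, "deaths_with_disease",
                f"deaths+institutionalizations ({c.deaths_with_disease + c.inst_with_disease}) "
                f"exceed prev+inc ({c.prev_count + c.inc_count})"))
        if table.registry_type == EPISODE_OF_CARE and c.seen_in_window is None:
            out.append(Violation(name, "seen_in_window",
                                 "required for episode-of-care registries"))
        if c.seen_in_window is not None and c.seen_in_window < c.inc_count:
            out.append(Violation(name, "seen_in_window",
                                 f"seen_in_window ({c.seen_in_window}) below inc_count ({c.inc_count})"))

    # age bands must partition [0, 100) within each (network, disease, sex)
    groups: dict[tuple[str, str, str], list[AgeBand]] = {}
    for key in table.rows:
        groups.setdefault((key.network, key.disease, key.sex), []).append(key.age_band)
    for (network, disease, sex), bands in groups.items():
        name = f"{network}/{disease}/{sex}"
        bands = sorted(bands)
        cursor = 0
        for band in bands:
            if band.lower < cursor:
                out.append(Violation(name, "age_band",
                                     f"band {band} overlaps previous band"))
            elif band.lower > cursor:
                out.append(Violation(name, "age_band",
                                     f"gap in age coverage before {band}"))
            cursor = max(cursor, band.upper)
        if cursor != AGE_CAP and not any(v.stratum == name and v.field == "age_band" for v in out):
            out.append(Violation(name, "age_band", f"age coverage ends at {cursor}, expected {AGE_CAP}"))
    return out


def read_standard_population(path) -> StandardPopulation:
    """Read standardization weights; renormalizes when the input sums != 1."""
    frame = pd.read_csv(path, dtype={"sex": str})
    missing = [c for c in STDPOP_COLUMNS if c not in frame.columns]
    if missing:
        raise RegistryParseError(f"missing column(s) {missing} in {path}")
    weights: dict[tuple[str, AgeBand], float] = {}
    for idx, rec in frame.iterrows():
        rownum = int(idx) + 2
        sex = str(rec["sex"]).strip()
        if sex not in SEXES:
            raise RegistryParseError(f"sex must be 'f' or 'm', got {sex!r}", row=rownum, column="sex")
        band = AgeBand(_parse_int(rec["age_lo"], rownum, "age_lo"),
                       _parse_int(rec["age_hi"], rownum, "age_hi"))
        w = _parse_float(rec["weight"], rownum, "weight")
        if w < 0:
            raise RegistryParseError(f"negative weight {w}", row=rownum, column="weight")
        key = (sex, band)
        if key in weights:
            raise RegistryParseError(f"duplicate stratum {key}", row=rownum, column="sex")
        weights[key] = w
    total = sum(weights.values())
    if total <= 0:
        raise RegistryParseError("standard population weights sum to zero")
    if abs(total - 1.0) > 1e-9:
        logger.info("standard population weights sum to %g; renormalizing", total)
        weights = {k: w / total for k, w in weights.items()}
    return StandardPopulation(weights=weights)


def write_standard_population(pop: StandardPopulation, path) -> None:
    records = [
        {"sex": sex, "age_lo": band.lower, "age_hi": band.upper, "weight": w}
        for (sex, band), w in sorted(pop.weights.items())
    ]
    pd.DataFrame.from_records(records, columns=STDPOP_COLUMNS).to_csv(path, index=False)


def uniform_standard_population(bands: Iterable[AgeBand] | None = None) -> StandardPopulation:
    """Equal weight on every (sex, band) stratum; handy default for tests/CLI."""
    bands = list(bands) if bands is not None else default_bands()
    n = 2 * len(bands)
    return StandardPopulation({(s, b): 1.0 / n for s in SEXES for b in bands})
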