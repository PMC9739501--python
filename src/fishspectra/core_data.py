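"""Domain types, validation and aggregation for fish-catch survey tables.

Three delimited-text tables are canonical:

* catch table      — one row per captured fish:
                     ``site,season,species,length_cm,weight_g``
* species table    — ``species,order,family,ecotype,origin,protection``
* site table       — ``site,lat,lon,altitude_m,T,DO,V,pH,TDS,TP,TN,CHL,NH3N,PO4``

The default dialect is comma-separated with dot decimals; both are
configurable through :class:`TableDialect`.
"""

from __future__ import annotations

import enum
from collections.abc import Iterable, Sequence
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import pandas as pd
from pydantic import BaseModel, ConfigDict, Field, field_validator

from fishspectra.errors import (
    ConfigurationError,
    EmptyCommunityError,
    MissingAttributesError,
    TableValidationError,
)


class Season(str, enum.Enum):
    """Survey period: wet (high-flow) or dry (low-flow) season."""

    WET = "wet"
    DRY = "dry"


class Ecotype(str, enum.Enum):
    """Resident fish vs species undertaking short spawning migrations."""

    SETTLED = "settled"
    SHORT_MIGRATORY = "short_migratory"


class Origin(str, enum.Enum):
    NATIVE = "native"
    EXOTIC = "exotic"


class CatchRecord(BaseModel):
    """One captured fish.

    Lengths are centimetres at 0.1 cm precision, weights grams at
    0.1 g precision; both must be strictly positive.
    """

    model_config = ConfigDict(frozen=True)

    site_id: str
    season: Season
    species: str
    body_length: float = Field(gt=0.0)
    body_weight: float = Field(gt=0.0)

    @field_validator("site_id", "species")
    @classmethod
    def _nonempty(cls, v: str) -> str:
        if not v.strip():
            raise ValueError("identifier must be non-empty")
        return v


class SpeciesAttributes(BaseModel):
    """Taxonomy and ecology of one species in the pool."""

    model_config = ConfigDict(frozen=True)

    species: str
    order: str
    family: str
    ecotype: Ecotype
    origin: Origin
    protection: Optional[str] = None


class SiteEnvironment(BaseModel):
    """Per-site spatial and water-quality vector.

    T water temperature (deg C), DO dissolved oxygen (mg/L), V flow
    velocity (m/s), TDS total dissolved solids (mg/L), TP total
    phosphorus (mg/L), TN total nitrogen (mg/L), CHL chlorophyll a
    (ug/L), NH3N ammonia nitrogen (mg/L), PO4 phosphate (mg/L).
    """

    model_config = ConfigDict(frozen=True)

    site_id: str
    lat: float
    lon: float
    altitude: float
    T: float
    DO: float = Field(gt=0.0)
    V: float = Field(ge=0.0)
    pH: float
    TDS: float = Field(ge=0.0)
    TP: float = Field(ge=0.0)
    TN: float = Field(ge=0.0)
    CHL: float = Field(ge=0.0)
    NH3N: float = Field(ge=0.0)
    PO4: float = Field(ge=0.0)
    # electrical conductivity (uS/cm); optional because many field
    # campaigns record TDS instead
    EC: Optional[float] = None


@dataclass(frozen=True)
class CommunitySummary:
    """Per-species abundance and biomass for one grouping of records.

    Invariants: ``sum(abundance.values()) == T``,
    ``sum(biomass.values()) == total_biomass`` and
    ``S == len(abundance)``.
    """

    group: tuple
    abundance: dict[str, int]
    biomass: dict[str, float]

    @property
    def S(self) -> int:
        return len(self.abundance)

    @property
    def T(self) -> int:
        return sum(self.abundance.values())

    @property
    def total_biomass(self) -> float:
        return sum(self.biomass.values())


@dataclass(frozen=True)
class TableDialect:
    """Delimited-text dialect: separator, decimal mark and header mapping.

    ``columns`` maps the canonical field names to the header names found
    in the file; identity by default.
    """

    sep: str = ","
    decimal: str = "."
    columns: dict[str, str] = field(default_factory=dict)

    def resolve(self, canonical: str) -> str:
        return self.columns.get(canonical, canonical)


CATCH_COLUMNS = ("site", "season", "species", "length_cm", "weight_g")
SPECIES_COLUMNS = ("species", "order", "family", "ecotype", "origin", "protection")
SITE_COLUMNS = (
    "site", "lat", "lon", "altitude_m",
    "T", "DO", "V", "pH", "TDS", "TP", "TN", "CHL", "NH3N", "PO4",
)


def _read_table(path: str | Path, dialect: TableDialect, required: Sequence[str]) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise ConfigurationError(f"table not found: {path}")
    df = pd.read_csv(path, sep=dialect.sep, decimal=dialect.decimal, dtype={})
    missing = [c for c in required if dialect.resolve(c) not in df.columns]
    if missing:
        raise ConfigurationError(
            f"{path}: missing column(s) {missing} (header has {list(df.columns)})"
        )
    return df.rename(columns={dialect.resolve(c): c for c in required})


def read_catch_table(
    path: str | Path, dialect: TableDialect | None = None
) -> list[CatchRecord]:
    """Read and validate a catch table.

    Every row becomes a :class:`CatchRecord`; rows with non-positive
    length or weight, or an unknown season, are collected and reported
    together with their 1-based file line numbers (header is line 1).

    Raises
    ------
    ConfigurationError
        if the file is missing or a required column is absent.
    TableValidationError
        if any row fails validation; ``.lines`` lists the bad lines.
    """
    dialect = dialect or TableDialect()
    df = _read_table(path, dialect, CATCH_COLUMNS)
    records: list[CatchRecord] = []
    bad: list[tuple[int, str]] = []
    for i, row in enumerate(df.itertuples(index=False)):
        line = i + 2  # header occupies line 1
        try:
            records.append(
                CatchRecord(
                    site_id=str(row.site),
                    season=Season(str(row.season)),
                    species=str(row.species),
                    body_length=float(row.length_cm),
                    body_weight=float(row.weight_g),
                )
            )
        except (ValueError, TypeError) as exc:
            bad.append((line, str(exc).splitlines()[0]))
    if bad:
        lines = [ln for ln, _ in bad]
        detail = "; ".join(f"line {ln}: {msg}" for ln, msg in bad[:10])
        raise TableValidationError(
            f"{path}: {len(bad)} invalid row(s) ({detail})", lines=lines
        )
    return records


def write_catch_table(
    records: Iterable[CatchRecord],
    path: str | Path,
    dialect: TableDialect | None = None,
) -> None:
    """Write records back to delimited text (round-trips at 0.1 precision)."""
    dialect = dialect or TableDialect()
    df = records_to_frame(records)
    df["length_cm"] = df["length_cm"].map(lambda v: f"{v:.1f}")
    df["weight_g"] = df["weight_g"].map(lambda v: f"{v:.1f}")
    df.to_csv(path, sep=dialect.sep, index=False)


def records_to_frame(records: Iterable[CatchRecord]) -> pd.DataFrame:
    """Flatten records into the canonical catch-table DataFrame."""
    return pd.DataFrame(
        [
            {
                "site": r.site_id,
                "season": r.season.value,
                "species": r.species,
                "length_cm": r.body_length,
                "weight_g": r.body_weight,
            }
            for r in records
        ],
        columns=list(CATCH_COLUMNS),
    )


def read_species_table(
    path: str | Path, dialect: TableDialect | None = None
) -> dict[str, SpeciesAttributes]:
    """Read the species attribute table, keyed by (case-sensitive) species id."""
    dialect = dialect or TableDialect()
    df = _read_table(path, dialect, SPECIES_COLUMNS[:-1])  # protection optional
    out: dict[str, SpeciesAttributes] = {}
    for row in df.itertuples(index=False):
        protection = getattr(row, "protection", None)
        if pd.isna(protection):
            protection = None
        attr = SpeciesAttributes(
            species=str(row.species),
            order=str(row.order),
            family=str(row.family),
            ecotype=Ecotype(str(row.ecotype)),
            origin=Origin(str(row.origin)),
            protection=protection,
        )
        if attr.species in out:
            raise TableValidationError(
                f"{path}: duplicate attribute row for species {attr.species!r}"
            )
        out[attr.species] = attr
    return out


def read_environment_table(
    path: str | Path, dialect: TableDialect | None = None
) -> dict[str, SiteEnvironment]:
    """Read the per-site environment table, keyed by site id."""
    dialect = dialect or TableDialect()
    df = _read_table(path, dialect, SITE_COLUMNS)
    out: dict[str, SiteEnvironment] = {}
    for row in df.itertuples(index=False):
        env = SiteEnvironment(
            site_id=str(row.site),
            lat=float(row.lat),
            lon=float(row.lon),
            altitude=float(row.altitude_m),
            T=float(row.T),
            DO=float(row.DO),
            V=float(row.V),
            pH=float(row.pH),
            TDS=float(row.TDS),
            TP=float(row.TP),
            TN=float(row.TN),
            CHL=float(row.CHL),
            NH3N=float(row.NH3N),
            PO4=float(row.PO4),
            EC=(float(row.EC) if "EC" in df.columns and pd.notna(row.EC) else None),
        )
        out[env.site_id] = env
    return out


_GROUP_FIELDS = {"site": "site_id", "season": "season", "all": None}


def _group_key(record: CatchRecord, group_by: Sequence[str]) -> tuple:
    key = []
    for g in group_by:
        if g == "site":
            key.append(record.site_id)
        elif g == "season":
            key.append(record.season.value)
        elif g == "all":
            key.append("all")
        else:
            raise ConfigurationError(f"unknown grouping field {g!r}")
    return tuple(key)


def summarize_community(
    records: Sequence[CatchRecord],
    group_by: Sequence[str] = ("all",),
    attributes: dict[str, SpeciesAttributes] | None = None,
) -> dict[tuple, CommunitySummary]:
    """Aggregate individual fish into per-group community summaries.

    ``group_by`` is a subset of ``{"site", "season", "all"}``; abundance is
    the record count per species and biomass the summed body weight.  If an
    attribute table is supplied, every species in the records must appear
    in it.
    """
    if not records:
        raise EmptyCommunityError("no catch records to summarize")
    if attributes is not None:
        unknown = sorted({r.species for r in records} - set(attributes))
        if unknown:
            raise MissingAttributesError(unknown)
    groups: dict[tuple, dict[str, list[float]]] = {}
    for rec in records:
        key = _group_key(rec, group_by)
        groups.setdefault(key, {}).setdefault(rec.species, []).append(rec.body_weight)
    out: dict[tuple, CommunitySummary] = {}
    for key in sorted(groups):
        per_species = groups[key]
        out[key] = CommunitySummary(
            group=key,
            abundance={sp: len(ws) for sp, ws in sorted(per_species.items())},
            biomass={sp: float(sum(ws)) for sp, ws in sorted(per_species.items())},
        )
    return out


def composition_tally(
    attributes: dict[str, SpeciesAttributes],
    records: Sequence[CatchRecord] | None = None,
) -> pd.DataFrame:
    """Tally species counts and shares by order, family, ecotype and origin.

    Percentages are of distinct *species*, not individuals, matching how
    faunal composition is conventionally reported.  If ``records`` is
    given, the tally is restricted to the species actually caught and any
    species lacking an attribute row raises an error.

    Returns a DataFrame with columns ``level, group, n_species, pct``;
    within each level the counts sum to S and the percentages to 100.
    """
    if records is not None:
        caught = {r.species for r in records}
        unknown = sorted(caught - set(attributes))
        if unknown:
            raise MissingAttributesError(unknown)
        attrs = [attributes[sp] for sp in sorted(caught)]
    else:
        attrs = list(attributes.values())
    if not attrs:
        raise EmptyCommunityError("no species to tally")
    S = len(attrs)
    rows = []
    for level, getter in (
        ("order", lambda a: a.order),
        ("family", lambda a: a.family),
        ("ecotype", lambda a: a.ecotype.value),
        ("origin", lambda a: a.origin.value),
    ):
        counts: dict[str, int] = {}
        for a in attrs:
            counts[getter(a)] = counts.get(getter(a), 0) + 1
        for grp in sorted(counts, key=lambda g: (-counts[g], g)):
            rows.append(
                {
                    "level": level,
                    "group": grp,
                    "n_species": counts[grp],
                    "pct": 100.0 * counts[grp] / S,
                }
            )
    return pd.DataFrame(rows, columns=["level", "group", "n_species", "pct"])
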