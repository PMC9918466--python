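"""Reading, validating, and writing the site table and country-area table.

The site table is a chronosequence of mangrove restoration sites: one row per
site with the restoration pathway (reforestation re-establishes mangroves where
they previously grew; afforestation establishes them on tidal flats or other
sites never occupied by mangroves; control rows are the unrestored paired
baselines of the space-for-time design), stand age, and carbon-pool densities
in Mg C ha^-1 (AGC aboveground biomass carbon, BGC belowground, SCS sediment
carbon to 1 m, TECS their sum).

The country-area table holds mangrove area lost per country / exclusive
economic zone over 1996-2016, broken down by loss driver.

All densities are Mg C ha^-1 and all areas hectares; the parsers never rescale
units. Missing values are empty cells, never sentinel numbers. Unknown extra
columns are carried through untouched (schema version "1").
"""

from __future__ import annotations

import csv
import re
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd
from pydantic import BaseModel, Field, field_validator, model_validator

SCHEMA_VERSION = "1"

#: columns the site schema understands; anything else is carried in ``extra``
SITE_COLUMNS = [
    "site_id", "longitude", "latitude", "region", "pathway", "age_years",
    "species", "prior_land_use", "agc", "bgc", "scs", "tecs",
    "map_mm", "mat_c", "salinity_psu", "toc_pct", "tn_pct", "source_id",
]
SITE_REQUIRED = ["site_id", "pathway", "age_years"]

DRIVERS = ["erosion", "settlement", "commodities", "clearing",
           "extreme_climate", "unknown"]

#: absolute / relative tolerance declared for the TECS = AGC+BGC+SCS check
TECS_ABS_TOL = 0.5
TECS_REL_TOL = 0.01

_INTERVAL_RE = re.compile(r"^\s*\d+(\.\d+)?\s*[-–~]\s*\d+(\.\d+)?\s*$")


class SchemaError(ValueError):
    """The file-level header or structure does not match the schema."""


class RowError(ValueError):
    """A single row violates an invariant; carries the 1-based data row number."""

    def __init__(self, row: int, message: str):
        self.row = row
        super().__init__(f"row {row}: {message}")


class Pathway(str, Enum):
    reforestation = "reforestation"
    afforestation = "afforestation"
    control = "control"


class SedimentLayer(BaseModel):
    """One measured depth interval of a sediment core."""

    top_cm: float = Field(ge=0)
    bottom_cm: float = Field(gt=0)
    soc_pct: float = Field(ge=0, le=100)
    bd_g_cm3: float = Field(gt=0)

    @model_validator(mode="after")
    def _ordered(self) -> "SedimentLayer":
        if self.bottom_cm <= self.top_cm:
            raise ValueError(f"layer bottom {self.bottom_cm} cm must exceed top {self.top_cm} cm")
        return self


class SedimentProfile(BaseModel):
    """Ordered, contiguous depth layers starting at the sediment surface (0 cm)."""

    layers: list[SedimentLayer]

    @model_validator(mode="after")
    def _contiguous(self) -> "SedimentProfile":
        if not self.layers:
            raise ValueError("profile has no layers")
        if self.layers[0].top_cm != 0:
            raise ValueError("profile must start at 0 cm")
        for upper, lower in zip(self.layers, self.layers[1:]):
            if lower.top_cm != upper.bottom_cm:
                raise ValueError(
                    f"layers not contiguous: {upper.bottom_cm} cm then {lower.top_cm} cm"
                )
        return self

    @property
    def bottom_cm(self) -> float:
        return self.layers[-1].bottom_cm


class SiteRecord(BaseModel):
    """One restoration (or paired control) site of the chronosequence."""

    site_id: str
    longitude: Optional[float] = Field(default=None, ge=-180, le=180)
    latitude: Optional[float] = Field(default=None, ge=-90, le=90)
    region: str = ""
    pathway: Pathway
    age_years: float = Field(ge=0)
    species: list[str] = Field(default_factory=list)
    prior_land_use: str = ""
    agc: Optional[float] = Field(default=None, ge=0)
    bgc: Optional[float] = Field(default=None, ge=0)
    scs: Optional[float] = Field(default=None, ge=0)
    tecs: Optional[float] = Field(default=None, ge=0)
    profile: Optional[SedimentProfile] = None
    map_mm: Optional[float] = None
    mat_c: Optional[float] = None
    salinity_psu: Optional[float] = None
    toc_pct: Optional[float] = None
    tn_pct: Optional[float] = None
    source_id: str = ""
    extra: dict[str, str] = Field(default_factory=dict)

    @field_validator("species", mode="before")
    @classmethod
    def _split_species(cls, v):
        if isinstance(v, str):
            return [s.strip() for s in v.split(";") if s.strip()]
        return v

    @model_validator(mode="after")
    def _tecs_consistent(self) -> "SiteRecord":
        if None not in (self.agc, self.bgc, self.scs, self.tecs):
            total = self.agc + self.bgc + self.scs
            tol = max(TECS_ABS_TOL, TECS_REL_TOL * total)
            if abs(self.tecs - total) > tol:
                raise ValueError(
                    f"tecs {self.tecs} inconsistent with agc+bgc+scs = {total:.3f} "
                    f"(tolerance {tol:.3f} Mg C ha^-1)"
                )
        return self


class CountryAreaRecord(BaseModel):
    """Mangrove loss area (ha) per country/EEZ by driver, 1996-2016."""

    country: str
    eez_id: str
    zone: str = ""
    loss_ha_by_driver: dict[str, float]
    period: tuple[int, int] = (1996, 2016)

    @model_validator(mode="after")
    def _check_drivers(self) -> "CountryAreaRecord":
        unknown_keys = set(self.loss_ha_by_driver) - set(DRIVERS)
        if unknown_keys:
            raise ValueError(f"unknown loss drivers: {sorted(unknown_keys)}")
        for d, v in self.loss_ha_by_driver.items():
            if v < 0:
                raise ValueError(f"negative area for driver {d}: {v} ha")
        return self

    @property
    def total_loss_ha(self) -> float:
        return sum(self.loss_ha_by_driver.values())


@dataclass
class RowDiagnostic:
    row: int
    message: str


@dataclass
class ReadResult:
    """Validated records plus row-level diagnostics for rejected rows."""

    records: list[SiteRecord]
    diagnostics: list[RowDiagnostic] = field(default_factory=list)

    def __iter__(self):
        return iter(self.records)

    def __len__(self):
        return len(self.records)


def _parse_float(raw: str, column: str):
    raw = (raw or "").strip()
    if raw == "":
        return None
    if _INTERVAL_RE.match(raw):
        # age intervals such as "10-25" are ambiguous and excluded outright
        raise ValueError(f"{column} given as interval '{raw}'; interval ages are rejected")
    try:
        return float(raw)
    except ValueError:
        raise ValueError(f"non-numeric value '{raw}' in column {column}") from None


def read_sites(
    path: str | Path,
    schema_version: str = SCHEMA_VERSION,
    *,
    strict: bool = True,
    profiles: Optional[Mapping[str, SedimentProfile]] = None,
) -> ReadResult:
    """Read and validate the site table.

    With ``strict=True`` any invalid row aborts the whole file; with
    ``strict=False`` invalid rows are dropped and reported as diagnostics.
    ``profiles`` optionally attaches sediment profiles by site_id
    (see :func:`read_profiles`).
    """
    if schema_version != SCHEMA_VERSION:
        raise SchemaError(f"unsupported schema version {schema_version!r}")
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None:
            raise SchemaError(f"{path}: empty file, no header")
        missing = [c for c in SITE_REQUIRED if c not in reader.fieldnames]
        if missing:
            raise SchemaError(f"{path}: missing required columns {missing}")
        known = set(SITE_COLUMNS)
        records: list[SiteRecord] = []
        diagnostics: list[RowDiagnostic] = []
        for i, row in enumerate(reader, start=1):
            try:
                records.append(_row_to_site(row, known, profiles))
            except Exception as exc:  # noqa: BLE001 - row-scoped validation
                msg = _first_error(exc)
                if strict:
                    raise RowError(i, msg) from exc
                diagnostics.append(RowDiagnostic(i, msg))
    return ReadResult(records, diagnostics)


def _first_error(exc: Exception) -> str:
    try:
        from pydantic import ValidationError

        if isinstance(exc, ValidationError):
            err = exc.errors()[0]
            loc = ".".join(str(p) for p in err["loc"]) or "record"
            return f"{loc}: {err['msg']}"
    except Exception:  # pragma: no cover - defensive
        pass
    return str(exc)


_NUMERIC_SITE_FIELDS = ["longitude", "latitude", "age_years", "agc", "bgc", "scs",
                        "tecs", "map_mm", "mat_c", "salinity_psu", "toc_pct", "tn_pct"]


def _row_to_site(row: Mapping[str, str], known: set[str],
                 profiles: Optional[Mapping[str, SedimentProfile]]) -> SiteRecord:
    data: dict = {}
    extra: dict[str, str] = {}
    for col, raw in row.items():
        if col is None:
            continue
        if col in known:
            data[col] = raw
        elif raw not in (None, ""):
            extra[col] = raw
    for col in _NUMERIC_SITE_FIELDS:
        if col in data:
            data[col] = _parse_float(data[col], col)
    for col in ("site_id", "region", "pathway", "prior_land_use", "source_id", "species"):
        if data.get(col) is None:
            data.pop(col, None)
    data["extra"] = extra
    if profiles is not None and data.get("site_id") in profiles:
        data["profile"] = profiles[data["site_id"]]
    return SiteRecord(**data)


def read_profiles(path: str | Path) -> dict[str, SedimentProfile]:
    """Read sediment profiles from a long-format CSV.

    Columns: ``site_id, top_cm, bottom_cm, soc_pct, bd_g_cm3``; layers of one
    site must appear in depth order.
    """
    df = pd.read_csv(path)
    required = {"site_id", "top_cm", "bottom_cm", "soc_pct", "bd_g_cm3"}
    missing = required - set(df.columns)
    if missing:
        raise SchemaError(f"{path}: missing profile columns {sorted(missing)}")
    out: dict[str, SedimentProfile] = {}
    for site_id, grp in df.groupby("site_id", sort=False):
        layers = [
            SedimentLayer(top_cm=r.top_cm, bottom_cm=r.bottom_cm,
                          soc_pct=r.soc_pct, bd_g_cm3=r.bd_g_cm3)
            for r in grp.itertuples()
        ]
        out[str(site_id)] = SedimentProfile(layers=layers)
    return out


def read_country_areas(path: str | Path) -> list[CountryAreaRecord]:
    """Read the country/EEZ loss table; one column per loss driver, areas in ha."""
    path = Path(path)
    df = pd.read_csv(path)
    for col in ("country", "eez_id"):
        if col not in df.columns:
            raise SchemaError(f"{path}: missing required column {col!r}")
    present_drivers = [d for d in DRIVERS if d in df.columns]
    if not present_drivers:
        raise SchemaError(f"{path}: no loss-driver columns found (expected among {DRIVERS})")
    dup = df.duplicated(subset=["country", "eez_id"])
    if dup.any():
        first = df[dup].iloc[0]
        raise SchemaError(
            f"{path}: duplicate (country, eez_id) = ({first['country']}, {first['eez_id']})"
        )
    records = []
    for i, row in enumerate(df.itertuples(index=False), start=1):
        row = row._asdict()
        loss = {}
        for d in present_drivers:
            v = row[d]
            v = 0.0 if pd.isna(v) else float(v)
            if v < 0:
                raise RowError(i, f"negative area for driver {d}: {v} ha")
            loss[d] = v
        records.append(
            CountryAreaRecord(
                country=str(row["country"]),
                eez_id=str(row["eez_id"]),
                zone=str(row.get("zone", "") or ""),
                loss_ha_by_driver=loss,
            )
        )
    return records


#: CSV float precision declared for write_results round-trips (Tg CO2-eq)
RESULT_DECIMALS = 6

RESULT_COLUMNS = ["scope", "country", "scenario", "pathway", "area_ha",
                  "agc_tg", "bgc_tg", "scs_tg", "total_tg", "ci_lo_tg", "ci_hi_tg"]


def write_results(results: Sequence, path: str | Path) -> None:
    """Write sequestration results as CSV (Tg CO2-eq, 6-decimal precision)."""
    results = list(results)
    if not results:
        raise ValueError("no results to write")
    rows = []
    for r in results:
        rows.append({
            "scope": r.scope,
            "country": r.country,
            "scenario": r.scenario,
            "pathway": r.pathway,
            "area_ha": r.area_ha,
            "agc_tg": r.per_pool.get("agc"),
            "bgc_tg": r.per_pool.get("bgc"),
            "scs_tg": r.per_pool.get("scs"),
            "total_tg": r.total_tg,
            "ci_lo_tg": r.ci_lo_tg,
            "ci_hi_tg": r.ci_hi_tg,
        })
    pd.DataFrame(rows, columns=RESULT_COLUMNS).to_csv(
        path, index=False, float_format=f"%.{RESULT_DECIMALS}f"
    )


def read_results(path: str | Path) -> pd.DataFrame:
    """Read back a results CSV written by :func:`write_results`."""
    return pd.read_csv(path)


def sites_to_frame(records: Iterable[SiteRecord]) -> pd.DataFrame:
    """Flatten site records to a DataFrame (profiles and extras dropped)."""
    rows = []
    for r in records:
        d = r.model_dump(exclude={"profile", "extra"})
        d["pathway"] = r.pathway.value
        d["species"] = ";".join(r.species)
        rows.append(d)
    return pd.DataFrame(rows)


def write_sites(records: Iterable[SiteRecord], path: str | Path) -> None:
    """Write site records in the same CSV schema :func:`read_sites` reads."""
    df = sites_to_frame(records)
    df = df[[c for c in SITE_COLUMNS if c in df.columns]]
    df.to_csv(path, index=False)
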