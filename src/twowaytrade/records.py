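"""Trade record data model, table readers and taxon/country normalization.

A trade table is a long-format CSV, one row per directed flow:

    year, exporter_iso3, importer_iso3, taxon_name, taxon_rank (optional),
    production_method, is_reexport, tonnes

Countries are identified by ISO 3166-1 alpha-3 codes; harmonizing country
names to codes is the caller's responsibility (a helper mapping is shipped
in :data:`COUNTRY_NAME_TO_ISO3` for convenience only).
"""

from __future__ import annotations

import math
import re
from collections import Counter
from dataclasses import dataclass, field, replace
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd

from twowaytrade.errors import ValidationError


class TaxonRank(str, Enum):
    SPECIES = "species"
    HIGHER = "higher"


class ProductionMethod(str, Enum):
    CAPTURE = "capture"
    AQUACULTURE = "aquaculture"
    UNKNOWN = "unknown"


class IUCNCategory(str, Enum):
    LC = "LC"
    NT = "NT"
    VU = "VU"
    EN = "EN"
    CR = "CR"
    DD = "DD"
    NA = "NA"


TRADE_COLUMNS = (
    "year",
    "exporter_iso3",
    "importer_iso3",
    "taxon_name",
    "production_method",
    "is_reexport",
    "tonnes",
)

#: Optional column; when present it overrides the binomial/whitelist rule.
TAXON_RANK_COLUMN = "taxon_rank"

REGION_COLUMNS = ("country_iso3", "continent", "subregion")
IUCN_COLUMNS = ("taxon_name", "iucn_category")

# Small convenience mapping for common country names; not a harmonizer.
COUNTRY_NAME_TO_ISO3: Mapping[str, str] = {
    "canada": "CAN",
    "united states": "USA",
    "united states of america": "USA",
    "germany": "DEU",
    "netherlands": "NLD",
    "denmark": "DNK",
    "sweden": "SWE",
    "spain": "ESP",
    "united kingdom": "GBR",
    "france": "FRA",
    "norway": "NOR",
    "belgium": "BEL",
    "finland": "FIN",
    "slovenia": "SVN",
    "portugal": "PRT",
    "ecuador": "ECU",
    "colombia": "COL",
    "china": "CHN",
    "russia": "RUS",
    "japan": "JPN",
    "thailand": "THA",
    "australia": "AUS",
}

_BINOMIAL_RE = re.compile(r"^[A-Z][a-z]+ [a-z]+$")
_TRUE_STRINGS = {"true", "t", "yes", "y", "1"}
_FALSE_STRINGS = {"false", "f", "no", "n", "0", ""}


@dataclass(frozen=True)
class TradeRecord:
    """One directed annual flow: exporter -> importer, taxon, tonnes."""

    year: int
    exporter: str
    importer: str
    taxon_name: str
    taxon_rank: TaxonRank
    production_method: ProductionMethod
    is_reexport: bool
    tonnes: float

    def __post_init__(self) -> None:
        if not math.isfinite(self.tonnes) or self.tonnes < 0:
            raise ValidationError(f"tonnes must be finite and >= 0, got {self.tonnes!r}")
        if self.exporter == self.importer:
            raise ValidationError(f"exporter equals importer: {self.exporter!r}")

    @property
    def key(self) -> tuple:
        """Deduplication key: everything but the volume."""
        return (
            self.year,
            self.exporter,
            self.importer,
            self.taxon_name,
            self.taxon_rank,
            self.production_method,
            self.is_reexport,
        )


@dataclass(frozen=True)
class RegionMap:
    """country code -> (continent, subregion) lookup."""

    continent: Mapping[str, str]
    subregion: Mapping[str, str]

    def __contains__(self, country: str) -> bool:
        return country in self.continent


@dataclass(frozen=True)
class IUCNTable:
    """Normalized taxon name -> Red List category lookup."""

    category: Mapping[str, IUCNCategory]

    def get(self, taxon_name: str) -> IUCNCategory:
        return self.category.get(taxon_name, IUCNCategory.NA)


@dataclass
class ValidationReport:
    """What happened while reading a trade table."""

    rows_in: int = 0
    rows_out: int = 0
    rejections: Counter = field(default_factory=Counter)
    duplicates_merged: int = 0
    zero_volume_rows: int = 0

    @property
    def rows_rejected(self) -> int:
        return sum(self.rejections.values())

    def as_dict(self) -> dict:
        return {
            "rows_in": self.rows_in,
            "rows_out": self.rows_out,
            "rows_rejected": self.rows_rejected,
            "rejections": dict(self.rejections),
            "duplicates_merged": self.duplicates_merged,
            "zero_volume_rows": self.zero_volume_rows,
        }


def normalize_taxon(
    raw_name: str, species_whitelist: Optional[Iterable[str]] = None
) -> tuple[str, TaxonRank]:
    """Normalize a taxon label and classify it as species-level or higher.

    Whitespace is trimmed and collapsed.  A two-token all-alphabetic name is
    treated as a binomial and canonicalized to ``Genus species`` casing and
    classified ``species``; anything else is classified ``higher``, unless
    the normalized name appears in *species_whitelist*.  Single-token names
    are capitalized (``ELASMOBRANCHII`` -> ``Elasmobranchii``); multi-token
    non-binomial names are lowercased.

    Idempotent: applying it twice gives the same result as once.
    """
    if raw_name is None:
        raise ValidationError("taxon name is missing")
    collapsed = " ".join(str(raw_name).split())
    if not collapsed:
        raise ValidationError("taxon name is empty")

    tokens = collapsed.split(" ")
    if len(tokens) == 2 and all(t.isalpha() for t in tokens):
        name = tokens[0].capitalize() + " " + tokens[1].lower()
        rank = TaxonRank.SPECIES
    elif len(tokens) == 1 and tokens[0].isalpha():
        name = tokens[0].capitalize()
        rank = TaxonRank.HIGHER
    else:
        name = collapsed.lower()
        rank = TaxonRank.HIGHER

    if species_whitelist is not None:
        whitelist = set(species_whitelist)
        if name in whitelist or collapsed in whitelist:
            rank = TaxonRank.SPECIES
    return name, rank


def _parse_bool(value) -> bool:
    if isinstance(value, bool):
        return value
    if isinstance(value, (int, float)) and not isinstance(value, bool):
        if value in (0, 1):
            return bool(value)
        raise ValidationError(f"cannot interpret {value!r} as a boolean")
    text = str(value).strip().lower()
    if text in _TRUE_STRINGS:
        return True
    if text in _FALSE_STRINGS:
        return False
    raise ValidationError(f"cannot interpret {value!r} as a boolean")


def _parse_method(value) -> ProductionMethod:
    text = str(value).strip().lower() if value is not None else ""
    if text in ("capture", "wild", "wild_capture", "wild-capture"):
        return ProductionMethod.CAPTURE
    if text in ("aquaculture", "farmed"):
        return ProductionMethod.AQUACULTURE
    return ProductionMethod.UNKNOWN


def read_trade_table(
    path: str | Path,
    species_whitelist: Optional[Iterable[str]] = None,
) -> tuple[list[TradeRecord], ValidationReport]:
    """Read and validate a trade CSV.

    Rows violating hard invariants (negative or non-finite tonnes, exporter
    equal to importer, unparseable year, empty taxon) are rejected and
    counted in the report by reason.  Rows sharing the full key (year,
    exporter, importer, taxon, method, re-export flag) are merged by summing
    tonnes.  Zero-tonne rows are retained but counted.

    Raises
    ------
    ValidationError
        If the file is empty or a required column is missing.
    """
    path = Path(path)
    try:
        frame = pd.read_csv(path, dtype=str, keep_default_na=False)
    except pd.errors.EmptyDataError:
        raise ValidationError(f"trade table {path} is empty") from None
    missing = [c for c in TRADE_COLUMNS if c not in frame.columns]
    if missing:
        raise ValidationError(f"trade table {path} is missing required column(s): {', '.join(missing)}")
    if frame.empty:
        raise ValidationError(f"trade table {path} has a header but no rows")

    whitelist = set(species_whitelist) if species_whitelist is not None else None
    has_rank = TAXON_RANK_COLUMN in frame.columns

    report = ValidationReport(rows_in=len(frame))
    merged: dict[tuple, TradeRecord] = {}

    for row in frame.itertuples(index=False):
        try:
            year = int(str(row.year).strip())
        except (TypeError, ValueError):
            report.rejections["bad_year"] += 1
            continue
        try:
            tonnes = float(str(row.tonnes).strip())
        except (TypeError, ValueError):
            report.rejections["bad_volume"] += 1
            continue
        if not math.isfinite(tonnes):
            report.rejections["bad_volume"] += 1
            continue
        if tonnes < 0:
            report.rejections["negative_volume"] += 1
            continue
        exporter = str(row.exporter_iso3).strip().upper()
        importer = str(row.importer_iso3).strip().upper()
        if not exporter or not importer:
            report.rejections["missing_country"] += 1
            continue
        if exporter == importer:
            report.rejections["self_trade"] += 1
            continue
        try:
            taxon_name, rank = normalize_taxon(row.taxon_name, whitelist)
        except ValidationError:
            report.rejections["empty_taxon"] += 1
            continue
        if has_rank:
            explicit = str(getattr(row, TAXON_RANK_COLUMN)).strip().lower()
            if explicit in (TaxonRank.SPECIES.value, TaxonRank.HIGHER.value):
                rank = TaxonRank(explicit)
        try:
            is_reexport = _parse_bool(row.is_reexport)
        except ValidationError:
            report.rejections["bad_reexport_flag"] += 1
            continue
        method = _parse_method(row.production_method)

        if tonnes == 0:
            report.zero_volume_rows += 1

        record = TradeRecord(
            year=year,
            exporter=exporter,
            importer=importer,
            taxon_name=taxon_name,
            taxon_rank=rank,
            production_method=method,
            is_reexport=is_reexport,
            tonnes=tonnes,
        )
        if record.key in merged:
            prev = merged[record.key]
            merged[record.key] = replace(prev, tonnes=prev.tonnes + tonnes)
            report.duplicates_merged += 1
        else:
            merged[record.key] = record

    records = list(merged.values())
    report.rows_out = len(records)
    return records, report


def records_to_frame(records: Sequence[TradeRecord]) -> pd.DataFrame:
    """Convert records to a DataFrame with the canonical column layout."""
    return pd.DataFrame(
        {
            "year": [r.year for r in records],
            "exporter_iso3": [r.exporter for r in records],
            "importer_iso3": [r.importer for r in records],
            "taxon_name": [r.taxon_name for r in records],
            "taxon_rank": [r.taxon_rank.value for r in records],
            "production_method": [r.production_method.value for r in records],
            "is_reexport": [r.is_reexport for r in records],
            "tonnes": [r.tonnes for r in records],
        }
    )


def write_trade_table(records: Sequence[TradeRecord], path: str | Path) -> None:
    """Write records back to CSV in the canonical input schema."""
    records_to_frame(records).to_csv(path, index=False)


def read_region_map(path: str | Path) -> RegionMap:
    """Read a country -> continent/subregion lookup CSV."""
    frame = _read_lookup(path, REGION_COLUMNS)
    continent: dict[str, str] = {}
    subregion: dict[str, str] = {}
    for row in frame.itertuples(index=False):
        code = str(row.country_iso3).strip().upper()
        cont = str(row.continent).strip()
        sub = str(row.subregion).strip()
        if not code or not cont or not sub:
            raise ValidationError(f"region map {path}: empty field in row for {code!r}")
        if code in continent:
            raise ValidationError(f"region map {path}: duplicate country {code}")
        continent[code] = cont
        subregion[code] = sub
    return RegionMap(continent=continent, subregion=subregion)


def read_iucn_table(path: str | Path) -> IUCNTable:
    """Read a taxon -> IUCN Red List category lookup CSV."""
    frame = _read_lookup(path, IUCN_COLUMNS)
    category: dict[str, IUCNCategory] = {}
    for row in frame.itertuples(index=False):
        name, _ = normalize_taxon(row.taxon_name)
        cat_text = str(row.iucn_category).strip().upper()
        try:
            cat = IUCNCategory(cat_text)
        except ValueError:
            raise ValidationError(
                f"IUCN table {path}: unknown category {cat_text!r} for {name!r}"
            ) from None
        if name in category:
            raise ValidationError(f"IUCN table {path}: duplicate taxon {name!r}")
        category[name] = cat
    return IUCNTable(category=category)


def _read_lookup(path: str | Path, columns: tuple[str, ...]) -> pd.DataFrame:
    path = Path(path)
    try:
        frame = pd.read_csv(path, dtype=str, keep_default_na=False)
    except pd.errors.EmptyDataError:
        raise ValidationError(f"lookup table {path} is empty") from None
    missing = [c for c in columns if c not in frame.columns]
    if missing:
        raise ValidationError(f"lookup table {path} is missing column(s): {', '.join(missing)}")
    return frame
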