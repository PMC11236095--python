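"""Exclusion rules: keep wild-capture, non-re-export, species-level records.

Rows failing more than one rule are attributed to the first matching
bucket, in the order aquaculture -> unknown method -> re-export ->
non-species.  The retained set does not depend on this order (the rules
are independent predicates); only the per-bucket attribution does.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import pandas as pd

from twowaytrade.errors import UndefinedMetricError
from twowaytrade.records import ProductionMethod, TaxonRank, TradeRecord

_BUCKETS = ("total", "aquaculture", "unknown_method", "reexport", "non_species", "retained")


@dataclass
class FilterReport:
    """Tonnage accounting for the exclusion funnel, overall and per year.

    Every input tonne lands in exactly one of the four exclusion buckets or
    in ``retained``; ``total`` is their sum.
    """

    total_tonnes: float = 0.0
    aquaculture_tonnes: float = 0.0
    unknown_method_tonnes: float = 0.0
    reexport_tonnes: float = 0.0
    non_species_tonnes: float = 0.0
    retained_tonnes: float = 0.0
    per_year: dict[int, dict[str, float]] = field(default_factory=dict)

    def _year_bucket(self, year: int) -> dict[str, float]:
        if year not in self.per_year:
            self.per_year[year] = {b: 0.0 for b in _BUCKETS}
        return self.per_year[year]

    def as_frame(self) -> pd.DataFrame:
        """One row per year plus a 'total' row, columns = buckets."""
        rows = []
        for year in sorted(self.per_year):
            rows.append({"year": year, **self.per_year[year]})
        rows.append(
            {
                "year": "total",
                "total": self.total_tonnes,
                "aquaculture": self.aquaculture_tonnes,
                "unknown_method": self.unknown_method_tonnes,
                "reexport": self.reexport_tonnes,
                "non_species": self.non_species_tonnes,
                "retained": self.retained_tonnes,
            }
        )
        return pd.DataFrame(rows, columns=["year", *_BUCKETS])

    def as_dict(self) -> dict:
        return {
            "total_tonnes": self.total_tonnes,
            "aquaculture_tonnes": self.aquaculture_tonnes,
            "unknown_method_tonnes": self.unknown_method_tonnes,
            "reexport_tonnes": self.reexport_tonnes,
            "non_species_tonnes": self.non_species_tonnes,
            "retained_tonnes": self.retained_tonnes,
            "per_year": {str(y): dict(v) for y, v in sorted(self.per_year.items())},
        }


def _bucket_for(record: TradeRecord) -> str:
    if record.production_method is ProductionMethod.AQUACULTURE:
        return "aquaculture"
    if record.production_method is ProductionMethod.UNKNOWN:
        return "unknown_method"
    if record.is_reexport:
        return "reexport"
    if record.taxon_rank is not TaxonRank.SPECIES:
        return "non_species"
    return "retained"


def apply_filters(records: Sequence[TradeRecord]) -> tuple[list[TradeRecord], FilterReport]:
    """Apply the three exclusion rules and account for every tonne.

    Returns the retained records (wild-capture, non-re-export,
    species-level) and a :class:`FilterReport`.  Empty input yields an empty
    output and a zeroed report.  Idempotent on its own output.
    """
    retained: list[TradeRecord] = []
    report = FilterReport()
    for record in records:
        bucket = _bucket_for(record)
        report.total_tonnes += record.tonnes
        yb = report._year_bucket(record.year)
        yb["total"] += record.tonnes
        yb[bucket] += record.tonnes
        if bucket == "retained":
            report.retained_tonnes += record.tonnes
            retained.append(record)
        elif bucket == "aquaculture":
            report.aquaculture_tonnes += record.tonnes
        elif bucket == "unknown_method":
            report.unknown_method_tonnes += record.tonnes
        elif bucket == "reexport":
            report.reexport_tonnes += record.tonnes
        else:
            report.non_species_tonnes += record.tonnes
    return retained, report


def species_level_fraction(report: FilterReport, year: Optional[int] = None) -> float:
    """Fraction of total tonnage that survives the funnel to species level.

    The numerator is the retained tonnage (species-level, assessed after
    the aquaculture / unknown-method / re-export exclusions); the
    denominator is the total tonnage for the scope.

    Raises
    ------
    UndefinedMetricError
        If the scoped total is zero or the year is absent from the report.
    """
    if year is None:
        total = report.total_tonnes
        retained = report.retained_tonnes
    else:
        if year not in report.per_year:
            raise UndefinedMetricError(f"no records for year {year}")
        total = report.per_year[year]["total"]
        retained = report.per_year[year]["retained"]
    if total <= 0:
        raise UndefinedMetricError("species-level fraction is undefined for zero total tonnage")
    return retained / total
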