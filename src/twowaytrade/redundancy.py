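"""The matched two-way (redundant) trade statistic.

For a canonical country pair {a, b}, a species s and a year y, with
directed annual export totals x (a->b) and z (b->a), the redundant volume
is ``2 * min(x, z)`` and the avoidable export per country is ``min(x, z)``.
One-way cells contribute nothing.
"""

from __future__ import annotations

import math
from collections import defaultdict
from dataclasses import dataclass
from typing import Sequence

import pandas as pd

from twowaytrade.records import TradeRecord


def _check_volume(value: float, name: str) -> float:
    value = float(value)
    if not math.isfinite(value):
        raise ValueError(f"{name} must be finite, got {value!r}")
    if value < 0:
        raise ValueError(f"{name} must be >= 0, got {value!r}")
    return value


def pair_redundancy(export_ab: float, export_ba: float) -> float:
    """Redundant two-way volume for one pair/species/year cell.

    Twice the minimum of the two directed volumes; symmetric,
    monotone and homogeneous of degree one in its arguments.
    """
    a = _check_volume(export_ab, "export_ab")
    b = _check_volume(export_ba, "export_ba")
    return 2.0 * min(a, b)


def avoided_exports(export_ab: float, export_ba: float) -> float:
    """Export volume each of the two countries could avoid: min of the two flows."""
    a = _check_volume(export_ab, "export_ab")
    b = _check_volume(export_ba, "export_ba")
    return min(a, b)


@dataclass(frozen=True)
class RedundantFlow:
    """Matched volume for one canonical pair x species x year cell.

    ``country_a < country_b`` lexicographically; ``export_ab`` is the
    a->b directed annual total and ``export_ba`` the reverse.
    """

    year: int
    country_a: str
    country_b: str
    species: str
    export_ab: float
    export_ba: float

    def __post_init__(self) -> None:
        if self.country_a >= self.country_b:
            raise ValueError(
                f"pair must be canonical (country_a < country_b), got "
                f"{self.country_a!r} >= {self.country_b!r}"
            )

    @property
    def matched_min(self) -> float:
        return min(self.export_ab, self.export_ba)

    @property
    def redundant_tonnes(self) -> float:
        return 2.0 * self.matched_min


def compute_redundant_flows(records: Sequence[TradeRecord]) -> list[RedundantFlow]:
    """Compute all redundant flows from filtered (species-level, wild-capture,
    non-re-export) records.

    Directed volumes are summed per (exporter, importer, species, year)
    before matching; cells where either direction is zero are omitted, so
    every returned flow has ``redundant_tonnes > 0``.  Output order is
    deterministic: sorted by (year, country_a, country_b, species).
    """
    directed: dict[tuple, float] = defaultdict(float)
    for r in records:
        directed[(r.year, r.exporter, r.importer, r.taxon_name)] += r.tonnes

    flows: list[RedundantFlow] = []
    for (year, exporter, importer, species), tonnes in directed.items():
        if exporter >= importer:
            continue  # visit each unordered pair once, from its canonical side
        reverse = directed.get((year, importer, exporter, species), 0.0)
        if tonnes > 0 and reverse > 0:
            flows.append(
                RedundantFlow(
                    year=year,
                    country_a=exporter,
                    country_b=importer,
                    species=species,
                    export_ab=tonnes,
                    export_ba=reverse,
                )
            )
    flows.sort(key=lambda f: (f.year, f.country_a, f.country_b, f.species))
    return flows


def flows_to_frame(flows: Sequence[RedundantFlow]) -> pd.DataFrame:
    """Full flow table with the documented field names."""
    return pd.DataFrame(
        {
            "year": [f.year for f in flows],
            "country_a": [f.country_a for f in flows],
            "country_b": [f.country_b for f in flows],
            "species": [f.species for f in flows],
            "export_ab": [f.export_ab for f in flows],
            "export_ba": [f.export_ba for f in flows],
            "matched_min": [f.matched_min for f in flows],
            "redundant_tonnes": [f.redundant_tonnes for f in flows],
        }
    )


def flows_to_edge_list(flows: Sequence[RedundantFlow]) -> pd.DataFrame:
    """Weighted undirected edge list (pair, year, species, redundant tonnes)
    suitable for network tools."""
    return pd.DataFrame(
        {
            "country_a": [f.country_a for f in flows],
            "country_b": [f.country_b for f in flows],
            "year": [f.year for f in flows],
            "species": [f.species for f in flows],
            "redundant_tonnes": [f.redundant_tonnes for f in flows],
        }
    )
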