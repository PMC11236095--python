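"""Summaries of redundant flows: annual series, country attribution, pair
and species rankings, region overlap, top-k coverage, conservation-status
shares, and the two headline regressions.

All rankings are deterministic: ties are broken by the entity key, and
every attribution conserves tonnage — yearly, country, pair and species
totals each sum to the global redundant tonnage.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence, Union

import pandas as pd
from scipy import stats

from twowaytrade.errors import UndefinedMetricError
from twowaytrade.filtering import apply_filters
from twowaytrade.records import (
    IUCNCategory,
    IUCNTable,
    ProductionMethod,
    RegionMap,
    TaxonRank,
    TradeRecord,
)
from twowaytrade.redundancy import RedundantFlow

_SHARE_EPS = 1e-12


# ---------------------------------------------------------------------------
# Annual series


@dataclass(frozen=True)
class AnnualSummary:
    year: int
    total_tonnes: float
    species_level_tonnes: float
    redundant_tonnes: float

    @property
    def redundant_share_of_total(self) -> float:
        if self.total_tonnes <= 0:
            return 0.0
        return self.redundant_tonnes / self.total_tonnes

    @property
    def redundant_share_of_species(self) -> float:
        if self.species_level_tonnes <= 0:
            return 0.0
        return self.redundant_tonnes / self.species_level_tonnes


def annual_series(
    records: Sequence[TradeRecord], flows: Sequence[RedundantFlow]
) -> list[AnnualSummary]:
    """Per-year totals: all trade, species-level (retained) trade, and
    redundant trade.  One row per year present in *records*."""
    _, report = apply_filters(records)
    redundant_by_year: dict[int, float] = {}
    for f in flows:
        redundant_by_year[f.year] = redundant_by_year.get(f.year, 0.0) + f.redundant_tonnes
    out = []
    for year in sorted(report.per_year):
        buckets = report.per_year[year]
        out.append(
            AnnualSummary(
                year=year,
                total_tonnes=buckets["total"],
                species_level_tonnes=buckets["retained"],
                redundant_tonnes=redundant_by_year.get(year, 0.0),
            )
        )
    return out


def percent_change(
    series: Union[Mapping[int, float], Sequence[AnnualSummary]],
    year_from: int,
    year_to: int,
) -> float:
    """Signed percent change of a yearly series between two years.

    *series* is either a year -> value mapping or a list of
    :class:`AnnualSummary` (the redundant tonnage is used).
    """
    if not isinstance(series, Mapping):
        series = {s.year: s.redundant_tonnes for s in series}
    for year in (year_from, year_to):
        if year not in series:
            raise UndefinedMetricError(f"year {year} not present in series")
    v_from, v_to = series[year_from], series[year_to]
    if v_from == 0:
        raise UndefinedMetricError("percent change from a zero baseline is undefined")
    return 100.0 * (v_to - v_from) / v_from


# ---------------------------------------------------------------------------
# Country attribution


@dataclass(frozen=True)
class CountrySummary:
    """Redundant-trade attribution for one country.

    ``redundant_export_tonnes`` is the sum of matched minima over every
    flow the country participates in (its avoidable exports), so country
    totals sum to the global redundant tonnage.
    """

    country: str
    total_export_tonnes: float
    species_level_export_tonnes: float
    redundant_export_tonnes: float
    n_redundant_species: int
    total_trade_tonnes: float  # exports + imports, alternative denominator

    def redundancy_proportion(self, basis: str = "exports") -> float:
        """Share of this country's trade that is redundant.

        basis='exports' uses total exports (post aquaculture/re-export
        exclusions, pre species filter); basis='trade' uses exports +
        imports on the same footing.
        """
        denom = {"exports": self.total_export_tonnes, "trade": self.total_trade_tonnes}.get(basis)
        if denom is None:
            raise ValueError(f"unknown proportion basis {basis!r}")
        if denom <= 0:
            return 0.0
        return self.redundant_export_tonnes / denom

    @property
    def species_level_fraction(self) -> float:
        if self.total_export_tonnes <= 0:
            return float("nan")
        return self.species_level_export_tonnes / self.total_export_tonnes


def country_attribution(
    flows: Sequence[RedundantFlow], records: Sequence[TradeRecord]
) -> list[CountrySummary]:
    """Credit each country its avoidable exports (matched_min per flow).

    *records* is the validated table before filtering; export denominators
    use the aquaculture/unknown-method/re-export exclusions but not the
    species-level filter.  Sorted by redundant exports descending, ties by
    country code.
    """
    eligible = [
        r
        for r in records
        if r.production_method is ProductionMethod.CAPTURE and not r.is_reexport
    ]
    exports: dict[str, float] = {}
    imports: dict[str, float] = {}
    species_exports: dict[str, float] = {}
    for r in eligible:
        exports[r.exporter] = exports.get(r.exporter, 0.0) + r.tonnes
        imports[r.importer] = imports.get(r.importer, 0.0) + r.tonnes
        if r.taxon_rank is TaxonRank.SPECIES:
            species_exports[r.exporter] = species_exports.get(r.exporter, 0.0) + r.tonnes

    redundant: dict[str, float] = {}
    redundant_species: dict[str, set[str]] = {}
    for f in flows:
        for country in (f.country_a, f.country_b):
            redundant[country] = redundant.get(country, 0.0) + f.matched_min
            redundant_species.setdefault(country, set()).add(f.species)

    countries = sorted(set(exports) | set(imports) | set(redundant))
    for country in redundant:
        # flows are derived from records, so every flow country must export
        assert country in exports, f"country {country} in flows but not in records"

    summaries = [
        CountrySummary(
            country=c,
            total_export_tonnes=exports.get(c, 0.0),
            species_level_export_tonnes=species_exports.get(c, 0.0),
            redundant_export_tonnes=redundant.get(c, 0.0),
            n_redundant_species=len(redundant_species.get(c, ())),
            total_trade_tonnes=exports.get(c, 0.0) + imports.get(c, 0.0),
        )
        for c in countries
    ]
    summaries.sort(key=lambda s: (-s.redundant_export_tonnes, s.country))
    return summaries


# ---------------------------------------------------------------------------
# Pair ranking and region overlap


@dataclass(frozen=True)
class PairSummary:
    country_a: str
    country_b: str
    redundant_tonnes: float
    share_of_global: float
    same_continent: Optional[bool]  # None when either country lacks a region
    same_subregion: Optional[bool]


@dataclass(frozen=True)
class RegionOverlap:
    """Aggregate same-continent / same-subregion overlap among pairs,
    on a distinct-pair count basis and a tonnage basis."""

    n_pairs: int
    n_pairs_known: int
    same_continent_pairs: int
    same_subregion_pairs: int
    same_continent_pair_fraction: float
    same_subregion_pair_fraction: float
    same_continent_tonnage_fraction: float
    same_subregion_tonnage_fraction: float


def pair_ranking(
    flows: Sequence[RedundantFlow], region_map: Optional[RegionMap] = None
) -> tuple[list[PairSummary], RegionOverlap]:
    """Rank canonical country pairs by redundant tonnage.

    Pairs whose countries are missing from *region_map* get region flags of
    ``None`` and are excluded from the overlap fraction denominators (a
    warning is emitted).  Shares sum to 1 over pairs when global redundancy
    is positive.
    """
    totals: dict[tuple[str, str], float] = {}
    for f in flows:
        key = (f.country_a, f.country_b)
        totals[key] = totals.get(key, 0.0) + f.redundant_tonnes
    global_total = sum(totals.values())

    summaries: list[PairSummary] = []
    n_known = same_cont = same_sub = 0
    known_tonnes = cont_tonnes = sub_tonnes = 0.0
    n_unknown = 0
    for (a, b), tonnes in totals.items():
        if region_map is not None and a in region_map and b in region_map:
            continent_match = region_map.continent[a] == region_map.continent[b]
            subregion_match = region_map.subregion[a] == region_map.subregion[b]
            n_known += 1
            known_tonnes += tonnes
            if continent_match:
                same_cont += 1
                cont_tonnes += tonnes
            if subregion_match:
                same_sub += 1
                sub_tonnes += tonnes
        else:
            continent_match = subregion_match = None
            n_unknown += 1
        summaries.append(
            PairSummary(
                country_a=a,
                country_b=b,
                redundant_tonnes=tonnes,
                share_of_global=tonnes / global_total if global_total > 0 else 0.0,
                same_continent=continent_match,
                same_subregion=subregion_match,
            )
        )
    if n_unknown and region_map is not None:
        warnings.warn(
            f"{n_unknown} pair(s) involve countries absent from the region map; "
            "excluded from overlap fractions",
            stacklevel=2,
        )
    summaries.sort(key=lambda s: (-s.redundant_tonnes, s.country_a, s.country_b))
    overlap = RegionOverlap(
        n_pairs=len(summaries),
        n_pairs_known=n_known,
        same_continent_pairs=same_cont,
        same_subregion_pairs=same_sub,
        same_continent_pair_fraction=same_cont / n_known if n_known else 0.0,
        same_subregion_pair_fraction=same_sub / n_known if n_known else 0.0,
        same_continent_tonnage_fraction=cont_tonnes / known_tonnes if known_tonnes > 0 else 0.0,
        same_subregion_tonnage_fraction=sub_tonnes / known_tonnes if known_tonnes > 0 else 0.0,
    )
    return summaries, overlap


# ---------------------------------------------------------------------------
# Species ranking, top-k coverage, conservation-status share


@dataclass(frozen=True)
class SpeciesSummary:
    species: str
    redundant_tonnes: float
    share_of_global: float
    iucn_category: IUCNCategory
    # (country_a, country_b, tonnes, share of this species' redundancy),
    # sorted by tonnes descending, ties by pair key
    partner_pairs: tuple[tuple[str, str, float, float], ...] = field(default=())


def species_ranking(
    flows: Sequence[RedundantFlow], iucn_table: Optional[IUCNTable] = None
) -> list[SpeciesSummary]:
    """Rank species by redundant tonnage with IUCN categories joined by
    normalized name (NA when absent)."""
    totals: dict[str, float] = {}
    pair_totals: dict[str, dict[tuple[str, str], float]] = {}
    for f in flows:
        totals[f.species] = totals.get(f.species, 0.0) + f.redundant_tonnes
        by_pair = pair_totals.setdefault(f.species, {})
        key = (f.country_a, f.country_b)
        by_pair[key] = by_pair.get(key, 0.0) + f.redundant_tonnes
    global_total = sum(totals.values())

    summaries = []
    for species, tonnes in totals.items():
        pairs = sorted(
            pair_totals[species].items(), key=lambda kv: (-kv[1], kv[0])
        )
        partner_pairs = tuple(
            (a, b, t, t / tonnes if tonnes > 0 else 0.0) for (a, b), t in pairs
        )
        summaries.append(
            SpeciesSummary(
                species=species,
                redundant_tonnes=tonnes,
                share_of_global=tonnes / global_total if global_total > 0 else 0.0,
                iucn_category=iucn_table.get(species) if iucn_table else IUCNCategory.NA,
                partner_pairs=partner_pairs,
            )
        )
    summaries.sort(key=lambda s: (-s.redundant_tonnes, s.species))
    return summaries


def topk_coverage(shares: Sequence[float], threshold: float) -> tuple[int, float]:
    """Smallest k such that the top-k descending shares cover *threshold*.

    *shares* must be sorted descending and sum to 1.  Returns (k, cumulative
    share at k).  Zero shares never count toward k.
    """
    if not 0 < threshold <= 1:
        raise ValueError(f"threshold must be in (0, 1], got {threshold!r}")
    if len(shares) == 0:
        raise UndefinedMetricError("top-k coverage of an empty ranking is undefined")
    cumulative = 0.0
    for k, share in enumerate(shares, start=1):
        if share <= 0:
            break
        cumulative += share
        if cumulative >= threshold - _SHARE_EPS:
            return k, cumulative
    raise UndefinedMetricError(
        f"shares sum to {cumulative:.6f} < threshold {threshold}; not a full distribution"
    )


@dataclass(frozen=True)
class ThreatenedShare:
    fraction: float  # tonnage-weighted share in categories {EN, VU}
    tonnes: float
    category_counts: Mapping[str, int]  # species counts per IUCN category


def threatened_share(summaries: Sequence[SpeciesSummary]) -> ThreatenedShare:
    """Tonnage-weighted fraction of redundant trade in EN or VU species,
    plus species counts per IUCN category."""
    total = sum(s.redundant_tonnes for s in summaries)
    threatened = sum(
        s.redundant_tonnes
        for s in summaries
        if s.iucn_category in (IUCNCategory.EN, IUCNCategory.VU)
    )
    counts: dict[str, int] = {}
    for s in summaries:
        counts[s.iucn_category.value] = counts.get(s.iucn_category.value, 0) + 1
    return ThreatenedShare(
        fraction=threatened / total if total > 0 else 0.0,
        tonnes=threatened,
        category_counts=counts,
    )


# ---------------------------------------------------------------------------
# Regressions


@dataclass(frozen=True)
class RegressionResult:
    slope: float
    intercept: float
    r_squared: float
    p_value: float
    n: int


_REGRESSION_FIELDS = ("total_export_tonnes", "species_level_fraction")


def redundancy_regression(
    summaries: Sequence[CountrySummary],
    x_field: str = "total_export_tonnes",
) -> RegressionResult:
    """OLS of per-country redundant exports on a chosen predictor.

    Predictors: 'total_export_tonnes' or 'species_level_fraction'.
    Countries with non-finite predictor values are dropped.  Requires at
    least 3 usable countries and non-degenerate predictor variance.
    """
    if x_field not in _REGRESSION_FIELDS:
        raise ValueError(f"x_field must be one of {_REGRESSION_FIELDS}, got {x_field!r}")
    xs, ys = [], []
    for s in summaries:
        x = getattr(s, x_field)
        if x == x:  # drop NaN predictors
            xs.append(float(x))
            ys.append(s.redundant_export_tonnes)
    if len(xs) < 3:
        raise UndefinedMetricError(f"regression needs >= 3 countries, got {len(xs)}")
    if min(xs) == max(xs):
        raise UndefinedMetricError("predictor has zero variance")
    with warnings.catch_warnings():
        # constant y triggers a harmless RuntimeWarning inside linregress
        warnings.simplefilter("ignore", RuntimeWarning)
        fit = stats.linregress(xs, ys)
    p_value = fit.pvalue if fit.pvalue == fit.pvalue else 1.0
    # constant y yields a NaN correlation; the explained fraction is 0
    r_squared = fit.rvalue**2 if fit.rvalue == fit.rvalue else 0.0
    return RegressionResult(
        slope=fit.slope,
        intercept=fit.intercept,
        r_squared=r_squared,
        p_value=p_value,
        n=len(xs),
    )


# ---------------------------------------------------------------------------
# Frame exports


def annual_to_frame(series: Sequence[AnnualSummary]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "year": [s.year for s in series],
            "total_tonnes": [s.total_tonnes for s in series],
            "species_level_tonnes": [s.species_level_tonnes for s in series],
            "redundant_tonnes": [s.redundant_tonnes for s in series],
            "redundant_share_of_total": [s.redundant_share_of_total for s in series],
        }
    )


def countries_to_frame(
    summaries: Sequence[CountrySummary], proportion_basis: str = "exports"
) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "country": [s.country for s in summaries],
            "total_export_tonnes": [s.total_export_tonnes for s in summaries],
            "species_level_export_tonnes": [s.species_level_export_tonnes for s in summaries],
            "redundant_export_tonnes": [s.redundant_export_tonnes for s in summaries],
            "redundancy_proportion": [s.redundancy_proportion(proportion_basis) for s in summaries],
            "n_redundant_species": [s.n_redundant_species for s in summaries],
        }
    )


def pairs_to_frame(summaries: Sequence[PairSummary]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "country_a": [s.country_a for s in summaries],
            "country_b": [s.country_b for s in summaries],
            "redundant_tonnes": [s.redundant_tonnes for s in summaries],
            "share_of_global": [s.share_of_global for s in summaries],
            "same_continent": [s.same_continent for s in summaries],
            "same_subregion": [s.same_subregion for s in summaries],
        }
    )


def species_to_frame(summaries: Sequence[SpeciesSummary]) -> pd.DataFrame:
    top_pair = [
        f"{s.partner_pairs[0][0]}-{s.partner_pairs[0][1]}" if s.partner_pairs else ""
        for s in summaries
    ]
    return pd.DataFrame(
        {
            "species": [s.species for s in summaries],
            "redundant_tonnes": [s.redundant_tonnes for s in summaries],
            "share_of_global": [s.share_of_global for s in summaries],
            "iucn_category": [s.iucn_category.value for s in summaries],
            "top_partner_pair": top_pair,
        }
    )
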