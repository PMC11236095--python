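"""Seeded synthetic trade-network generator with exact ground truth.

Generates sparse directed species-level flows with a planted fraction of
two-way (matched) cells, plus contaminant rows (aquaculture, re-export,
coarse-taxon) injected as *additional* rows so the clean ground truth is
known exactly and serves as an oracle for the whole pipeline.

Randomness is per-cell keyed: each (year, pair, species) cell gets its own
generator seeded from (seed, year index, pair index, species index) with a
fixed draw order, so changing unrelated config fields never reshuffles a
cell's draws.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from twowaytrade.errors import ValidationError
from twowaytrade.records import IUCNCategory, IUCNTable, RegionMap

# Real fish binomials so the taxon-rank classifier is exercised realistically.
SPECIES_POOL = (
    "Clupea harengus",
    "Gadus morhua",
    "Katsuwonus pelamis",
    "Scomber scombrus",
    "Trachurus trachurus",
    "Merluccius senegalensis",
    "Apostichopus japonicus",
    "Thunnus albacares",
    "Thunnus obesus",
    "Salmo salar",
    "Engraulis ringens",
    "Sardina pilchardus",
    "Pleuronectes platessa",
    "Solea solea",
    "Melanogrammus aeglefinus",
    "Pollachius virens",
    "Micromesistius poutassou",
    "Sprattus sprattus",
    "Mallotus villosus",
    "Xiphias gladius",
    "Hippoglossus hippoglossus",
    "Reinhardtius hippoglossoides",
    "Sebastes marinus",
    "Anguilla anguilla",
    "Dicentrarchus labrax",
    "Sparus aurata",
    "Lophius piscatorius",
    "Merlangius merlangus",
    "Brosme brosme",
    "Molva molva",
)

# Coarse group labels that must be classified as higher-rank and excluded.
COARSE_LABELS = (
    "miscellaneous marine fishes",
    "elasmobranchii",
    "miscellaneous marine molluscs",
    "marine animals nei",
    "miscellaneous coastal fishes",
)

# Volumes are quantized to multiples of 2^-10 t: dyadic rationals at this
# scale sum exactly in double precision, so ground-truth comparisons can use
# exact equality regardless of summation order.
_QUANTUM = 1.0 / 1024.0


def _draw_volume(rng: np.random.Generator, config: "SyntheticConfig") -> float:
    raw = rng.lognormal(config.volume_log_mean, config.volume_log_sigma)
    return max(round(raw / _QUANTUM) * _QUANTUM, _QUANTUM)


_IUCN_WEIGHTS = {
    IUCNCategory.LC: 0.35,
    IUCNCategory.NT: 0.08,
    IUCNCategory.VU: 0.10,
    IUCNCategory.EN: 0.05,
    IUCNCategory.CR: 0.02,
    IUCNCategory.DD: 0.20,
    IUCNCategory.NA: 0.20,
}


@dataclass(frozen=True)
class SyntheticConfig:
    """Parameters of the synthetic trade network.

    ``edge_density`` is the probability that a (pair, species, year) cell
    trades at all; ``two_way_fraction`` the conditional probability that a
    trading cell trades in both directions.  Volumes are log-normal with
    the stated log-location and log-scale.  Contaminant rates are per clean
    directed row.
    """

    n_countries: int = 8
    n_species: int = 6
    year_start: int = 2000
    year_end: int = 2002
    edge_density: float = 0.3
    two_way_fraction: float = 0.3
    volume_log_mean: float = 2.0
    volume_log_sigma: float = 1.0
    aquaculture_rate: float = 0.1
    reexport_rate: float = 0.1
    coarse_taxon_rate: float = 0.1
    n_continents: int = 2
    subregions_per_continent: int = 2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_countries < 2:
            raise ValidationError("n_countries must be >= 2")
        if self.n_species < 1:
            raise ValidationError("n_species must be >= 1")
        if self.n_species > len(SPECIES_POOL):
            raise ValidationError(f"n_species must be <= {len(SPECIES_POOL)}")
        if self.year_end < self.year_start:
            raise ValidationError("year_end must be >= year_start")
        for name in ("edge_density", "two_way_fraction", "aquaculture_rate",
                     "reexport_rate", "coarse_taxon_rate"):
            value = getattr(self, name)
            if not 0.0 <= value <= 1.0:
                raise ValidationError(f"{name} must be in [0, 1], got {value!r}")
        if self.volume_log_sigma <= 0:
            raise ValidationError("volume_log_sigma must be > 0")
        if self.n_continents < 1:
            raise ValidationError("n_continents must be >= 1")
        if self.subregions_per_continent < 1:
            raise ValidationError("subregions_per_continent must be >= 1")

    @property
    def years(self) -> range:
        return range(self.year_start, self.year_end + 1)


@dataclass
class GroundTruth:
    """Exact record of what was generated.

    ``cells`` maps (year, country_a, country_b, species) with a < b to the
    clean directed volumes (vol_ab, vol_ba); one-way cells carry one zero.
    Contaminant tonnage is tallied per exclusion bucket.
    """

    cells: dict[tuple[int, str, str, str], tuple[float, float]] = field(default_factory=dict)
    contaminant_tonnes: dict[str, float] = field(
        default_factory=lambda: {"aquaculture": 0.0, "reexport": 0.0, "non_species": 0.0}
    )
    contaminant_rows: dict[str, int] = field(
        default_factory=lambda: {"aquaculture": 0, "reexport": 0, "non_species": 0}
    )
    n_trading_cells: int = 0
    n_two_way_cells: int = 0

    @property
    def clean_tonnes(self) -> float:
        return sum(ab + ba for ab, ba in self.cells.values())

    @property
    def realized_two_way_fraction(self) -> float:
        if self.n_trading_cells == 0:
            return float("nan")
        return self.n_two_way_cells / self.n_trading_cells

    def to_json(self) -> str:
        payload = {
            "cells": [
                {"year": y, "country_a": a, "country_b": b, "species": s,
                 "vol_ab": ab, "vol_ba": ba}
                for (y, a, b, s), (ab, ba) in sorted(self.cells.items())
            ],
            "contaminant_tonnes": self.contaminant_tonnes,
            "contaminant_rows": self.contaminant_rows,
            "n_trading_cells": self.n_trading_cells,
            "n_two_way_cells": self.n_two_way_cells,
        }
        return json.dumps(payload, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "GroundTruth":
        payload = json.loads(text)
        gt = cls(
            contaminant_tonnes=payload["contaminant_tonnes"],
            contaminant_rows=payload["contaminant_rows"],
            n_trading_cells=payload["n_trading_cells"],
            n_two_way_cells=payload["n_two_way_cells"],
        )
        for cell in payload["cells"]:
            gt.cells[(cell["year"], cell["country_a"], cell["country_b"], cell["species"])] = (
                cell["vol_ab"],
                cell["vol_ba"],
            )
        return gt


@dataclass
class SyntheticDataset:
    trade_frame: pd.DataFrame
    region_frame: pd.DataFrame
    iucn_frame: pd.DataFrame
    region_map: RegionMap
    iucn_table: IUCNTable
    ground_truth: GroundTruth
    config: SyntheticConfig


def country_codes(n: int) -> list[str]:
    """Deterministic synthetic alpha-3 codes: XAA, XAB, ... (X prefix avoids
    collisions with real ISO assignments in test fixtures)."""
    if n > 26 * 26:
        raise ValidationError("at most 676 synthetic countries supported")
    return [f"X{chr(65 + i // 26)}{chr(65 + i % 26)}" for i in range(n)]


def generate(config: SyntheticConfig) -> SyntheticDataset:
    """Generate a trade table, region map, IUCN table and exact ground truth.

    Fully reproducible: the same config (including seed) yields identical
    frames.  Contaminants are extra rows tagged in the ground truth; the
    clean rows alone determine the expected redundant flows.
    """
    countries = country_codes(config.n_countries)
    species = list(SPECIES_POOL[: config.n_species])
    pairs = [
        (countries[i], countries[j])
        for i in range(config.n_countries)
        for j in range(i + 1, config.n_countries)
    ]

    rows: list[dict] = []
    truth = GroundTruth()

    def add_row(year, exporter, importer, taxon, rank, method, reexport, tonnes):
        rows.append(
            {
                "year": year,
                "exporter_iso3": exporter,
                "importer_iso3": importer,
                "taxon_name": taxon,
                "taxon_rank": rank,
                "production_method": method,
                "is_reexport": reexport,
                "tonnes": tonnes,
            }
        )

    for year_idx, year in enumerate(config.years):
        for pair_idx, (a, b) in enumerate(pairs):
            for species_idx, sp in enumerate(species):
                rng = np.random.default_rng([config.seed, year_idx, pair_idx, species_idx])
                # Fixed draw order: trade?, two-way?, direction, vol1, vol2,
                # then one (coin, volume) pair per contaminant type per row.
                if rng.random() >= config.edge_density:
                    continue
                truth.n_trading_cells += 1
                two_way = rng.random() < config.two_way_fraction
                forward = rng.random() < 0.5  # used only for one-way cells
                vol1 = _draw_volume(rng, config)
                vol2 = _draw_volume(rng, config)
                if two_way:
                    truth.n_two_way_cells += 1
                    vol_ab, vol_ba = vol1, vol2
                elif forward:
                    vol_ab, vol_ba = vol1, 0.0
                else:
                    vol_ab, vol_ba = 0.0, vol1
                truth.cells[(year, a, b, sp)] = (vol_ab, vol_ba)

                directed = []
                if vol_ab > 0:
                    directed.append((a, b, vol_ab))
                if vol_ba > 0:
                    directed.append((b, a, vol_ba))
                for exporter, importer, tonnes in directed:
                    add_row(year, exporter, importer, sp, "species", "capture", False, tonnes)
                    if rng.random() < config.aquaculture_rate:
                        t = _draw_volume(rng, config)
                        add_row(year, exporter, importer, sp, "species", "aquaculture", False, t)
                        truth.contaminant_tonnes["aquaculture"] += t
                        truth.contaminant_rows["aquaculture"] += 1
                    if rng.random() < config.reexport_rate:
                        t = _draw_volume(rng, config)
                        add_row(year, exporter, importer, sp, "species", "capture", True, t)
                        truth.contaminant_tonnes["reexport"] += t
                        truth.contaminant_rows["reexport"] += 1
                    if rng.random() < config.coarse_taxon_rate:
                        t = _draw_volume(rng, config)
                        label = COARSE_LABELS[int(rng.integers(len(COARSE_LABELS)))]
                        add_row(year, exporter, importer, label, "higher", "capture", False, t)
                        truth.contaminant_tonnes["non_species"] += t
                        truth.contaminant_rows["non_species"] += 1

    trade_frame = pd.DataFrame(
        rows,
        columns=[
            "year", "exporter_iso3", "importer_iso3", "taxon_name",
            "taxon_rank", "production_method", "is_reexport", "tonnes",
        ],
    )

    # Region map: countries round-robin over continents, then over the
    # subregions nested within their continent.
    continents = [f"Continent {i + 1}" for i in range(config.n_continents)]
    continent_of: dict[str, str] = {}
    subregion_of: dict[str, str] = {}
    per_continent_counter = [0] * config.n_continents
    for idx, code in enumerate(countries):
        ci = idx % config.n_continents
        si = per_continent_counter[ci] % config.subregions_per_continent
        per_continent_counter[ci] += 1
        continent_of[code] = continents[ci]
        subregion_of[code] = f"{continents[ci]} Subregion {si + 1}"
    region_frame = pd.DataFrame(
        {
            "country_iso3": countries,
            "continent": [continent_of[c] for c in countries],
            "subregion": [subregion_of[c] for c in countries],
        }
    )
    region_map = RegionMap(continent=continent_of, subregion=subregion_of)

    # IUCN categories drawn once per species from a fixed marginal.
    iucn_rng = np.random.default_rng([config.seed, 0xC0DE])
    categories = list(_IUCN_WEIGHTS)
    weights = np.array([_IUCN_WEIGHTS[c] for c in categories])
    weights = weights / weights.sum()
    assigned = [
        categories[int(iucn_rng.choice(len(categories), p=weights))] for _ in species
    ]
    iucn_frame = pd.DataFrame(
        {"taxon_name": species, "iucn_category": [c.value for c in assigned]}
    )
    iucn_table = IUCNTable(category=dict(zip(species, assigned)))

    return SyntheticDataset(
        trade_frame=trade_frame,
        region_frame=region_frame,
        iucn_frame=iucn_frame,
        region_map=region_map,
        iucn_table=iucn_table,
        ground_truth=truth,
        config=config,
    )


@dataclass(frozen=True)
class ExpectedRedundancy:
    """Redundancy computed directly from ground-truth clean volumes."""

    total: float
    by_year: Mapping[int, float]
    by_country: Mapping[str, float]  # avoidable exports (min) per country
    by_pair: Mapping[tuple[str, str], float]
    by_species: Mapping[str, float]


def expected_redundancy(truth: GroundTruth) -> ExpectedRedundancy:
    """The oracle: apply the 2*min rule to every clean ground-truth cell."""
    total = 0.0
    by_year: dict[int, float] = {}
    by_country: dict[str, float] = {}
    by_pair: dict[tuple[str, str], float] = {}
    by_species: dict[str, float] = {}
    for (year, a, b, sp), (vol_ab, vol_ba) in truth.cells.items():
        matched = min(vol_ab, vol_ba)
        if matched <= 0:
            continue
        redundant = 2.0 * matched
        total += redundant
        by_year[year] = by_year.get(year, 0.0) + redundant
        by_country[a] = by_country.get(a, 0.0) + matched
        by_country[b] = by_country.get(b, 0.0) + matched
        by_pair[(a, b)] = by_pair.get((a, b), 0.0) + redundant
        by_species[sp] = by_species.get(sp, 0.0) + redundant
    return ExpectedRedundancy(
        total=total,
        by_year=by_year,
        by_country=by_country,
        by_pair=by_pair,
        by_species=by_species,
    )
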