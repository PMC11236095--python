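"""Shared fixtures and the independent brute-force oracle.

The oracle enumerates every (year, unordered pair, species) combination
with plain loops and dictionaries — deliberately independent of the
package's grouped/pivoted implementation path.
"""

from __future__ import annotations

import numpy as np
import pytest

from twowaytrade.records import ProductionMethod, TaxonRank, TradeRecord

# Volumes in fixtures are multiples of 2^-10 so every sum is exact in
# double precision and oracle comparisons can use exact equality.
QUANTUM = 1.0 / 1024.0

SPECIES_NAMES = [
    "Clupea harengus",
    "Gadus morhua",
    "Katsuwonus pelamis",
    "Scomber scombrus",
    "Trachurus trachurus",
]


def make_record(
    exporter="AAA",
    importer="BBB",
    tonnes=1.0,
    year=2000,
    taxon="Gadus morhua",
    rank=TaxonRank.SPECIES,
    method=ProductionMethod.CAPTURE,
    reexport=False,
):
    return TradeRecord(
        year=year,
        exporter=exporter,
        importer=importer,
        taxon_name=taxon,
        taxon_rank=rank,
        production_method=method,
        is_reexport=reexport,
        tonnes=tonnes,
    )


def random_filtered_records(rng, n_countries=6, n_species=4, n_years=3, n_rows=50,
                            reciprocal_prob=0.4):
    """Random already-filtered records (capture, non-re-export, species-level).

    A fraction of rows gets a reverse-direction companion so that two-way
    cells actually occur. Duplicate directed keys are allowed on purpose:
    the pipeline must sum them before matching.
    """
    countries = [f"C{i:02d}" for i in range(n_countries)]
    species = SPECIES_NAMES[:n_species]
    years = [2000 + i for i in range(n_years)]
    records = []
    for _ in range(n_rows):
        i, j = rng.choice(n_countries, size=2, replace=False)
        sp = species[rng.integers(n_species)]
        year = years[rng.integers(n_years)]
        tonnes = (int(rng.integers(1, 20000))) * QUANTUM
        records.append(make_record(countries[i], countries[j], tonnes, year, sp))
        if rng.random() < reciprocal_prob:
            tonnes_back = (int(rng.integers(1, 20000))) * QUANTUM
            records.append(make_record(countries[j], countries[i], tonnes_back, year, sp))
    return records


# ---------------------------------------------------------------------------
# Brute-force oracle


def oracle_directed_totals(records):
    totals = {}
    for r in records:
        key = (r.year, r.exporter, r.importer, r.taxon_name)
        totals[key] = totals.get(key, 0.0) + r.tonnes
    return totals


def oracle_redundant_cells(records):
    """Exhaustive triple loop over (year, pair, species).

    Returns {(year, a, b, species): (export_ab, export_ba, redundant)} with
    a < b, keeping only cells matched in both directions.
    """
    directed = oracle_directed_totals(records)
    countries = sorted({r.exporter for r in records} | {r.importer for r in records})
    species = sorted({r.taxon_name for r in records})
    years = sorted({r.year for r in records})
    cells = {}
    for year in years:
        for ai, a in enumerate(countries):
            for b in countries[ai + 1:]:
                for sp in species:
                    ab = directed.get((year, a, b, sp), 0.0)
                    ba = directed.get((year, b, a, sp), 0.0)
                    if ab > 0 and ba > 0:
                        cells[(year, a, b, sp)] = (ab, ba, 2.0 * min(ab, ba))
    return cells


def oracle_by_year(cells):
    out = {}
    for (year, _, _, _), (_, _, red) in cells.items():
        out[year] = out.get(year, 0.0) + red
    return out


def oracle_by_country(cells):
    out = {}
    for (_, a, b, _), (ab, ba, _) in cells.items():
        matched = min(ab, ba)
        out[a] = out.get(a, 0.0) + matched
        out[b] = out.get(b, 0.0) + matched
    return out


def oracle_by_pair(cells):
    out = {}
    for (_, a, b, _), (_, _, red) in cells.items():
        out[(a, b)] = out.get((a, b), 0.0) + red
    return out


def oracle_by_species(cells):
    out = {}
    for (_, _, _, sp), (_, _, red) in cells.items():
        out[sp] = out.get(sp, 0.0) + red
    return out


def oracle_total(cells):
    return sum(red for _, _, red in cells.values())


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def worked_example_records():
    """The canonical 10 t / 5 t two-record example."""
    return [
        make_record("AAA", "BBB", 10.0),
        make_record("BBB", "AAA", 5.0),
    ]
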