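# twowaytrade

Quantify **redundant two-way trade** — the matched exchange of the same
species between the same two countries in the same year — in bilateral
species-level trade flow tables.

For a country pair with directed annual export volumes `x` (a→b) and `z`
(b→a) of one species, the redundant volume is `2 × min(x, z)` and each
country could avoid exporting `min(x, z)` tonnes with no change to either
country's final supply. The package:

- reads and validates long-format trade CSVs (deduplication, taxon
  normalization, binomial species-level detection with optional whitelist
  and explicit-rank override);
- applies the exclusion funnel (aquaculture, unknown production method,
  re-exports, records not resolved to species level) with exact tonnage
  accounting per year;
- computes redundant flows for every canonical country pair × species ×
  year cell;
- aggregates them into annual series, per-country attribution (avoidable
  exports, redundancy proportions, redundant-species counts), partner-pair
  rankings with continent/subregion overlap, species rankings with IUCN
  Red List category joins, top-k cumulative coverage, threatened-species
  shares, and OLS regressions of redundant exports on total exports or
  species-level reporting fraction;
- ships a seeded synthetic trade-network generator with exact ground truth
  (planted two-way fraction, injected contaminant rows) used as an oracle
  for end-to-end testing.

## Input formats

All inputs are UTF-8 CSVs with a header row.

- **Trade table**: `year, exporter_iso3, importer_iso3, taxon_name,
  taxon_rank (optional), production_method, is_reexport, tonnes`.
  Countries are ISO 3166-1 alpha-3 codes; `production_method` is
  `capture` / `aquaculture` (anything else is treated as `unknown` and
  excluded into its own report bucket); `tonnes` is live weight.
- **Region map**: `country_iso3, continent, subregion`.
- **IUCN lookup**: `taxon_name, iucn_category` with categories
  `LC/NT/VU/EN/CR/DD/NA`.

## CLI

```sh
# full analysis: writes filter report, flow table, edge list, all summary
# tables and a headline.json into --outdir
twowaytrade run --trade trade.csv --regions regions.csv --iucn iucn.csv \
    --outdir results/ --proportion-basis exports --topk-threshold 0.9

# synthetic data with exact ground truth (trade.csv, regions.csv,
# iucn.csv, ground_truth.json)
twowaytrade simulate --outdir sim/ --seed 7 --n-countries 10 \
    --n-species 8 --two-way-fraction 0.3
```

`run` is fully deterministic; all randomness is confined to `simulate`.
`simulate` also accepts a YAML config file (`--config`), with flags taking
precedence.

The Python API mirrors the CLI stages: `read_trade_table` →
`apply_filters` → `compute_redundant_flows` → `annual_series` /
`country_attribution` / `pair_ranking` / `species_ranking` /
`topk_coverage` / `threatened_share` / `redundancy_regression`, plus
`twowaytrade.synthetic.generate` / `expected_redundancy`.

## Tests

```sh
python -m pytest -q tests/
```

`tests/test_acceptance.py` holds the acceptance suite: the worked example,
brute-force oracle equivalence on random fixtures, conservation of
redundant tonnage across all aggregations, algebraic properties of the
statistic, synthetic parameter recovery, exact filter accounting, and
regression sanity/CI coverage.

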