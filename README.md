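# healthaccess

Geographic accessibility of health facilities: least-cost travel-time
surfaces over a friction raster, access population coverage (APC) at time
thresholds, facility density and service summaries, and facility-network
scenario comparison. A seeded synthetic-world generator provides every input
the pipeline needs, so the whole analysis runs end-to-end without external
data.

## What it computes

Given a friction surface (minutes per meter of motorised travel), a
population raster, an optional zone raster and urban mask, and one or more
facility registries (CSV point lists with tier and service attributes), the
package produces:

- a **travel-time raster**: per-cell minimum minutes to the nearest facility,
  by exact multi-source Dijkstra over the friction grid (8-connected by
  default, with 4- and 16-connected options; edge cost is the mean of the two
  cells' friction times the inter-center distance);
- **APC** at configurable thresholds (default 30/60/120 min): the percentage
  of a stratum's population within the threshold;
- **travel-time summaries** (mean/SD, median/IQR), population- or
  pixel-weighted, stratified by zone and rural/urban;
- **red-zone population** (beyond 60 minutes) and a four-band
  blue/green/yellow/red heatmap classification;
- facility **density per ten million people**, **service-availability
  summaries** with explicit handling of unknown values, and coordinate
  **deduplication** with a merge log;
- **scenario comparisons** across nested facility-tier unions (directory
  centres + teaching/district hospitals, progressively adding community and
  primary health centres, and a public-system-only variant), with
  monotonicity of access checked as an internal invariant.

Grids are projected/equal-area with square cells in meters; callers must
pre-project geographic data. Raster I/O is single-band GeoTIFF (via
`tifffile`), honoring the nodata tag; unreachable cells are `+inf` in memory
and nodata on disk.

## CLI

```bash
# generate a synthetic world (4 GeoTIFFs + 5 tier CSVs + config)
healthaccess synth --seed 42 --out world/

# directory-centres-only analysis
healthaccess situational \
    --friction world/friction.tif --population world/population.tif \
    --zones world/zones.tif --urban-mask world/urban_mask.tif \
    --facilities world/facilities_PCC.csv --out run/

# scenario comparison (tiers repeatable; default scenarios I-IV)
healthaccess scenarios \
    --friction world/friction.tif --population world/population.tif \
    --tier-csv PCC world/facilities_PCC.csv --tier-csv TH world/facilities_TH.csv \
    --tier-csv DH world/facilities_DH.csv --tier-csv CHC world/facilities_CHC.csv \
    --tier-csv PHC world/facilities_PHC.csv --out scen/

# re-derive a report from an existing travel-time raster
healthaccess report --travel-time run/travel_time.tif \
    --population world/population.tif --out rep/
```

Logs go to stderr, tables and rasters to files; every run writes a
`run_manifest.json`. Exit codes: 0 success, 2 validation failure, 3
internal-consistency failure.

## Layout

```
src/healthaccess/
  raster_core.py     grid model, GeoTIFF read/write, alignment checks
  facilities.py      registry ingestion, dedup, service summaries, density
  traveltime.py      multi-source Dijkstra + Bellman-Ford test oracle
  access_metrics.py  APC, summaries, red zone, heatmap, stratified report
  scenarios.py       tier unions and comparative runs
  synthetic_data.py  seeded synthetic country generator
  cli.py             synth / situational / scenarios / report subcommands
```
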