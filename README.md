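# phenanom

Annual-anomaly statistics for bird spring-migration phenology from daily
ringing (mist-netting) capture counts, with climate-covariate attribution.

The pipeline:

1. **Ingestion** (`phenanom.ringing`) — reads capture tables, deduplicates
   to the first capture of each ring per season, tallies daily counts over
   fixed calendar windows (spring = 1 Apr–15 May, autumn = 14 Aug–29 Oct),
   drops seasons with fewer than 30 captures, and normalizes autumn
   juvenile counts to a 50-net season.
2. **Anomaly core** (`phenanom.anomaly`) — converts each season to a
   cumulative percentage arrival curve, averages curves with equal yearly
   weight into a multiyear baseline, and computes the annual anomaly (AA):
   the summed daily gap between baseline and year curve divided by 100, a
   signed timing statistic in days (positive = later than baseline; a sign
   flag flips the convention). Percentile thresholds on the baseline define
   three contiguous main periods (thirds of passage, MP1–MP3) and nine
   overlapping 20-percentile sub-periods (SP1–SP9) into which AA is
   decomposed; the main-period anomalies sum exactly to the overall AA.
3. **Climate covariates** (`phenanom.climate`) — turns monthly climate
   index series (NAO, SOI, IOD, SCAND, Sahel precipitation/temperature,
   local temperature) into per-year seasonal means with the standard
   window/lag roster (Apr–May, Nov–Mar straddling the year boundary,
   Aug–Oct and Jun–Jul of the previous year), z-standardizes them, and
   screens collinear pairs.
4. **Model selection** (`phenanom.models`) — all-subsets OLS ranked by
   small-sample-corrected AIC (AICc, k = p + 2), top-model sets
   (ΔAICc < 2), per-variable contribution scores, partial correlations
   (pR), variance inflation factors, year-trend tests with
   Benjamini–Hochberg correction, and the 9 × 9 moving-window profile of
   sign-inverted pR across sub-periods.
5. **Juvenile analysis** (`phenanom.juveniles`) — regresses spring
   anomalies on the square root of the previous autumn's per-50-nets
   juvenile count (configured outlier autumns excluded), plus Pearson
   correlations and mean migration speed from direct ringing recoveries.
6. **Synthetic data** (`phenanom.simulate`) — a seeded generator of
   multi-cohort passage under known climate forcing (days-per-SD effects),
   with recaptures, low-count seasons, effort variation and a serialized
   truth bundle, so the full chain is testable without external data.

## CLI

```sh
# generate a synthetic study (captures.csv, effort.csv, climate/, truth.json)
phenanom simulate -c examples/scenario.yaml -o scratch/demo

# anomaly tables: baseline curve, period dates, per-period AA series
phenanom anomaly --captures scratch/demo/captures.csv --out-dir scratch/out

# model selection + trends + window profile + juvenile regressions
phenanom models --captures scratch/demo/captures.csv \
    --effort scratch/demo/effort.csv \
    --climate-dir scratch/demo/climate --out-dir scratch/out

# simulate + analyse + report parameter recovery in one step
phenanom recover -c examples/scenario.yaml -o scratch/recover
```

All subcommands also accept a YAML run config (`-c run.yaml`) mirroring
`phenanom.pipeline.RunConfig`. Output CSVs carry a `# config=<hash>`
header; identical configs produce byte-identical outputs.

## Reproducing published numbers

The original 1982–2017 daily ringing dataset and the direct-recovery table
are third-party archives deposited with the source study; they are not
redistributable here and the offline test environment cannot download
them. To run the full reproduction (acceptance tests
`TestPublishedNumbers` and targets t1–t9/t12 of the acceptance report),
convert the archives to CSV and place them under `data/`:

- `data/captures.csv` — columns `ring_id, date` (ISO 8601), `age_class`
  (`full_grown` / `juvenile` / `adult`), `site`; one row per capture,
  springs 1982–2017 and autumns 1981–2016.
- `data/effort.csv` — columns `year, season, nets` (`season` is
  `spring` / `autumn`).
- `data/recoveries.csv` — columns `ring_date, find_date` and either
  `distance_km` or `ring_lat, ring_lon, find_lat, find_lon`.
- `data/climate/*.csv` — monthly index series, columns
  `index_name, year, month, value` (index names `TLEB, NAO, SCAND, PSAH,
  TSAH, IOD, SOI`).

Without these files the published-number acceptance tests fail (by
design, with an explanatory message) and the report omits those targets.
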