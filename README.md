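# searchsurge

Excess search-interest analysis for daily query-fraction time series.

Given per-geography, per-topic daily series of query fractions (searches
matching a term set per 10 million total searches), `searchsurge`:

1. fits a pre-event **ARIMA baseline** — differencing order by successive
   KPSS tests (with an AR(1)-prewhitened long-run variance for honest size
   under persistence), ARMA orders by stepwise AICc search in the
   Hyndman–Khandakar style;
2. forecasts a **counterfactual** over the post-event window with
   psi-weight prediction intervals;
3. quantifies **excess search interest** — per-day and cumulative
   observed/expected ratios on the percent scale, with model-residual
   **bootstrap** percentile confidence intervals (pointwise, seeded,
   reproducible);
4. summarizes **geographic/topic structure**: cumulative query fractions,
   rankings with fold-vs-mean contrasts, within-geography topic shares,
   leading-topic tallies, a one-way random-effects ICC, and bottom-k vs
   top-k group contrasts;
5. associates topic shares with a **political covariate** (2016 vote share):
   OLS dose-response lines with t-based CIs and a winner breakdown.

A synthetic-data generator produces state × topic panels with known baseline
dynamics, a multiplicative event surge decaying to an elevated floor, and
covariate-driven topic preferences — every downstream stage can be checked
against injected ground truth.

## Tests

```bash
python -m pytest -q tests/
```

`tests/test_acceptance.py` holds the simulation-based acceptance checks
(order-selection sanity vs an exhaustive oracle, bootstrap coverage of
injected excess, regression CI coverage, byte-level pipeline
reproducibility); it is the slow part of the suite (~10 min on one CPU).

## CLI

```bash
# generate a synthetic panel (series CSV, covariates CSV, ground-truth JSON)
searchsurge simulate --config examples/demo.yaml --out-dir out/

# counterfactual forecast for one series
searchsurge counterfactual --series out/series.csv --geography AK --topic union \
    --baseline-start 2018-07-01 --event-date 2020-05-25 --post-end 2020-07-05 \
    --out forecast.json

# excess with bootstrap CIs
searchsurge excess --series out/series.csv --geography AK --topic union \
    --baseline-start 2018-07-01 --event-date 2020-05-25 --post-end 2020-07-05 \
    -B 1000 --seed 1 --out excess.json

# state-level summaries / political association
searchsurge geo --series out/series.csv --covariates out/covariates.csv \
    --baseline-start 2018-07-01 --event-date 2020-05-25 --post-end 2020-07-05 \
    --out-dir geo_out/
searchsurge political --series out/series.csv --covariates out/covariates.csv \
    --baseline-start 2018-07-01 --event-date 2020-05-25 --post-end 2020-07-05 \
    --out-dir pol_out/

# full pipeline: simulate/load -> counterfactual -> excess -> geo -> political
searchsurge run --config examples/demo.yaml --out-dir report/
```

The pipeline writes `report.json` + `report.md` (plus CSVs); under a fixed
config and seed the bundle is byte-identical across runs.  Logging and stage
timings go to stderr only.

## Data formats

- **long CSV** (canonical): header `geography,topic,date,qf`, ISO dates,
  one row per series-day.
- **trends_widetable**: a public-Trends-style export (preamble line, blank
  line, `Day,<name>,...` header); `"<1"` cells are imputed with a
  configurable constant (default 0.5).  Column names `GEO:topic` carry the
  geography.
- **covariates CSV**: header `geography,vote_share_trump,winner`.

Analyses run on the query-fraction scale; conversion to absolute search
counts (`searchsurge.excess.absolute_volume`) requires a user-supplied total
daily search-volume series.

## Package layout

| module | contents |
| --- | --- |
| `searchsurge.data_model` | `QuerySeries`, `AnalysisWindow`, `CovariateTable`, CSV readers/writers, window slicing |
| `searchsurge.synthetic` | `SyntheticConfig`, ARMA baseline sampler, event-effect injection, panel generator with ground truth |
| `searchsurge.counterfactual` | KPSS differencing choice, `fit_arima`, stepwise `select_order`, forecast recursion, path simulation |
| `searchsurge.excess` | `excess_ratios`, `bootstrap_excess_ci`, `significance_flags`, `absolute_volume` |
| `searchsurge.geo_topics` | `StatePanel`, rankings, topic shares, tallies, ICC, group contrasts |
| `searchsurge.political` | vote-share dose-response OLS, winner breakdown |
| `searchsurge.cli` | `run_pipeline` and the `searchsurge` command group |
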