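# faersignal

Signal detection for spontaneous adverse-event reports in the FAERS
quarterly ASCII dialect, built as a reusable, tested pipeline:

* **Synthetic data with ground truth** (`faersignal.synth`) — generates
  `$`-delimited DEMO/DRUG/REAC/THER files with planted disproportionality
  signals, injected duplicate report groups (with a known intended
  survivor), partial/corrupted dates, missing demographics, and
  Weibull-distributed onset latencies. Byte-identical output for a given
  config + seed.
* **I/O** (`faersignal.io`) — typed readers/writers for the FAERS dialect
  (plain or gzip), partial-date parsing at day/month/year precision.
* **Cohort building** (`faersignal.cohort`) — FDA-rule deduplication
  (per CASEID keep latest FDA_DT, ties broken by highest PRIMARYID),
  primary-suspect cohort selection with whole-word synonym matching on
  verbatim drug names, and PT→SOC mapping from a user-supplied two-column
  file (MedDRA itself is licensed and is not bundled).
* **Disproportionality** (`faersignal.dispro`) — ROR with log-normal CI,
  PRR with Yates-corrected χ², BCPNN shrinkage information component with
  closed-form IC025, and MGPS: a two-gamma mixture prior fitted by
  marginal maximum likelihood across all drug–event pairs, EBGM via the
  digamma closed form and EBGM05 by root-finding on the posterior CDF.
  A pair is a signal only when all four detectors clear their
  (configurable) thresholds.
* **Pipeline** (`faersignal.pipeline`) — baseline characteristics table,
  PT- and SOC-level signal tables, top-K positive selection, sensitivity
  re-analysis excluding co-medicated reports, age-subgroup re-analysis.
* **Time to onset** (`faersignal.tto`) — latency extraction with
  exclusion tallies, median/IQR summaries, and Weibull MLE (interval-
  censored by default to handle day rounding) with Wald CIs and
  early/random/wear-out classification.

## CLI

```sh
# generate a synthetic dataset
faersignal simulate config.yaml data/

# run the full analysis (dedup -> cohort -> baseline -> signals ->
# sensitivity -> subgroups -> TTO)
faersignal analyze data/ config.yaml results/
```

Stage shortcuts `baseline`, `signals`, `sensitivity`, `subgroups`,
`tto`, and `report` take the same arguments and write subsets of the
output. Every run writes `run_manifest.json` with a config hash, input
and output digests, and per-stage report counts; reruns on identical
inputs produce identical digests. Exit codes: 0 success, 1 usage or
configuration error, 2 data error.

Example `config.yaml`:

```yaml
simulate:
  n_reports: 50000
  n_drugs: 20
  n_events: 100
  seed: 42
  background_rate: 0.001
  duplicate_rate: 0.05
  planted_signals:
    - [MIRTAZAPINE, EVENT 0001, 5.0]
analyze:
  target_synonyms_file: synonyms.txt      # one synonym per line
  soc_map_file: soc_map.tsv               # PT<TAB>SOC
  sensitivity_synonyms_file: exclusions.txt
  top_k: 50
  thresholds: {min_a: 3, ror_lo_gt: 1, prr_ge: 2, chi2_ge: 4,
               ic025_gt: 0, ebgm05_gt: 2}
```

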