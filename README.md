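# artdecision

Decision-analytic model of unexplained-infertility management, comparing a
capacitation-score-guided strategy (**CS-TI**: score test first; a low score
routes the couple directly to up to 3 IVF-ICSI cycles, a normal score to up
to 3 timed IUI cycles then up to 3 IVF-ICSI cycles) against the **standard of
care** (**SOC**: up to 3 IUI cycles then up to 3 IVF-ICSI cycles).  Outcomes
are cumulative clinical pregnancy, cumulative live birth (conditional on
pregnancy, by conceiving modality), expected treatment cycles, and IUI/IVF/
total costs in 2016 USD, per maternal-age band, with CS-TI − SOC deltas.

The package provides:

- `artdecision.parameters` — the typed parameter table (baselines plus
  low–high 95% sensitivity ranges), a bundled default table
  (`src/artdecision/data/default_parameters.csv`), CSV/TSV and YAML loaders
  with full validation, and method-of-moments distribution fitting (beta for
  probabilities, zero-truncated normal for costs, sd = range/3.92).
- `artdecision.decision_model` — closed-form (capped-geometric) evaluation of
  the whole tree: `cumulative_pregnancy`, `modality_split`,
  `cumulative_live_birth`, `expected_cycle_counts`, `costs`, `evaluate`,
  `baseline_tables`.
- `artdecision.cohort_sim` — patient-level Bernoulli microsimulation of
  couples traversing the tree; serves as a brute-force oracle for the closed
  forms (`simulate_couple`, `simulate_cohort`, deterministic given a seed).
- `artdecision.psa` — probabilistic sensitivity analysis: independent
  parameter sampling, Monte Carlo means and percentile 95% credibility
  intervals, with the baseline closed-form value reported alongside.
- `artdecision.owsa` — one-way sensitivity analysis: tornado tables ranking
  parameter influence per outcome and age band (`run_owsa`,
  `most_influential`, `top_parameter_counts`).
- `artdecision.report` / `artdecision.cli` — formatting (`92.88%`, `$6,484`,
  half-up) and a CLI.

## CLI

```sh
artdecision baseline  --out out/                  # baseline outcome tables
artdecision psa       --n-draws 10000 --seed 1 --out out/
artdecision owsa      --outcome pregnancy_delta --age '<35' --out out/
artdecision simulate  --strategy SOC --age '<35' --cohort-size 200000 --seed 1 --out out/
```

All commands accept `--params <file>` (CSV/TSV/YAML; see the bundled default
table for the schema) and append a run log (`run_log.txt`) recording the
seed, draw count, and parameter-file digest.  Outputs are comma-separated
text, one age band per row.

## Notes

- Per-cycle conception probabilities are constant across repeated cycles and
  cycles are independent; timed-IUI conceptions use the age-specific IUI
  live-birth probability; the score test itself carries no cost.
- The PSA reports plain Monte Carlo means; for nonlinear outcomes these need
  not equal the baseline evaluation, so the summary carries both, labeled.
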