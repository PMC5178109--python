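# clariped

Pediatric emergency risk-classification toolkit: a five-level urgency
scale (Blue < Green < Yellow < Orange < Red) assigned in two steps, plus
the statistics used to evaluate reliability and validity of the scale,
and a synthetic-data module so everything is testable without external
datasets.

**Step 1 — vital-sign score.** Respiratory rate, heart rate and SpO2 are
scored 0–4 against age-stratified band tables (five age groups from
newborn to >12 years); when the heart-rate sub-score is elevated (≥2), 1
or 2 points are subtracted depending on axillary temperature. The total
(0–12, clamped at 0) maps to a color: Blue (0), Green (1–2), Yellow
(3–5), Orange (6–9), Red (≥10).

**Step 2 — discriminators.** A data-driven catalog of clinical
discriminators (mandatory general ones — pain, general appearance, fever
report, age, returns — and complaint-triggered ones grouped by organ
system) asserts minimum urgency levels. The final level is the maximum
of the score color and all triggered discriminators: upgrades only,
never downgrades. Each level carries a maximum waiting time and a
destination (Red: immediate, resuscitation room; Orange: 10 min,
observation room; Yellow/Green/Blue: 30/90/180 min, waiting room).
Life-threat (Red) discriminators set a fast-path flag: straight to care,
classification recorded retrospectively.

All thresholds — band tables, strata, temperature correction, color map,
policy, and the full discriminator catalog — live in versioned YAML
files under `src/clariped/data/`; the engine contains no clinical
numbers.

## Library overview

| Module | Contents |
| --- | --- |
| `clariped.vipe` | age strata, band tables, `vipe_score`, `color_from_total` |
| `clariped.discriminators` | `Encounter` model, catalog loader, guard engine |
| `clariped.classify` | `classify`, `fast_path_check`, `classify_batch`, policy |
| `clariped.agreement` | Fleiss' kappa (overall, per-category, SE/z/p), rater simulator |
| `clariped.validity` | urgency × resource-bin tables, percentages, chi-square (+ Monte-Carlo p) |
| `clariped.synthetic` | score-table inversion, cohort and vignette generators |
| `clariped.io` | CSV schema, readers/writers with per-row error reports |

```python
from clariped import Encounter, classify

enc = Encounter(age_days=730, rr=65, hr=155, spo2=93, axtemp_c=39.0,
                pain_level=2, general_appearance="ill")
result = classify(enc)
result.final_level, result.max_wait_minutes, result.triggered_codes
```

## Command line

```bash
clariped simulate --n 500 --seed 42 --out cohort.csv --labels labels.csv
clariped classify --input cohort.csv --out results.csv --errors errors.csv
clariped validity --input results_with_resources.csv          # or --table counts.csv
clariped kappa --ratings ratings.csv --out kappa.json         # long or count form
clariped catalog-lint --vocab                                  # census + overlap checks
```

Exit codes: 0 success, 1 validation failure, 2 I/O failure. Encounter
CSV columns are documented in `clariped.io.ENCOUNTER_COLUMNS`; finding
codes in the catalog vocabulary (`clariped catalog-lint --vocab`).

## Notes

- The published 5–12 y heart-rate table contains an overlapping band
  boundary at 50 bpm; it is kept verbatim in the config, reported as a
  warning at load time, and resolved in favour of the higher score
  (safety-first). `clariped catalog-lint` surfaces it.
- Measured values are rounded to the nearest integer (half away from
  zero) before band lookup, matching the integer band grid.
- Optional measurements (CBG, BP) never trigger a rule when absent; the
  engine records a "measurement indicated but absent" advisory instead.
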