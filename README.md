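# gaitnirs

Analysis pipeline for block-design functional near-infrared spectroscopy
(fNIRS) recorded during a treadmill walking task, with a synthetic-data
generator standing in for raw trial recordings.

The pipeline implements:

- **study_model** — 48-channel dual-hemisphere montage (16 sources, 16
  detectors, ~3 cm pairs), the 4×(30 s walk + 30 s rest) task design at
  3.46 Hz, subject metadata, and cohort scenario presets.
- **synthetic_fnirs** — forward simulation of dual-wavelength (760/850 nm)
  raw intensities: boxcar ⊛ double-gamma hemodynamic response, forward
  modified Beer–Lambert law, physiological noise (cardiac, respiratory,
  Mayer waves, drift, spikes, baseline shifts), and injectable bad channels.
- **preprocessing** — channel QC (gain ≥ 7 or intensity CV > 0.15 excludes a
  channel; more than 8 bad channels excludes the subject), discontinuity and
  spike removal, zero-phase Butterworth bandpass (0.01–0.20 Hz).
- **mbll** — optical-density conversion and 2×2 modified Beer–Lambert
  inversion to Δoxy-Hb / Δdeoxy-Hb (µM).
- **activation_auc** — the biomarker: per-channel sums of oxy-Hb over each
  30 s walk block, averaged over the 4 blocks, aggregated into
  more-affected-hemisphere (MAff), less-affected-hemisphere (LAff) and
  total (Tot = MAff + LAff, exactly) values.
- **training_intensity** — relative training intensity (mean session speed /
  baseline gait speed, corrected by the load fraction for body-weight-
  supported training) with a within-arm median split.
- **group_statistics** — Shapiro-gated t / Mann–Whitney / Wilcoxon
  comparisons, pooled-variance t tests from summary statistics, mixed
  group×time ANOVA, Spearman correlations, 2×2 chi-square, and a full
  cohort analysis battery.
- **cli_io** — text recording format (wide TSV + JSON sidecar), YAML/JSON
  configuration, and the `gaitnirs` CLI.

## Test

```bash
python -m pytest -q tests/
```

The suite includes two seeded calibration tests (type-I error and power of
the statistical battery over hundreds of simulated cohorts) that take a few
minutes; everything else runs in seconds.

## CLI

```bash
# end-to-end: simulate a study-like cohort, run QC → cleaning → MBLL →
# AUC → RTI → statistics, and write the cohort table + reports
gaitnirs run-all --scenario study_like --seed 7 --outdir out/

# individual stages
gaitnirs simulate --scenario study_like --seed 7 --outdir raw/
gaitnirs qc raw/RAGT001_T0.tsv
gaitnirs activation raw/RAGT001_T0.tsv --side right
gaitnirs rti training_log.tsv
gaitnirs stats out/cohort_table.tsv --alpha 0.05
```

Scenario presets: `study_like` (12 + 12 treated subjects at three
timepoints plus 5 healthy controls at baseline, opposite longitudinal
activation trends per arm) and `null` (no group differences, for
calibration). All thresholds, filter bands and Beer–Lambert parameters can
be overridden via a YAML config passed with `--config`.

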