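# vhitkit

Analysis toolkit for video head-impulse test (vHIT) recordings and the
associated cohort statistics:

- **`vhitkit.synthetic`** — simulator for head-impulse trials (Gaussian
  velocity pulses with analytically known peak acceleration, programmable
  VOR gain, catch-up saccades, blink artifacts, noise) and for patient
  cohorts with programmable gain-to-cognition associations.
- **`vhitkit.qc`** — per-trial quality control: peak head acceleration via a
  local-polynomial derivative, strict per-canal acceleration thresholds
  (2500 deg/s² horizontal, 1500 deg/s² vertical), blink and gain-outlier
  rejection, and the ≥10-valid-impulses sufficiency rule.
- **`vhitkit.gain`** — VOR gain by two estimators: the 40-ms window centered
  at peak head acceleration (primary) and the rectified area ratio over the
  impulse support, plus per-canal aggregation.
- **`vhitkit.saccades`** — catch-up saccade detection on the slow-phase-
  removed residual (60 deg/s threshold) and reversed-saccade classification
  against a configurable saccadic main-sequence model.
- **`vhitkit.classify`** — normative mean±2SD classification per canal
  (published control ranges shipped as defaults), cognitive z-score
  thresholds (−2.0 primary, −1.0 sensitivity), patient-level side patterns,
  and cohort counts with integer percentages.
- **`vhitkit.stats`** — Spearman, Mann–Whitney (exact for pooled n ≤ 20),
  χ²/Fisher contingency tests, logistic regression by IRLS with optional
  Firth penalty, backward elimination (stay rule p ≤ 0.10), and the primary
  association pipeline with its sensitivity reruns.
- **`vhitkit.io` / `vhitkit.pipeline` / `vhitkit.cli`** — CSV/JSON trial and
  cohort formats, YAML pipeline configuration, and a deterministic
  end-to-end driver.

## CLI

```bash
vhitkit simulate-trials --seed 1 --out-dir trials/ --n-trials 15
vhitkit qc trials/
vhitkit gain trials/
vhitkit saccades trials/
vhitkit simulate-cohort --seed 1 --out cohort.csv
vhitkit classify cohort.csv
vhitkit analyze cohort.csv
vhitkit run-all --config configs/demo.yaml --seed 1 --out-dir out/
```

`run-all` writes a report bundle (QC report, gain table, saccade table,
classification counts, association results) that is byte-identical across
reruns with the same config and seed. Exit codes: 0 success, 2 validation
error, 1 stage failure.

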