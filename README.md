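# frrf

Single-turnover chlorophyll fluorescence (FRRf) simulation, fitting and
photophysiology pipeline.

A fast-repetition-rate fluorometer excites photosystem II with a train of
microsecond flashlets, cumulatively driving a single photochemical turnover
(the fluorescence *induction* rise), then watches reaction centres reopen
(the *relaxation* decay). This package provides:

- **`frrf.frrf_model`** — the forward biophysical model: connectivity-shaped
  closure→fluorescence mapping, per-flashlet dose recursion, biexponential
  reopening, and flashlet-dose calibration (saturate the rise by a target
  flashlet).
- **`frrf.fitting`** — bounded nonlinear least-squares estimation of
  (F0, FM, σ, ρ) from induction curves and (τ1, τ2, α1) from relaxation
  curves, with deterministic documented initialization.
- **`frrf.derived_params`** — the standard derived photophysiology: F0′
  estimation from paired 1-s-dark fits, qP, the quantum-yield partition
  Y(PSII) + Y(NPQ) + Y(NO) ≡ 1, and absolute electron transport rate
  (e⁻ PSII⁻¹ s⁻¹).
- **`frrf.protocol`** — light protocols (a canonical non-sequential rapid
  light curve with revisited light levels, and 1200 s light / 900 s dark
  induction–recovery runs), timestamp-keyed pairing of in-light and
  1-s-dark measurements into per-step records, and the revisit/first-visit
  ETR comparison (`upregulation_index`).
- **`frrf.synthetic_data`** — a seeded generator producing complete
  experiments with known ground truth: time-dependent Y(NPQ) induction above
  a light threshold with incomplete dark reversal, a linear σ′ decline with
  Y(NPQ), closure-dependent and light-history-accelerated τ1, a DTT mode
  that suppresses regulated quenching, and multiplicative measurement noise.
- **`frrf.stats`** — closed-form OLS with slope t-tests and per-experiment
  σ′ normalisation.
- **`frrf.io_cli`** — CSV readers/writers with provenance headers, validated
  JSON/YAML run configs, and the `frrf` command line.

## Command line

```sh
# generate a synthetic non-sequential RLC (transients.csv + truth.csv)
frrf simulate --seed 1 --out run/

# per-measurement fits
frrf fit --input run/transients.csv --out fits.csv

# full pipeline: pair measurements, derive yields and ETR per light step
frrf pipeline --input run/transients.csv --out table.csv

# pooled regression, e.g. normalised sigma' against Y(NPQ)
frrf regress --input table.csv --out regression.csv
```

All outputs are deterministic for a given config + seed and carry
provenance headers (`# config_hash`, `# seed`, `# frrf_version`). A config
file (`--config`, JSON or YAML; unknown keys rejected) can override the
light sequence, flashlet train and generator physiology; see
`frrf.io_cli.schema()` for the accepted keys.

### Transient CSV contract

One row per sample point, columns:

```
measurement_id, timestamp_s, light_context, actinic_par, phase, time_us, fluorescence
```

`light_context ∈ {dark_adapted, actinic, dark_1s}`,
`phase ∈ {induction, relaxation}`. Instrument exports need only be munged
into this shape to enter the pipeline.

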