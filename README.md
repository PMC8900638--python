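# dynergy

EEG emotion-recognition pipeline built around a single *energy sequence* per
trial: multichannel recordings are projected onto a region-weighted
cross-channel average, sliced into overlapping windows, summarized by a
49-entry dynamic feature set, optionally reduced with a mutual-information +
PCA procedure, and classified over the window sequence by a bidirectional
LSTM network. A synthetic EEG generator with controllable class structure
makes the whole pipeline testable without any external dataset.

## Layout

| Module | Role |
| --- | --- |
| `dynergy.signal_io` | EDF/CSV/HDF5 recording and feature-table I/O; montage region-weight configuration with built-in 62-channel and 32-channel presets |
| `dynergy.energy` | energy-sequence projection (uniform or regional weights) and the moving-window iterator |
| `dynergy.features` | windowed feature set: 9 time-domain values, Hjorth + AR-spectrum features per band, approximate entropy, db4 wavelet entropies, differential entropy |
| `dynergy.mipca` | mutual-information matrix, eigendecomposition, contribution-rate cutoff, projection |
| `dynergy.model` | Bi-LSTM → dropout → LSTM → dense classifier (pure numpy, RMSprop), LOSO and stratified 10-fold protocols, RBF C-SVC baseline |
| `dynergy.synthetic` | seeded synthetic EEG bundles with per-class band-power structure |

The region presets use four regions with coefficient sums 0.4 / 0.3 / 0.2 /
0.1, split equally across the channels of each region. Window defaults are
4-s width with a 2-s step, which yields 29 windows on a 60-s trial (800
samples per window at 200 Hz, 512 at 128 Hz).

### The 49-feature inventory

The default inventory has exactly 49 uniquely named entries:

- time domain (9): `mean, sd, diff1, diff1_norm, diff2, diff2_norm, nsi,
  energy, fd` (population SD; NSI over 20 segments; Higuchi FD with
  k_max = 8),
- Hjorth (15): `hjorth_{activity,mobility,complexity}_{theta,alpha,beta,gamma,all}`
  via DFT-mask band-limiting,
- AR spectrum (10): `ar_max_freq_*` and `ar_power_sum_*` over the same five
  bands (Burg order 10, 512-point grid, periodogram fallback on unstable
  fits),
- dynamical (15): `apen` (m = 2, r = 0.2·SD, Chebyshev, self-matches),
  `we_a6, we_d1..we_d6, we_total` (db4, six levels), and
  `de_{delta,theta,alpha,beta,gamma,all}`.

**Caveat:** only the *count* of 49 is fixed by the method; the exact
enumeration is this package's reconstruction and is fully configurable via
`FeatureInventory`. The named subsets `seed17` (17 columns) and `deap19`
(19 columns) reproduce the published selected-feature layouts; because the
full-band Hjorth mobility/complexity entries appear in both their
time-domain and frequency-domain slots, those two columns are repeated (the
second occurrence is suffixed `#2`).

## CLI

```bash
dynergy simulate --preset seed-like --subjects 5 --trials-per-subject 20 --seed 1 --out bundle/
dynergy project bundle/trial_0000.h5 --weights regional --out energy.csv
dynergy extract bundle/trial_0000.h5 --subset seed17 --out features.csv
dynergy reduce features.csv --cutoff 0.95 --out mipca.h5
dynergy train --protocol kfold --subjects 5 --trials-per-subject 20 --seed 1
```

## Notes

- Headline accuracies on SEED/DEAP are **not** reproduced here: both
  datasets are registration-gated downloads. Evaluation protocols (LOSO,
  stratified 10-fold) are exercised on synthetic bundles instead.
- Printed montage tables contain a few non-standard labels; the presets
  normalize `EP1→FP1`, `AP4→AF4`, `01→O1`, `FC8→FT8`, and the duplicated
  `FC5` in region 1 → `FC1` (the only otherwise-missing 62-channel label).
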