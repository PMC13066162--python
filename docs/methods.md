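# Methods

This note documents the models, parameters and numerical choices behind
`pulseflux`: what the synthetic phantom generator emulates, how the signal
chain measures it, and where genuinely open design decisions were resolved.

## The measurement model

Three vessel–tissue phantoms of graded wall stiffness (Young's modulus
0.82 / 1.48 / 2.06 MPa — healthy / intermediate / unhealthy) sit in a
pulsatile bench circulation at 60 bpm, perfused with one of two
blood-mimicking fluids (BMFs): an intralipid oil-in-water emulsion or an
LPFS polystyrene-microsphere suspension. Two modalities are recorded for
4 minutes per condition:

* **PPG** at 530, 655 and 940 nm, 2000 Hz. PPG is volumetric: a stiffer
  vessel expands less per stroke, so the pulsatile amplitude and the area
  under the pulse fall with stiffness.
* **LDF flux** (perfusion units). Under laminar flow, `F = (Pa − Pv)/R`
  with `R = 8µL/(πr⁴)`; rising effective resistance with stiffness lowers
  the DC flux level. The `tube_resistance` and `poiseuille_flow` utilities
  expose exactly these relations and can be used to parameterize the
  generator's class flux levels.

## The synthetic phantom generator

No public recordings exist, so `synthetic_phantom` generates signals with
the statistical structure the analysis relies on. Its defaults *are* the
study conditions: 240 s records, 60 bpm, PPG at 2000 Hz, LDF at 40 Hz
(the device's output rate is not documented; 40 Hz is typical and the
analysis uses only window means, which are rate-insensitive), flux
smoothed with the device's 1.0 s exponential time constant.

**Beat model.** One beat is a raised-cosine rise from the onset datum to a
unit peak over a rise fraction (default 0.3 of the period), a raised-cosine
decay to a terminal offset by 0.7 of the period, and a terminal plateau at
that offset. The terminal offset grows with stiffness (0.02 / 0.10 / 0.22
of peak): a stiff vessel's sharper pulse has not returned to its datum when
the next upstroke begins. Beats are tiled at the pump period (jitter
default 0 — the pump is metronomic), scaled by the class/channel amplitude,
plus sinusoidal baseline wander (0.05 a.u. at 0.21 Hz, emulating slow
thermal/pump drift) and white noise.

**Default class structure** (all gaps ≥ 5 window-level noise SDs, so the
class ordering is stable across seeds):

| quantity | healthy | intermediate | unhealthy |
|---|---|---|---|
| PPG amplitude, intralipid green (a.u.) | 1.00 | 0.80 | 0.60 |
| PPG amplitude, intralipid red | 0.90 | 0.72 | 0.54 |
| PPG amplitude, intralipid IR | 0.50 | 0.40 | 0.30 |
| PPG amplitude, LPFS green/red/IR | 1.40/1.30/1.20 | ×0.8 | ×0.6 |
| LDF DC flux, intralipid (PU) | 800 | 550 | 300 |
| LDF DC flux, LPFS (PU) | 500 | 380 | 260 |

LPFS scatters less than intralipid, so LPFS amplitudes exceed intralipid's
at matched class and wavelength; the intralipid emulsion suppresses and
degrades the IR channel (amplitude lowered, noise SD ×4: 0.02 vs 0.005
a.u.); intralipid yields higher flux with a wider healthy-to-unhealthy
spread (500 vs 240 PU). PPG noise (0.005 a.u.) reflects bench-grade,
motion-free acquisition.

**Amplitude calibration.** Configured amplitudes are stated *post-filter*:
the band-pass (below) attenuates the beat's harmonic stack by a few
percent, so the generator pre-compensates by a single scalar gain measured
on a noiseless template train with the same fiducial estimator the feature
extractor uses. This makes "configured amplitude" and "amplitude the
pipeline measures" the same quantity, which is what the parameter-recovery
tests verify. `filter_compensation=False` restores raw peak-minus-foot
semantics.

**What the generator does not emulate** — and hence what passing tests do
not establish about real data: optical photon transport (class amplitudes
are imposed, not derived from scattering physics), motion and contact
artefacts, heart-rate and waveform variability (no dicrotic notch by
default; fixed pump rate), drift nonstationarity beyond sinusoidal wander,
and any overlap between classes (an `overlap_mode` hook exists but the
default is strictly monotone). Results on this generator demonstrate that
the pipeline measures what it claims under its stated noise model, not
that real phantoms separate this cleanly.

## Preprocessing

* PPG: Chebyshev type-I band-pass, order 2, 0.5–6 Hz. The filter family's
  type and ripple are not fully specified by convention; type I with
  0.5 dB passband ripple is the common PPG choice (sharp transition,
  controlled ripple) and both are exposed in `FilterSpec`. Applied with
  `sosfiltfilt` (forward–backward): zero phase, so fiducial timing is
  unbiased; "order 2" names the designed prototype, the two-pass response
  is its squared magnitude. Recordings are filtered once, then windowed —
  per-window filtering would create 24 transient regions.
* LDF: same family/order low-pass, default cut-off 2.0 Hz (keeps the 1 Hz
  pulsatile fundamental, removes pump harmonics; no value is conventional,
  this one is exposed). An even-order Chebyshev-I prototype sits at its
  ripple floor at DC, which would scale the flux mean by ~−1 dB over two
  passes; the designed SOS is therefore renormalized to exactly unit DC
  gain so the window mean — the quantity of interest — is preserved.

## PPG features

Beats are segmented on the filtered trace: systolic peaks are local maxima
with ≥ 0.6 beat-period separation and prominence ≥ 0.25 × the median
peak-to-trough excursion; each foot is the minimum between consecutive
peaks (ties break to the *last* minimum — the end of a flat diastolic
floor, immediately before the upstroke) and serves as the end of one beat
and the onset of the next. The minimum before the first peak supplies the
first onset; the final peak's beat is discarded because its terminal foot
is not bracketed by a following peak, so n beats yield n−1 segments.

Per-beat features (each a single stated formula so alternatives can be
swapped):

* **amplitude** = value(peak) − value(onset);
* **AUC** = trapezoidal integral of the pulse above the straight chord
  joining its onset to its end point;
* **slope ratio** = [(peak − onset)/rise time] / [(peak − end)/fall time];
  beats with a non-positive downslope are flagged invalid and excluded
  from the window median;
* **end-datum difference** = terminal pulse value − onset value, where the
  terminal value is read 0.15 of the foot-to-foot interval before the next
  onset. Reading *at* the next onset would compare two consecutive minima,
  which are equal for any periodic signal (the quantity would be
  identically zero and carry no stiffness information); the terminal
  reading measures the physiologically meaningful quantity — how far the
  pulse remains above its datum when the next upstroke begins — and grows
  with stiffness as intended.

Fiducial *values* are read from a local quadratic least-squares fit
(±0.1 s) evaluated at the detected index. Reading raw samples at an
argmax/argmin is selection-biased (the chosen sample carries favourable
noise: high at peaks, low at feet), which on the noisy IR channel biases
amplitude upward by amounts comparable to its standard error; the local
fit averages this out. Window aggregation is the median over beats whose
onset and end both lie inside the 10-s window (boundary-spanning beats
belong to no window; medians are used uniformly for robustness, mean
available as an option).

## LDF features

The DC component is operationalized as the window mean of the low-pass
filtered flux (the zero-phase, unit-DC-gain low-pass preserves means, so
this equals the raw window mean up to attenuated high-frequency content).
Per-recording trends are summarized by an ordinary least-squares quadratic
of the 24 window means against window midpoint times (midpoints are the
unbiased single-time representative of a window; one fit per recording).

## Statistics

Pairwise class comparisons use the Kruskal–Wallis rank test (tie-corrected
H, chi-square reference with k−1 df, k=2 machinery for pairs) at
α = 0.05. PPG features are pooled across the three wavelengths before
testing — one p-value per feature and pair, 72 window values per class at
defaults — without per-wavelength standardization (raw pooling mixes
amplitude scales; a `standardize_first`-style pre-transform would change
ranks only across wavelengths, and the rank test needs no scale
alignment for a location shift shared by all channels; raw pooling is the
default, Holm adjustment is available but off, matching the raw-p
convention). LDF flux is tested on its 24 per-window values per class.
Feature ranking correlates per-window values against the recording's
Young's modulus (treated as a continuous covariate with three levels),
retains p < 0.05 and orders by |r|, ties broken by feature name. An
all-identical sample is a degenerate but legal Kruskal–Wallis input and
returns H = 0, p = 1.

## Classification

Feature matrices hold one row per 10-s window — the four PPG features, and
for the multimodal variant the LDF DC mean flux joined on (class, window);
models are trained separately per wavelength. Three binary soft-margin
linear SVMs (C = 1) are combined one-vs-all through the coding matrix
diag(+1) / off-diag(−1); prediction decodes to the codeword with minimal
aggregate hinge loss over the binary decision values, ties to the lowest
class index. Columns are standardized with training-set statistics only
(refit within every CV fold — no leakage). Evaluation: stratified random
70/30 holdout (22 of 72 windows at defaults) for the confusion matrix,
overall accuracy and per-class precision/recall/F1, plus stratified
shuffled 5-fold cross-validation; splits and folds are seeded and the seed
is recorded in the report. Stratification is a deliberate choice — it
guarantees every class in every fold — so reported numbers correspond to
"random split" protocols only up to that refinement.

A geometric caveat documented because it is easy to trip over: with three
*collinear* class centres, the middle class is not linearly separable from
the union of its neighbours, the middle one-vs-all learner degenerates,
and hinge decoding sits at a knife edge on the margin. The phantom feature
set avoids this in practice because its features have unequal relative
gaps (flux and end-datum break the symmetry), and the test fixtures place
synthetic clouds in general position.

## Numerical and reproducibility choices

* All randomness flows from a single integer seed through per-record
  `SeedSequence` streams; datasets, reports and `summary.json` are
  byte-identical across reruns with the same configuration.
* Signal files are two-column CSV (12 significant digits; round-trips to
  <1e-9) with a JSON metadata sidecar; the time column is stored explicitly
  and validated for uniform spacing (1e-6 s tolerance).
* Truncated tail windows are discarded, never padded: per-window statistics
  must rest on equal-duration evidence.
* Degenerate inputs fail loudly and early: config validation runs before
  any computation, windows outside a recording are bounds errors, quadratic
  fits require three distinct times, classifiers require every class in
  training and ≥ 5 rows per class for 5-fold CV.

## Problem sizes

Tests and the acceptance script run the full default factorial (24
recordings, 4 min each; 480 000 PPG samples per record) where the claim
concerns the study conditions, and compact configurations (20–120 s,
reduced replicate counts) for pipeline plumbing, replicate-heavy null
calibrations and robustness sweeps; each test states its own sizes.

## Known limitations

* The synthetic recovery results bound the pipeline's behaviour only under
  the generator's noise model (white + sinusoidal wander); real LDF and
  PPG noise is heavier-tailed and nonstationary.
* The end-datum definition is terminal-elevation-based (see above); other
  conventions (e.g. reading exactly at the next onset) measure a different
  — for periodic signals, degenerate — quantity.
* Slope-ratio is the least stable feature by construction (two-point
  slopes on noisy fiducials); it is retained for completeness, not
  recommended as a stiffness marker.
* The paper-style protocol reports a single holdout split; with 72 windows
  the holdout confusion matrix has coarse (1/22) granularity, which is why
  the cross-validated accuracy is reported alongside it.
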