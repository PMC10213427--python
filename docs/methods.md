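# Methods

This note documents the models, numerical choices and limitations of
`mfdfc` at the level of detail a user needs to interpret its output.

## Frequency-band model

Band edges follow the natural-logarithm ladder: edge n sits at `e^(1/2 − k)`
Hz so that Slow-k spans `[e^(1/2 − k), e^(3/2 − k)]` and neighbouring bands
differ by exactly a factor *e* (a unit step on the log-frequency axis).
Rounded to four decimals this gives Slow-5 = 0.0111–0.0302 Hz and
Slow-4 = 0.0302–0.0821 Hz.  Two rungs round to a different fourth decimal
than the values usually quoted in the applied literature (e⁻²·⁵ = 0.08209 →
0.0821 rather than 0.0820, and e⁻⁵·⁵ = 0.00409 → 0.0041 rather than
0.0040); the ladder is authoritative here and the discrepancy is pure
rounding.  An alternative construction sometimes described — dividing and
multiplying each band's centre frequency by 1.65 — is inconsistent with the
ratio-*e* ladder at the third decimal and is not used.

Applied to a sampled series the ladder is clipped: the top edge to the
Nyquist frequency 1/(2·TR), the bottom to a *minimal reliable frequency*
(default 7.32·10⁻⁴ Hz).  Bands falling entirely outside are dropped.  At
TR = 2 s this yields seven bands, Slow-8 … Slow-2, with Slow-2 clipped to
0.2231–0.25 Hz.  The minimal reliable frequency is a configuration constant
(`min_reliable_hz`); 7.32·10⁻⁴ = 3/4096 Hz·s⁻¹-grid units, i.e. three bins
of the default padded grid, which is a plausible origin for the constant,
but it is deliberately kept a constant rather than a derived quantity.  The
*conservative lowest frequency* 1/(padded_length · TR/2) = 2.44·10⁻⁴ Hz at
the defaults is reported by `conservative_lowest_frequency`.

### Band-pass filtering

`bandpass` demeans the series, zero-pads it to `padded_length` (default
2¹² = 4096), zeroes every DFT coefficient outside `[f_low, f_high)` (the
topmost band is closed at Nyquist; DC is always removed), inverse-transforms
and truncates to the input length.  Numerical notes:

* Demeaning before padding is essential: appending zeros to a nonzero-mean
  series creates a boxcar step whose broadband leakage would contaminate
  every band.  With demeaning, a constant series maps exactly to zero.
* The rectangular mask has edge ringing; comparisons against analytic
  signals should trim ~a window's worth of edge samples.
* Band edges are half-open on the discrete grid so adjacent bands are
  disjoint and their filtered outputs sum to the demeaned input (interior
  relative residual < 1%).
* The mask is a projection, hence exactly idempotent, only while the signal
  stays on the padded grid.  Truncating the output to the input length
  re-introduces a small out-of-band component, so filtering a
  already-filtered series changes it at the ~10% level.  This is inherent
  to truncate-then-repad, not an implementation artifact; the test suite
  asserts exact idempotence on the native grid and approximate idempotence
  with padding.

## ALFF and fALFF

ALFF is the sum of spectral amplitudes √(aₖ² + bₖ²) over the band, divided
by the number of time points; fALFF divides band ALFF by full-range ALFF
(0–Nyquist, DC excluded), giving a scale-invariant fraction in [0, 1].
fALFF is computed on the unfiltered series, with band selection inside the
spectral sum — series are never filtered twice.

The amplitude spectrum is evaluated on the series' **native** frequency
grid by default (`padded_length=None`).  Zero-padding interpolates the
spectrum, spreading each tone's amplitude over many fine bins; because ALFF
sums *amplitudes* rather than power, that redistribution inflates the
out-of-band sum (a pure in-band tone's band fraction drops to ~0.74 under
4096-point padding) and would make fALFF strongly padding-dependent.  On the
native grid a tone with an integer number of cycles yields fALFF exactly 1
in its band and exactly 0 elsewhere, and white noise yields a band fraction
equal to the bandwidth fraction in expectation.  Padding remains available
as an explicit argument for users who want the interpolated grid, and
remains the default where it belongs — the band table and the band-pass
mask, where only mask placement matters.

ROI series are formed by averaging voxel series within each ROI *before*
any amplitude measure (mean-then-fALFF, not fALFF-then-mean).  The two
orders differ for heterogeneous ROIs; mean-then-measure matches how the
connectivity stage must operate (correlations need a single series per ROI)
and is used consistently.

## Sliding-window connectivity

Windows of `width` TRs start at sample 0 and advance by `step` TRs
(defaults 15/20/25/30 and 5); trailing samples not covered by a full window
are dropped, so a 142-point series yields 26/25/24/23 segments at the four
default widths.  Within each window the Pearson correlation of the two
band-passed ROI series is computed.  A zero-variance window has no defined
correlation; it is recorded as 0 with a logged warning (only degenerate
synthetic inputs can produce one).  Feature vectorisation order is frozen —
band block, then segment, then upper-triangle pair (row-major) — and
recorded per column in the matrix's index map, so feature ids are stable
across runs.  Under the Combined scheme each band block is filtered with
its own band; under the Conventional scheme the per-band ROI lists are kept
as separate blocks but filtered with the single 0.01–0.08 Hz band.
Distinct window widths per band are supported (`mixed_window_features`);
blocks with differing segment counts concatenate band-block-wise.

## Feature selection and classification

**RFE ranking.**  A linear support-vector regressor (C = 1) is fit on
z-scored features; the feature with the smallest mean |coefficient| across
`cv_folds` training partitions (default 10, seeded; `cv_folds=1` fits on
the full sample) is eliminated, and the procedure repeats.  The reverse
elimination order is the ranking; each feature's reported weight is its
mean |coefficient| at elimination.  Ties break by ascending column index.
An elimination fraction (`step_fraction`) is available for high-dimensional
matrices; the default removes one feature per iteration.  The regressor's
convergence tolerance is deliberately loose (tol 10⁻³, 3000 iterations):
only the coefficient *order* matters for elimination.

**Top-N sweep.**  For N = 1 … n_max the top-N ranked features are
classified by cross-validated SVM and the best-accuracy N (smallest, on
ties) defines the selected set.  With strong effects and ~92 subjects the
accuracy curve saturates at 1.0 after a handful of features, so the
selected set is a small, high-precision subset of the truly discriminative
features; recovering a *complete* effect set requires aggregating selected
sets across repeated seeded runs, which is how the recovery tests measure
it.

**SVM.**  The default hyperparameter grid has 22 combinations: linear
C ∈ {1, 10, 100, 1000}; polynomial C = 1, degree ∈ {2, 3}; RBF
C ∈ {1, 10, 100, 1000} × γ ∈ {1, 0.1, 0.01, 0.001}.  Per repeat the outer
stratified k-fold assignment is reshuffled (seeded); within each training
fold an inner grid search picks the best combination by CV accuracy, and
metrics come from pooled held-out predictions.  Features are z-scored with
statistics fit on the training folds only (required for the C grid to be
comparable across features).  AUC uses continuous decision scores.
Undefined rates (zero denominators in precision/recall) are reported as
NaN, never silently as 0.

**Leaky vs. leak-free workflows.**  Ranking and sweeping on the full sample
and then reporting the swept CV accuracy — the workflow
selection-then-classification studies typically describe — lets test folds
inform the selection and is optimistic.  Both workflows are provided:
`run_falff_stage` uses the rank-once workflow to identify "abnormal" ROIs
(its purpose is selection, not honest error estimation), while
`nested_cv_accuracy` redoes ranking and the top-N choice inside every
training partition and is the estimate used for null calibration.  On
effect-free cohorts the nested estimate sits within binomial sampling
bounds of 50%; the rank-once estimate generally does not, which is the
point of keeping both.

## Synthetic cohort generator

Defaults mirror a balanced resting-state case/control study: 46 subjects
per group, 90 ROIs, 142 time points at TR = 2 s.  Each ROI series is a sum
of one band-limited component per in-range N3L band — 8 sinusoids at
frequencies drawn uniformly in the band with uniform random phases,
normalised to unit standard deviation — plus white Gaussian noise
(`noise_sd`, default 1.0, i.e. noise variance comparable to a single band's
signal variance).  Component amplitudes are drawn lognormally per
(subject, ROI, band) with σ = `subject_amplitude_sd` (default 0.25),
emulating between-subject amplitude variability; without it fALFF features
are nearly deterministic and any group effect is trivially separable from a
single feature.  Labels are cases-then-controls, optionally shuffled by
seed.  Effects:

* *Amplitude (fALFF) effects* multiply the in-band component amplitude for
  case subjects at stated (ROI, band) targets.  fALFF of such sums is
  analytically predictable, which is why sinusoid mixtures were chosen.
* *Connectivity (dFC) effects* build the in-band components of a stated ROI
  pair from a shared latent component mixed with weight √ρ (sign carried on
  the second ROI for negative ρ), so the pair's expected in-band correlation
  is ρ, group-specific.

Everything is deterministic given the spec (including its seed).  What the
generator deliberately does **not** model: hemodynamic response shape,
scanner drift, motion and physiological artifacts, spatial voxel structure
(an optional writer emits ROI-constant voxel volumes purely to exercise the
NIfTI reader), spatial correlation between ROIs beyond the injected pairs,
and 1/f-shaped background spectra.  Passing the recovery and calibration
tests therefore shows the *pipeline machinery* is sound — effects injected
under the pipeline's own assumptions are found, and absent effects are not
invented — but says nothing about sensitivity on real BOLD data, whose
noise structure is far richer.

## Problem sizes in the test suite

Unit tests run on reduced cohorts (8–24 subjects, 4–12 ROIs) with full-length
142-point series.  The statistical acceptance checks use the full
92 × 90 × 142 cohort shape with: 10 seeded cohorts and a 30-point top-N
sweep under a linear C = 1 probe grid for amplitude-effect recovery; 5
seeded cohorts for pair-count recovery (ranking with a 10% elimination
fraction over the 520-column dFC matrix); and 3 repeats of 10-fold nested
CV for null calibration.  These sizes are the package's own test-scale
choices; all parameters scale up through the public APIs.

## Known limitations

* The printed classification accuracies of any particular real cohort are
  not reproduced here; the real-data path consumes already-preprocessed
  NIfTI volumes and has been validated structurally, not against a
  published cohort.
* The ideal rectangular mask trades passband fidelity for edge ringing; no
  tapered or FIR/IIR alternatives are provided.
* dFC state clustering (k-means "brain states"), tapered windows and
  DCC/GARCH estimators are out of scope.
* The rank-once workflow's accuracies are optimistic by construction; use
  `nested_cv_accuracy` when an unbiased generalisation estimate matters.
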