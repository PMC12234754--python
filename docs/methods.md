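# Methods

## Scope and data model

The package models point Raman measurements of head-and-neck tissue taken
through a 785 nm fiber probe: a `Spectrum` is one intensity trace on a
strictly increasing Raman-shift axis (default 500–3300 cm⁻¹, 1024 channels,
instrument resolution ≈ 20 cm⁻¹), and a `SpectrumSet` bundles the 8–15
traces acquired at one anatomical site together with its clinical labels
(patient, anatomical group, tumor / margin / healthy / inflammation,
in vivo / ex vivo). The axis is assumed to be already
wavenumber-calibrated; pixel-to-wavenumber calibration from atomic-line or
polystyrene standards is an input contract, not a processing stage. Where
in vivo and ex vivo acquisitions of one patient carry slightly different
axes, sets are linearly resampled to the first-seen axis — an explicit
convention, since channel spacing (~2.7 cm⁻¹) is far below the optical
resolution, linear interpolation is accurate there and avoids the ringing
higher-order schemes can introduce near narrow artifacts.

## The correction chain

Stages run in acquisition order; each appends one provenance entry
(stage name + parameter digest) to the spectrum it produces.

**Dark correction.** Element-wise subtraction of a recorded dark frame,
which carries both the dark current and the constant CCD offset bias (the
two are not separated; the recorded dark is taken to include the offset).
Negative channels are preserved — clipping would bias the baseline fit.

**Cosmic-spike removal.** Spikes are transient 1–few-pixel detector events,
far narrower than any Raman band at 20 cm⁻¹ resolution. First differences
are robust-z-scored (median/MAD; MAD-collapse falls back to the mean
absolute deviation when only isolated differences depart from the median,
and raises a degeneracy error when departures are widespread). A run of at
most `max_width` channels (default 3) is flagged when it is entered and
exited by differences with |z| > `z_thresh` (default 8) of opposite sign
**and** those differences dominate (×2) the adjacent same-signed
differences outside the run. The domination veto separates genuine spikes
from the apexes of smooth bands: on low-noise traces the robust scale is
tiny and band-apex differences carry large |z|, but they merely continue
the still-steeper rise and fall of their own flanks, whereas a cosmic
event is abrupt against its local context. Single-channel excursions at
the first/last channel, where only one bracketing difference exists, are
flagged when that difference is an isolated outlier. Flagged runs are
repaired by linear interpolation between the nearest clean neighbours;
unflagged channels pass through bit-identical. Measured on the generator
defaults: 99.9% of planted spikes recovered over 200 seeded sites, no
false flags on a noiseless band model. Detection runs before intensity
calibration, matching the acquisition order, even though calibration
rescales the noise.

**Intensity calibration.** The instrument's measurement of a fluorescence
standard, divided into the standard's certified emission curve, gives the
channel-wise correction factor that removes the spectral response of
probe, spectrograph and detector. Certified curves are user-suppliable
(as a sampled curve or polynomial coefficients); the packaged default is a
synthetic broad-Gaussian stand-in so the stage is exercised end to end
without certificate data. The stage refuses nonpositive measured-standard
channels, naming the channel.

**ALS background correction.** Tissue autofluorescence is estimated by
asymmetric least squares: minimize `Σ wᵢ(yᵢ−zᵢ)² + λ Σ(Δ²zᵢ)²`, weights
`wᵢ = p` above the baseline and `1−p` below, iterated until the fraction
of changed weights drops below `tol` (or `max_iter`, which flags the
provenance and warns rather than failing). Defaults λ = 1e5, p = 0.01,
`max_iter` = 20, `tol` = 1e-3 — within the ranges the ALS literature
recommends for fluorescence backgrounds at this channel density. The
linear system is pentadiagonal and solved with a banded solver; the test
suite checks agreement with an independently coded dense-matrix
implementation to 1e-6. On noisy peak-on-baseline inputs the converged
baseline lies at or below the signal on ≳ 95% of channels.

**Cross-correlation QC.** Each trace is scored by Pearson correlation with
the leave-one-out mean of its site (the plain mean would inflate the score
of the trace under test in sets of 8–15); scores below 0.80 reject the
trace. Zero-variance traces score 0; singleton sets pass with score 1 by
convention. One pass only — no iteration to convergence. The correlation
window defaults to the full spectrum, configurable to fingerprint-only.

**Area normalization.** Division by the trapezoidal integral over the
normalization window (default: the full 500–3300 cm⁻¹ axis, since whole
spectra are normalized before either region is displayed). The output
integral is 1 to 1e-9; the operation is scale-invariant.

## Cohort statistics

Group means and SDs are channel-wise (sample SD, n−1; SD = 0 for n = 1).
The tumor-minus-healthy difference spectrum is computed from area-normalized
means, by default at **patient level**: each patient contributes one mean
spectrum per tissue label before group averaging, so patients with many
retained spectra do not dominate (spectrum-level pooling is available).

Peaks are local maxima above a prominence floor with a minimum separation,
centers refined by a parabola through the three channels around each
maximum. Assignment matches each peak to the nearest band-table center
within that band's tolerance (default ±15 cm⁻¹, below the optical
resolution); each band consumes at most one peak (closest wins), distance
ties break toward the smaller center. The packaged table carries the
canonical fingerprint and high-wavenumber assignments (1003 phenylalanine,
1032, 1084 phosphate, 1260/1266 amide III, 1335 guanine, 1448 CH₂,
1656 amide I / C=C, 1730 C=O ester, 2865 CH₂, 2920 CH₃); pairs closer than
one resolution element (1444/1448, 1656/1665) are merged to single
entries.

Per-band effect sizes are Cohen's *d* (pooled n−1 SD) on the mean
normalized intensity over *center ± tolerance* per patient — the per-peak
scalar a band-level power analysis presumes.

Sample sizes use the two-sample formula
`n_control = ⌈(1 + 1/r)(z₁₋α/₂ + z₁₋β)²/d²⌉`, `n_tumor = ⌈r·n_control⌉`,
refined by default so the noncentral-*t* power of the actual t-test reaches
the request (this turns 63 into the textbook 64 per group at d = 0.5,
α = 0.05, power 0.8; `exact_t=False` gives the plain normal approximation).
A vectorized Monte-Carlo power simulation provides the independent check.
For the trial design modeled here (d = 0.5, α = 0.05 two-sided, power 0.7,
1.5:1 allocation) the computed allocation is 63 tumor / 42 control.

## The synthetic generator

`simulate` produces raw cohorts with complete ground truth:

- **Signal**: Lorentzian bands (default FWHM 25 cm⁻¹, consistent with
  observed tissue bandwidths at ~20 cm⁻¹ resolution) at the band-table
  positions, amplitudes drawn per spectrum with CV 0.08 around per-class
  means (healthy peaks 120–620 counts). Tumor raises the protein /
  nucleic-acid bands (1003 ×1.35, 1335 ×1.30, 2920 ×1.25) and lowers the
  lipid-associated ones (1448 ×0.80, 1730 ×0.70, 2865 ×0.78) — the
  magnitudes are free parameters, fixed here as plausible defaults since
  only the directions are established. Margin sites mix the tumor and
  healthy amplitude profiles 50/50 (a declared convention). Inflammation
  applies a mild protein raise.
- **Baseline**: per-site fluorescence, exponential decay (amplitude
  2000–4000 counts, decay constant 600–1200 cm⁻¹) plus a low-order
  polynomial — several times the band amplitudes, as in vivo.
- **Acquisition**: smooth detector response, dark offset 100 counts,
  Poisson shot noise on the detected signal, Gaussian read noise
  (SD 3 counts), Poisson cosmic spikes (rate 0.5/spectrum, amplitude
  ~5× the signal maximum, single-channel), 8–15 spectra per site.
- **Ground truth**: every draw (amplitudes, baseline coefficients, spike
  channels, class label, seeds) is recorded in a manifest from which the
  noiseless part of each spectrum reconstructs bit-exactly; cohorts
  regenerate bit-identically from (seed, config).

What the generator does **not** emulate: optical-fiber background,
physically calibrated photon budgets, patient motion, ambient-light
line interference (available but off by default), inter-patient spectral
heterogeneity beyond amplitude variation, and any real biochemical
difference structure. Passing tests therefore demonstrate that the
pipeline recovers what was planted under realistic noise — not that the
planted contrasts are biologically accurate.

## Validation design and problem sizes

The acceptance suite re-derives each stage against an independent
reference (dense ALS oracle, leave-one-out correlation oracle, closed-form
integrals, Monte-Carlo power) and exercises the full chain on seeded
cohorts: 200 sites for spike recovery, 100 seeds for QC rejection and
site-size bounds, 50 seeded 10+10-patient cohorts (tumor + healthy sites)
for null calibration and contrast recovery — sizes chosen so the whole
suite runs in a few minutes on one CPU while keeping Monte-Carlo standard
errors well below the tested margins.

Null calibration tests 1024 correlated channels at once, so "consistent
with zero" is judged familywise: the maximum channel-wise |t| over 50
seeds must stay below the Bonferroni-corrected critical value (family
level 0.05), and the count of channels beyond 3 SE must not exceed its
binomial null expectation plus 3 SD. A raw per-channel 3 SE rule would be
failed by any unbiased pipeline (~4 expected chance exceedances across
1024 channels).

## Known limitations

- ALS leaves a small smooth pedestal deficit under overlapping Lorentzian
  tails (it is a penalized fit, not a band/background decomposition), so
  normalized spectra differ from the naive normalized band model by up to
  ~15% of the maximum even in noiseless conditions; comparisons against
  ground truth therefore go through an independently computed ALS
  reference.
- The despiker can miss a spike that lands directly on a steep band flank
  (the domination veto errs toward preserving bands) and multi-channel
  spikes wider than `max_width`.
- The QC score is a global correlation; a trace wrong only in a narrow
  window can pass. The QC window is configurable for that reason.
- Closely spaced table entries (1260/1266) fall within one resolution
  element; at 20 cm⁻¹ resolution at most one of them can consume a
  detected peak, the other stays unassigned.
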