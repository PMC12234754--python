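"""Spectral correction chain from raw CCD counts to cleaned, normalized spectra.

The stages, applied in acquisition-pipeline order:

1. ``subtract_dark`` — remove dark current and the constant CCD offset bias
   using a recorded dark spectrum.
2. ``remove_cosmic_spikes`` — differential (first-difference) detection of
   narrow cosmic-ray events with robust z-scoring, repaired by linear
   interpolation between the nearest clean neighbours.
3. ``intensity_correct`` — relative intensity calibration against a
   NIST-traceable fluorescence standard (SRM-2241 style): the ratio of the
   certified emission curve to the measured standard spectrum is applied
   channelwise, flattening the instrument's spectral response.
4. ``baseline_als`` — asymmetric least squares background estimation
   (Eilers-style): the baseline z minimizes
   ``sum_i w_i (y_i - z_i)^2 + lam * sum_i (D2 z)_i^2`` with asymmetric
   weights ``w_i = p`` where ``y_i > z_i`` else ``1 - p``, iterated to
   convergence.  Tissue autofluorescence is slowly varying, so a heavily
   smoothed, below-the-peaks baseline captures it.
5. ``qc_filter`` — reject traces that do not correlate with the rest of
   their measurement site (uncorrectable background or no Raman signal),
   scored by Pearson correlation against the leave-one-out mean.
6. ``area_normalize`` — scale to unit trapezoidal integral so spectral
   shapes are comparable across acquisitions.

``preprocess_pipeline`` ties the stages together in exactly that order and
emits a QC report.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
from scipy.linalg import solve_banded

from .core import (
    ShapeError,
    Spectrum,
    SpectrumSet,
    WavenumberAxis,
    resample_to_axis,
)

__all__ = [
    "ALSParams",
    "DespikeParams",
    "QCParams",
    "ResponseCurve",
    "PipelineConfig",
    "PipelineResult",
    "CalibrationError",
    "ConfigurationError",
    "NumericDegeneracyError",
    "NormalizationError",
    "PipelineStageError",
    "subtract_dark",
    "remove_cosmic_spikes",
    "intensity_correct",
    "baseline_als",
    "qc_filter",
    "area_normalize",
    "preprocess_pipeline",
    "response_from_polynomial",
]


class CalibrationError(ValueError):
    """Measured calibration standard unusable (nonpositive channel)."""


class ConfigurationError(ValueError):
    """Pipeline inputs missing or inconsistent before any computation."""


class NumericDegeneracyError(ArithmeticError):
    """A robust scale estimate collapsed to zero on nonconstant data."""


class NormalizationError(ValueError):
    """Nonpositive integral in area normalization."""


class PipelineStageError(RuntimeError):
    """Wraps a stage failure with the stage name attached."""

    def __init__(self, stage: str, original: Exception):
        super().__init__(f"stage {stage!r} failed: {original}")
        self.stage = stage
        self.original = original


# ---------------------------------------------------------------------------
# parameter containers
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ALSParams:
    """Asymmetric least squares baseline parameters.

    lam
        Smoothness penalty on the second difference of the baseline;
        larger values give stiffer baselines.  Default 1e5 suits broad
        tissue autofluorescence sampled at ~2.7 cm^-1 per channel.
    p
        Asymmetry weight given to channels above the baseline; must be
        below 0.5 so that the baseline hugs the signal from below.
    max_iter, tol
        Iteration cap and convergence tolerance on the fraction of
        channels whose asymmetric weight changed between iterations.
    """

    lam: float = 1e5
    p: float = 0.01
    max_iter: int = 20
    tol: float = 1e-3

    def __post_init__(self) -> None:
        if not (0 < self.p < 0.5):
            raise ValueError("p must lie in (0, 0.5)")
        if self.lam <= 0:
            raise ValueError("lam must be positive")
        if self.max_iter < 1:
            raise ValueError("max_iter must be >= 1")
        if self.tol <= 0:
            raise ValueError("tol must be positive")

    def to_dict(self) -> dict:
        return {"lam": self.lam, "p": self.p, "max_iter": self.max_iter,
                "tol": self.tol}


@dataclass(frozen=True)
class DespikeParams:
    """Cosmic-spike detector parameters.

    z_thresh is a robust z-score threshold on first differences; max_width
    bounds the spike width in channels (cosmic events span 1-few pixels,
    far narrower than any Raman band at 20 cm^-1 resolution).
    """

    z_thresh: float = 8.0
    max_width: int = 3

    def __post_init__(self) -> None:
        if self.z_thresh <= 0:
            raise ValueError("z_thresh must be positive")
        if not (1 <= self.max_width <= 4):
            raise ValueError("max_width must be in [1, 4]")

    def to_dict(self) -> dict:
        return {"z_thresh": self.z_thresh, "max_width": self.max_width}


@dataclass(frozen=True)
class QCParams:
    """Cross-correlation quality filter parameters."""

    min_correlation: float = 0.80
    max_pass_fraction_drop: float = 0.5

    def __post_init__(self) -> None:
        if not (-1 < self.min_correlation < 1):
            raise ValueError("min_correlation must lie in (-1, 1)")
        if not (0 <= self.max_pass_fraction_drop <= 1):
            raise ValueError("max_pass_fraction_drop must lie in [0, 1]")

    def to_dict(self) -> dict:
        return {"min_correlation": self.min_correlation,
                "max_pass_fraction_drop": self.max_pass_fraction_drop}


@dataclass(frozen=True)
class ResponseCurve:
    """Relative detector sensitivity (or certified emission) vs wavenumber."""

    axis: WavenumberAxis
    relative_sensitivity: np.ndarray
    source: str = "measured_standard"  # or "certified_polynomial"

    def __post_init__(self) -> None:
        v = np.asarray(self.relative_sensitivity, dtype=float)
        object.__setattr__(self, "relative_sensitivity", v)
        if v.size != len(self.axis):
            raise ShapeError("response length != axis length")
        if not np.all(v > 0):
            raise ValueError("relative sensitivity must be strictly positive")
        if self.source not in ("certified_polynomial", "measured_standard"):
            raise ValueError(f"unknown source {self.source!r}")

    def sampled_on(self, axis: WavenumberAxis) -> np.ndarray:
        """Sensitivity values on another axis (linear interpolation)."""
        if axis == self.axis:
            return self.relative_sensitivity
        if axis.values[0] < self.axis.values[0] or axis.values[-1] > self.axis.values[-1]:
            raise CalibrationError("response curve does not cover requested axis")
        return np.interp(axis.values, self.axis.values, self.relative_sensitivity)


def response_from_polynomial(coeffs, axis: WavenumberAxis) -> ResponseCurve:
    """Certified emission curve from polynomial coefficients in wavenumber.

    ``coeffs`` are ordinary polynomial coefficients (highest power first, as
    ``numpy.polyval`` expects) in the normalized variable
    ``u = (nu - nu_min) / (nu_max - nu_min)``; certificate suppliers state
    their own parametrization, so the coefficients are configuration, not
    constants of this package.
    """
    u = (axis.values - axis.values[0]) / (axis.values[-1] - axis.values[0])
    vals = np.polyval(np.asarray(coeffs, dtype=float), u)
    if np.any(vals <= 0):
        raise CalibrationError("certified polynomial nonpositive on axis")
    return ResponseCurve(axis, vals, source="certified_polynomial")


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------

def subtract_dark(raw: Spectrum, dark: Spectrum) -> Spectrum:
    """Subtract a recorded dark spectrum (dark current + CCD offset bias).

    Negative results are preserved — clipping would bias the downstream
    baseline estimate.
    """
    if raw.axis != dark.axis:
        raise ShapeError("raw and dark spectra must share one axis")
    y = raw.intensities - dark.intensities
    return raw.with_stage("subtract_dark", {}, y)


def _robust_z(d: np.ndarray) -> np.ndarray:
    med = np.median(d)
    dev = np.abs(d - med)
    mad = np.median(dev)
    if mad == 0.0:
        # Most differences sit exactly at the median (flat or heavily
        # quantized data).  A few isolated departures are exactly what a
        # cosmic spike on a flat trace looks like, so fall back to the mean
        # absolute deviation; if departures are widespread the robust scale
        # is meaningless and we refuse to guess.
        differing = float(np.mean(dev > 0))
        if differing == 0.0:
            return np.zeros_like(d)
        if differing > 0.25:
            raise NumericDegeneracyError(
                "MAD of first differences is zero on widely nonconstant data"
            )
        return (d - med) / (1.4826 * float(dev.mean()))
    return (d - med) / (1.4826 * mad)


def remove_cosmic_spikes(
    s: Spectrum, params: DespikeParams = DespikeParams()
) -> tuple[Spectrum, np.ndarray]:
    """Flag and repair cosmic-ray spikes; returns (spectrum, boolean mask).

    A spike is a run of at most ``max_width`` channels entered and exited by
    first differences whose robust z-scores exceed ``z_thresh`` with
    opposite signs (a sharp up-down or down-up excursion).  The entry and
    exit differences must also dominate the same-signed differences
    immediately outside the run (factor 2): a cosmic event is abrupt
    against its local context, whereas the apex of a smooth Raman band —
    whose differences can carry large z-scores on nearly noise-free
    traces — continues the steeper rise and fall of its own flanks and is
    left alone.  A single-channel excursion at either end of the spectrum,
    where the second bracketing difference does not exist, is flagged when
    its one difference is an isolated outlier.  Flagged runs are replaced
    by linear
    interpolation between the nearest unflagged neighbours; unflagged
    channels are returned bit-identical.
    """
    n = len(s)
    if n < 2 * params.max_width + 3:
        raise ValueError("spectrum too short for despiking")
    y = s.intensities
    d = np.diff(y)
    mask = np.zeros(n, dtype=bool)
    z = _robust_z(d)
    if np.any(z != 0.0):
        th = params.z_thresh
        m = z.size

        def same_sign_context(k: int, sign: float) -> float:
            # magnitude of the adjacent outside difference if it continues
            # in the same direction; opposite-signed neighbours (e.g. the
            # exit of an adjacent spike) are no context for smoothness
            if 0 <= k < m and z[k] * sign > 0:
                return abs(z[k])
            return 0.0

        i = 0
        while i < m:
            zi = z[i]
            if abs(zi) > th:
                sign = 1.0 if zi > 0 else -1.0
                before = same_sign_context(i - 1, sign)
                # exit difference of opposite sign within max_width channels
                for j in range(i + 1, min(i + params.max_width, m - 1) + 1):
                    if -sign * z[j] > th:
                        after = same_sign_context(j + 1, -sign)
                        if abs(zi) > 2.0 * before and abs(z[j]) > 2.0 * after:
                            mask[i + 1 : j + 1] = True
                            i = j  # resume at the exit difference
                        break
            i += 1
        # single-channel excursions at the spectrum ends: only one
        # bracketing difference exists, flag it when isolated
        if abs(z[0]) > th and abs(z[1]) <= th:
            mask[0] = True
        if abs(z[m - 1]) > th and abs(z[m - 2]) <= th:
            mask[n - 1] = True
    if mask.any():
        idx = np.arange(n)
        repaired = y.copy()
        repaired[mask] = np.interp(idx[mask], idx[~mask], y[~mask])
    else:
        repaired = y
    out = s.with_stage("despike", params.to_dict(), repaired)
    return out, mask


def intensity_correct(
    s: Spectrum, measured_standard: Spectrum, certified: ResponseCurve
) -> Spectrum:
    """Relative intensity calibration against a fluorescence standard.

    The instrument's measurement of the standard, divided into the
    certified emission curve, yields the channelwise correction factor
    that removes the spectral response of probe, spectrograph and CCD.
    """
    if measured_standard.axis != s.axis:
        measured_standard = resample_to_axis(measured_standard, s.axis)
    meas = measured_standard.intensities
    bad = np.flatnonzero(meas <= 0)
    if bad.size:
        nu = s.axis.values[bad[0]]
        raise CalibrationError(
            f"measured standard nonpositive at channel {int(bad[0])} "
            f"({nu:.1f} cm^-1)"
        )
    cert = certified.sampled_on(s.axis)
    y = s.intensities * (cert / meas)
    return s.with_stage("intensity_correct", {"certified_source": certified.source}, y)


@lru_cache(maxsize=8)
def _d2_penalty_diagonals(n: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Diagonals (main, first, second) of D2^T D2 for length-n signals."""
    main = np.full(n, 6.0)
    main[[0, -1]] = 1.0
    main[[1, -2]] = 5.0
    off1 = np.full(n - 1, -4.0)
    off1[[0, -1]] = -2.0
    off2 = np.full(n - 2, 1.0)
    return main, off1, off2


def als_baseline_array(y: np.ndarray, params: ALSParams) -> tuple[np.ndarray, bool]:
    """ALS baseline of a raw array; returns (baseline, converged).

    Solves ``(W + lam * D2^T D2) z = W y`` with a pentadiagonal banded
    solver, updating ``w_i = p`` where ``y_i > z_i`` else ``1 - p`` until
    the fraction of changed weights drops below ``tol``.
    """
    y = np.asarray(y, dtype=float)
    n = y.size
    main, off1, off2 = _d2_penalty_diagonals(n)
    lam = params.lam
    ab = np.zeros((5, n))
    ab[0, 2:] = lam * off2
    ab[1, 1:] = lam * off1
    ab[3, :-1] = lam * off1
    ab[4, :-2] = lam * off2
    w = np.ones(n)
    z = y
    converged = False
    for _ in range(params.max_iter):
        ab[2] = lam * main + w
        z = solve_banded((2, 2), ab, w * y)
        w_new = np.where(y > z, params.p, 1.0 - params.p)
        changed = float(np.mean(w_new != w))
        w = w_new
        if changed < params.tol:
            converged = True
            break
    return z, converged


def baseline_als(
    s: Spectrum, params: ALSParams = ALSParams()
) -> tuple[Spectrum, Spectrum]:
    """Asymmetric least squares background correction.

    Returns ``(corrected, baseline)`` where ``corrected = y - baseline``.
    Non-convergence within ``max_iter`` is recorded in the provenance
    parameters and warned about, but the result is still returned.
    """
    if len(s) < 8:
        raise ValueError("spectrum too short for baseline estimation")
    z, converged = als_baseline_array(s.intensities, params)
    pdict = params.to_dict()
    if not converged:
        pdict["warning"] = "nonconverged"
        warnings.warn("ALS baseline did not converge within max_iter",
                      RuntimeWarning, stacklevel=2)
    corrected = s.with_stage("baseline_als", pdict, s.intensities - z)
    baseline = s.with_stage("baseline_als:baseline", pdict, z)
    return corrected, baseline


def _pearson(a: np.ndarray, b: np.ndarray) -> float:
    """Pearson correlation with the zero-variance convention score 0."""
    a = a - a.mean()
    b = b - b.mean()
    na = float(np.dot(a, a))
    nb = float(np.dot(b, b))
    if na == 0.0 or nb == 0.0:
        return 0.0
    return float(np.dot(a, b) / np.sqrt(na * nb))


def qc_filter(
    spectrum_set: SpectrumSet, params: QCParams = QCParams()
) -> tuple[SpectrumSet, SpectrumSet, np.ndarray]:
    """Cross-correlation cleaning of one measurement site.

    Each spectrum is scored by its Pearson correlation with the
    leave-one-out mean of the set (the plain mean would inflate the score
    of the very trace under test in sets of only 8-15 spectra).  Spectra
    scoring below ``min_correlation`` are rejected.  A singleton set is
    kept with score 1 by convention.
    """
    n = len(spectrum_set)
    if n == 0:
        raise ValueError("cannot QC-filter an empty spectrum set")
    if n == 1:
        return spectrum_set, SpectrumSet(spectrum_set.metadata, []), np.array([1.0])
    mat = spectrum_set.as_matrix()
    total = mat.sum(axis=0)
    scores = np.empty(n)
    for i in range(n):
        loo_mean = (total - mat[i]) / (n - 1)
        scores[i] = _pearson(mat[i], loo_mean)
    keep = scores >= params.min_correlation
    rejected_fraction = 1.0 - keep.mean()
    if rejected_fraction > params.max_pass_fraction_drop:
        warnings.warn(
            f"QC rejected {rejected_fraction:.0%} of the set "
            f"(> {params.max_pass_fraction_drop:.0%})",
            RuntimeWarning, stacklevel=2,
        )
    meta = spectrum_set.metadata
    kept = SpectrumSet(meta, [s for s, k in zip(spectrum_set.spectra, keep) if k])
    rej = SpectrumSet(meta, [s for s, k in zip(spectrum_set.spectra, keep) if not k])
    return kept, rej, scores


def area_normalize(
    s: Spectrum, window: tuple[float, float] | None = None
) -> Spectrum:
    """Scale to unit trapezoidal integral over ``window`` (default: full axis)."""
    x = s.axis.values
    if window is None:
        mask = np.ones(x.size, dtype=bool)
        lo, hi = float(x[0]), float(x[-1])
    else:
        lo, hi = window
        mask = (x >= lo) & (x <= hi)
        if mask.sum() < 2:
            raise NormalizationError(f"window [{lo}, {hi}] covers < 2 channels")
    area = float(np.trapezoid(s.intensities[mask], x[mask]))
    if area <= 0:
        raise NormalizationError(f"nonpositive integral {area:g} over [{lo}, {hi}]")
    return s.with_stage("area_normalize", {"lo": lo, "hi": hi},
                        s.intensities / area)


# ---------------------------------------------------------------------------
# full chain
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PipelineConfig:
    """Per-stage parameters of the full correction chain."""

    als: ALSParams = ALSParams()
    despike: DespikeParams = DespikeParams()
    qc: QCParams = QCParams()
    normalization_window: tuple[float, float] | None = None
    qc_window: tuple[float, float] | None = None

    def to_dict(self) -> dict:
        return {
            "als": self.als.to_dict(),
            "despike": self.despike.to_dict(),
            "qc": self.qc.to_dict(),
            "normalization_window": self.normalization_window,
            "qc_window": self.qc_window,
        }


@dataclass
class PipelineResult:
    """Outcome of ``preprocess_pipeline`` for one measurement site."""

    processed: SpectrumSet
    rejected: SpectrumSet
    qc_scores: np.ndarray
    spike_masks: list[np.ndarray]
    report: dict = field(default_factory=dict)


def preprocess_pipeline(
    raw_set: SpectrumSet,
    dark: Spectrum,
    measured_standard: Spectrum,
    certified: ResponseCurve,
    config: PipelineConfig = PipelineConfig(),
) -> PipelineResult:
    """Run the full correction chain on one site, in acquisition order.

    dark subtraction -> cosmic-spike removal -> intensity calibration ->
    ALS background correction -> cross-correlation QC -> area
    normalization.  Stage failures are re-raised with the stage name
    attached; a per-site QC report (scores, kept/rejected, stage parameter
    digests) is returned alongside the cleaned set.
    """
    if dark is None:
        raise ConfigurationError("dark spectrum is required")
    if measured_standard is None or certified is None:
        raise ConfigurationError("calibration standard (measured + certified) required")
    if len(raw_set) == 0:
        raise ConfigurationError("empty spectrum set")

    def _stage(name, fn, *args):
        try:
            return fn(*args)
        except Exception as exc:  # attach stage name, keep the original
            raise PipelineStageError(name, exc) from exc

    spike_masks: list[np.ndarray] = []
    corrected: list[Spectrum] = []
    for s in raw_set.spectra:
        s1 = _stage("subtract_dark", subtract_dark, s, dark)
        s2, mask = _stage("despike", remove_cosmic_spikes, s1, config.despike)
        spike_masks.append(mask)
        s3 = _stage("intensity_correct", intensity_correct, s2,
                    measured_standard, certified)
        s4, _ = _stage("baseline_als", baseline_als, s3, config.als)
        corrected.append(s4)

    site = SpectrumSet(raw_set.metadata, corrected)
    if config.qc_window is not None:
        lo, hi = config.qc_window
        windowed = SpectrumSet(raw_set.metadata,
                               [crop_s for crop_s in (_window(s, lo, hi) for s in corrected)])
        _, _, scores = _stage("qc_filter", qc_filter, windowed, config.qc)
        keep = scores >= config.qc.min_correlation
        kept = SpectrumSet(site.metadata,
                           [s for s, k in zip(site.spectra, keep) if k])
        rejected = SpectrumSet(site.metadata,
                               [s for s, k in zip(site.spectra, keep) if not k])
    else:
        kept, rejected, scores = _stage("qc_filter", qc_filter, site, config.qc)

    normalized = [
        _stage("area_normalize", area_normalize, s, config.normalization_window)
        for s in kept.spectra
    ]
    processed = SpectrumSet(site.metadata, normalized)
    report = {
        "site": raw_set.metadata.to_dict(),
        "n_input": len(raw_set),
        "n_kept": len(processed),
        "n_rejected": len(rejected),
        "qc_scores": [float(v) for v in scores],
        "spike_channels": [np.flatnonzero(m).tolist() for m in spike_masks],
        "stage_params": config.to_dict(),
    }
    return PipelineResult(processed, rejected, scores, spike_masks, report)


def _window(s: Spectrum, lo: float, hi: float) -> Spectrum:
    from .core import crop

    return crop(s, lo, hi)
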