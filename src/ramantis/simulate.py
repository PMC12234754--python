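"""Forward model for fiber-probe tissue Raman spectra with ground truth.

Emulates intraoperative point measurements through a 785 nm fiber probe:
a handful of Lorentzian Raman bands at the canonical fingerprint and
high-wavenumber positions riding on a strong, slowly varying tissue
autofluorescence baseline, filtered by a smooth detector response, offset
by dark counts, and degraded by Poisson shot noise, Gaussian read noise
and occasional single-pixel cosmic spikes.  Tumor tissue raises
protein/nucleic-acid band amplitudes (1003, 1335, 2920 cm^-1) and lowers
lipid-associated ones (1448, 1730, 2865 cm^-1) relative to healthy
tissue; margin sites mix the two amplitude profiles 50/50.

Every random draw is seeded and recorded in a ground-truth manifest from
which the noiseless part of each spectrum can be reconstructed bit-exactly,
so each preprocessing stage can be tested against known truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .core import SiteMetadata, Spectrum, SpectrumSet, WavenumberAxis
from .preprocess import ResponseCurve

__all__ = [
    "SimBand",
    "BaselineFamily",
    "TissueModel",
    "AcquisitionModel",
    "CohortConfig",
    "simulate_spectrum",
    "simulate_site",
    "simulate_cohort",
    "reconstruct_noiseless",
    "default_certified_emission",
]

_MAX_SEED = 2**31 - 1


@dataclass(frozen=True)
class SimBand:
    """One planted Raman band: Lorentzian shape + per-class amplitude model.

    ``fwhm`` is the full width at half maximum in cm^-1 (>= half the
    instrument resolution); amplitudes are peak heights in detector counts
    before the response curve; ``cv`` is the coefficient of variation of
    the per-spectrum amplitude draw.
    """

    center: float
    fwhm: float = 25.0
    amp_healthy: float = 300.0
    amp_tumor: float = 300.0
    amp_inflammation: float = 300.0
    cv: float = 0.08

    def __post_init__(self) -> None:
        if self.fwhm < 10.0:
            raise ValueError("band width must be >= resolution_hint / 2")
        if min(self.amp_healthy, self.amp_tumor, self.amp_inflammation) < 0:
            raise ValueError("amplitudes must be nonnegative")

    def mean_amplitude(self, class_label: str) -> float:
        if class_label == "healthy":
            return self.amp_healthy
        if class_label == "tumor":
            return self.amp_tumor
        if class_label == "inflammation":
            return self.amp_inflammation
        if class_label == "margin":  # transitional zone: 50/50 mix
            return 0.5 * (self.amp_tumor + self.amp_healthy)
        raise ValueError(f"unknown tissue class {class_label!r}")


@dataclass(frozen=True)
class BaselineFamily:
    """Smooth fluorescence model: exponential decay + quadratic polynomial.

    Coefficients are drawn uniformly from the stated ranges once per
    measurement site — autofluorescence varies between sites much more
    than between consecutive acquisitions at one site.
    """

    exp_amp: tuple[float, float] = (2000.0, 4000.0)
    exp_tau: tuple[float, float] = (600.0, 1200.0)
    c0: tuple[float, float] = (150.0, 400.0)
    c1: tuple[float, float] = (-100.0, 100.0)
    c2: tuple[float, float] = (-50.0, 50.0)

    def draw(self, rng: np.random.Generator) -> dict[str, float]:
        return {
            "exp_amp": float(rng.uniform(*self.exp_amp)),
            "exp_tau": float(rng.uniform(*self.exp_tau)),
            "c0": float(rng.uniform(*self.c0)),
            "c1": float(rng.uniform(*self.c1)),
            "c2": float(rng.uniform(*self.c2)),
        }

    @staticmethod
    def evaluate(coeffs: dict[str, float], axis: WavenumberAxis) -> np.ndarray:
        nu = axis.values
        u = (nu - nu[0]) / (nu[-1] - nu[0])
        return (coeffs["exp_amp"] * np.exp(-(nu - nu[0]) / coeffs["exp_tau"])
                + coeffs["c0"] + coeffs["c1"] * u + coeffs["c2"] * u**2)


def _default_bands() -> tuple[SimBand, ...]:
    # (center, healthy amplitude, tumor multiplier, inflammation multiplier)
    spec = [
        (1003.0, 420.0, 1.35, 1.12),
        (1032.0, 220.0, 1.00, 1.00),
        (1084.0, 230.0, 1.00, 1.00),
        (1260.0, 210.0, 1.00, 1.00),
        (1266.0, 180.0, 1.00, 1.00),
        (1335.0, 200.0, 1.30, 1.00),
        (1448.0, 380.0, 0.80, 1.00),
        (1656.0, 360.0, 1.00, 1.00),
        (1730.0, 120.0, 0.70, 1.00),
        (2865.0, 520.0, 0.78, 1.00),
        (2920.0, 620.0, 1.25, 1.08),
    ]
    return tuple(
        SimBand(center=c, amp_healthy=a, amp_tumor=a * mt, amp_inflammation=a * mi)
        for c, a, mt, mi in spec
    )


@dataclass(frozen=True)
class TissueModel:
    """Planted band table plus fluorescence baseline family."""

    bands: tuple[SimBand, ...] = field(default_factory=_default_bands)
    baseline: BaselineFamily = BaselineFamily()

    def with_contrasts_zeroed(self) -> "TissueModel":
        """All classes share the healthy amplitude profile (null model)."""
        return TissueModel(
            bands=tuple(
                replace(b, amp_tumor=b.amp_healthy, amp_inflammation=b.amp_healthy)
                for b in self.bands
            ),
            baseline=self.baseline,
        )

    def band_profiles(self, axis: WavenumberAxis) -> np.ndarray:
        """Unit-amplitude Lorentzian profile per band, shape (n_bands, n_ch)."""
        nu = axis.values[None, :]
        centers = np.array([b.center for b in self.bands])[:, None]
        gamma = np.array([b.fwhm / 2.0 for b in self.bands])[:, None]
        return gamma**2 / ((nu - centers) ** 2 + gamma**2)


def _default_response(axis: WavenumberAxis) -> ResponseCurve:
    nu = axis.values
    sens = 0.6 + 0.4 * np.exp(-(((nu - 1800.0) / 1200.0) ** 2))
    return ResponseCurve(axis, sens, source="measured_standard")


def default_certified_emission(axis: WavenumberAxis) -> ResponseCurve:
    """Synthetic stand-in for a certified fluorescence-standard emission curve.

    A broad Gaussian emission profile, strictly positive over the axis.
    Real certificates supply their own polynomial; this curve exists so the
    calibration stage is exercised end to end without certificate data.
    """
    nu = axis.values
    em = np.exp(-(((nu - 1600.0) / 1800.0) ** 2))
    return ResponseCurve(axis, em, source="certified_polynomial")


@dataclass(frozen=True)
class AcquisitionModel:
    """Instrument model: axis, response, dark, noise and spike statistics."""

    axis: WavenumberAxis = field(default_factory=WavenumberAxis.default)
    dark_offset: float = 100.0
    response: ResponseCurve | None = None
    read_noise_sd: float = 3.0
    shot_noise: bool = True
    spike_rate: float = 0.5
    spike_amplitude: float = 5.0
    spectra_per_site: tuple[int, int] = (8, 15)
    #: optional ambient-light interference: (center cm^-1, amplitude counts,
    #: FWHM cm^-1) narrow lines added to the detected signal; default none
    ambient_lines: tuple[tuple[float, float, float], ...] = ()

    def __post_init__(self) -> None:
        if self.spike_rate < 0:
            raise ValueError("spike_rate must be >= 0")
        lo, hi = self.spectra_per_site
        if not (1 <= lo <= hi):
            raise ValueError("invalid spectra_per_site range")
        if self.response is None:
            object.__setattr__(self, "response", _default_response(self.axis))

    def response_values(self) -> np.ndarray:
        return self.response.sampled_on(self.axis)

    def dark_spectrum(self) -> Spectrum:
        """The recorded (master, noise-averaged) dark frame."""
        return Spectrum(self.axis, np.full(len(self.axis), self.dark_offset),
                        [("simulate:dark", "")])

    def measured_standard(self, certified: ResponseCurve | None = None) -> Spectrum:
        """What the instrument records measuring the calibration standard
        (dark-corrected): certified emission times the spectral response."""
        if certified is None:
            certified = default_certified_emission(self.axis)
        y = self.response_values() * certified.sampled_on(self.axis)
        return Spectrum(self.axis, y, [("simulate:standard", "")])


# ---------------------------------------------------------------------------
# generators
# ---------------------------------------------------------------------------

def simulate_spectrum(
    tissue: TissueModel,
    acq: AcquisitionModel,
    class_label: str,
    seed: int,
    baseline_coeffs: dict[str, float] | None = None,
) -> tuple[Spectrum, dict]:
    """One raw spectrum plus its ground-truth manifest entry.

    ``spectrum = response * (sum of band Lorentzians + baseline)
    + dark_offset + shot/read noise + cosmic spikes``; fully determined by
    ``seed``.  Site-level baseline coefficients may be supplied; otherwise
    they are drawn here.
    """
    rng = np.random.default_rng(seed)
    if baseline_coeffs is None:
        baseline_coeffs = tissue.baseline.draw(rng)
    means = np.array([b.mean_amplitude(class_label) for b in tissue.bands])
    cvs = np.array([b.cv for b in tissue.bands])
    amps = means * np.maximum(0.0, 1.0 + cvs * rng.standard_normal(means.size))

    profiles = tissue.band_profiles(acq.axis)
    signal = amps @ profiles + BaselineFamily.evaluate(baseline_coeffs, acq.axis)
    detected = acq.response_values() * signal + _ambient(acq)

    if acq.shot_noise:
        counts = rng.poisson(np.maximum(detected, 0.0)).astype(float)
    else:
        counts = detected
    y = counts + acq.dark_offset
    if acq.read_noise_sd > 0:
        y = y + rng.normal(0.0, acq.read_noise_sd, y.size)

    n_spikes = int(rng.poisson(acq.spike_rate))
    spike_channels: list[int] = []
    spike_heights: list[float] = []
    if n_spikes > 0:
        chans = rng.integers(0, y.size, n_spikes)
        base_height = acq.spike_amplitude * float(detected.max())
        for c in chans:
            h = base_height * float(rng.uniform(0.5, 1.5))
            y[int(c)] += h
            spike_channels.append(int(c))
            spike_heights.append(h)

    entry = {
        "seed": int(seed),
        "class_label": class_label,
        "amplitudes": {f"{b.center:g}": float(a)
                       for b, a in zip(tissue.bands, amps)},
        "baseline_coeffs": baseline_coeffs,
        "spike_channels": spike_channels,
        "spike_heights": spike_heights,
    }
    return Spectrum(acq.axis, y, [("simulate", str(seed))]), entry


def _ambient(acq: AcquisitionModel) -> np.ndarray:
    """Deterministic ambient-light line interference on the detector."""
    out = np.zeros(len(acq.axis))
    nu = acq.axis.values
    for center, amplitude, fwhm in acq.ambient_lines:
        sigma = fwhm / 2.355
        out += amplitude * np.exp(-0.5 * ((nu - center) / sigma) ** 2)
    return out


def reconstruct_noiseless(
    tissue: TissueModel, acq: AcquisitionModel, entry: dict
) -> np.ndarray:
    """Bit-exact noiseless part of a manifest entry's spectrum."""
    amps = np.array([entry["amplitudes"][f"{b.center:g}"] for b in tissue.bands])
    signal = amps @ tissue.band_profiles(acq.axis) + BaselineFamily.evaluate(
        entry["baseline_coeffs"], acq.axis
    )
    return acq.response_values() * signal + _ambient(acq) + acq.dark_offset


def simulate_site(
    tissue: TissueModel,
    acq: AcquisitionModel,
    metadata: SiteMetadata,
    seed: int,
) -> tuple[SpectrumSet, dict]:
    """All spectra of one measurement site (8-15 by default).

    The spectrum count is uniform over ``acq.spectra_per_site``; baseline
    coefficients are drawn once per site and shared across its spectra.
    """
    rng = np.random.default_rng(seed)
    lo, hi = acq.spectra_per_site
    n = int(rng.integers(lo, hi + 1))
    coeffs = tissue.baseline.draw(rng)
    child_seeds = rng.integers(0, _MAX_SEED, n)
    spectra, entries = [], []
    for cs in child_seeds:
        s, e = simulate_spectrum(tissue, acq, metadata.tissue_label, int(cs),
                                 baseline_coeffs=coeffs)
        spectra.append(s)
        entries.append(e)
    manifest = {
        "site_seed": int(seed),
        "metadata": metadata.to_dict(),
        "n_spectra": n,
        "entries": entries,
    }
    return SpectrumSet(metadata, spectra), manifest


@dataclass(frozen=True)
class CohortConfig:
    """Cohort layout: patients per anatomical group and sites per patient."""

    patients_per_group: tuple[tuple[str, int], ...] = (
        ("oral cavity", 10), ("oropharynx", 10),
    )
    sites_per_patient: tuple[str, ...] = ("tumor", "margin", "healthy")
    subgroups: tuple[tuple[str, str], ...] = (
        ("oral cavity", "tongue"), ("oropharynx", "tonsil"),
        ("larynx", "glottis"), ("hypopharynx", "sinus piriformis"),
    )

    def __post_init__(self) -> None:
        if not self.patients_per_group or sum(n for _, n in self.patients_per_group) == 0:
            raise ValueError("cohort config lists no patients")
        if not self.sites_per_patient:
            raise ValueError("cohort config lists no sites per patient")

    def subgroup_of(self, group: str) -> str:
        return dict(self.subgroups).get(group, "")

    def to_dict(self) -> dict:
        return {
            "patients_per_group": [list(t) for t in self.patients_per_group],
            "sites_per_patient": list(self.sites_per_patient),
        }


def simulate_cohort(
    config: CohortConfig,
    seed: int,
    tissue: TissueModel | None = None,
    acq: AcquisitionModel | None = None,
) -> tuple[list[SpectrumSet], dict]:
    """A full synthetic cohort (default: 10 + 10 patients, 3 sites each)."""
    tissue = tissue if tissue is not None else TissueModel()
    acq = acq if acq is not None else AcquisitionModel()
    rng = np.random.default_rng(seed)
    sites: list[SpectrumSet] = []
    site_manifests: list[dict] = []
    pnum = 0
    for group, n_patients in config.patients_per_group:
        for _ in range(n_patients):
            pnum += 1
            pid = f"P{pnum:03d}"
            for label in config.sites_per_patient:
                meta = SiteMetadata(
                    patient_id=pid,
                    anatomical_group=group,
                    tissue_label=label,
                    subgroup=config.subgroup_of(group),
                )
                site_seed = int(rng.integers(0, _MAX_SEED))
                st, man = simulate_site(tissue, acq, meta, site_seed)
                sites.append(st)
                site_manifests.append(man)
    manifest = {
        "seed": int(seed),
        "config": config.to_dict(),
        "n_patients": pnum,
        "n_sites": len(sites),
        "sites": site_manifests,
    }
    return sites, manifest
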