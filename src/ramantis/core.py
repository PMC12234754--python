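"""Core containers for point Raman spectra of tissue.

A measurement consists of several raw CCD traces taken at one anatomical
site through a fiber-optic probe.  Everything downstream (dark correction,
despiking, intensity calibration, baseline removal, QC, normalization,
cohort statistics) operates on the types defined here:

``WavenumberAxis``
    the Raman-shift axis in cm^-1, strictly increasing.
``Spectrum``
    one intensity trace on an axis, carrying a provenance trail of the
    processing stages applied to it.
``SiteMetadata`` / ``SpectrumSet``
    the 8-15 spectra of one measurement site plus its clinical labels.
``PatientRecord``
    one row of a cohort table (group, subgroup, TNM stage, histopathology).

The axis is assumed to be already wavenumber-calibrated (relative to
785 nm excitation); pixel-to-wavenumber calibration from atomic-line or
polystyrene standards is an input contract, not something this package
performs.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

__all__ = [
    "ANATOMICAL_GROUPS",
    "TISSUE_LABELS",
    "MODALITIES",
    "WavenumberAxis",
    "Spectrum",
    "SiteMetadata",
    "SpectrumSet",
    "PatientRecord",
    "resample_to_axis",
    "crop",
    "ShapeError",
    "RangeError",
]

#: Closed vocabulary of head-and-neck anatomical groups.
ANATOMICAL_GROUPS = ("oral cavity", "oropharynx", "larynx", "hypopharynx")
#: Closed vocabulary of tissue labels assigned at a measurement site.
TISSUE_LABELS = ("tumor", "margin", "healthy", "inflammation")
MODALITIES = ("in_vivo", "ex_vivo")


class ShapeError(ValueError):
    """Axes or array lengths do not match."""


class RangeError(ValueError):
    """A wavenumber window falls outside the spectrum's axis."""


def _params_digest(params: dict) -> str:
    """Stable 12-hex digest of a parameter mapping (order independent)."""
    blob = json.dumps(params, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


@dataclass(frozen=True)
class WavenumberAxis:
    """Raman-shift axis in cm^-1.

    Parameters
    ----------
    values
        Strictly increasing Raman shifts, one per detector channel, all in
        [0, 4000] cm^-1, length >= 8.
    resolution_hint
        Instrument spectral resolution in cm^-1 (default 20, the resolution
        of the fiber-probe system this package models).
    """

    values: np.ndarray
    resolution_hint: float = 20.0

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", v)
        if v.ndim != 1 or v.size < 8:
            raise ValueError("axis needs at least 8 channels")
        if not np.all(np.diff(v) > 0):
            raise ValueError("axis must be strictly increasing")
        if v[0] < 0 or v[-1] > 4000:
            raise ValueError("axis values must lie within [0, 4000] cm^-1")

    def __len__(self) -> int:
        return self.values.size

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, WavenumberAxis):
            return NotImplemented
        return self.values.shape == other.values.shape and np.array_equal(
            self.values, other.values
        )

    def __hash__(self) -> int:  # frozen dataclass with array field
        return hash((self.values.size, float(self.values[0]), float(self.values[-1])))

    @property
    def spacing(self) -> float:
        """Median channel spacing in cm^-1."""
        return float(np.median(np.diff(self.values)))

    @classmethod
    def default(cls, n_channels: int = 1024, lo: float = 500.0,
                hi: float = 3300.0, resolution_hint: float = 20.0) -> "WavenumberAxis":
        """The 500-3300 cm^-1 axis used throughout, 1024 channels."""
        return cls(np.linspace(lo, hi, n_channels), resolution_hint)


@dataclass
class Spectrum:
    """One intensity trace on a wavenumber axis with processing provenance.

    ``provenance`` is an append-only list of ``(stage_name, params_digest)``
    pairs; every processing stage appends exactly one entry, so the trail
    records the full history of the trace.
    """

    axis: WavenumberAxis
    intensities: np.ndarray
    provenance: list[tuple[str, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        y = np.asarray(self.intensities, dtype=float)
        if y.ndim != 1 or y.size != len(self.axis):
            raise ShapeError(
                f"intensities length {y.size} != axis length {len(self.axis)}"
            )
        if not np.all(np.isfinite(y)):
            raise ValueError("intensities must be finite")
        self.intensities = y

    def __len__(self) -> int:
        return self.intensities.size

    def with_stage(self, stage: str, params: dict, intensities: np.ndarray,
                   axis: WavenumberAxis | None = None) -> "Spectrum":
        """Return a new spectrum with one provenance entry appended."""
        return Spectrum(
            axis=axis if axis is not None else self.axis,
            intensities=np.asarray(intensities, dtype=float),
            provenance=[*self.provenance, (stage, _params_digest(params))],
        )

    def copy(self) -> "Spectrum":
        return Spectrum(self.axis, self.intensities.copy(), list(self.provenance))


@dataclass(frozen=True)
class SiteMetadata:
    """Clinical labels of one measurement site."""

    patient_id: str
    anatomical_group: str
    tissue_label: str
    subgroup: str = ""
    modality: str = "in_vivo"

    def __post_init__(self) -> None:
        if self.anatomical_group not in ANATOMICAL_GROUPS:
            raise ValueError(
                f"unknown anatomical_group {self.anatomical_group!r}; "
                f"expected one of {ANATOMICAL_GROUPS}"
            )
        if self.tissue_label not in TISSUE_LABELS:
            raise ValueError(
                f"unknown tissue_label {self.tissue_label!r}; "
                f"expected one of {TISSUE_LABELS}"
            )
        if self.modality not in MODALITIES:
            raise ValueError(f"unknown modality {self.modality!r}")

    def to_dict(self) -> dict:
        return {
            "patient_id": self.patient_id,
            "anatomical_group": self.anatomical_group,
            "subgroup": self.subgroup,
            "tissue_label": self.tissue_label,
            "modality": self.modality,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SiteMetadata":
        return cls(
            patient_id=d["patient_id"],
            anatomical_group=d["anatomical_group"],
            tissue_label=d["tissue_label"],
            subgroup=d.get("subgroup", ""),
            modality=d.get("modality", "in_vivo"),
        )


@dataclass
class SpectrumSet:
    """The spectra collected at one measurement site, sharing one axis."""

    metadata: SiteMetadata
    spectra: list[Spectrum]

    def __post_init__(self) -> None:
        if self.spectra:
            axis = self.spectra[0].axis
            for s in self.spectra[1:]:
                if s.axis != axis:
                    raise ShapeError("all spectra of a set must share one axis")

    def __len__(self) -> int:
        return len(self.spectra)

    @property
    def axis(self) -> WavenumberAxis:
        if not self.spectra:
            raise ValueError("empty spectrum set has no axis")
        return self.spectra[0].axis

    def as_matrix(self) -> np.ndarray:
        """Stack intensities into an (n_spectra, n_channels) array."""
        return np.vstack([s.intensities for s in self.spectra])


@dataclass(frozen=True)
class PatientRecord:
    """One row of a cohort table: staging and histopathological outcome."""

    number: int
    group: str
    subgroup: str
    tnm: str
    histopathology: str

    def __post_init__(self) -> None:
        if self.group not in ANATOMICAL_GROUPS:
            raise ValueError(
                f"unknown group {self.group!r}; expected one of {ANATOMICAL_GROUPS}"
            )


# ---------------------------------------------------------------------------
# axis operations
# ---------------------------------------------------------------------------

def resample_to_axis(s: Spectrum, target: WavenumberAxis) -> Spectrum:
    """Linearly interpolate a spectrum onto ``target``.

    The target range must lie inside the source range; extrapolation is
    refused because the probe records nothing outside its spectral window.
    """
    src = s.axis.values
    tgt = target.values
    if tgt[0] < src[0] or tgt[-1] > src[-1]:
        raise RangeError(
            f"target range [{tgt[0]:g}, {tgt[-1]:g}] extends beyond "
            f"source range [{src[0]:g}, {src[-1]:g}]"
        )
    y = np.interp(tgt, src, s.intensities)
    params = {"target_lo": float(tgt[0]), "target_hi": float(tgt[-1]),
              "target_n": int(tgt.size)}
    return s.with_stage("resample", params, y, axis=target)


def crop(s: Spectrum, lo: float, hi: float) -> Spectrum:
    """Keep channels with ``lo <= wavenumber <= hi`` (order preserved)."""
    if lo >= hi:
        raise RangeError(f"invalid window: lo={lo} >= hi={hi}")
    mask = (s.axis.values >= lo) & (s.axis.values <= hi)
    if int(mask.sum()) == 0:
        raise RangeError(
            f"window [{lo}, {hi}] does not overlap axis "
            f"[{s.axis.values[0]:g}, {s.axis.values[-1]:g}]"
        )
    new_axis = WavenumberAxis(s.axis.values[mask], s.axis.resolution_hint)
    return s.with_stage("crop", {"lo": lo, "hi": hi}, s.intensities[mask],
                        axis=new_axis)


def common_axis(sets: Sequence[SpectrumSet]) -> WavenumberAxis:
    """First-seen axis of a collection; used as resampling target."""
    for st in sets:
        if len(st):
            return st.axis
    raise ValueError("no spectra in collection")
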