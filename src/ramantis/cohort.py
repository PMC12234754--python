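"""Group-level statistics for tissue Raman cohorts.

Covers what a feasibility-stage clinical Raman study reports before any
classifier is trained: per-group mean and standard-deviation spectra, the
tumor-minus-healthy difference spectrum, peak detection with band
assignment against a molecular band table, per-band Cohen's d effect
sizes, and the two-sample sample-size computation used for trial planning.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
from scipy.signal import find_peaks
from scipy.stats import norm

from .core import ShapeError, Spectrum, SpectrumSet

__all__ = [
    "BandAssignment",
    "Peak",
    "CohortSummary",
    "PowerSpec",
    "DegenerateVarianceError",
    "default_band_table",
    "load_band_table",
    "group_mean_sd",
    "difference_spectrum",
    "detect_peaks",
    "assign_bands",
    "band_effect_size",
    "band_scalar",
    "required_sample_size",
    "monte_carlo_power",
    "summarize_cohort",
]


class DegenerateVarianceError(ArithmeticError):
    """Pooled standard deviation is zero; effect size undefined."""


@dataclass(frozen=True)
class BandAssignment:
    """A named molecular band: center, matching tolerance and label.

    Tolerance defaults to 15 cm^-1 — below the ~20 cm^-1 instrument
    resolution, so positional deviations within it are not significant.
    """

    center: float
    assignment: str
    region: str = "fingerprint"
    tolerance: float = 15.0

    def __post_init__(self) -> None:
        if not (500 <= self.center <= 3300):
            raise ValueError("band center must lie in [500, 3300] cm^-1")
        if not (0 < self.tolerance <= 20):
            raise ValueError("tolerance must be in (0, resolution_hint]")
        if self.region not in ("fingerprint", "high_wavenumber"):
            raise ValueError(f"unknown region {self.region!r}")


@dataclass(frozen=True)
class Peak:
    """A detected spectral peak (parabolically refined center)."""

    center: float
    height: float
    prominence: float


def load_band_table(path) -> list[BandAssignment]:
    """Read a band table from delimited text (center, tolerance, region, assignment)."""
    bands: list[BandAssignment] = []
    with open(path) as fh:
        for raw in fh:
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if parts[0].lower() == "center":
                continue
            center, tolerance, region, assignment = parts[:4]
            bands.append(BandAssignment(float(center), assignment, region,
                                        float(tolerance)))
    centers = [b.center for b in bands]
    if len(set(centers)) != len(centers):
        raise ValueError("band table centers must be unique")
    return bands


def default_band_table() -> list[BandAssignment]:
    """The packaged fingerprint + high-wavenumber band table.

    Entries separated by less than one resolution element (CH2 bending at
    1444/1448; amide I / C=C at 1656/1665) are merged to single bands.
    """
    ref = resources.files("ramantis.data").joinpath("band_table.tsv")
    with resources.as_file(ref) as path:
        return load_band_table(path)


# ---------------------------------------------------------------------------
# group statistics
# ---------------------------------------------------------------------------

def group_mean_sd(spectra: list[Spectrum]) -> tuple[Spectrum, Spectrum]:
    """Channelwise mean and sample SD (n-1 denominator; n=1 gives SD=0)."""
    if not spectra:
        raise ValueError("need at least one spectrum")
    axis = spectra[0].axis
    for s in spectra[1:]:
        if s.axis != axis:
            raise ShapeError("spectra must share one axis")
    mat = np.vstack([s.intensities for s in spectra])
    mean = mat.mean(axis=0)
    sd = mat.std(axis=0, ddof=1) if mat.shape[0] > 1 else np.zeros(mat.shape[1])
    return (Spectrum(axis, mean, [("group_mean", str(mat.shape[0]))]),
            Spectrum(axis, sd, [("group_sd", str(mat.shape[0]))]))


def difference_spectrum(tumor_mean: Spectrum, healthy_mean: Spectrum) -> Spectrum:
    """Tumor-minus-healthy difference of two (area-normalized) mean spectra."""
    if tumor_mean.axis != healthy_mean.axis:
        raise ShapeError("difference requires identical axes")
    return Spectrum(tumor_mean.axis,
                    tumor_mean.intensities - healthy_mean.intensities,
                    [("difference", "tumor-healthy")])


# ---------------------------------------------------------------------------
# peaks and bands
# ---------------------------------------------------------------------------

def detect_peaks(
    s: Spectrum, min_prominence: float, min_separation_cm: float
) -> list[Peak]:
    """Local maxima above a prominence floor, parabolically refined.

    Centers are refined by fitting a parabola through the three channels
    around each maximum, recovering sub-channel positions (the channel
    spacing, ~2.7 cm^-1 on the default axis, is far below instrument
    resolution, but refinement removes discretization bias).
    """
    x = s.axis.values
    y = s.intensities
    spacing = s.axis.spacing
    if min_separation_cm < spacing:
        raise ValueError("min_separation below channel spacing")
    distance = max(1, int(round(min_separation_cm / spacing)))
    idx, props = find_peaks(y, prominence=min_prominence, distance=distance)
    peaks = []
    for i, prom in zip(idx, props["prominences"]):
        if 0 < i < y.size - 1:
            denom = y[i - 1] - 2 * y[i] + y[i + 1]
            delta = 0.0 if denom == 0 else 0.5 * (y[i - 1] - y[i + 1]) / denom
            delta = float(np.clip(delta, -0.5, 0.5))
            center = x[i] + delta * (x[i + 1] - x[i - 1]) / 2.0
            height = y[i] - 0.25 * (y[i - 1] - y[i + 1]) * delta
        else:
            center, height = float(x[i]), float(y[i])
        peaks.append(Peak(float(center), float(height), float(prom)))
    return sorted(peaks, key=lambda p: p.center)


def assign_bands(
    peaks: list[Peak], table: list[BandAssignment]
) -> list[tuple[Peak, BandAssignment | None]]:
    """Match detected peaks to band-table entries.

    Each peak goes to the nearest band center lying within that band's
    tolerance; each band consumes at most one peak (the closest wins);
    distance ties break toward the smaller band center.  Unmatched peaks
    are labelled unassigned (None).  The result preserves peak input
    order and is independent of it.
    """
    centers = [b.center for b in table]
    if len(set(centers)) != len(centers):
        raise ValueError("band table centers must be unique")
    candidates = []
    for pi, p in enumerate(peaks):
        for b in table:
            dist = abs(p.center - b.center)
            if dist <= b.tolerance:
                candidates.append((dist, b.center, pi, b))
    assigned: dict[int, BandAssignment] = {}
    used_bands: set[float] = set()
    for dist, bcenter, pi, b in sorted(candidates):
        if pi in assigned or bcenter in used_bands:
            continue
        assigned[pi] = b
        used_bands.add(bcenter)
    return [(p, assigned.get(i)) for i, p in enumerate(peaks)]


def band_scalar(s: Spectrum, band: BandAssignment) -> float:
    """Per-band scalar statistic: mean intensity over center +/- tolerance."""
    x = s.axis.values
    mask = np.abs(x - band.center) <= band.tolerance
    if not mask.any():
        raise ValueError(f"band {band.center} cm^-1 outside spectrum axis")
    return float(s.intensities[mask].mean())


# ---------------------------------------------------------------------------
# effect sizes and sample size
# ---------------------------------------------------------------------------

def band_effect_size(group_a, group_b) -> float:
    """Cohen's d: standardized mean difference with pooled (n-1) SD."""
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs n >= 2")
    va, vb = a.var(ddof=1), b.var(ddof=1)
    pooled = ((a.size - 1) * va + (b.size - 1) * vb) / (a.size + b.size - 2)
    if pooled == 0.0:
        raise DegenerateVarianceError("pooled SD is zero")
    return float((a.mean() - b.mean()) / math.sqrt(pooled))


@dataclass(frozen=True)
class PowerSpec:
    """Two-sample design: effect size d, alpha (two-sided), power, ratio r.

    ``ratio`` is the allocation ratio n_tumor / n_control.
    """

    d: float
    alpha: float = 0.05
    power: float = 0.8
    ratio: float = 1.0

    def __post_init__(self) -> None:
        if self.d <= 0:
            raise ValueError("d must be positive")
        if not (0 < self.alpha < 1):
            raise ValueError("alpha must lie in (0, 1)")
        if not (0 < self.power < 1):
            raise ValueError("power must lie in (0, 1)")
        if self.ratio <= 0:
            raise ValueError("ratio must be positive")


def required_sample_size(spec: PowerSpec, exact_t: bool = True) -> tuple[int, int]:
    """Two-sample sample size for a standardized mean difference.

    Starts from the normal approximation
    ``n_control = ceil((1 + 1/r) (z_{1-a/2} + z_{1-b})^2 / d^2)`` with
    ``n_tumor = ceil(r * n_control)``, then (by default) increases the
    control-arm size until the noncentral-t power of the two-sample t-test
    at that allocation reaches the request — the small upward refinement
    that turns 63 into the textbook 64 per group at d = 0.5, alpha = 0.05,
    power 0.8.  ``exact_t=False`` returns the plain normal-approximation
    allocation.
    """
    z_a = norm.ppf(1 - spec.alpha / 2.0)
    z_b = norm.ppf(spec.power)
    n_control = math.ceil((1 + 1 / spec.ratio) * (z_a + z_b) ** 2 / spec.d ** 2)
    if exact_t:
        from scipy.stats import nct, t as t_dist

        def power_at(nc: int) -> float:
            nt = math.ceil(spec.ratio * nc)
            df = nt + nc - 2
            ncp = spec.d / math.sqrt(1 / nt + 1 / nc)
            tcrit = t_dist.ppf(1 - spec.alpha / 2.0, df)
            return float(nct.sf(tcrit, df, ncp) + nct.cdf(-tcrit, df, ncp))

        while power_at(n_control) < spec.power:
            n_control += 1
    n_tumor = math.ceil(spec.ratio * n_control)
    return n_tumor, n_control


def monte_carlo_power(
    spec: PowerSpec, n_tumor: int, n_control: int, n_sim: int = 2000,
    seed: int = 0,
) -> float:
    """Simulated two-sample t-test power at a given allocation."""
    from scipy.stats import t as t_dist

    rng = np.random.default_rng(seed)
    a = rng.standard_normal((n_sim, n_tumor)) + spec.d
    b = rng.standard_normal((n_sim, n_control))
    ma, mb = a.mean(axis=1), b.mean(axis=1)
    va, vb = a.var(axis=1, ddof=1), b.var(axis=1, ddof=1)
    sp = np.sqrt(((n_tumor - 1) * va + (n_control - 1) * vb)
                 / (n_tumor + n_control - 2))
    tstat = (ma - mb) / (sp * math.sqrt(1 / n_tumor + 1 / n_control))
    tcrit = t_dist.ppf(1 - spec.alpha / 2.0, n_tumor + n_control - 2)
    return float(np.mean(np.abs(tstat) > tcrit))


# ---------------------------------------------------------------------------
# cohort summary
# ---------------------------------------------------------------------------

@dataclass
class CohortSummary:
    """Per-group mean/SD spectra, difference spectrum and band effects."""

    group_means: dict[str, Spectrum]
    group_sds: dict[str, Spectrum]
    group_sizes: dict[str, int]
    difference: Spectrum | None
    band_effects: dict[float, float] = field(default_factory=dict)

    def to_dict(self) -> dict:
        out = {
            "group_sizes": self.group_sizes,
            "band_effects": {f"{c:g}": d for c, d in self.band_effects.items()},
        }
        if self.difference is not None:
            out["difference_extrema"] = {
                "max_cm": float(self.difference.axis.values[
                    int(np.argmax(self.difference.intensities))]),
                "min_cm": float(self.difference.axis.values[
                    int(np.argmin(self.difference.intensities))]),
            }
        return out


def summarize_cohort(
    sites: list[SpectrumSet],
    band_table: list[BandAssignment] | None = None,
    patient_level: bool = True,
) -> CohortSummary:
    """Mean/SD spectra per tissue label, difference spectrum, band effects.

    With ``patient_level=True`` (default) each patient contributes one mean
    spectrum per tissue label before group averaging, so patients with many
    spectra do not dominate; ``patient_level=False`` averages over all
    individual spectra instead.
    """
    if band_table is None:
        band_table = default_band_table()
    by_label: dict[str, list[Spectrum]] = {}
    if patient_level:
        per_patient: dict[tuple[str, str], list[Spectrum]] = {}
        for st in sites:
            if len(st) == 0:
                continue
            key = (st.metadata.patient_id, st.metadata.tissue_label)
            per_patient.setdefault(key, []).extend(st.spectra)
        for (pid, label), spectra in per_patient.items():
            pmean, _ = group_mean_sd(spectra)
            by_label.setdefault(label, []).append(pmean)
    else:
        for st in sites:
            by_label.setdefault(st.metadata.tissue_label, []).extend(st.spectra)

    means, sds, sizes = {}, {}, {}
    for label, spectra in by_label.items():
        means[label], sds[label] = group_mean_sd(spectra)
        sizes[label] = len(spectra)

    diff = None
    effects: dict[float, float] = {}
    if "tumor" in means and "healthy" in means:
        diff = difference_spectrum(means["tumor"], means["healthy"])
        if sizes["tumor"] >= 2 and sizes["healthy"] >= 2:
            for band in band_table:
                tum = [band_scalar(s, band) for s in by_label["tumor"]]
                heal = [band_scalar(s, band) for s in by_label["healthy"]]
                try:
                    effects[band.center] = band_effect_size(tum, heal)
                except DegenerateVarianceError:
                    continue
    return CohortSummary(means, sds, sizes, diff, effects)
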