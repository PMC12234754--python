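"""End-to-end study computations over synthetic cohorts.

These functions wire the generator, the preprocessing chain and the
cohort statistics into the workflows the analysis scripts and validation
checks run: processing one simulated site to band assignments, computing
a cohort-level tumor-minus-healthy difference spectrum, and surveying
generator behaviour over many seeds.
"""

from __future__ import annotations

from .cohort import (
    BandAssignment,
    Peak,
    assign_bands,
    default_band_table,
    detect_peaks,
    group_mean_sd,
    summarize_cohort,
)
from .core import SiteMetadata, Spectrum
from .preprocess import PipelineConfig, ResponseCurve, preprocess_pipeline
from .simulate import (
    AcquisitionModel,
    CohortConfig,
    TissueModel,
    default_certified_emission,
    simulate_cohort,
    simulate_site,
)

__all__ = [
    "calibration_inputs",
    "process_site",
    "site_band_assignments",
    "cohort_difference",
    "site_size_survey",
]


def calibration_inputs(acq: AcquisitionModel):
    """Dark frame, measured standard and certified curve for a simulated run."""
    certified = default_certified_emission(acq.axis)
    return acq.dark_spectrum(), acq.measured_standard(certified), certified


def process_site(site, acq: AcquisitionModel,
                 config: PipelineConfig = PipelineConfig()):
    """Full correction chain on one simulated site."""
    dark, standard, certified = calibration_inputs(acq)
    return preprocess_pipeline(site, dark, standard, certified, config)


def site_band_assignments(
    tissue_label: str = "healthy",
    seed: int = 42,
    n_spectra: int = 12,
    tissue: TissueModel | None = None,
    acq: AcquisitionModel | None = None,
    band_table: list[BandAssignment] | None = None,
    prominence_fraction: float = 0.05,
) -> list[tuple[Peak, BandAssignment | None]]:
    """Simulate one site, preprocess it, and assign the mean spectrum's peaks.

    Returns the ``(peak, band-or-None)`` pairs of the site's mean spectrum;
    the prominence floor is ``prominence_fraction`` of the mean spectrum's
    intensity range.
    """
    tissue = tissue if tissue is not None else TissueModel()
    if acq is None:
        acq = AcquisitionModel(spectra_per_site=(n_spectra, n_spectra))
    meta = SiteMetadata("P001", "oral cavity", tissue_label, subgroup="tongue")
    site, _ = simulate_site(tissue, acq, meta, seed)
    res = process_site(site, acq)
    mean, _ = group_mean_sd(res.processed.spectra)
    floor = prominence_fraction * float(
        mean.intensities.max() - mean.intensities.min()
    )
    peaks = detect_peaks(mean, min_prominence=floor, min_separation_cm=20.0)
    table = band_table if band_table is not None else default_band_table()
    return assign_bands(peaks, table)


def assigned_center(pairs, band_center: float) -> float:
    """Detected center of the peak assigned to the band table entry at
    ``band_center`` cm^-1."""
    for peak, band in pairs:
        if band is not None and band.center == band_center:
            return peak.center
    raise LookupError(f"no peak assigned to the {band_center:g} cm^-1 band")


def cohort_difference(
    seed: int,
    tissue: TissueModel | None = None,
    acq: AcquisitionModel | None = None,
    config: CohortConfig | None = None,
) -> Spectrum:
    """Patient-level tumor-minus-healthy difference spectrum for one cohort."""
    tissue = tissue if tissue is not None else TissueModel()
    acq = acq if acq is not None else AcquisitionModel()
    if config is None:
        config = CohortConfig(sites_per_patient=("tumor", "healthy"))
    sites, _ = simulate_cohort(config, seed, tissue=tissue, acq=acq)
    processed = [process_site(st, acq).processed for st in sites]
    summary = summarize_cohort(processed)
    if summary.difference is None:
        raise RuntimeError("cohort lacks tumor or healthy sites")
    return summary.difference


def site_size_survey(
    seeds,
    tissue: TissueModel | None = None,
    acq: AcquisitionModel | None = None,
) -> list[int]:
    """Spectra-per-site counts over many seeded simulated sites."""
    tissue = tissue if tissue is not None else TissueModel()
    acq = acq if acq is not None else AcquisitionModel()
    meta = SiteMetadata("P001", "oropharynx", "tumor", subgroup="tonsil")
    return [len(simulate_site(tissue, acq, meta, int(s))[0]) for s in seeds]
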