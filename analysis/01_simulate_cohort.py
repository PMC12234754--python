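#!/usr/bin/env python
"""Simulate the default synthetic cohort: 10 oral-cavity + 10 oropharynx
patients, each measured at a tumor, a margin and a healthy site, 8-15 raw
fiber-probe spectra per site.

Raw spectra (hundreds of files) go to scratch/cohort/; a compact summary
of the ground-truth manifest goes to results/.
"""

import argparse
import json
from pathlib import Path

from ramantis import io as rio
from ramantis.simulate import (
    AcquisitionModel,
    CohortConfig,
    TissueModel,
    default_certified_emission,
    simulate_cohort,
)
from ramantis.core import Spectrum

ROOT = Path(__file__).resolve().parents[1]


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=1)
    args = ap.parse_args()

    config = CohortConfig()
    acq = AcquisitionModel()
    cohort, manifest = simulate_cohort(config, args.seed)

    out = ROOT / "scratch" / "cohort"
    out.mkdir(parents=True, exist_ok=True)
    for i, site in enumerate(cohort):
        name = f"site_{i:03d}_{site.metadata.patient_id}_{site.metadata.tissue_label}"
        rio.write_site(out / name, site)
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)

    certified = default_certified_emission(acq.axis)
    rio.write_spectrum_file(out / "dark.txt", acq.dark_spectrum())
    rio.write_spectrum_file(out / "standard_measured.txt",
                            acq.measured_standard(certified))
    rio.write_spectrum_file(out / "certified.txt",
                            Spectrum(acq.axis, certified.relative_sensitivity))

    n_spectra = sum(len(s) for s in cohort)
    spikes = sum(len(e["spike_channels"])
                 for sm in manifest["sites"] for e in sm["entries"])
    summary = {
        "seed": args.seed,
        "config_digest": rio.config_digest(config.to_dict()),
        "n_patients": manifest["n_patients"],
        "n_sites": manifest["n_sites"],
        "n_spectra": n_spectra,
        "n_planted_spikes": spikes,
        "spectra_per_site_range": [
            min(len(s) for s in cohort), max(len(s) for s in cohort)],
    }
    res = ROOT / "results"
    res.mkdir(exist_ok=True)
    with open(res / "cohort_summary.json", "w") as fh:
        json.dump(summary, fh, indent=1, sort_keys=True)
    print(f"simulated {summary['n_sites']} sites / {n_spectra} spectra "
          f"({spikes} planted cosmic spikes) -> {out}")


if __name__ == "__main__":
    main()
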