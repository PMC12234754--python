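#!/usr/bin/env python
"""Cohort statistics on the preprocessed spectra: per-group mean +/- SD
spectra, the tumor-minus-healthy difference spectrum, peak detection with
band assignment, and per-band Cohen's d effect sizes.

Reads scratch/processed/ (written by 02); writes tables, summary JSON and
figures to results/.
"""

import json
from pathlib import Path

import numpy as np

from ramantis import io as rio
from ramantis.cohort import (
    assign_bands,
    default_band_table,
    detect_peaks,
    summarize_cohort,
)

ROOT = Path(__file__).resolve().parents[1]


def main():
    proc = ROOT / "scratch" / "processed"
    res = ROOT / "results"
    res.mkdir(exist_ok=True)

    sites = [rio.read_site(d) for d in sorted(proc.iterdir())
             if d.is_dir() and d.name.startswith("site_")]
    table = default_band_table()
    summary = summarize_cohort(sites, table)

    for label, mean in summary.group_means.items():
        sd = summary.group_sds[label]
        with open(res / f"group_{label}.tsv", "w") as fh:
            fh.write("# wavenumber_cm-1\tmean\tsd\n")
            for nu, m, s in zip(mean.axis.values, mean.intensities,
                                sd.intensities):
                fh.write(f"{nu:.12g}\t{m:.12g}\t{s:.12g}\n")
    rio.write_spectrum_file(res / "difference_tumor_minus_healthy.tsv",
                            summary.difference)

    mean_t = summary.group_means["tumor"]
    floor = 0.05 * float(mean_t.intensities.max() - mean_t.intensities.min())
    peaks = detect_peaks(mean_t, floor, 20.0)
    pairs = assign_bands(peaks, table)
    assigned = [
        {"detected_cm": round(p.center, 1), "band_cm": b.center,
         "assignment": b.assignment}
        for p, b in pairs if b is not None
    ]

    doc = summary.to_dict()
    doc["assigned_peaks_tumor_mean"] = assigned
    with open(res / "cohort_analysis.json", "w") as fh:
        json.dump(doc, fh, indent=1, sort_keys=True)

    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, axes = plt.subplots(len(summary.group_means) + 1, 1,
                             figsize=(8, 9), sharex=True)
    for ax, (label, mean) in zip(axes, sorted(summary.group_means.items())):
        sd = summary.group_sds[label]
        ax.plot(mean.axis.values, mean.intensities, lw=1)
        ax.fill_between(mean.axis.values,
                        mean.intensities - sd.intensities,
                        mean.intensities + sd.intensities, alpha=0.3)
        ax.set_ylabel(label)
    d = summary.difference
    axes[-1].plot(d.axis.values, d.intensities, color="firebrick", lw=1)
    axes[-1].axhline(0, color="gray", lw=0.5)
    axes[-1].set_ylabel("tumor $-$ healthy")
    axes[-1].set_xlabel("Raman shift (cm$^{-1}$)")
    fig.tight_layout()
    fig.savefig(res / "cohort_spectra.png", dpi=120)

    x, y = d.axis.values, d.intensities
    fp = (x >= 800) & (x <= 1800)
    peak_nu = x[fp][np.argmax(np.abs(y[fp]))]
    print(f"groups: { {k: v for k, v in sorted(summary.group_sizes.items())} }")
    print(f"largest fingerprint contrast at {peak_nu:.0f} cm^-1")
    print("band effect sizes (tumor vs healthy, Cohen's d):")
    for c, dval in sorted(summary.band_effects.items()):
        print(f"  {c:6.0f} cm^-1  d = {dval:+.2f}")
    print("tables and figures -> results/")


if __name__ == "__main__":
    main()
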