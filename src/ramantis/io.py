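"""Readers and writers: two-column spectrum files, JSON metadata sidecars,
the cohort patient table, and run configuration with stable digests.

Spectrum files are plain delimited text — one ``wavenumber<TAB>intensity``
row per channel, ``#``-prefixed header lines — with a ``.meta.json``
sidecar carrying the site metadata.  Vendor formats are out of scope; the
text form survives any transport and diffs cleanly.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np

from .core import PatientRecord, SiteMetadata, Spectrum, SpectrumSet, WavenumberAxis

__all__ = [
    "ParseError",
    "VocabularyError",
    "RunConfig",
    "read_spectrum_file",
    "write_spectrum_file",
    "read_site",
    "write_site",
    "parse_patient_table",
    "packaged_patient_table",
    "config_digest",
]


class ParseError(ValueError):
    """Malformed spectrum or table file."""


class VocabularyError(ValueError):
    """A table value falls outside its closed vocabulary."""


_GROUP_ALIASES = {
    "oral cavity": "oral cavity",
    "oropharynx": "oropharynx",
    "larynx": "larynx",
    "hypopharynx": "hypopharynx",
}


def read_spectrum_file(path, resolution_hint: float = 20.0) -> Spectrum:
    """Read a two-column delimited spectrum file.

    ``#`` header lines and blank lines are ignored; rows are sorted by
    wavenumber (with a warning) if out of order; fewer than 8 data rows or
    a non-numeric row is an error naming the offending line.
    """
    path = Path(path)
    nus: list[float] = []
    ys: list[float] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.replace(",", "\t").split()
            if len(parts) < 2:
                raise ParseError(f"{path.name}:{lineno}: expected two columns")
            try:
                nus.append(float(parts[0]))
                ys.append(float(parts[1]))
            except ValueError as exc:
                raise ParseError(
                    f"{path.name}:{lineno}: non-numeric row {line!r}"
                ) from exc
    if len(nus) < 8:
        raise ParseError(f"{path.name}: only {len(nus)} data rows (need >= 8)")
    nu = np.array(nus)
    y = np.array(ys)
    if not np.all(np.diff(nu) > 0):
        warnings.warn(f"{path.name}: wavenumbers out of order; sorting",
                      RuntimeWarning, stacklevel=2)
        order = np.argsort(nu)
        nu, y = nu[order], y[order]
    return Spectrum(WavenumberAxis(nu, resolution_hint), y)


def write_spectrum_file(path, s: Spectrum, header: dict | None = None) -> None:
    """Write a spectrum as two-column text with ``#`` header lines.

    Values carry 12 significant digits, enough for a faithful round trip
    of calibrated intensities.
    """
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("# wavenumber_cm-1\tintensity\n")
        for key, val in (header or {}).items():
            fh.write(f"# {key}: {val}\n")
        for nu, y in zip(s.axis.values, s.intensities):
            fh.write(f"{nu:.12g}\t{y:.12g}\n")


def write_site(directory, site: SpectrumSet, manifest: dict | None = None) -> None:
    """Write one site: numbered spectrum files + metadata sidecar."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for i, s in enumerate(site.spectra):
        write_spectrum_file(directory / f"spectrum_{i:02d}.txt", s)
    with open(directory / "site.meta.json", "w") as fh:
        json.dump(site.metadata.to_dict(), fh, indent=1, sort_keys=True)
        fh.write("\n")
    if manifest is not None:
        with open(directory / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=1, sort_keys=True)
            fh.write("\n")


def read_site(directory, resolution_hint: float = 20.0) -> SpectrumSet:
    """Read a site directory written by :func:`write_site`."""
    directory = Path(directory)
    with open(directory / "site.meta.json") as fh:
        meta = SiteMetadata.from_dict(json.load(fh))
    spectra = [
        read_spectrum_file(p, resolution_hint)
        for p in sorted(directory.glob("spectrum_*.txt"))
    ]
    if not spectra:
        raise ParseError(f"{directory}: no spectrum files")
    return SpectrumSet(meta, spectra)


def parse_patient_table(path) -> list[PatientRecord]:
    """Parse a cohort table (columns No, Group, Subgroup, TNM, Histopathology)."""
    records: list[PatientRecord] = []
    seen: set[int] = set()
    with open(path) as fh:
        header = None
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.split("\t")
            if header is None:
                header = [h.strip().lower() for h in parts]
                required = {"no", "group", "subgroup", "tnm", "histopathology"}
                if not required.issubset(header):
                    raise ParseError(
                        f"{path}: missing columns {sorted(required - set(header))}"
                    )
                continue
            row = dict(zip(header, (p.strip() for p in parts)))
            group = row["group"].lower()
            if group not in _GROUP_ALIASES:
                raise VocabularyError(
                    f"{path}:{lineno}: unknown group {row['group']!r}"
                )
            number = int(row["no"])
            if number in seen:
                raise ParseError(f"{path}:{lineno}: duplicate patient number {number}")
            seen.add(number)
            records.append(PatientRecord(
                number=number,
                group=_GROUP_ALIASES[group],
                subgroup=row["subgroup"],
                tnm=row["tnm"],
                histopathology=row["histopathology"],
            ))
    return records


def packaged_patient_table() -> list[PatientRecord]:
    """The cohort table packaged with this distribution (25 patients)."""
    ref = resources.files("ramantis.data").joinpath("table1.tsv")
    with resources.as_file(ref) as path:
        return parse_patient_table(path)


# ---------------------------------------------------------------------------
# run configuration
# ---------------------------------------------------------------------------

def config_digest(config: dict) -> str:
    """12-hex digest of a configuration mapping, stable under key order."""
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


@dataclass
class RunConfig:
    """Serializable description of one pipeline run."""

    seed: int = 0
    output_dir: str = "results"
    stage_params: dict = field(default_factory=dict)
    cohort: dict = field(default_factory=dict)
    band_table_path: str | None = None

    def to_dict(self) -> dict:
        return {
            "seed": self.seed,
            "output_dir": self.output_dir,
            "stage_params": self.stage_params,
            "cohort": self.cohort,
            "band_table_path": self.band_table_path,
        }

    @property
    def digest(self) -> str:
        return config_digest(self.to_dict())
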