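"""MSP I/O: 4D metabolite libraries and exported feature spectra.

Dialect (one entry per blank-line-separated block)::

    Name: kynurenic acid
    Formula: C10H7NO3
    Adduct: [M+H]+
    PrecursorMZ: 190.0499
    RT: 190.0
    CCS: 147.0
    RTProvenance: experimental
    MS2Provenance: experimental
    Num Peaks: 2
    89.0386 1500
    144.0444 8000

``RT`` (seconds) and ``CCS`` (A^2) field names are defined by this package;
MSP has no standard key for either.  ``Num Peaks: 0`` marks an MS1-only
entry (no MS2 spectrum).
"""

from __future__ import annotations

import numpy as np

from ..models import FeatureGroup, LibraryEntry

__all__ = ["read_msp_library", "write_msp_library", "write_spectra_msp", "MSPError"]


class MSPError(ValueError):
    """Malformed MSP input."""


def _parse_blocks(path):
    blocks, meta, peaks, n_expected = [], {}, [], None
    name = None
    with open(path) as fh:
        for raw in fh:
            line = raw.strip()
            if not line:
                if meta or peaks:
                    blocks.append((name, meta, peaks, n_expected))
                    meta, peaks, n_expected, name = {}, [], None, None
                continue
            if ":" in line and not line[0].isdigit():
                key, _, value = line.partition(":")
                key = key.strip().lower()
                value = value.strip()
                meta[key] = value
                if key == "name":
                    name = value
                if key == "num peaks":
                    n_expected = int(value)
            else:
                parts = line.replace(";", " ").split()
                peaks.append((float(parts[0]), float(parts[1])))
    if meta or peaks:
        blocks.append((name, meta, peaks, n_expected))
    return blocks


def read_msp_library(path) -> list[LibraryEntry]:
    """Read a 4D metabolite library from ``path``."""
    entries = []
    for name, meta, peaks, n_expected in _parse_blocks(path):
        label = name or f"entry #{len(entries) + 1}"
        if n_expected is not None and n_expected != len(peaks):
            raise MSPError(
                f"{label}: Num Peaks says {n_expected} but {len(peaks)} peak lines found"
            )
        try:
            entries.append(
                LibraryEntry(
                    name=label,
                    formula=meta.get("formula", ""),
                    exact_mass=float(meta.get("exactmass", "nan")),
                    adduct=meta.get("adduct", ""),
                    mz=float(meta["precursormz"]),
                    rt=float(meta["rt"]) if "rt" in meta else None,
                    ccs=float(meta["ccs"]) if "ccs" in meta else None,
                    ms2=np.array(peaks).reshape(-1, 2) if peaks else None,
                    rt_provenance=meta.get("rtprovenance", "predicted"),
                    ms2_provenance=meta.get("ms2provenance", "predicted"),
                )
            )
        except (KeyError, ValueError) as exc:
            raise MSPError(f"{label}: {exc}") from exc
    return entries


def write_msp_library(entries: list[LibraryEntry], path) -> None:
    with open(path, "w") as fh:
        for e in entries:
            fh.write(f"Name: {e.name}\n")
            fh.write(f"Formula: {e.formula}\n")
            fh.write(f"Adduct: {e.adduct}\n")
            fh.write(f"ExactMass: {e.exact_mass:.6f}\n")
            fh.write(f"PrecursorMZ: {e.mz:.6f}\n")
            if e.rt is not None:
                fh.write(f"RT: {e.rt:.3f}\n")
            if e.ccs is not None:
                fh.write(f"CCS: {e.ccs:.3f}\n")
            fh.write(f"RTProvenance: {e.rt_provenance}\n")
            fh.write(f"MS2Provenance: {e.ms2_provenance}\n")
            n = 0 if e.ms2 is None else len(e.ms2)
            fh.write(f"Num Peaks: {n}\n")
            if e.ms2 is not None:
                for mz, inten in e.ms2:
                    fh.write(f"{mz:.6f} {inten:.6g}\n")
            fh.write("\n")


def write_spectra_msp(groups: list[FeatureGroup], path) -> None:
    """Export each feature's representative MS2 spectrum (spectra.msp)."""
    with open(path, "w") as fh:
        for g in groups:
            if g.representative_ms2 is None:
                continue
            rec = g.representative_ms2
            fh.write(f"Name: {g.feature_id or 'feature'}\n")
            fh.write(f"PrecursorMZ: {g.mz:.6f}\n")
            fh.write(f"RT: {g.rt:.3f}\n")
            fh.write(f"CCS: {g.ccs:.3f}\n")
            fh.write(f"Mobility: {g.mobility:.6f}\n")
            fh.write(f"Num Peaks: {rec.n_fragments}\n")
            for mz, inten in rec.fragments:
                fh.write(f"{mz:.6f} {inten:.6g}\n")
            fh.write("\n")
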