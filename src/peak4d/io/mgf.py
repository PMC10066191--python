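"""MGF I/O for DDA MS2 records (via pyteomics).

Dialect: standard MGF with mandatory ``RTINSECONDS`` plus the nonstandard
keys ``MOBILITY`` (precursor 1/K0, V*s/cm^2) and ``FRAME`` (1-based frame
index).  The bottom-up assembly workflow needs precursor mobility and frame
index for every MS2 spectrum; records lacking either key are rejected and
counted.
"""

from __future__ import annotations

import numpy as np
from pyteomics import mgf as _mgf

from ..models import MS2Record

__all__ = ["read_mgf", "write_mgf", "MGFError"]


class MGFError(ValueError):
    """Malformed MGF input."""


def read_mgf(path, strict: bool = True) -> tuple[list[MS2Record], int]:
    """Read MS2 records from ``path``.

    Returns ``(records, n_rejected)`` where ``n_rejected`` counts spectra
    missing the mandatory MOBILITY/FRAME/RTINSECONDS/PEPMASS keys.  With
    ``strict`` (default), a structurally broken file raises :class:`MGFError`
    naming the spectrum position.
    """
    records: list[MS2Record] = []
    rejected = 0
    try:
        with _mgf.read(str(path), use_index=False) as reader:
            for pos, spec in enumerate(reader, start=1):
                params = spec.get("params", {})
                try:
                    pepmass = params["pepmass"][0]
                    rt = float(params["rtinseconds"])
                    mob = float(params["mobility"])
                    frame = int(params["frame"])
                except (KeyError, TypeError, IndexError):
                    rejected += 1
                    continue
                frags = np.column_stack(
                    [spec.get("m/z array", []), spec.get("intensity array", [])]
                ) if len(spec.get("m/z array", [])) else np.empty((0, 2))
                records.append(
                    MS2Record(
                        precursor_mz=float(pepmass),
                        precursor_rt=rt,
                        precursor_mobility=mob,
                        precursor_frame=frame,
                        fragments=frags,
                        title=str(params.get("title", f"spectrum_{pos}")),
                    )
                )
    except Exception as exc:
        if isinstance(exc, MGFError):
            raise
        raise MGFError(
            f"failed to parse MGF {path} near spectrum {len(records) + rejected + 1}: {exc}"
        ) from exc
    return records, rejected


def write_mgf(records: list[MS2Record], path) -> None:
    """Write MS2 records to ``path`` in the repo's MGF dialect."""
    spectra = []
    for i, rec in enumerate(records, start=1):
        spectra.append(
            {
                "m/z array": rec.fragments[:, 0],
                "intensity array": rec.fragments[:, 1],
                "params": {
                    "title": rec.title or f"spectrum_{i}",
                    "pepmass": rec.precursor_mz,
                    "rtinseconds": rec.precursor_rt,
                    "mobility": rec.precursor_mobility,
                    "frame": rec.precursor_frame,
                },
            }
        )
    _mgf.write(spectra, str(path), file_mode="w")
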