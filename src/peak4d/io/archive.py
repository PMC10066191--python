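"""Single-file columnar frame-archive container (HDF5).

The archive holds two tables -- ``frames`` (index, rt, ms_level,
isolation_low, isolation_high) and ``points`` (frame_index, mz, mobility,
intensity) -- plus a metadata attribute block.  A single file keeps a run
atomic and slicing by frame range fast.  All floating-point columns are
stored as float64, so round trips are bit-exact.
"""

from __future__ import annotations

import json

import h5py
import numpy as np

from ..models import Frame, FrameArchive

__all__ = ["write_archive", "read_archive", "FormatError"]

_FORMAT_VERSION = 1


class FormatError(ValueError):
    """Malformed frame-archive container."""


def write_archive(archive: FrameArchive, path) -> None:
    """Write ``archive`` to ``path``, overwriting any existing file."""
    archive.validate()
    n_frames = len(archive.frames)
    counts = np.array([f.n_points for f in archive.frames], dtype=np.int64)
    total = int(counts.sum())

    frame_index = np.array([f.index for f in archive.frames], dtype=np.int64)
    rt = np.array([f.rt for f in archive.frames], dtype=np.float64)
    ms_level = np.array([f.ms_level for f in archive.frames], dtype=np.int64)
    iso = np.full((n_frames, 2), np.nan)
    for i, f in enumerate(archive.frames):
        if f.isolation is not None:
            iso[i] = f.isolation

    mz = np.empty(total)
    mobility = np.empty(total)
    intensity = np.empty(total)
    pos = 0
    for f in archive.frames:
        mz[pos : pos + f.n_points] = f.mz
        mobility[pos : pos + f.n_points] = f.mobility
        intensity[pos : pos + f.n_points] = f.intensity
        pos += f.n_points

    with h5py.File(path, "w") as h5:
        h5.attrs["format_version"] = _FORMAT_VERSION
        h5.attrs["run_id"] = archive.run_id
        h5.attrs["metadata"] = json.dumps(archive.metadata, sort_keys=True)
        g = h5.create_group("frames")
        g.create_dataset("index", data=frame_index)
        g.create_dataset("rt", data=rt)
        g.create_dataset("ms_level", data=ms_level)
        g.create_dataset("isolation", data=iso)
        g.create_dataset("n_points", data=counts)
        p = h5.create_group("points")
        p.create_dataset("mz", data=mz)
        p.create_dataset("mobility", data=mobility)
        p.create_dataset("intensity", data=intensity)


def read_archive(path) -> FrameArchive:
    """Read a frame archive written by :func:`write_archive`."""
    with h5py.File(path, "r") as h5:
        for key in ("run_id", "metadata"):
            if key not in h5.attrs:
                raise FormatError(f"archive missing metadata key {key!r}")
        run_id = str(h5.attrs["run_id"])
        metadata = json.loads(h5.attrs["metadata"])
        try:
            g, p = h5["frames"], h5["points"]
            frame_index = g["index"][:]
            rt = g["rt"][:]
            ms_level = g["ms_level"][:]
            iso = g["isolation"][:]
            counts = g["n_points"][:]
            mz = p["mz"][:]
            mobility = p["mobility"][:]
            intensity = p["intensity"][:]
        except KeyError as exc:
            raise FormatError(f"archive missing table: {exc}") from exc

    if counts.sum() != len(mz):
        raise FormatError("points table length does not match frame point counts")
    offsets = np.concatenate([[0], np.cumsum(counts)])
    frames = []
    for i in range(len(frame_index)):
        lo, hi = offsets[i], offsets[i + 1]
        isolation = None if np.isnan(iso[i, 0]) else (float(iso[i, 0]), float(iso[i, 1]))
        try:
            frames.append(
                Frame(
                    index=int(frame_index[i]),
                    rt=float(rt[i]),
                    ms_level=int(ms_level[i]),
                    mz=mz[lo:hi],
                    mobility=mobility[lo:hi],
                    intensity=intensity[lo:hi],
                    isolation=isolation,
                )
            )
        except ValueError as exc:
            raise FormatError(f"frame {int(frame_index[i])}: {exc}") from exc
    # metadata JSON turns the grid tuple into a list; normalize back
    if "mobility_grid" in metadata:
        metadata["mobility_grid"] = tuple(metadata["mobility_grid"])
    try:
        return FrameArchive(run_id=run_id, frames=frames, metadata=metadata)
    except ValueError as exc:
        raise FormatError(str(exc)) from exc
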