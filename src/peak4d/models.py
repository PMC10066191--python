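"""Domain containers for 4D (m/z, RT, mobility, intensity) metabolomics data.

A *frame* is one complete m/z-mobility scan at a fixed LC retention time
(trapped-ion-mobility terminology).  A run is a *frame archive*: an ordered
sequence of frames plus acquisition metadata.  Downstream stages produce
``MS2Record`` (fragmentation spectra), ``Peak4D`` (assembled features),
``FeatureGroup`` (cross-sample aligned features) and ``LibraryEntry``
(annotatable metabolites).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import NamedTuple

import numpy as np

__all__ = [
    "FramePoint",
    "Frame",
    "FrameArchive",
    "MS2Record",
    "Peak4D",
    "FeatureGroup",
    "LibraryEntry",
    "Seed",
]


class FramePoint(NamedTuple):
    """A single centroided MS1 data point within one frame."""

    mz: float
    mobility: float  # reduced inverse mobility 1/K0, V*s/cm^2
    intensity: float


@dataclass
class Frame:
    """One m/z-mobility scan at a fixed retention time.

    Points are stored as parallel numpy arrays sorted by m/z so that m/z
    window queries reduce to ``searchsorted`` slices.
    """

    index: int  # 1-based, mirrors vendor convention
    rt: float  # seconds
    ms_level: int  # 1 or 2
    mz: np.ndarray
    mobility: np.ndarray
    intensity: np.ndarray
    isolation: tuple[float, float] | None = None  # (low, high) m/z, DIA MS2 only

    def __post_init__(self) -> None:
        self.mz = np.asarray(self.mz, dtype=np.float64)
        self.mobility = np.asarray(self.mobility, dtype=np.float64)
        self.intensity = np.asarray(self.intensity, dtype=np.float64)
        if not (len(self.mz) == len(self.mobility) == len(self.intensity)):
            raise ValueError(f"frame {self.index}: point arrays differ in length")
        if self.index < 1:
            raise ValueError(f"frame index must be >= 1, got {self.index}")
        if self.ms_level not in (1, 2):
            raise ValueError(f"frame {self.index}: ms_level must be 1 or 2")
        if len(self.mz) and np.any(np.diff(self.mz) < 0):
            order = np.argsort(self.mz, kind="stable")
            self.mz = self.mz[order]
            self.mobility = self.mobility[order]
            self.intensity = self.intensity[order]
        if np.any(self.intensity < 0):
            raise ValueError(f"frame {self.index}: negative intensities")

    @property
    def n_points(self) -> int:
        return len(self.mz)

    def slice_mz(self, low: float, high: float) -> slice:
        """Index slice of points with ``low <= mz <= high``."""
        lo = int(np.searchsorted(self.mz, low, side="left"))
        hi = int(np.searchsorted(self.mz, high, side="right"))
        return slice(lo, hi)


@dataclass
class FrameArchive:
    """A full LC-IM-MS run: frames plus acquisition metadata.

    ``metadata`` must provide ``mode`` (DDA|DIA|AIF), ``cycle_time`` (s) and
    ``mobility_grid`` = (min, max, step) in V*s/cm^2.
    """

    run_id: str
    frames: list[Frame]
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.validate()
        self._ms1 = [f for f in self.frames if f.ms_level == 1]
        self._ms1_rts = np.array([f.rt for f in self._ms1])

    def validate(self) -> None:
        idx = [f.index for f in self.frames]
        if any(b <= a for a, b in zip(idx, idx[1:])):
            raise ValueError("frame indices must be strictly increasing")
        ms1_rts = [f.rt for f in self.frames if f.ms_level == 1]
        if any(b <= a for a, b in zip(ms1_rts, ms1_rts[1:])):
            raise ValueError("MS1 frame RTs must be strictly increasing")
        for key in ("mode", "cycle_time", "mobility_grid"):
            if key not in self.metadata:
                raise ValueError(f"archive metadata missing key {key!r}")

    @property
    def ms1_frames(self) -> list[Frame]:
        return self._ms1

    @property
    def ms1_rts(self) -> np.ndarray:
        return self._ms1_rts

    @property
    def mobility_grid(self) -> np.ndarray:
        lo, hi, step = self.metadata["mobility_grid"]
        n = int(round((hi - lo) / step)) + 1
        return lo + step * np.arange(n)

    def frame_by_index(self, index: int) -> Frame:
        for f in self.frames:
            if f.index == index:
                return f
        raise KeyError(f"frame index {index} not in archive {self.run_id!r}")

    def nearest_ms1(self, rt: float) -> Frame:
        """MS1 frame with the smallest RT difference to ``rt``."""
        if not self._ms1:
            raise ValueError("archive has no MS1 frames")
        return self._ms1[int(np.argmin(np.abs(self._ms1_rts - rt)))]

    def ms1_position(self, frame: Frame) -> int:
        """Position of ``frame`` within the MS1-frame sequence."""
        for i, f in enumerate(self._ms1):
            if f.index == frame.index:
                return i
        raise KeyError(f"frame {frame.index} is not an MS1 frame of this archive")


@dataclass
class MS2Record:
    """A fragmentation spectrum with its 3D precursor coordinates."""

    precursor_mz: float
    precursor_rt: float
    precursor_mobility: float
    precursor_frame: int
    fragments: np.ndarray  # shape (n, 2): columns m/z, intensity, sorted by m/z
    title: str = ""

    def __post_init__(self) -> None:
        frag = np.asarray(self.fragments, dtype=np.float64).reshape(-1, 2)
        if len(frag) and np.any(np.diff(frag[:, 0]) < 0):
            frag = frag[np.argsort(frag[:, 0], kind="stable")]
        if np.any(frag[:, 1] < 0):
            raise ValueError("fragment intensities must be non-negative")
        self.fragments = frag

    @property
    def n_fragments(self) -> int:
        return len(self.fragments)

    def spectral_intensity(self, top_n: int = 10) -> float:
        """Sum of the ``top_n`` most intense fragments (all if fewer)."""
        if not len(self.fragments):
            return 0.0
        inten = np.sort(self.fragments[:, 1])[::-1]
        return float(inten[:top_n].sum())

    def with_fragments(self, fragments: np.ndarray) -> "MS2Record":
        return replace(self, fragments=fragments)


@dataclass
class Seed:
    """Starting coordinates for bottom-up assembly of one 4D peak."""

    mz: float
    mobility: float
    rt: float
    frame: int | None = None  # absent for list-seeded mode
    origin: str = "unique-MS2"  # "unique-MS2" | "precursor-list" | "targeted"
    seed_id: int | None = None

    def __post_init__(self) -> None:
        if self.mz <= 0 or self.mobility <= 0:
            raise ValueError("seed mz and mobility must be positive")


@dataclass
class Peak4D:
    """An assembled 4D feature."""

    mz: float  # intensity-reweighted
    rt: float  # EIC apex, s
    mobility: float  # EIM apex, 1/K0
    ccs: float  # A^2
    intensity: float  # integrated 3D peak volume
    eim_bounds: tuple[float, float]
    eic_bounds: tuple[float, float]
    snr: float
    norm_noise: float
    seed: Seed | None = None
    ms2: MS2Record | None = None
    sample: str | None = None


@dataclass
class FeatureGroup:
    """A cross-sample aligned feature with per-sample intensities."""

    mz: float  # median over member peaks
    rt: float  # median, corrected RT scale
    mobility: float
    ccs: float
    intensities: dict  # sample -> float; missing samples absent until gap fill
    peaks: dict = field(default_factory=dict)  # sample -> Peak4D
    representative_ms2: MS2Record | None = None
    n_samples: int = 0
    gap_filled: bool = False
    feature_id: str | None = None

    @property
    def fraction_present(self) -> float:
        if self.n_samples == 0:
            return 0.0
        return len(self.peaks) / self.n_samples


@dataclass
class LibraryEntry:
    """An annotatable metabolite: identity plus theoretical/measured 4D values.

    Provenance flags record whether RT and MS2 are experimental (in-house),
    experimental-public, or predicted; they drive the annotation confidence
    level.
    """

    name: str
    formula: str
    exact_mass: float
    adduct: str
    mz: float
    rt: float | None = None
    ccs: float | None = None
    ms2: np.ndarray | None = None  # fragment list (n, 2)
    rt_provenance: str = "predicted"  # "experimental" | "predicted"
    ms2_provenance: str = "predicted"  # "experimental" | "experimental-public" | "predicted"

    def __post_init__(self) -> None:
        if self.ms2 is not None:
            ms2 = np.asarray(self.ms2, dtype=np.float64).reshape(-1, 2)
            if len(ms2) and np.any(np.diff(ms2[:, 0]) < 0):
                ms2 = ms2[np.argsort(ms2[:, 0], kind="stable")]
            self.ms2 = ms2
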