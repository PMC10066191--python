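"""Bottom-up assembly of 4D peaks.

Detection runs in reverse order of the physical separation.  Each seed (the
precursor of a unique MS2 spectrum, or an entry of a user-supplied precursor
list) initiates five steps:

1. precursor search -- the most intense MS1 point near the seed's m/z and
   mobility in the precursor frame;
2. EIM detection -- an extracted ion mobilogram is assembled around that
   point within the frame and peak-picked after LOESS smoothing (13-point
   span);
3. EIM extension -- the mobilogram detection is repeated in up to 30
   adjacent MS1 frames around the precursor frame;
4. EIC detection -- per-frame mobilogram-peak intensities are projected onto
   the LC axis and peak-picked (11-point span);
5. 4D integration -- MS1 points in the 5 frames nearest the EIC apex and
   within 0.015 V*s/cm^2 of the per-frame EIM apexes are integrated; the
   reported m/z is the intensity-weighted mean of those points.

A series of fidelity criteria (apex-to-seed tolerances, signal continuity
around the apex, S/N >= 3, normalized standard noise < 0.35) rejects
assemblies that do not look like chromatographic/mobilogram peaks.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from statsmodels.nonparametric.smoothers_lowess import lowess

from .ccs import CCSParams, ccs_to_mobility, mobility_to_ccs
from .models import Frame, FrameArchive, FramePoint, MS2Record, Peak4D, Seed
from .tolerances import ToleranceRule, mz_half_width

__all__ = [
    "DetectionParams",
    "EIMPeak",
    "EICPeak",
    "loess_smooth",
    "detect_peak_1d",
    "locate_precursor",
    "extract_mobilogram",
    "detect_eim",
    "extend_eim",
    "assemble_eic",
    "integrate_4d",
    "check_fidelity",
    "detect_from_seeds",
    "seeds_from_unique_spectra",
    "seeds_from_list",
    "extract_dia_ms2",
]


@dataclass(frozen=True)
class DetectionParams:
    """All tunable detection parameters with their default values."""

    rule: ToleranceRule = ToleranceRule()
    mobility_search_tol: float = 0.015  # precursor-point search, V*s/cm^2
    eim_half_window: float = 0.05  # mobilogram extraction half-range
    eim_span: int = 13  # mobilogram peak span, grid points
    eic_span: int = 11  # chromatogram peak span, frames
    extension_frames: int = 30  # adjacent MS1 frames scanned in step 3
    max_eim_gap: int = 2  # consecutive failed frames that stop a side
    integration_frames: int = 5
    integration_mobility_tol: float = 0.015
    rt_fidelity_tol: float = 10.0  # s
    mobility_fidelity_tol: float = 0.015
    min_snr: float = 3.0
    max_norm_noise: float = 0.35
    continuity_points: int = 3
    ccs: CCSParams = field(default_factory=CCSParams)


@dataclass
class EIMPeak:
    """A detected extracted-ion-mobilogram peak in one frame."""

    frame: int  # frame index
    apex_mobility: float
    bounds: tuple[float, float]  # mobility
    apex_intensity: float
    summed_intensity: float
    grid: np.ndarray  # mobility axis of the trace
    raw: np.ndarray
    smoothed: np.ndarray
    apex_idx: int
    bound_idx: tuple[int, int]


@dataclass
class EICPeak:
    """A detected extracted-ion-chromatogram peak."""

    apex_rt: float
    bounds: tuple[float, float]  # s
    frame_range: tuple[int, int]  # first/last MS1 frame index scanned
    rts: np.ndarray
    raw: np.ndarray
    smoothed: np.ndarray
    apex_idx: int
    bound_idx: tuple[int, int]


def loess_smooth(y: np.ndarray, span_points: int) -> np.ndarray:
    """Single-pass local-linear LOESS over an evenly spaced trace."""
    n = len(y)
    if n < 3:
        return np.asarray(y, dtype=float)
    frac = min(max(span_points / n, 3.0 / n), 1.0)
    x = np.arange(n, dtype=float)
    return lowess(y, x, frac=frac, it=0, return_sorted=False)


def detect_peak_1d(
    x: np.ndarray,
    y: np.ndarray,
    span_points: int,
    anchor: float,
) -> tuple[int, tuple[int, int], np.ndarray] | None:
    """Peak-pick a 1D trace.

    LOESS-smooths ``y``, finds apexes (points that are the maximum of their
    centered ``span_points`` window and strictly exceed their neighbours),
    and returns the apex nearest ``anchor`` along ``x`` with its bounds
    (nearest local minima or zero crossings of the raw trace) and the
    smoothed trace.  Returns None when the trace is shorter than the span or
    has no strict local maximum.
    """
    n = len(y)
    if n < span_points:
        return None
    ys = loess_smooth(np.asarray(y, dtype=float), span_points)
    h = span_points // 2
    # strictness epsilon guards against numerical wiggle on flat traces
    eps = 1e-6 * float(np.max(np.abs(ys))) if np.any(ys) else 0.0
    candidates = []
    for i in range(n):
        lo, hi = max(0, i - h), min(n, i + h + 1)
        window = ys[lo:hi]
        if ys[i] <= 0 or ys[i] < window.max():
            continue
        left_ok = i == 0 or ys[i] > ys[i - 1] + eps
        right_ok = i == n - 1 or ys[i] > ys[i + 1] + eps
        if left_ok and right_ok and not (i == 0 and i == n - 1):
            candidates.append(i)
    if not candidates:
        return None
    apex = min(candidates, key=lambda i: abs(x[i] - anchor))
    raw = np.asarray(y, dtype=float)
    j = apex
    while j > 0 and ys[j - 1] < ys[j] and raw[j - 1] > 0:
        j -= 1
    k = apex
    while k < n - 1 and ys[k + 1] < ys[k] and raw[k + 1] > 0:
        k += 1
    return apex, (j, k), ys


def locate_precursor(
    seed: Seed,
    archive: FrameArchive,
    params: DetectionParams = DetectionParams(),
) -> tuple[FramePoint, Frame] | None:
    """Find the most intense MS1 point matching the seed's m/z and mobility.

    The precursor frame is the seed's frame index if given (it must resolve
    to an MS1 frame), otherwise the MS1 frame with RT nearest the seed RT.
    """
    if seed.frame is not None:
        frame = archive.frame_by_index(seed.frame)
        if frame.ms_level != 1:
            frame = archive.nearest_ms1(frame.rt)
    else:
        frame = archive.nearest_ms1(seed.rt)
    hw = mz_half_width(seed.mz, params.rule)
    sl = frame.slice_mz(seed.mz - hw, seed.mz + hw)
    mob = frame.mobility[sl]
    inten = frame.intensity[sl]
    mask = np.abs(mob - seed.mobility) <= params.mobility_search_tol
    if not mask.any():
        return None
    rel = np.nonzero(mask)[0]
    best = rel[np.argmax(inten[rel])]
    i = sl.start + best
    return FramePoint(float(frame.mz[i]), float(frame.mobility[i]), float(frame.intensity[i])), frame


def extract_mobilogram(
    frame: Frame,
    mz: float,
    center_mobility: float,
    archive_grid: np.ndarray,
    params: DetectionParams = DetectionParams(),
) -> tuple[np.ndarray, np.ndarray]:
    """Accumulate frame intensities onto the mobility grid.

    Points within the m/z window and within ``eim_half_window`` of
    ``center_mobility`` are binned to their nearest grid cell; grid cells
    with no points are zero.  Returns (grid_slice, trace).
    """
    lo = center_mobility - params.eim_half_window
    hi = center_mobility + params.eim_half_window
    step = archive_grid[1] - archive_grid[0] if len(archive_grid) > 1 else 1.0
    g0 = int(np.searchsorted(archive_grid, lo - 0.5 * step))
    g1 = int(np.searchsorted(archive_grid, hi + 0.5 * step))
    grid = archive_grid[g0:g1]
    trace = np.zeros(len(grid))
    hw = mz_half_width(mz, params.rule)
    sl = frame.slice_mz(mz - hw, mz + hw)
    mob = frame.mobility[sl]
    inten = frame.intensity[sl]
    mask = (mob >= grid[0] - 0.5 * step) & (mob <= grid[-1] + 0.5 * step) if len(grid) else np.zeros(0, bool)
    if mask.any():
        cells = np.clip(np.rint((mob[mask] - grid[0]) / step).astype(int), 0, len(grid) - 1)
        np.add.at(trace, cells, inten[mask])
    return grid, trace


def detect_eim(
    frame: Frame,
    mz: float,
    anchor_mobility: float,
    archive_grid: np.ndarray,
    params: DetectionParams = DetectionParams(),
) -> EIMPeak | None:
    grid, raw = extract_mobilogram(frame, mz, anchor_mobility, archive_grid, params)
    res = detect_peak_1d(grid, raw, params.eim_span, anchor_mobility)
    if res is None:
        return None
    apex, (j, k), ys = res
    if abs(grid[apex] - anchor_mobility) > params.mobility_search_tol + 1e-12:
        return None
    return EIMPeak(
        frame=frame.index,
        apex_mobility=float(grid[apex]),
        bounds=(float(grid[j]), float(grid[k])),
        apex_intensity=float(raw[apex]),
        summed_intensity=float(raw[j : k + 1].sum()),
        grid=grid,
        raw=raw,
        smoothed=ys,
        apex_idx=apex,
        bound_idx=(j, k),
    )


def extend_eim(
    archive: FrameArchive,
    seed: Seed,
    precursor_frame: Frame,
    first_eim: EIMPeak,
    params: DetectionParams = DetectionParams(),
) -> tuple[dict[int, EIMPeak], tuple[int, int]]:
    """Repeat EIM detection in adjacent MS1 frames (step 3).

    Up to ``extension_frames/2`` frames per side, re-anchored on the
    precursor mobility; a side stops after ``max_eim_gap`` consecutive
    frames without a detected mobilogram peak.  Returns the per-MS1-position
    EIM map and the (first, last) MS1 positions scanned.
    """
    grid = archive.mobility_grid
    pos0 = archive.ms1_position(precursor_frame)
    ms1 = archive.ms1_frames
    anchor = first_eim.apex_mobility
    eims: dict[int, EIMPeak] = {pos0: first_eim}
    half = params.extension_frames // 2
    scanned_lo = scanned_hi = pos0
    for direction in (-1, +1):
        misses = 0
        for off in range(1, half + 1):
            pos = pos0 + direction * off
            if pos < 0 or pos >= len(ms1):
                break
            if direction < 0:
                scanned_lo = min(scanned_lo, pos)
            else:
                scanned_hi = max(scanned_hi, pos)
            eim = detect_eim(ms1[pos], seed.mz, anchor, grid, params)
            if eim is None:
                misses += 1
                if misses >= params.max_eim_gap:
                    break
            else:
                misses = 0
                eims[pos] = eim
    return eims, (scanned_lo, scanned_hi)


def assemble_eic(
    eims: dict[int, EIMPeak],
    archive: FrameArchive,
    scanned: tuple[int, int],
) -> tuple[np.ndarray, np.ndarray]:
    """Project per-frame EIM summed intensities onto the LC axis (step 4).

    The trace covers the contiguous scanned MS1 positions; frames without a
    detected EIM contribute zero.  Returns (frame RTs, intensities).
    """
    lo, hi = scanned
    positions = np.arange(lo, hi + 1)
    rts = archive.ms1_rts[positions]
    values = np.array([eims[p].summed_intensity if p in eims else 0.0 for p in positions])
    return rts, values


def integrate_4d(
    archive: FrameArchive,
    eic: EICPeak,
    eims: dict[int, EIMPeak],
    seed: Seed,
    params: DetectionParams = DetectionParams(),
) -> tuple[float, float, float] | None:
    """Integrate the 4D peak volume (step 5).

    Sums MS1 point intensities in the ``integration_frames`` frames nearest
    the EIC apex, within the seed's m/z window and within
    ``integration_mobility_tol`` of the per-frame EIM apex.  Returns
    (reweighted m/z, reported mobility, integrated intensity) or None when
    no point qualifies.
    """
    positions = sorted(eims)
    pos_rts = archive.ms1_rts[positions]
    order = np.argsort(np.abs(pos_rts - eic.apex_rt), kind="stable")
    chosen = [positions[i] for i in order[: params.integration_frames]]
    hw = mz_half_width(seed.mz, params.rule)
    total = 0.0
    weighted_mz = 0.0
    for pos in chosen:
        frame = archive.ms1_frames[pos]
        eim = eims[pos]
        sl = frame.slice_mz(seed.mz - hw, seed.mz + hw)
        mob = frame.mobility[sl]
        inten = frame.intensity[sl]
        mzs = frame.mz[sl]
        mask = np.abs(mob - eim.apex_mobility) <= params.integration_mobility_tol
        total += float(inten[mask].sum())
        weighted_mz += float((inten[mask] * mzs[mask]).sum())
    if total <= 0:
        return None
    apex_pos = min(eims, key=lambda p: abs(archive.ms1_rts[p] - eic.apex_rt))
    return weighted_mz / total, eims[apex_pos].apex_mobility, total


def _continuous(raw: np.ndarray, apex: int, n_required: int) -> bool:
    """At least ``n_required`` consecutive nonzero raw points adjacent to the
    apex on each side (or up to the trace boundary)."""
    n = len(raw)
    left = 0
    i = apex - 1
    while i >= 0 and raw[i] > 0 and left < n_required:
        left += 1
        i -= 1
    if left < n_required and i >= 0:
        return False
    right = 0
    i = apex + 1
    while i < n and raw[i] > 0 and right < n_required:
        right += 1
        i += 1
    if right < n_required and i < n:
        return False
    return True


def check_fidelity(
    eic: EICPeak,
    eim: EIMPeak,
    apex_rt: float,
    apex_mobility: float,
    seed: Seed,
    params: DetectionParams = DetectionParams(),
) -> tuple[bool, str, float, float]:
    """Evaluate the four fidelity criteria.

    Returns (passed, first violated criterion or "", S/N, normalized noise).
    S/N is the EIC apex over a noise estimate (median of the trace outside
    the peak bounds; 10th percentile of the whole trace when fewer than 5
    such positions exist).  Normalized standard noise is the s.d. of the
    raw-minus-smoothed residuals inside the peak bounds over the apex
    height.
    """
    j, k = eic.bound_idx
    apex_height = float(eic.raw[eic.apex_idx])
    outside = np.concatenate([eic.raw[:j], eic.raw[k + 1 :]])
    # baseline-like positions only: a co-eluting neighbour's flank outside
    # the bounds must not masquerade as noise
    outside = outside[outside <= 0.5 * apex_height]
    if len(outside) >= 5:
        noise = float(np.median(outside))
    else:
        noise = float(np.percentile(eic.raw, 10))
    snr = np.inf if noise <= 0 else apex_height / noise
    inside = eic.raw[j : k + 1] - eic.smoothed[j : k + 1]
    norm_noise = float(np.std(inside) / apex_height) if apex_height > 0 else np.inf

    if abs(apex_rt - seed.rt) > params.rt_fidelity_tol:
        return False, "rt-tolerance", snr, norm_noise
    if abs(apex_mobility - seed.mobility) > params.mobility_fidelity_tol:
        return False, "mobility-tolerance", snr, norm_noise
    if not _continuous(eic.raw, eic.apex_idx, params.continuity_points) or not _continuous(
        eim.raw, eim.apex_idx, params.continuity_points
    ):
        return False, "continuity", snr, norm_noise
    if snr < params.min_snr:
        return False, "snr", snr, norm_noise
    if norm_noise >= params.max_norm_noise:
        return False, "norm-noise", snr, norm_noise
    return True, "", snr, norm_noise


def detect_one(
    archive: FrameArchive,
    seed: Seed,
    params: DetectionParams = DetectionParams(),
) -> tuple[Peak4D | None, str]:
    """Run steps 1-5 plus fidelity for one seed.

    Returns (peak, "") on success or (None, failure stage).
    """
    located = locate_precursor(seed, archive, params)
    if located is None:
        return None, "precursor"
    point, frame = located
    grid = archive.mobility_grid
    first_eim = detect_eim(frame, seed.mz, point.mobility, grid, params)
    if first_eim is None:
        return None, "eim"
    eims, scanned = extend_eim(archive, seed, frame, first_eim, params)
    rts, values = assemble_eic(eims, archive, scanned)
    res = detect_peak_1d(rts, values, params.eic_span, seed.rt)
    if res is None:
        return None, "eic"
    apex, (j, k), ys = res
    eic = EICPeak(
        apex_rt=float(rts[apex]),
        bounds=(float(rts[j]), float(rts[k])),
        frame_range=(archive.ms1_frames[scanned[0]].index, archive.ms1_frames[scanned[1]].index),
        rts=rts,
        raw=values,
        smoothed=ys,
        apex_idx=apex,
        bound_idx=(j, k),
    )
    integ = integrate_4d(archive, eic, eims, seed, params)
    if integ is None:
        return None, "integration"
    mz, mobility, intensity = integ
    apex_pos = min(eims, key=lambda p: abs(archive.ms1_rts[p] - eic.apex_rt))
    apex_eim = eims[apex_pos]
    ok, reason, snr, norm_noise = check_fidelity(eic, apex_eim, eic.apex_rt, mobility, seed, params)
    if not ok:
        return None, f"fidelity:{reason}"
    peak = Peak4D(
        mz=mz,
        rt=eic.apex_rt,
        mobility=mobility,
        ccs=float(mobility_to_ccs(mobility, mz, params.ccs)),
        intensity=intensity,
        eim_bounds=apex_eim.bounds,
        eic_bounds=eic.bounds,
        snr=snr,
        norm_noise=norm_noise,
        seed=seed,
        sample=archive.run_id,
    )
    return peak, ""


def detect_from_seeds(
    archive: FrameArchive,
    seeds: list[Seed],
    params: DetectionParams = DetectionParams(),
) -> tuple[list[Peak4D], list[dict]]:
    """Full bottom-up assembly for every seed; at most one peak per seed.

    The log records, per seed, the stage at which detection failed (empty
    for successful seeds).
    """
    peaks: list[Peak4D] = []
    log: list[dict] = []
    for i, seed in enumerate(seeds):
        if seed.seed_id is None:
            seed.seed_id = i
        peak, stage = detect_one(archive, seed, params)
        log.append({"seed_id": seed.seed_id, "mz": seed.mz, "rt": seed.rt,
                    "mobility": seed.mobility, "origin": seed.origin, "stage": stage})
        if peak is not None:
            peaks.append(peak)
    return peaks, log


def seeds_from_unique_spectra(records: list[MS2Record]) -> list[Seed]:
    return [
        Seed(
            mz=r.precursor_mz,
            mobility=r.precursor_mobility,
            rt=r.precursor_rt,
            frame=r.precursor_frame,
            origin="unique-MS2",
            seed_id=i,
        )
        for i, r in enumerate(records)
    ]


def seeds_from_list(seed_df: pd.DataFrame, ccs_params: CCSParams = CCSParams()) -> list[Seed]:
    """Seeds from a precursor list with columns mz, rt, ccs; mobility is
    obtained by inverting the Mason-Schamp conversion."""
    return [
        Seed(
            mz=float(row.mz),
            mobility=float(ccs_to_mobility(row.ccs, row.mz, ccs_params)),
            rt=float(row.rt),
            frame=None,
            origin="precursor-list",
            seed_id=i,
        )
        for i, row in enumerate(seed_df.itertuples(index=False))
    ]


def extract_dia_ms2(
    archive: FrameArchive,
    peak: Peak4D,
    params: DetectionParams = DetectionParams(),
    min_mobility_points: int = 3,
) -> MS2Record | None:
    """Assemble a DIA MS2 spectrum at the peak's RT and mobility apex.

    From the MS2 frame nearest the RT apex whose isolation window covers the
    peak m/z, fragment ions within the peak's EIM mobility bounds are
    grouped by m/z; a group is accepted only if its points occupy at least
    ``min_mobility_points`` contiguous mobility grid cells (true signals
    ride the precursor's mobility profile).  Returns None when no isolation
    window covers the precursor.
    """
    ms2_frames = [
        f
        for f in archive.frames
        if f.ms_level == 2
        and f.isolation is not None
        and f.isolation[0] <= peak.mz <= f.isolation[1]
    ]
    if not ms2_frames:
        return None
    frame = min(ms2_frames, key=lambda f: abs(f.rt - peak.rt))
    lo, hi = peak.eim_bounds
    mask = (frame.mobility >= lo) & (frame.mobility <= hi)
    mzs = frame.mz[mask]
    mobs = frame.mobility[mask]
    ints = frame.intensity[mask]
    if not len(mzs):
        return None
    step = archive.metadata["mobility_grid"][2]
    fragments = []
    start = 0
    for i in range(1, len(mzs) + 1):
        if i == len(mzs) or mzs[i] - mzs[i - 1] > mz_half_width(float(mzs[i - 1]), params.rule):
            g_mob = mobs[start:i]
            g_int = ints[start:i]
            g_mz = mzs[start:i]
            cells = np.unique(np.rint(g_mob / step).astype(np.int64))
            runs = np.split(cells, np.nonzero(np.diff(cells) > 1)[0] + 1)
            if max(len(r) for r in runs) >= min_mobility_points:
                fragments.append(
                    (float((g_mz * g_int).sum() / g_int.sum()), float(g_int.sum()))
                )
            start = i
    if not fragments:
        return None
    return MS2Record(
        precursor_mz=peak.mz,
        precursor_rt=peak.rt,
        precursor_mobility=peak.mobility,
        precursor_frame=frame.index,
        fragments=np.array(fragments),
        title=f"{archive.run_id}.dia@{peak.rt:.1f}s",
    )
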