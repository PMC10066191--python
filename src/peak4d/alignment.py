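"""Cross-sample alignment, grouping and quantification.

Per-sample peak lists are combined into one feature table in five stages:
landmark matching against a reference sample, LOESS retention-time
correction, density-based grouping on (m/z, mobility) bins with a Gaussian
RT kernel, targeted re-detection of peaks missing in some samples,
minimum-fraction filtering, and gap filling by mandatory integration so the
final table has no missing values.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import warnings

import numpy as np
from sklearn.isotonic import IsotonicRegression
from statsmodels.nonparametric.smoothers_lowess import lowess

from .dereplication import cosine_similarity
from .detection import DetectionParams, detect_one
from .models import FeatureGroup, FrameArchive, MS2Record, Peak4D, Seed
from .tolerances import ToleranceRule, mz_half_width

__all__ = [
    "AlignmentParams",
    "Landmark",
    "match_landmarks",
    "correct_rt",
    "group_features",
    "redetect_missing",
    "filter_min_frac",
    "gap_fill",
    "assign_ms2",
    "align_and_group",
]


@dataclass(frozen=True)
class AlignmentParams:
    rule: ToleranceRule = ToleranceRule()
    rt_match_tol: float = 30.0  # landmark / MS2-assignment RT tolerance, s
    mobility_match_tol: float = 0.015
    ms2_match_cutoff: float = 0.8  # dot product when both peaks carry MS2
    min_landmarks: int = 10
    mz_bin: float = 0.015  # Da, absolute
    mobility_bin: float = 0.015
    rt_bandwidth: float = 5.0  # Gaussian kernel bandwidth, s
    min_frac: float = 0.5
    detection: DetectionParams = field(default_factory=DetectionParams)


@dataclass
class Landmark:
    ref_peak: Peak4D
    sample_peak: Peak4D
    ms2_similarity: float | None


def _pair_ok(a: Peak4D, b: Peak4D, p: AlignmentParams) -> tuple[bool, float | None]:
    if abs(a.mz - b.mz) > mz_half_width(min(a.mz, b.mz), p.rule):
        return False, None
    if abs(a.rt - b.rt) > p.rt_match_tol:
        return False, None
    if abs(a.mobility - b.mobility) > p.mobility_match_tol:
        return False, None
    sim = None
    if a.ms2 is not None and b.ms2 is not None:
        sim = cosine_similarity(a.ms2.fragments, b.ms2.fragments, p.rule)
        if sim < p.ms2_match_cutoff:
            return False, sim
    return True, sim


def match_landmarks(
    ref: list[Peak4D],
    sample: list[Peak4D],
    params: AlignmentParams = AlignmentParams(),
) -> list[Landmark]:
    """Best-reciprocal 4D matches between the reference and one sample.

    A candidate pair must agree in m/z, RT, mobility (and MS2 dot product
    when both peaks have spectra); each peak is used at most once, keeping
    the closest match in normalized 4D distance.
    """
    cand = []
    for i, a in enumerate(ref):
        for j, b in enumerate(sample):
            ok, sim = _pair_ok(a, b, params)
            if ok:
                d = np.hypot(
                    np.hypot((a.rt - b.rt) / params.rt_match_tol,
                             (a.mobility - b.mobility) / params.mobility_match_tol),
                    (a.mz - b.mz) / mz_half_width(min(a.mz, b.mz), params.rule),
                )
                cand.append((float(d), i, j, sim))
    cand.sort(key=lambda t: t[0])
    used_ref: set[int] = set()
    used_sample: set[int] = set()
    out = []
    for _, i, j, sim in cand:
        if i in used_ref or j in used_sample:
            continue
        used_ref.add(i)
        used_sample.add(j)
        out.append(Landmark(ref_peak=ref[i], sample_peak=sample[j], ms2_similarity=sim))
    return out


def correct_rt(
    sample: list[Peak4D],
    landmarks: list[Landmark],
    params: AlignmentParams = AlignmentParams(),
) -> list[Peak4D]:
    """LOESS RT correction of a sample onto the reference RT scale.

    A LOESS fit of reference RT against sample RT over the landmarks is
    made monotone by isotonic post-adjustment and applied by interpolation;
    peaks outside the landmark range are shifted by the boundary offset.
    With fewer than ``min_landmarks`` landmarks the correction is the
    identity (with a warning).
    """
    if len(landmarks) < params.min_landmarks:
        warnings.warn(
            f"only {len(landmarks)} landmarks; RT correction falls back to identity",
            stacklevel=2,
        )
        return sample
    x = np.array([lm.sample_peak.rt for lm in landmarks])
    y = np.array([lm.ref_peak.rt for lm in landmarks])
    order = np.argsort(x, kind="stable")
    x, y = x[order], y[order]
    fitted = lowess(y, x, frac=0.75, it=1, return_sorted=False)
    fitted = IsotonicRegression().fit_transform(x, fitted)
    lo_off = fitted[0] - x[0]
    hi_off = fitted[-1] - x[-1]

    def apply(rt: float) -> float:
        if rt <= x[0]:
            return rt + lo_off
        if rt >= x[-1]:
            return rt + hi_off
        return float(np.interp(rt, x, fitted))

    out = []
    for pk in sample:
        corrected = Peak4D(**{**pk.__dict__})
        corrected.rt = apply(pk.rt)
        out.append(corrected)
    return out


def _split_sorted(values: np.ndarray, gap: float) -> list[np.ndarray]:
    """Split sorted-index groups where consecutive values differ by more
    than ``gap`` (anchored by gaps rather than a fixed grid)."""
    order = np.argsort(values, kind="stable")
    if len(order) == 0:
        return []
    breaks = np.nonzero(np.diff(values[order]) > gap)[0] + 1
    return np.split(order, breaks)


def _rt_density_segments(rts: np.ndarray, bandwidth: float) -> list[np.ndarray]:
    """Assign peaks to contiguous RT density regions.

    A Gaussian kernel density with fixed bandwidth is profiled on a fine RT
    grid; local maxima define group centres and local minima the
    boundaries.  Returns a list of index arrays.
    """
    if len(rts) == 1:
        return [np.array([0])]
    lo, hi = rts.min() - 3 * bandwidth, rts.max() + 3 * bandwidth
    grid = np.linspace(lo, hi, max(int((hi - lo) / (bandwidth / 5)), 16))
    dens = np.exp(-0.5 * ((grid[:, None] - rts[None, :]) / bandwidth) ** 2).sum(axis=1)
    maxima = [
        i
        for i in range(1, len(grid) - 1)
        if dens[i] >= dens[i - 1] and dens[i] > dens[i + 1]
    ]
    if len(maxima) <= 1:
        return [np.arange(len(rts))]
    cuts = []
    for a, b in zip(maxima, maxima[1:]):
        cuts.append(grid[a + int(np.argmin(dens[a : b + 1]))])
    labels = np.searchsorted(np.asarray(cuts), rts)
    return [np.nonzero(labels == k)[0] for k in range(len(cuts) + 1) if np.any(labels == k)]


def group_features(
    peaks_by_sample: dict[str, list[Peak4D]],
    params: AlignmentParams = AlignmentParams(),
) -> list[FeatureGroup]:
    """Density-based grouping of corrected peaks into cross-sample features.

    Peaks are binned by m/z (0.015 Da) and mobility (0.015 V*s/cm^2), then
    segmented along RT by Gaussian kernel density (bandwidth 5 s).  Within a
    group, at most one peak per sample is kept (the most intense).
    """
    flat: list[tuple[str, Peak4D]] = [
        (s, pk) for s, pks in peaks_by_sample.items() for pk in pks
    ]
    n_samples = len(peaks_by_sample)
    if not flat:
        return []
    mzs = np.array([pk.mz for _, pk in flat])
    groups: list[FeatureGroup] = []
    for mz_idx in _split_sorted(mzs, params.mz_bin):
        mobs = np.array([flat[i][1].mobility for i in mz_idx])
        for mob_rel in _split_sorted(mobs, params.mobility_bin):
            bin_idx = mz_idx[mob_rel]
            rts = np.array([flat[i][1].rt for i in bin_idx])
            for seg in _rt_density_segments(rts, params.rt_bandwidth):
                members = [flat[i] for i in bin_idx[seg]]
                best: dict[str, Peak4D] = {}
                for s, pk in members:
                    if s not in best or pk.intensity > best[s].intensity:
                        best[s] = pk
                member_peaks = list(best.values())
                groups.append(
                    FeatureGroup(
                        mz=float(np.median([p.mz for p in member_peaks])),
                        rt=float(np.median([p.rt for p in member_peaks])),
                        mobility=float(np.median([p.mobility for p in member_peaks])),
                        ccs=float(np.median([p.ccs for p in member_peaks])),
                        intensities={s: p.intensity for s, p in best.items()},
                        peaks=best,
                        n_samples=n_samples,
                    )
                )
    return groups


def redetect_missing(
    archives_by_sample: dict[str, FrameArchive],
    group: FeatureGroup,
    params: AlignmentParams = AlignmentParams(),
) -> FeatureGroup:
    """Targeted bottom-up detection in samples where the group is missing.

    The group's median m/z and mobility seed a full detection (precursor
    frame: MS1 frame nearest the group RT); re-assembled peaks must pass the
    same fidelity criteria.
    """
    for sample, archive in archives_by_sample.items():
        if sample in group.peaks:
            continue
        seed = Seed(mz=group.mz, mobility=group.mobility, rt=group.rt,
                    frame=None, origin="targeted")
        peak, _stage = detect_one(archive, seed, params.detection)
        if peak is not None:
            group.peaks[sample] = peak
            group.intensities[sample] = peak.intensity
    return group


def filter_min_frac(groups: list[FeatureGroup], min_frac: float = 0.5) -> list[FeatureGroup]:
    """Keep groups detected in at least ``min_frac`` of the samples."""
    return [g for g in groups if g.fraction_present >= min_frac]


def mandatory_integration(
    archive: FrameArchive,
    mz: float,
    rt: float,
    mobility: float,
    params: AlignmentParams = AlignmentParams(),
) -> float:
    """Gap-filling integral: signal in the 5 frames nearest ``rt``, within
    the m/z tolerance and 0.015 V*s/cm^2 of ``mobility``; no fidelity check."""
    det = params.detection
    order = np.argsort(np.abs(archive.ms1_rts - rt), kind="stable")[: det.integration_frames]
    hw = mz_half_width(mz, params.rule)
    total = 0.0
    for pos in order:
        frame = archive.ms1_frames[int(pos)]
        sl = frame.slice_mz(mz - hw, mz + hw)
        mask = np.abs(frame.mobility[sl] - mobility) <= det.integration_mobility_tol
        total += float(frame.intensity[sl][mask].sum())
    return total


def gap_fill(
    archives_by_sample: dict[str, FrameArchive],
    group: FeatureGroup,
    params: AlignmentParams = AlignmentParams(),
) -> FeatureGroup:
    """Replace missing intensities by mandatory integration (zero when no
    point qualifies); afterwards the group has one intensity per sample."""
    for sample, archive in archives_by_sample.items():
        if sample not in group.intensities:
            group.intensities[sample] = mandatory_integration(
                archive, group.mz, group.rt, group.mobility, params
            )
    group.gap_filled = True
    return group


def assign_ms2(
    groups: list[FeatureGroup],
    unique_spectra_by_sample: dict[str, list[MS2Record]],
    params: AlignmentParams = AlignmentParams(),
) -> list[FeatureGroup]:
    """Give each group the most intense matching unique MS2 spectrum.

    A spectrum matches when its precursor m/z, RT and mobility agree with
    the group within the landmark tolerances; intensity is the top-10
    fragment sum.
    """
    all_spectra = [r for recs in unique_spectra_by_sample.values() for r in recs]
    for g in groups:
        best: MS2Record | None = None
        for rec in all_spectra:
            if abs(rec.precursor_mz - g.mz) > mz_half_width(g.mz, params.rule):
                continue
            if abs(rec.precursor_rt - g.rt) > params.rt_match_tol:
                continue
            if abs(rec.precursor_mobility - g.mobility) > params.mobility_match_tol:
                continue
            if best is None or rec.spectral_intensity() > best.spectral_intensity():
                best = rec
        g.representative_ms2 = best
    return groups


def align_and_group(
    peaks_by_sample: dict[str, list[Peak4D]],
    archives_by_sample: dict[str, FrameArchive],
    params: AlignmentParams = AlignmentParams(),
    reference: str | None = None,
    unique_spectra_by_sample: dict[str, list[MS2Record]] | None = None,
) -> list[FeatureGroup]:
    """Full alignment stage: correct, group, re-detect, filter, gap-fill.

    ``reference`` defaults to the middle sample in (insertion) injection
    order.
    """
    samples = list(peaks_by_sample)
    if reference is None:
        reference = samples[len(samples) // 2]
    ref_peaks = peaks_by_sample[reference]
    corrected: dict[str, list[Peak4D]] = {}
    for s in samples:
        if s == reference:
            corrected[s] = peaks_by_sample[s]
            continue
        lms = match_landmarks(ref_peaks, peaks_by_sample[s], params)
        corrected[s] = correct_rt(peaks_by_sample[s], lms, params)
    groups = group_features(corrected, params)
    for g in groups:
        if len(g.peaks) < len(samples):
            redetect_missing(archives_by_sample, g, params)
    groups = filter_min_frac(groups, params.min_frac)
    for g in groups:
        gap_fill(archives_by_sample, g, params)
    if unique_spectra_by_sample is not None:
        assign_ms2(groups, unique_spectra_by_sample, params)
    return groups
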