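"""Synthetic LC-IM-MS data with known ground truth.

Every downstream stage (dereplication, 4D peak detection, alignment,
annotation) is exercised on archives generated here, so no vendor raw data
is needed.  A ground-truth peak is a separable Gaussian in retention time
and mobility; its points are laid on the frame/mobility grid with
ppm-scale m/z jitter, and the per-peak point intensities are normalized so
the total simulated signal of a peak equals its abundance exactly when the
grids cover +/-4 sigma.  DDA MS2 records are emitted near each apex,
repeated to emulate redundant fragmentation, with precursor jitter kept
well inside the dereplication binning tolerances (real DDA triggers close
to the apex).  Noise points are uniform in m/z and mobility with
exponential intensities.

Defaults mirror the acquisition conditions the pipeline targets: 0.53 s
cycle time, mobility range 0.45-1.45 V*s/cm^2 on a 0.001 grid (so the
13-point mobilogram peak span corresponds to 0.013 V*s/cm^2), RT peak
sigma ~2.5 s (11-point chromatographic span at half height), mobility
sigma ~0.006.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .ccs import CCSParams, ccs_to_mobility
from .models import Frame, FrameArchive, MS2Record

__all__ = [
    "GroundTruthPeak",
    "SimulationConfig",
    "simulate_dataset",
    "simulate_replicates",
    "dilution_series",
    "random_truth",
    "isomer_pair_truth",
    "truth_table",
    "expected_box_intensity",
]


@dataclass(frozen=True)
class GroundTruthPeak:
    mz: float  # Da
    rt_apex: float  # s
    mobility_apex: float  # 1/K0, V*s/cm^2
    abundance: float  # total peak volume (counts)
    rt_sigma: float = 2.5  # s
    mobility_sigma: float = 0.006  # V*s/cm^2
    ms2_template: tuple = ()  # ((mz, relative_intensity), ...)
    identity: str | None = None


@dataclass(frozen=True)
class SimulationConfig:
    n_ms1_frames: int = 150
    cycle_time: float = 0.53  # s
    mobility_grid: tuple = (0.45, 1.45, 0.001)  # (min, max, step), V*s/cm^2
    mz_range: tuple = (60.0, 1200.0)
    noise_point_rate: float = 20.0  # mean noise points per MS1 frame
    noise_intensity_scale: float = 30.0  # exponential mean, counts
    mz_jitter_ppm: float = 2.0
    ms2_redundancy: float = 3.0  # mean fragmentations per peak
    ms2_rt_jitter: float = 2.0  # uniform half-width, s (< half the 20 s bin tol)
    ms2_mobility_jitter: float = 0.005  # uniform half-width (< half the 0.030 bin tol)
    ms2_intensity_cv: float = 0.10
    acquisition: str = "DDA"  # "DDA" | "DIA"
    dia_windows: tuple = ()  # ((low, high) m/z, ...), used when acquisition == "DIA"
    seed: int = 42

    def __post_init__(self) -> None:
        lo, hi, step = self.mobility_grid
        if step <= 0 or hi <= lo:
            raise ValueError("mobility grid misconfigured (need step > 0, max > min)")
        if self.cycle_time <= 0 or self.n_ms1_frames < 1:
            raise ValueError("need positive cycle_time and at least one MS1 frame")

    @property
    def grid(self) -> np.ndarray:
        lo, hi, step = self.mobility_grid
        n = int(round((hi - lo) / step)) + 1
        return lo + step * np.arange(n)

    @property
    def ms1_rts(self) -> np.ndarray:
        return self.cycle_time * (1.0 + np.arange(self.n_ms1_frames))


def _gaussian_weights(grid: np.ndarray, apex: float, sigma: float, span: float = 4.0):
    """Discrete Gaussian weights on ``grid`` within ``span`` sigma of the
    apex, normalized to sum to 1.  Returns (mask_indices, weights)."""
    idx = np.nonzero(np.abs(grid - apex) <= span * sigma)[0]
    if len(idx) == 0:
        return idx, np.empty(0)
    w = np.exp(-0.5 * ((grid[idx] - apex) / sigma) ** 2)
    return idx, w / w.sum()


def simulate_dataset(
    truth: list[GroundTruthPeak],
    config: SimulationConfig,
    run_id: str = "sim",
) -> tuple[FrameArchive, list[MS2Record], pd.DataFrame]:
    """Simulate one run: frame archive, DDA MS2 records and the truth table.

    Deterministic for a fixed (truth, config) pair: the same seed yields a
    bit-identical archive.
    """
    rng = np.random.default_rng(config.seed)
    grid = config.grid
    rts = config.ms1_rts
    n_windows = len(config.dia_windows) if config.acquisition == "DIA" else 0
    frames_per_cycle = 1 + n_windows

    # per-MS1-frame point buffers
    buf_mz = [[] for _ in range(config.n_ms1_frames)]
    buf_mob = [[] for _ in range(config.n_ms1_frames)]
    buf_int = [[] for _ in range(config.n_ms1_frames)]
    # DIA MS2 buffers: [frame][window] -> lists
    dia_buf = [
        [([], [], []) for _ in range(n_windows)] for _ in range(config.n_ms1_frames)
    ]

    for peak in truth:
        f_idx, w_rt = _gaussian_weights(rts, peak.rt_apex, peak.rt_sigma)
        m_idx, w_mob = _gaussian_weights(grid, peak.mobility_apex, peak.mobility_sigma)
        if len(f_idx) == 0 or len(m_idx) == 0:
            continue
        for fi, wf in zip(f_idx, w_rt):
            inten = peak.abundance * wf * w_mob
            jitter = rng.normal(0.0, config.mz_jitter_ppm * 1e-6, size=len(m_idx))
            buf_mz[fi].append(peak.mz * (1.0 + jitter))
            buf_mob[fi].append(grid[m_idx])
            buf_int[fi].append(inten)
            if n_windows and peak.ms2_template:
                for wi, (lo, hi) in enumerate(config.dia_windows):
                    if not (lo <= peak.mz <= hi):
                        continue
                    mzs, mobs, ints = dia_buf[fi][wi]
                    for fmz, frel in peak.ms2_template:
                        fj = rng.normal(0.0, config.mz_jitter_ppm * 1e-6, size=len(m_idx))
                        mzs.append(fmz * (1.0 + fj))
                        mobs.append(grid[m_idx])
                        ints.append(frel * peak.abundance * wf * w_mob)

    # noise points, per MS1 frame
    mz_lo, mz_hi = config.mz_range
    for fi in range(config.n_ms1_frames):
        n_noise = rng.poisson(config.noise_point_rate)
        if n_noise:
            buf_mz[fi].append(rng.uniform(mz_lo, mz_hi, size=n_noise))
            buf_mob[fi].append(grid[rng.integers(0, len(grid), size=n_noise)])
            buf_int[fi].append(rng.exponential(config.noise_intensity_scale, size=n_noise))

    frames: list[Frame] = []
    ms1_index_of = np.empty(config.n_ms1_frames, dtype=int)
    for fi in range(config.n_ms1_frames):
        index = fi * frames_per_cycle + 1
        ms1_index_of[fi] = index
        mz = np.concatenate(buf_mz[fi]) if buf_mz[fi] else np.empty(0)
        mob = np.concatenate(buf_mob[fi]) if buf_mob[fi] else np.empty(0)
        inten = np.concatenate(buf_int[fi]) if buf_int[fi] else np.empty(0)
        frames.append(Frame(index=index, rt=float(rts[fi]), ms_level=1,
                            mz=mz, mobility=mob, intensity=inten))
        for wi in range(n_windows):
            mzs, mobs, ints = dia_buf[fi][wi]
            frames.append(
                Frame(
                    index=index + 1 + wi,
                    rt=float(rts[fi]) + config.cycle_time * (wi + 1) / frames_per_cycle,
                    ms_level=2,
                    mz=np.concatenate(mzs) if mzs else np.empty(0),
                    mobility=np.concatenate(mobs) if mobs else np.empty(0),
                    intensity=np.concatenate(ints) if ints else np.empty(0),
                    isolation=tuple(config.dia_windows[wi]),
                )
            )

    archive = FrameArchive(
        run_id=run_id,
        frames=frames,
        metadata={
            "mode": config.acquisition,
            "cycle_time": config.cycle_time,
            "mobility_grid": tuple(config.mobility_grid),
        },
    )

    # redundant DDA MS2 sampling near each apex
    records: list[MS2Record] = []
    if config.acquisition == "DDA":
        for pi, peak in enumerate(truth):
            if not peak.ms2_template:
                continue
            n_rep = 1 + rng.poisson(max(config.ms2_redundancy - 1.0, 0.0))
            for r in range(n_rep):
                rt = peak.rt_apex + rng.uniform(-config.ms2_rt_jitter, config.ms2_rt_jitter)
                mob = peak.mobility_apex + rng.uniform(
                    -config.ms2_mobility_jitter, config.ms2_mobility_jitter
                )
                pmz = peak.mz * (1.0 + rng.normal(0.0, config.mz_jitter_ppm * 1e-6))
                fi = int(np.argmin(np.abs(rts - rt)))
                frag = np.array(peak.ms2_template, dtype=float)
                scale = peak.abundance * np.exp(-0.5 * ((rt - peak.rt_apex) / peak.rt_sigma) ** 2)
                noise = np.exp(rng.normal(0.0, config.ms2_intensity_cv, size=len(frag)))
                frag = np.column_stack(
                    [
                        frag[:, 0] * (1.0 + rng.normal(0.0, config.mz_jitter_ppm * 1e-6, len(frag))),
                        frag[:, 1] * scale * noise / 1e3,
                    ]
                )
                records.append(
                    MS2Record(
                        precursor_mz=float(pmz),
                        precursor_rt=float(rt),
                        precursor_mobility=float(mob),
                        precursor_frame=int(ms1_index_of[fi]),
                        fragments=frag,
                        title=f"{run_id}.peak{pi}.rep{r}",
                    )
                )

    return archive, records, truth_table(truth)


def truth_table(truth: list[GroundTruthPeak]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "mz": [p.mz for p in truth],
            "rt_apex": [p.rt_apex for p in truth],
            "mobility_apex": [p.mobility_apex for p in truth],
            "abundance": [p.abundance for p in truth],
            "identity": [p.identity for p in truth],
        }
    )


def simulate_replicates(
    truth: list[GroundTruthPeak],
    config: SimulationConfig,
    n: int,
    cv: float = 0.15,
) -> list[tuple[FrameArchive, list[MS2Record], pd.DataFrame]]:
    """Simulate ``n`` technical replicates.

    Replicate ``r`` uses seed ``config.seed + r`` and multiplies every
    abundance by a lognormal technical error with coefficient of variation
    ``cv`` (cv=0 reproduces the truth abundances exactly).
    """
    if n < 1:
        raise ValueError("need n >= 1 replicates")
    out = []
    sigma = float(np.sqrt(np.log1p(cv**2)))
    for r in range(n):
        cfg = replace(config, seed=config.seed + r)
        rng = np.random.default_rng(10_000_019 + cfg.seed)
        if cv > 0:
            factors = np.exp(rng.normal(-0.5 * sigma**2, sigma, size=len(truth)))
        else:
            factors = np.ones(len(truth))
        t_r = [replace(p, abundance=p.abundance * f) for p, f in zip(truth, factors)]
        out.append(simulate_dataset(t_r, cfg, run_id=f"rep{r + 1}"))
    return out


def dilution_series(
    truth: list[GroundTruthPeak],
    config: SimulationConfig,
    factors: list[float],
) -> list[tuple[FrameArchive, list[MS2Record], pd.DataFrame]]:
    """One dataset per dilution factor f >= 1, abundances scaled by 1/f;
    the noise model is unchanged."""
    if any(f < 1 for f in factors):
        raise ValueError("dilution factors must be >= 1")
    out = []
    for f in factors:
        t_f = [replace(p, abundance=p.abundance / f) for p in truth]
        out.append(simulate_dataset(t_f, config, run_id=f"dil{f:g}x"))
    return out


def _default_template(rng: np.random.Generator, precursor_mz: float) -> tuple:
    n = int(rng.integers(4, 9))
    frag_mz = np.sort(rng.uniform(50.0, max(precursor_mz - 10.0, 60.0), size=n))
    rel = rng.uniform(50.0, 1000.0, size=n)
    return tuple((float(m), float(i)) for m, i in zip(frag_mz, rel))


def random_truth(
    n: int,
    seed: int = 0,
    mz_range: tuple = (80.0, 900.0),
    rt_range: tuple = (15.0, 65.0),
    mobility_range: tuple = (0.55, 1.35),
    abundance_range: tuple = (2e5, 2e6),
    min_mz_sep: float = 0.5,
) -> list[GroundTruthPeak]:
    """Draw ``n`` well-separated ground-truth peaks.

    Peaks are m/z-separated by at least ``min_mz_sep`` so each is a distinct
    feature under the default tolerances.
    """
    rng = np.random.default_rng(seed)
    mzs: list[float] = []
    while len(mzs) < n:
        cand = float(rng.uniform(*mz_range))
        if all(abs(cand - m) > min_mz_sep for m in mzs):
            mzs.append(cand)
    peaks = []
    for i, mz in enumerate(mzs):
        peaks.append(
            GroundTruthPeak(
                mz=mz,
                rt_apex=float(rng.uniform(*rt_range)),
                mobility_apex=float(rng.uniform(*mobility_range)),
                abundance=float(np.exp(rng.uniform(np.log(abundance_range[0]),
                                                   np.log(abundance_range[1])))),
                ms2_template=_default_template(rng, mz),
                identity=f"truth_{i}",
            )
        )
    return peaks


def isomer_pair_truth(
    mz: float,
    rt: float,
    ccs: float,
    delta_ccs_pct: float,
    delta_rt: float = 0.0,
    abundance: float = 1e6,
    ccs_params: CCSParams = CCSParams(),
    seed: int = 5,
) -> list[GroundTruthPeak]:
    """A co-eluting same-m/z isomer pair at a controlled CCS difference.

    The second isomer's CCS is ``ccs * (1 + delta_ccs_pct/100)`` and its RT
    apex is shifted by ``delta_rt`` seconds -- the scenarios where ion
    mobility (or, for sub-percent CCS differences, the LC dimension) must
    resolve the pair.
    """
    rng = np.random.default_rng(seed)
    ccs2 = ccs * (1.0 + delta_ccs_pct / 100.0)
    pair = []
    for k, (c, dt) in enumerate([(ccs, 0.0), (ccs2, delta_rt)]):
        pair.append(
            GroundTruthPeak(
                mz=mz,
                rt_apex=rt + dt,
                mobility_apex=float(ccs_to_mobility(c, mz, ccs_params)),
                abundance=abundance,
                ms2_template=_default_template(rng, mz),
                identity=f"isomer_{k + 1}",
            )
        )
    return pair


def expected_box_intensity(
    peak: GroundTruthPeak,
    config: SimulationConfig,
    n_frames: int = 5,
    mobility_half_width: float = 0.015,
) -> float:
    """Ground-truth signal mass inside the 4D integration box.

    The detector integrates the ``n_frames`` MS1 frames nearest the EIC apex
    and mobility within ``mobility_half_width`` of the EIM apex; this oracle
    evaluates the same box on the noise-free generator weights.
    """
    rts = config.ms1_rts
    grid = config.grid
    f_idx, w_rt = _gaussian_weights(rts, peak.rt_apex, peak.rt_sigma)
    m_idx, w_mob = _gaussian_weights(grid, peak.mobility_apex, peak.mobility_sigma)
    order = np.argsort(np.abs(rts[f_idx] - peak.rt_apex), kind="stable")[:n_frames]
    rt_mass = w_rt[order].sum()
    apex_cell = grid[m_idx][np.argmax(w_mob)]
    mob_mass = w_mob[np.abs(grid[m_idx] - apex_cell) <= mobility_half_width].sum()
    return float(peak.abundance * rt_mass * mob_mass)
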