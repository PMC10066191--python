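"""Bottom-up 4D peak assembly: 1D peak picking, precursor search,
mobilogram/chromatogram assembly, integration, fidelity, DIA MS2."""

import numpy as np
import pytest

from peak4d.detection import (
    DetectionParams,
    EICPeak,
    EIMPeak,
    detect_from_seeds,
    detect_one,
    detect_peak_1d,
    extract_dia_ms2,
    extract_mobilogram,
    integrate_4d,
    locate_precursor,
    seeds_from_list,
    seeds_from_unique_spectra,
)
from peak4d.dereplication import dereplicate
from peak4d.models import Frame, FrameArchive, Peak4D, Seed
from peak4d.simulate import (
    GroundTruthPeak,
    SimulationConfig,
    isomer_pair_truth,
    random_truth,
    simulate_dataset,
)


class TestDetectPeak1D:
    def grid(self, n=101):
        return np.linspace(0.0, 1.0, n)

    def test_clean_gaussian_apex_at_truth(self):
        x = self.grid()
        y = 1000 * np.exp(-0.5 * ((x - 0.5) / 0.05) ** 2)
        apex, (j, k), ys = detect_peak_1d(x, y, 13, anchor=0.5)
        assert abs(x[apex] - 0.5) <= x[1] - x[0]
        assert j < apex < k

    def test_flat_trace_has_no_apex(self):
        x = self.grid(21)
        assert detect_peak_1d(x, np.full(21, 5.0), 13, anchor=0.5) is None

    def test_trace_shorter_than_span_absent(self):
        x = self.grid(7)
        y = np.exp(-0.5 * ((x - 0.5) / 0.1) ** 2)
        assert detect_peak_1d(x, y, 13, anchor=0.5) is None

    def test_nearest_apex_to_anchor_selected(self):
        x = self.grid(201)
        y = 1000 * np.exp(-0.5 * ((x - 0.30) / 0.04) ** 2)
        y += 2000 * np.exp(-0.5 * ((x - 0.70) / 0.04) ** 2)
        apex, _, _ = detect_peak_1d(x, y, 13, anchor=0.35)
        assert abs(x[apex] - 0.30) < 0.05  # nearer, although less intense
        apex2, _, _ = detect_peak_1d(x, y, 13, anchor=0.65)
        assert abs(x[apex2] - 0.70) < 0.05

    @pytest.mark.parametrize("sigma", [0.03, 0.05, 0.08, 0.12])
    def test_loess_never_shifts_clean_apex_more_than_one_step(self, sigma):
        x = self.grid(151)
        y = 500 * np.exp(-0.5 * ((x - 0.48) / sigma) ** 2)
        apex, _, _ = detect_peak_1d(x, y, 13, anchor=0.48)
        assert abs(x[apex] - x[np.argmax(y)]) <= (x[1] - x[0]) + 1e-12


class TestLocatePrecursor:
    def test_most_intense_matching_point(self, tiny_archive):
        seed = Seed(mz=100.001, mobility=0.80, rt=1.0, frame=1)
        point, frame = locate_precursor(seed, tiny_archive)
        assert point.intensity == 30.0
        assert frame.index == 1

    def test_absent_when_no_point_within_tolerance(self, tiny_archive):
        seed = Seed(mz=100.001, mobility=1.0, rt=1.0, frame=1)  # mobility off by 0.2
        assert locate_precursor(seed, tiny_archive) is None

    def test_unknown_frame_index_raises(self, tiny_archive):
        seed = Seed(mz=100.0, mobility=0.8, rt=1.0, frame=99)
        with pytest.raises(KeyError, match="99"):
            locate_precursor(seed, tiny_archive)

    def test_list_seeded_mode_uses_nearest_rt_frame(self, tiny_archive):
        seed = Seed(mz=100.001, mobility=0.80, rt=2.1, frame=None, origin="precursor-list")
        point, frame = locate_precursor(seed, tiny_archive)
        assert frame.index == 2 and point.intensity == 20.0


class TestExtractMobilogram:
    def test_empty_frame_all_zero(self, tiny_archive):
        grid = tiny_archive.mobility_grid
        g, trace = extract_mobilogram(tiny_archive.frames[2], 100.0, 0.8, grid)
        assert np.all(trace == 0.0)

    def test_single_point_single_cell(self, tiny_archive):
        grid = tiny_archive.mobility_grid
        g, trace = extract_mobilogram(tiny_archive.frames[1], 100.001, 0.801, grid)
        nz = np.nonzero(trace)[0]
        assert len(nz) == 1
        assert g[nz[0]] == pytest.approx(0.801)
        assert trace[nz[0]] == 20.0


def test_integration_weighted_mean(tiny_archive):
    # two qualifying points (100.000, 10) and (100.002, 30) in frame 1
    eim = EIMPeak(frame=1, apex_mobility=0.800, bounds=(0.795, 0.805),
                  apex_intensity=40.0, summed_intensity=40.0,
                  grid=np.array([0.8]), raw=np.array([40.0]),
                  smoothed=np.array([40.0]), apex_idx=0, bound_idx=(0, 0))
    eic = EICPeak(apex_rt=1.0, bounds=(0.5, 1.5), frame_range=(1, 1),
                  rts=np.array([1.0]), raw=np.array([40.0]),
                  smoothed=np.array([40.0]), apex_idx=0, bound_idx=(0, 0))
    seed = Seed(mz=100.001, mobility=0.8, rt=1.0, frame=1)
    params = DetectionParams(integration_frames=1)
    mz, mobility, intensity = integrate_4d(tiny_archive, eic, {0: eim}, seed, params)
    assert intensity == pytest.approx(40.0)
    assert mz == pytest.approx(100.0015, abs=1e-6)
    assert mobility == pytest.approx(0.800)


class TestEndToEnd:
    def _detect(self, truth, seed=41, **cfg_kwargs):
        cfg = SimulationConfig(seed=seed, **cfg_kwargs)
        archive, records, _ = simulate_dataset(truth, cfg)
        unique, _ = dereplicate(records)
        peaks, log = detect_from_seeds(archive, seeds_from_unique_spectra(unique))
        return cfg, archive, unique, peaks, log

    def test_recovers_truth_peaks_with_tight_apexes(self):
        truth = random_truth(10, seed=41)
        _, _, unique, peaks, _ = self._detect(truth)
        assert len(peaks) >= 9
        for p in peaks:
            t = min(truth, key=lambda t: abs(t.mz - p.mz))
            assert abs(p.rt - t.rt_apex) <= 2.0
            assert abs(p.mobility - t.mobility_apex) <= 0.003
            assert abs(p.mz - t.mz) / t.mz * 1e6 <= 10.0

    def test_detection_is_deterministic(self):
        truth = random_truth(5, seed=43)
        cfg = SimulationConfig(seed=43)
        archive, records, _ = simulate_dataset(truth, cfg)
        unique, _ = dereplicate(records)
        p1, _ = detect_from_seeds(archive, seeds_from_unique_spectra(unique))
        p2, _ = detect_from_seeds(archive, seeds_from_unique_spectra(unique))
        assert [(a.mz, a.rt, a.mobility, a.intensity) for a in p1] == [
            (a.mz, a.rt, a.mobility, a.intensity) for a in p2]

    def test_reported_apex_within_seed_tolerances(self):
        truth = random_truth(8, seed=47)
        _, _, _, peaks, _ = self._detect(truth, seed=47)
        for p in peaks:
            assert abs(p.rt - p.seed.rt) <= 10.0
            assert abs(p.mobility - p.seed.mobility) <= 0.015

    def test_seed_in_empty_region_fails_at_precursor_stage(self):
        cfg = SimulationConfig(seed=51, noise_point_rate=0.0)
        archive, _, _ = simulate_dataset([], cfg)
        seeds = [Seed(mz=500.0, mobility=0.9, rt=40.0, origin="precursor-list")]
        peaks, log = detect_from_seeds(archive, seeds)
        assert peaks == [] and log[0]["stage"] == "precursor"

    def test_peak_near_run_start_one_sided_extension(self):
        peak = GroundTruthPeak(mz=300.0, rt_apex=2.0, mobility_apex=0.9, abundance=1e6,
                               ms2_template=((120.0, 500.0), (180.0, 800.0)))
        cfg = SimulationConfig(seed=53, noise_point_rate=0.0)
        archive, records, _ = simulate_dataset([peak], cfg)
        unique, _ = dereplicate(records)
        peaks, _ = detect_from_seeds(archive, seeds_from_unique_spectra(unique))
        assert len(peaks) == 1
        assert abs(peaks[0].rt - 2.0) <= 2.0

    def test_apex_far_from_seed_fails_rt_tolerance(self):
        peak = GroundTruthPeak(mz=300.0, rt_apex=40.0, mobility_apex=0.9, abundance=1e6)
        cfg = SimulationConfig(seed=57, noise_point_rate=0.0)
        archive, _, _ = simulate_dataset([peak], cfg)
        seed = Seed(mz=300.0, mobility=0.9, rt=52.0, origin="precursor-list")
        peaks, log = detect_from_seeds(archive, [seed])
        assert peaks == []
        assert log[0]["stage"] in ("fidelity:rt-tolerance", "eic", "precursor")

    def test_intensity_monotone_across_noise_free_dilutions(self):
        truth = random_truth(4, seed=59)
        base = None
        for f in (1.0, 4.0, 16.0):
            scaled = [GroundTruthPeak(**{**t.__dict__, "abundance": t.abundance / f})
                      for t in truth]
            _, _, _, peaks, _ = self._detect(scaled, seed=59, noise_point_rate=0.0)
            total = sum(p.intensity for p in peaks)
            if base is not None:
                assert total < base
            base = total

    def test_coeluting_isomer_pair_resolved_in_mobility(self):
        pair = isomer_pair_truth(mz=310.0, rt=30.0, ccs=170.0, delta_ccs_pct=2.6)
        _, _, unique, peaks, _ = self._detect(pair, seed=61)
        assert len(peaks) == 2
        mobs = sorted(p.mobility for p in peaks)
        assert mobs[1] - mobs[0] > 0.01

    def test_seeds_from_list_round_trip_ccs(self):
        import pandas as pd
        df = pd.DataFrame({"mz": [300.0], "rt": [30.0], "ccs": [170.0]})
        seeds = seeds_from_list(df)
        from peak4d.ccs import mobility_to_ccs
        assert mobility_to_ccs(seeds[0].mobility, 300.0) == pytest.approx(170.0, rel=1e-9)


class TestDIAExtraction:
    def _dia_dataset(self):
        truth = random_truth(4, seed=63, mz_range=(100.0, 500.0))
        cfg = SimulationConfig(seed=63, acquisition="DIA",
                               dia_windows=((50.0, 300.0), (300.0, 650.0)))
        archive, _, _ = simulate_dataset(truth, cfg)
        seeds = [Seed(mz=t.mz, mobility=t.mobility_apex, rt=t.rt_apex,
                      origin="precursor-list") for t in truth]
        peaks, _ = detect_from_seeds(archive, seeds)
        return truth, archive, peaks

    def test_recovers_fragment_templates(self):
        truth, archive, peaks = self._dia_dataset()
        assert len(peaks) == len(truth)
        for p in peaks:
            t = min(truth, key=lambda t: abs(t.mz - p.mz))
            rec = extract_dia_ms2(archive, p)
            assert rec is not None
            template = np.sort([m for m, _ in t.ms2_template])
            assert len(rec.fragments) == len(template)
            assert np.allclose(np.sort(rec.fragments[:, 0]), template, rtol=2e-5)

    def test_single_mobility_cell_fragment_rejected(self):
        frames = [
            Frame(index=1, rt=1.0, ms_level=1, mz=[300.0], mobility=[0.9], intensity=[100.0]),
            Frame(index=2, rt=1.5, ms_level=2, mz=[150.0], mobility=[0.9], intensity=[50.0],
                  isolation=(200.0, 400.0)),
        ]
        archive = FrameArchive("x", frames, {"mode": "DIA", "cycle_time": 1.0,
                                             "mobility_grid": (0.4, 1.5, 0.001)})
        peak = Peak4D(mz=300.0, rt=1.0, mobility=0.9, ccs=170.0, intensity=100.0,
                      eim_bounds=(0.88, 0.92), eic_bounds=(0.0, 2.0),
                      snr=10.0, norm_noise=0.1)
        assert extract_dia_ms2(archive, peak) is None

    def test_uncovered_precursor_absent(self):
        truth, archive, peaks = self._dia_dataset()
        p = peaks[0]
        p_out = Peak4D(**{**p.__dict__, "mz": 900.0})
        assert extract_dia_ms2(archive, p_out) is None
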