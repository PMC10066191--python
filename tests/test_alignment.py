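"""Cross-sample alignment: landmarks, RT correction, grouping, min-frac,
gap filling, MS2 assignment."""

import numpy as np
import pytest

from peak4d.alignment import (
    AlignmentParams,
    align_and_group,
    correct_rt,
    filter_min_frac,
    gap_fill,
    group_features,
    match_landmarks,
    redetect_missing,
)
from peak4d.models import FeatureGroup, MS2Record, Peak4D
from peak4d.simulate import SimulationConfig, random_truth, simulate_dataset, simulate_replicates
from peak4d.dereplication import dereplicate
from peak4d.detection import detect_from_seeds, seeds_from_unique_spectra
from peak4d.pipeline import process_sample
from peak4d.config import PipelineConfig


def make_peak(mz=300.0, rt=30.0, mobility=0.9, intensity=1000.0, ms2=None):
    return Peak4D(mz=mz, rt=rt, mobility=mobility, ccs=170.0, intensity=intensity,
                  eim_bounds=(mobility - 0.01, mobility + 0.01), eic_bounds=(rt - 5, rt + 5),
                  snr=10.0, norm_noise=0.1, ms2=ms2)


class TestLandmarks:
    def test_identical_lists_all_self_matched(self):
        peaks = [make_peak(mz=200.0 + 10 * i, rt=20.0 + 5 * i) for i in range(8)]
        lms = match_landmarks(peaks, peaks)
        assert len(lms) == 8
        assert all(lm.ref_peak is lm.sample_peak for lm in lms)

    def test_uniform_shift_matched_with_expected_delta(self):
        ref = [make_peak(mz=200.0 + 10 * i, rt=20.0 + 5 * i) for i in range(10)]
        sample = [make_peak(mz=p.mz, rt=p.rt + 5.0) for p in ref]
        lms = match_landmarks(ref, sample)
        assert len(lms) == 10
        deltas = [lm.sample_peak.rt - lm.ref_peak.rt for lm in lms]
        assert np.allclose(deltas, 5.0)

    def test_reciprocal_best_is_unique(self):
        ref = [make_peak(rt=30.0), make_peak(rt=32.0)]
        sample = [make_peak(rt=30.5)]
        lms = match_landmarks(ref, sample)
        assert len(lms) == 1
        assert lms[0].ref_peak.rt == 30.0  # the closer of the two


class TestRTCorrection:
    def _landmarks(self, shift_fn, n=20):
        ref = [make_peak(mz=150.0 + 20 * i, rt=10.0 + 3.0 * i) for i in range(n)]
        sample = [make_peak(mz=p.mz, rt=shift_fn(p.rt)) for p in ref]
        return match_landmarks(ref, sample), sample

    def test_zero_shift_is_near_identity(self):
        lms, sample = self._landmarks(lambda rt: rt)
        corrected = correct_rt(sample, lms)
        assert max(abs(c.rt - s.rt) for c, s in zip(corrected, sample)) < 0.5

    def test_linear_drift_recovered(self):
        lms, sample = self._landmarks(lambda rt: rt * 1.02)
        corrected = correct_rt(sample, lms)
        ref_rts = [10.0 + 3.0 * i for i in range(20)]
        resid = [abs(c.rt - r) for c, r in zip(corrected, ref_rts)]
        assert max(resid) < 1.0

    def test_extrapolation_uses_boundary_offset(self):
        lms, sample = self._landmarks(lambda rt: rt + 4.0)
        outside = [make_peak(rt=200.0)]  # beyond the landmark range
        corrected = correct_rt(outside, lms)
        assert corrected[0].rt == pytest.approx(200.0 - 4.0, abs=0.5)

    def test_too_few_landmarks_identity_with_warning(self):
        lms, sample = self._landmarks(lambda rt: rt + 4.0, n=5)
        with pytest.warns(UserWarning, match="landmarks"):
            corrected = correct_rt(sample, lms)
        assert [c.rt for c in corrected] == [s.rt for s in sample]


class TestGrouping:
    def test_same_coordinates_one_group(self):
        peaks = {f"s{i}": [make_peak()] for i in range(4)}
        groups = group_features(peaks)
        assert len(groups) == 1
        assert len(groups[0].peaks) == 4

    def test_rt_clusters_30s_apart_split(self):
        peaks = {
            "s1": [make_peak(rt=30.0), make_peak(rt=60.0)],
            "s2": [make_peak(rt=30.5), make_peak(rt=60.5)],
        }
        groups = group_features(peaks)
        assert len(groups) == 2
        rts = sorted(g.rt for g in groups)
        assert rts[0] == pytest.approx(30.25, abs=1.0)
        assert rts[1] == pytest.approx(60.25, abs=1.0)

    def test_mobility_bin_separation(self):
        peaks = {
            "s1": [make_peak(mobility=0.90), make_peak(mobility=0.95)],
        }
        groups = group_features(peaks)
        assert len(groups) == 2

    def test_grouping_is_partition(self):
        rng = np.random.default_rng(5)
        peaks = {
            f"s{j}": [make_peak(mz=100.0 + 50 * i + rng.normal(0, 0.002),
                                rt=20.0 + 4 * i + rng.normal(0, 0.5),
                                mobility=0.7 + 0.05 * i + rng.normal(0, 0.001))
                      for i in range(6)]
            for j in range(3)
        }
        groups = group_features(peaks)
        n_in = sum(len(v) for v in peaks.values())
        n_grouped = sum(len(g.peaks) for g in groups)
        assert n_grouped == n_in  # every peak in exactly one group

    def test_at_most_one_peak_per_sample_keeps_most_intense(self):
        peaks = {"s1": [make_peak(intensity=100.0), make_peak(intensity=900.0)]}
        groups = group_features(peaks)
        assert len(groups) == 1
        assert groups[0].intensities["s1"] == 900.0


class TestMinFrac:
    def _group(self, present, total=6):
        g = FeatureGroup(mz=300.0, rt=30.0, mobility=0.9, ccs=170.0,
                         intensities={f"s{i}": 1.0 for i in range(present)},
                         peaks={f"s{i}": make_peak() for i in range(present)},
                         n_samples=total)
        return g

    def test_three_of_six_kept_two_dropped_at_half(self):
        kept = filter_min_frac([self._group(3), self._group(2)], 0.5)
        assert len(kept) == 1 and len(kept[0].peaks) == 3

    def test_min_frac_zero_keeps_all(self):
        assert len(filter_min_frac([self._group(0), self._group(1)], 0.0)) == 2


class TestRedetectAndGapFill:
    def test_unseeded_peak_recovered_and_truly_absent_not(self):
        # sample B has the peak but no MS2 record; sample C has no peak at all
        truth = random_truth(5, seed=67)
        cfg = SimulationConfig(seed=67)
        config = PipelineConfig()
        arch_a, recs_a, _ = simulate_dataset(truth, cfg, run_id="A")
        arch_b, recs_b, _ = simulate_dataset(truth, SimulationConfig(seed=68), run_id="B")
        target = truth[0]
        recs_b = [r for r in recs_b if abs(r.precursor_mz - target.mz) > 1.0]
        truth_c = [t for t in truth if t.identity != target.identity]
        arch_c, recs_c, _ = simulate_dataset(truth_c, SimulationConfig(seed=69), run_id="C")

        peaks = {}
        for name, arch, recs in [("A", arch_a, recs_a), ("B", arch_b, recs_b),
                                 ("C", arch_c, recs_c)]:
            pks, _, _ = process_sample(arch, config, ms2_records=recs)
            peaks[name] = pks
        groups = group_features(peaks)
        g = min(groups, key=lambda g: abs(g.mz - target.mz))
        assert "A" in g.peaks and "B" not in g.peaks
        archives = {"A": arch_a, "B": arch_b, "C": arch_c}
        redetect_missing(archives, g)
        assert "B" in g.peaks  # present in the raw data, recovered
        assert "C" not in g.peaks  # truly absent, fidelity fails

    def test_gap_fill_completes_and_leaves_complete_groups_unchanged(self):
        truth = random_truth(3, seed=71)
        arch, _, _ = simulate_dataset(truth, SimulationConfig(seed=71), run_id="A")
        empty_arch, _, _ = simulate_dataset([], SimulationConfig(seed=72, noise_point_rate=0.0),
                                            run_id="B")
        g = FeatureGroup(mz=truth[0].mz, rt=truth[0].rt_apex,
                         mobility=truth[0].mobility_apex, ccs=170.0,
                         intensities={"A": 500.0}, peaks={"A": make_peak()}, n_samples=2)
        gap_fill({"A": arch, "B": empty_arch}, g)
        assert g.gap_filled
        assert g.intensities["A"] == 500.0  # present value untouched
        assert g.intensities["B"] == 0.0  # empty region integrates to zero

    def test_gap_fill_recovers_signal_where_peak_exists(self):
        truth = random_truth(1, seed=73)
        arch, _, _ = simulate_dataset(truth, SimulationConfig(seed=73, noise_point_rate=0.0),
                                      run_id="A")
        g = FeatureGroup(mz=truth[0].mz, rt=truth[0].rt_apex,
                         mobility=truth[0].mobility_apex, ccs=170.0,
                         intensities={}, peaks={}, n_samples=1)
        gap_fill({"A": arch}, g)
        assert g.intensities["A"] > 0.1 * truth[0].abundance


class TestAssignMS2:
    def test_most_intense_spectrum_wins(self, record_factory):
        from peak4d.alignment import assign_ms2
        g = FeatureGroup(mz=300.0, rt=30.0, mobility=0.9, ccs=170.0,
                         intensities={}, n_samples=1)
        weak = record_factory(fragments=[(100.0, 1e4)], title="weak")
        strong = record_factory(fragments=[(100.0, 1e5)], title="strong")
        far = record_factory(mz=400.0, fragments=[(100.0, 1e6)], title="far")
        assign_ms2([g], {"s1": [weak, far], "s2": [strong]})
        assert g.representative_ms2.title == "strong"

    def test_no_nearby_spectrum_gives_none(self, record_factory):
        from peak4d.alignment import assign_ms2
        g = FeatureGroup(mz=300.0, rt=30.0, mobility=0.9, ccs=170.0,
                         intensities={}, n_samples=1)
        assign_ms2([g], {"s1": [record_factory(mz=500.0)]})
        assert g.representative_ms2 is None


def test_end_to_end_replicate_quantification():
    """Six technical replicates at CV 15%: the aligned, gap-filled table
    reproduces every truth feature with replicate-level precision."""
    truth = random_truth(12, seed=77)
    cfg = SimulationConfig(seed=77)
    reps = simulate_replicates(truth, cfg, n=6, cv=0.15)
    config = PipelineConfig()
    peaks, archives, spectra = {}, {}, {}
    for i, (arch, recs, _) in enumerate(reps):
        name = f"rep{i + 1}"
        pks, unique, _ = process_sample(arch, config, ms2_records=recs)
        peaks[name], archives[name], spectra[name] = pks, arch, unique
    groups = align_and_group(peaks, archives, config.alignment_params(),
                             unique_spectra_by_sample=spectra)
    assert len(groups) == len(truth)
    for g in groups:
        assert len(g.intensities) == 6  # no missing entries after gap fill
        assert g.representative_ms2 is not None
    rsds = []
    for g in groups:
        v = np.array(list(g.intensities.values()))
        rsds.append(v.std(ddof=1) / v.mean() * 100)
    assert np.median(rsds) < 25.0
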