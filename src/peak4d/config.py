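"""Pipeline configuration: every tunable parameter with its default.

The flat key set round-trips through YAML so a run can write a resolved
configuration snapshot sufficient to reproduce it exactly.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, fields

import yaml

from .annotation import MatchTolerances, ScoreWeights
from .alignment import AlignmentParams
from .ccs import CCSParams
from .detection import DetectionParams
from .tolerances import ToleranceRule, TrapezoidParams

__all__ = ["PipelineConfig"]


@dataclass
class PipelineConfig:
    # m/z tolerance
    mz_ppm: float = 20.0
    mz_abs_floor_da: float = 0.004
    mz_floor_below: float = 200.0
    # dereplication
    derep_min_intensity: float = 30.0
    derep_min_relative: float = 0.01
    derep_rt_bin_tol: float = 20.0
    derep_mobility_bin_tol: float = 0.030
    derep_rt_tol_min: float = 10.0
    derep_rt_tol_max: float = 20.0
    derep_mobility_tol_min: float = 0.015
    derep_mobility_tol_max: float = 0.030
    derep_cutoff: float = 1.0
    # detection
    eim_span: int = 13
    eic_span: int = 11
    eim_half_window: float = 0.05
    extension_frames: int = 30
    integration_frames: int = 5
    integration_mobility_tol: float = 0.015
    rt_fidelity_tol: float = 10.0
    mobility_fidelity_tol: float = 0.015
    min_snr: float = 3.0
    max_norm_noise: float = 0.35
    # CCS conversion
    ccs_temperature: float = 305.0
    ccs_charge: int = 1
    # alignment & grouping
    align_rt_tol: float = 30.0
    align_mobility_tol: float = 0.015
    align_ms2_cutoff: float = 0.8
    group_mz_bin: float = 0.015
    group_mobility_bin: float = 0.015
    group_rt_bandwidth: float = 5.0
    min_frac: float = 0.5
    # annotation
    ann_rt_tol_min: float = 30.0
    ann_rt_tol_max: float = 90.0
    ann_ccs_tol_min: float = 3.0
    ann_ccs_tol_max: float = 6.0
    ann_ms2_cutoff: float = 0.8
    ann_combined_cutoff: float = 0.6
    ann_w_rt: float = 0.2
    ann_w_ccs: float = 0.4
    ann_w_ms2: float = 0.4

    # --- derived parameter objects -------------------------------------
    def tolerance_rule(self) -> ToleranceRule:
        return ToleranceRule(self.mz_ppm, self.mz_abs_floor_da, self.mz_floor_below)

    def ccs_params(self) -> CCSParams:
        return CCSParams(temperature=self.ccs_temperature, charge=self.ccs_charge)

    def detection_params(self) -> DetectionParams:
        return DetectionParams(
            rule=self.tolerance_rule(),
            eim_half_window=self.eim_half_window,
            eim_span=self.eim_span,
            eic_span=self.eic_span,
            extension_frames=self.extension_frames,
            integration_frames=self.integration_frames,
            integration_mobility_tol=self.integration_mobility_tol,
            rt_fidelity_tol=self.rt_fidelity_tol,
            mobility_fidelity_tol=self.mobility_fidelity_tol,
            min_snr=self.min_snr,
            max_norm_noise=self.max_norm_noise,
            ccs=self.ccs_params(),
        )

    def alignment_params(self) -> AlignmentParams:
        return AlignmentParams(
            rule=self.tolerance_rule(),
            rt_match_tol=self.align_rt_tol,
            mobility_match_tol=self.align_mobility_tol,
            ms2_match_cutoff=self.align_ms2_cutoff,
            mz_bin=self.group_mz_bin,
            mobility_bin=self.group_mobility_bin,
            rt_bandwidth=self.group_rt_bandwidth,
            min_frac=self.min_frac,
            detection=self.detection_params(),
        )

    def match_tolerances(self) -> MatchTolerances:
        return MatchTolerances(
            mz=self.tolerance_rule(),
            rt=TrapezoidParams(self.ann_rt_tol_min, self.ann_rt_tol_max),
            ccs=TrapezoidParams(self.ann_ccs_tol_min, self.ann_ccs_tol_max),
            ms2_cutoff=self.ann_ms2_cutoff,
            combined_cutoff=self.ann_combined_cutoff,
        )

    def score_weights(self) -> ScoreWeights:
        return ScoreWeights(self.ann_w_rt, self.ann_w_ccs, self.ann_w_ms2)

    # --- YAML round trip -------------------------------------------------
    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)
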