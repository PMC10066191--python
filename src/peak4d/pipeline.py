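"""End-to-end orchestration: dereplicate -> detect -> align -> annotate.

``run_pipeline`` consumes per-sample frame archives (plus MGF files for DDA
or a seed list for targeted mode), and writes the standard outputs:
``features_filled.csv`` (quantified feature table), ``spectra.msp``
(representative MS2 spectra), ``ScoreCombine.csv`` (annotations, when a
library is given), per-seed detection logs, and a resolved-config snapshot.
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd

from .alignment import align_and_group
from .annotation import annotate
from .config import PipelineConfig
from .dereplication import dereplicate
from .detection import (
    detect_from_seeds,
    extract_dia_ms2,
    seeds_from_list,
    seeds_from_unique_spectra,
)
from .io import (
    read_archive,
    read_mgf,
    read_msp_library,
    read_seed_list,
    write_annotation_table,
    write_feature_table,
    write_spectra_msp,
)
from .io.tables import assign_feature_ids
from .models import FeatureGroup, FrameArchive, MS2Record

__all__ = ["run_pipeline", "process_sample"]


class StageError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"stage {stage!r} failed: {message}")
        self.stage = stage


def process_sample(
    archive: FrameArchive,
    config: PipelineConfig,
    ms2_records: list[MS2Record] | None = None,
    seed_df: pd.DataFrame | None = None,
):
    """Dereplicate (DDA) and detect 4D peaks for one sample.

    Returns (peaks, unique_spectra, detection_log).
    """
    unique: list[MS2Record] = []
    if ms2_records is not None:
        unique, _clusters = dereplicate(
            ms2_records,
            rule=config.tolerance_rule(),
            cutoff=config.derep_cutoff,
            min_intensity=config.derep_min_intensity,
            min_relative=config.derep_min_relative,
        )
        seeds = seeds_from_unique_spectra(unique)
    elif seed_df is not None:
        seeds = seeds_from_list(seed_df, config.ccs_params())
    else:
        raise StageError("detect", "need MS2 records (DDA) or a seed list")
    peaks, log = detect_from_seeds(archive, seeds, config.detection_params())
    if ms2_records is not None:
        by_seed = {s.seed_id: rec for s, rec in zip(seeds, unique)}
        for pk in peaks:
            pk.ms2 = by_seed.get(pk.seed.seed_id)
    return peaks, unique, log


def run_pipeline(
    sample_inputs: dict,
    out_dir,
    config: PipelineConfig | None = None,
    mode: str = "dda",
    library_path=None,
    seed_list_path=None,
    reference: str | None = None,
) -> list[FeatureGroup]:
    """Run the full workflow over multiple samples.

    ``sample_inputs`` maps sample name to either a dict with keys
    ``archive`` (path or FrameArchive) and optionally ``mgf`` (path) /
    ``ms2`` (records), or directly to an archive.  ``mode`` is ``dda``
    (MS2-seeded), ``seed-list`` (targeted; needs ``seed_list_path``) or
    ``dia`` (targeted seeds + in-archive MS2 frames).
    """
    if mode not in ("dda", "dia", "seed-list"):
        raise StageError("config", f"unknown mode {mode!r}")
    config = config or PipelineConfig()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    archives: dict[str, FrameArchive] = {}
    ms2_by_sample: dict[str, list[MS2Record] | None] = {}
    for name, spec in sample_inputs.items():
        if not isinstance(spec, dict):
            spec = {"archive": spec}
        arch = spec["archive"]
        archives[name] = arch if isinstance(arch, FrameArchive) else read_archive(arch)
        if mode == "dda":
            if "ms2" in spec:
                ms2_by_sample[name] = spec["ms2"]
            elif "mgf" in spec:
                records, n_rej = read_mgf(spec["mgf"])
                ms2_by_sample[name] = records
                if n_rej:
                    print(f"[{name}] rejected {n_rej} MGF records lacking mandatory keys")
            else:
                raise StageError("input", f"sample {name!r}: DDA mode needs MS2 spectra")
        else:
            ms2_by_sample[name] = None

    seed_df = None
    if mode in ("dia", "seed-list"):
        if seed_list_path is None:
            raise StageError("input", f"mode {mode!r} needs a seed list")
        seed_df = read_seed_list(seed_list_path)

    peaks_by_sample = {}
    unique_by_sample = {}
    for name, archive in archives.items():
        peaks, unique, log = process_sample(
            archive, config, ms2_records=ms2_by_sample[name], seed_df=seed_df
        )
        peaks_by_sample[name] = peaks
        unique_by_sample[name] = unique
        pd.DataFrame(log).to_csv(out / f"detection_log_{name}.csv", index=False)

    groups = align_and_group(
        peaks_by_sample,
        archives,
        config.alignment_params(),
        reference=reference,
        unique_spectra_by_sample=unique_by_sample if mode == "dda" else None,
    )
    assign_feature_ids(groups)

    if mode in ("dia", "seed-list"):
        # assign MS2 from DIA frames of the most intense sample per feature
        for g in groups:
            if not g.peaks:
                continue
            best_sample = max(g.peaks, key=lambda s: g.peaks[s].intensity)
            g.representative_ms2 = extract_dia_ms2(
                archives[best_sample], g.peaks[best_sample], config.detection_params()
            )

    write_feature_table(groups, out / "features_filled.csv", samples=list(archives))
    write_spectra_msp(groups, out / "spectra.msp")

    if library_path is not None:
        library = read_msp_library(library_path)
        annotations = annotate(groups, library, config.match_tolerances(), config.score_weights())
        write_annotation_table(annotations, out / "ScoreCombine.csv")

    config.to_yaml(out / "config_resolved.yaml")
    with open(out / "run_summary.json", "w") as fh:
        json.dump(
            {
                "mode": mode,
                "samples": list(archives),
                "n_peaks_per_sample": {s: len(p) for s, p in peaks_by_sample.items()},
                "n_features": len(groups),
            },
            fh,
            indent=2,
        )
    return groups
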