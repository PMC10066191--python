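"""CSV outputs (feature and annotation tables) and the seed-list input.

Numeric formatting is fixed (m/z 4 decimals, RT and CCS 1 decimal,
intensities as integers) to keep outputs diff-stable across runs.
"""

from __future__ import annotations

import pandas as pd

from ..models import FeatureGroup

__all__ = ["feature_id", "assign_feature_ids", "write_feature_table",
           "write_annotation_table", "read_seed_list"]


def feature_id(mz: float, rt: float, ccs: float) -> str:
    """Encode a feature as ``M<mz>T<rt>C<ccs>`` with values rounded to
    integers (e.g. m/z 206.08, RT 169 s, CCS 147 A^2 -> ``M206T169C147``)."""
    return f"M{round(mz)}T{round(rt)}C{round(ccs)}"


def assign_feature_ids(groups: list[FeatureGroup]) -> None:
    """Assign ids in place; colliding ids get a numeric suffix (_2, _3, ...)."""
    seen: dict[str, int] = {}
    for g in groups:
        base = feature_id(g.mz, g.rt, g.ccs)
        n = seen.get(base, 0) + 1
        seen[base] = n
        g.feature_id = base if n == 1 else f"{base}_{n}"


def write_feature_table(groups: list[FeatureGroup], path, samples: list[str] | None = None) -> None:
    """Write the quantified feature table (``features_filled.csv``).

    Every group must be gap filled: one row per feature, one intensity column
    per sample, no empty cells.
    """
    for g in groups:
        if not g.gap_filled:
            raise ValueError(
                f"group {g.feature_id or feature_id(g.mz, g.rt, g.ccs)} is not gap-filled"
            )
    if samples is None:
        samples = sorted({s for g in groups for s in g.intensities})
    if any(g.feature_id is None for g in groups):
        assign_feature_ids(groups)
    rows = []
    for g in groups:
        row = {
            "feature_id": g.feature_id,
            "mz": f"{g.mz:.4f}",
            "rt": f"{g.rt:.1f}",
            "ccs": f"{g.ccs:.1f}",
            "mobility": f"{g.mobility:.4f}",
        }
        for s in samples:
            if s not in g.intensities:
                raise ValueError(f"group {g.feature_id} missing intensity for sample {s!r}")
            row[s] = int(round(g.intensities[s]))
        rows.append(row)
    cols = ["feature_id", "mz", "rt", "ccs", "mobility"] + list(samples)
    pd.DataFrame(rows, columns=cols).to_csv(path, index=False)


def write_annotation_table(annotations, path) -> None:
    """Write the multidimensional-match table (``ScoreCombine.csv``).

    One row per (feature, candidate) pair; candidates of each feature sorted
    by combined score descending.
    """
    rows = []
    by_feature: dict[str, list] = {}
    for ann in annotations:
        by_feature.setdefault(ann.feature_id, []).append(ann)
    for fid in by_feature:
        ranked = sorted(
            by_feature[fid],
            key=lambda a: (-a.combined, a.delta_ccs_pct, a.delta_mz),
        )
        for ann in ranked:
            rows.append(
                {
                    "feature_id": ann.feature_id,
                    "candidate": ann.candidate.name,
                    "adduct": ann.candidate.adduct,
                    "score_mz": f"{ann.score_mz:.4f}",
                    "score_rt": f"{ann.score_rt:.4f}",
                    "score_ccs": f"{ann.score_ccs:.4f}",
                    "score_ms2": "" if ann.score_ms2 is None else f"{ann.score_ms2:.4f}",
                    "combined": f"{ann.combined:.4f}",
                    "level": ann.level,
                    "flag": ann.flag,
                }
            )
    cols = ["feature_id", "candidate", "adduct", "score_mz", "score_rt",
            "score_ccs", "score_ms2", "combined", "level", "flag"]
    pd.DataFrame(rows, columns=cols).to_csv(path, index=False)


def read_seed_list(path) -> pd.DataFrame:
    """Read a precursor seed list CSV with columns ``mz``, ``rt``, ``ccs``."""
    df = pd.read_csv(path)
    missing = {"mz", "rt", "ccs"} - set(df.columns)
    if missing:
        raise ValueError(f"seed list {path} missing columns: {sorted(missing)}")
    return df
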