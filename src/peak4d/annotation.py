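"""Multidimensional metabolite annotation.

Features are matched against a 4D library by sequential filters -- MS1
within the m/z tolerance, then RT and CCS within the maximum trapezoidal
tolerance -- and the surviving candidates are scored:

    Score = W_RT * Score_RT + W_CCS * Score_CCS + W_MS2 * Score_MS2

with trapezoidal RT/CCS scores (penalty-free within 30 s / 3%, zero beyond
90 s / 6%), a normalized-dot-product MS2 score (cutoff 0.8 when the library
carries an experimental spectrum), weights 0.2/0.4/0.4 and a combined-score
cutoff of 0.6.  Confidence levels follow the provenance of the matched RT
and MS2 values: level 1 (experimental in-house RT + experimental MS2),
level 2 (experimental-public MS2, predicted RT), level 3 (no experimental
MS2 available; the candidate is kept with MS1/RT/CCS scores only and
flagged for external in-silico MS2 scoring).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

from .models import FeatureGroup, LibraryEntry
from .tolerances import ToleranceRule, TrapezoidParams, mz_half_width, score_trapezoid
from .dereplication import cosine_similarity

__all__ = [
    "ADDUCT_SHIFTS",
    "MatchTolerances",
    "ScoreWeights",
    "Annotation",
    "adduct_mz",
    "delta_ccs",
    "score_ms2",
    "combine_score",
    "annotate",
]

_PROTON = 1.0072765
_NA = 22.9897693
_NH4 = 18.0338254
_H2O = 18.0105646
_HCOO = 44.9976543

#: m/z shift added to the neutral exact mass, per supported adduct.
ADDUCT_SHIFTS: dict[str, float] = {
    "[M+H]+": _PROTON,
    "[M+Na]+": _NA,
    "[M+NH4]+": _NH4,
    "[M+H-H2O]+": _PROTON - _H2O,
    "[M-H]-": -_PROTON,
    "[M+Na-2H]-": _NA - 2 * _PROTON,
    "[M+HCOO]-": _HCOO,
}


def adduct_mz(exact_mass: float, adduct: str) -> float:
    """Theoretical single-charge m/z of ``adduct`` for a neutral mass."""
    if adduct not in ADDUCT_SHIFTS:
        raise ValueError(f"unsupported adduct {adduct!r}")
    return exact_mass + ADDUCT_SHIFTS[adduct]


@dataclass(frozen=True)
class MatchTolerances:
    mz: ToleranceRule = ToleranceRule()
    rt: TrapezoidParams = TrapezoidParams(30.0, 90.0)  # s
    ccs: TrapezoidParams = TrapezoidParams(3.0, 6.0)  # percent
    ms2_cutoff: float = 0.8
    combined_cutoff: float = 0.6


@dataclass(frozen=True)
class ScoreWeights:
    w_rt: float = 0.2
    w_ccs: float = 0.4
    w_ms2: float = 0.4

    def __post_init__(self) -> None:
        if min(self.w_rt, self.w_ccs, self.w_ms2) < 0:
            raise ValueError("weights must be non-negative")
        if abs(self.w_rt + self.w_ccs + self.w_ms2 - 1.0) > 1e-9:
            raise ValueError("weights must sum to 1")


@dataclass
class Annotation:
    feature_id: str
    candidate: LibraryEntry
    score_mz: float
    score_rt: float
    score_ccs: float
    score_ms2: float | None
    combined: float
    level: int
    delta_mz: float
    delta_ccs_pct: float
    flag: str = ""


def delta_ccs(experimental: float, library: float) -> float:
    """Relative CCS difference in percent, on the library denominator."""
    if library <= 0:
        raise ValueError("library CCS must be positive")
    return abs(experimental - library) / library * 100.0


def score_ms2(experimental, library, rule: ToleranceRule = ToleranceRule()) -> float:
    """Normalized intensity dot product between the experimental spectrum
    and a library fragment list, in [0, 1]."""
    return cosine_similarity(experimental, library, rule)


def combine_score(
    score_rt: float,
    score_ccs: float,
    score_ms2_value: float | None,
    w: ScoreWeights = ScoreWeights(),
) -> float:
    """Weighted combined score.

    When no MS2 score exists (level-3 candidates) the RT/CCS weights are
    renormalized so the combined score stays in [0, 1].
    """
    if score_ms2_value is None:
        total = w.w_rt + w.w_ccs
        return (w.w_rt * score_rt + w.w_ccs * score_ccs) / total
    return w.w_rt * score_rt + w.w_ccs * score_ccs + w.w_ms2 * score_ms2_value


def _confidence(entry: LibraryEntry, ms2_scored: bool) -> tuple[int, str]:
    if ms2_scored and entry.ms2_provenance == "experimental" and entry.rt_provenance == "experimental":
        return 1, ""
    if ms2_scored and entry.ms2_provenance.startswith("experimental"):
        return 2, ""
    return 3, "level-3: MS2 unscored"


def annotate(
    groups: list[FeatureGroup],
    library: list[LibraryEntry],
    tol: MatchTolerances = MatchTolerances(),
    w: ScoreWeights = ScoreWeights(),
) -> list[Annotation]:
    """Sequential 4D match of every feature against the library.

    Candidates outside the m/z tolerance, RT tol_max or CCS tol_max are
    excluded before scoring; MS2-scored candidates below the MS2 cutoff and
    any candidate below the combined cutoff are discarded.  Results are
    sorted per feature by combined score (ties: smaller dCCS, then smaller
    dm/z).
    """
    if not library:
        warnings.warn("empty metabolite library; no annotations", stacklevel=2)
        return []
    out: list[Annotation] = []
    for g in groups:
        fid = g.feature_id or f"M{round(g.mz)}T{round(g.rt)}C{round(g.ccs)}"
        for entry in library:
            d_mz = abs(g.mz - entry.mz)
            if d_mz > mz_half_width(entry.mz, tol.mz):
                continue
            if entry.rt is None or entry.ccs is None:
                continue
            d_rt = abs(g.rt - entry.rt)
            if d_rt > tol.rt.tol_max:
                continue
            d_ccs = delta_ccs(g.ccs, entry.ccs)
            if d_ccs > tol.ccs.tol_max:
                continue
            s_rt = score_trapezoid(d_rt, tol.rt)
            s_ccs = score_trapezoid(d_ccs, tol.ccs)
            s_ms2 = None
            if entry.ms2 is not None and g.representative_ms2 is not None:
                s_ms2 = score_ms2(g.representative_ms2.fragments, entry.ms2, tol.mz)
                if s_ms2 < tol.ms2_cutoff:
                    continue
            combined = combine_score(s_rt, s_ccs, s_ms2, w)
            if combined < tol.combined_cutoff:
                continue
            level, flag = _confidence(entry, ms2_scored=s_ms2 is not None)
            out.append(
                Annotation(
                    feature_id=fid,
                    candidate=entry,
                    score_mz=1.0,
                    score_rt=s_rt,
                    score_ccs=s_ccs,
                    score_ms2=s_ms2,
                    combined=combined,
                    level=level,
                    delta_mz=d_mz,
                    delta_ccs_pct=d_ccs,
                    flag=flag,
                )
            )
    out.sort(key=lambda a: (a.feature_id, -a.combined, a.delta_ccs_pct, a.delta_mz))
    return out
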