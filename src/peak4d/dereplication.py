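"""MS2 spectral dereplication.

DDA acquisition fragments the same precursor repeatedly, producing redundant
MS2 spectra.  Dereplication collapses them: spectra are cleaned, binned by
precursor m/z, RT and mobility, clustered within each bin by a 3D distance
combining trapezoidal RT/mobility distances with a spectral dot-product
distance, and each cluster is represented by its most intense spectrum.

The 3D distance between spectra i and j is

    Dist_3D = sqrt(W_RT * Dist_RT^2 + W_mob * Dist_mob^2 + W_MS2 * Dist_MS2^2)

with unit weights by default.  RT and mobility distances are trapezoidal
(penalty-free within 10 s / 0.015 V*s/cm^2, saturating at 20 s / 0.030);
the spectral distance is one minus the normalized intensity dot product.
Hierarchical clustering uses complete linkage cut at distance 1, so any two
spectra within a cluster are within the cutoff of each other.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from .models import MS2Record
from .tolerances import ToleranceRule, TrapezoidParams, mz_half_width, trapezoid_distance

__all__ = [
    "DistanceWeights",
    "SpectrumCluster",
    "clean_spectrum",
    "bin_spectra",
    "match_fragments",
    "spectral_distance",
    "distance_3d",
    "cluster_bin",
    "dereplicate",
    "RT_TRAPEZOID",
    "MOBILITY_TRAPEZOID",
]

#: Default precursor trapezoids: penalty-free tolerance, acceptable tolerance.
RT_TRAPEZOID = TrapezoidParams(10.0, 20.0)
MOBILITY_TRAPEZOID = TrapezoidParams(0.015, 0.030)

#: Default binning tolerances (connected-component linking).
RT_BIN_TOL = 20.0
MOBILITY_BIN_TOL = 0.030


@dataclass(frozen=True)
class DistanceWeights:
    w_rt: float = 1.0
    w_mobility: float = 1.0
    w_ms2: float = 1.0

    def __post_init__(self) -> None:
        if min(self.w_rt, self.w_mobility, self.w_ms2) < 0:
            raise ValueError("weights must be non-negative")
        if self.w_rt + self.w_mobility + self.w_ms2 == 0:
            raise ValueError("weights must not all be zero")


@dataclass
class SpectrumCluster:
    members: list[MS2Record]
    representative: MS2Record


def clean_spectrum(record: MS2Record, min_intensity: float = 30.0,
                   min_relative: float = 0.01) -> MS2Record:
    """Purify a spectrum: drop fragments below ``min_intensity`` absolute
    counts or below ``min_relative`` of the base peak.  Order preserved."""
    frag = record.fragments
    if not len(frag):
        return record
    base = frag[:, 1].max()
    keep = (frag[:, 1] >= min_intensity) & (frag[:, 1] >= min_relative * base)
    return record.with_fragments(frag[keep])


def bin_spectra(
    records: list[MS2Record],
    rule: ToleranceRule = ToleranceRule(),
    rt_tol: float = RT_BIN_TOL,
    mob_tol: float = MOBILITY_BIN_TOL,
) -> list[list[MS2Record]]:
    """Partition records into precursor bins.

    Bins are the connected components of the graph linking any two records
    whose precursor m/z, RT and mobility differences are simultaneously
    within tolerance; components make the partition independent of record
    order.
    """
    n = len(records)
    if n == 0:
        return []
    mz = np.array([r.precursor_mz for r in records])
    rt = np.array([r.precursor_rt for r in records])
    mob = np.array([r.precursor_mobility for r in records])

    parent = np.arange(n)

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    order = np.argsort(mz, kind="stable")
    mz_s, rt_s, mob_s = mz[order], rt[order], mob[order]
    max_hw = mz_half_width(float(mz_s[-1]), rule)
    for a in range(n):
        for b in range(a + 1, n):
            dmz = mz_s[b] - mz_s[a]
            if dmz > max_hw:
                break
            hw = mz_half_width(min(mz_s[a], mz_s[b]), rule)
            if dmz <= hw and abs(rt_s[b] - rt_s[a]) <= rt_tol and abs(mob_s[b] - mob_s[a]) <= mob_tol:
                ra, rb = find(order[a]), find(order[b])
                if ra != rb:
                    parent[rb] = ra
    bins: dict[int, list[MS2Record]] = {}
    for i in range(n):
        bins.setdefault(find(i), []).append(records[i])
    return list(bins.values())


def match_fragments(a: np.ndarray, b: np.ndarray,
                    rule: ToleranceRule = ToleranceRule()) -> list[tuple[int, int]]:
    """Greedy nearest-m/z fragment pairing within the m/z tolerance.

    Candidate pairs are sorted by |delta m/z|; each fragment is used at most
    once.  Unmatched fragments take no pair (they still count in the norms
    of the dot product).
    """
    pairs = []
    for i in range(len(a)):
        hw = mz_half_width(float(a[i, 0]), rule)
        for j in range(len(b)):
            d = abs(a[i, 0] - b[j, 0])
            if d <= hw:
                pairs.append((d, i, j))
    pairs.sort(key=lambda t: t[0])
    used_a: set[int] = set()
    used_b: set[int] = set()
    out = []
    for _, i, j in pairs:
        if i in used_a or j in used_b:
            continue
        used_a.add(i)
        used_b.add(j)
        out.append((i, j))
    return out


def cosine_similarity(a: np.ndarray, b: np.ndarray,
                      rule: ToleranceRule = ToleranceRule()) -> float:
    """Normalized intensity dot product of two fragment lists in [0, 1].

    Fragment weights are raw intensities (m/z exponent 0); unmatched
    fragments contribute to the norms only.
    """
    if not len(a) or not len(b):
        return 0.0
    pairs = match_fragments(a, b, rule)
    if not pairs:
        return 0.0
    dot = sum(a[i, 1] * b[j, 1] for i, j in pairs)
    norm = np.sqrt((a[:, 1] ** 2).sum() * (b[:, 1] ** 2).sum())
    return float(dot / norm) if norm > 0 else 0.0


def spectral_distance(a: MS2Record, b: MS2Record,
                      rule: ToleranceRule = ToleranceRule()) -> float:
    """1 - cosine similarity of the two cleaned fragment lists; empty
    spectra give distance 1."""
    return 1.0 - cosine_similarity(a.fragments, b.fragments, rule)


def distance_3d(
    a: MS2Record,
    b: MS2Record,
    w: DistanceWeights = DistanceWeights(),
    rt_p: TrapezoidParams = RT_TRAPEZOID,
    mob_p: TrapezoidParams = MOBILITY_TRAPEZOID,
    rule: ToleranceRule = ToleranceRule(),
) -> float:
    d_rt = trapezoid_distance(abs(a.precursor_rt - b.precursor_rt), rt_p)
    d_mob = trapezoid_distance(abs(a.precursor_mobility - b.precursor_mobility), mob_p)
    d_ms2 = spectral_distance(a, b, rule)
    return float(
        np.sqrt(w.w_rt * d_rt**2 + w.w_mobility * d_mob**2 + w.w_ms2 * d_ms2**2)
    )


def _representative(members: list[MS2Record]) -> MS2Record:
    # max top-10 fragment intensity sum; ties broken by earliest frame index
    return min(members, key=lambda r: (-r.spectral_intensity(), r.precursor_frame))


def cluster_bin(
    bin_records: list[MS2Record],
    cutoff: float = 1.0,
    w: DistanceWeights = DistanceWeights(),
    rt_p: TrapezoidParams = RT_TRAPEZOID,
    mob_p: TrapezoidParams = MOBILITY_TRAPEZOID,
    rule: ToleranceRule = ToleranceRule(),
) -> list[SpectrumCluster]:
    """Complete-linkage hierarchical clustering of one bin, cut at
    ``cutoff`` (default 1) on the 3D distance."""
    n = len(bin_records)
    if n == 0:
        return []
    if n == 1:
        return [SpectrumCluster(members=list(bin_records), representative=bin_records[0])]
    dmat = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            dmat[i, j] = dmat[j, i] = distance_3d(
                bin_records[i], bin_records[j], w, rt_p, mob_p, rule
            )
    # exclusive cutoff: records at exactly the cutoff distance stay apart,
    # so co-binned precursors with unrelated MS2 spectra (3D distance 1 when
    # RT/mobility agree) are not collapsed into one seed
    labels = fcluster(linkage(squareform(dmat), method="complete"),
                      t=cutoff - 1e-9, criterion="distance")
    clusters = []
    for lab in sorted(set(labels)):
        members = [bin_records[i] for i in np.nonzero(labels == lab)[0]]
        clusters.append(SpectrumCluster(members=members, representative=_representative(members)))
    return clusters


def dereplicate(
    records: list[MS2Record],
    rule: ToleranceRule = ToleranceRule(),
    cutoff: float = 1.0,
    min_intensity: float = 30.0,
    min_relative: float = 0.01,
    w: DistanceWeights = DistanceWeights(),
    rt_p: TrapezoidParams = RT_TRAPEZOID,
    mob_p: TrapezoidParams = MOBILITY_TRAPEZOID,
) -> tuple[list[MS2Record], list[SpectrumCluster]]:
    """Full dereplication: clean -> bin -> cluster -> representatives.

    Returns ``(unique_spectra, clusters)``; every input record belongs to
    exactly one cluster.
    """
    cleaned = [clean_spectrum(r, min_intensity, min_relative) for r in records]
    clusters: list[SpectrumCluster] = []
    for b in bin_spectra(cleaned, rule):
        clusters.extend(cluster_bin(b, cutoff, w, rt_p, mob_p, rule))
    return [c.representative for c in clusters], clusters
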