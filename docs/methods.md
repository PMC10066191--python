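# Methods

This note documents the models, parameter choices and numerical decisions
behind `peak4d`, and what the synthetic benchmarks do and do not show.

## Data model

A run is a *frame archive*: an ordered list of frames, each a complete
m/z–mobility scan at one LC retention time, stored as a single HDF5 file
with two columnar tables (`frames`: index, RT, MS level, isolation window;
`points`: frame index, m/z, mobility, intensity) plus a JSON metadata block
(acquisition mode, cycle time, mobility grid).  All floats are float64, so
round trips are bit-exact.  Conventions throughout: RT in seconds, mobility
as reduced inverse mobility 1/K₀ in V·s/cm², m/z in Da, frame indices
1-based.  Vendor raw access is out of scope; a converter only needs to emit
this container, plus MGF for DDA MS2 spectra (standard keys plus
`MOBILITY=<1/K0>` and `FRAME=<index>`, `RTINSECONDS` mandatory — the
assembly needs precursor mobility and frame index for every spectrum).
MSP carries 4D libraries; since MSP has no standard key for retention time
or collision cross-section, this package defines `RT` (seconds) and `CCS`
(Å²), plus `RTProvenance`/`MS2Provenance` flags.

## MS2 spectral dereplication

Spectra are purified (fragments below 30 counts or below 1 % of the base
peak are dropped), then binned by precursor m/z (20 ppm, 0.004 Da floor
below 200 Da), RT (20 s) and mobility (0.030 V·s/cm²).  Binning is realized
as connected components of the pairwise within-tolerance graph, which makes
the partition independent of record order.  Within a bin, the 3D distance

    Dist_3D = sqrt(W_RT·D_RT² + W_mob·D_mob² + W_MS2·D_MS2²),  W = 1

combines trapezoidal RT/mobility distances (penalty-free below 10 s /
0.015 V·s/cm², saturating at 20 s / 0.030 — the penalty-free tolerance is
necessarily the smaller of the two) with a spectral distance
1 − cosine, where fragment weights are raw intensities (m/z exponent 0)
and fragments are paired greedily by nearest m/z within the global m/z
tolerance; unmatched fragments count in the norms only.

Clustering is complete-linkage HCA cut at distance 1, so every
within-cluster pair is within the cutoff.  The cut is *exclusive*: two
spectra at distance exactly 1 — the distance of co-binned precursors whose
RT and mobility agree but whose fragment sets are disjoint — are not
merged.  An inclusive cut would collapse every such pair into one seed and
make co-eluting isomers with distinct fragmentation invisible to the
downstream EIC separation; the exclusive cut keeps genuinely redundant
spectra (distance well below 1) merged while preserving those seeds.  Each
cluster is represented by its most intense member (sum of the top-10
fragment intensities, all if fewer; ties broken by earliest frame index).

## Bottom-up 4D peak detection

The five assembly steps and their defaults:

| step | parameter | default | note |
|------|-----------|---------|------|
| 1 precursor search | m/z window | 20 ppm / 0.004 Da floor | |
| | mobility window | ±0.015 V·s/cm² | |
| 2 EIM detection | extraction half-range | ±0.05 V·s/cm² | "0.1 V·s/cm² around the point" read as total width |
| | peak span | 13 grid points | ≈ 0.013 V·s/cm² on the 0.001 grid |
| 3 EIM extension | frames | 30 (15 per side) | stops on a side after 2 consecutive failures |
| 4 EIC detection | peak span | 11 frames | ≈ 5.8 s at the 0.53 s cycle |
| 5 integration | frames | 5 nearest EIC apex | |
| | mobility tolerance | ±0.015 of per-frame EIM apex | |

1D peak picking LOESS-smooths the trace (local linear, single pass, span =
span_points/length — the smallest-assumption smoother consistent with
locally weighted scatterplot smoothing), takes as apex candidates points
that are the maximum of their centered span window and strictly exceed
their neighbours (with a 10⁻⁶-relative epsilon so numerical wiggle on flat
traces cannot fabricate maxima), and returns the candidate nearest the
anchor (precursor mobility for EIMs, precursor RT for EICs).  Bounds are
the nearest local minima of the smoothed trace or zero crossings of the raw
trace.  Extension re-anchors every frame's EIM on the precursor mobility
(not the previous frame's apex), which prevents drift onto a mobility
neighbour.  The reported mobility is the EIM apex of the frame nearest the
EIC apex; the reported m/z is the intensity-weighted mean over the
integrated points.

Fidelity criteria, applied in order: apex within 10 s and 0.015 V·s/cm² of
the seed; at least 3 consecutive nonzero raw points adjacent to the apex on
each side (or to the trace boundary), on both the EIC and the EIM; S/N ≥ 3;
normalized standard noise < 0.35.  Two estimators needed definition:

- **S/N noise estimate** — median of the EIC raw trace outside the peak
  bounds, restricted to baseline-like positions (≤ half the apex height);
  if fewer than 5 such positions remain, the 10th percentile of the whole
  trace.  Without the half-height restriction, the flank of a co-eluting
  partner outside the bounds dominates the median and RT-resolved isomer
  pairs are spuriously rejected at S/N ≈ 1.
- **Normalized standard noise** — s.d. of (raw − LOESS-smoothed) residuals
  inside the peak bounds, divided by the apex height.

CCS conversion uses the single-field Mason–Schamp constant
18509.8632163405 (K₀ in cm²·V⁻¹·s⁻¹, masses in Da, CCS in Å²), N₂ exact
mass 28.0061480 Da, drift-gas temperature 305 K, ion mass M = m/z·z; the
constant agrees with a first-principles derivation from CODATA constants to
2·10⁻⁷ relative.  The conversion is linear in 1/K₀ and exactly invertible,
which the precursor-list workflow uses to turn seed CCS values back into
mobilities.

## Alignment, grouping, quantification

Peaks of each sample are matched to a reference sample (default: the middle
sample in injection order) by best-reciprocal 4D agreement — m/z tolerance,
RT ≤ 30 s, mobility ≤ 0.015 V·s/cm², and MS2 dot product ≥ 0.8 when both
peaks carry spectra.  These landmark tolerances are package defaults chosen
to mirror the annotation-side tolerances; all are configurable.  With ≥ 10
landmarks, a LOESS fit of reference RT on sample RT (made monotone by
isotonic post-adjustment) corrects the sample's RTs; outside the landmark
range the boundary offset is applied; with fewer landmarks the correction
is the identity and a warning is emitted.

Grouping bins corrected peaks by m/z and mobility (0.015 Da and
0.015 V·s/cm², absolute, anchored by splitting sorted values at gaps larger
than the bin size rather than on a fixed grid), then segments each bin
along RT by a Gaussian kernel density (bandwidth 5 s): density maxima
define group centres, the minima between adjacent maxima define boundaries.
Each group keeps at most one peak per sample (the most intense).  Samples
missing from a group are re-detected with a targeted seed (median m/z and
mobility, group RT, nearest-RT MS1 frame as precursor) under the full
fidelity criteria; groups below the minimum fraction (0.5) are dropped;
remaining gaps are filled by mandatory integration (5 frames, m/z
tolerance, 0.015 V·s/cm², no fidelity check — zero when nothing qualifies),
so the final table has no missing values.  Feature identifiers encode
rounded coordinates (`M206T169C147`); collisions get a numeric suffix.
The minimum fraction is evaluated over all samples; per-class evaluation is
left to the caller by running classes separately.

## Annotation

Library m/z values follow single-charge adduct arithmetic over the constant
table (proton 1.0072765, Na 22.9897693, NH₄ 18.0338254, H₂O 18.0105646,
HCOO 44.9976543), applied additively — e.g. [M+Na]⁺ = M + 22.9897693.  This
omits the ~0.5 mDa electron-mass correction on metal adducts; it is the
convention the library format pins, and experimental and library m/z are
compared within the same 20 ppm window, so the offset cancels for libraries
built with the same table.

Candidates pass sequential filters (MS1 window; ΔRT ≤ 90 s; ΔCCS ≤ 6 %,
computed on the library denominator) and are scored with trapezoidal
RT/CCS scores (knots 30/90 s and 3/6 %), an MS2 normalized dot product
(cutoff 0.8 — a candidate with a library spectrum scoring below the cutoff
is rejected outright), and the weighted combination 0.2/0.4/0.4 with cutoff
0.6.  For candidates without an experimental library spectrum the RT/CCS
weights are renormalized (1/3, 2/3) so the combined score stays on the same
scale, and the annotation is flagged `level-3: MS2 unscored`; exporting
such candidates with their experimental spectra (MSP) leaves in-silico
fragmentation scoring to external tools.  Confidence levels: 1 when both
the matched RT and MS2 are experimental in-house values, 2 when the MS2 is
experimental-public and the RT predicted, 3 otherwise.  Ties in the
combined score break by smaller ΔCCS, then smaller Δm/z.  Library RT
recalibration onto the experimental gradient is accepted as a user-supplied
monotone mapping; the identity is used when absent.

## Synthetic data generator

The generator emulates the acquisition the pipeline targets: MS1 frames
every 0.53 s; a mobility grid of 0.45–1.45 V·s/cm² in 0.001 steps (so the
13-point EIM span equals 0.013 V·s/cm²); Gaussian elution profiles with
default σ of 2.5 s in RT and 0.006 V·s/cm² in mobility, matching the
11-point / 13-point half-height spans; centroid m/z jitter of 2 ppm;
uniform noise points (20 per frame) with exponential intensities (mean 30
counts).  Per-peak point intensities are the product of *normalized*
discrete RT and mobility weights over a ±4σ support, so the total signal of
a peak equals its abundance exactly — which gives an analytic oracle for
the integration step (the truth mass inside the 5-frame × ±0.015 box).

DDA redundancy: each peak is fragmented 1 + Poisson(redundancy − 1) times
(default mean 3), with precursor jitter uniform within ±2 s, ±0.005
V·s/cm² and ppm-scale m/z — inside ±half of every dereplication binning
tolerance, so redundant spectra are guaranteed co-binned, and near the
apex, as data-dependent acquisition triggers in reality (a precursor
recorded 10 s off-apex would place the apex outside the ±15-frame
extension window, which instruments do not do).  Replicates multiply
abundances by lognormal technical error at a configurable CV (default
0.15 in the benchmarks); dilution series scale abundances by 1/f with the
noise model unchanged.  Isomer pairs are generated at controlled ΔCCS (via
the inverse Mason–Schamp map) and ΔRT; the benchmark grid is ΔCCS
4.8/2.6/2.3 % co-eluting and 0.7 % with ΔRT 6 s (the mobility-resolved and
EIC-resolved regimes).

What the generator does *not* emulate: TIMS physics and mobility
calibration drift, isotope envelopes, adduct chemistry, chimeric DIA
co-isolation beyond a single window, detector saturation, and
chromatographic tailing.  Passing benchmarks therefore demonstrate the
correctness and calibration of the algorithms on ideal unimodal peaks under
additive noise — not performance on real biological matrices, where peak
shape violations and chemical background dominate the error budget.

## Benchmark problem sizes

The shipped tests and the acceptance script use 10–50 ground-truth peaks
per run, 150 MS1 frames, 6 replicates, 5 dilution levels, 1000 noise-only
seeds and a 50-entry annotation library: large enough that recall, RSD and
linearity are meaningful ensemble statistics, small enough that the full
suite runs in well under a minute per stage on one core.

## Known limitations

- One seed yields at most one peak; overlapping isomers whose MS2 spectra
  are similar enough to co-cluster produce a single seed and hence a single
  feature.
- The EIC-step separation of sub-percent-ΔCCS pairs requires the RT apexes
  to be ≥ ~2σ apart; closer pairs merge into one chromatographic mode.
- Density grouping with a 5 s bandwidth merges cross-sample features whose
  corrected RTs differ by less than roughly the bandwidth.
- Level-3 candidates are flagged, not MS2-scored; in-silico fragmentation
  ranking is delegated to external tools.
- The trapezoidal CCS tolerances (3/6 %) are calibrated for predicted
  library CCS values; with high-accuracy experimental libraries they should
  be narrowed by configuration.
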