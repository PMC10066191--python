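# peak4d

Bottom-up assembly of 4D peaks for ion-mobility-resolved (LC–IM–MS)
untargeted metabolomics.

## The problem

Coupling liquid chromatography, ion mobility and mass spectrometry gives
every metabolite ion four coordinates — m/z, retention time (RT), reduced
inverse mobility 1/K₀ (convertible to a collision cross-section, CCS) and an
MS/MS spectrum — and separates isomers that co-elute on LC alone.  The extra
dimension makes the data large and structurally complex: conventional
pipelines reduce the 4D space to 3D slices before peak picking, which masks
signal and costs sensitivity, especially for co-eluting isomers with small
mobility differences.

`peak4d` takes the opposite, *bottom-up* route: a mass spectrum is the
smallest unit of the dataset, and each feature is rebuilt in reverse order
of the physical separation.  Starting from the precursor of a unique MS2
spectrum (or an entry of a user-supplied precursor list), the assembly runs

1. **precursor search** — the most intense MS1 point matching the seed m/z
   (20 ppm, 0.004 Da floor below 200 Da) and mobility (±0.015 V·s/cm²) in
   the precursor frame;
2. **EIM detection** — an extracted ion mobilogram over ±0.05 V·s/cm² is
   LOESS-smoothed and peak-picked with a 13-point span;
3. **EIM extension** — the mobilogram detection is repeated in 30 adjacent
   MS1 frames;
4. **EIC detection** — per-frame mobilogram intensities are projected onto
   the LC axis and peak-picked with an 11-point span;
5. **4D integration** — MS1 points in the 5 frames nearest the EIC apex and
   within 0.015 V·s/cm² of the EIM apexes form the peak volume; the
   reported m/z is their intensity-weighted mean.

Fidelity criteria (apex within 10 s / 0.015 V·s/cm² of the seed, continuous
signal around the apex, S/N ≥ 3, normalized standard noise < 0.35) reject
assemblies that do not look like real peaks.  Mobility converts to CCS via
the single-field Mason–Schamp relation

    CCS = convertor · z · (1/K₀) · sqrt(1/(T·M)) · sqrt((M+m)/m)

Around this core the package provides:

- **MS2 spectral dereplication** — redundant DDA spectra are binned by
  precursor m/z/RT/mobility and clustered by the 3D distance
  `sqrt(W_RT·D_RT² + W_mob·D_mob² + W_MS2·D_MS2²)` (trapezoidal RT/mobility
  distances, spectral dot-product distance, complete-linkage HCA cut at 1);
- **alignment and quantification** — landmark-based LOESS RT correction,
  density grouping on (m/z, mobility) bins with a 5 s RT kernel, targeted
  re-detection, a minimum-fraction filter (0.5) and gap filling, producing a
  complete feature table;
- **multidimensional annotation** — sequential MS1/RT/CCS filters with
  trapezoidal scores (30/90 s, 3/6 %), an MS2 dot product (cutoff 0.8), a
  combined score `0.2·S_RT + 0.4·S_CCS + 0.4·S_MS2` (cutoff 0.6) and
  MSI-style confidence levels 1–3;
- **a synthetic LC–IM–MS generator** with known ground truth (Gaussian
  RT/mobility profiles, ppm m/z jitter, redundant DDA sampling, noise
  points), so the whole pipeline is testable without vendor raw files.

## Worked example

Simulate a small DDA run, dereplicate, and detect:

```bash
peak4d simulate --n-peaks 4 --seed 6 --out demo
peak4d run --archive s1=demo/archive.h5 --mgf s1=demo/spectra.mgf --out demo_out
```

which prints

```
wrote 150 frames, 16 MS2 records to demo
4 features written to demo_out/features_filled.csv
```

`demo_out/features_filled.csv` then holds one row per feature with its
m/z, RT (s), CCS (Å²), mobility, and one integer intensity column per
sample, e.g.

```
feature_id,mz,rt,ccs,mobility,s1
M361T24C197,361.4821,24.4,197.1,0.9480,459200
M383T42C275,382.6351,41.9,275.1,1.3260,150802
```

The identifier `M361T24C197` encodes rounded m/z, RT and CCS.  The 16 MS2
records (redundant fragmentations of 4 peaks) collapsed to 4 unique
spectra; each seeded one 4D peak whose integrated volume, apex RT and
mobility match the generator's ground truth.  `demo_out/spectra.msp` holds
each feature's representative MS2 spectrum, and — when a 4D library is
supplied via `--library` — `ScoreCombine.csv` lists scored candidates.

The same stages are available as a library API
(`peak4d.dereplication.dereplicate`, `peak4d.detection.detect_from_seeds`,
`peak4d.alignment.align_and_group`, `peak4d.annotation.annotate`,
`peak4d.pipeline.run_pipeline`).

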