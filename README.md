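# phagesensor

Pattern-recognition analysis for phage-based colorimetric sensor arrays.

Colorimetric sensor chips built from self-assembled M13 bacteriophage films
reflect a structural colour set by Bragg's law, λ = 2·n_eff·d.  When an
analyte vapour penetrates the film the nanostructure swells (d → d·(1+s)),
the reflected peak red-shifts, and the chip changes colour.  A 3×3 array —
three engineered phage coats (wild, RGD, EEEE) × three film colours
(red/green/blue, set by the deposition pulling speed) — turns one exposure
into a 9-cell colour-change fingerprint.  This package provides the full
numerical pipeline for discriminating chemicals from such fingerprints:

1. **simulate** — generate synthetic chip images with known ground truth
   (Bragg optics → CIE 1931 colorimetry → sRGB rendering → Gaussian pixel
   noise), emulating a campaign of 8 drug analytes (4 estrogens: E1, E2,
   E3, EE2; 4 antibiotics: AMX, AMP, TET, PEN) at 30/60/90/120 °C;
2. **extract** — per-cell mean RGB over a centred ~1000-pixel ROI, giving
   signed responses ΔR, ΔG, ΔB per cell;
3. **distance** — the colour distance between two response patterns a, b,

       D(a,b) = Σᵢ [(ΔRᵢᵃ−ΔRᵢᵇ)² + (ΔGᵢᵃ−ΔGᵢᵇ)² + (ΔBᵢᵃ−ΔBᵢᵇ)²]

   summed over the n bins of the pattern (optionally square-rooted to a
   true Euclidean metric);
4. **cluster** — agglomerative hierarchical clustering of the distance
   matrix with Ward.D linkage, implemented in-repo via the Lance–Williams
   recurrence; merge heights track the increment of the error sum of
   squares (ESS).  Cutting the dendrogram at k = 2 separates estrogens
   from antibiotics; nearest-pattern classification assigns unknowns.

## Worked example

```sh
python analysis/01_simulate_chips.py
python analysis/02_extract_features.py
python analysis/03_distance_matrix.py
python analysis/04_cluster_dendrogram.py
```

prints (abridged):

```
wrote 32 pre/post image pairs to results/dataset
mean |ΔRGB| per pattern: min 23.0, max 50.3 counts
mean within-class distance:  622
mean between-class distance: 122668
8 leaves, 7 merges
merge heights: 59, 83, 101, 110, 1625, 1752, 488807
k=2 cut vs ground-truth classes: ARI = 1.000
```

32 image pairs are the 8 analytes × 4 temperatures.  Each analyte's four
9-bin patterns are concatenated into one 36-bin vector, so the 8×8 distance
matrix compares whole temperature profiles.  Same-class analytes sit ~200×
closer than cross-class pairs; the four lowest merges pair up drugs within
a class, the last merge joins the two class clusters at a far greater
height, and the k = 2 cut recovers the estrogen/antibiotic split exactly
(adjusted Rand index 1.0).

The same pipeline is scriptable through a CLI
(`phagesensor simulate|extract|distance|cluster|analyze`); `analyze` also
renders |ΔRGB| difference maps and a dendrogram plot, and records a run
manifest with checksums for provenance.

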