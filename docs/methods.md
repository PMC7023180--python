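# Methods

## Sensing model

A chip carries a 3×3 grid of unit cells.  Rows are the three engineered
phage coats (wild, RGD — integrin-binding; EEEE — tetraglutamate, acidic),
columns the three film colours obtained at pulling speeds of 30/40/50
μm/min.  Each film is a quasi-periodic photonic structure: at normal
incidence it reflects a band centred at the first-order Bragg wavelength

    λ = 2 · n_eff · d · (1 + s),

with `d` the unswollen bundle period, `n_eff` the effective refractive
index, and `s` the fractional swelling caused by analyte uptake.  The
simulator models the reflected spectrum as a Gaussian peak (FWHM 30 nm,
amplitude 0.9, baseline 0.05) on that centre, clamped to the visible range
[380, 780] nm.  This is deliberately the simplest optical model consistent
with the Bragg mechanism; no transfer-matrix interference or
angle-dependent scattering is attempted.

Swelling follows a saturating-binding law with a temperature gain:

    s = s_max · e / (e + a(phage, analyte)) · g(analyte, T),   s ∈ [0, s_max].

`e` is the configured exposure (arbitrary units, default 1), `a` the
half-saturation of a phage coat toward an analyte, and `g` a per-analyte
multiplicative factor per temperature level — a stand-in for the way
vapour pressure rises with temperature and strengthens the reaction.
Whether real films saturate or reverse at high temperature is unknown;
`g` is a free dial, default a linear ramp 0.55 → 1.00 over 30 → 120 °C.

## Colorimetry

Spectra are rendered to 8-bit sRGB through the CIE 1931 2° standard
observer, tabulated at 10 nm over 380–780 nm, followed by the standard
sRGB (D65-referenced) XYZ→linear-RGB matrix, sRGB gamma, and rounding with
clipping (a gamut flag reports clipped channels).  The reflectance spectrum
is integrated directly (equal-energy stimulus, Y-normalised so a unit flat
spectrum has Y = 1) rather than weighted by an illuminant SPD; any
consistent rendering path serves here, since the analysis operates on
colour *differences* produced and measured within the same path.  Tests
cross-check the 10 nm integration against an independent 1 nm numerical
integration.

## Default study conditions

8 analytes in two classes (estrogens E1, E2, E3, EE2; antibiotics AMX,
AMP, TET, PEN) at 4 temperatures (30, 60, 90, 120 °C) on 9 cells.  Film
periods are chosen so the resting colours sit at ≈650/550/450 nm with
n_eff = 1.45 (the true periodicities and index of phage films are not
published; both are plain configuration).  `s_max` = 0.12.  Class binding
profiles (half-saturations): estrogens {wild 0.6, RGD 0.25, EEEE 2.5},
antibiotics {wild 1.8, RGD 2.2, EEEE 0.35} — estrogens engage the
wild/RGD coats, the acidic EEEE coat prefers the antibiotics.  Within a
class, each drug's affinities are scaled by 0.88/0.96/1.04/1.12 and its
temperature ramp tweaked by ±2%, so same-class drugs respond similarly
but not identically — encoding the observation that chemically similar
substances land close together in the dendrogram.  A `class_contrast`
dial interpolates the two class profiles in log-affinity space (0 = the
classes coincide); it exists for sensitivity checks only.

Pixel noise is i.i.d. Gaussian per pixel and channel (default sd 2.0
counts — ordinary webcam-grade noise), rounded and clipped; there is no
spatial correlation, vignetting, illumination drift, or chip-to-chip
misregistration.  Passing tests therefore demonstrate the *analysis*
pipeline, not robustness to real-camera artefacts; real photographs would
additionally need registration, which is out of scope (the layout is
assumed known, as with a fixed chamber).

All randomness derives from the single scenario seed through
`numpy.random.SeedSequence`; per-image streams are keyed by (seed, analyte
index, temperature index, pre/post phase, replicate), so datasets are
byte-reproducible and replicate measurements are independent.

## Signal definition

A cell's signal is the arithmetic mean RGB over a centred square ROI.
"~1000 pixels" is read as total pixel count: the default ROI is 32×32 =
1024 pixels (configurable).  The response is the *signed* change
post − pre per channel, kept at full floating precision; an absolute-value
option exists but is off by default, since sign preserves the direction of
the spectral shift.  ΔRGB is paired against the same chip's pre-exposure
image, not a separate blank.

Temperatures are combined by concatenation by default: one 36-bin vector
(9 cells × 4 temperatures, temperature-major) per analyte, so clustering
sees each chemical's whole temperature profile.  A per-temperature mode
analyses each temperature separately.

## Colour distance

The dissimilarity between two patterns is the sum over bins of squared
per-channel ΔRGB differences ("squared" dialect, the default and the
conventional input to Ward.D), or its square root ("euclidean" dialect, a
true metric satisfying the triangle inequality).  No normalisation of
channels or bins is applied.  Distances are double precision.

## Ward.D clustering

Agglomeration is implemented from first principles via the Lance–Williams
recurrence with Ward coefficients αᵢ = (nᵢ+nₖ)/(nᵢ+nⱼ+nₖ), β =
−nₖ/(nᵢ+nⱼ+nₖ), γ = 0, applied to the distances *as given* (the Ward.D
convention; `ward_d2` squares the input first and roots the heights, and
single/complete/average linkage are available for comparison).  When the
input is squared-Euclidean, each merge height equals exactly twice the ESS
increment of that merge — the quantity Ward's criterion minimises — which
the test suite verifies against a from-scratch agglomeration that
recomputes ESS from coordinates at every step.  Ward linkage is reducible,
so heights are monotone non-decreasing; this is asserted on every run.

Ties at the minimum merging distance go to the lexicographically smallest
(left id, right id) pair — deterministic and recorded.  Heights are kept in
the recurrence's own units with no rescaling.  The dendrogram cut at k
clusters removes the k−1 highest merges (k = 2 is the headline
estrogen-vs-antibiotic cut, but k is a free parameter); unknown samples are
assigned the class of the nearest reference pattern under the same
distance, with the distance reported so callers can threshold rejects.

Cophenetic matrices (lowest-merge height per leaf pair) are ultrametric by
construction and checked against a brute-force lowest-common-ancestor
oracle; trees export to Newick with branch lengths as height differences,
verified to round-trip through an independent parser.

## Numerical and size choices

Monte-Carlo tests use a compact 3×3 layout (12 px cells, 8×8 ROI) so that
hundreds of replicate campaigns render in seconds; full-size checks use
the default 224×224 px chip.  Two-class recovery is measured over 20
seeded replicate campaigns; held-out classification over 104 noisy
queries; the Ward oracle over 200 random point sets with n ≤ 8 in 1–3
dimensions.  Comparisons against oracles use 1e-9 relative tolerance;
noise-free round trips are required to be exact to the bit.

## Known limitations

- The optical model is phenomenological; peak width/amplitude do not vary
  with swelling, phage type, or viewing angle.
- The affinity and temperature-gain values are invented study conditions
  with realistic structure, not fitted to measurements; absolute distances
  and merge heights are therefore not comparable to laboratory units.
- No automatic cell detection: images must match the declared layout.
- The squared-vs-rooted distance choice for dendrograms is a genuine
  ambiguity of the method as described; both dialects are first-class and
  the choice is logged in every run manifest.
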