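# Methods

## Data model

A `SpectralCube` holds absorbance (rows × cols × bands, float32) with an
ascending, uniformly spaced `WavenumberAxis` in cm⁻¹ (2 cm⁻¹ step,
800–4000 cm⁻¹ storage range) and a pixel pitch in µm (6.25 by default;
25 after 4×4 binning). On disk a single ENVI dialect is supported:
plain-text header plus band-sequential float32 little-endian raster.
Files stored with descending wavelength lists (a common instrument
convention) are re-ordered on read so that band indices, integrals and
centers of gravity always run in one canonical direction. Tile stitching
(separately focused acquisition regions) sizes the mosaic to the
bounding box, zero-fills uncovered pixels — which the amide-I mask later
removes — and lets the last-written tile win on overlap.

## Preprocessing

*Tissue mask.* A pixel is tissue iff its **raw** absorbance at the band
nearest 1652 cm⁻¹ (amide I) is ≥ 0.30 AU, inclusive. The threshold reads
section thickness, so it must precede normalization. 0.30 AU is roughly
an order of magnitude above the simulated peak-to-peak noise.

*Baseline.* Two-point linear correction with anchors fixed for all
spectra: (900, 1800) cm⁻¹ spanning the fingerprint/amide region and
(2800, 3600) cm⁻¹ for amide A. The anchor values are a package default
(configurable per run and logged): they sit in windows where the class
models carry no band intensity, which makes the correction idempotent
and exact for linear drift. Bands outside both intervals are left
unchanged.

*Normalization.* Division by the amide-I peak height (windowed maximum,
±6 cm⁻¹). Pixels with non-positive height are flagged and routed to the
unclassified class but stay in the raster, so rendered images remain
spatially aligned. After normalization every ratio metric is exactly
thickness-invariant in the noiseless limit.

*Named-band lookups* use the nearest band, no interpolation: the 2 cm⁻¹
step is far below the ~25 cm⁻¹ band widths. Peak heights are windowed
maxima (±6 cm⁻¹, configurable) to tolerate small calibration jitter.

*Residual-paraffin QC.* The paraffin CH-bending band (1464 cm⁻¹)
overlaps the tissue CH₂-bending band at 1452 cm⁻¹ so strongly (12 cm⁻¹
apart at 25 cm⁻¹ FWHM) that any plain band-height or local-chord readout
of A(1464) is biased by ~0.1 AU on clean tissue. The QC score therefore
estimates the paraffin amplitude per pixel by linear least squares over
1424–1504 cm⁻¹ with four components — constant, linear slope, unit
Gaussian at 1452 and unit Gaussian at 1464 — and averages the 1464
coefficient over kept pixels after amide-I normalization. On clean
phantoms the score is zero to within the noise floor; on contaminated
ones it returns the injected height (times the mean inverse thickness
when contamination is added post hoc at fixed height). It is a QC
number, not a gate.

## Spectral metrics

Four families, all tolerant of NaN propagation (an undefined metric is
dropped from that pixel's classifier product):

- **peak_height_ratio(p₁, p₂)** — windowed heights; undefined if the
  denominator ≤ 1e-6.
- **band_area(l, r)** — trapezoidal integral above the chord through the
  spectrum's values at l and r (local two-point baseline); may be
  negative.
- **area_to_height_ratio**, **area_to_area_ratio** — compositions of the
  above.
- **center_of_gravity(l, r, cg₁, cg₂)** — absorbance-weighted mean
  wavenumber; the local baseline is anchored at (l, r), the
  baseline-corrected absorbance is clipped at zero (keeping the weighted
  mean well defined), and weights are summed over [cg₁, cg₂]. The
  alternative reading of the last two parameters — CG over [l, r],
  affinely mapped so cg₁→0, cg₂→1 — is available as
  `cog_mode="normalized"`; both orderings agree on which of two spectra
  has the higher value, and the anchored reading is the default.

The default library contains the 27 published definitions; an extended
mode appends height ratios of every annotated band to amide I as a step
toward the larger metric space the method admits. 1236 vs 1239 (and
1027 vs 1032) are treated as distinct band positions as printed; with
the ±6 cm⁻¹ window they read nearly the same bands, which is harmless
since downstream weighting handles redundant metrics.

## Classifier

Weighted Gaussian naive Bayes. Per class and metric, mean and standard
deviation (ddof=1, floored at 1e-6) over kept, labeled, finite values;
sample vectors are sorted before the moment computation so that fitting
is bit-exactly invariant to pixel ordering. Metric weights are
max(AUC−½, 0) normalized to mean 1, using each metric's best one-vs-rest
AUC (Mann–Whitney rank statistic, tie-aware, oriented ≥ ½); uniform
weights are a config switch, as is a Laplace-smoothed 64-bin histogram
likelihood for non-Gaussian metric distributions. Priors are uniform by
default — biopsy class abundances are not population-representative —
and overridable. Posteriors are computed in the log domain and
normalized with logsumexp. The decision rule assigns argmax posterior if
it reaches the threshold (default 0.5), else *unclassified*; ties break
to the lowest class code. Optional metric selection keeps the union of
each class's top-k metrics by AUC (ties by lower minimum error, then
name), deterministic by construction; the default uses the full library,
since AUC weighting already down-weights uninformative metrics.

## Evaluation

ROC curves sweep thresholds over the distinct posterior values
(descending), one point per distinct score plus endpoints; AUC by
trapezoid. This route is implementation-independent of the rank-
statistic AUC used in metric scoring, and the two agree to 1e-9 —
a dual-route check in the test suite. Pixels with undefined posterior
score −∞: a labeled positive the classifier declined to score is a
permanent miss, keeping Pd honest. Pd@Pfa interpolates linearly;
vertical segments resolve to the highest Pd at that Pfa. Confusion
tables are column-normalized per truth class with an explicit
unclassified row, so each column sums to 100%.

The sample-level rejection call counts lymphocyte pixels, groups them
into foci (8-connected components of ≥ 4 pixels, configurable) and tests
encroachment (any lymphocyte pixel 8-adjacent to myocardium). Positive
requires burden above a negligible threshold (default 0.1% of tissue
pixels) *and* encroachment; both knobs are config-exposed since no
canonical values exist.

## Phantom simulator

Each class spectrum is a sum of Gaussian bands (FWHM 25 cm⁻¹ in the
fingerprint, 120 cm⁻¹ for amide A; line shapes configurable, Lorentzian
available) with height 1 at amide I. The per-class height patterns are
fixed simulator constants chosen so the observed tissue contrasts hold:
amide III/collagen (1238) and 1204 elevated in both fibrosis classes and
endocardium over myocardium; glycogen (1030) elevated in myocardium and
depressed at fibrosis; lymphocytes offset from muscle at 1236 and in the
CH region. Only these orderings are anchored to real-tissue evidence;
absolute heights are simulator parameters.

A pixel spectrum is `thickness · Σpeaks + slope · (ν − ν₀) + ε`,
with thickness ~ U(0.7, 1.3) per pixel, slope ~ N(0, 2·10⁻⁵ AU/cm⁻¹),
and ε i.i.d. Gaussian per band. The noise SD for a target SNR *s* is
`1/(5.0 · 1.6 · s)`: 5.0 is the expected peak-to-peak range of ~101
i.i.d. normals (the 1800–2000 cm⁻¹ signal-free window at 2 cm⁻¹ step),
and the 1.6 margin makes the *realized* amide-I-to-peak-to-peak ratio
exceed the nominal SNR in essentially every draw rather than on average
— at the default s = 500 the 5th-percentile realized ratio is ≈ 590.

The `layered_biopsy` layout places an endocardium band along one tissue
edge, a fibrosis-endocardium band beneath it, myocardium bulk with
elliptical fibrosis patches, and circular lymphocyte foci (3 foci of
radius 5 px by default, pairwise separated so each is one connected
component), inside a non-tissue border whose near-zero absorbance the
amide mask removes. With boundary mixing on, each tissue pixel
8-adjacent to a different tissue class becomes a convex mixture
`f · own + (1−f) · neighbor` with f ~ U(0.55, 0.9), recorded in the
ground truth as the dominant-class fraction — linear-in-absorbance
mixing is the standard Beer–Lambert assumption for thin sections. All
randomness flows from one seed in a documented order (layout, thickness,
slopes, mixing, noise), so equal specs give bit-identical phantoms.

What the phantom does **not** emulate: spectrally correlated detector
noise (real FT-IR noise is not white; the classifier only consumes band
ratios, which limits the impact), Mie/resonant-Mie scattering and
reflective-substrate dispersion artifacts, per-tile focus differences in
stitched acquisitions, and intra-class biochemical heterogeneity beyond
thickness/baseline variation. Passing tests therefore demonstrate the
pipeline's correctness and its noise behavior under the stated
acquisition statistics, not clinical performance on patient biopsies.

## Problem sizes and numerical choices

The standard study configuration is a 200×200-pixel phantom
(≈ 37,600 tissue pixels, 1601 bands), with training and validation on
independent realizations; the test suite uses 36–100-pixel rasters where
a property does not need the full size. Tolerances: axis uniformity
1e-9 cm⁻¹; metric denominators 1e-6; likelihood SD floor 1e-6; posterior
normalization checked to 1e-9. Degenerate inputs: empty masks,
single-class truths, all-NaN pixels and sub-threshold posteriors all
have defined, tested behavior (errors or unclassified, never silent
drops). Known limitation: with boundary mixing on, training-set AUC is
not strictly monotone in SNR — at very high SNR the tight likelihoods
rank mixed pixels more erratically — so the noise-monotonicity property
is stated (and tested) on unmixed phantoms.
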