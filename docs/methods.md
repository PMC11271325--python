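# Methods

## The measurement problem

Acute macular neuroretinopathy (AMN) presents as a sharply demarcated
parafoveal lesion that is hyporeflective on infrared (IR) cSLO imaging.
Whether the lesion reflects a perfusion deficit in the deep retinal
capillary plexus or in the choroidal circulation is read off en-face OCT
angiography: if perfusion inside the lesion is depressed relative to
healthy tissue *of the same eye* in a given vascular slab, that slab's
circulation is implicated.  `octavad` implements that comparison as a
deterministic pipeline: human segmentations in, region geometry, vessel
area density (VAD), overlap scores and paired statistics out.

Inputs per eye are en-face slab exports (SVP, ICP, DCP, choriocapillaris,
choroid) plus the co-registered IR image, and an ITK-Snap-style label map
on the IR image marking the lesion (label 1) and the foveal avascular zone
(FAZ, label 2).  No automatic segmentation, registration or resampling is
performed; all images of one eye must share dimensions.

## Control-region geometry

Two intra-eye comparators are constructed from the lesion and FAZ masks,
using 0-based row/column pixel-center coordinates throughout:

* **Adjacent tissue control (ATC).**  The lesion footprint is scaled by a
  linear factor *s* (default 2) about the lesion centroid and the lesion
  itself plus any FAZ pixels are removed, leaving a band of directly
  adjacent tissue roughly one lesion-radius wide.  Scaling is rasterized by
  inverse-mapping each candidate pixel center into lesion coordinates with
  nearest-neighbour lookup (halves round up, deterministically).  "Size
  doubling" is interpreted as linear doubling (×4 area for a solid shape);
  area doubling (*s* = √2) is available by passing `scale=sqrt(2)`.  The
  midpoint is the mask centroid, not the bounding-box center — centroids
  are robust to ragged manual outlines.
* **Ring segment (RS).**  The closed annulus centered on the fovea whose
  inner and outer circles are tangent to the lesion: radii are the min and
  max Euclidean distances from the fovea center to lesion pixel centers;
  the lesion is removed from the annulus.  The fovea center is the FAZ-mask
  centroid — the only construction that uses exactly the available inputs.
  The RS is *not* FAZ-excluded; FAZ overlap is reported as a diagnostic.
  The rationale for the RS is vascular architecture: tissue at equal
  eccentricity from the fovea should be approximately homogeneous in
  perfusion.

Both constructions raise descriptive errors (with area diagnostics) when a
region comes out empty, warn on single-radius lesions, and silently clip at
the frame border while logging clipped counts.

## VAD quantification

Per slab, one global Otsu threshold is computed over the full image on a
256-bin histogram (ties broken toward the smaller threshold); a pixel is
perfused iff strictly above threshold.  VAD of a region is the perfused
fraction among its evaluated pixels.  The threshold is deliberately global:
a per-region threshold would let a genuine perfusion deficit shift its own
threshold and cancel itself out of the lesion-vs-control comparison (a
per-region mode exists behind `per_region_threshold=True` for sensitivity
analysis).

For the SVP only, large retinal vessels are excluded from the evaluated
area: multi-scale Frangi vesselness restricted to large scales (default
σ = 4–10 px at a 512 px frame; scale proportionally) is binarized and the
resulting pixels are removed from numerator *and* denominator.  The default
binarization is Otsu of the nonzero vesselness response with a noise floor
of mean + 3 sd of that response.  The floor matters: on images without
large tubular structures the vesselness response is diffuse and unimodal,
and a bare Otsu split marks an arbitrary 15–20% of the frame as "vessel";
with the floor, structure-free images yield essentially empty masks
(≤ 1.5% coverage over 20 seeded noise images) while a 12 px bright tube is
still recovered along its full centerline.  A hysteresis variant was
evaluated and rejected — weak-threshold continuation floods connected noise
components.  No vesselness filtering is applied to ICP/DCP or to the
choriocapillaris/choroid, where ridge filters suppress the granular flow
signal being measured.

## Cohort statistics

For each slab × comparator (ATC, RS), the per-eye lesion VAD is compared to
the per-eye control VAD with a two-sided paired-samples t-test
(t = mean(d)·√n / sd(d), df = n−1).  Bonferroni correction uses an explicit
family size `m_comparisons` (default 10 = 5 slabs × 2 comparators; always
logged in the output so a reproduction states its choice).  Effect size is
the percent reduction of the cohort mean lesion VAD relative to the cohort
mean control VAD, 100·(m_ctl − m_les)/m_ctl; a mean-of-per-eye-reductions
variant is available.  Degenerate difference vectors (sd = 0) raise rather
than return a misleading p.

## En-face overlap

Overlap of the IR lesion with lesion footprints segmented on en-face OCT
reconstructions at the ellipsoid zone (EZ) and the OPL/Henle-fiber junction
is scored with the Sørensen–Dice coefficient 2|A∩B|/(|A|+|B|), masks taken
literally with no morphological cleanup.  EZ-vs-IR and OPL-vs-IR Dice
scores are compared across eyes with the same paired t-test.  Eligibility
of eyes for this analysis (lesion visible at both levels) is an input
decision, not computed.

## The phantom generator

Because patient images cannot be redistributed, every pipeline stage is
validated on seeded phantoms that carry the statistical structure the
analysis assumes:

* **Perfusion textures** are thresholded band-pass noise: white noise
  Gaussian-filtered at half the layer's feature scale, thresholded at the
  empirical quantile giving the configured perfused fraction.  Defaults
  (fraction, scale at 512 px): SVP 0.40/3 px, ICP 0.35/2.5 px,
  DCP 0.35/2.5 px, CC 0.42/1.5 px, choroid 0.39/8 px — control-region VAD
  then sits in the range reported for healthy parafoveal tissue, and a
  27%/41% lesion deficit in CC/choroid depresses lesion VAD to ≈0.31/≈0.23.
* **Lesion deficits** multiply the perfused fraction inside the lesion by
  (1 − deficit), realized as a stricter threshold on the same smooth field
  (the weakest flow pixels drop out first).
* **Geometry**: circular FAZ (default radius 40 px at 512) rendered
  avascular in the three retinal plexuses only; elliptical or blob-shaped
  parafoveal lesion strictly outside the FAZ; bright large-vessel arcades
  in the SVP drawn as quadratic arcs of configurable width whose midpoints
  stay peripheral to the macula (curvature default 0.9) — arcades crossing
  the parafovea would be anatomically wrong and would contaminate the
  lesion/control comparison with vessel-crossing noise.
* **Noise**: additive Gaussian (default sd 12) clipped to [0, 255];
  multiplicative speckle behind a flag.
* **En-face fixtures**: the EZ footprint equals the IR lesion (optionally
  displaced to emulate segmentation disagreement); the OPL footprint is
  displaced radially away from the fovea (or horizontally, "nasal") by a
  configured magnitude, emulating Henle-fiber obliquity.
  `displacement_for_dice` inverts the closed-form two-disk lens-overlap
  formula so a target Dice can be turned into a displacement.
* **Cohorts**: per-eye child seeds from a `SeedSequence`; lesion size,
  eccentricity and orientation jittered ±15% for between-eye variability.
  All outputs are bit-reproducible given the master seed.

The generator records its own ground truth (true per-region perfused
fractions on the pre-noise binary texture, the large-vessel mask), so
recovery can be asserted against what was actually drawn.

What the phantoms do *not* model: anatomically grown vascular trees,
projection artifacts, OCT speckle physics, segmentation errors of the
device's layer finding, or motion artifacts.  Passing tests therefore
demonstrate the correctness and calibration of the *quantification*, not
robustness to device-specific artifacts.

## Desk-scale problem sizes

Monte-Carlo validation runs at reduced frame sizes with geometry scaled
linearly from the 512 px reference: null calibration (type-I error of the
per-layer paired test under zero deficit) uses 1000 six-eye cohorts at
128 px; effect recovery (CC deficit 0.27, choroid 0.41) uses 50 six-eye
cohorts at 256 px, where lesion areas (~480 px) give per-region sampling
noise comparable to real 512 px scans — at 128 px the ~120 px lesions leave
the 27% CC effect underpowered, which is a property of the tiny frame, not
of the method.  Observed behaviour: all ten layer × comparator null
rejection rates fall in [0.03, 0.07]; recovered mean reductions land within
a few percentage points of the injected 27%/41%.

## Numerical and degenerate-input choices

* Otsu: between-class variance maximized over integer bins 0–255; constant
  images raise a degenerate-histogram error.
* Intensities: 8-bit after load; 16-bit PNGs rescaled; RGB converted by the
  Rec. 601 luminance transform (Pillow's integer implementation).
* NIfTI: lossless integer storage, identity affine; arrays stored so a
  round trip through the package is pixel-exact.
* CSV: floats written at 17 significant digits; rows deterministically
  sorted per record kind; byte-identical across runs for identical inputs.
* Scaling rasterization: nearest neighbour with half-up rounding —
  documented so the ×2-scaled solid square has exactly 4× the pixels.

## Known limitations

* Choroidal OCTA quantification inherits the modality's susceptibility to
  projection and shadowing artifacts; the pipeline measures what the slab
  shows.
* The Frangi large-vessel configuration is a declared default, not a
  device-matched calibration; small frames (< ~200 px) cannot separate
  arcade width from capillary texture and exclusion degrades to a near
  no-op there.
* Percent reductions of cohort means and means of per-eye reductions can
  differ for heterogeneous cohorts; both are provided, the former is the
  default summary.
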