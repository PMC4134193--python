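# Methods notes

This note records the model assumptions, parameter choices and numerical
conventions behind `wmhseg`, and what the synthetic phantom does and does
not establish about real data.

## Pipeline model and assumptions

The segmentation treats one hemisphere at a time and assumes three
co-acquired sequences: T1w (anatomy; WM bright), FLAIR (CSF suppressed;
WMHs, infarcts and edema bright) and DWI (acute infarct cores strongly
bright, peri-infarct edema *reduced* peripherally). Intensities are
arbitrary scanner units; every decision threshold is therefore defined on
a normalized [0, 100] scale built per image and per mask region.

Key parameters (all in `PipelineConfig`, all adjustable):

| parameter | default | units / scale | role |
|---|---|---|---|
| `fusion_k` | 0.8 | fraction | T1w weight in the fused image |
| `wmh_threshold` | 65 | normalized FLAIR [0,100] | candidate nomination (strict >) |
| `junction_band_coefficient` | 0.5 | SD multiple | junction band half-margin |
| `junction_fraction` | 0.8 | fraction | component removal (strict >) |
| `peak_offset` | 19 | normalized DWI [0,100] | infarct threshold above histogram peak |
| `label_overlap_fraction` | 0.8 | fraction | whole-component infarct removal (inclusive ≥) |
| `histogram_bins` | 101 | — | unit-width DWI histogram bins on [0,100] |

The deliberate asymmetry between the junction rule (strictly more than
80 %) and the infarct rule (at least 80 %) is part of the method's
contract and is pinned by boundary-exact tests.

### Decisions where the design was genuinely open

- **Probability binarization** is strict (`p > 0.5`); a voxel at exactly
  0.5 falls to background.
- **Candidate components** are 3-D 26-connected (confluent lesions cross
  slices); the junction neighborhood is the in-plane 2-D 8-neighborhood
  evaluated slice by slice, since an "8-neighbor" count is a 2-D notion at
  6 mm slice pitch. Both are configurable (`candidate_connectivity`,
  `junction_neighborhood = "26-3d"`).
- **Junction band** endpoints are inclusive ("between" read as a closed
  interval); an empty band (GM bound above WM bound) warns and disables
  the filter rather than failing.
- **Normalization** is strict min–max over the in-mask voxels — the 65 and
  +19 thresholds are defined on that scale — with a percentile variant
  (`normalization_mode="percentile"`) for robustness experiments only.
- **Pre-fusion harmonization**: T1w and FLAIR are each min–max scaled to
  [0, 100] over the brain before blending, because raw dynamic ranges
  differ per sequence and a fixed k = 0.8 is only meaningful on a common
  range.
- **DWI histogram ties** resolve to the lower modal bin: a lower peak
  means a lower infarct threshold, more subtraction, and thus higher WMH
  specificity — the conservative direction.
- **Bland–Altman differences** are reference − automated (semi − auto);
  bias signs reported elsewhere follow this convention.
- **ICC form**: all six McGraw–Wong forms are computed (via pingouin);
  two-way, absolute-agreement, single-measures ICC(A,1) is primary, as the
  appropriate form for "do the two methods produce the same number".
- **SDs** are sample (n−1) standard deviations throughout the evaluation
  module.

## External tools treated as inputs

Atlas-based tissue segmentation, nonlinear template registration, and
dedicated brain extraction are mature external tools and are *not*
reimplemented. The pipeline consumes their products — subject-space GM/WM
probability maps, the ex-brainstem–cerebellum–corpus-callosum exclusion
mask, a brain mask — as files. Built-in stand-ins keep the pipeline
runnable without them: a 3-class Gaussian-mixture intensity classifier
(tied variance; classes ordered by mean, WM brightest on the T1w-dominant
fused image; mixture fitted on a capped random subsample of in-brain
voxels, posteriors evaluated everywhere, fixed seed), an Otsu +
largest-component + hole-fill brain mask, and a full-volume exclusion
mask. The tied-variance choice is load-bearing: with per-class variances,
a tightly fitted WM class can hand bright WMH voxels to a broader
neighboring class; a shared variance guarantees the brightest class claims
every sufficiently bright voxel.

## Registration

Rigid, 6 parameters (Euler angles Rz·Ry·Rx and translation about the
fixed-volume center), fitted by maximizing NMI = (H(a)+H(b))/H(a,b) with
equal-width histograms between robust 0.5–99.5 percentile limits
(default 32 bins during optimization). The search is multi-resolution
(4×, 2×, 1× in-plane downsampling; the slice axis is never downsampled
below 8 slices) Powell, derivative-free and deterministic. Both images
are Gaussian-smoothed in-plane (σ = 1 voxel per level) for the metric:
linear interpolation otherwise imprints local maxima on the NMI landscape
that can bias recovered rotations by ~0.5°. The transform maps fixed-space
physical points to moving-space points, so resampling the moving image
through the fitted transform lands it on the fixed grid; masks and label
maps resample nearest-neighbor, images linearly. Out-of-view voxels are
flagged invalid, never zero-filled, and excluded from all statistics.

## The synthetic phantom

The generator emulates the image *structure* the pipeline keys on, not MR
physics: an ellipsoidal brain with cortical GM shell, deep WM, CSF
ventricles, a cerebellum-like lobe and midline callosum block (both
outside the ground-truth exclusion mask), WMH ellipsoids in deep WM,
infarct cores with a thin in-plane edema ring, in-plane Gaussian blur as
the gray/white junction surrogate, and additive Gaussian noise (Rician
optional). Default grid 128×128×24 at 0.9×0.9×6 mm (slice pitch = 5 mm
thickness + 1 mm gap; volume computation treats pitch as the full z extent
of a voxel).

Contrast choices worth recording:

- Fused WMH/infarct intensity sits slightly *above* the WM mean, so the
  junction band (which ends 0.5 SD below the WM mean) cannot swallow
  lesions — mirroring the purpose of fusion, which is precisely to raise
  lesion intensity toward WM before tissue classification.
- DWI uses dark CSF and parenchyma near the top of the range, so that in
  a no-infarct hemisphere the histogram peak lies within 19 normalized
  units of the maximum and the infarct stage correctly finds nothing.
- The default infarct (in-plane core radius 13.5 mm, 0.9 mm edema ring)
  makes the FLAIR-bright blob ≥ 80 % covered by the DWI-detected core, so
  the whole-label rule fires and removes the edema crescent — the
  structure that defeats naive voxelwise subtraction.

What passing phantom tests do **not** show: robustness to bias fields,
partial-volume and flow artifacts, cortical folding, multi-site intensity
variation, or rater ambiguity at WMH/infarct interfaces. The packaged
cohort tables carry the real-data evidence; the phantom establishes
algorithmic correctness (thresholds, rules, registration, bookkeeping)
under controlled truth.

## Problem sizes and determinism

Unit tests run phantoms at 64×64×16 (1.8 mm in-plane) with lesions
enlarged and blur kept at constant physical width, chosen so
partial-volume shells do not dominate small lesions; acceptance checks run
the full 128×128×24 default including registration. Every stochastic
component (noise, mixture initialization, subsampling) is seeded; repeated
runs are bit-identical.

## Known limitations

- The GMM stand-in is intensity-only; real tissue priors (atlas-based)
  are strictly better and should be supplied when available.
- Hemispheres are independent; no interhemispheric symmetry prior.
- No bias-field correction; strongly shaded images should be corrected
  upstream.
- Min–max normalization is sensitive to single extreme voxels by design
  (the thresholds were defined on that scale); the percentile mode exists
  for sensitivity analysis but changes the meaning of the thresholds.
- The printed ICC coefficients of the packaged cohort tables cannot be
  reproduced to the third decimal from the rounded published volumes under
  any standard ICC form; the computed ICC(A,1) values agree to within
  0.02, and all other published aggregates reproduce exactly.
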