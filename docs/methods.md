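# Methods

`gwtbss` re-implements, on fully synthetic data, a tract-based spatial
statistics (TBSS) pipeline in which the registration target is a
group-wise atlas, together with the simulation framework used to measure
how the choice of registration target affects false positives
(specificity) and the detection of true effects (sensitivity).  This note
records the models, the parameters that matter, the numerical choices,
and what the synthetic experiments can and cannot show.

## The pipeline

Given a cohort of fractional-anisotropy (FA) volumes, the pipeline

1. aligns every subject into a common space (one of four strategies, below),
2. averages the aligned images into a mean FA map (only where every
   subject contributes data; voxels that any subject maps from outside
   its field of view are excluded),
3. extracts the white-matter skeleton of the mean FA map — voxels above
   an FA threshold of 0.2 that are local maxima along the
   tract-perpendicular directions,
4. projects each subject's FA onto the skeleton: per skeleton voxel, the
   maximum FA over that voxel's local search region, so that modest
   residual misalignment does not dilute tract-centre values, and
5. tests each skeleton voxel with a permutation-based GLM: group-contrast
   t statistics, threshold-free cluster enhancement (TFCE, E = 0.5,
   H = 2, dh = max/100, 26-connectivity restricted to the skeleton), and
   family-wise error control by the permutation distribution of the
   maximum enhanced statistic (default 5000 permutations, alpha = 0.05;
   exact enumeration when the group sizes admit fewer distinct
   relabelings).  With nuisance covariates the default permutation scheme
   is Freedman–Lane (permute residuals of the nuisance-only model); plain
   label permutation is available behind a flag.  One-sided tests are
   computed per direction; the evaluation experiments test the
   reduced-FA direction, which is the direction misalignment produces
   around expanding ventricles, so the null family-wise error rate
   calibrates at alpha rather than 2·alpha.

### Registration strategies

* **ST** — every subject straight to the standard-space template
  (linear, then non-rigid).
* **RS** — pairwise registrations identify the *most representative
  subject* (minimum mean non-rigid deformation needed to receive the
  others); subjects map through it, and it is affine-mapped to the
  template.  Full pairwise cost is quadratic; a `max_pairs` cap
  subsamples partners evenly per candidate.
* **SS** — the mean of ST-aligned images becomes a second-pass
  *study-specific* registration target for the original images.
* **GW** — an iterative unbiased atlas: register all subjects to the
  current atlas, replace the atlas by the mean of the registered images,
  repeat over a coarse-to-fine schedule (one rigid iteration — so the
  random choice of the initial subject cannot bias the result — then
  four affine and ten non-rigid iterations), and finally affine-register
  the atlas to the standard template.  Each iteration registers the
  *original* images to the current atlas (stateless per iteration); the
  non-rigid optimiser is warm-started from the previous iteration's
  solution, which changes nothing about what is being estimated, only
  how fast it converges.  The linear part is re-estimated once when the
  non-rigid phase begins and then held fixed.

  A free atlas evolution can wander: all subjects acquire a common
  deformation pattern and the atlas settles a consistent warp away from
  the cohort barycentre (with the anatomy drifting towards the field-of-
  view edge).  After the schedule finishes, the common (mean) deformation
  is removed from every subject's field, the subjects are re-registered
  once against the corrected atlas, and the residual mean is removed
  again.  This anchors the final cohort at the cohort barycentre without
  fighting the per-iteration optimisation, whose convergence the
  variance trace records.

## Registration model

All transforms use the pull-back convention (a transform maps an output
grid point, in mm, to the source sampling location); images resample with
trilinear interpolation and zero fill outside the field of view (labels
use nearest-neighbour).  Composition is evaluated with a single
interpolation.

* **Linear**: rigid (6 parameters) or affine (12: translation, rotation,
  log-scale, shear), optimised by multi-resolution Powell search on a
  normalised-cross-correlation metric.  Three design details matter on
  FA-like images and were each adopted after the naive variant failed:
  the metric's images are smoothed ~0.8 voxel per pyramid level
  (interpolation artifacts otherwise spike the metric at integer-voxel
  shifts), the metric is evaluated on a fixed interior box (~8 mm
  margin) so the evaluation domain cannot change with the candidate
  transform (a sliding domain rewards shrinking the overlap), and
  out-of-field samples are masked with an overlap weight.  For an affine
  fit the coarsest level searches only the rigid parameters.
* **Non-rigid, `pipeline`**: a parametric coarse-control-point model
  (control spacing 4 voxels, trilinear control-to-grid interpolation, two
  image resolutions).  Updates are demons-style intensity forces
  restricted onto the control grid, with a 12 mm displacement cap.
* **Non-rigid, `independent`**: non-parametric demons — per-voxel SSD
  forces, capped at half a voxel per iteration, fluid (sigma = 1 voxel)
  and diffusion (sigma = 0.5 voxel) Gaussian regularisation, three image
  resolutions, the same 12 mm cap.  This second, structurally different
  algorithm manufactures the artificial warps of the specificity
  experiment, so the evaluation warp does not share a deformation model
  with the pipeline under test.
* Both non-rigid paths stop a resolution level after the relative MSE
  improvement falls below 0.5% twice — on noise-only image pairs the
  optimiser would otherwise keep "improving" by fitting noise.
* **Matched-resolution registration**: inside the pipeline the non-rigid
  stage registers a lightly smoothed copy (sigma = 1.5 mm) of the moving
  image.  Pipeline targets are averages or population templates, visibly
  smoother than any single subject, and matching a crisp image to a
  blurred one rewards deformations that fake the blur (large
  high-frequency displacement patterns that average neighbouring values).
* Field inversion is fixed-point iteration (50 iterations, tolerance
  0.05 voxel).  Deformation magnitude is the grid mean of |u| in mm.

## Skeletonisation and projection

Perpendicular directions come from the Hessian of the smoothed
(sigma = 1 voxel) mean FA: the tract tangent is the eigenvector of least
absolute curvature and the other two eigenvectors span the cross-section.
A voxel joins the skeleton if its *raw* mean FA exceeds the threshold and
is a (tie-tolerant) local maximum along both perpendicular eigenvectors
and does not increase along the local gradient direction.  The raw-value
test matters: smoothing across a stair-stepped discrete ridge displaces
the maximum by up to a voxel.  The gradient test removes off-centre caps
(for example outside a bend) where all curvatures are negative yet FA
still climbs towards the tract centre.

Projection reads *voxel* values (no interpolation, so a subject's true
local maximum is recovered exactly) over the voxels of the skeleton
voxel's nearest-neighbour partition cell within `max_search_mm`
(default 8 mm).  For a tube skeleton those cells are the perpendicular
slabs; for a sheet, the across-sheet columns — the partition itself
encodes the perpendicular search geometry.  Cells of 26-adjacent skeleton
voxels are merged into the search, because an oblique ridge rasterises to
staircase corners whose cells would otherwise wall off the search exactly
where the tract went.

## The phantom

A template FA volume (48³ voxels, 2 mm spacing) holds curved tube tracts
with a Gaussian cross-profile (peak ≈ 0.70 after band-limiting,
sigma = 3.5 mm, below 0.2 beyond the 6.5 mm tube radius) over a 0.07
background, three low-contrast deep-grey-like blobs (below the skeleton
threshold; they anchor registration along the tract axis, where tubes
alone would pose an artificial aperture problem), and a central CSF-like
ventricle (FA 0.03).  The first two tracts are *periventricular*,
hugging the ventricle on either side the way the fornix and callosal
body do — exactly the geometry in which ventricular expansion displaces
white matter.  Tracts on one side run parallel; converging tubes would
merge their FA profiles into a single ridge.  The volume is band-limited
with a 1 mm Gaussian: FA maps are smooth at the voxel scale, and a sharp
phantom would make trilinear interpolation error dominate every warp.

Subjects are the template warped by seeded smooth random displacement
fields (white-noise vectors, Gaussian-smoothed, rescaled to a maximum
amplitude) plus clipped Gaussian noise; subject images fill their field
of view (edge-extended warping), as acquired maps do.  Atrophy is an
analytic radial expansion centred on the ventricle — zero at the centre,
peaking (at `severity` mm) near the ventricle boundary, smooth decay —
composed with a mild random field.  The returned ground-truth field is
the forward (tissue-motion) field, whose divergence is positive inside
the ventricle; resampling internally uses its numerical inverse.

### Study conditions

The canonical experiment emulates ten controls and ten atrophy targets:

| parameter | value | rationale |
|---|---|---|
| inter-subject warp | 4 mm max amplitude, 8 mm smoothness | moderate anatomical variability |
| FA noise | sd 0.02 | repeat-scan FA variability |
| atrophy severity | 7 mm peak expansion | marked, visibly enlarged AD-like ventricles |
| standard template | cohort anatomy deformed by a fixed 6 mm smooth field, blurred 2 mm | population templates differ systematically from a patient cohort (age, ventricle size) and are averages, visibly smoother than any subject |
| smoothing-kernel candidates | 0.5, 1, 1.5, 2 mm | interpolation-matching grid; the study cohort selects 1.5 mm |
| scaled-down statistics | 500 permutations, n = 10 + 10, 48³ | desk-scale replicate of the protocol defaults (5000 permutations remain the configurable default) |

These conditions were fixed once, as the regime the method is *for*:
direct registration to a mismatched population template must be genuinely
stressed by atrophy-scale deformation, while remaining within what a
group-wise atlas (whose target sits near the cohort barycentre) can
absorb.  With mild deformation every strategy aligns this simple phantom
essentially perfectly and the strategies become indistinguishable.

## What the phantom does and does not show

The phantom reproduces the *mechanisms* — tract geometry with a
perpendicular FA profile, inter-subject warps, ventricular expansion,
interpolation smoothing, template mismatch — but not the complexity of
real FA data: no orientation-dependent noise, no crossing or branching
tracts, no cortical folding, no genuinely unrepresentable anatomical
differences, and far fewer skeleton voxels (~10²) than a real study
(~10⁵).  Registration on the phantom is *easier* than on real brains, so
strategy differences here are smaller than in practice: passing the
ordering checks (group-wise ≤ direct-to-template in false positives,
variance, and projected-FA loss) demonstrates the machinery orders the
strategies correctly in the regime where they differ, not that effect
sizes match a clinical study.  The statistical layer, by contrast, is
exact on any data: permutation calibration and the TFCE/enumeration
oracles hold regardless of the phantom's realism.

## Numerical choices and degenerate inputs

* All randomness flows through named integer seeds
  (`numpy.random.default_rng`); fixed seeds reproduce cohorts and
  statistics bit-exactly.  Registration is deterministic (fixed
  initialisation, no sampling).
* Ties: representative-subject selection takes the lowest index;
  skeleton local-maximum ties (flat directions) keep the voxel; the
  kernel selector breaks RMSE ties toward the smaller width.
* Empty ventricle masks, rank-deficient designs, non-positive TFCE
  parameters, mismatched grids and unknown modes raise errors naming the
  constraint; an all-below-threshold mean FA yields an empty skeleton
  with a warning.
* p-values use the add-one estimator, never below 1/(n_perm + 1); exact
  enumeration includes the identity relabeling.
* The variance-of-difference summary is the voxel mean of the
  across-subject variance of aligned FA, recorded per group-wise
  iteration and comparable with the study-specific cohort.

## Known limitations

* The registration contract is behavioural (alignment quality on
  FA-like images), not bit-compatible with any external tool; its
  deformation-magnitude estimates are conservative (regularisation
  under-reports large deformations), which compresses the
  representative-subject ranking between near-tied candidates.
* The group-wise atlas update is a plain arithmetic mean; no sharpening
  or median variants.
* Projection uses one documented search rule (partition cells with
  neighbour merging); no distance-weighted variants.
* Laterality is not modelled: phantom tracts carry symmetric ids.
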