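"""Common-space alignment strategies for the TBSS registration step.

Four ways of choosing the registration target are provided, mirroring the
landscape of group FA studies:

* ``ST`` (standard): every subject is registered, linearly then
  non-rigidly, straight to the standard-space FA template.
* ``RS`` (most representative subject): pairwise non-rigid registrations
  identify the subject needing the least mean deformation to receive all
  others; subjects are registered to it, and it is affine-mapped to the
  template.
* ``SS`` (study-specific template): the mean of ST-aligned images becomes
  a second-pass registration target for the original images.
* ``GW`` (group-wise atlas): an unbiased iterative atlas — register all
  subjects to the current atlas, update the atlas to the mean of the
  registered images, repeat over a coarse-to-fine schedule (rigid, then
  affine, then non-rigid) — finally affine-mapped to the template.

All strategies produce an :class:`AlignedCohort` on the template grid, so
downstream skeletonisation and statistics are strategy-agnostic.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .core import ScalarVolume
from .imgreg import (DisplacementField, deformation_magnitude, gaussian_smooth,
                     register_linear, register_nonrigid, resample)

logger = logging.getLogger(__name__)

__all__ = ["AlignedCohort", "AtlasTrace", "align_standard", "select_representative",
           "build_study_template", "build_groupwise_atlas", "DEFAULT_GW_SCHEDULE",
           "variance_of_difference"]

DEFAULT_GW_SCHEDULE = ("rigid",) + ("affine",) * 4 + ("nonrigid",) * 10


@dataclass
class AlignedCohort:
    """Subjects aligned onto one common grid, with their transforms."""

    aligned_fa: list[ScalarVolume]
    transforms: list            # per subject: list of image-op transforms
    strategy: str
    reference_image: ScalarVolume

    def __post_init__(self) -> None:
        grid = self.reference_image
        for v in self.aligned_fa:
            if not grid.same_grid(v):
                raise ValueError("aligned volumes must share the reference grid")

    @property
    def n_subjects(self) -> int:
        return len(self.aligned_fa)


@dataclass
class AtlasTrace:
    """Per-iteration record of group-wise atlas construction."""

    variances: list[float]      # mean-over-voxels variance of (subject - atlas)
    schedule: list[str]
    atlases: list[ScalarVolume] | None = None


def variance_of_difference(volumes) -> float:
    """Mean over voxels of the across-subject variance of aligned FA.

    Differences to the group mean have zero average, so this equals the
    mean voxel-wise variance of (subject − average image).
    """
    vols = list(getattr(volumes, "aligned_fa", volumes))
    stack = np.stack([v.data for v in vols])
    return float(np.mean(np.var(stack, axis=0, ddof=1)))


MATCH_BLUR_MM = 1.5  # moving-image smoothing for matched-resolution registration


def _register_subject(subject: ScalarVolume, target: ScalarVolume,
                      nonrigid: str = "pipeline",
                      init_params: np.ndarray | None = None):
    """Linear (affine) + non-rigid registration of one subject to a target.

    The non-rigid stage works on a lightly smoothed copy of the moving
    image (matched-resolution registration): pipeline targets are averages
    or population templates, visibly smoother than a single subject, and
    matching a crisp image to a blurred one would otherwise reward
    deformations that fake the blur.  Returns (transform list in image-op
    order, aligned image on the target grid) with a single final
    interpolation.
    """
    aff = register_linear(subject, target, kind="affine", init_params=init_params)
    lin = resample(subject, aff, out_grid=target)
    fld = register_nonrigid(gaussian_smooth(lin, MATCH_BLUR_MM), target, algorithm=nonrigid)
    transforms = [aff, fld]
    aligned = resample(subject, transforms, out_grid=target)
    return transforms, aligned


def align_standard(subjects, template: ScalarVolume,
                   nonrigid: str = "pipeline") -> AlignedCohort:
    """ST-TBSS: register every subject directly to the standard template."""
    subjects = list(subjects)
    if len(subjects) < 2:
        raise ValueError("need at least 2 subjects")
    aligned, transforms = [], []
    for i, sub in enumerate(subjects):
        try:
            tr, img = _register_subject(sub, template, nonrigid)
        except Exception as exc:  # pragma: no cover - defensive
            raise RuntimeError(f"registration failed for subject {i}") from exc
        transforms.append(tr)
        aligned.append(img)
        logger.debug("ST aligned subject %d", i)
    return AlignedCohort(aligned, transforms, "ST", template)


def select_representative(subjects, template: ScalarVolume,
                          max_pairs: int | None = None,
                          nonrigid: str = "pipeline"):
    """RS-TBSS: pick the subject needing minimum mean non-rigid deformation.

    All pairwise (linear + non-rigid) registrations are computed; for each
    candidate reference the mean deformation magnitude of the fields
    aligning every other subject *to* it is recorded, and the argmin wins
    (ties toward the lower index).  ``max_pairs`` caps the total number of
    pairwise registrations by subsampling the 'other' subjects evenly per
    candidate — full pairwise is quadratic and the cap keeps large cohorts
    tractable.

    Returns ``(index, AlignedCohort)`` where the cohort maps every subject
    through its non-rigid transform to the reference composed with the
    reference's affine to the template.
    """
    subjects = list(subjects)
    n = len(subjects)
    if n < 3:
        raise ValueError("representative selection needs at least 3 subjects")
    per_candidate = n - 1
    if max_pairs is not None and n * (n - 1) > max_pairs:
        per_candidate = max(2, max_pairs // n)
        logger.info("subsampling pairwise registrations: %d per candidate", per_candidate)

    mean_def = np.empty(n)
    for s in range(n):
        others = [j for j in range(n) if j != s]
        if per_candidate < len(others):
            sel = np.linspace(0, len(others) - 1, per_candidate).round().astype(int)
            others = [others[k] for k in np.unique(sel)]
        mags = []
        for j in others:
            aff = register_linear(subjects[j], subjects[s], kind="affine")
            lin = resample(subjects[j], aff, out_grid=subjects[s])
            fld = register_nonrigid(lin, subjects[s], algorithm=nonrigid)
            mags.append(deformation_magnitude(fld))
        mean_def[s] = float(np.mean(mags))
    ref_idx = int(np.argmin(mean_def))  # argmin takes the lowest index on ties
    logger.info("representative subject: %d (mean deformation %.3f mm)",
                ref_idx, mean_def[ref_idx])

    reference = subjects[ref_idx]
    ref_to_template = register_linear(reference, template, kind="affine")
    aligned, transforms = [], []
    for i, sub in enumerate(subjects):
        if i == ref_idx:
            tr = [ref_to_template]
        else:
            aff = register_linear(sub, reference, kind="affine")
            lin = resample(sub, aff, out_grid=reference)
            fld = register_nonrigid(lin, reference, algorithm=nonrigid)
            tr = [aff, fld, ref_to_template]
        transforms.append(tr)
        aligned.append(resample(sub, tr, out_grid=template))
    cohort = AlignedCohort(aligned, transforms, "RS", template)
    return ref_idx, cohort


def build_study_template(subjects, template: ScalarVolume,
                         nonrigid: str = "pipeline") -> AlignedCohort:
    """SS-TBSS: align to the template, average, re-register originals to
    the average (the study-specific template)."""
    stage1 = align_standard(subjects, template, nonrigid=nonrigid)
    study_template = template.like(
        np.mean([v.data for v in stage1.aligned_fa], axis=0))
    aligned, transforms = [], []
    for i, sub in enumerate(subjects):
        tr, img = _register_subject(sub, study_template, nonrigid)
        transforms.append(tr)
        aligned.append(img)
    return AlignedCohort(aligned, transforms, "SS", study_template)


def build_groupwise_atlas(subjects, template: ScalarVolume,
                          schedule=DEFAULT_GW_SCHEDULE, seed: int = 0,
                          nonrigid: str = "pipeline",
                          keep_atlases: bool = False,
                          min_improvement: float | None = None):
    """GW-TBSS: iterative unbiased atlas, then affine to the template.

    Each iteration registers every *original* subject to the current atlas
    with the stage's deformation model and replaces the atlas by the mean
    of the registered images.  The schedule must start with a rigid stage
    so the random choice of the initial atlas subject introduces no bias.
    The finished atlas is affine-registered to the standard template and
    that affine is composed into every subject's transform.

    Returns ``(AlignedCohort, AtlasTrace)``.
    """
    subjects = list(subjects)
    n = len(subjects)
    if n < 2:
        raise ValueError("need at least 2 subjects")
    schedule = list(schedule)
    if not schedule or schedule[0] != "rigid":
        raise ValueError("the schedule must start with a rigid stage")
    for st in schedule:
        if st not in ("rigid", "affine", "nonrigid"):
            raise ValueError(f"unknown schedule stage {st!r}")

    rng = np.random.default_rng(seed)
    init = int(rng.integers(n))
    atlas = subjects[init].copy()
    logger.info("initial atlas: subject %d", init)

    variances: list[float] = []
    atlases: list[ScalarVolume] = []
    warm: list[np.ndarray | None] = [None] * n
    warm_field: list[np.ndarray | None] = [None] * n
    fixed_aff: list = [None] * n      # affine frozen once non-rigid refinement starts
    fixed_lin: list = [None] * n
    transforms: list[list] = [[] for _ in range(n)]
    registered = subjects
    for it, stage in enumerate(schedule):
        regs, trs = [], []
        for i, sub in enumerate(subjects):
            if stage in ("rigid", "affine"):
                aff = register_linear(sub, atlas, kind=stage, init_params=warm[i])
                warm[i] = aff.info.get("params")
                tr = [aff]
                reg = resample(sub, tr, out_grid=atlas)
            else:
                if fixed_aff[i] is None:
                    # the linear part settles during the global stages; it is
                    # re-estimated once as non-rigid refinement begins and
                    # then held fixed while the field iterates
                    aff = register_linear(sub, atlas, kind="affine", init_params=warm[i])
                    warm[i] = aff.info.get("params")
                    fixed_aff[i] = aff
                    fixed_lin[i] = resample(sub, aff, out_grid=atlas)
                opts = {}
                if nonrigid == "pipeline" and warm_field[i] is not None:
                    # warm start from the previous iteration's solution —
                    # still a fresh registration to the current atlas
                    opts["init_coeffs"] = warm_field[i]
                fld = register_nonrigid(gaussian_smooth(fixed_lin[i], MATCH_BLUR_MM),
                                        atlas, algorithm=nonrigid, **opts)
                warm_field[i] = getattr(fld, "coeffs", None)
                tr = [fixed_aff[i], fld]
                reg = resample(fixed_lin[i], fld)
            trs.append(tr)
            regs.append(reg)
        new_atlas = atlas.like(np.mean([r.data for r in regs], axis=0))
        var = float(np.mean(np.var(np.stack([r.data for r in regs]), axis=0, ddof=1)))
        variances.append(var)
        if keep_atlases:
            atlases.append(new_atlas)
        atlas = new_atlas
        transforms = trs
        registered = regs
        logger.info("GW iteration %d (%s): variance %.3e", it, stage, var)
        if (min_improvement is not None and len(variances) >= 2
                and variances[-2] > 0
                and (variances[-2] - var) / variances[-2] < min_improvement):
            logger.info("early stop at iteration %d", it)
            break

    # unbiased-frame correction, applied after convergence: the free atlas
    # evolution can wander to a self-consistent anatomy a common
    # deformation away from the cohort barycentre.  Removing the mean
    # field pins the cohort at the barycentre; because the individual fits
    # were optimal in the wandered frame, one refinement pass against the
    # corrected atlas follows, and its (small) residual mean is removed in
    # turn.
    if any(len(tr) == 2 for tr in transforms):
        def _demean(flds):
            mean_u = np.mean([f.vectors for f in flds], axis=0)
            out = []
            for f in flds:
                g = DisplacementField(f.vectors - mean_u, f.voxel_size)
                if getattr(f, "coeffs", None) is not None:
                    g.coeffs = f.coeffs  # refinement warm start; mean removal
                out.append(g)           # happens in vector space
            return out

        flds = _demean([tr[1] for tr in transforms])
        regs = [resample(fixed_lin[i], flds[i]) for i in range(n)]
        atlas = atlas.like(np.mean([r.data for r in regs], axis=0))
        refined = []
        for i in range(n):
            opts = {}
            if nonrigid == "pipeline" and getattr(flds[i], "coeffs", None) is not None:
                mean_c = np.mean([getattr(f, "coeffs") for f in flds], axis=0)
                opts["init_coeffs"] = flds[i].coeffs - mean_c
            refined.append(register_nonrigid(gaussian_smooth(fixed_lin[i], MATCH_BLUR_MM),
                                             atlas, algorithm=nonrigid, **opts))
        flds = _demean(refined)
        for i in range(n):
            transforms[i] = [transforms[i][0], flds[i]]
        regs = [resample(fixed_lin[i], flds[i]) for i in range(n)]
        atlas = atlas.like(np.mean([r.data for r in regs], axis=0))

    atlas_to_template = register_linear(atlas, template, kind="affine")
    aligned, full_transforms = [], []
    for i in range(n):
        tr = transforms[i] + [atlas_to_template]
        full_transforms.append(tr)
        aligned.append(resample(subjects[i], tr, out_grid=template))
    cohort = AlignedCohort(aligned, full_transforms, "GW",
                           resample(atlas, atlas_to_template, out_grid=template))
    trace = AtlasTrace(variances, schedule[: len(variances)],
                       atlases if keep_atlases else None)
    return cohort, trace


def build_cohort(subjects, template: ScalarVolume, strategy: str, seed: int = 0,
                 **kwargs):
    """Dispatch on strategy name; returns (AlignedCohort, AtlasTrace | None)."""
    strategy = strategy.upper()
    if strategy == "ST":
        return align_standard(subjects, template, **kwargs), None
    if strategy == "RS":
        _, cohort = select_representative(subjects, template, **kwargs)
        return cohort, None
    if strategy == "SS":
        return build_study_template(subjects, template, **kwargs), None
    if strategy == "GW":
        return build_groupwise_atlas(subjects, template, seed=seed, **kwargs)
    raise ValueError(f"unknown strategy {strategy!r}")
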