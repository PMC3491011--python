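"""Synthetic FA phantoms.

Generates cohorts of FA-like volumes with known tract geometry
(smooth curved tubes with a Gaussian cross-profile over a low-FA
background), a central CSF-like ventricle, seeded inter-subject warps,
atrophy-like ventricular expansion, and planted fractional FA reductions.
These stand in for the standard-space FA template, the tract-label atlas,
and the control / atrophied cohorts of the evaluation experiments.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .core import LabelVolume, ScalarVolume
from .imgreg import DisplacementField, compose, invert, resample, _grid_world

__all__ = [
    "PhantomTemplate",
    "CohortSpec",
    "make_template",
    "make_standard_template",
    "make_subject",
    "make_cohort",
    "simulate_atrophy",
    "reduce_fa",
]

# FA levels of the synthetic tissue classes.  The tract peak sits well above
# the 0.2 skeletonisation threshold and the tube profile decays below 0.2 at
# the tube boundary; the background mimics grey matter / minor WM and the
# ventricle mimics CSF.
PEAK_FA = 0.75
BACKGROUND_FA = 0.07
VENTRICLE_FA = 0.03
TUBE_SIGMA_MM = 3.5   # Gaussian cross-profile width
TUBE_RADIUS_MM = 6.5  # nominal tube boundary (profile < 0.2 beyond this)
TEMPLATE_SMOOTH_MM = 1.0  # final band-limiting so trilinear resampling is benign
VENTRICLE_RADIUS_MM = 7.0


@dataclass
class PhantomTemplate:
    """Ground-truth template: FA volume, tract labels, centrelines, ventricle."""

    fa_volume: ScalarVolume
    tract_labels: LabelVolume
    centrelines: list[np.ndarray]  # one (n_i, 3) voxel-coordinate array per tract
    ventricle_mask: np.ndarray     # boolean volume

    @property
    def n_tracts(self) -> int:
        return len(self.centrelines)


@dataclass
class CohortSpec:
    """Parameters of one synthetic cohort."""

    n_subjects: int = 10
    seed: int = 0
    warp_amplitude: float = 4.0    # mm, max inter-subject displacement
    warp_smoothness: float = 8.0   # mm, Gaussian width of the random field
    noise_sd: float = 0.02         # FA units
    atrophy_severity: float = 0.0  # dimensionless; peak expansion in mm

    def __post_init__(self) -> None:
        if self.n_subjects < 2:
            raise ValueError("a cohort needs at least 2 subjects")
        if self.warp_amplitude < 0 or self.noise_sd < 0 or self.atrophy_severity < 0:
            raise ValueError("warp_amplitude, noise_sd and atrophy_severity must be >= 0")


def _curve_points(grid_shape, voxel_size, x_offset_mm, wobble_mm, phase, n_samples=400):
    """A smooth curve running along the y axis at a lateral offset, with
    sinusoidal wobble in x and z.  Returns world-mm points."""
    ext = (np.asarray(grid_shape) - 1) * np.asarray(voxel_size)
    t = np.linspace(0.0, 1.0, n_samples)
    y = t * ext[1]
    x = ext[0] / 2 + x_offset_mm + wobble_mm * np.sin(2 * np.pi * t + phase)
    z = ext[2] / 2 + wobble_mm * np.cos(2 * np.pi * t * 0.75 + phase * 1.3)
    return np.stack([x, y, z], axis=-1)


def make_template(grid_shape=(48, 48, 48), voxel_size_mm=(2.0, 2.0, 2.0),
                  n_tracts: int = 3, seed: int = 0) -> PhantomTemplate:
    """Build a phantom template with ``n_tracts`` curved tube tracts and a
    central low-FA ventricle.  Deterministic for a fixed seed."""
    grid_shape = tuple(int(n) for n in grid_shape)
    voxel_size = tuple(float(v) for v in voxel_size_mm)
    if min(grid_shape) < 32:
        raise ValueError("grid_shape must be at least 32 voxels per axis")
    if n_tracts < 1:
        raise ValueError("n_tracts must be >= 1")
    ext = (np.asarray(grid_shape) - 1) * np.asarray(voxel_size)
    # the first two tracts are periventricular (hugging the ventricle on
    # either side, like the fornix and callosal body): exactly the
    # geometry where atrophy-driven ventricular expansion displaces white
    # matter; further tracts sit laterally outward
    peri = VENTRICLE_RADIUS_MM + 5.0
    offsets = [peri, -peri, peri + 19.0, -peri - 19.0, peri + 38.0, -peri - 38.0][:n_tracts]
    if n_tracts > 6:
        raise ValueError("at most 6 tracts fit the phantom layout")
    if max(abs(o) for o in offsets) + TUBE_RADIUS_MM > ext[0] / 2:
        raise ValueError(
            f"grid of extent {ext[0]:.0f} mm too small for {n_tracts} tracts; "
            f"needs half-extent > {max(abs(o) for o in offsets) + TUBE_RADIUS_MM:.0f} mm"
        )

    rng = np.random.default_rng(seed)
    h = np.asarray(voxel_size)
    fa = np.full(grid_shape, BACKGROUND_FA)
    labels = np.zeros(grid_shape, dtype=np.int16)
    best_dist = np.full(grid_shape, np.inf)
    centrelines: list[np.ndarray] = []
    # tracts on one side run parallel (shared wobble), like neighbouring
    # association tracts; otherwise converging tubes would merge their
    # FA profiles into a single ridge
    side_params = {s: (float(rng.uniform(1.0, 2.0)), float(rng.uniform(0, 2 * np.pi)))
                   for s in (+1, -1)}
    for tract_id, off in enumerate(offsets, start=1):
        wobble, phase = side_params[+1 if off >= 0 else -1]
        pts = _curve_points(grid_shape, voxel_size, off, wobble, phase)
        # rasterise the centreline: unique voxels in curve order
        vox = np.round(pts / h).astype(int)
        vox = np.clip(vox, 0, np.asarray(grid_shape) - 1)
        keep = np.ones(len(vox), dtype=bool)
        keep[1:] = np.any(vox[1:] != vox[:-1], axis=1)
        cl = vox[keep]
        _, first = np.unique(cl, axis=0, return_index=True)
        cl = cl[np.sort(first)]
        centrelines.append(cl)
        # distance (mm) from every voxel to the rasterised centreline
        on = np.zeros(grid_shape, dtype=bool)
        on[tuple(cl.T)] = True
        dist = ndimage.distance_transform_edt(~on, sampling=voxel_size)
        profile = BACKGROUND_FA + (PEAK_FA - BACKGROUND_FA) * np.exp(-dist**2 / (2 * TUBE_SIGMA_MM**2))
        closer = dist < best_dist
        fa = np.where(closer, np.maximum(fa, profile), fa)
        in_tube = (dist <= TUBE_RADIUS_MM) & closer
        labels[in_tube] = tract_id
        best_dist = np.minimum(best_dist, dist)

    # deep-grey-like blobs: mild FA bumps (below the skeleton threshold) at
    # fixed asymmetric positions; without them the phantom would be nearly
    # translation-invariant along the tract axis and registration would
    # face an artificial aperture problem real anatomy does not pose
    centre = ext / 2.0
    world = _grid_world(grid_shape, voxel_size)
    for frac in np.array([[0.12, 0.22, 0.05], [-0.10, -0.18, -0.08],
                          [0.05, -0.30, 0.10]]):
        pos = centre + frac * ext
        d2 = np.sum((world - pos) ** 2, axis=-1)
        fa = np.maximum(fa, BACKGROUND_FA + 0.08 * np.exp(-d2 / (2 * 4.0 ** 2)))

    # central ventricle: low-FA ellipsoid
    r = np.linalg.norm((world - centre) / np.array([1.0, 1.6, 1.0]), axis=-1)
    ventricle = r <= VENTRICLE_RADIUS_MM
    fa = np.where(ventricle, VENTRICLE_FA, fa)
    labels[ventricle] = 0
    # band-limit: FA maps are smooth at the voxel scale, and a sharp phantom
    # would make trilinear interpolation error dominate every warp
    fa = ndimage.gaussian_filter(fa, [TEMPLATE_SMOOTH_MM / hh for hh in voxel_size])
    fa = np.clip(fa, 0.0, 1.0)
    return PhantomTemplate(
        fa_volume=ScalarVolume(fa, voxel_size),
        tract_labels=LabelVolume(labels.astype(float), voxel_size),
        centrelines=centrelines,
        ventricle_mask=ventricle,
    )


def make_standard_template(template: PhantomTemplate, offset_mm: float = 6.0,
                           smoothness_mm: float = 14.0, blur_mm: float = 2.0,
                           seed: int = 4242) -> ScalarVolume:
    """A standard-space FA template with a systematic anatomical offset.

    Real group studies register to a population-average template whose
    anatomy differs systematically from the study cohort (for instance in
    age and ventricle size) and which is visibly smoother than any single
    subject, being an average over many imperfectly aligned brains.  This
    emulates both: the cohort's generating template is deformed by a fixed
    seeded smooth field of amplitude ``offset_mm`` and blurred by
    ``blur_mm``, so direct registration to "standard space" must overcome
    a consistent anatomical mismatch toward a soft target.
    """
    rng = np.random.default_rng([int(seed), 17])
    vol = template.fa_volume
    fld = _random_smooth_field(vol.shape, vol.voxel_size, offset_mm,
                               smoothness_mm, rng)
    out = resample(vol, fld, boundary="extend")
    if blur_mm > 0:
        out.data = ndimage.gaussian_filter(out.data, [blur_mm / hh for hh in vol.voxel_size])
    out.data = np.clip(out.data, 0.0, 1.0)
    return out


def _random_smooth_field(shape, voxel_size, amplitude_mm, smoothness_mm, rng) -> DisplacementField:
    """White-noise vectors, Gaussian-smoothed, rescaled to a max amplitude."""
    u = rng.standard_normal(tuple(shape) + (3,))
    if amplitude_mm == 0:
        return DisplacementField(np.zeros_like(u), voxel_size)
    sig_vox = [max(smoothness_mm, 1e-6) / hh for hh in voxel_size]
    for k in range(3):
        u[..., k] = ndimage.gaussian_filter(u[..., k], sig_vox)
    mags = np.linalg.norm(u, axis=-1)
    peak = mags.max()
    if peak > 0:
        u *= amplitude_mm / peak
    return DisplacementField(u, voxel_size)


def make_subject(template: PhantomTemplate, spec: CohortSpec,
                 subject_index: int) -> tuple[ScalarVolume, DisplacementField]:
    """One synthetic subject: template warped by a seeded random smooth
    displacement field plus clipped Gaussian noise.  Returns the image and
    the ground-truth (pull-back) field; deterministic for a fixed
    (seed, subject_index)."""
    rng = np.random.default_rng([spec.seed, int(subject_index)])
    vol = template.fa_volume
    fld = _random_smooth_field(vol.shape, vol.voxel_size,
                               spec.warp_amplitude, spec.warp_smoothness, rng)
    if spec.warp_amplitude > 0:
        # edge extension: a subject's FA map fills its field of view, as an
        # acquired map would
        img = resample(vol, fld, boundary="extend")
    else:
        img = vol.copy()
    if spec.noise_sd > 0:
        img = img.like(img.data + rng.normal(0.0, spec.noise_sd, img.shape))
    img.data = np.clip(img.data, 0.0, 1.0)
    return img, fld


def make_cohort(template: PhantomTemplate, spec: CohortSpec):
    """All subjects of a cohort, with their ground-truth fields."""
    pairs = [make_subject(template, spec, i) for i in range(spec.n_subjects)]
    return [p[0] for p in pairs], [p[1] for p in pairs]


def simulate_atrophy(volume: ScalarVolume, ventricle_mask: np.ndarray,
                     severity: float, seed: int = 0,
                     random_amplitude_mm: float = 1.0,
                     random_smoothness_mm: float = 10.0,
                     ) -> tuple[ScalarVolume, DisplacementField]:
    """Atrophy-like deformation: radial ventricular expansion plus a mild
    random component.

    The expansion is an analytic outward field centred on the ventricle,
    peaking (at ``severity`` mm) near the ventricle boundary and decaying
    smoothly with distance, so ground truth is known at any severity.
    Returns the deformed image and the forward (tissue-motion) field, whose
    divergence is positive inside the ventricle; resampling internally uses
    its numerical inverse (the pull-back field).
    """
    if severity < 0:
        raise ValueError("severity must be >= 0")
    ventricle_mask = np.asarray(ventricle_mask, dtype=bool)
    if not ventricle_mask.any():
        raise ValueError("ventricle mask is empty")
    h = np.asarray(volume.voxel_size)
    world = _grid_world(volume.shape, volume.voxel_size)
    idx = np.argwhere(ventricle_mask)
    centre = idx.mean(axis=0) * h
    # effective ventricle radius from its volume
    r0 = max((3 * idx.shape[0] * np.prod(h) / (4 * np.pi)) ** (1 / 3), float(h.min()))
    delta = world - centre
    r = np.linalg.norm(delta, axis=-1)
    with np.errstate(invalid="ignore", divide="ignore"):
        unit = np.where(r[..., None] > 1e-9, delta / np.maximum(r, 1e-9)[..., None], 0.0)
    # outward magnitude: 0 at the centre, peak = severity mm at r0, smooth decay
    mag = severity * (r / r0) * np.exp(0.5 * (1.0 - (r / r0) ** 2))
    forward = DisplacementField(unit * mag[..., None], volume.voxel_size)

    rng = np.random.default_rng([int(seed), 971]) if random_amplitude_mm > 0 else None
    if severity == 0 and (rng is None or random_amplitude_mm == 0):
        return volume.copy(), forward
    pull = invert(forward)
    if rng is not None and random_amplitude_mm > 0:
        rand = _random_smooth_field(volume.shape, volume.voxel_size,
                                    random_amplitude_mm, random_smoothness_mm, rng)
        total_pull = compose(rand, pull)  # expansion applied first, then the random warp
    else:
        total_pull = pull
    deformed = resample(volume, total_pull, boundary="extend")
    deformed.data = np.clip(deformed.data, 0.0, 1.0)
    return deformed, forward


def reduce_fa(volume: ScalarVolume, mask: np.ndarray, fraction: float) -> ScalarVolume:
    """Multiply FA inside ``mask`` by (1 - fraction); everything else unchanged."""
    if not 0 <= fraction < 1:
        raise ValueError("fraction must lie in [0, 1)")
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != volume.shape:
        raise ValueError("mask/volume shape mismatch")
    out = volume.data.copy()
    out[mask] *= (1.0 - fraction)
    return volume.like(out)
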