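"""Registration primitives: linear and non-rigid alignment, resampling,
displacement-field algebra, and the interpolation-matched smoothing-kernel
selection.

Conventions
-----------
* All transforms use the *pull-back* convention: a transform ``T`` maps a
  point of the fixed (output) grid, in world mm, to the location in the
  moving (input) image at which the output voxel is sampled.
* ``resample(I, [T1, T2])`` equals ``resample(resample(I, T1), T2)`` but is
  computed with a single interpolation.
* Displacement fields store per-voxel 3-vectors in mm on the fixed grid;
  the sampled location is ``x + u(x)``.

The two non-rigid algorithms are deliberately distinct code paths: a
parametric coarse-control-point method (``pipeline``) used inside the TBSS
registration step, and a non-parametric demons method (``independent``)
used only to manufacture the artificial warps of the specificity
experiment, so the evaluation warp does not share a deformation model with
the pipeline being evaluated.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage, optimize

from .core import ScalarVolume

__all__ = [
    "AffineTransform",
    "DisplacementField",
    "identity_affine",
    "register_linear",
    "register_nonrigid",
    "resample",
    "compose",
    "invert",
    "as_field",
    "deformation_magnitude",
    "gaussian_smooth",
    "ncc",
    "rmse",
    "select_kernel_width",
]


# --------------------------------------------------------------------------
# transform types
# --------------------------------------------------------------------------

@dataclass
class AffineTransform:
    """4x4 homogeneous world-coordinate (mm) mapping, pull-back convention."""

    matrix: np.ndarray
    kind: str = "affine"  # "rigid" | "affine"
    info: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.shape != (4, 4):
            raise ValueError("affine matrix must be 4x4")
        if abs(np.linalg.det(self.matrix[:3, :3])) < 1e-12:
            raise ValueError("affine matrix is singular")
        if self.kind == "rigid":
            lin = self.matrix[:3, :3]
            if not np.allclose(lin @ lin.T, np.eye(3), atol=1e-6) or np.linalg.det(lin) < 0:
                raise ValueError("rigid transform must have an orthonormal, det=+1 linear part")

    def apply(self, pts: np.ndarray) -> np.ndarray:
        """Map (..., 3) world points."""
        return pts @ self.matrix[:3, :3].T + self.matrix[:3, 3]

    def inverse(self) -> "AffineTransform":
        return AffineTransform(np.linalg.inv(self.matrix), kind=self.kind)

    def save(self, path) -> None:
        np.savetxt(path, self.matrix, header=f"kind: {self.kind}")

    @classmethod
    def load(cls, path) -> "AffineTransform":
        with open(path) as fh:
            first = fh.readline()
        kind = "affine"
        if "kind:" in first:
            kind = first.split("kind:")[1].strip()
        return cls(np.loadtxt(path), kind=kind)


def identity_affine(kind: str = "rigid") -> AffineTransform:
    return AffineTransform(np.eye(4), kind=kind)


@dataclass
class DisplacementField:
    """Per-voxel displacement (mm) on a reference grid, pull-back convention."""

    vectors: np.ndarray  # (X, Y, Z, 3), mm
    voxel_size: tuple[float, float, float]

    def __post_init__(self) -> None:
        self.vectors = np.asarray(self.vectors, dtype=float)
        if self.vectors.ndim != 4 or self.vectors.shape[-1] != 3:
            raise ValueError("displacement field must have shape (X, Y, Z, 3)")
        if not np.all(np.isfinite(self.vectors)):
            raise ValueError("displacement field contains non-finite values")
        self.voxel_size = tuple(float(v) for v in self.voxel_size)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.vectors.shape[:3]  # type: ignore[return-value]

    def apply(self, pts: np.ndarray) -> np.ndarray:
        """Map (..., 3) world points: ``x + u(x)`` with trilinear sampling of u."""
        vox = pts / np.asarray(self.voxel_size)
        coords = np.moveaxis(vox, -1, 0)
        u = np.stack(
            [ndimage.map_coordinates(self.vectors[..., k], coords, order=1, mode="nearest")
             for k in range(3)],
            axis=-1,
        )
        return pts + u

    def magnitudes(self) -> np.ndarray:
        return np.linalg.norm(self.vectors, axis=-1)


Transform = AffineTransform | DisplacementField


def _grid_world(shape, voxel_size) -> np.ndarray:
    """(X, Y, Z, 3) world coordinates of every voxel centre."""
    axes = [np.arange(n) * h for n, h in zip(shape, voxel_size)]
    return np.stack(np.meshgrid(*axes, indexing="ij"), axis=-1)


def _point_map(transforms, pts: np.ndarray) -> np.ndarray:
    """Evaluate the sampling map of a sequence of image-op transforms.

    ``transforms`` is ordered as the warps are applied to the image; the
    resulting map is ``T1(T2(...Tk(x)))``.
    """
    out = pts
    for t in reversed(list(transforms)):
        out = t.apply(out)
    return out


# --------------------------------------------------------------------------
# resampling and field algebra
# --------------------------------------------------------------------------

_ORDERS = {"trilinear": 1, "nearest": 0}


def resample(volume: ScalarVolume, transform, interpolation: str = "trilinear",
             out_grid: ScalarVolume | None = None,
             boundary: str = "zero") -> ScalarVolume:
    """Pull-back resampling of ``volume`` through one transform or a
    composition (sequence applied first-to-last). Out-of-field voxels are 0
    (``boundary="extend"`` replicates edge values instead, used by the
    phantom generator whose images must fill the field of view).
    """
    if interpolation not in _ORDERS:
        raise ValueError(f"unknown interpolation mode {interpolation!r}")
    order = _ORDERS[interpolation]
    transforms = transform if isinstance(transform, (list, tuple)) else [transform]
    ref = out_grid if out_grid is not None else volume
    for t in transforms:
        if isinstance(t, DisplacementField):
            ref_shape, ref_h = t.shape, t.voxel_size
            break
    else:
        ref_shape, ref_h = ref.shape, ref.voxel_size
    pts = _grid_world(ref_shape, ref_h)
    src = _point_map(transforms, pts)
    vox = src / np.asarray(volume.voxel_size)
    coords = np.moveaxis(vox, -1, 0)
    mode = {"zero": "constant", "extend": "nearest"}[boundary]
    out = ndimage.map_coordinates(volume.data.astype(float), coords, order=order,
                                  mode=mode, cval=0.0)
    return ScalarVolume(out, ref_h)


def as_field(transform, shape, voxel_size) -> DisplacementField:
    """Materialise any transform (or composition) as a field on a grid."""
    transforms = transform if isinstance(transform, (list, tuple)) else [transform]
    pts = _grid_world(shape, voxel_size)
    return DisplacementField(_point_map(transforms, pts) - pts, voxel_size)


def compose(a, b, shape=None, voxel_size=None) -> DisplacementField:
    """Composite field such that resampling with it applies ``b`` then ``a``
    (``resample(I, compose(a, b)) == resample(resample(I, b), a)``).
    """
    for t in (b, a):
        if isinstance(t, DisplacementField):
            shape, voxel_size = t.shape, t.voxel_size
            break
    if shape is None:
        raise ValueError("compose of two affines needs an explicit grid")
    return as_field([b, a], shape, voxel_size)


def invert(fld: DisplacementField, max_iter: int = 50, tol_voxel: float = 0.05) -> DisplacementField:
    """Fixed-point inversion: find ``v`` with ``v(x) = -u(x + v(x))``."""
    h = np.asarray(fld.voxel_size)
    pts = _grid_world(fld.shape, fld.voxel_size)
    v = np.zeros_like(fld.vectors)
    prev_res = np.inf
    for _ in range(max_iter):
        mapped = fld.apply(pts + v)  # x + v + u(x+v)
        v_new = -(mapped - (pts + v))
        res = float(np.mean(np.linalg.norm(v_new - v, axis=-1))) / float(h.min())
        v = v_new
        if res < tol_voxel:
            break
        if res > 10 * max(prev_res, 1.0):
            raise RuntimeError("field inversion diverged")
        prev_res = res
    return DisplacementField(v, fld.voxel_size)


def deformation_magnitude(fld: DisplacementField) -> float:
    """Mean Euclidean displacement over the grid, in mm."""
    return float(np.mean(fld.magnitudes()))


def gaussian_smooth(volume: ScalarVolume, sigma_mm: float) -> ScalarVolume:
    """Gaussian smoothing with sigma given in mm (converted per axis)."""
    if sigma_mm <= 0:
        return volume.copy()
    sig_vox = [sigma_mm / h for h in volume.voxel_size]
    return volume.like(ndimage.gaussian_filter(volume.data.astype(float), sig_vox))


def ncc(a: np.ndarray, b: np.ndarray) -> float:
    """Normalised cross-correlation of two equally shaped arrays."""
    a = np.asarray(a, dtype=float).ravel()
    b = np.asarray(b, dtype=float).ravel()
    a = a - a.mean()
    b = b - b.mean()
    denom = np.sqrt((a @ a) * (b @ b))
    if denom == 0:
        return 0.0
    return float((a @ b) / denom)


def rmse(a: np.ndarray, b: np.ndarray) -> float:
    return float(np.sqrt(np.mean((np.asarray(a, float) - np.asarray(b, float)) ** 2)))


# --------------------------------------------------------------------------
# linear registration
# --------------------------------------------------------------------------

def _params_to_matrix(p: np.ndarray, kind: str, centre: np.ndarray) -> np.ndarray:
    tx, ty, tz, rx, ry, rz = p[:6]
    cx, cy, cz = np.cos([rx, ry, rz])
    sx, sy, sz = np.sin([rx, ry, rz])
    Rx = np.array([[1, 0, 0], [0, cx, -sx], [0, sx, cx]])
    Ry = np.array([[cy, 0, sy], [0, 1, 0], [-sy, 0, cy]])
    Rz = np.array([[cz, -sz, 0], [sz, cz, 0], [0, 0, 1]])
    lin = Rz @ Ry @ Rx
    if kind == "affine":
        scale = np.exp(p[6:9])
        sh = p[9:12]
        shear = np.array([[1, sh[0], sh[1]], [0, 1, sh[2]], [0, 0, 1]])
        lin = lin @ shear @ np.diag(scale)
    mat = np.eye(4)
    mat[:3, :3] = lin
    mat[:3, 3] = centre - lin @ centre + p[:3]
    return mat


def _pyramid(vol: ScalarVolume, factor: int, extra_sigma_vox: float = 0.0) -> ScalarVolume:
    """Smooth + subsample one pyramid level.

    ``extra_sigma_vox`` adds smoothing measured in voxels of the *level*
    grid; the similarity metric needs it so that interpolation artifacts
    (NCC spikes at integer-voxel shifts) do not trap the optimiser.
    """
    data = vol.data.astype(np.float32)
    sigma = factor * np.hypot(0.5, extra_sigma_vox)
    if factor == 1:
        if extra_sigma_vox > 0:
            data = ndimage.gaussian_filter(data, extra_sigma_vox)
        return ScalarVolume(data, vol.voxel_size)
    sm = ndimage.gaussian_filter(data, sigma)
    sl = tuple(slice(None, None, factor) for _ in range(3))
    return ScalarVolume(sm[sl], tuple(h * factor for h in vol.voxel_size))


def _affine_resample_fast(moving: ScalarVolume, matrix: np.ndarray,
                          fixed: ScalarVolume) -> np.ndarray:
    """order-1 resample of moving through a world matrix onto fixed's grid."""
    hm = np.asarray(moving.voxel_size)
    hf = np.asarray(fixed.voxel_size)
    A = (matrix[:3, :3] * hf[None, :]) / hm[:, None]
    off = matrix[:3, 3] / hm
    return ndimage.affine_transform(moving.data.astype(np.float32, copy=False), A,
                                    offset=off, output_shape=fixed.shape, order=1,
                                    mode="constant", cval=-1.0)


_N_PARAMS = {"rigid": 6, "affine": 12}


def register_linear(moving: ScalarVolume, fixed: ScalarVolume, kind: str = "affine",
                    init_params: np.ndarray | None = None,
                    max_evals: tuple[int, ...] = (120, 60, 24)) -> AffineTransform:
    """Linear registration maximising normalised cross-correlation.

    Multi-resolution Powell optimisation over translation + rotation
    (rigid) or + log-scale + shear (affine).  Deterministic: fixed
    initialisation (identity unless ``init_params`` warm-starts it), no
    randomness.  If the optimiser fails to beat the initialisation the
    initial transform is returned with ``info['warning']`` set.
    """
    if kind not in _N_PARAMS:
        raise ValueError(f"unknown linear registration kind {kind!r}")
    n_par = _N_PARAMS[kind]
    p = np.zeros(n_par) if init_params is None else np.asarray(init_params, float).copy()
    if p.size < n_par:  # warm-start rigid params into an affine problem
        p = np.concatenate([p, np.zeros(n_par - p.size)])
    centre = (np.asarray(fixed.shape) - 1) * np.asarray(fixed.voxel_size) / 2.0

    scales = np.array([2.0, 2.0, 2.0, 0.05, 0.05, 0.05, 0.05, 0.05, 0.05, 0.05, 0.05, 0.05][:n_par])
    factors = [f for f in (4, 2, 1) if min(fixed.shape) // f >= 8] or [1]
    warning = None
    for level, factor in enumerate(factors):
        mov_l = _pyramid(moving, factor, extra_sigma_vox=0.8)
        fix_l = _pyramid(fixed, factor, extra_sigma_vox=0.8)
        # metric domain: a fixed interior box (about an 8 mm margin), so the
        # evaluation region does not change with the candidate transform —
        # a sliding region would let the optimiser cherry-pick overlap or
        # reward out-of-field extrapolation
        margin = [max(1, int(round(8.0 / h))) for h in fix_l.voxel_size]
        box = tuple(slice(m, max(n - m, m + 1)) for m, n in zip(margin, fix_l.shape))
        fix_data = fix_l.data.astype(float)[box]
        # staged search: only the rigid parameters at the coarsest level
        n_free = 6 if (kind == "affine" and level == 0 and len(factors) > 1) else n_par

        def cost(q):
            full = np.concatenate([q, p[n_free:]]) if q.size < n_par else q
            mat = _params_to_matrix(full, kind, centre)
            warped = _affine_resample_fast(mov_l, mat, fix_l)[box]
            # out-of-field samples (flagged negative) carry no information
            valid = warped >= 0
            n_valid = int(valid.sum())
            if n_valid < 32:
                return 1.0
            return -ncc(warped[valid], fix_data[valid]) * (n_valid / warped.size)

        direc = np.diag(scales[:n_free] / (level + 1))
        res = optimize.minimize(
            cost, p[:n_free], method="Powell",
            options={"maxfev": max_evals[min(level, len(max_evals) - 1)],
                     "xtol": 1e-3, "ftol": 1e-5, "direc": direc},
        )
        if cost(res.x) <= cost(p[:n_free]):
            p = np.concatenate([res.x, p[n_free:]])
        elif level == len(factors) - 1:
            warning = "optimiser failed to improve on initialisation"
    info = {"params": p}
    if warning:
        info["warning"] = warning
    return AffineTransform(_params_to_matrix(p, kind, centre), kind=kind, info=info)


# --------------------------------------------------------------------------
# non-rigid registration
# --------------------------------------------------------------------------

def _sample_at(data: np.ndarray, pts_vox: np.ndarray, mode: str = "constant") -> np.ndarray:
    return ndimage.map_coordinates(data, np.moveaxis(pts_vox, -1, 0), order=1,
                                   mode=mode, cval=0.0)


def _resample_field(u: np.ndarray, target_shape, scale, order: int = 1) -> np.ndarray:
    """Sample a vector field defined on one grid at the voxel centres of
    another.  ``scale[i]`` is the source-grid coordinate advance per target
    voxel (both grids share the world origin of voxel 0), i.e.
    ``h_target[i] / h_source[i]``.  Vector values (mm) are unchanged."""
    out = np.empty(tuple(target_shape) + (3,))
    scale = np.broadcast_to(np.asarray(scale, float), (3,))
    coords = np.meshgrid(
        *[np.arange(t) * sc for t, sc in zip(target_shape, scale)],
        indexing="ij",
    )
    for k in range(3):
        out[..., k] = ndimage.map_coordinates(u[..., k], coords, order=order, mode="nearest")
    return out


def _demons_force(mov_data, fix_data, u, base, h, grad, grad_sq, alpha2,
                  cap_voxels: float = 0.5):
    """One demons force evaluation: (mse, capped force in mm).

    The moving image is sampled with edge extension so the shrinking
    field of view does not manufacture spurious border forces; the final
    pipeline resampling still zero-fills out-of-field voxels.
    """
    warped = _sample_at(mov_data, (base + u) / h, mode="nearest")
    diff = fix_data - warped
    mse = float(np.mean(diff ** 2))
    denom = grad_sq + alpha2 * diff ** 2
    with np.errstate(invalid="ignore", divide="ignore"):
        step = diff[..., None] * grad / denom[..., None]
    step[denom < 1e-12] = 0.0
    mag = np.linalg.norm(step, axis=-1)
    cap = cap_voxels * float(h.min())
    big = mag > cap
    step[big] *= (cap / mag[big])[..., None]
    return mse, step


def _demons(moving: ScalarVolume, fixed: ScalarVolume, iters=(40, 25, 12),
            sigma_fluid: float = 1.0, sigma_diffusion: float = 0.5,
            max_displacement_mm: float = 12.0) -> DisplacementField:
    """Non-parametric demons: SSD force field, Gaussian-regularised (fluid +
    diffusion), iterated over a resolution pyramid."""
    factors = [f for f in (4, 2, 1) if min(fixed.shape) // f >= 8] or [1]
    u = None
    prev_factor = None
    for level, factor in enumerate(factors):
        mov_l, fix_l = _pyramid(moving, factor), _pyramid(fixed, factor)
        h = np.asarray(fix_l.voxel_size)
        shape = fix_l.shape
        if u is None:
            u = np.zeros(shape + (3,))
        else:
            u = _resample_field(u, shape, prev_factor and factor / prev_factor)
        prev_factor = factor
        base = _grid_world(shape, fix_l.voxel_size)
        mov_data = mov_l.data
        fix_data = fix_l.data
        grad = np.stack(np.gradient(fix_data, *h), axis=-1)
        grad_sq = np.sum(grad ** 2, axis=-1)
        alpha2 = 1.0 / float(np.mean(h)) ** 2
        best_u, best_mse = u.copy(), np.inf
        stall = 0
        for _ in range(iters[min(level, len(iters) - 1)]):
            mse, step = _demons_force(mov_data, fix_data, u, base, h, grad, grad_sq, alpha2)
            if mse < best_mse * (1 - 5e-3):
                best_mse, best_u, stall = mse, u.copy(), 0
            else:
                if mse < best_mse:
                    best_mse, best_u = mse, u.copy()
                stall += 1
                if stall >= 2:
                    break
            step = np.stack([ndimage.gaussian_filter(step[..., k], sigma_fluid)
                             for k in range(3)], axis=-1)
            u = u + step
            if sigma_diffusion > 0:
                u = np.stack([ndimage.gaussian_filter(u[..., k], sigma_diffusion)
                              for k in range(3)], axis=-1)
            u = _cap_magnitude(u, max_displacement_mm)
        u = best_u
    return DisplacementField(u, fixed.voxel_size)


def _cap_magnitude(u: np.ndarray, cap_mm: float) -> np.ndarray:
    """Clip per-point displacement norms to a maximum (bounded deformation)."""
    mag = np.linalg.norm(u, axis=-1)
    over = mag > cap_mm
    if over.any():
        u = u.copy()
        u[over] *= (cap_mm / mag[over])[..., None]
    return u


def _ffd(moving: ScalarVolume, fixed: ScalarVolume, control_spacing_vox: int = 4,
         iters=(30, 15), interp_order: int = 1,
         init_coeffs: np.ndarray | None = None,
         max_displacement_mm: float = 12.0,
         sigma_ctrl: float = 0.0) -> DisplacementField:
    """Parametric coarse-control-point registration.

    The displacement model is a coarse control-point grid spline-upsampled
    to the image grid (free-form-deformation style).  Updates are
    demons-like intensity forces restricted (smoothed + sampled) onto the
    control grid, so the deformation never leaves the low-dimensional
    parametric space -- the structural contrast with the non-parametric
    demons path.
    """
    sc = int(control_spacing_vox)
    factors = [f for f in (2, 1) if min(fixed.shape) // f >= 12] or [1]
    c = None
    prev_factor = None
    if init_coeffs is not None:
        # warm start: resume from a previous solution's control grid
        # (defined at full resolution, i.e. factor 1)
        c = init_coeffs.copy()
        prev_factor = 1
    for level, factor in enumerate(factors):
        mov_l, fix_l = _pyramid(moving, factor), _pyramid(fixed, factor)
        h = np.asarray(fix_l.voxel_size)
        shape = fix_l.shape
        ctrl_shape = tuple(int(np.ceil((n - 1) / sc)) + 1 for n in shape)
        if c is None:
            c = np.zeros(ctrl_shape + (3,))
        else:
            # control grids of consecutive levels share the world origin;
            # spacing in world mm halves with the image spacing
            c = _resample_field(c, ctrl_shape, factor / prev_factor)
        prev_factor = factor
        base = _grid_world(shape, fix_l.voxel_size)
        mov_data = mov_l.data
        fix_data = fix_l.data
        grad = np.stack(np.gradient(fix_data, *h), axis=-1)
        grad_sq = np.sum(grad ** 2, axis=-1)
        alpha2 = 1.0 / float(np.mean(h)) ** 2
        ctrl_coords = np.meshgrid(
            *[np.arange(cs) * sc for cs in ctrl_shape], indexing="ij"
        )  # dense-grid positions of the control points
        sigma_aa = sc / 2.0
        best_c, best_mse = c.copy(), np.inf
        stall = 0
        for _ in range(iters[min(level, len(iters) - 1)]):
            u = _resample_field(c, shape, 1.0 / sc, order=interp_order)
            mse, step = _demons_force(mov_data, fix_data, u, base, h, grad, grad_sq, alpha2)
            if mse < best_mse * (1 - 5e-3):
                best_mse, best_c, stall = mse, c.copy(), 0
            else:
                if mse < best_mse:
                    best_mse, best_c = mse, c.copy()
                stall += 1
                if stall >= 2:
                    break
            step_ctrl = np.empty_like(c)
            for k in range(3):
                sm = ndimage.gaussian_filter(step[..., k], sigma_aa)
                step_ctrl[..., k] = ndimage.map_coordinates(sm, ctrl_coords, order=1,
                                                            mode="nearest")
            c = c + step_ctrl
            if sigma_ctrl > 0:
                # diffusion regularisation on the control grid: suppresses
                # high-frequency alternating displacements, which could
                # otherwise fake a blur of the moving image
                c = np.stack([ndimage.gaussian_filter(c[..., k], sigma_ctrl)
                              for k in range(3)], axis=-1)
            c = _cap_magnitude(c, max_displacement_mm)
        c = best_c
    u = _resample_field(c, fixed.shape, 1.0 / sc, order=interp_order)
    out = DisplacementField(u, fixed.voxel_size)
    out.coeffs = c  # control-grid coefficients, for warm-started re-registration
    return out


def register_nonrigid(moving: ScalarVolume, fixed: ScalarVolume,
                      algorithm: str = "pipeline", **opts) -> DisplacementField:
    """Non-rigid registration of ``moving`` to ``fixed`` (pre-aligned linearly).

    ``pipeline``     parametric coarse-control-point model (used in the TBSS
                     registration step);
    ``independent``  non-parametric demons (used for the artificial warps of
                     the specificity evaluation, avoiding a shared
                     deformation model).
    """
    if moving.shape != fixed.shape:
        raise ValueError(f"shape mismatch: {moving.shape} vs {fixed.shape}")
    if algorithm == "pipeline":
        return _ffd(moving, fixed, **opts)
    if algorithm == "independent":
        return _demons(moving, fixed, **opts)
    raise ValueError(f"unknown non-rigid algorithm {algorithm!r}")


# --------------------------------------------------------------------------
# kernel-width selection
# --------------------------------------------------------------------------

def select_kernel_width(originals, warped_back, candidate_sigmas_mm=(0.5, 1.0, 1.5, 2.0)):
    """Pick the Gaussian width (mm) matching interpolation-induced smoothing.

    Each original is smoothed at every candidate sigma and compared (RMSE)
    with its inverse-warped counterpart; the sigma minimising the average
    RMSE wins, ties toward the smaller sigma.
    """
    candidates = sorted(float(s) for s in candidate_sigmas_mm)
    if not candidates:
        raise ValueError("candidate sigma set is empty")
    if len(originals) != len(warped_back):
        raise ValueError("originals and warped_back lists differ in length")
    table = []
    for sig in candidates:
        errs = [rmse(gaussian_smooth(o, sig).data, w.data)
                for o, w in zip(originals, warped_back)]
        table.append(float(np.mean(errs)))
    return candidates[int(np.argmin(table))]
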