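"""Mean-FA construction, white-matter skeletonisation and the TBSS
perpendicular-maximum projection step.

The skeleton is the set of tract-centre voxels of the mean FA map: voxels
above the FA threshold that are local maxima of (smoothed) mean FA along
the tract-perpendicular direction(s) estimated from the local Hessian.
Projection then searches, per skeleton voxel and per subject, along the
perpendicular direction — or over the perpendicular disc where the local
geometry is tube-like rather than sheet-like — for the subject's highest
FA, bounded by the search radius and by a nearest-skeleton-voxel partition
so neighbouring skeleton voxels never claim the same off-skeleton maximum.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .core import ScalarVolume

__all__ = ["Skeleton", "ProjectedMatrix", "mean_fa", "skeletonize", "project", "project_cohort"]

DEFAULT_FA_THRESHOLD = 0.2
DEFAULT_MAX_SEARCH_MM = 8.0


@dataclass
class Skeleton:
    """Centre-of-tract voxels of a mean FA map plus per-voxel search geometry.

    ``direction`` is the unit tract-perpendicular direction (Hessian
    eigenvector of most negative curvature); ``direction2`` spans the rest
    of the perpendicular plane and ``tubeness`` flags voxels whose two
    perpendicular curvatures are comparable (tube-like), where projection
    searches the full perpendicular disc.
    """

    mask: np.ndarray                  # boolean volume
    coords: np.ndarray                # (N, 3) voxel indices of skeleton voxels
    direction: np.ndarray             # (N, 3) unit vectors, world (mm) axes
    direction2: np.ndarray            # (N, 3) unit vectors, world (mm) axes
    tubeness: np.ndarray              # (N,) bool
    fa_threshold: float
    voxel_size: tuple[float, float, float]
    mean_fa: np.ndarray | None = None
    _partition: np.ndarray | None = field(default=None, repr=False)
    _distances: np.ndarray | None = field(default=None, repr=False)
    _adjacency: tuple | None = field(default=None, repr=False)

    @property
    def n_voxels(self) -> int:
        return int(self.coords.shape[0])

    def partition(self) -> np.ndarray:
        """Volume of nearest-skeleton-voxel ids (index into ``coords``)."""
        if self._partition is None:
            ids = np.full(self.mask.shape, -1, dtype=np.int64)
            ids[tuple(self.coords.T)] = np.arange(self.n_voxels)
            idx = ndimage.distance_transform_edt(
                ~self.mask, sampling=self.voxel_size, return_distances=False,
                return_indices=True)
            self._partition = ids[tuple(idx)]
        return self._partition

    def distances(self) -> np.ndarray:
        """Volume of distances (mm) to the nearest skeleton voxel."""
        if self._distances is None:
            self._distances = ndimage.distance_transform_edt(
                ~self.mask, sampling=self.voxel_size)
        return self._distances

    def adjacency(self):
        """26-connectivity pairs (i, j) between skeleton voxels, both orders."""
        if self._adjacency is None:
            ids = np.full(self.mask.shape, -1, dtype=np.int64)
            ids[tuple(self.coords.T)] = np.arange(self.n_voxels)
            pairs_i, pairs_j = [], []
            for di in (-1, 0, 1):
                for dj in (-1, 0, 1):
                    for dk in (-1, 0, 1):
                        if di == dj == dk == 0:
                            continue
                        shifted = np.roll(ids, (di, dj, dk), axis=(0, 1, 2))
                        # forbid wrap-around contributions
                        sl = [slice(None)] * 3
                        for ax, d in enumerate((di, dj, dk)):
                            if d == 1:
                                sl2 = list(sl); sl2[ax] = 0
                                shifted[tuple(sl2)] = -1
                            elif d == -1:
                                sl2 = list(sl); sl2[ax] = -1
                                shifted[tuple(sl2)] = -1
                        both = (ids >= 0) & (shifted >= 0)
                        pairs_i.append(ids[both])
                        pairs_j.append(shifted[both])
            self._adjacency = (np.concatenate(pairs_i), np.concatenate(pairs_j))
        return self._adjacency


@dataclass
class ProjectedMatrix:
    """Subjects x skeleton-voxels table of projected FA."""

    values: np.ndarray          # (n_subjects, n_skeleton_voxels)
    skeleton_ref: Skeleton
    subject_ids: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be 2D (subjects x skeleton voxels)")
        if self.values.shape[1] != self.skeleton_ref.n_voxels:
            raise ValueError("column count must equal skeleton voxel count")


def mean_fa(volumes) -> ScalarVolume:
    """Voxel-wise arithmetic mean of aligned FA images on one grid.

    Voxels where any subject carries no data (FA = 0, e.g. mapped from
    outside that subject's field of view) are set to zero: group analysis
    is only meaningful where every subject contributes.
    """
    vols = list(getattr(volumes, "aligned_fa", volumes))
    if len(vols) < 2:
        raise ValueError("need at least 2 aligned subjects")
    first = vols[0]
    for v in vols[1:]:
        if not first.same_grid(v):
            raise ValueError("aligned volumes are not on a common grid")
    stack = np.stack([v.data for v in vols])
    mean = stack.mean(axis=0)
    mean[~np.all(stack > 0, axis=0)] = 0.0
    return first.like(mean)


def _hessian_eig(data: np.ndarray, voxel_size, sigma_vox: float = 1.0):
    """Eigen-decomposition of the smoothed-FA Hessian at every voxel.

    Returns (smoothed, eigenvalues ascending (X,Y,Z,3), eigenvectors
    (X,Y,Z,3,3) with [..., :, j] the j-th eigenvector, world-mm axes).
    """
    h = np.asarray(voxel_size)
    sm = ndimage.gaussian_filter(data.astype(float), sigma_vox)
    hess = np.empty(data.shape + (3, 3))
    for i in range(3):
        for j in range(i, 3):
            order = [0, 0, 0]
            order[i] += 1
            order[j] += 1
            d = ndimage.gaussian_filter(sm, 0.5, order=order)
            d /= h[i] * h[j]
            hess[..., i, j] = d
            hess[..., j, i] = d
    vals, vecs = np.linalg.eigh(hess)
    return sm, vals, vecs


def skeletonize(mean_fa_volume: ScalarVolume, fa_threshold: float = DEFAULT_FA_THRESHOLD,
                tube_ratio: float = 0.5) -> Skeleton:
    """Extract the tract-centre skeleton of a mean FA map.

    A voxel joins the skeleton when its mean FA exceeds ``fa_threshold``
    and the smoothed FA is a local maximum along the perpendicular
    direction(s): the Hessian eigenvector of most negative curvature, and
    additionally the second perpendicular axis where the structure is
    tube-like (second curvature within ``tube_ratio`` of the first), which
    keeps a curved tube's skeleton a line rather than a surface.
    """
    data = np.asarray(mean_fa_volume.data, dtype=float)
    h = np.asarray(mean_fa_volume.voxel_size)
    above = data > fa_threshold
    if not above.any():
        warnings.warn("no voxels above the FA threshold; skeleton is empty")
        return Skeleton(np.zeros_like(above), np.empty((0, 3), int), np.empty((0, 3)),
                        np.empty((0, 3)), np.empty(0, bool), fa_threshold,
                        mean_fa_volume.voxel_size, mean_fa=data)

    sm, vals, vecs = _hessian_eig(data, h)
    cand = np.argwhere(above)
    lam = vals[tuple(cand.T)]          # (M, 3) ascending
    vec = vecs[tuple(cand.T)]          # (M, 3, 3)
    # the tract tangent is the axis of least absolute curvature; the other
    # two eigenvectors span the perpendicular cross-section
    tangent_idx = np.argmin(np.abs(lam), axis=1)
    m = lam.shape[0]
    perp_idx = np.argsort(np.abs(lam), axis=1)[:, 1:]  # two largest |curvature|
    lam_perp = np.take_along_axis(lam, perp_idx, axis=1)
    order = np.argsort(lam_perp, axis=1)               # more negative first
    perp_idx = np.take_along_axis(perp_idx, order, axis=1)
    rows = np.arange(m)
    e0 = vec[rows, :, perp_idx[:, 0]]
    e1 = vec[rows, :, perp_idx[:, 1]]
    lam0 = lam[rows, perp_idx[:, 0]]
    lam1 = lam[rows, perp_idx[:, 1]]
    tube = (lam0 < 0) & (lam1 <= tube_ratio * lam0)    # both strongly negative

    # sample smoothed FA one voxel ahead/behind along each perpendicular axis;
    # ties (flat directions, e.g. along a sheet) keep the voxel
    step_mm = float(h.min())
    centre_vox = cand.astype(float)
    # the max test runs on the raw mean FA (the smoothed field only supplies
    # directions): smoothing across a stair-stepped discrete ridge would
    # displace the maximum by up to a voxel
    val_c = data[tuple(cand.T)]

    def _along(dirs):
        out = []
        for sgn in (+1.0, -1.0):
            pts = centre_vox + sgn * step_mm * dirs / h
            out.append(ndimage.map_coordinates(data, pts.T, order=1, mode="nearest"))
        return out

    # near-tie tolerance: where the continuous ridge runs between voxel
    # centres, the two straddling voxels differ by a fraction of a percent
    # of FA; both belong on the (then locally 2-voxel) skeleton
    tol = 2e-3
    keep = np.ones(m, dtype=bool)
    for e in (e0, e1):
        fp, fm = _along(e)
        keep &= (val_c + tol >= fp) & (val_c + tol >= fm)

    # a ridge point must also not climb along the local gradient — this
    # removes off-centre caps (e.g. outside a bend) where all curvatures
    # are negative but FA still increases towards the tract centre
    grads = np.stack(np.gradient(data, *h), axis=-1)[tuple(cand.T)]
    gn = np.linalg.norm(grads, axis=1)
    sig = gn > 1e-6
    eg = np.zeros_like(grads)
    eg[sig] = grads[sig] / gn[sig, None]
    fp, fm = _along(eg)
    tol_g = 1e-4
    keep &= ~sig | ((val_c + tol_g >= fp) & (val_c + tol_g >= fm))

    coords = cand[keep]
    mask = np.zeros_like(above)
    mask[tuple(coords.T)] = True
    return Skeleton(mask, coords, e0[keep], e1[keep], tube[keep],
                    fa_threshold, mean_fa_volume.voxel_size, mean_fa=data)


def project(subject_fa: ScalarVolume, skeleton: Skeleton,
            max_search_mm: float = DEFAULT_MAX_SEARCH_MM) -> np.ndarray:
    """Project one subject's FA onto the skeleton (one row of the matrix).

    Each skeleton voxel records the maximum subject FA over the integer
    voxels of its search region: the voxels whose nearest skeleton voxel it
    is (for a tube skeleton these cells are the perpendicular slabs, for a
    sheet the across-sheet columns), within ``max_search_mm`` of the
    skeleton.  Cells of 26-adjacent skeleton voxels are merged into the
    search, because a discretised oblique ridge rasterises to staircase
    corners whose cells would otherwise wall off the search exactly where
    the tract went.  Values are read at voxel centres (no interpolation),
    so a subject's true local maximum is recovered exactly.
    """
    if subject_fa.data.shape != skeleton.mask.shape:
        raise ValueError("subject is not on the skeleton grid")
    if skeleton.n_voxels == 0:
        return np.empty(0)
    part = skeleton.partition()
    dist = skeleton.distances()
    eligible = dist <= max_search_mm + 1e-9
    cellmax = np.full(skeleton.n_voxels, -np.inf)
    np.maximum.at(cellmax, part[eligible], subject_fa.data[eligible].astype(float))
    # own voxel is always in its own cell (distance 0), so cellmax is finite
    out = cellmax.copy()
    if max_search_mm > 0:
        ai, aj = skeleton.adjacency()
        if ai.size:
            np.maximum.at(out, ai, cellmax[aj])
    return out


def project_cohort(volumes, skeleton: Skeleton,
                   max_search_mm: float = DEFAULT_MAX_SEARCH_MM,
                   subject_ids=None) -> ProjectedMatrix:
    """Project every subject of an aligned cohort onto the skeleton."""
    vols = list(getattr(volumes, "aligned_fa", volumes))
    rows = np.stack([project(v, skeleton, max_search_mm) for v in vols])
    if subject_ids is None:
        subject_ids = [f"sub-{i:03d}" for i in range(len(vols))]
    return ProjectedMatrix(rows, skeleton, list(subject_ids))
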