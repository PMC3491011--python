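"""Voxel-wise inference on skeleton-projected FA.

Per skeleton voxel a general linear model (intercept + group + optional
nuisance covariates) yields the group-contrast t statistic; maps are
enhanced with threshold-free cluster enhancement (TFCE) restricted to the
skeleton, and family-wise error is controlled by the permutation
distribution of the maximum enhanced statistic.  With covariates the
default permutation scheme is Freedman–Lane (permute nuisance-model
residuals); plain label permutation is available behind a flag.  When the
group sizes admit fewer distinct relabelings than requested, the
permutation test switches to exact enumeration.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from itertools import combinations

import numpy as np

from .skeleton import ProjectedMatrix, Skeleton

try:
    from numba import njit
    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover - numba is a hard dependency in practice
    _HAVE_NUMBA = False

logger = logging.getLogger(__name__)

__all__ = ["DesignInfo", "StatResult", "tstat_map", "tfce", "permutation_fwe"]

TFCE_E = 0.5
TFCE_H = 2.0


@dataclass
class DesignInfo:
    """Group labels, optional nuisance covariates, and the tested direction.

    ``contrast='greater'`` tests group-1 mean > group-0 mean (after
    adjusting for covariates); ``'less'`` the opposite.
    """

    group: np.ndarray
    covariates: np.ndarray | None = None
    contrast: str = "less"

    def __post_init__(self) -> None:
        self.group = np.asarray(self.group)
        uniq = np.unique(self.group)
        if uniq.size != 2:
            raise ValueError("group must carry exactly two distinct labels")
        self.group = (self.group == uniq[1]).astype(float)
        if self.group.sum() == 0 or self.group.sum() == self.group.size:
            raise ValueError("both groups must be non-empty")
        if self.covariates is not None:
            self.covariates = np.atleast_2d(np.asarray(self.covariates, float))
            if self.covariates.shape[0] != self.group.size:
                self.covariates = self.covariates.T
            if self.covariates.shape[0] != self.group.size:
                raise ValueError("covariate rows must match subjects")
        if self.contrast not in ("greater", "less"):
            raise ValueError("contrast must be 'greater' or 'less'")

    @property
    def n(self) -> int:
        return int(self.group.size)

    def matrix(self, group: np.ndarray | None = None) -> np.ndarray:
        g = self.group if group is None else group
        cols = [np.ones(self.n), g]
        if self.covariates is not None:
            cols.extend(self.covariates.T)
        X = np.column_stack(cols)
        if np.linalg.matrix_rank(X) < X.shape[1]:
            # identify the offending column for the error message
            for j in range(2, X.shape[1]):
                if np.linalg.matrix_rank(np.delete(X, j, axis=1)) == np.linalg.matrix_rank(X):
                    raise ValueError(f"design is rank deficient: covariate column {j - 2}")
            raise ValueError("design is rank deficient: group column is confounded")
        return X


def _glm_t(Y: np.ndarray, X: np.ndarray) -> np.ndarray:
    """Group-coefficient t statistic per column of Y (voxels)."""
    n, p = X.shape
    XtX_inv = np.linalg.inv(X.T @ X)
    beta = XtX_inv @ X.T @ Y                     # (p, V)
    resid = Y - X @ beta
    dof = n - p
    sigma2 = np.einsum("iv,iv->v", resid, resid) / dof
    se = np.sqrt(np.maximum(sigma2 * XtX_inv[1, 1], 0.0))
    with np.errstate(invalid="ignore", divide="ignore"):
        t = beta[1] / se
    # voxels with (numerically) zero residual variance carry no evidence
    degenerate = sigma2 <= 1e-24 * float(np.mean(Y * Y) + 1e-300)
    t[degenerate | (se == 0)] = 0.0
    return t


def tstat_map(matrix: ProjectedMatrix, design: DesignInfo) -> np.ndarray:
    """Per-skeleton-voxel group-contrast t statistic (positive = group 1
    larger, after covariate adjustment)."""
    Y = matrix.values
    if Y.shape[0] != design.n:
        raise ValueError("subjects in matrix and design differ")
    return _glm_t(Y, design.matrix())


# --------------------------------------------------------------------------
# TFCE
# --------------------------------------------------------------------------

def _skeleton_edges(skeleton) -> tuple[np.ndarray, np.ndarray]:
    if isinstance(skeleton, Skeleton):
        ai, aj = skeleton.adjacency()
        keep = ai < aj
        return ai[keep], aj[keep]
    # boolean mask: build 26-connectivity pairs among True voxels
    mask = np.asarray(skeleton, bool)
    ids = np.full(mask.shape, -1, dtype=np.int64)
    coords = np.argwhere(mask)
    ids[tuple(coords.T)] = np.arange(coords.shape[0])
    pi, pj = [], []
    offsets = [(di, dj, dk) for di in (-1, 0, 1) for dj in (-1, 0, 1)
               for dk in (-1, 0, 1)][: 13]  # half of the 26 neighbourhood
    for off in offsets:
        src = [slice(max(-o, 0), mask.shape[ax] - max(o, 0)) for ax, o in enumerate(off)]
        dst = [slice(max(o, 0), mask.shape[ax] - max(-o, 0)) for ax, o in enumerate(off)]
        a = ids[tuple(src)]
        b = ids[tuple(dst)]
        both = (a >= 0) & (b >= 0)
        pi.append(a[both])
        pj.append(b[both])
    return np.concatenate(pi), np.concatenate(pj)


if _HAVE_NUMBA:
    @njit(cache=True)
    def _tfce_core(stat, order, edge_i, edge_j, edge_minstat, edge_order,
                   thresholds, E, H, dh):  # pragma: no cover - jitted
        n = stat.shape[0]
        parent = np.full(n, -1, dtype=np.int64)
        size = np.ones(n, dtype=np.int64)
        active = np.zeros(n, dtype=np.bool_)
        out = np.zeros(n)
        iv = 0
        ie = 0
        m = order.shape[0]
        me = edge_order.shape[0]
        for ti in range(thresholds.shape[0] - 1, -1, -1):
            h = thresholds[ti]
            while iv < m and stat[order[iv]] >= h:
                active[order[iv]] = True
                iv += 1
            while ie < me and edge_minstat[edge_order[ie]] >= h:
                e = edge_order[ie]
                a, b = edge_i[e], edge_j[e]
                ra = a
                while parent[ra] >= 0:
                    ra = parent[ra]
                rb = b
                while parent[rb] >= 0:
                    rb = parent[rb]
                if ra != rb:
                    if size[ra] < size[rb]:
                        ra, rb = rb, ra
                    parent[rb] = ra
                    size[ra] += size[rb]
                # path compression
                while parent[a] >= 0:
                    nxt = parent[a]
                    parent[a] = ra
                    a = nxt
                while parent[b] >= 0:
                    nxt = parent[b]
                    parent[b] = ra
                    b = nxt
                ie += 1
            inc = h ** H * dh
            for k in range(iv):
                v = order[k]
                r = v
                while parent[r] >= 0:
                    r = parent[r]
                out[v] += size[r] ** E * inc
        return out


def _tfce_python(stat, edges, thresholds, E, H, dh):
    """Plain-python fallback: per-threshold connected components."""
    n = stat.shape[0]
    out = np.zeros(n)
    ei, ej = edges
    for h in thresholds:
        sup = stat >= h
        # union-find over supra-threshold voxels
        parent = np.arange(n)

        def find(x):
            while parent[x] != x:
                parent[x] = parent[parent[x]]
                x = parent[x]
            return x

        for a, b in zip(ei, ej):
            if sup[a] and sup[b]:
                ra, rb = find(a), find(b)
                if ra != rb:
                    parent[rb] = ra
        roots = np.array([find(v) if sup[v] else -1 for v in range(n)])
        counts = {}
        for r in roots:
            if r >= 0:
                counts[r] = counts.get(r, 0) + 1
        for v in range(n):
            if sup[v]:
                out[v] += counts[roots[v]] ** E * h ** H * dh
    return out


def tfce(stat_values: np.ndarray, skeleton, E: float = TFCE_E, H: float = TFCE_H,
         dh: float | None = None, _edges=None) -> np.ndarray:
    """Threshold-free cluster enhancement on skeleton voxels (one-sided).

    ``enh(p) = sum over h = dh, 2dh, ... <= max(stat) of e(h, p)^E h^H dh``
    where ``e(h, p)`` is the voxel count of the connected component of the
    supra-threshold set {stat >= h} containing p, with 26-connectivity
    restricted to the skeleton.  Negative input values contribute nothing.
    """
    stat = np.maximum(np.asarray(stat_values, dtype=float), 0.0)
    if E <= 0 or H <= 0:
        raise ValueError("E and H must be positive")
    if dh is not None and dh <= 0:
        raise ValueError("dh must be positive")
    smax = float(stat.max()) if stat.size else 0.0
    if smax <= 0:
        return np.zeros_like(stat)
    if dh is None:
        dh = smax / 100.0
    thresholds = np.arange(dh, smax + 1e-12, dh)
    if thresholds.size == 0:
        return np.zeros_like(stat)
    edges = _edges if _edges is not None else _skeleton_edges(skeleton)
    ei, ej = edges
    if not _HAVE_NUMBA:
        return _tfce_python(stat, edges, thresholds, E, H, dh)
    order = np.argsort(-stat, kind="stable")
    if ei.size:
        edge_minstat = np.minimum(stat[ei], stat[ej])
        edge_order = np.argsort(-edge_minstat, kind="stable")
    else:
        edge_minstat = np.empty(0)
        edge_order = np.empty(0, dtype=np.int64)
    return _tfce_core(stat, order, ei.astype(np.int64), ej.astype(np.int64),
                      edge_minstat, edge_order, thresholds, E, H, float(dh))


# --------------------------------------------------------------------------
# permutation FWE
# --------------------------------------------------------------------------

@dataclass
class StatResult:
    """Skeleton-wise inference result."""

    tstat: np.ndarray          # signed group-coefficient t per skeleton voxel
    tfce: np.ndarray           # enhanced directed statistic
    p_fwe: np.ndarray          # FWE-corrected p per skeleton voxel
    n_permutations: int
    seed: int | None
    exact: bool = False
    max_distribution: np.ndarray | None = None

    def significant(self, alpha: float = 0.05) -> np.ndarray:
        return self.p_fwe < alpha


def _directed(t: np.ndarray, contrast: str) -> np.ndarray:
    return t if contrast == "greater" else -t


def permutation_fwe(matrix: ProjectedMatrix, design: DesignInfo,
                    n_permutations: int = 5000, seed: int = 0,
                    alpha: float = 0.05, scheme: str = "freedman-lane",
                    E: float = TFCE_E, H: float = TFCE_H,
                    dh: float | None = None) -> StatResult:
    """Max-TFCE permutation test with FWE-corrected p-values.

    Random permutations use the add-one estimator
    ``p = (1 + #{perm max >= obs}) / (n_permutations + 1)``; when the
    number of distinct group relabelings is at most ``n_permutations`` the
    test enumerates all of them exactly (identity included).
    """
    if n_permutations < 1:
        raise ValueError("n_permutations must be >= 1")
    if scheme not in ("freedman-lane", "labels"):
        raise ValueError("scheme must be 'freedman-lane' or 'labels'")
    Y = matrix.values
    X = design.matrix()
    edges = _skeleton_edges(matrix.skeleton_ref)
    t_obs = _glm_t(Y, X)
    stat_obs = _directed(t_obs, design.contrast)
    # dh fixed from the observed map so permuted maps see identical thresholds
    smax = float(np.maximum(stat_obs, 0).max(initial=0.0))
    dh_eff = dh if dh is not None else (smax / 100.0 if smax > 0 else None)
    enh_obs = (tfce(stat_obs, matrix.skeleton_ref, E, H, dh_eff, _edges=edges)
               if dh_eff else np.zeros_like(stat_obs))

    n = design.n
    n1 = int(design.group.sum())
    n_distinct = math.comb(n, n1)
    exact = n_distinct <= n_permutations
    if exact:
        logger.info("exact enumeration over %d relabelings", n_distinct)
        groups = np.zeros((n_distinct, n))
        for r, idx in enumerate(combinations(range(n), n1)):
            groups[r, list(idx)] = 1.0
        perm_iter = ("relabel", groups)
    else:
        rng = np.random.default_rng(seed)
        perm_iter = ("permute", [rng.permutation(n) for _ in range(n_permutations)])

    # Freedman-Lane: permute residuals of the nuisance-only model
    if design.covariates is not None and scheme == "freedman-lane":
        Z = np.column_stack([np.ones(n)] + list(design.covariates.T))
    else:
        Z = np.ones((n, 1))
    gamma = np.linalg.lstsq(Z, Y, rcond=None)[0]
    fitted = Z @ gamma
    resid = Y - fitted

    kind, items = perm_iter
    maxes = np.empty(len(items))
    for r, item in enumerate(items):
        if kind == "relabel":
            tp = _glm_t(Y, design.matrix(group=item))
        elif scheme == "labels":
            tp = _glm_t(Y, design.matrix(group=design.group[item]))
        else:
            Yp = fitted + resid[item]
            tp = _glm_t(Yp, X)
        sp = _directed(tp, design.contrast)
        if dh_eff:
            ep = tfce(sp, matrix.skeleton_ref, E, H, dh_eff, _edges=edges)
            maxes[r] = ep.max(initial=0.0)
        else:
            maxes[r] = 0.0

    if exact:
        exceed = (maxes[None, :] >= enh_obs[:, None] - 1e-12).sum(axis=1)
        p = exceed / n_distinct
    else:
        exceed = (maxes[None, :] >= enh_obs[:, None] - 1e-12).sum(axis=1)
        p = (1.0 + exceed) / (len(items) + 1.0)
    return StatResult(tstat=t_obs, tfce=np.where(stat_obs > 0, enh_obs, 0.0),
                      p_fwe=p, n_permutations=len(items), seed=seed, exact=exact,
                      max_distribution=maxes)
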