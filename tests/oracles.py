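"""Independent brute-force reference implementations used only in tests."""

import numpy as np


def tfce_brute_force(stat, edges, E=0.5, H=2.0, dh=0.1):
    """Threshold sweep with per-threshold connected components found by BFS.

    ``edges`` is an iterable of (i, j) index pairs on the flat stat array.
    """
    stat = np.maximum(np.asarray(stat, float), 0.0)
    n = stat.size
    out = np.zeros(n)
    smax = stat.max() if n else 0.0
    if smax <= 0:
        return out
    adj = {i: [] for i in range(n)}
    for a, b in edges:
        adj[a].append(b)
        adj[b].append(a)
    h = dh
    while h <= smax + 1e-12:
        sup = stat >= h
        seen = np.zeros(n, bool)
        for s0 in range(n):
            if sup[s0] and not seen[s0]:
                comp, queue = [s0], [s0]
                seen[s0] = True
                while queue:
                    x = queue.pop()
                    for y in adj[x]:
                        if sup[y] and not seen[y]:
                            seen[y] = True
                            comp.append(y)
                            queue.append(y)
                for c in comp:
                    out[c] += len(comp) ** E * h ** H * dh
        h += dh
    return out


def line_skeleton(n):
    """A 1D chain of n skeleton voxels embedded in a 3D mask, with edges."""
    mask = np.zeros((n + 2, 3, 3), bool)
    mask[1:n + 1, 1, 1] = True
    edges = [(i, i + 1) for i in range(n - 1)]
    return mask, edges


def grid_skeleton(shape2d, rng):
    """A random 2D patch skeleton (8-connected) embedded in 3D."""
    nx, ny = shape2d
    keep = rng.random((nx, ny)) > 0.3
    mask = np.zeros((nx + 2, ny + 2, 3), bool)
    mask[1:nx + 1, 1:ny + 1, 1] = keep
    coords = np.argwhere(mask)
    index = {tuple(c): i for i, c in enumerate(coords)}
    edges = []
    for (x, y, z), i in index.items():
        for dx in (-1, 0, 1):
            for dy in (-1, 0, 1):
                for dz in (-1, 0, 1):
                    if (dx, dy, dz) == (0, 0, 0):
                        continue
                    j = index.get((x + dx, y + dy, z + dz))
                    if j is not None and j > i:
                        edges.append((i, j))
    return mask, coords, edges
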