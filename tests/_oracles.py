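"""Independent oracles used by the test suite.

Each oracle reimplements a result through a different route than the
library (enumeration, closed form, alternative algorithm) so agreement is
meaningful.
"""

from __future__ import annotations

from functools import lru_cache

import numpy as np


def brute_force_global_score(a: tuple, b: tuple, substitution,
                             gap_penalty: float) -> float:
    """Optimal global alignment score by plain recursion over the three
    moves (no DP table shared with the implementation)."""

    @lru_cache(maxsize=None)
    def rec(i: int, j: int) -> float:
        if i == len(a) and j == len(b):
            return 0.0
        best = -float("inf")
        if i < len(a) and j < len(b):
            best = max(best, substitution(a[i], b[j]) + rec(i + 1, j + 1))
        if i < len(a):
            best = max(best, -gap_penalty + rec(i + 1, j))
        if j < len(b):
            best = max(best, -gap_penalty + rec(i, j + 1))
        return best

    return rec(0, 0)


def quaternion_rmsd(a: np.ndarray, b: np.ndarray) -> float:
    """Optimal superposition RMSD via the quaternion eigenvalue method
    (Horn): largest eigenvalue of the 4x4 key matrix built from the
    cross-covariance, entirely independent of the SVD route."""
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    ac = a - a.mean(axis=0)
    bc = b - b.mean(axis=0)
    m = bc.T @ ac
    sxx, sxy, sxz = m[0]
    syx, syy, syz = m[1]
    szx, szy, szz = m[2]
    key = np.array([
        [sxx + syy + szz, syz - szy, szx - sxz, sxy - syx],
        [syz - szy, sxx - syy - szz, sxy + syx, szx + sxz],
        [szx - sxz, sxy + syx, -sxx + syy - szz, syz + szy],
        [sxy - syx, szx + sxz, syz + szy, -sxx - syy + szz],
    ])
    lam = np.linalg.eigvalsh(key).max()
    n = a.shape[0]
    e0 = (ac ** 2).sum() + (bc ** 2).sum()
    return float(np.sqrt(max(e0 - 2.0 * lam, 0.0) / n))


def random_additive_tree(rng: np.random.Generator, n_taxa: int):
    """A random binary tree with positive branch lengths and its exact
    leaf-to-leaf path-length matrix.

    Returns (ids, distance matrix).  Distances are additive by
    construction, so neighbor-joining must recover them exactly.
    """
    ids = [f"T{i:02d}" for i in range(n_taxa)]
    # leaf-to-leaf distances via random agglomeration: maintain, for each
    # active cluster, the distance from every contained leaf to the
    # cluster root
    dist = np.zeros((n_taxa, n_taxa))
    clusters: list[tuple[list[int], dict[int, float]]] = [
        ([i], {i: 0.0}) for i in range(n_taxa)
    ]
    while len(clusters) > 1:
        i, j = sorted(rng.choice(len(clusters), size=2, replace=False))
        (la, da), (lb, db) = clusters[i], clusters[j]
        ea = rng.uniform(0.05, 1.0)
        eb = rng.uniform(0.05, 1.0)
        for x in la:
            for y in lb:
                dist[x, y] = dist[y, x] = da[x] + ea + eb + db[y]
        merged = (la + lb,
                  {**{x: da[x] + ea for x in la},
                   **{y: db[y] + eb for y in lb}})
        clusters = [c for k, c in enumerate(clusters) if k not in (i, j)]
        clusters.append(merged)
    return ids, dist


def grid_isoelectric_point(charge_fn, n_points: int = 14000) -> float:
    """pI by dense grid scan of the charge function on (0, 14)."""
    grid = np.linspace(1e-6, 14 - 1e-6, n_points)
    values = np.array([charge_fn(ph) for ph in grid])
    return float(grid[np.argmin(np.abs(values))])
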