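"""Independent oracles used only by the test suite.

Each routine here is deliberately implemented along a different path from the
package code it checks: a quaternion (Horn) eigen-solver instead of Kabsch
SVD, a projection-formula dihedral, naive python-loop Boltzmann summation,
level-sweep basin flooding, and an exhaustive neighbour-count clustering
loop.
"""

import math

import numpy as np


def quaternion_rmsd(mobile: np.ndarray, reference: np.ndarray) -> float:
    """Minimum RMSD over rigid transforms via Horn's quaternion method."""
    x = mobile - mobile.mean(axis=0)
    y = reference - reference.mean(axis=0)
    s = x.T @ y
    sxx, sxy, sxz = s[0]
    syx, syy, syz = s[1]
    szx, szy, szz = s[2]
    k = np.array(
        [
            [sxx + syy + szz, syz - szy, szx - sxz, sxy - syx],
            [syz - szy, sxx - syy - szz, sxy + syx, szx + sxz],
            [szx - sxz, sxy + syx, -sxx + syy - szz, syz + szy],
            [sxy - syx, szx + sxz, syz + szy, -sxx - syy + szz],
        ]
    )
    lam = np.linalg.eigvalsh(k).max()
    msd = max(0.0, ((x**2).sum() + (y**2).sum() - 2.0 * lam) / len(x))
    return math.sqrt(msd)


def projection_dihedral(p0, p1, p2, p3) -> float:
    """Dihedral via the projection ('praxeolitic') formulation."""
    p0, p1, p2, p3 = map(np.asarray, (p0, p1, p2, p3))
    b0 = p0 - p1
    b1 = p2 - p1
    b2 = p3 - p2
    b1 = b1 / np.linalg.norm(b1)
    v = b0 - (b0 @ b1) * b1
    w = b2 - (b2 @ b1) * b1
    x = v @ w
    y = np.cross(b1, v) @ w
    return math.atan2(y, x)


def naive_marginal(values: np.ndarray, dy: float, kbt: float, axis: int) -> np.ndarray:
    """−kbt·ln Σ exp(−F/kbt)·dy by direct high-precision summation."""
    values = np.asarray(values, dtype=float)
    if axis == 0:
        values = values.T
    out = []
    for row in values:
        total = math.fsum(math.exp(-v / kbt) * dy for v in row)
        out.append(-kbt * math.log(total))
    return np.array(out)


def flood_minima(f: np.ndarray, min_depth: float):
    """Interior local minima with persistence ≥ min_depth, by brute force.

    For every interior strict-with-plateau local minimum, scan outward in
    both directions for the first strictly lower value, tracking the running
    maximum; the basin depth is the lower of the two pass heights minus the
    minimum (inf if no lower value exists on a side).
    """
    n = len(f)
    minima = []
    i = 1
    while i < n - 1:
        if f[i] < f[i - 1]:
            j = i
            while j + 1 < n and f[j + 1] == f[i]:
                j += 1
            if j < n - 1 and f[j + 1] > f[i]:
                minima.append(i)
            i = j + 1
        else:
            i += 1
    kept = []
    for i in minima:
        depths = []
        for step in (-1, 1):
            peak = -math.inf
            depth = math.inf
            j = i + step
            while 0 <= j < n:
                peak = max(peak, f[j])
                if f[j] < f[i]:
                    depth = peak - f[i]
                    break
                j += step
            depths.append(depth)
        if min(depths) >= min_depth:
            kept.append(i)
    barriers = [
        float(max(f[a : b + 1])) for a, b in zip(kept[:-1], kept[1:])
    ]
    return kept, barriers


def exhaustive_clusters(frames, sel_indices, cutoff):
    """Leader clustering with neighbour counts recomputed exhaustively.

    Uses the quaternion RMSD oracle for the pairwise distances so the whole
    path is independent of the package's Kabsch code.
    """
    n = len(frames)
    neigh = [
        [
            j
            for j in range(n)
            if quaternion_rmsd(frames[i][sel_indices], frames[j][sel_indices]) <= cutoff
        ]
        for i in range(n)
    ]
    alive = set(range(n))
    clusters = []
    while alive:
        best, best_count = None, -1
        for i in sorted(alive):
            count = sum(1 for j in neigh[i] if j in alive)
            if count > best_count:
                best, best_count = i, count
        members = sorted(j for j in neigh[best] if j in alive)
        clusters.append((best, members))
        alive -= set(members)
    return clusters
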