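"""Independent reference implementations used as oracles in the tests.

These deliberately avoid the production code paths: the clustering oracle
is a straight-line loop over explicit per-pair superpositions, and the
RMSD oracle minimises over rotations numerically (random-restart
quaternion search with local refinement) instead of using the SVD
identity.
"""

from __future__ import annotations

import numpy as np
from scipy.optimize import minimize
from scipy.spatial.transform import Rotation


def naive_kabsch_rmsd(X: np.ndarray, Y: np.ndarray) -> float:
    """Production-independent minimised RMSD via explicit SVD on one pair."""
    xc = X - X.mean(axis=0)
    yc = Y - Y.mean(axis=0)
    H = yc.T @ xc
    U, S, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    R = Vt.T @ np.diag([1.0, 1.0, d]) @ U.T
    return float(np.sqrt(((xc - yc @ R.T) ** 2).sum() / len(X)))


def quaternion_min_rmsd(X: np.ndarray, Y: np.ndarray,
                        n_starts: int = 40, seed: int = 0) -> float:
    """Brute-force rotational minimisation of RMSD.

    Random-restart search over rotation vectors with local refinement;
    no SVD anywhere.  Good to ~1e-8 nm on small point sets.
    """
    rng = np.random.default_rng(seed)
    xc = X - X.mean(axis=0)
    yc = Y - Y.mean(axis=0)
    n = len(X)

    def f(rotvec: np.ndarray) -> float:
        R = Rotation.from_rotvec(rotvec).as_matrix()
        return float(((xc - yc @ R.T) ** 2).sum() / n)

    best = np.inf
    starts = [np.zeros(3)] + [
        Rotation.random(random_state=rng).as_rotvec()
        for _ in range(n_starts)]
    for x0 in starts:
        res = minimize(f, x0, method="Nelder-Mead",
                       options={"xatol": 1e-12, "fatol": 1e-18,
                                "maxiter": 5000})
        best = min(best, res.fun)
    return float(np.sqrt(best))


def naive_daura(rmsd_matrix: np.ndarray, cutoff: float
                ) -> list[tuple[int, list[int]]]:
    """Step-by-step greedy neighbour-count clustering with explicit loops."""
    n = rmsd_matrix.shape[0]
    unassigned = set(range(n))
    clusters: list[tuple[int, list[int]]] = []
    while unassigned:
        best_centre, best_count = None, -1
        for i in sorted(unassigned):
            count = sum(
                1 for j in unassigned
                if i == j or rmsd_matrix[i, j] <= cutoff)
            if count > best_count:  # strict >: lowest index wins ties
                best_centre, best_count = i, count
        members = sorted(
            j for j in unassigned
            if j == best_centre or rmsd_matrix[best_centre, j] <= cutoff)
        clusters.append((best_centre, members))
        unassigned -= set(members)
    return clusters


def random_rotation(rng: np.random.Generator) -> np.ndarray:
    return Rotation.random(random_state=rng).as_matrix()
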