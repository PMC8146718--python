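"""Geometric kernel: torsion angles, Ramachandran classification, Kabsch
superposition and RMSD matrices.

Angles are degrees in (-180, 180] (IUPAC sign convention); distances nm.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .model import Ensemble, SelectionError, StructureModel

__all__ = [
    "GeometryError",
    "dihedral",
    "TorsionSet",
    "backbone_torsions",
    "RamaRegions",
    "DEFAULT_RAMA_REGIONS",
    "classify_rama",
    "rama_segments",
    "SuperpositionResult",
    "kabsch",
    "pairwise_rmsd",
]


class GeometryError(ValueError):
    """Raised for degenerate geometry (collinear points, too few atoms)."""


def _wrap_deg(angle: float) -> float:
    """Wrap into (-180, 180]."""
    a = (angle + 180.0) % 360.0 - 180.0
    return 180.0 if a == -180.0 else a


def dihedral(p1, p2, p3, p4) -> float:
    """Signed dihedral angle p1-p2-p3-p4 in degrees, range (-180, 180].

    Zero for a planar cis arrangement, 180 for trans.  Raises
    :class:`GeometryError` if three consecutive points are collinear (the
    angle is then undefined).
    """
    p1, p2, p3, p4 = (np.asarray(p, dtype=float) for p in (p1, p2, p3, p4))
    b1 = p2 - p1
    b2 = p3 - p2
    b3 = p4 - p3
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    b2n = np.linalg.norm(b2)
    if b2n == 0.0:
        raise GeometryError("coincident central points")
    if np.linalg.norm(n1) < 1e-12 or np.linalg.norm(n2) < 1e-12:
        raise GeometryError("collinear points: dihedral undefined")
    x = float(np.dot(n1, n2))
    y = float(np.dot(np.cross(n1, n2), b2 / b2n))
    return _wrap_deg(np.degrees(np.arctan2(y, x)))


@dataclass
class TorsionSet:
    """Per-residue backbone torsions for one chain; NaN marks undefined."""

    chain_id: str
    res_seqs: np.ndarray          # (n,) residue numbers, ordered
    phi: np.ndarray               # (n,) degrees, NaN where undefined
    psi: np.ndarray
    omega: np.ndarray

    def as_dict(self) -> dict[int, tuple[float, float, float]]:
        return {
            int(r): (float(f), float(s), float(w))
            for r, f, s, w in zip(self.res_seqs, self.phi, self.psi, self.omega)
        }


def backbone_torsions(model: StructureModel, chain_id: str) -> TorsionSet:
    """Phi/psi/omega for every residue of one chain.

    phi(i) = C(i-1)-N(i)-CA(i)-C(i); psi(i) = N(i)-CA(i)-C(i)-N(i+1);
    omega(i) = CA(i-1)-C(i-1)-N(i)-CA(i).  A gap in residue numbering breaks
    the chain: no torsion is computed across it.  A missing backbone atom
    makes the affected torsions NaN rather than raising.
    """
    res_list = model.chains.get(chain_id)
    if not res_list or len(res_list) < 2:
        raise GeometryError(f"chain {chain_id!r} needs >= 2 residues")

    def pos(res: int, name: str) -> np.ndarray | None:
        try:
            return model.get_position(chain_id, res, name)
        except KeyError:
            return None

    n = len(res_list)
    phi = np.full(n, np.nan)
    psi = np.full(n, np.nan)
    omega = np.full(n, np.nan)
    for k, res in enumerate(res_list):
        N, CA, C = pos(res, "N"), pos(res, "CA"), pos(res, "C")
        prev_ok = k > 0 and res_list[k - 1] == res - 1
        next_ok = k < n - 1 and res_list[k + 1] == res + 1
        try:
            if prev_ok and all(p is not None for p in (N, CA, C)):
                Cp = pos(res - 1, "C")
                if Cp is not None:
                    phi[k] = dihedral(Cp, N, CA, C)
            if next_ok and all(p is not None for p in (N, CA, C)):
                Nn = pos(res + 1, "N")
                if Nn is not None:
                    psi[k] = dihedral(N, CA, C, Nn)
            if prev_ok and N is not None and CA is not None:
                CAp, Cp = pos(res - 1, "CA"), pos(res - 1, "C")
                if CAp is not None and Cp is not None:
                    omega[k] = dihedral(CAp, Cp, N, CA)
        except GeometryError:
            pass  # degenerate coordinates: leave NaN
    return TorsionSet(chain_id, np.asarray(res_list, dtype=int),
                      phi, psi, omega)


@dataclass(frozen=True)
class RamaRegions:
    """Rectangular alpha/beta basins on the Ramachandran plot (degrees).

    ``beta_psi`` is a union of intervals since the beta basin wraps through
    psi = 180.  The defaults are standard basin boxes; they are a declared
    convention of this package, configurable by the caller.
    """

    alpha_phi: tuple[float, float] = (-160.0, -20.0)
    alpha_psi: tuple[float, float] = (-90.0, 30.0)
    beta_phi: tuple[float, float] = (-180.0, -45.0)
    beta_psi: tuple[tuple[float, float], ...] = ((45.0, 180.0),
                                                 (-180.0, -150.0))

    def classify(self, phi: float, psi: float) -> str:
        if np.isnan(phi) or np.isnan(psi):
            return "undefined"
        if (self.alpha_phi[0] <= phi <= self.alpha_phi[1]
                and self.alpha_psi[0] <= psi <= self.alpha_psi[1]):
            return "alpha"
        if self.beta_phi[0] <= phi <= self.beta_phi[1] and any(
                lo <= psi <= hi for lo, hi in self.beta_psi):
            return "beta"
        return "other"


DEFAULT_RAMA_REGIONS = RamaRegions()


def classify_rama(torsions: TorsionSet,
                  regions: RamaRegions = DEFAULT_RAMA_REGIONS) -> list[str]:
    """Per-residue basin label: alpha / beta / other / undefined."""
    return [regions.classify(f, s)
            for f, s in zip(torsions.phi, torsions.psi)]


def rama_segments(labels: Sequence[str], min_len: int = 2
                  ) -> list[tuple[str, int, int]]:
    """Runs of >= ``min_len`` identical alpha/beta labels.

    Returns (label, start_index, end_index) with inclusive 0-based indices —
    the rule used to colour secondary-structure stretches: two or more
    adjacent residues in the same basin count as a segment, a lone residue
    does not.
    """
    segments: list[tuple[str, int, int]] = []
    i = 0
    n = len(labels)
    while i < n:
        j = i
        while j + 1 < n and labels[j + 1] == labels[i]:
            j += 1
        if labels[i] in ("alpha", "beta") and j - i + 1 >= min_len:
            segments.append((labels[i], i, j))
        i = j + 1
    return segments


@dataclass(frozen=True)
class SuperpositionResult:
    """Optimal rigid-body fit of Y onto X: x ~ rotation @ y + translation."""

    rotation: np.ndarray      # (3,3), proper (det = +1)
    translation: np.ndarray   # (3,), nm
    rmsd: float               # nm

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return coords @ self.rotation.T + self.translation


def kabsch(X: np.ndarray, Y: np.ndarray) -> SuperpositionResult:
    """Least-squares rigid superposition of Y onto X (Kabsch, via SVD).

    Minimises RMSD over rotations and translations; the reflection branch is
    corrected so the rotation is always proper.  Requires n >= 3 paired,
    non-collinear points.
    """
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    if X.shape != Y.shape or X.ndim != 2 or X.shape[1] != 3:
        raise GeometryError("X and Y must be matching (n,3) arrays")
    n = X.shape[0]
    if n < 3:
        raise GeometryError("need at least 3 points for superposition")
    xc = X - X.mean(axis=0)
    yc = Y - Y.mean(axis=0)
    for name, c in (("X", xc), ("Y", yc)):
        s = np.linalg.svd(c, compute_uv=False)
        if s[1] <= 1e-12 * max(1.0, s[0]):
            raise GeometryError(f"{name} points are collinear: rotation "
                                "is not uniquely determined")
    H = yc.T @ xc
    U, S, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    diff = xc - yc @ R.T
    rmsd = float(np.sqrt((diff ** 2).sum() / n))
    t = X.mean(axis=0) - R @ Y.mean(axis=0)
    return SuperpositionResult(rotation=R, translation=t, rmsd=rmsd)


def _rmsd_matrix(coords: np.ndarray) -> np.ndarray:
    """All-pairs Kabsch-minimised RMSD from stacked coords (F, n, 3).

    Uses the singular-value identity
    min RMSD^2(i,j) = (|xi|^2 + |xj|^2 - 2(s1+s2+sign(det H)*s3)) / n
    on centred coordinates, with batched 3x3 SVDs per row.
    """
    F, n, _ = coords.shape
    C = coords - coords.mean(axis=1, keepdims=True)
    ssd = np.einsum("fij,fij->f", C, C)
    D = np.zeros((F, F))
    for i in range(F - 1):
        H = np.einsum("fnj,nk->fjk", C[i + 1:], C[i])  # maps frame j -> i
        S = np.linalg.svd(H, compute_uv=False)
        sign = np.sign(np.linalg.det(H))
        sign[sign == 0] = 1.0
        trace = S[:, 0] + S[:, 1] + sign * S[:, 2]
        sq = (ssd[i] + ssd[i + 1:] - 2.0 * trace) / n
        row = np.sqrt(np.maximum(sq, 0.0))
        # the cancellation in the identity loses precision for near-zero
        # RMSD; recompute those few entries from the explicit residual
        tiny = np.nonzero(row < 1e-6)[0]
        for k in tiny:
            j = i + 1 + int(k)
            U2, _, Vt2 = np.linalg.svd(H[k])
            d2 = np.sign(np.linalg.det(Vt2.T @ U2.T))
            R = Vt2.T @ np.diag([1.0, 1.0, d2]) @ U2.T
            row[k] = np.sqrt(((C[i] - C[j] @ R.T) ** 2).sum() / n)
        D[i, i + 1:] = row
    D += D.T
    return D


def pairwise_rmsd(ensemble: Ensemble, selection: str) -> np.ndarray:
    """Symmetric matrix of pairwise minimised RMSD over selected atoms (nm).

    The same atom selection is used for fitting and for RMSD evaluation.
    """
    idx = ensemble.frames[0].select_indices(selection)
    if idx.size == 0:
        raise SelectionError(f"selection {selection!r} matches no atoms")
    return _rmsd_matrix(ensemble.coords(idx))
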