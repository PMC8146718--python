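"""Synthetic peptide ensembles with known ground truth.

This module stands in for trajectory data that cannot be redistributed: it
builds peptide backbones from torsion angles by internal-coordinate chain
extension (NeRF-style placement), samples trajectory-like conformational
ensembles whose per-frame basin states follow a Markov rule, and generates
chemical-shift tables at a prescribed helical fraction.  It emulates the
statistical structure of a simulation — multiple torsion basins,
frame-to-frame correlation, distinct starting states — never its
energetics: there is no force field, no solvent and no thermodynamics.

Defaults target the 13-residue linker peptide KKADEQQAQFRQA (protein
numbering 38-50).  Only backbone atoms (N, CA, C, O, amide H) plus a Cbeta
stub are built; that is all the in-scope backbone analyses need.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .model import (AA_ONE_TO_THREE, Ensemble, StructureError,
                    StructureModel)
from .nmr import ShiftTable
from .refdata import HELIX_DELTA, NUCLEI, RANDOM_COIL_SHIFTS

__all__ = [
    "LINKER_SEQUENCE",
    "LINKER_START_RES",
    "BasinSpec",
    "DEFAULT_BASINS",
    "EnsembleDesign",
    "place_atom",
    "build_backbone",
    "sample_ensemble",
    "synth_shifts",
]

LINKER_SEQUENCE = "KKADEQQAQFRQA"
LINKER_START_RES = 38  # protein numbering of the first peptide residue

# standard backbone internal coordinates (nm, degrees)
B_N_CA = 0.1458
B_CA_C = 0.1525
B_C_N = 0.1329
B_C_O = 0.1231
B_N_H = 0.100
B_CA_CB = 0.1530
A_C_N_CA = 121.7
A_N_CA_C = 111.2
A_CA_C_N = 116.2
A_CA_C_O = 120.8
A_C_N_H = 119.0


def place_atom(a: np.ndarray, b: np.ndarray, c: np.ndarray,
               bond: float, angle_deg: float, dihedral_deg: float
               ) -> np.ndarray:
    """Place atom d from reference atoms a-b-c by internal coordinates.

    ``bond`` = |d-c|, ``angle_deg`` = angle b-c-d, ``dihedral_deg`` =
    dihedral a-b-c-d.  This is the standard natural-extension placement
    used to grow a chain residue by residue.
    """
    bc = c - b
    bc /= np.linalg.norm(bc)
    ab = b - a
    n = np.cross(ab, bc)
    nn = np.linalg.norm(n)
    if nn < 1e-12:
        raise StructureError("collinear reference atoms in place_atom")
    n /= nn
    m = np.cross(n, bc)
    ang = np.radians(angle_deg)
    dih = np.radians(dihedral_deg)
    d_local = np.array([
        -bond * np.cos(ang),
        bond * np.sin(ang) * np.cos(dih),
        bond * np.sin(ang) * np.sin(dih),
    ])
    return c + d_local[0] * bc + d_local[1] * m + d_local[2] * n


def build_backbone(
    sequence: str,
    phi: np.ndarray,
    psi: np.ndarray,
    omega: np.ndarray | None = None,
    start_res: int = LINKER_START_RES,
    chain_id: str = "A",
    acetyl_cap: bool = False,
    amide_cap: bool = False,
    with_cb: bool = True,
    model_id: int = 1,
) -> StructureModel:
    """Build a peptide backbone from per-residue torsions.

    ``phi[i]``/``psi[i]`` are the torsions of residue i (0-based over the
    sequence); phi[0] is used only when an N-terminal acetyl cap provides
    the preceding carbonyl, psi[-1] only to orient the terminal carbonyl /
    C-terminal cap.  NaN entries fall back to 180 (extended).  ``omega``
    defaults to 180 (all-trans, no cis sampling).

    The built model round-trips: measuring torsions on the result recovers
    the requested values to numerical precision.
    """
    seq = sequence.upper()
    n = len(seq)
    if n < 2:
        raise StructureError("need at least 2 residues")
    phi = np.asarray(phi, dtype=float)
    psi = np.asarray(psi, dtype=float)
    if phi.shape != (n,) or psi.shape != (n,):
        raise StructureError(
            f"torsion arrays must have length {n} (sequence length)")
    omega_arr = (np.full(n, 180.0) if omega is None
                 else np.asarray(omega, dtype=float))
    if omega_arr.shape != (n,):
        raise StructureError("omega array length mismatch")
    phi = np.where(np.isfinite(phi), phi, 180.0)
    psi = np.where(np.isfinite(psi), psi, 180.0)
    omega_arr = np.where(np.isfinite(omega_arr), omega_arr, 180.0)
    for res1 in seq:
        if res1 not in AA_ONE_TO_THREE:
            raise StructureError(f"unknown residue code {res1!r}")

    # grow N, CA, C for every residue
    N = np.zeros((n, 3))
    CA = np.zeros((n, 3))
    C = np.zeros((n, 3))
    N[0] = (0.0, 0.0, 0.0)
    CA[0] = (B_N_CA, 0.0, 0.0)
    ang = np.radians(180.0 - A_N_CA_C)
    C[0] = CA[0] + B_CA_C * np.array([np.cos(ang), np.sin(ang), 0.0])
    for i in range(1, n):
        N[i] = place_atom(N[i - 1], CA[i - 1], C[i - 1],
                          B_C_N, A_CA_C_N, psi[i - 1])
        CA[i] = place_atom(CA[i - 1], C[i - 1], N[i],
                           B_N_CA, A_C_N_CA, omega_arr[i])
        C[i] = place_atom(C[i - 1], N[i], CA[i],
                          B_CA_C, A_N_CA_C, phi[i])

    names: list[str] = []
    elements: list[str] = []
    res_seqs: list[int] = []
    res_names: list[str] = []
    coords: list[np.ndarray] = []

    def add(name: str, elem: str, res_idx: int, res_name: str,
            pos: np.ndarray) -> None:
        names.append(name)
        elements.append(elem)
        res_seqs.append(res_idx)
        res_names.append(res_name)
        coords.append(pos)

    if acetyl_cap:
        cap_res = start_res - 1
        c_ace = place_atom(C[0], CA[0], N[0], B_C_N, A_C_N_CA, phi[0])
        o_ace = place_atom(CA[0], N[0], c_ace, B_C_O, 122.5, 0.0)
        ch3 = place_atom(CA[0], N[0], c_ace, 0.152, 116.0, 180.0)
        add("CH3", "C", cap_res, "ACE", ch3)
        add("C", "C", cap_res, "ACE", c_ace)
        add("O", "O", cap_res, "ACE", o_ace)

    for i, res1 in enumerate(seq):
        res3 = AA_ONE_TO_THREE[res1]
        res_idx = start_res + i
        add("N", "N", res_idx, res3, N[i])
        # amide hydrogen: trans to CA(i-1) across the peptide bond
        if res3 != "PRO" and (i > 0 or acetyl_cap):
            if i > 0:
                ref_ca, ref_c = CA[i - 1], C[i - 1]
            else:
                ref_ca, ref_c = coords[names.index("CH3")], c_ace
            h = place_atom(ref_ca, ref_c, N[i], B_N_H, A_C_N_H, 0.0)
            add("H", "H", res_idx, res3, h)
        add("CA", "C", res_idx, res3, CA[i])
        if with_cb and res3 != "GLY":
            cb = _place_cb(N[i], CA[i], C[i])
            add("CB", "C", res_idx, res3, cb)
        add("C", "C", res_idx, res3, C[i])
        # carbonyl O: anti to the next N across the C(sp2) plane
        if i < n - 1:
            o = place_atom(N[i], CA[i], C[i], B_C_O, A_CA_C_O,
                           psi[i] + 180.0)
        else:
            o = place_atom(N[i], CA[i], C[i], B_C_O, A_CA_C_O,
                           psi[i] + 180.0)
        add("O", "O", res_idx, res3, o)
        if i == n - 1:
            if amide_cap:
                nt = place_atom(N[i], CA[i], C[i], B_C_N, A_CA_C_N, psi[i])
                add("N", "N", start_res + n, "NH2", nt)
                h1 = place_atom(CA[i], C[i], nt, B_N_H, A_C_N_H, 0.0)
                h2 = place_atom(CA[i], C[i], nt, B_N_H, A_C_N_H, 180.0)
                add("HN1", "H", start_res + n, "NH2", h1)
                add("HN2", "H", start_res + n, "NH2", h2)
            else:
                oxt = place_atom(N[i], CA[i], C[i], B_C_O, A_CA_C_O,
                                 psi[i])
                add("OXT", "O", res_idx, res3, oxt)

    chain_ids = [chain_id] * len(names)
    return StructureModel(names, elements, res_seqs, res_names, chain_ids,
                          np.array(coords), model_id=model_id)


def _place_cb(n_pos: np.ndarray, ca_pos: np.ndarray, c_pos: np.ndarray
              ) -> np.ndarray:
    """Tetrahedral Cbeta stub off CA (L-configuration by construction)."""
    b_n = n_pos - ca_pos
    b_n /= np.linalg.norm(b_n)
    b_c = c_pos - ca_pos
    b_c /= np.linalg.norm(b_c)
    bisector = b_n + b_c
    bisector /= np.linalg.norm(bisector)
    perp = np.cross(b_n, b_c)
    perp /= np.linalg.norm(perp)
    # angle N-CA-CB ~ 110.5 deg on both sides
    cos_mu, sin_mu = 0.620, 0.785
    return ca_pos + B_CA_CB * (-cos_mu * bisector + sin_mu * perp)


@dataclass(frozen=True)
class BasinSpec:
    """A torsion basin: wrapped-normal (phi, psi) well on the Ramachandran map."""

    name: str
    phi_mean: float
    psi_mean: float
    sd: float = 12.0  # circular standard deviation, degrees

    def __post_init__(self) -> None:
        if self.sd <= 0:
            raise ValueError("basin std-dev must be positive")
        for v in (self.phi_mean, self.psi_mean):
            if not -180.0 < v <= 180.0:
                raise ValueError("basin means must lie in (-180, 180]")


DEFAULT_BASINS: dict[str, BasinSpec] = {
    "alpha": BasinSpec("alpha", -57.0, -47.0),
    "beta": BasinSpec("beta", -120.0, 130.0),
    "ppII": BasinSpec("ppII", -75.0, 145.0),
    # "hairpin" is a conformer CLASS, not a torsion well: residues in the
    # design's turn region draw from alpha, the flanks from beta, which
    # reliably yields compact hairpin-like conformers.  The entry below
    # only registers the name; its well parameters are never sampled.
    "hairpin": BasinSpec("hairpin", -90.0, 0.0),
}


@dataclass(frozen=True)
class EnsembleDesign:
    """Recipe for a synthetic trajectory-like ensemble.

    ``basin_weights`` is the stationary mixture over basin names; states
    evolve per frame by a Markov rule: with probability ``switching_prob``
    the state is redrawn from the mixture, otherwise it persists
    (``switching_prob = 1`` gives independent frames, 0 freezes the start
    state).  ``collective`` switches the whole peptide between basins as
    one unit (the regime of a short peptide hopping between conformational
    wells); otherwise each residue carries its own chain.
    The ``hairpin`` state is a conformer class rather than a single well:
    residues inside ``turn_region`` (protein numbering, inclusive; default
    the three central residues) draw from the alpha well and the flanks
    from the beta well, which yields compact hairpin-like conformers with
    short N-terminal-NH to C-terminal-CO distances.
    """

    sequence: str = LINKER_SEQUENCE
    basin_weights: tuple[tuple[str, float], ...] = (("alpha", 1.0),)
    switching_prob: float = 0.2
    n_frames: int = 200
    dt_ps: float = 5.0
    seed: int = 0
    source_label: str = "synthetic"
    start_res: int = LINKER_START_RES
    collective: bool = True
    turn_region: tuple[int, int] | None = None
    basins: tuple[BasinSpec, ...] = tuple(DEFAULT_BASINS.values())
    sd_override: float | None = None

    def __post_init__(self) -> None:
        w = dict(self.basin_weights)
        total = sum(w.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError("basin weights must sum to 1")
        if not 0.0 <= self.switching_prob <= 1.0:
            raise ValueError("switching probability must be in [0, 1]")
        if self.n_frames < 1:
            raise ValueError("need at least one frame")
        known = {b.name for b in self.basins}
        missing = set(w) - known
        if missing:
            raise ValueError(f"unknown basins in weights: {sorted(missing)}")

    def basin(self, name: str) -> BasinSpec:
        for b in self.basins:
            if b.name == name:
                spec = b
                break
        else:
            raise KeyError(name)
        if self.sd_override is not None:
            spec = replace(spec, sd=self.sd_override)
        return spec


def sample_ensemble(design: EnsembleDesign
                    ) -> tuple[Ensemble, list[str], np.ndarray]:
    """Draw a synthetic ensemble; returns (ensemble, frame_labels, states).

    ``frame_labels`` is the per-frame majority basin (the design's ground
    truth for cluster-recovery tests); ``states`` is the full per-frame,
    per-residue basin-state path as an integer array indexing
    ``[name for name, _ in design.basin_weights]``.  Fully reproducible
    from ``design.seed``.
    """
    rng = np.random.default_rng(design.seed)
    names = [name for name, _ in design.basin_weights]
    probs = np.array([w for _, w in design.basin_weights])
    n_res = len(design.sequence)
    n_frames = design.n_frames

    if design.collective:
        path = np.zeros(n_frames, dtype=int)
        path[0] = rng.choice(len(names), p=probs)
        for f in range(1, n_frames):
            if rng.random() < design.switching_prob:
                path[f] = rng.choice(len(names), p=probs)
            else:
                path[f] = path[f - 1]
        states = np.repeat(path[:, None], n_res, axis=1)
    else:
        states = np.zeros((n_frames, n_res), dtype=int)
        states[0] = rng.choice(len(names), size=n_res, p=probs)
        for f in range(1, n_frames):
            redraw = rng.random(n_res) < design.switching_prob
            states[f] = np.where(
                redraw, rng.choice(len(names), size=n_res, p=probs),
                states[f - 1])

    # turn region for the hairpin conformer class (protein numbering)
    lo, hi = design.turn_region if design.turn_region is not None else (
        design.start_res + (n_res - 3) // 2,
        design.start_res + (n_res - 3) // 2 + 2)
    in_turn = np.array([lo <= design.start_res + i <= hi
                        for i in range(n_res)])

    frames: list[StructureModel] = []
    frame_labels: list[str] = []
    for f in range(n_frames):
        phi = np.empty(n_res)
        psi = np.empty(n_res)
        for i in range(n_res):
            state_name = names[states[f, i]]
            if state_name == "hairpin":
                # compact hairpin-like conformer: alpha turn, extended flanks
                spec = design.basin("alpha" if in_turn[i] else "beta")
            else:
                spec = design.basin(state_name)
            phi[i] = _wrap(rng.normal(spec.phi_mean, spec.sd))
            psi[i] = _wrap(rng.normal(spec.psi_mean, spec.sd))
        frames.append(build_backbone(
            design.sequence, phi, psi, start_res=design.start_res,
            model_id=f + 1))
        counts = np.bincount(states[f], minlength=len(names))
        frame_labels.append(names[int(np.argmax(counts))])
    times = design.dt_ps * np.arange(1, n_frames + 1)
    ens = Ensemble(frames, times, source_label=design.source_label,
                   frame_labels=frame_labels)
    return ens, frame_labels, states


def _wrap(angle: float) -> float:
    a = (angle + 180.0) % 360.0 - 180.0
    return 180.0 if a == -180.0 else a


def synth_shifts(
    helicity: float | np.ndarray,
    noise_sd: float = 0.05,
    seed: int = 0,
    sequence: str = LINKER_SEQUENCE,
    start_res: int = LINKER_START_RES,
) -> ShiftTable:
    """Chemical shifts for a peptide at a prescribed helical fraction.

    shift(i, k) = coil(i, k) + f(i) * helix_delta(k) + N(0, noise_sd)

    using the same bundled reference tables as the propensity analysis, so
    a propensity score computed from the output recovers f by construction.
    ``noise_sd`` is in ppm and is applied to every nucleus (0.05 ppm is a
    realistic assignment/reference uncertainty for a small peptide).
    """
    n = len(sequence)
    f = np.broadcast_to(np.asarray(helicity, dtype=float), (n,)).copy()
    if np.any((f < 0) | (f > 1)):
        raise ValueError("helicity fractions must be in [0, 1]")
    rng = np.random.default_rng(seed)
    shifts: dict[str, list[float]] = {k: [] for k in NUCLEI}
    for i, res1 in enumerate(sequence):
        if res1 not in RANDOM_COIL_SHIFTS:
            raise ValueError(f"unknown residue type {res1!r}")
        ca, cb, ha = RANDOM_COIL_SHIFTS[res1]
        coil = {"CA": ca, "CB": cb, "HA": ha}
        for nuc in NUCLEI:
            base = coil[nuc] + f[i] * HELIX_DELTA[nuc]
            noise = rng.normal(0.0, noise_sd) if noise_sd > 0 else 0.0
            shifts[nuc].append(base + noise)
    res_seqs = [start_res + i for i in range(n)]
    return ShiftTable.from_records(res_seqs, list(sequence), shifts)
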