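"""Geometric hydrogen bonds, helix-bond taxonomy, salt bridges and
inter-chain contact maps.

The hydrogen-bond criterion is purely geometric and strict on both sides:
a bond exists iff the hydrogen-acceptor distance is smaller than 0.25 nm
AND the donor-hydrogen-acceptor angle is larger than 135 degrees.  Exactly
0.25 nm or exactly 135 degrees is NOT a bond.

Bond identity strings are diffable against trajectory-analysis tables:
``"45 NH-41 O"`` means the backbone amide of residue 45 donating to the
backbone carbonyl of residue 41.  Side-chain hydrogens keep GROMOS-style
labels: PDB ``HE22`` (Gln) becomes ``NHE22``; ``HH11`` (Arg) becomes
``NH11``; hydroxyl donors are labelled by their oxygen (``OG``, ``OH``).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy.spatial.distance import cdist

from .model import Ensemble, StructureError, StructureModel

__all__ = [
    "HBondRecord",
    "PopulationTable",
    "SaltBridge",
    "ContactMap",
    "place_amide_hydrogens",
    "detect_hbonds",
    "classify_helix_bond",
    "hbond_populations",
    "interface_contacts",
]

log = logging.getLogger(__name__)

HBOND_DIST_NM = 0.25       # strict <
HBOND_ANGLE_DEG = 135.0    # strict >
NH_BOND_NM = 0.100

#: side-chain donor hydrogens: res_name -> {H name: heavy-atom name}
SIDECHAIN_DONORS: dict[str, dict[str, str]] = {
    "ARG": {"HE": "NE", "HH11": "NH1", "HH12": "NH1",
            "HH21": "NH2", "HH22": "NH2"},
    "LYS": {"HZ1": "NZ", "HZ2": "NZ", "HZ3": "NZ"},
    "GLN": {"HE21": "NE2", "HE22": "NE2"},
    "ASN": {"HD21": "ND2", "HD22": "ND2"},
    "SER": {"HG": "OG"},
    "THR": {"HG1": "OG1"},
    "TYR": {"HH": "OH"},
    "TRP": {"HE1": "NE1"},
}

#: side-chain acceptor atoms per residue type
SIDECHAIN_ACCEPTORS: dict[str, tuple[str, ...]] = {
    "ASP": ("OD1", "OD2"),
    "GLU": ("OE1", "OE2"),
    "ASN": ("OD1",),
    "GLN": ("OE1",),
    "SER": ("OG",),
    "THR": ("OG1",),
}

#: charged-group atoms for salt-bridge detection
ACIDIC_ATOMS = {"ASP": ("OD1", "OD2"), "GLU": ("OE1", "OE2")}
BASIC_ATOMS = {"ARG": ("NE", "NH1", "NH2"), "LYS": ("NZ",),
               "HIS": ("ND1", "NE2")}

BACKBONE_AMIDE_H = ("H", "HN")


def _gromos_h_label(h_name: str, heavy_name: str) -> str:
    """Trajectory-table label for a donor hydrogen.

    Backbone amide -> NH.  Side-chain N-H: ``HH11`` -> ``NH11`` (leading HH
    collapses onto the N), otherwise prefix N (``HE22`` -> ``NHE22``).
    Hydroxyl donors are labelled by the oxygen itself.
    """
    if h_name in BACKBONE_AMIDE_H:
        return "NH"
    if heavy_name.startswith("O"):
        return heavy_name
    if h_name.startswith("HH"):
        return "N" + h_name[1:]
    return "N" + h_name


@dataclass(frozen=True)
class HBondRecord:
    """One geometric hydrogen bond in one conformer."""

    donor_chain: str
    donor_res: int
    donor_heavy: str
    donor_h: str
    acceptor_chain: str
    acceptor_res: int
    acceptor_atom: str
    d_ha: float          # nm
    angle_dha: float     # degrees

    @property
    def is_backbone_backbone(self) -> bool:
        return self.donor_heavy == "N" and self.acceptor_atom in ("O", "OXT")

    @property
    def bond_id(self) -> str:
        d_lab = _gromos_h_label(self.donor_h, self.donor_heavy)
        same_chain = self.donor_chain == self.acceptor_chain
        if same_chain:
            return (f"{self.donor_res} {d_lab}-"
                    f"{self.acceptor_res} {self.acceptor_atom}")
        return (f"{self.donor_chain}{self.donor_res} {d_lab}-"
                f"{self.acceptor_chain}{self.acceptor_res} "
                f"{self.acceptor_atom}")


@dataclass
class PopulationTable:
    """Per-bond fraction of frames in which the bond is present."""

    fractions: dict[str, float]
    n_frames: int

    def percent(self) -> dict[str, float]:
        return {k: 100.0 * v for k, v in self.fractions.items()}

    def sorted_items(self) -> list[tuple[str, float]]:
        return sorted(self.fractions.items(), key=lambda kv: (-kv[1], kv[0]))


@dataclass(frozen=True)
class SaltBridge:
    acidic_chain: str
    acidic_res: int
    acidic_atom: str
    basic_chain: str
    basic_res: int
    basic_atom: str
    distance: float  # nm


@dataclass
class ContactMap:
    """Residue-pair contacts between two chains."""

    chain_a: str
    chain_b: str
    # (resA, resB) -> (contact class, min interatomic distance nm)
    entries: dict[tuple[int, int], tuple[str, float]] = field(
        default_factory=dict)

    def by_class(self, contact_class: str) -> list[tuple[int, int]]:
        return sorted(k for k, (c, _) in self.entries.items()
                      if c == contact_class)

    def mirrored(self) -> "ContactMap":
        return ContactMap(
            self.chain_b, self.chain_a,
            {(b, a): v for (a, b), v in self.entries.items()},
        )


# --------------------------------------------------------------------------
# hydrogen placement
# --------------------------------------------------------------------------

def place_amide_hydrogens(model: StructureModel) -> StructureModel:
    """Construct missing backbone amide hydrogens analytically.

    For each non-proline residue with a preceding residue in the same chain,
    H is placed 0.100 nm from N along the in-plane direction opposite the
    bisector of the C(i-1)->N and CA->N bonds.  Residues that already carry
    an amide H are left untouched (the operation is idempotent); prolines
    and chain-N-termini get no H.  A missing flanking heavy atom skips that
    H with a logged warning.
    """
    from .model import AtomRecord  # local import to avoid cycle at import time

    atoms = list(model.atoms())
    out: list[AtomRecord] = []
    has_h = {(a.chain_id, a.res_seq) for a in atoms
             if a.atom_name in BACKBONE_AMIDE_H}
    chains = model.chains
    for a in atoms:
        out.append(a)
        if a.atom_name != "N":
            continue
        res, ch = a.res_seq, a.chain_id
        if a.res_name == "PRO" or (ch, res) in has_h:
            continue
        # preceding residue must be sequential within the chain
        res_list = chains[ch]
        k = res_list.index(res)
        prev_res: int | None = None
        if k > 0 and res_list[k - 1] == res - 1:
            prev_res = res - 1
        elif model.residue_names(ch).get(res - 1) == "ACE":
            prev_res = res - 1
        if prev_res is None:
            continue
        try:
            c_prev = model.get_position(ch, prev_res, "C")
            ca = model.get_position(ch, res, "CA")
        except KeyError:
            log.warning("cannot place H on %s%d: flanking heavy atom missing",
                        ch, res)
            continue
        u_c = c_prev - a.position
        u_c /= np.linalg.norm(u_c)
        u_ca = ca - a.position
        u_ca /= np.linalg.norm(u_ca)
        bisector = u_c + u_ca
        norm = np.linalg.norm(bisector)
        if norm < 1e-8:
            log.warning("degenerate geometry at %s%d: H skipped", ch, res)
            continue
        h_pos = a.position - NH_BOND_NM * bisector / norm
        out.append(AtomRecord("H", "H", res, a.res_name, ch, h_pos))
    return StructureModel.from_atoms(out, model_id=model.model_id)


# --------------------------------------------------------------------------
# detection
# --------------------------------------------------------------------------

def _collect_donors(model: StructureModel, include_sidechains: bool
                    ) -> list[tuple[int, int]]:
    """(heavy_index, h_index) donor pairs present in the model."""
    index: dict[tuple[str, int, str], int] = {}
    for i in range(model.n_atoms):
        index[(model.chain_ids[i], int(model.res_seqs[i]),
               model.atom_names[i])] = i
    donors: list[tuple[int, int]] = []
    for i in range(model.n_atoms):
        name = model.atom_names[i]
        ch = model.chain_ids[i]
        res = int(model.res_seqs[i])
        res_name = model.res_names[i]
        if name in BACKBONE_AMIDE_H:
            j = index.get((ch, res, "N"))
            if j is not None:
                donors.append((j, i))
        elif include_sidechains and res_name in SIDECHAIN_DONORS:
            heavy = SIDECHAIN_DONORS[res_name].get(name)
            if heavy is not None:
                j = index.get((ch, res, heavy))
                if j is not None:
                    donors.append((j, i))
        elif res_name == "NH2" and name.startswith("H"):
            # C-terminal amide cap donates through its nitrogen
            j = index.get((ch, res, "N"))
            if j is not None:
                donors.append((j, i))
    return donors


def _collect_acceptors(model: StructureModel, include_sidechains: bool
                       ) -> list[int]:
    acc: list[int] = []
    for i in range(model.n_atoms):
        name = model.atom_names[i]
        res_name = model.res_names[i]
        if name in ("O", "OXT"):
            acc.append(i)   # backbone carbonyl / terminal carboxylate / ACE O
        elif include_sidechains and \
                name in SIDECHAIN_ACCEPTORS.get(res_name, ()):
            acc.append(i)
    return acc


def detect_hbonds(
    model: StructureModel,
    include_sidechains: bool = True,
    d_cut: float = HBOND_DIST_NM,
    angle_cut: float = HBOND_ANGLE_DEG,
) -> list[HBondRecord]:
    """All donor->acceptor pairs satisfying the strict geometric criterion.

    Donors are N-H/O-H groups whose hydrogen is present in the model (use
    :func:`place_amide_hydrogens` first for X-ray inputs); acceptors are
    backbone carbonyl O plus standard side-chain carbonyl/carboxylate/
    hydroxyl oxygens.  An amide donating to its own residue's side chain is
    allowed; a hydroxyl donating to itself is not.
    """
    donors = _collect_donors(model, include_sidechains)
    if not donors:
        raise StructureError(
            "no donor hydrogens in model; run place_amide_hydrogens first")
    acceptors = _collect_acceptors(model, include_sidechains)
    if not acceptors:
        return []
    h_idx = np.array([h for _, h in donors])
    d_idx = np.array([d for d, _ in donors])
    a_idx = np.array(acceptors)
    dist = cdist(model.coords[h_idx], model.coords[a_idx])  # (nd, na)
    records: list[HBondRecord] = []
    for di, hi_row in enumerate(dist):
        close = np.nonzero(hi_row < d_cut)[0]
        for aj in close:
            ai = int(a_idx[aj])
            dheavy = int(d_idx[di])
            if ai == dheavy:
                continue
            h = model.coords[int(h_idx[di])]
            dvec = model.coords[dheavy] - h
            avec = model.coords[ai] - h
            cosang = np.dot(dvec, avec) / (
                np.linalg.norm(dvec) * np.linalg.norm(avec))
            angle = float(np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0))))
            if angle > angle_cut:
                records.append(HBondRecord(
                    donor_chain=model.chain_ids[dheavy],
                    donor_res=int(model.res_seqs[dheavy]),
                    donor_heavy=model.atom_names[dheavy],
                    donor_h=model.atom_names[int(h_idx[di])],
                    acceptor_chain=model.chain_ids[ai],
                    acceptor_res=int(model.res_seqs[ai]),
                    acceptor_atom=model.atom_names[ai],
                    d_ha=float(hi_row[aj]),
                    angle_dha=angle,
                ))
    records.sort(key=lambda r: (r.donor_chain, r.donor_res, r.donor_h,
                                r.acceptor_chain, r.acceptor_res,
                                r.acceptor_atom))
    return records


def classify_helix_bond(bond: HBondRecord) -> str:
    """Helix taxonomy of a backbone-backbone bond.

    Donor minus acceptor residue offset of 4 is the alpha-helical
    NH(i)-CO(i-4) bond; offset 3 is the 3_10-helix NH(i)-CO(i-3) bond;
    anything else (including all side-chain bonds) is ``other``.
    """
    if not bond.is_backbone_backbone:
        return "other"
    offset = bond.donor_res - bond.acceptor_res
    if offset == 4:
        return "alpha_i_i4"
    if offset == 3:
        return "three10_i_i3"
    return "other"


def hbond_populations(
    ensemble: Ensemble,
    frame_indices: Sequence[int] | None = None,
    include_sidechains: bool = True,
    auto_place_h: bool = True,
) -> PopulationTable:
    """Fraction of frames in which each hydrogen bond occurs.

    ``frame_indices`` restricts the statistic to a subset (e.g. one
    cluster); populations are counts of frames containing the bond divided
    by the number of frames considered.
    """
    if ensemble.n_frames == 0:
        raise StructureError("empty ensemble")
    idx = (range(ensemble.n_frames) if frame_indices is None
           else [int(i) for i in frame_indices])
    idx = list(idx)
    if not idx:
        raise StructureError("no frames selected")
    counts: dict[str, int] = {}
    for i in idx:
        frame = ensemble.frames[i]
        if auto_place_h and not any(n in BACKBONE_AMIDE_H
                                    for n in frame.atom_names):
            frame = place_amide_hydrogens(frame)
        seen = {b.bond_id for b in detect_hbonds(frame, include_sidechains)}
        for bid in seen:
            counts[bid] = counts.get(bid, 0) + 1
    n = len(idx)
    return PopulationTable({k: v / n for k, v in sorted(counts.items())}, n)


# --------------------------------------------------------------------------
# interfaces
# --------------------------------------------------------------------------

def _chain_heavy_indices(model: StructureModel, chain: str) -> np.ndarray:
    idx = [i for i in range(model.n_atoms)
           if model.chain_ids[i] == chain and model.elements[i] != "H"]
    return np.array(idx, dtype=int)


def _is_polar(model: StructureModel, i: int) -> bool:
    return model.elements[i] in ("N", "O")


def _is_acidic(model: StructureModel, i: int) -> bool:
    name, res = model.atom_names[i], model.res_names[i]
    if name in ACIDIC_ATOMS.get(res, ()):
        return True
    return name == "OXT"  # C-terminal carboxylate


def _is_basic(model: StructureModel, i: int, nterm: dict[str, int]) -> bool:
    name, res = model.atom_names[i], model.res_names[i]
    if name in BASIC_ATOMS.get(res, ()):
        return True
    # free N-terminal amino group
    return (name == "N"
            and nterm.get(model.chain_ids[i]) == int(model.res_seqs[i]))


def interface_contacts(
    assembly: StructureModel,
    chain_a: str,
    chain_b: str,
    contact_cut: float = 0.40,
    salt_cut: float = 0.40,
    hbond_heavy_cut: float = 0.35,
) -> ContactMap:
    """Residue-level contact map between two chains of an assembly.

    Classification per residue pair (salt bridge takes precedence):

    - ``saltbridge``: any acidic carboxylate O within ``salt_cut`` of a
      basic side-chain N (or terminal charged group);
    - ``hbond``: any polar N/O - N/O pair within ``hbond_heavy_cut``
      (a heavy-atom proxy for the hydrogen-bond criterion, since
      crystallographic inputs carry no hydrogens);
    - ``vdw``: any heavy-atom pair within ``contact_cut``.

    This is a distance-based proxy for buried-interface analysis, not a
    surface-area calculation.
    """
    chains = assembly.chains
    for ch in (chain_a, chain_b):
        if ch not in chains:
            raise StructureError(f"chain {ch!r} not in assembly "
                                 f"(has {sorted(chains)})")
    if chain_a == chain_b:
        raise StructureError("interface requires two distinct chains")
    ia = _chain_heavy_indices(assembly, chain_a)
    ib = _chain_heavy_indices(assembly, chain_b)
    nterm = {ch: res_list[0] for ch, res_list in chains.items()}
    dist = cdist(assembly.coords[ia], assembly.coords[ib])
    cmap = ContactMap(chain_a, chain_b)
    close_pairs = np.nonzero(dist <= contact_cut)
    pair_info: dict[tuple[int, int], tuple[str, float]] = {}
    for pa, pb in zip(*close_pairs):
        i, j = int(ia[pa]), int(ib[pb])
        d = float(dist[pa, pb])
        key = (int(assembly.res_seqs[i]), int(assembly.res_seqs[j]))
        cls = "vdw"
        if d <= salt_cut and (
                (_is_acidic(assembly, i) and _is_basic(assembly, j, nterm))
                or (_is_basic(assembly, i, nterm) and _is_acidic(assembly, j))):
            cls = "saltbridge"
        elif d <= hbond_heavy_cut and _is_polar(assembly, i) \
                and _is_polar(assembly, j):
            cls = "hbond"
        rank = {"vdw": 0, "hbond": 1, "saltbridge": 2}
        old = pair_info.get(key)
        if old is None:
            pair_info[key] = (cls, d)
        else:
            best_cls = cls if rank[cls] > rank[old[0]] else old[0]
            pair_info[key] = (best_cls, min(d, old[1]))
    cmap.entries = dict(sorted(pair_info.items()))
    return cmap
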