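"""Coordinate containers: atoms, structure models, ensembles and numbering maps.

All internal distances are in nanometres. PDB files carry angstroms; the
conversion happens exactly once, at ingest (see :mod:`conformens.pdbio`), so
every geometric threshold in the package (hydrogen-bond 0.25 nm, clustering
cutoff 0.15 nm, contact 0.4 nm) is expressed in nm.

Residue numbering is kept verbatim as authored.  For the PmScsC linker
peptide (sequence KKADEQQAQFRQA) the peptide-local residues 1-13 correspond
to protein residues 38-50; :class:`NumberingMap` converts between the two so
that all public selections can use protein numbering.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator, Sequence

import numpy as np

__all__ = [
    "STANDARD_AA",
    "StructureError",
    "SelectionError",
    "AtomRecord",
    "StructureModel",
    "NumberingMap",
    "map_numbering",
    "Ensemble",
    "pool_ensembles",
]

#: Three-letter codes of the 20 standard amino acids.
STANDARD_AA = {
    "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
    "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL",
}

AA_THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}
AA_ONE_TO_THREE = {v: k for k, v in AA_THREE_TO_ONE.items()}


class StructureError(ValueError):
    """Raised for invalid or inconsistent structural data."""


class SelectionError(ValueError):
    """Raised when an atom-selection expression is invalid or empty."""


@dataclass(frozen=True, eq=False)
class AtomRecord:
    """A single atom: PDB-style identity plus a position in nanometres."""

    atom_name: str
    element: str
    res_seq: int
    res_name: str
    chain_id: str
    position: np.ndarray  # shape (3,), nm

    def __post_init__(self) -> None:
        if not self.atom_name:
            raise StructureError("atom_name must be non-empty")
        pos = np.asarray(self.position, dtype=float)
        if pos.shape != (3,) or not np.all(np.isfinite(pos)):
            raise StructureError(
                f"position of {self.atom_name} must be a finite 3-vector"
            )
        object.__setattr__(self, "position", pos)


class StructureModel:
    """One conformer: an ordered set of atoms with chain/residue identity.

    Metadata (names, residue numbers, chains) is stored in parallel arrays so
    that frames of an ensemble can share it; coordinates are an (n_atoms, 3)
    float array in nm.
    """

    __slots__ = (
        "atom_names", "elements", "res_seqs", "res_names", "chain_ids",
        "coords", "model_id",
    )

    def __init__(
        self,
        atom_names: Sequence[str],
        elements: Sequence[str],
        res_seqs: Sequence[int],
        res_names: Sequence[str],
        chain_ids: Sequence[str],
        coords: np.ndarray,
        model_id: int = 1,
    ) -> None:
        n = len(atom_names)
        coords = np.asarray(coords, dtype=float)
        if coords.shape != (n, 3):
            raise StructureError(
                f"coords shape {coords.shape} does not match {n} atoms"
            )
        if not (len(elements) == len(res_seqs) == len(res_names)
                == len(chain_ids) == n):
            raise StructureError("metadata arrays have inconsistent lengths")
        if not np.all(np.isfinite(coords)):
            raise StructureError("non-finite coordinates")
        self.atom_names = list(atom_names)
        self.elements = list(elements)
        self.res_seqs = np.asarray(res_seqs, dtype=int)
        self.res_names = list(res_names)
        self.chain_ids = list(chain_ids)
        self.coords = coords
        self.model_id = int(model_id)
        self._check_unique()

    def _check_unique(self) -> None:
        seen: set[tuple[str, int, str]] = set()
        for ch, rs, an in zip(self.chain_ids, self.res_seqs, self.atom_names):
            key = (ch, int(rs), an)
            if key in seen:
                raise StructureError(
                    f"duplicate atom (chain {ch}, residue {rs}, atom {an})"
                )
            seen.add(key)

    # ---------------------------------------------------------------- basic
    @property
    def n_atoms(self) -> int:
        return len(self.atom_names)

    def __len__(self) -> int:
        return self.n_atoms

    @classmethod
    def from_atoms(cls, atoms: Iterable[AtomRecord], model_id: int = 1
                   ) -> "StructureModel":
        atoms = list(atoms)
        if not atoms:
            raise StructureError("cannot build a model from zero atoms")
        return cls(
            [a.atom_name for a in atoms],
            [a.element for a in atoms],
            [a.res_seq for a in atoms],
            [a.res_name for a in atoms],
            [a.chain_id for a in atoms],
            np.array([a.position for a in atoms], dtype=float),
            model_id=model_id,
        )

    def atoms(self) -> Iterator[AtomRecord]:
        for i in range(self.n_atoms):
            yield AtomRecord(
                self.atom_names[i], self.elements[i], int(self.res_seqs[i]),
                self.res_names[i], self.chain_ids[i], self.coords[i].copy(),
            )

    @property
    def chains(self) -> dict[str, list[int]]:
        """Map chain id -> ordered unique residue numbers in that chain."""
        out: dict[str, list[int]] = {}
        for ch, rs in zip(self.chain_ids, self.res_seqs):
            lst = out.setdefault(ch, [])
            if not lst or lst[-1] != rs:
                if int(rs) not in lst:
                    lst.append(int(rs))
        return out

    def residue_names(self, chain_id: str) -> dict[int, str]:
        """Map residue number -> residue name for one chain."""
        out: dict[int, str] = {}
        for ch, rs, rn in zip(self.chain_ids, self.res_seqs, self.res_names):
            if ch == chain_id:
                out.setdefault(int(rs), rn)
        return out

    def atom_index(self, chain_id: str, res_seq: int, atom_name: str) -> int:
        """Index of one atom; raises KeyError if absent."""
        for i in range(self.n_atoms):
            if (self.chain_ids[i] == chain_id
                    and self.res_seqs[i] == res_seq
                    and self.atom_names[i] == atom_name):
                return i
        raise KeyError(f"no atom (chain {chain_id}, res {res_seq}, {atom_name})")

    def get_position(self, chain_id: str, res_seq: int, atom_name: str
                     ) -> np.ndarray:
        return self.coords[self.atom_index(chain_id, res_seq, atom_name)]

    # ----------------------------------------------------------- derivation
    def with_coords(self, coords: np.ndarray, model_id: int | None = None
                    ) -> "StructureModel":
        """Same topology, new coordinates (metadata lists are shared)."""
        m = StructureModel.__new__(StructureModel)
        m.atom_names = self.atom_names
        m.elements = self.elements
        m.res_seqs = self.res_seqs
        m.res_names = self.res_names
        m.chain_ids = self.chain_ids
        coords = np.asarray(coords, dtype=float)
        if coords.shape != (self.n_atoms, 3):
            raise StructureError("coords shape mismatch in with_coords")
        m.coords = coords
        m.model_id = self.model_id if model_id is None else int(model_id)
        return m

    def subset(self, indices: np.ndarray, model_id: int | None = None
               ) -> "StructureModel":
        idx = np.asarray(indices, dtype=int)
        return StructureModel(
            [self.atom_names[i] for i in idx],
            [self.elements[i] for i in idx],
            self.res_seqs[idx],
            [self.res_names[i] for i in idx],
            [self.chain_ids[i] for i in idx],
            self.coords[idx],
            model_id=self.model_id if model_id is None else model_id,
        )

    def same_topology(self, other: "StructureModel") -> bool:
        if self.n_atoms != other.n_atoms:
            return False
        if self.atom_names is other.atom_names and \
                self.res_seqs is other.res_seqs and \
                self.chain_ids is other.chain_ids:
            return True
        return (self.atom_names == other.atom_names
                and np.array_equal(self.res_seqs, other.res_seqs)
                and self.chain_ids == other.chain_ids
                and self.res_names == other.res_names)

    def first_differing_atom(self, other: "StructureModel") -> str:
        """Human-readable description of the first topology mismatch."""
        n = min(self.n_atoms, other.n_atoms)
        for i in range(n):
            if (self.atom_names[i] != other.atom_names[i]
                    or self.res_seqs[i] != other.res_seqs[i]
                    or self.chain_ids[i] != other.chain_ids[i]):
                return (f"atom {i}: {self.chain_ids[i]}/{self.res_seqs[i]}/"
                        f"{self.atom_names[i]} vs {other.chain_ids[i]}/"
                        f"{other.res_seqs[i]}/{other.atom_names[i]}")
        return f"atom counts differ ({self.n_atoms} vs {other.n_atoms})"

    # ------------------------------------------------------------ selection
    def select_indices(self, expression: str) -> np.ndarray:
        """Indices of atoms matching a selection expression.

        Grammar: clauses joined by ``and``; each clause is one of
        ``chain A[,B]``, ``resseq 40-48[,52]``, ``name N,CA,C``,
        ``resname ALA,GLY``.  Example (the clustering selection for the
        linker peptide): ``"resseq 40-48 and name N,CA,C"``.
        """
        mask = np.ones(self.n_atoms, dtype=bool)
        expr = expression.strip()
        if not expr:
            raise SelectionError("empty selection expression")
        for clause in expr.split(" and "):
            parts = clause.strip().split(None, 1)
            if len(parts) != 2:
                raise SelectionError(f"cannot parse clause {clause!r}")
            key, arg = parts[0].lower(), parts[1].strip()
            if key == "chain":
                wanted = {c.strip() for c in arg.split(",")}
                m = np.array([c in wanted for c in self.chain_ids])
            elif key == "resseq":
                wanted_res: set[int] = set()
                for tok in arg.split(","):
                    tok = tok.strip()
                    if "-" in tok[1:]:  # allow negative singletons
                        lo_s, hi_s = tok.rsplit("-", 1)
                        lo, hi = int(lo_s), int(hi_s)
                        wanted_res.update(range(lo, hi + 1))
                    else:
                        wanted_res.add(int(tok))
                m = np.isin(self.res_seqs, sorted(wanted_res))
            elif key == "name":
                wanted = {n.strip().upper() for n in arg.split(",")}
                m = np.array([n.upper() in wanted for n in self.atom_names])
            elif key == "resname":
                wanted = {n.strip().upper() for n in arg.split(",")}
                m = np.array([n.upper() in wanted for n in self.res_names])
            else:
                raise SelectionError(f"unknown selection keyword {key!r}")
            mask &= m
        return np.nonzero(mask)[0]

    def __repr__(self) -> str:
        return (f"StructureModel(model_id={self.model_id}, "
                f"n_atoms={self.n_atoms}, chains={sorted(set(self.chain_ids))})")


@dataclass(frozen=True)
class NumberingMap:
    """Offset between peptide-local and protein residue numbering.

    ``offset=37`` maps peptide residue 1 to protein residue 38, the
    convention for the PmScsC linker construct.  ``local_min``/``local_max``
    bound the residues the map covers (inclusive, in source numbering).
    """

    offset: int
    local_min: int | None = None
    local_max: int | None = None

    def covers(self, res_seq: int) -> bool:
        if self.local_min is not None and res_seq < self.local_min:
            return False
        if self.local_max is not None and res_seq > self.local_max:
            return False
        return True

    def inverse(self) -> "NumberingMap":
        lo = None if self.local_min is None else self.local_min + self.offset
        hi = None if self.local_max is None else self.local_max + self.offset
        return NumberingMap(-self.offset, lo, hi)


def map_numbering(model: StructureModel, nmap: NumberingMap) -> StructureModel:
    """Renumber residues by ``nmap.offset``; atom order is unchanged.

    Raises :class:`StructureError` listing any residue outside the map.
    """
    outside = sorted({int(r) for r in model.res_seqs if not nmap.covers(int(r))})
    if outside:
        raise StructureError(f"residues outside numbering map: {outside}")
    m = StructureModel(
        model.atom_names, model.elements, model.res_seqs + nmap.offset,
        model.res_names, model.chain_ids, model.coords.copy(),
        model_id=model.model_id,
    )
    return m


class Ensemble:
    """Time-ordered conformers sharing one topology.

    ``times`` are picoseconds, strictly increasing; ``frame_labels`` carries
    per-frame provenance (the source trajectory each frame came from), which
    survives pooling and subsampling.
    """

    __slots__ = ("frames", "times", "source_label", "frame_labels")

    def __init__(
        self,
        frames: Sequence[StructureModel],
        times: Sequence[float],
        source_label: str = "",
        frame_labels: Sequence[str] | None = None,
    ) -> None:
        frames = list(frames)
        if not frames:
            raise StructureError("an ensemble needs at least one frame")
        times_arr = np.asarray(times, dtype=float)
        if times_arr.shape != (len(frames),):
            raise StructureError("len(times) != len(frames)")
        if np.any(np.diff(times_arr) <= 0):
            raise StructureError("frame times must be strictly increasing")
        first = frames[0]
        for k, f in enumerate(frames[1:], start=1):
            if not first.same_topology(f):
                raise StructureError(
                    "frames differ in topology: "
                    + first.first_differing_atom(f)
                )
        if frame_labels is None:
            frame_labels = [source_label] * len(frames)
        elif len(frame_labels) != len(frames):
            raise StructureError("len(frame_labels) != len(frames)")
        self.frames = frames
        self.times = times_arr
        self.source_label = source_label
        self.frame_labels = list(frame_labels)

    def __len__(self) -> int:
        return len(self.frames)

    @property
    def n_frames(self) -> int:
        return len(self.frames)

    def coords(self, indices: np.ndarray | None = None) -> np.ndarray:
        """Stacked coordinates, optionally restricted to atom ``indices``.

        Returns shape (n_frames, n_sel, 3).
        """
        if indices is None:
            return np.stack([f.coords for f in self.frames])
        idx = np.asarray(indices, dtype=int)
        return np.stack([f.coords[idx] for f in self.frames])

    def subset_frames(self, frame_indices: Sequence[int],
                      source_label: str | None = None) -> "Ensemble":
        idx = list(int(i) for i in frame_indices)
        return Ensemble(
            [self.frames[i] for i in idx],
            self.times[idx],
            self.source_label if source_label is None else source_label,
            [self.frame_labels[i] for i in idx],
        )


def pool_ensembles(ensembles: Sequence[Ensemble]) -> Ensemble:
    """Concatenate trajectories into one ensemble, preserving provenance.

    Times of each successive trajectory are offset so the pooled time axis
    stays strictly increasing; per-frame source labels record origin.
    """
    if not ensembles:
        raise StructureError("nothing to pool")
    frames: list[StructureModel] = []
    labels: list[str] = []
    times: list[float] = []
    t_offset = 0.0
    first = ensembles[0].frames[0]
    for ens in ensembles:
        if not first.same_topology(ens.frames[0]):
            raise StructureError(
                "cannot pool ensembles with differing topology: "
                + first.first_differing_atom(ens.frames[0])
            )
        dt = float(np.median(np.diff(ens.times))) if len(ens) > 1 else 1.0
        frames.extend(ens.frames)
        labels.extend(ens.frame_labels)
        times.extend((t_offset + ens.times - ens.times[0] + dt).tolist())
        t_offset = times[-1]
    label = "+".join(dict.fromkeys(e.source_label for e in ensembles))
    return Ensemble(frames, times, source_label=label, frame_labels=labels)
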