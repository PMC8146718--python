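"""Reading and writing PDB coordinate files.

Parsing is delegated to gemmi; coordinates are converted from angstrom to
nanometres exactly once, here.  Multi-model PDB is the ensemble interchange
format: one MODEL record per frame.  Missing residues in a chain (as in
crystal structures with disordered loops) are simply absent from the model —
they are never imputed.

Altloc policy: where alternate conformers exist, the highest-occupancy one
is kept; ties are broken by altloc letter order, which makes reads
deterministic.
"""

from __future__ import annotations

import math
from pathlib import Path
from typing import Sequence

import gemmi
import numpy as np

from .model import Ensemble, StructureError, StructureModel

__all__ = ["PDBParseError", "read_models", "write_models", "ensemble_from_pdb"]

ANGSTROM_PER_NM = 10.0


class PDBParseError(StructureError):
    """Raised when a coordinate file cannot be parsed."""


def _validate_pdb_lines(path: Path) -> None:
    """Cheap pre-scan: every ATOM/HETATM line must carry parseable fields."""
    with open(path, "r", errors="replace") as fh:
        for lineno, line in enumerate(fh, start=1):
            rec = line[:6].strip()
            if rec not in ("ATOM", "HETATM"):
                continue
            if len(line.rstrip("\n")) < 54:
                raise PDBParseError(
                    f"{path}: line {lineno}: truncated {rec} record"
                )
            try:
                int(line[22:26])
                for lo, hi in ((30, 38), (38, 46), (46, 54)):
                    float(line[lo:hi])
            except ValueError as exc:
                raise PDBParseError(
                    f"{path}: line {lineno}: malformed {rec} record ({exc})"
                ) from exc


def read_models(path: str | Path, format: str = "pdb") -> list[StructureModel]:
    """Read a (possibly multi-model) coordinate file into StructureModels.

    Parameters
    ----------
    path:
        PDB file; ``format`` may be ``"pdb"`` or ``"cif"`` (minimal mmCIF
        support via gemmi).
    """
    path = Path(path)
    if not path.exists():
        raise PDBParseError(f"no such file: {path}")
    if path.stat().st_size == 0:
        raise PDBParseError(f"empty coordinate file: {path}")
    if format == "pdb":
        _validate_pdb_lines(path)
        st = gemmi.read_structure(str(path), format=gemmi.CoorFormat.Pdb)
    elif format == "cif":
        st = gemmi.read_structure(str(path), format=gemmi.CoorFormat.Mmcif)
    else:
        raise ValueError(f"unsupported format {format!r}")

    models: list[StructureModel] = []
    for midx, gm in enumerate(st, start=1):
        names: list[str] = []
        elements: list[str] = []
        res_seqs: list[int] = []
        res_names: list[str] = []
        chain_ids: list[str] = []
        coords: list[tuple[float, float, float]] = []
        for chain in gm:
            for res in chain:
                if res.name == "HOH":
                    continue
                # altloc: group atoms by name, keep highest occupancy
                by_name: dict[str, gemmi.Atom] = {}
                for atom in res:
                    prev = by_name.get(atom.name)
                    if prev is None:
                        by_name[atom.name] = atom
                    else:
                        key_new = (-(atom.occ if not math.isnan(atom.occ)
                                     else 1.0), atom.altloc or "~")
                        key_old = (-(prev.occ if not math.isnan(prev.occ)
                                     else 1.0), prev.altloc or "~")
                        if key_new < key_old:
                            by_name[atom.name] = atom
                for atom in res:
                    if by_name.get(atom.name) is not atom:
                        continue
                    names.append(atom.name)
                    elements.append(atom.element.name)
                    res_seqs.append(res.seqid.num)
                    res_names.append(res.name)
                    chain_ids.append(chain.name)
                    coords.append((atom.pos.x / ANGSTROM_PER_NM,
                                   atom.pos.y / ANGSTROM_PER_NM,
                                   atom.pos.z / ANGSTROM_PER_NM))
        if names:
            mid = int(getattr(gm, "num", midx)) or midx
            models.append(StructureModel(
                names, elements, res_seqs, res_names, chain_ids,
                np.array(coords, dtype=float), model_id=mid,
            ))
    if not models:
        raise PDBParseError(f"no atoms found in {path}")
    return models


def _format_atom_name(name: str, element: str) -> str:
    """PDB column-13..16 atom-name alignment."""
    if len(name) >= 4:
        return name[:4]
    if len(element) == 2:
        return f"{name:<4s}"
    return f" {name:<3s}"


def write_models(models: Sequence[StructureModel], path: str | Path) -> None:
    """Write models as a (multi-model) PDB file; nm converted back to angstrom."""
    models = list(models)
    if not models:
        raise StructureError("nothing to write")
    path = Path(path)
    multi = len(models) > 1
    ids = [m.model_id for m in models]
    if len(set(ids)) != len(ids):  # MODEL numbers must be unique in a file
        ids = list(range(1, len(models) + 1))
    lines: list[str] = []
    for model, mid in zip(models, ids):
        if multi:
            lines.append(f"MODEL     {mid:4d}")
        serial = 0
        prev_chain = None
        for i in range(model.n_atoms):
            ch = model.chain_ids[i]
            if prev_chain is not None and ch != prev_chain:
                lines.append("TER")
            prev_chain = ch
            serial += 1
            x, y, z = model.coords[i] * ANGSTROM_PER_NM
            name = _format_atom_name(model.atom_names[i], model.elements[i])
            rec = "ATOM" if model.res_names[i] in _PDB_ATOM_RESNAMES else "HETATM"
            lines.append(
                f"{rec:<6s}{serial % 100000:5d} {name} "
                f"{model.res_names[i]:>3s} {ch[:1]}"
                f"{int(model.res_seqs[i]) % 10000:4d}    "
                f"{x:8.3f}{y:8.3f}{z:8.3f}{1.0:6.2f}{0.0:6.2f}"
                f"          {model.elements[i]:>2s}"
            )
        lines.append("TER")
        if multi:
            lines.append("ENDMDL")
    lines.append("END")
    path.write_text("\n".join(lines) + "\n")


# residue names written as ATOM records (standard amino acids plus caps)
from .model import STANDARD_AA as _STD  # noqa: E402

_PDB_ATOM_RESNAMES = _STD | {"ACE", "NH2"}


def ensemble_from_pdb(
    path: str | Path,
    dt_ps: float = 5.0,
    source_label: str | None = None,
    t0_ps: float | None = None,
) -> Ensemble:
    """Read a multi-model PDB as an :class:`Ensemble`.

    PDB carries no time axis, so frame times are synthesised as
    ``t0 + k*dt`` with ``t0`` defaulting to ``dt`` (the first saved
    configuration of a trajectory written every ``dt`` ps).
    """
    models = read_models(path)
    t0 = dt_ps if t0_ps is None else t0_ps
    times = t0 + dt_ps * np.arange(len(models))
    label = source_label if source_label is not None else Path(path).stem
    return Ensemble(models, times, source_label=label)
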