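"""Secondary chemical shifts, SSP-style propensity scores and Karplus
back-calculation of 3J_HNalpha couplings.

The secondary shift of a nucleus is observed minus random-coil reference
for the same residue type; positive dCa-dCb means helix, negative means
extended structure.  The propensity score normalises windowed secondary
shifts by the fully-formed reference shifts, so +1 reads as a fully helical
ensemble, -1 as fully extended, and intermediate values as the fractional
population of that structure class.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .model import AA_ONE_TO_THREE, AA_THREE_TO_ONE
from .refdata import (HELIX_DELTA, KARPLUS_HN_HA, NUCLEI,
                      RANDOM_COIL_SHIFTS, SHEET_DELTA, coil_j_reference)

__all__ = [
    "ShiftTable",
    "read_shifts_tsv",
    "secondary_shifts",
    "ssp_score",
    "predict_j",
]


@dataclass
class ShiftTable:
    """Per-residue chemical shifts (ppm) for a peptide sequence.

    ``data`` is a DataFrame indexed by residue number with columns
    ``res_name`` (1-letter) and a subset of ``CA``, ``CB``, ``HA`` (NaN
    where unassigned).  ``reference`` records the chemical-shift reference
    compound (DSS by convention).
    """

    data: pd.DataFrame
    reference: str = "DSS"

    def __post_init__(self) -> None:
        if "res_name" not in self.data.columns:
            raise ValueError("ShiftTable needs a res_name column")
        bad = [r for r in self.data["res_name"] if r not in AA_ONE_TO_THREE]
        if bad:
            raise ValueError(f"unknown residue types: {sorted(set(bad))}")

    @property
    def res_seqs(self) -> np.ndarray:
        return self.data.index.to_numpy()

    @property
    def sequence(self) -> str:
        return "".join(self.data["res_name"])

    @classmethod
    def from_records(cls, res_seqs, res_names, shifts: dict[str, list],
                     reference: str = "DSS") -> "ShiftTable":
        df = pd.DataFrame({"res_name": list(res_names)},
                          index=pd.Index(res_seqs, name="res_seq"))
        for nuc, vals in shifts.items():
            df[nuc] = vals
        return cls(df, reference=reference)


def read_shifts_tsv(path: str | Path) -> ShiftTable:
    """Read a long-format shift table.

    Expected columns: ``res_seq``, ``res_name`` (1- or 3-letter), ``atom``
    (CA/CB/HA), ``shift_ppm``.
    """
    long = pd.read_csv(path, sep="\t")
    required = {"res_seq", "res_name", "atom", "shift_ppm"}
    if not required.issubset(long.columns):
        raise ValueError(f"shift TSV needs columns {sorted(required)}")

    def one_letter(name: str) -> str:
        name = str(name).strip().upper()
        return AA_THREE_TO_ONE.get(name, name)

    long = long.assign(res_name=long["res_name"].map(one_letter),
                       atom=long["atom"].str.upper())
    wide = long.pivot_table(index="res_seq", columns="atom",
                            values="shift_ppm", aggfunc="first")
    names = long.groupby("res_seq")["res_name"].first()
    df = pd.DataFrame({"res_name": names})
    for nuc in NUCLEI:
        if nuc in wide.columns:
            df[nuc] = wide[nuc]
    df.index.name = "res_seq"
    return ShiftTable(df)


def _coil_value(res1: str, nucleus: str) -> float:
    try:
        ca, cb, ha = RANDOM_COIL_SHIFTS[res1]
    except KeyError as exc:
        raise ValueError(
            f"no random-coil reference for residue type {res1!r}") from exc
    return {"CA": ca, "CB": cb, "HA": ha}[nucleus]


def secondary_shifts(obs: ShiftTable,
                     coil: ShiftTable | None = None) -> pd.DataFrame:
    """Per-residue secondary shifts: dCA, dCB, dHA, dCA-dCB.

    ``coil`` defaults to the bundled random-coil reference; a residue
    lacking an observed nucleus yields NaN for that delta, never zero.
    """
    rows = {}
    for res_seq, row in obs.data.iterrows():
        res1 = row["res_name"]
        deltas = {}
        for nuc in NUCLEI:
            o = row.get(nuc, np.nan)
            if coil is not None:
                if res_seq not in coil.data.index:
                    raise ValueError(f"coil table lacks residue {res_seq}")
                c = coil.data.loc[res_seq].get(nuc, np.nan)
            else:
                c = _coil_value(res1, nuc)
            deltas["d" + nuc] = float(o) - float(c) \
                if np.isfinite(o) and np.isfinite(c) else np.nan
        deltas["dCA_dCB"] = deltas["dCA"] - deltas["dCB"]
        deltas["res_name"] = res1
        rows[res_seq] = deltas
    out = pd.DataFrame.from_dict(rows, orient="index")
    out.index.name = "res_seq"
    return out[["res_name", "dCA", "dCB", "dHA", "dCA_dCB"]]


# per-nucleus sign that makes a helical shift contribute positively;
# without this alignment Ca (+) and Ha/Cb (-) helix shifts would cancel
_HELIX_SIGN = {k: (1.0 if v >= 0 else -1.0) for k, v in HELIX_DELTA.items()}


def ssp_score(
    deltas: pd.DataFrame,
    window: int = 5,
    weights: dict[str, float] | None = None,
    nuclei: tuple[str, ...] = NUCLEI,
) -> pd.Series:
    """Windowed secondary-structure propensity score per residue.

    score(i) = [sum over window, nuclei of w_k * sign_k * ddelta_obs]
             / [sum over window, nuclei of w_k * |ddelta_ss|]

    where ``ddelta_ss`` is the fully-formed reference shift of the class
    (helix if the windowed numerator is >= 0, sheet otherwise) and
    ``sign_k`` aligns every nucleus so helix contributes positively.
    Windows are truncated at the termini, so a score is reported for every
    residue; ``window`` must be odd.  A residue with no observed nucleus in
    its whole window gives NaN.
    """
    if window < 1 or window % 2 == 0:
        raise ValueError("window must be an odd integer >= 1")
    if weights is None:
        weights = {k: 1.0 for k in nuclei}
    n = len(deltas)
    half = window // 2
    # per-residue, per-nucleus terms
    obs = np.full((n, len(nuclei)), np.nan)
    for j, nuc in enumerate(nuclei):
        col = "d" + nuc
        if col in deltas.columns:
            obs[:, j] = deltas[col].to_numpy(dtype=float)
    w = np.array([weights.get(k, 0.0) for k in nuclei])
    sgn = np.array([_HELIX_SIGN[k] for k in nuclei])
    helix_mag = np.array([abs(HELIX_DELTA[k]) for k in nuclei])
    sheet_mag = np.array([abs(SHEET_DELTA[k]) for k in nuclei])
    scores = np.full(n, np.nan)
    present = np.isfinite(obs)
    for i in range(n):
        lo, hi = max(0, i - half), min(n, i + half + 1)
        m = present[lo:hi]
        if not m.any():
            continue
        num = float(np.nansum((obs[lo:hi] * sgn * w)[m]))
        mag = helix_mag if num >= 0 else sheet_mag
        den = float(((np.ones_like(obs[lo:hi]) * mag * w)[m]).sum())
        scores[i] = num / den if den > 0 else np.nan
    return pd.Series(scores, index=deltas.index, name=f"SSP_w{window}")


def predict_j(
    phi_samples: dict[int, np.ndarray],
    karplus: tuple[float, float, float] = KARPLUS_HN_HA,
    sequence: dict[int, str] | None = None,
) -> pd.DataFrame:
    """Ensemble-averaged 3J_HNalpha per residue, with a coil reference.

    ``phi_samples`` maps residue number to an array of phi angles in
    degrees (a single-element array gives the pointwise Karplus value).
    If ``sequence`` (residue number -> 1-letter code) is given, the coil
    reference accounts for the preceding residue's type.
    J values are clipped to the physically meaningful [0, 12] Hz range.
    """
    a, b, c = karplus
    rows = {}
    for res, phis in sorted(phi_samples.items()):
        phis = np.atleast_1d(np.asarray(phis, dtype=float))
        if phis.size == 0:
            raise ValueError(f"residue {res}: empty phi sample set")
        x = np.cos(np.radians(phis - 60.0))
        j = float(np.mean(a * x * x + b * x + c))
        prev = sequence.get(res - 1) if sequence else None
        rows[res] = {"J_pred": np.clip(j, 0.0, 12.0),
                     "J_coil": coil_j_reference(prev)}
    out = pd.DataFrame.from_dict(rows, orient="index")
    out.index.name = "res_seq"
    return out
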