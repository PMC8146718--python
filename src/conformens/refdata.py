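"""Bundled reference tables for the NMR propensity calculations.

Random-coil chemical shifts (ppm, DSS-referenced) follow the peptide
random-coil compilation of Wishart et al., J. Biomol. NMR 5 (1995) 67-81.
The fully-formed secondary-structure reference shifts (helix / sheet
deltas) are class-average values of the kind used by shift-based
secondary-structure propensity methods; they are uniform across residue
types, a documented simplification.

The random-coil 3J_HNalpha table is MODEL-DERIVED (synthetic in that
sense): it is the Karplus-equation expectation over a two-state coil
phi mixture (a beta-region and an alpha-region well), with the beta
weight adjusted by the class of the preceding residue (beta-branched or
aromatic predecessors shift the coil ensemble toward extended phi, glycine
the other way).  It stands in for published preceding-residue-dependent
coil predictions, which are not bundled here.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "RANDOM_COIL_SHIFTS",
    "HELIX_DELTA",
    "SHEET_DELTA",
    "NUCLEI",
    "KARPLUS_HN_HA",
    "coil_j_reference",
]

#: residue (1-letter) -> (Calpha, Cbeta, Halpha) random-coil shift, ppm.
#: Glycine has no Cbeta (NaN).
RANDOM_COIL_SHIFTS: dict[str, tuple[float, float, float]] = {
    "A": (52.5, 19.1, 4.32),
    "R": (56.0, 30.9, 4.34),
    "N": (53.1, 38.9, 4.74),
    "D": (54.2, 41.1, 4.64),
    "C": (58.2, 28.0, 4.55),
    "Q": (55.7, 29.4, 4.34),
    "E": (56.6, 29.9, 4.35),
    "G": (45.1, float("nan"), 3.96),
    "H": (55.0, 29.0, 4.73),
    "I": (61.1, 38.8, 4.17),
    "L": (55.1, 42.4, 4.34),
    "K": (56.2, 33.1, 4.32),
    "M": (55.4, 32.9, 4.48),
    "F": (57.7, 39.6, 4.62),
    "P": (63.3, 31.7, 4.42),
    "S": (58.3, 63.8, 4.47),
    "T": (61.8, 69.8, 4.35),
    "W": (57.5, 29.6, 4.66),
    "Y": (57.9, 38.8, 4.55),
    "V": (62.2, 32.9, 4.12),
}

NUCLEI = ("CA", "CB", "HA")

#: fully-formed secondary shift (observed minus coil) for each nucleus, ppm
HELIX_DELTA: dict[str, float] = {"CA": 2.8, "CB": -0.5, "HA": -0.38}
SHEET_DELTA: dict[str, float] = {"CA": -1.5, "CB": 2.2, "HA": 0.38}

#: Karplus coefficients (A, B, C) in Hz for 3J(HN-Halpha) vs phi,
#: J = A cos^2(phi - 60) + B cos(phi - 60) + C  (a standard parameterisation)
KARPLUS_HN_HA: tuple[float, float, float] = (6.51, -1.76, 1.60)

# coil phi mixture used to derive the model coil-J reference
_COIL_BETA_PHI = -120.0   # extended well centre, degrees
_COIL_ALPHA_PHI = -65.0   # alpha well centre, degrees
_COIL_BETA_WEIGHT = 0.60  # baseline extended-well population

#: preceding-residue classes adjusting the extended-well weight
_BETA_BRANCHED_OR_AROMATIC = set("IVTFYW")


def _karplus(phi_deg: float, coeffs=KARPLUS_HN_HA) -> float:
    a, b, c = coeffs
    x = np.cos(np.radians(phi_deg - 60.0))
    return float(a * x * x + b * x + c)


def coil_j_reference(preceding_residue: str | None) -> float:
    """Model random-coil 3J_HNalpha (Hz) given the preceding residue type.

    Baseline coil ensemble: 60% extended (phi = -120) / 40% alpha
    (phi = -65).  A beta-branched or aromatic predecessor raises the
    extended weight to 0.67; a glycine predecessor lowers it to 0.53.
    """
    w_beta = _COIL_BETA_WEIGHT
    if preceding_residue is not None:
        p = preceding_residue.upper()
        if p in _BETA_BRANCHED_OR_AROMATIC:
            w_beta = 0.67
        elif p == "G":
            w_beta = 0.53
    return (w_beta * _karplus(_COIL_BETA_PHI)
            + (1.0 - w_beta) * _karplus(_COIL_ALPHA_PHI))
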