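import numpy as np
import pytest

from conformens.model import AtomRecord, StructureModel
from conformens.synth import (LINKER_SEQUENCE, EnsembleDesign,
                              build_backbone, sample_ensemble)

N_RES = len(LINKER_SEQUENCE)


@pytest.fixture(scope="session")
def helix_model():
    """Ideal alpha-helical 13-mer (phi = -57, psi = -47), protein numbering."""
    return build_backbone(LINKER_SEQUENCE,
                          np.full(N_RES, -57.0), np.full(N_RES, -47.0))


@pytest.fixture(scope="session")
def strand_model():
    """Extended 13-mer (phi = -120, psi = +120)."""
    return build_backbone(LINKER_SEQUENCE,
                          np.full(N_RES, -120.0), np.full(N_RES, 120.0))


# The three-conformer-class recovery fixture: narrow torsion wells (6 deg)
# so the classes are cleanly separated in RMSD (intra-class diameter well
# below the 0.25 nm cutoff used in the recovery tests, inter-class minimum
# well above it), independent frames so class counts are binomial.
THREE_BASIN_WEIGHTS = (("alpha", 0.4), ("beta", 0.35), ("hairpin", 0.25))
THREE_BASIN_SEED = 2024
THREE_BASIN_SD = 6.0
THREE_BASIN_CUTOFF = 0.25
CLUSTER_SELECTION = "resseq 40-48 and name N,CA,C"


def make_three_basin_design(n_frames: int = 600,
                            seed: int = THREE_BASIN_SEED) -> EnsembleDesign:
    return EnsembleDesign(
        basin_weights=THREE_BASIN_WEIGHTS, switching_prob=1.0,
        n_frames=n_frames, seed=seed, sd_override=THREE_BASIN_SD)


@pytest.fixture(scope="session")
def three_basin_600():
    """600-frame three-class ensemble with ground-truth labels."""
    ens, labels, states = sample_ensemble(make_three_basin_design())
    return ens, labels


@pytest.fixture()
def salt_bridge_assembly():
    """Two-chain toy assembly: Asp OD1 (chain A) 0.35 nm from Lys NZ (B)."""
    atoms = [
        AtomRecord("N", "N", 41, "ASP", "A", np.array([0.0, 0.5, 0.0])),
        AtomRecord("CA", "C", 41, "ASP", "A", np.array([0.1, 0.4, 0.0])),
        AtomRecord("CB", "C", 41, "ASP", "A", np.array([0.2, 0.3, 0.0])),
        AtomRecord("CG", "C", 41, "ASP", "A", np.array([0.3, 0.2, 0.0])),
        AtomRecord("OD1", "O", 41, "ASP", "A", np.array([0.4, 0.1, 0.0])),
        AtomRecord("OD2", "O", 41, "ASP", "A", np.array([0.3, 0.05, 0.1])),
        AtomRecord("N", "N", 120, "LYS", "B", np.array([1.1, 0.3, 0.0])),
        AtomRecord("CA", "C", 120, "LYS", "B", np.array([1.0, 0.2, 0.0])),
        AtomRecord("NZ", "N", 120, "LYS", "B", np.array([0.75, 0.1, 0.0])),
    ]
    return StructureModel.from_atoms(atoms)
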