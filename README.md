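# conformens

Conformational-ensemble analysis for short peptides, built around the
workflow used to characterise the PmScsC linker peptide (sequence
**KKADEQQAQFRQA**, protein residues 38–50) — a "shape-shifter" segment that
appears as an α-helix, a β-strand or a loop in different crystal forms of
the trimeric disulphide isomerase, yet is essentially disordered in
solution.

The package answers the questions that characterisation poses, on any
multi-model ensemble of a short peptide:

- **Which hydrogen bonds exist, and how often?**  A purely geometric
  criterion: a bond exists iff the H···acceptor distance is **< 0.25 nm**
  and the donor–H–acceptor angle is **> 135°** (both strict).  Per-bond
  populations over an ensemble reproduce the layout of trajectory H-bond
  tables (`"45 NH-41 O"` = amide of residue 45 donating to the carbonyl of
  41).  Bonds at donor–acceptor offset *i*→*i−4* are α-helical,
  *i*→*i−3* are 3₁₀-type.
- **What conformational families are present?**  Greedy neighbour-counting
  (Daura) clustering on the Kabsch-minimised RMSD of backbone N, CA, C
  atoms of the central residues (40–48), cutoff 0.15 nm, on frames 10 ps
  apart — with per-cluster populations, source-trajectory provenance and
  Ramachandran-run annotation (≥ 2 adjacent residues in the α or β basin).
- **How helical is the peptide by NMR?**  Secondary shifts
  (ΔCα−ΔCβ, ΔHα against a bundled random-coil reference), a windowed
  secondary-structure propensity score (+1 fully helical, −1 fully
  extended, read as a fractional population), and Karplus back-calculation
  of ³J_HNα from φ ensembles with a preceding-residue-dependent coil
  reference.
- **What stabilises each conformation in a crystal?**  Residue-level
  inter-chain contact maps (van der Waals / hydrogen bond / salt bridge by
  distance criteria) for multi-chain assemblies.

Because MD trajectories are rarely redistributable, a first-class
**synthetic generator** builds peptide backbones from torsion angles
(NeRF-style internal-coordinate placement), samples trajectory-like
ensembles whose frames hop between Ramachandran basins under a Markov
rule with known ground-truth labels, and synthesises chemical-shift tables
at a prescribed helicity — so every analysis stage has a closed-loop
recovery test.

## Worked example

```python
import numpy as np
from conformens import (build_backbone, detect_hbonds, classify_helix_bond,
                        sample_ensemble, EnsembleDesign, daura_cluster,
                        synth_shifts, secondary_shifts, ssp_score)

# an ideal alpha-helical 13-mer shows the full i -> i-4 hydrogen-bond ladder
helix = build_backbone("KKADEQQAQFRQA", np.full(13, -57.0), np.full(13, -47.0))
bonds = [b for b in detect_hbonds(helix) if b.is_backbone_backbone]
print(len(bonds), bonds[3].bond_id, classify_helix_bond(bonds[3]))
# -> 9 45 NH-41 O alpha_i_i4

# a three-class synthetic ensemble is recovered as three pure clusters
design = EnsembleDesign(
    basin_weights=(("alpha", 0.4), ("beta", 0.35), ("hairpin", 0.25)),
    switching_prob=1.0, n_frames=600, seed=2024, sd_override=6.0)
ens, labels, _ = sample_ensemble(design)
cs = daura_cluster(ens, "resseq 40-48 and name N,CA,C", 0.25)
print(len(cs.clusters), [c.size for c in cs.clusters])
# -> 3 [236, 192, 172]

# propensity scores close the loop on a 10%-helical shift table
scores = ssp_score(secondary_shifts(synth_shifts(0.10, noise_sd=0.0)), window=5)
print(round(float(scores.mean()), 3))
# -> 0.1
```

A score of ~0.10 reads as ~10 % of the ensemble populating a regular
helical conformation — the disordered-peptide regime.

There is also a CLI (`conformens analyze-ensemble | cluster | hbonds |
contacts | nmr | synth`); `conformens --help` lists the stages.

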