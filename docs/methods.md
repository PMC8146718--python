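# Methods

This note documents the models, conventions and numerical choices behind
`conformens`, and what the synthetic-data closures do and do not
demonstrate about real data.

## Units, numbering, coordinates

All internal distances are nanometres; conversion from the ångström of PDB
files happens once, at ingest.  Angles are degrees in (−180°, 180°] with
the IUPAC sign convention (cross-checked against MDAnalysis).  Author
residue numbering is preserved verbatim; for the PmScsC linker construct
the peptide-local residues 1–13 map to protein residues 38–50
(`NumberingMap(offset=37)`), and all public selections use protein
numbering — the clustering selection "residues 40–48" is peptide residues
3–11.  Altloc conflicts keep the highest-occupancy conformer (ties by
altloc letter), making reads deterministic.  Missing residues stay
missing; nothing is imputed.  Hydrogens are never constructed at read
time — placement is an explicit geometry operation, keeping I/O lossless.

## Hydrogen bonds

A bond exists iff d(H···A) < 0.25 nm **and** ∠(D–H–A) > 135°, both
inequalities strict, matching the "smaller than"/"larger than" reading of
the criterion.  Donors are backbone amides plus the standard side-chain
N–H/O–H groups (Arg, Lys, Gln, Asn, Ser, Thr, Tyr, Trp); acceptors are
backbone carbonyls plus side-chain carbonyl/carboxylate/hydroxyl oxygens.
An amide may donate to its own residue's side chain (bonds like
"46 NH-46 OE1" are real in trajectory tables).  Detection is an exhaustive
vectorised all-pairs scan; the tests hold it equal to an independent
naive double loop.  Bond identifiers follow trajectory-table conventions:
backbone amide → `NH`, carbonyl → `O`; side-chain hydrogens map from PDB
names by prefixing `N` (HE22 → NHE22) except geminal `HH*` names, which
collapse onto the nitrogen (HH11 → NH11); hydroxyl donors are labelled by
their oxygen.

For X-ray inputs, amide hydrogens are placed analytically: 0.100 nm from
N, in the C(i−1)–N–CA plane, opposite the bisector of the two N bonds.
Prolines and chain N-termini get none.  This analytic placement can
differ from force-field-built hydrogens at the ~0.01 nm level, which is
one reason populations on crystal structures should be read as geometric,
not energetic, statements.

Interface contacts between chains are residue-level distance proxies:
any heavy-atom pair ≤ 0.4 nm is a contact; polar N/O pairs ≤ 0.35 nm are
classed `hbond` (crystal structures carry no hydrogens, so the strict
H-based criterion cannot be applied there); acidic carboxylate oxygen to
basic side-chain nitrogen ≤ 0.4 nm is a `saltbridge`, which takes
precedence.  No buried-surface-area or interface free-energy scoring is
attempted.

## Clustering

The Daura greedy algorithm: compute, among unassigned frames, each
frame's neighbour count (RMSD ≤ cutoff, self included); the frame with
the most neighbours becomes a centre and its neighbourhood a cluster;
remove and repeat.  Ties break to the lowest frame index, so runs are
bit-reproducible; a frame with no neighbours is a singleton; every frame
lands in exactly one cluster.  Clusters are numbered by decreasing size.
RMSD uses the same atom selection for fitting and evaluation (backbone
N/CA/C of residues 40–48 by default, cutoff 0.15 nm, frames 10 ps apart).
Subsampling keeps frames at t = k·spacing for k ≥ 1 — the t = 0 frame is
excluded, which is what makes four 100 ns trajectories saved every 5 ps
pool to exactly 40,000 frames at 10 ps spacing.

The pairwise RMSD matrix is computed with the singular-value identity
(min RMSD² = (‖x‖² + ‖y‖² − 2(σ₁+σ₂±σ₃))/n on centred coordinates,
batched 3×3 SVDs).  The identity loses precision by cancellation when the
true RMSD is near zero, so entries below 10⁻⁶ nm are recomputed from the
explicit rotated residual, restoring 10⁻⁹-level accuracy for
rigid-transform invariance.  Kabsch superposition guards the reflection
branch (det = +1 always) and refuses collinear point sets, where the
rotation is not unique.

## Ramachandran annotation

Basin boxes (configurable; these defaults are this package's convention,
not a claim about any particular published figure):
α: φ ∈ [−160°, −20°], ψ ∈ [−90°, +30°];
β: φ ∈ [−180°, −45°], ψ ∈ [45°, 180°] ∪ [−180°, −150°].
Runs of ≥ 2 adjacent residues with the same α/β label are reported as
segments; a lone residue is not a segment.

## NMR propensity

Secondary shifts are observed minus random-coil reference per nucleus
(Cα, Cβ, Hα); the bundled coil set is the peptide compilation of Wishart
et al. (1995), DSS-referenced.  The propensity score is

score(i) = Σ_win Σ_k w_k·s_k·Δδ_obs / Σ_win Σ_k w_k·|Δδ_ss(class)|

with uniform nucleus weights w_k by default, the class (helix/sheet)
chosen by the sign of the windowed numerator, and s_k the sign of the
helix reference for nucleus k (+ for Cα, − for Cβ and Hα).  The sign
alignment is a deliberate design choice: without it the Cα and Hα helix
contributions would cancel in the raw sum.  Fully-formed reference shifts
are class averages (helix: +2.8/−0.5/−0.38 ppm; sheet: −1.5/+2.2/+0.38
ppm for Cα/Cβ/Hα), uniform across residue types — a simplification that
makes the score exactly linear in helicity, at the cost of residue-level
fidelity to any specific published reference set.  Exact per-residue
agreement with published propensity profiles is therefore not asserted
anywhere.  Windows are truncated at the termini so every residue gets a
score; the default window is 5 residues, and window 1 disables averaging.

³J_HNα is back-calculated by the Karplus equation
J = A·cos²(φ−60°) + B·cos(φ−60°) + C with A, B, C = 6.51, −1.76, 1.60 Hz
(a standard HN–Hα parameterisation, configurable), averaged over the φ
ensemble.  φ = −57° gives 3.74 Hz, near the canonical regular-helix value.
The random-coil J reference is model-derived (and labelled as such): the
Karplus expectation over a two-state coil φ mixture (60 % extended at
−120°, 40 % α at −65°), with the extended weight raised to 0.67 after a
β-branched/aromatic residue and lowered to 0.53 after glycine.  It stands
in for published preceding-residue-dependent coil predictions and should
be treated as a qualitative baseline (≈ 7.8 Hz), not a literature value.

## Synthetic generator

Backbones grow by internal-coordinate (NeRF-style) placement with
standard bond lengths (N–CA 0.1458, CA–C 0.1525, C–N 0.1329, C=O 0.1231,
N–H 0.100 nm) and angles; ω is fixed at 180° (no cis sampling); Cβ is a
tetrahedral stub and side chains beyond it are omitted — every in-scope
backbone analysis needs only backbone + Cβ.  Optional N-acetyl and
C-amide caps add a carbonyl acceptor and an NH₂ donor respectively.
Building is exact: measured torsions equal requested torsions to 10⁻⁶°.

Ensembles draw per-residue (φ, ψ) from wrapped-normal wells (α at
−57/−47, β at −120/+130, ppII at −75/+145; default width 12°, a
realistic basin fluctuation).  Frame-to-frame correlation follows a
Markov redraw rule with probability `switching_prob`; `collective=True`
(default) hops the whole peptide between wells as one unit, the regime of
a short peptide exchanging between conformational families.  The
"hairpin" state is a conformer class, not a well: turn-region residues
(default the three central ones) draw α and the flanks β, which produces
compact hairpin-like conformers with short N-terminal-NH⋯C-terminal-CO
distances.  Shift tables are coil + f·Δδ_helix + Gaussian noise
(default 0.05 ppm, a realistic assignment uncertainty), using the same
reference tables as the analysis, so propensity recovery is exact in the
noise-free limit.

The generator emulates statistical structure only.  Passing recovery
tests shows the analysis chain is correct and self-consistent; it does
not show that any force field samples these basins with these weights,
nor that real shift dispersions follow the uniform class-average
references.

### Study conditions used by the tests and the acceptance script

- Frame bookkeeping uses the real trajectory arithmetic (4 × 100 ns at
  5 ps, 10 ps spacing → 40,000 frames) on lightweight shared-coordinate
  frames, so it runs in seconds.
- The three-class recovery fixture uses 600 independent frames
  (switching probability 1, so class counts are exactly binomial), well
  width 6° and cutoff 0.25 nm.  The narrow wells and the wider-than-
  default cutoff realise the separation regime the recovery test is
  about (intra-class RMSD diameter ≈ 0.14–0.24 nm, inter-class minimum
  ≈ 0.28–0.45 nm on the fitted selection, measured at design time);
  recovery is then exact across seeds.  With the default 12° wells the
  classes overlap in RMSD and greedy clustering fragments them — that
  regime is exercised by the oracle-equivalence tests instead, which
  assert partition identity rather than purity.
- Propensity recovery averages 20 noisy replicates at helicity 0.10,
  mirroring the reading that a mean score of ~0.10 corresponds to ~10 %
  helical population.

## Known limitations

- No trajectory-format readers beyond multi-model PDB (by design); no
  DSSP-style H-bond-energy secondary structure; no helix–coil partition
  functions; no interface surface-area scoring.
- NMR-STAR input is not parsed; shift tables are TSV.
- The Cβ stub's chirality convention is fixed but arbitrary; no analysis
  in the package depends on it.
- Interface "hbond" classification on crystal structures is a heavy-atom
  distance proxy and will over-count relative to a hydrogen-explicit
  criterion.
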