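# Methods

This note documents the model, the sampler, the estimators, the defaults
and the design decisions behind them.  It states no empirical number that
the test suite or `scripts/acceptance.py` does not itself compute.

## The coarse-grained model

**Beads.** Three beads per nucleotide: P at the phosphate, S at C1', B at
the glycosidic nitrogen (N9 for purines, N1 for pyrimidines).  The S
anchor is a configurable choice (`map_pdb_to_beads` and the template use
C1'; switching to C4' is a one-line change in the template constants).

**Rigid helices.** Maximal stacks of consecutive canonical pairs are
grouped into rigid bodies with ideal A-form geometry generated from
fiber-like cylindrical parameters: rise 2.81 Å, twist 32.7° per step,
S beads at radius 9.4 Å (C1'–C1' ≈ 10.4 Å across a pair), B beads at
radius 8.0 Å, P beads at 9.7 Å midway between consecutive sugars.  Every
equilibrium bond length and backbone angle of the force field is
*measured from this template*, so built helices are exactly strain-free.

**Energy function.**

| term | form | default |
| --- | --- | --- |
| bonds (P–S, S–B, S–P(+1), B–X) | k(r − r₀)² | k = 20 kcal/mol/Å², r₀ from template |
| backbone angles (P–S–P, S–P–S) | k(θ − θ₀)² | k = 2 kcal/mol/rad² (weak: unpaired residues stay freely rotatable) |
| backbone dihedrals | k(1 − cos(φ − φ₀)) | canonical-pair constant 4 kcal/mol; noncanonical-pair residues feel one fourth of it; applied only to noncanonical-pair residues, because canonical in-helix torsions are already fixed by the rigid groups |
| excluded volume | k(σᵢⱼ − r)², r < σᵢⱼ = rᵢ + rⱼ | k = 10 kcal/mol/Å²; radii P 2.1, S 2.9, B 2.8, X 2.8 Å |
| paired-base attraction | flat −ε to 7.5 Å, linear to 0 at 10 Å | ε = 0.5 kcal/mol, exclusively between base beads of (noncanonical) paired residues |

Pairs within three bonds of each other, beads of the same rigid group,
and all bead combinations inside a noncanonical pair are excluded from
the repulsion (1–4 backbone neighbors sit at A-form stacking distance,
inside the repulsive core).  Electrostatics and any other attraction are
deliberately absent: the model isolates connectivity + sterics.  The
exact constants of the original coarse-grained force field are not
public; these defaults were chosen once on physical grounds (helices can
neither self-clash nor thread through one another; single strands are
close to freely jointed) and every constant is overridable from a
key=value config (`rnatopo show-config`).

**Noncanonical internal-loop pairs** are declared only through the
pair-list input channel.  One of the two bases — the purine when exactly
one member is a purine, else the 5'-most — carries an extra steric bead
(bonded at 4 Å) that fills the pair volume; the pair is tied by
flat-bottom NOEs (B–B 5.5–7.5 Å, S–S 11–14 Å, f_max = k_min = k_max =
2 kcal/mol/Å²) and feels the weak base–base attraction.

**Restraints.** NOEs are flat-bottom with harmonic walls and a linear
continuation once the restraint force reaches f_max; dihedral restraints
use the periodic K(1 − cos(φ − φ₀)) form; the radius-of-gyration
restraint is harmonic in R_g (target configurable, default constant
10 kcal/mol/Å² — the target is prescribed, the constant is not).  The
triple-helix (TH) roster restrains eight S-bead pairs plus the two
backbone torsions spanning the P4→P6 step with K = 50 kcal/mol.  Without
reference coordinates (the crystal structure is an optional download) the
NOE windows default to 4–12 Å and the P4/P6 torsion targets to the values
of an ideal continuous A-form stack — the native triple helix is P4/P6
coaxial, so the ideal-stack torsions are the natural stand-in for the
crystal values.  With reference coordinates, windows are ±1 Å of the
measured distances and torsion targets are the measured angles.

## Initial conformation

Chains are laid out from the secondary-structure tree: a depth-first walk
places non-crossing helices as rigid template copies along the walk
direction, branches splay by ~35–55°, and unpaired residues step ~6 Å.
A maximal non-crossing helix subset forms the tree; pseudoknot helices
are then snapped to template geometry by superposing the template onto
the walk positions of their own strands.  A seeded relaxation run (plain
300 K MC with sterics on throughout, so closing the stretched pseudoknot
bonds cannot thread the chain through a helix) anneals the layout until
every bond is within 1 Å of rest length and the worst steric overlap is
below 0.8 Å; the build retries with fresh relaxation seeds (12 stages)
before failing with diagnostics.

## Monte Carlo and replica exchange

Equilibrium observables depend only on the Boltzmann distribution, so
Metropolis MC replaces the original molecular dynamics.  "Steps" are MC
moves; published dynamics step counts are treated as sampling-effort
guidance, not equivalences.  The proposal catalog is static:

* **bead** displacements (free beads, ±0.7 Å cube);
* **crankshaft** rotations of unpaired runs about the axis through their
  flanking anchors (±1.2 rad), plus per-helix cranks about the axis
  through the helix's two external backbone anchors (quarter amplitude);
* **rigid-subtree** rotations about the attachment bead (±1.0 rad).  A
  subtree is any chain interval no base pair crosses — the
  pseudoknot-safe generalization of pivot moves; the smaller side of the
  cut moves.  Moves that would split a rigid group are simply not in the
  catalog (proposing and rejecting them would burn cycles at these bond
  constants without changing the sampled distribution);
* **pinned-helix** wiggles (small rotation about the centroid plus small
  translation) — together with the helix cranks, the only global channel
  for pseudoknot helices, which belong to no valid subtree;
* **tapered junction** moves: a helix (or a directly stacked helix
  tandem, e.g. a coaxial step) rotates as a rigid body by ±0.45 rad while
  up to three flanking unpaired residues follow with decaying fractions
  (0.7/0.45/0.2) of the rotation.  This spreads the boundary strain over
  the linkers and is the main accelerator of interhelical orientation
  mixing.  Tapered motion is not rigid, so these entries evaluate all
  touched energy terms including within-set sterics.

All proposals are symmetric (uniform axes, symmetric angle/displacement
distributions, state-independent entry selection), giving plain
Metropolis acceptance and detailed balance per move class.  Replica
exchange uses neighbor-only swaps in alternating parity sweeps with the
standard min(1, exp[(βᵢ − βⱼ)(Eᵢ − Eⱼ)]) rule; the default ladder is
eight exponentially spaced temperatures spanning 300–400 K with
exchanges every 500 moves.  Analysis uses the bottom-temperature (300 K)
series with a configurable equilibration cutoff (default: first 1 % of
recorded frames; the study runs use 10 %).  All randomness derives from
a single seed through `numpy.random.SeedSequence`; replica trajectories
are bit-reproducible given (seed, config).

## Estimators

**Euler angles.** Helix frames: z along the best-fit helix axis oriented
5'→3' of the reference strand (obtained by superposing the ideal
template onto the helix's sugar beads — exact for built helices), x
toward the reference 5' sugar bead projected ⊥ z, y = z × x.  The
relative rotation A→B is decomposed in the ZYZ convention; at the gimbal
locus (β = 0 or 180°) γ := 0.  The original frame convention of the
field is not restated in public sources; this one is fixed and
documented.  Fractions and mutual information are convention-robust
(relabeling bins); absolute angle values are not, and are flagged as
convention-dependent wherever reported.

**Fractions.** F_samp = occupied bins / total bins on the (α, β, γ) grid
(10° default; 30°/60° for 2× and 3× joint junction grids).  No sin β
volume correction is applied — the statistic is the raw occupied
fraction, and any reference constant must use the same convention.
Bin edges start at −180° (α, γ) and 0° (β); edge samples belong to the
higher bin (β = 180° to the last bin).  F_norm divides the 60°-bin
fraction of a density-matched random subsample (N_conf chosen to keep
N_conf/N_bin equal to the reference's) by the externally supplied
reference fraction; the reference constant is never defaulted.

**Mutual information.** Plug-in MI on 45° bins, reported in bits;
MI_norm = MI/H(X,Y).  The analytic first-order occupancy bias
(K_xy − K_x − K_y + 1)/(2N ln 2) is attached to every estimate.  For
finite MC runs a second, usually larger inflation comes from temporal
correlation: both series drift through orientation basins on the same
clock, which the occupancy term does not capture.  `mi_norm_excess`
therefore also reports a circular-shift null — MI_norm of the same two
series with one circularly time-shifted, which preserves marginals and
autocorrelation while destroying instantaneous coupling — and the excess
over it.  Genuine correlation survives the subtraction (verified on
synthetic correlated rotation pairs); pure sampling artifacts do not.
Desk-scale MI values quoted by this package are such excess values.

**Free energies.** ΔG_topo = −RT ln(p/(1−p)) at T = 300 K (R =
1.9872×10⁻³ kcal/(mol·K)); contact probability p counts frames with at
least `min_pairs` S-bead pairs under the 14 Å cutoff (1 for
residue-level maps, 2 for TL/TLR and J6/P3 contacts).  Errors come from
a seeded block bootstrap over contiguous frame blocks (default 50
blocks, 1000 resamples).  p ∈ {0, 1} yields a one-sided bound from the
pseudocount 1/(N+1); bounds are flagged and never silently aggregated
with values.  ΔΔG_coop is the conditional-minus-unconditional
difference, computed either from a restrained companion ensemble or by
masking unrestrained frames with the P4/P6 coaxial-stacking proxy
(β_h(P4,P6) > 150° and facing end-pair centroid gap < 7 Å; thresholds
configurable — the published stacking criteria are not public, and at
desk scale the strict thresholds fire rarely, so the property tests use
a documented relaxed variant).  ΔG_fold applies the reference-transfer
relation with the experimental reference (−0.3 kcal/mol) and simulated
reference penalty (2.9 kcal/mol) as defaults.  The Gaussian-chain pivot
estimate is ΔΔG = −RT·(3/2)·ln(n_b/n_a).

## Synthetic data

The generators emulate, with exact embedded ground truth: ideal freely
jointed chains (⟨R_ee²⟩ = n b²), rotation pairs with tunable correlation
(0 = independent uniform, 1 = identical, intermediate = perturbation by
a shrinking random rotation; MI monotone in the parameter), and
two-bead contact ensembles with exact Bernoulli contact probability.
They are deterministic under fixed seeds.  What they do **not** emulate:
temporal correlation of MC trajectories (frames are i.i.d.), real
force-field geometry, or any sequence dependence — so passing estimator
tests on them certifies the statistics, not the physics.

The *Azoarcus* fixture is data, not code: TSV files reconstructed from
the published secondary structure and restraint-roster residue
identities (crystal numbering 12–206 per PDB 1U6B chain B).  Helix
fills and most linker identities are synthetic placeholders — hence the
fixture name — but the helix architecture, both pseudoknots, the GAAA
loops, the 11-nt receptors, the P9/P9A bulge and the linker lengths
match the published description, and two alternative internal-loop pair
sets can be supplied as alternate pair-list files.  The tethered
TL/TLR reference fixture is a GAAA-tetraloop hairpin joined by a 9-nt
oligo-U tether to an 11-nt-receptor hairpin whose residues 26–50 are
held by backbone dihedral restraints (K = 50 kcal/mol) around the built
receptor conformation.

## Problem sizes and numerical choices

The study-scale runs use eight replicas recording every 20 moves: the
shared test ensembles pool two independent unrestrained runs of 3×10⁵
MC moves per replica (global-arrangement modes decorrelate between
runs), the restrained companion run uses 4×10⁵ moves after a fold-in
stage (boosted NOE constants assemble the motif, since restrained
sampling is meant to start with the restraints satisfied), and
`scripts/acceptance.py` uses 7×10⁵ / 5×10⁵ moves per replica.  Global quantities (R_g, the strongly sampled
contacts, the temporal-null MI) are stable at this scale; absolute
occupied-bin fractions and rare-contact penalties converge from below
and reach their long-run values only with substantially longer runs —
re-running the same estimators with larger `total_steps` is the intended
path to full-fidelity numbers.  Known limitations: the pseudoknot core
(P3/P7) is the slowest-mixing degree of freedom, so its pairwise
fraction is the most underestimated at fixed budget; absolute ΔG_topo
values inherit the stand-in excluded-volume constants (orderings and
signs are robust to them, magnitudes shift by a few tenths of a
kcal/mol); and the exchange acceptance pattern of the MC energy scale is
denser than that of the original dynamics engine, so published exchange
rates are not reproduced (nor meant to be).
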