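# rnatopo

Topological constraints on RNA tertiary folding: a three-bead
coarse-grained model of an RNA with fixed secondary structure, an
equilibrium replica-exchange Monte Carlo sampler, and the analysis stack
that turns sampled ensembles into interhelical statistics and
conformational free energies.

## The scientific problem

RNA tertiary interactions (A-minor contacts, base triples,
tetraloop/tetraloop-receptor docks) are chemically non-specific, yet large
RNAs such as the 195-nt *Azoarcus* group I ribozyme fold specifically.  A
major source of that specificity is *topological constraint*: once the
secondary structure is fixed, chain connectivity and helix sterics alone
strongly restrict which 3D arrangements — and hence which tertiary
contacts — are reachable.  This package isolates exactly that physics:

* **Model.** Each nucleotide is three beads (P = phosphate, S = sugar at
  C1', B = base at the glycosidic nitrogen).  Canonical base pairs are
  permanently bonded into rigid ideal A-form helices; all other
  nucleotides are freely rotatable chains with soft bonded terms; the only
  nonbonded interactions are a purely repulsive excluded volume and a weak
  attraction between paired base beads.  Noncanonical internal-loop pairs
  get an extra steric bead, quarter-strength backbone dihedrals and fixed
  flat-bottom NOE restraints instead of rigid grouping.
* **Sampling.** Metropolis Monte Carlo (bead, crankshaft, rigid-subtree,
  helix and tapered-junction moves) with temperature replica exchange over
  eight exponentially spaced windows spanning 300–400 K.
* **Analysis.** For each helix pair, interhelical Euler angles
  (α<sub>h</sub>, β<sub>h</sub>, γ<sub>h</sub>) in a ZYZ twist–bend–twist
  convention; occupied-bin fractions F<sub>samp</sub> (10° bins; 30°/60°
  joint grids for pseudoknotted junctions, with density-matched F<sub>norm</sub>);
  normalized mutual information MI<sub>norm</sub> = MI/H(X,Y) on 45° bins;
  and contact free energies

      ΔG_topo = −RT ln( P / (1 − P) ),   T = 300 K,

  where P is the probability that defining sugar-bead distances fall
  under 14 Å (≥2 pairs for TL/TLR contacts).  Cooperativity is the
  conditional difference ΔΔG_coop(x, y) = ΔG_topo(x | y) − ΔG_topo(x),
  and absolute folding energies follow the reference-transfer relation
  ΔG_fold = ΔG_fold^ref − ΔG_topo^ref + ΔG_topo.

Shipped fixtures include toy structures (hairpin, bulged two-way
junction, minimal H-type pseudoknot), the tethered GAAA-tetraloop /
11-nt-receptor reference system, and a synthetic reconstruction of the
*Azoarcus* ribozyme secondary structure (crystal numbering per PDB 1U6B
chain B; see `src/rnatopo/data/azoarcus_synthetic/meta.json` for
provenance).

## Worked example

```python
import numpy as np
from rnatopo import synthetic, sampler, energetics

fx = synthetic.fixtures()["tl_tlr_reference"]
chain = fx.build(seed=2)                       # build + relax the chain
restraints = synthetic.tlr_reference_restraints(chain, fx)

cdef = energetics.region_contact(chain, "TL", "TLR", min_pairs=2)
obs = {"contact": energetics.make_contact_observer(chain, cdef)}
config = sampler.SamplerConfig(total_steps=600_000, record_interval=20,
                               seed=4, equilibration_fraction=0.1)
traj = sampler.remd_run(chain, restraints, config, observers=obs)

mask = traj.production("contact").astype(bool)
res = energetics.contact_probability_from_mask(mask, seed=1)
print(f"p = {res.p:.4f}, dG_topo = {res.dg:.2f} kcal/mol, CI = {res.ci}")
```

This prints (seeds as above):

```
p = 0.0284, dG_topo = 2.11 kcal/mol, CI = (2.04, 2.18)
```

i.e. even with the receptor hairpin held in its docked-ready
conformation, chain connectivity and sterics alone make the
tetraloop/receptor encounter a ≳2 kcal/mol uphill event — the entropic
price a tertiary contact must pay before any favorable chemistry is
counted.  The same pipeline on the ribozyme fixture yields an extended
unfolded ensemble (mean R<sub>g</sub> ≈ 40 Å versus ≈ 30 Å for the
crystal fold) in which native TL/TLR contacts are cheaper than their
non-native competitors and triple-helix formation cooperatively
stabilizes the native L9/J5 dock.

A command-line interface mirrors the library
(`rnatopo sample`, `rnatopo analyze-euler`, `rnatopo analyze-mi`,
`rnatopo analyze-dg`, `rnatopo analyze-coop`, `rnatopo fixtures`,
`rnatopo synth`; `rnatopo show-config` prints every force-field default).
Each invocation writes a manifest (config, seeds, input digests, output
inventory) so stochastic results reproduce bit-for-bit.

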