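"""Synthetic ensembles with known statistics, and the fixture library.

Every generator is deterministic under a fixed seed and embeds a
machine-readable record of the statistic it enforces, so tests compare
estimators against construction-time ground truth instead of re-derived
constants.

The fixture library covers a toy hairpin, a bulged two-way junction, a
minimal H-type pseudoknot, the tethered tetraloop/tetraloop-receptor
reference system, and the 195-nt Azoarcus group I ribozyme (synthetic
reconstruction of the published secondary structure; see the fixture's
meta.json for provenance and crystal numbering).
"""

from __future__ import annotations

import importlib.resources
import json
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.transform import Rotation

from . import builder, secstruct
from .euler import EulerSeries, decompose_zyz


@dataclass
class SyntheticSpec:
    generator: str
    params: dict
    ground_truth: dict


# ---------------------------------------------------------------------------
# generators


@dataclass
class IdealChainEnsemble:
    frames: np.ndarray            # (n_frames, n_links + 1, 3)
    bond_length: float
    spec: SyntheticSpec

    def end_to_end_sq(self) -> np.ndarray:
        d = self.frames[:, -1] - self.frames[:, 0]
        return (d * d).sum(axis=1)


def gen_ideal_chain(n_links: int, bond_length: float, n_frames: int,
                    seed: int = 0) -> IdealChainEnsemble:
    """Freely jointed chain: i.i.d. uniform random bond directions.

    Ground truth: <R_ee^2> = n_links * bond_length^2 exactly.
    """
    if n_links < 1:
        raise ValueError("need at least one link")
    rng = np.random.default_rng(seed)
    z = rng.normal(size=(n_frames, n_links, 3))
    z /= np.linalg.norm(z, axis=-1, keepdims=True)
    steps = np.concatenate([np.zeros((n_frames, 1, 3)), z * bond_length], axis=1)
    frames = np.cumsum(steps, axis=1)
    spec = SyntheticSpec(
        "ideal_chain",
        {"n_links": n_links, "bond_length": bond_length,
         "n_frames": n_frames, "seed": seed},
        {"mean_ree_sq": n_links * bond_length**2},
    )
    return IdealChainEnsemble(frames, bond_length, spec)


def gen_rotation_pair(correlation: float, n: int, seed: int = 0
                      ) -> tuple[EulerSeries, EulerSeries, SyntheticSpec]:
    """Two orientation series with tunable correlation in [0, 1].

    0 -> independent uniform rotations; 1 -> identical; intermediate ->
    the second rotation is the first perturbed by a random rotation whose
    angle shrinks with the parameter, so mutual information increases
    monotonically in it.
    """
    if not 0.0 <= correlation <= 1.0:
        raise ValueError("correlation must be in [0, 1]")
    rng = np.random.default_rng(seed)
    r1 = Rotation.random(n, random_state=rng)
    if correlation == 0.0:
        r2 = Rotation.random(n, random_state=rng)
    elif correlation == 1.0:
        r2 = r1
    else:
        axes = rng.normal(size=(n, 3))
        axes /= np.linalg.norm(axes, axis=1, keepdims=True)
        angles = rng.uniform(0.0, (1.0 - correlation) * np.pi, size=n)
        r2 = r1 * Rotation.from_rotvec(axes * angles[:, None])
    x = EulerSeries(np.array([decompose_zyz(m) for m in r1.as_matrix()]),
                    pair=("synthetic", "X"))
    y = EulerSeries(np.array([decompose_zyz(m) for m in r2.as_matrix()]),
                    pair=("synthetic", "Y"))
    spec = SyntheticSpec("rotation_pair",
                         {"correlation": correlation, "n": n, "seed": seed},
                         {"mi_monotone_in_correlation": True,
                          "identical": correlation == 1.0,
                          "independent": correlation == 0.0})
    return x, y, spec


@dataclass
class ContactEnsemble:
    frames: np.ndarray          # (n, 2, 3): the two sugar beads
    mask: np.ndarray            # exact Bernoulli contact indicator
    cutoff: float
    min_pairs: int
    spec: SyntheticSpec


def gen_contact_ensemble(p_target: float, n_frames: int, seed: int = 0,
                         cutoff: float = 14.0) -> ContactEnsemble:
    """Independent frames placing two sugar beads inside/outside the
    cutoff with exact Bernoulli probability ``p_target``."""
    if not 0.0 < p_target < 1.0:
        raise ValueError("p_target must be in (0, 1)")
    rng = np.random.default_rng(seed)
    mask = rng.random(n_frames) < p_target
    d_in = rng.uniform(4.0, cutoff - 0.5, size=n_frames)
    d_out = rng.uniform(cutoff + 2.0, 3.0 * cutoff, size=n_frames)
    d = np.where(mask, d_in, d_out)
    dirs = rng.normal(size=(n_frames, 3))
    dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)
    frames = np.zeros((n_frames, 2, 3))
    frames[:, 1] = dirs * d[:, None]
    spec = SyntheticSpec("contact_ensemble",
                         {"p_target": p_target, "n_frames": n_frames,
                          "seed": seed, "cutoff": cutoff},
                         {"p": p_target, "n_contacts": int(mask.sum())})
    return ContactEnsemble(frames, mask, cutoff, 1, spec)


# ---------------------------------------------------------------------------
# fixtures


@dataclass
class Fixture:
    name: str
    structure: secstruct.SecondaryStructure
    regions: dict = field(default_factory=dict)
    meta: dict = field(default_factory=dict)
    restraint_rosters: dict = field(default_factory=dict)

    def build(self, params=None, seed: int = 0, relax: bool = True,
              relax_moves: int | None = None) -> builder.CoarseChain:
        return builder.build_chain(self.structure, params=params,
                                   regions=self.regions, relax=relax,
                                   relax_moves=relax_moves, seed=seed)


def _data_text(*parts) -> str:
    node = importlib.resources.files("rnatopo").joinpath("data")
    for p in parts:
        node = node.joinpath(p)
    return node.read_text()


def _load_packaged(name: str) -> Fixture:
    seq = _data_text(name, "sequence.txt").strip()
    pairs = _data_text(name, "pairs.tsv")
    regions = secstruct.parse_regions(_data_text(name, "regions.tsv"))
    meta = json.loads(_data_text(name, "meta.json"))
    numbering = None
    try:
        numbering = {}
        for ln in _data_text(name, "numbering.tsv").splitlines()[1:]:
            pos, crystal = ln.split("\t")
            numbering[int(pos)] = crystal
    except FileNotFoundError:
        numbering = None
    ss = secstruct.parse_structure(pairs, sequence=seq, numbering_map=numbering)
    rosters = {}
    for kind in ("TH", "L9J5"):
        try:
            rosters[kind] = _data_text(name, f"restraints_{kind}.tsv")
        except FileNotFoundError:
            pass
    return Fixture(meta.get("name", name), ss, regions, meta, rosters)


def fixtures() -> dict[str, Fixture]:
    """The structure library used throughout tests and examples."""
    lib: dict[str, Fixture] = {}
    lib["hairpin"] = Fixture(
        "hairpin",
        secstruct.parse_structure("(((...)))", sequence="GGGAAACCC"),
        regions={"stem": [1, 2, 3, 7, 8, 9], "loop": [4, 5, 6]},
        meta={"description": "toy 9-nt hairpin (3-bp stem, 3-nt loop)"},
    )
    lib["two_way_junction"] = Fixture(
        "two_way_junction",
        secstruct.parse_structure("((((...((((....))))))))",
                                  sequence="GGGGAAAGGGGUUCGCCCCCCCC"),
        regions={"H1": list(range(1, 5)) + list(range(20, 24)),
                 "H2": list(range(8, 12)) + list(range(16, 20)),
                 "bulge": [5, 6, 7], "loop": [12, 13, 14, 15]},
        meta={"description": "two 4-bp helices separated by a 3-nt bulge"},
    )
    lib["pseudoknot"] = Fixture(
        "pseudoknot",
        secstruct.parse_structure("((((..[[[[))))..]]]]",
                                  sequence="GGGGAAGGGGCCCCAACCCC"),
        regions={"S1": list(range(1, 5)) + list(range(11, 15)),
                 "S2": list(range(7, 11)) + list(range(17, 21)),
                 "L1": [5, 6], "L2": [15, 16]},
        meta={"description": "minimal H-type pseudoknot (crossing stems)"},
    )
    lib["tl_tlr_reference"] = _load_packaged("tl_tlr_reference")
    lib["azoarcus"] = _load_packaged("azoarcus_synthetic")
    return lib


def tlr_reference_restraints(chain: builder.CoarseChain,
                             fixture: Fixture) -> builder.RestraintSet:
    """Backbone dihedral restraints (K = 50 kcal/mol) holding the receptor
    hairpin (residues 26-50) of the reference system in its built
    conformation during production sampling."""
    lo, hi = fixture.meta["restrained_span"]
    return builder.tether_dihedral_restraints(
        chain, range(lo, hi + 1), chain.coords.copy(),
        K=float(fixture.meta.get("dihedral_K", 50.0)))
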