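"""Force-field parameterization of the three-bead chain.

The model isolates chain connectivity and sterics: bonded terms keep the
chain intact, rigid groups keep helices A-form, a purely repulsive
excluded-volume term provides sterics, and the only attraction is a weak
well between base beads of (noncanonical) paired residues.  Electrostatics
and stacking/attractive nonbonded terms are deliberately absent.

Every constant is a plain dataclass field and can be overridden from a
key=value config file; defaults are the package's documented choices (see
docs/methods.md), not fitted values.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

from . import geometry

#: ideal gas constant, kcal/(mol K)
R_KCAL = 1.9872e-3


@dataclass
class ForceFieldParams:
    # bond force constants (kcal/mol/Å^2); equilibrium lengths come from
    # the A-form template so built helices are strain-free
    k_bond: float = 20.0
    bond_lengths: dict = field(default_factory=geometry.template_bond_lengths)
    #: extra steric bead of a noncanonical pair: bond length to its base bead
    extra_bead_bond: float = 4.0

    # backbone angle terms (kcal/mol/rad^2); weak so unpaired nucleotides
    # stay freely rotatable
    k_angle: float = 2.0
    angle_targets: dict = field(default_factory=geometry.template_backbone_angles)

    # backbone dihedral force constant for canonically paired residues
    # (kcal/mol); noncanonical-pair residues feel one fourth of it.
    # Canonical in-helix dihedrals are redundant with the rigid grouping,
    # so only noncanonical-pair residues actually receive the term.
    k_dihedral_paired: float = 4.0
    noncanonical_dihedral_factor: float = 0.25

    # excluded volume: E = k_ev (sigma_ij - r)^2 for r < sigma_ij,
    # sigma_ij = radius_i + radius_j
    k_ev: float = 10.0
    radius_P: float = 2.1
    radius_S: float = 2.9
    radius_B: float = 2.8
    radius_X: float = 2.8  # extra noncanonical steric bead

    # weak attraction exclusively between paired base beads (kcal/mol);
    # flat well to r_on, linear switch-off by r_off
    pair_attraction_eps: float = 0.5
    pair_attraction_r_on: float = 7.5
    pair_attraction_r_off: float = 10.0

    # fixed internal restraints of a noncanonical pair (Å windows)
    nc_noe_bb: tuple = (5.5, 7.5)
    nc_noe_ss: tuple = (11.0, 14.0)
    nc_noe_k: float = 2.0   # kcal/mol/Å^2 (k_min = k_max)
    nc_noe_fmax: float = 2.0  # kcal/mol/Å force cap

    def radius_of(self, bead_type: int) -> float:
        return (self.radius_P, self.radius_S, self.radius_B, self.radius_X)[bead_type]

    def override(self, **kw) -> "ForceFieldParams":
        return replace(self, **kw)

    @classmethod
    def from_config(cls, text: str) -> "ForceFieldParams":
        """Parse ``key = value`` lines (unknown keys rejected)."""
        kw = {}
        base = cls()
        for ln in text.splitlines():
            ln = ln.split("#", 1)[0].strip()
            if not ln:
                continue
            key, val = (t.strip() for t in ln.split("=", 1))
            if not hasattr(base, key):
                raise KeyError(f"unknown force-field parameter {key!r}")
            cur = getattr(base, key)
            if isinstance(cur, dict):
                raise KeyError(f"{key} must be overridden programmatically")
            kw[key] = type(cur)(eval(val, {}, {}))  # numeric/tuple literals
        return cls(**kw)

    def to_config(self) -> str:
        lines = []
        for name in ("k_bond", "extra_bead_bond", "k_angle", "k_dihedral_paired",
                     "noncanonical_dihedral_factor", "k_ev", "radius_P",
                     "radius_S", "radius_B", "radius_X", "pair_attraction_eps",
                     "pair_attraction_r_on", "pair_attraction_r_off",
                     "nc_noe_bb", "nc_noe_ss", "nc_noe_k", "nc_noe_fmax"):
            lines.append(f"{name} = {getattr(self, name)}")
        return "\n".join(lines) + "\n"
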