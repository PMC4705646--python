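"""Construct the three-bead coarse-grained chain and its energy topology.

Each nucleotide carries three beads: P (phosphate), S (sugar, anchored at
C1') and B (base, anchored at the glycosidic nitrogen N9/N1).  Canonical
base pairs are permanently bonded and grouped into rigid A-form helices;
all other nucleotides are freely rotatable chains held together by soft
bonded terms.  Noncanonical internal-loop pairs are not rigidified:
one of the two bases receives an extra steric bead, both residues feel a
weak base-base attraction and quarter-strength backbone dihedrals, and the
pair is tied by fixed flat-bottom NOE restraints (B-B 5.5-7.5 Å,
S-S 11-14 Å).
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field

import numpy as np

from . import geometry
from .forcefield import ForceFieldParams
from .secstruct import (
    NONCANONICAL,
    SecondaryStructure,
    TopologyGraph,
    decompose_topology,
)

P, S, B, X = 0, 1, 2, 3
BEAD_NAMES = "PSBX"
PURINES = set("AG")


class BuildError(RuntimeError):
    pass


# ---------------------------------------------------------------------------
# restraints


@dataclass
class RestraintSet:
    """NOE (flat-bottom, force-capped), dihedral and R_g restraints.

    noe rows: (bead_i, bead_j, r_min, r_max, k_min, k_max, f_max)
    dihedral rows: ((b0, b1, b2, b3), phi0_deg, K)
    rg: (target Å, force constant) or None
    """

    noe: list = field(default_factory=list)
    dihedral: list = field(default_factory=list)
    rg: tuple | None = None
    label: str = "custom"

    def __post_init__(self):
        for row in self.noe:
            i, j, rmin, rmax, kmin, kmax, fmax = row
            if rmin > rmax:
                raise ValueError(f"NOE r_min {rmin} > r_max {rmax}")
            if min(kmin, kmax, fmax) < 0:
                raise ValueError("restraint constants must be >= 0")
        if self.rg is not None and min(self.rg) <= 0:
            raise ValueError("rg restraint needs positive target and constant")

    def to_tsv(self, chain: "CoarseChain") -> str:
        lines = ["kind\ta\tb\tc\td\tr_min\tr_max\tk\tf_max\tphi0"]
        for i, j, rmin, rmax, kmin, kmax, fmax in self.noe:
            lines.append(
                f"noe\t{chain.bead_label(i)}\t{chain.bead_label(j)}\t\t\t"
                f"{rmin:g}\t{rmax:g}\t{kmin:g}\t{fmax:g}\t"
            )
        for quad, phi0, kk in self.dihedral:
            names = "\t".join(chain.bead_label(b) for b in quad)
            lines.append(f"dihedral\t{names}\t\t\t{kk:g}\t\t{phi0:.2f}")
        if self.rg is not None:
            lines.append(f"rg\t\t\t\t\t\t\t{self.rg[1]:g}\t\t{self.rg[0]:g}")
        return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# chain


@dataclass
class CoarseChain:
    ss: SecondaryStructure
    params: ForceFieldParams
    topology: TopologyGraph
    coords: np.ndarray          # (n_beads, 3) current/initial conformation
    bead_res: np.ndarray        # 1-based residue per bead
    bead_type: np.ndarray       # 0=P 1=S 2=B 3=X
    group_id: np.ndarray        # rigid group per bead, -1 = free
    group_names: list           # helix name per group id
    bonds: np.ndarray           # (nb, 2) int
    bond_r0: np.ndarray
    bond_k: np.ndarray
    angles: np.ndarray          # (na, 3) int
    angle_theta0: np.ndarray    # radians
    angle_k: np.ndarray
    dihedrals: np.ndarray       # (nd, 4) int  (force-field torsions)
    dihedral_phi0: np.ndarray   # radians
    dihedral_k: np.ndarray
    internal_noe: list          # noncanonical-pair NOEs (RestraintSet rows)
    attraction_pairs: np.ndarray  # (np_, 2) int, base beads of nc pairs
    extra_bead_of: dict         # nc pair (i, j) -> bead index of X

    @property
    def n_res(self) -> int:
        return self.ss.length

    @property
    def n_beads(self) -> int:
        return len(self.coords)

    def bead_index(self, res: int, bead: int) -> int:
        if bead == X:
            for (i, j), bx in self.extra_bead_of.items():
                if res in (i, j):
                    return bx
            raise KeyError(f"residue {res} has no extra bead")
        return 3 * (res - 1) + bead

    def bead_label(self, idx: int) -> str:
        res = int(self.bead_res[idx])
        return f"{self.ss.crystal_name(res)}:{BEAD_NAMES[int(self.bead_type[idx])]}"

    def beads_of_type(self, bead: int) -> np.ndarray:
        return np.nonzero(self.bead_type == bead)[0]

    def s_beads_of(self, residues) -> np.ndarray:
        return np.array([self.bead_index(r, S) for r in residues], dtype=np.int64)

    def helix_bead_indices(self, helix_name: str) -> np.ndarray:
        gid = self.group_names.index(helix_name)
        return np.nonzero(self.group_id == gid)[0]

    def radii(self) -> np.ndarray:
        return np.array([self.params.radius_of(t) for t in self.bead_type])

    def region(self, name: str) -> list[int]:
        try:
            return self.topology.regions[name]
        except KeyError:
            raise KeyError(f"region {name!r} not defined for this chain") from None


# ---------------------------------------------------------------------------
# A-form helix construction


def build_aform_helix(pairs) -> tuple[np.ndarray, np.ndarray]:
    """Idealized A-form duplex bead geometry for a run of consecutive pairs.

    Returns (strand1, strand2) arrays of shape (n_bp, 3, 3) with P, S, B
    bead positions per residue; the whole duplex forms one rigid group.
    """
    n_bp = len(pairs)
    if n_bp < 1:
        raise BuildError("helix needs at least one pair")
    return geometry.aform_duplex(n_bp)


# ---------------------------------------------------------------------------
# chain assembly


def build_chain(
    ss: SecondaryStructure,
    params: ForceFieldParams | None = None,
    init: np.ndarray | None = None,
    regions: dict | None = None,
    relax: bool = True,
    relax_moves: int | None = None,
    seed: int = 0,
) -> CoarseChain:
    """Build the coarse chain: beads, bonded topology, rigid helices.

    Without ``init``, beads start from a deterministic extended layout
    (helices as ideal A-form rigid bodies, unpaired residues on a line)
    and a seeded relaxation run removes steric overlap and closes the
    stretched pseudoknot/loop bonds.  With ``init`` (one row per bead,
    e.g. from :func:`map_pdb_to_beads`), coordinates are used as given and
    rigid groups adopt the supplied helix geometry.
    """
    params = params or ForceFieldParams()
    tg = decompose_topology(ss, regions=regions)
    n = ss.length
    n_beads = 3 * n
    bead_res = np.repeat(np.arange(1, n + 1), 3)
    bead_type = np.tile(np.array([P, S, B]), n)

    nc_pairs = [(p.i, p.j) for p in ss.pairs if p.pair_class == NONCANONICAL]
    extra_bead_of = {}
    extra_rows = []
    for (i, j) in nc_pairs:
        ri, rj = ss.sequence[i - 1], ss.sequence[j - 1]
        # the extra steric bead goes on the purine if exactly one member is
        # a purine, else on the 5'-most residue
        if (ri in PURINES) != (rj in PURINES):
            host = i if ri in PURINES else j
        else:
            host = i
        extra_bead_of[(i, j)] = n_beads + len(extra_rows)
        extra_rows.append(host)
    if extra_rows:
        bead_res = np.concatenate([bead_res, np.array(extra_rows)])
        bead_type = np.concatenate([bead_type, np.full(len(extra_rows), X)])
        n_beads += len(extra_rows)

    def bi(res, bead):
        return 3 * (res - 1) + bead

    # rigid groups: one per canonical helix
    group_id = np.full(n_beads, -1, dtype=np.int32)
    group_names = []
    for g, h in enumerate(tg.helices):
        group_names.append(h.name)
        for res in h.residues():
            for t in (P, S, B):
                group_id[bi(res, t)] = g

    # bonds
    bl = params.bond_lengths
    bonds, r0 = [], []
    for res in range(1, n + 1):
        bonds.append((bi(res, P), bi(res, S))); r0.append(bl["PS"])
        bonds.append((bi(res, S), bi(res, B))); r0.append(bl["SB"])
        if res < n:
            bonds.append((bi(res, S), bi(res + 1, P))); r0.append(bl["SP"])
    for (i, j), bx in extra_bead_of.items():
        host = int(bead_res[bx])
        bonds.append((bi(host, B), bx)); r0.append(params.extra_bead_bond)
    bonds = np.array(bonds, dtype=np.int64)
    bond_r0 = np.array(r0)
    bond_k = np.full(len(bonds), params.k_bond)

    # backbone angles
    at = params.angle_targets
    angles, th0 = [], []
    for res in range(1, n + 1):
        if res < n:
            angles.append((bi(res, P), bi(res, S), bi(res + 1, P)))
            th0.append(np.deg2rad(at["PSP"]))
            angles.append((bi(res, S), bi(res + 1, P), bi(res + 1, S)))
            th0.append(np.deg2rad(at["SPS"]))
    angles = np.array(angles, dtype=np.int64)
    angle_theta0 = np.array(th0)
    angle_k = np.full(len(angles), params.k_angle)

    # force-field dihedrals: noncanonical-pair residues only (quarter
    # strength); canonical in-helix torsions are fixed by the rigid groups
    tmpl_phi = _template_dihedral_targets()
    dihedrals, phi0, dk = [], [], []
    k_nc = params.k_dihedral_paired * params.noncanonical_dihedral_factor
    nc_residues = sorted({r for ij in nc_pairs for r in ij})
    for res in nc_residues:
        if 1 < res:
            dihedrals.append((bi(res - 1, S), bi(res, P), bi(res, S),
                              bi(res + 1, P) if res < n else bi(res, B)))
            phi0.append(np.deg2rad(tmpl_phi["SPSP"]))
            dk.append(k_nc)
        if res < n:
            dihedrals.append((bi(res, P), bi(res, S), bi(res + 1, P),
                              bi(res + 1, S)))
            phi0.append(np.deg2rad(tmpl_phi["PSPS"]))
            dk.append(k_nc)
    dihedrals = np.array(dihedrals, dtype=np.int64) if dihedrals else np.empty((0, 4), np.int64)
    dihedral_phi0 = np.array(phi0)
    dihedral_k = np.array(dk)

    # fixed internal NOEs + base-base attraction of noncanonical pairs
    internal_noe = []
    attraction = []
    for (i, j) in nc_pairs:
        kk, fmax = params.nc_noe_k, params.nc_noe_fmax
        bb = params.nc_noe_bb
        sscfg = params.nc_noe_ss
        internal_noe.append((bi(i, B), bi(j, B), bb[0], bb[1], kk, kk, fmax))
        internal_noe.append((bi(i, S), bi(j, S), sscfg[0], sscfg[1], kk, kk, fmax))
        attraction.append((bi(i, B), bi(j, B)))
    attraction = np.array(attraction, dtype=np.int64) if attraction else np.empty((0, 2), np.int64)

    # initial coordinates
    if init is not None:
        init = np.asarray(init, dtype=float)
        if init.shape != (n_beads, 3):
            raise BuildError(
                f"init coordinates cover {init.shape[0]} beads, need {n_beads}"
            )
        if not np.all(np.isfinite(init)):
            raise BuildError("init coordinates contain non-finite values")
        coords = init.copy()
    else:
        coords = _layout_coords(ss, tg, params, n_beads, bead_res, bead_type,
                                extra_bead_of, branch_seed=seed)

    chain = CoarseChain(
        ss=ss, params=params, topology=tg, coords=coords,
        bead_res=bead_res, bead_type=bead_type, group_id=group_id,
        group_names=group_names, bonds=bonds, bond_r0=bond_r0, bond_k=bond_k,
        angles=angles, angle_theta0=angle_theta0, angle_k=angle_k,
        dihedrals=dihedrals, dihedral_phi0=dihedral_phi0, dihedral_k=dihedral_k,
        internal_noe=internal_noe, attraction_pairs=attraction,
        extra_bead_of=extra_bead_of,
    )

    if init is None and relax:
        from . import sampler  # local import: sampler builds on this module

        moves = relax_moves if relax_moves is not None else max(20000, 600 * n)
        ok = False
        for stage in range(12):
            ok = sampler.relax_chain(chain, n_moves=moves,
                                     seed=seed + 17 * stage)
            if ok:
                break
        if not ok:
            raise BuildError(
                "relaxation failed to remove steric overlap / close bonds "
                "within the retry budget; inspect chain.coords"
            )
    return chain


def _template_dihedral_targets() -> dict[str, float]:
    s1, _ = geometry.aform_duplex(5)
    spsp = geometry.dihedral(s1[1, 1], s1[2, 0], s1[2, 1], s1[3, 0])
    psps = geometry.dihedral(s1[2, 0], s1[2, 1], s1[3, 0], s1[3, 1])
    return {"SPSP": spsp, "PSPS": psps}


def _layout_coords(ss, tg, params, n_beads, bead_res, bead_type, extra_bead_of,
                   branch_seed: int = 0):
    """Deterministic starting layout from the secondary-structure tree.

    The chain is walked depth-first: non-crossing helices are placed as
    ideal A-form rigid bodies along the current walk direction, enclosed
    residues continue from the helix far end with a rotated direction
    (splaying branches apart), unpaired residues step ~6 Å each.  A
    maximal non-crossing helix subset forms the tree; the remaining
    (pseudoknot) helices are snapped to template geometry between their
    laid-out strands afterwards, leaving only modest boundary-bond
    stretches for the relaxation run to close with sterics on.
    """
    n = ss.length
    coords = np.zeros((n_beads, 3))
    step = 6.0

    # greedy maximal non-crossing helix subset, longest first
    kept: list = []
    for h in sorted(tg.helices, key=lambda h: -h.n_pairs):
        o = h.outer
        crosses = any(
            (k.outer[0] < o[0] <= k.outer[1] < o[1])
            or (o[0] < k.outer[0] <= o[1] < k.outer[1])
            for k in kept
        )
        if not crosses:
            kept.append(h)
    helix_at = {h.strand1[0]: h for h in kept}
    dropped = [h for h in tg.helices if h not in kept]

    rng = np.random.default_rng(10_000 + branch_seed)

    def branch_rot(direction):
        axis = rng.normal(size=3)
        axis -= axis @ direction * direction
        nrm = np.linalg.norm(axis)
        if nrm < 1e-9:
            axis = np.array([0.0, 0.0, 1.0])
        else:
            axis /= nrm
        ang = np.deg2rad(35.0 + 20.0 * rng.random())
        return geometry.rotation_about_axis(axis, ang) @ direction

    def frame_for(direction):
        """Rotation taking template +z to ``direction`` (right-handed)."""
        z = direction / np.linalg.norm(direction)
        ref = np.array([0.0, 0.0, 1.0])
        if abs(z @ ref) > 0.95:
            ref = np.array([0.0, 1.0, 0.0])
        x = np.cross(ref, z)
        x /= np.linalg.norm(x)
        y = np.cross(z, x)
        return np.column_stack([x, y, z])

    def put_ss(res, pos, direction):
        coords[3 * (res - 1) + S] = pos
        coords[3 * (res - 1) + P] = pos - direction * 2.4 + (0.0, 0.0, 0.9)
        coords[3 * (res - 1) + B] = pos + (0.4, 1.2, -0.4)

    def place_helix(h, pos, direction):
        s1, s2 = geometry.aform_duplex(h.n_pairs)
        rot = frame_for(direction)
        shift = pos - rot @ s1[0, 1]
        for m, res in enumerate(range(h.strand1[0], h.strand1[1] + 1)):
            for t in (P, S, B):
                coords[3 * (res - 1) + t] = rot @ s1[m, t] + shift
        for m, res in enumerate(range(h.strand2[0], h.strand2[1] + 1)):
            for t in (P, S, B):
                coords[3 * (res - 1) + t] = rot @ s2[m, t] + shift

    def walk(lo, hi, pos, direction):
        res = lo
        while res <= hi:
            h = helix_at.get(res)
            if h is not None and h.strand2[1] <= hi:
                place_helix(h, pos, direction)
                inner_lo = h.strand1[1] + 1
                inner_hi = h.strand2[0] - 1
                far = coords[3 * (h.strand1[1] - 1) + S] + direction * step
                if inner_lo <= inner_hi:
                    walk(inner_lo, inner_hi, far, branch_rot(direction))
                pos = coords[3 * (h.strand2[1] - 1) + S] + direction * step * 0.5
                direction = branch_rot(direction)
                res = h.strand2[1] + 1
            else:
                put_ss(res, pos, direction)
                pos = pos + direction * step
                res += 1

    walk(1, n, np.zeros(3), np.array([1.0, 0.0, 0.0]))

    # snap pseudoknot helices to template geometry, superposed onto the
    # laid-out (single-strand walk) positions of their own residues
    for h in dropped:
        s1, s2 = geometry.aform_duplex(h.n_pairs)
        res1 = list(range(h.strand1[0], h.strand1[1] + 1))
        res2 = list(range(h.strand2[0], h.strand2[1] + 1))
        tmpl = np.vstack([s1[:, S], s2[:, S]])
        laid = np.array([coords[3 * (r - 1) + S] for r in res1 + res2])
        rot, trans = geometry.kabsch_transform(tmpl, laid)
        for m, res in enumerate(res1):
            for t in (P, S, B):
                coords[3 * (res - 1) + t] = rot @ s1[m, t] + trans
        for m, res in enumerate(res2):
            for t in (P, S, B):
                coords[3 * (res - 1) + t] = rot @ s2[m, t] + trans

    for (i, j), bx in extra_bead_of.items():
        host = int(bead_res[bx])
        coords[bx] = coords[3 * (host - 1) + B] + (0.0, 0.0, -params.extra_bead_bond)
    return coords


# ---------------------------------------------------------------------------
# PDB mapping


def map_pdb_to_beads(
    pdb_source,
    ss: SecondaryStructure,
    chain_id: str | None = None,
    impute_missing_p: bool = True,
) -> tuple[np.ndarray, list[str]]:
    """Map all-atom PDB coordinates onto P/S/B beads.

    P bead <- P atom; S bead <- C1'; B bead <- N9 (purines) / N1
    (pyrimidines).  Residues are matched through ``ss.numbering_map`` when
    present (crystal numbering), else by sequential residue id.  Returns
    ``(coords (3n, 3), gap_report)``; extra noncanonical beads are not
    produced here (the builder adds them).  A missing 5'-terminal P is
    imputed from O5' when ``impute_missing_p`` and reported.
    """
    import biotite.structure as struc
    from biotite.structure.io.pdb import PDBFile

    if isinstance(pdb_source, (str, bytes)) or hasattr(pdb_source, "read"):
        pdbfile = PDBFile.read(pdb_source)
        atoms = pdbfile.get_structure(model=1)
    else:
        atoms = pdb_source
    if chain_id is not None:
        atoms = atoms[atoms.chain_id == chain_id]
        if atoms.array_length() == 0:
            raise BuildError(f"chain {chain_id!r} not present in PDB input")

    n = ss.length
    coords = np.full((3 * n, 3), np.nan)
    report: list[str] = []
    for pos in range(1, n + 1):
        crystal = ss.crystal_name(pos)
        res_id = int("".join(ch for ch in crystal if ch.isdigit()))
        sel = atoms[atoms.res_id == res_id]
        if sel.array_length() == 0:
            report.append(f"residue {crystal}: absent from PDB")
            continue
        resname = str(sel.res_name[0]).strip()
        base_atom = "N9" if resname and resname[-1] in "AG" else "N1"

        def grab(name):
            hit = sel[sel.atom_name == name]
            return hit.coord[0] if hit.array_length() else None

        p = grab("P")
        s = grab("C1'")
        b = grab(base_atom)
        if b is None:
            b = grab("N1") if base_atom == "N9" else grab("N9")
        if p is None and impute_missing_p:
            o5 = grab("O5'")
            if o5 is not None:
                p = o5
                report.append(f"residue {crystal}: P imputed from O5'")
        for t, val, label in ((P, p, "P"), (S, s, "C1'"), (B, b, base_atom)):
            if val is None:
                report.append(f"residue {crystal}: missing atom {label}")
            else:
                coords[3 * (pos - 1) + t] = val
    return coords, report


# ---------------------------------------------------------------------------
# coarse PDB I/O


def write_coarse_pdb(chain: CoarseChain, path_or_file, coords=None) -> None:
    """Write beads as pseudo-atoms (P/S/B/X), one residue per nucleotide."""
    import biotite.structure as struc
    from biotite.structure.io.pdb import PDBFile

    coords = chain.coords if coords is None else np.asarray(coords)
    arr = struc.AtomArray(chain.n_beads)
    arr.coord = coords.astype(np.float32)
    arr.chain_id = np.full(chain.n_beads, "A")
    arr.res_id = chain.bead_res.astype(int)
    arr.res_name = np.array([chain.ss.sequence[r - 1].replace("U", "U")
                             for r in chain.bead_res])
    arr.atom_name = np.array([BEAD_NAMES[t] for t in chain.bead_type])
    arr.element = np.full(chain.n_beads, "C")
    arr.hetero = np.full(chain.n_beads, False)
    pdbf = PDBFile()
    pdbf.set_structure(arr)
    pdbf.write(path_or_file)


def read_coarse_pdb(path_or_file) -> np.ndarray:
    from biotite.structure.io.pdb import PDBFile

    atoms = PDBFile.read(path_or_file).get_structure(model=1)
    return np.asarray(atoms.coord, dtype=float)


# ---------------------------------------------------------------------------
# restraint rosters


def _load_fixture_text(fixture: str, name: str) -> str:
    root = importlib.resources.files("rnatopo") / "data" / fixture / name
    return root.read_text()


def _parse_roster(text: str, chain: CoarseChain):
    noe_rows, dih_rows = [], []
    for ln in text.splitlines()[1:]:
        if not ln.strip():
            continue
        cols = ln.split("\t")
        kind = cols[0]
        if kind == "noe_SS":
            a = chain.bead_index(chain.ss.position_of(cols[1]), S)
            b = chain.bead_index(chain.ss.position_of(cols[2]), S)
            noe_rows.append((a, b))
        elif kind == "dihedral":
            quad = []
            for tok in cols[1:5]:
                resname, bead = tok.split(":")
                quad.append(chain.bead_index(chain.ss.position_of(resname),
                                             {"P": P, "S": S, "B": B}[bead]))
            kval = float(cols[5].split("=")[1])
            dih_rows.append((tuple(quad), kval))
    return noe_rows, dih_rows


#: default flat-bottom window (Å) for tertiary-contact NOEs when no
#: reference coordinates are available to measure crystal distances
DEFAULT_NOE_WINDOW = (4.0, 12.0)
NOE_K = 2.0      # kcal/mol/Å^2 (f_max = k_min = k_max = 2, as printed)
NOE_FMAX = 2.0   # kcal/mol/Å
TH_DIHEDRAL_K = 50.0  # kcal/mol
RG_DEFAULT_K = 10.0   # kcal/mol/Å^2


def make_restraints(
    kind: str,
    chain: CoarseChain,
    reference: np.ndarray | None = None,
    rg_target: float = 32.0,
    roster_text: str | None = None,
    fixture: str = "azoarcus_synthetic",
) -> RestraintSet:
    """Build a named restraint set.

    ``TH`` — the triple-helix roster: 8 S-bead NOEs plus the two backbone
    dihedrals spanning the P4->P6 step restrained with K = 50 kcal/mol.
    ``L9J5`` — 4 S-bead NOEs docking L9 into the J5 receptor.
    ``RG32`` — a single harmonic radius-of-gyration restraint (target
    ``rg_target``).
    With ``reference`` coordinates (one row per bead), NOE windows are set
    to +-1 Å of the measured distance and dihedral targets to the measured
    angles; otherwise documented defaults apply (window 4-12 Å, dihedral
    targets from the ideal continuous A-form stack).
    """
    kind = kind.upper().replace("/", "")
    if kind == "RG32":
        return RestraintSet(rg=(rg_target, RG_DEFAULT_K), label="RG32")
    if kind not in ("TH", "L9J5", "CUSTOM"):
        raise ValueError(f"unknown restraint kind {kind!r}")
    if kind == "CUSTOM":
        return RestraintSet(label="custom")

    if roster_text is None:
        roster_text = _load_fixture_text(fixture, f"restraints_{kind}.tsv")
    noe_rows, dih_rows = _parse_roster(roster_text, chain)

    noe = []
    for a, b in noe_rows:
        if reference is not None:
            d = float(np.linalg.norm(reference[a] - reference[b]))
            rmin, rmax = d - 1.0, d + 1.0
        else:
            rmin, rmax = DEFAULT_NOE_WINDOW
        noe.append((a, b, rmin, rmax, NOE_K, NOE_K, NOE_FMAX))

    dihedral = []
    tmpl = _template_dihedral_targets()
    for quad, kval in dih_rows:
        if reference is not None:
            phi0 = geometry.dihedral(*(reference[b] for b in quad))
        else:
            # the native triple helix stacks P4 on P6 coaxially: target the
            # torsions of an ideal continuous A-form backbone
            types = [int(chain.bead_type[b]) for b in quad]
            phi0 = tmpl["SPSP"] if types == [S, P, S, P] else tmpl["PSPS"]
            if types not in ([S, P, S, P], [P, S, P, S]):
                phi0 = tmpl["SPSP"]
        dihedral.append((quad, phi0, kval))
    return RestraintSet(noe=noe, dihedral=dihedral, label=kind)


def tether_dihedral_restraints(
    chain: CoarseChain,
    residues,
    reference: np.ndarray,
    K: float = TH_DIHEDRAL_K,
) -> RestraintSet:
    """Backbone dihedral restraints holding a residue span in its reference
    conformation (used for the receptor hairpin of the TL/TLR reference
    system, K = 50 kcal/mol)."""
    residues = sorted(residues)
    rows = []
    for res in residues:
        if res + 1 in residues:
            quad = (chain.bead_index(res, P), chain.bead_index(res, S),
                    chain.bead_index(res + 1, P), chain.bead_index(res + 1, S))
            phi0 = geometry.dihedral(*(reference[b] for b in quad))
            rows.append((quad, phi0, K))
        if res + 1 in residues and res + 2 in residues:
            quad = (chain.bead_index(res, S), chain.bead_index(res + 1, P),
                    chain.bead_index(res + 1, S), chain.bead_index(res + 2, P))
            phi0 = geometry.dihedral(*(reference[b] for b in quad))
            rows.append((quad, phi0, K))
    return RestraintSet(dihedral=rows, label="tether")
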