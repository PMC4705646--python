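"""Boltzmann sampling of the coarse-grained chain.

Equilibrium ensembles are generated with Metropolis Monte Carlo plus
temperature replica exchange.  The move set operates on a static catalog:

* single-bead displacements of free (non-rigid) beads,
* crankshaft rotations of unpaired runs about the axis through their
  flanking anchors,
* rigid-subtree rotations about an attachment bead (the generalization of
  pivot moves that is valid under pseudoknot closure: a subtree is any
  chain interval no base pair crosses, so no rigid group is ever split),
* small rigid rotations/translations of individual helices (the only move
  available to pseudoknot helices that belong to no valid subtree).

All proposals are symmetric, so acceptance is min(1, exp(-dE/RT)).
Replica exchange swaps neighboring temperatures with the standard
min(1, exp[(beta_i - beta_j)(E_i - E_j)]) criterion.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field

import numpy as np

from . import _kernels, geometry
from .builder import B, P, S, CoarseChain, RestraintSet
from .forcefield import R_KCAL

DEFAULT_T_MIN, DEFAULT_T_MAX, DEFAULT_N_REPLICAS = 300.0, 400.0, 8


def exponential_ladder(
    t_min: float = DEFAULT_T_MIN,
    t_max: float = DEFAULT_T_MAX,
    n: int = DEFAULT_N_REPLICAS,
) -> tuple[float, ...]:
    """Exponentially spaced temperature ladder spanning [t_min, t_max]."""
    if n == 1:
        return (t_min,)
    ratio = (t_max / t_min) ** (1.0 / (n - 1))
    return tuple(t_min * ratio**k for k in range(n))


def metropolis_probability(delta_e: float, temperature: float) -> float:
    """Closed-form Metropolis acceptance probability."""
    if delta_e <= 0:
        return 1.0
    return math.exp(-delta_e / (R_KCAL * temperature))


# ---------------------------------------------------------------------------
# system assembly


@dataclass
class System:
    """Chain + restraints flattened into kernel-ready arrays."""

    chain: CoarseChain
    restraints: RestraintSet | None
    arrays: dict
    catalog: dict
    n_beads: int

    def energy(self, coords=None) -> tuple[float, dict]:
        """Total energy (kcal/mol) and per-term breakdown."""
        a = self.arrays
        coords = self.chain.coords if coords is None else np.asarray(coords, float)
        if not np.all(np.isfinite(coords)):
            raise ValueError("non-finite coordinates")
        out = _kernels.total_energy(
            coords, a["radii"], a["group_id"], a["excl"],
            a["bond_i"], a["bond_j"], a["bond_r0"], a["bond_k"],
            a["ang_a"], a["ang_b"], a["ang_c"], a["ang_th0"], a["ang_k"],
            a["dih"], a["dih_phi0"], a["dih_k"],
            a["noe_i"], a["noe_j"], a["noe_rmin"], a["noe_rmax"],
            a["noe_kmin"], a["noe_kmax"], a["noe_fmax"],
            a["att_i"], a["att_j"], a["att_eps"], a["att_ron"], a["att_roff"],
            a["k_ev"], a["rg_on"], a["rg_target"], a["rg_k"],
        )
        total, eb, ea, ed, ee, et, en, er = out
        return total, {
            "bond": eb, "angle": ea, "dihedral": ed, "excluded_volume": ee,
            "attraction": et, "noe": en, "rg": er,
        }


def _exclusion_table(chain: CoarseChain) -> np.ndarray:
    n = chain.n_beads
    adj: list[set[int]] = [set() for _ in range(n)]
    for (i, j) in chain.bonds:
        adj[i].add(j)
        adj[j].add(i)
    # exclude pairs within 3 bonds: 1-4 backbone neighbors (e.g. S(i) and
    # B(i+1)) sit at A-form stacking distance, inside the repulsive core
    excl_sets: list[set[int]] = [set() for _ in range(n)]
    for i in range(n):
        for j in adj[i]:
            excl_sets[i].add(j)
            for k in adj[j]:
                if k == i:
                    continue
                excl_sets[i].add(k)
                for m in adj[k]:
                    if m != i and m != j:
                        excl_sets[i].add(m)
    # noncanonical pairs: their NOEs/attraction define the pair geometry,
    # so excluded volume is dropped among all beads of the two residues
    # (and their extra steric bead), exactly as for a rigid canonical pair
    for (ri, rj), bx in chain.extra_bead_of.items():
        beads = [bx]
        for t in (P, S, B):
            beads.append(chain.bead_index(ri, t))
            beads.append(chain.bead_index(rj, t))
        for a in beads:
            for bcl in beads:
                if a != bcl:
                    excl_sets[a].add(bcl)
    width = max(1, max(len(s) for s in excl_sets))
    table = np.full((n, width), -1, dtype=np.int64)
    for i, s in enumerate(excl_sets):
        table[i, :len(s)] = sorted(s)
    return table


def _residue_beads(chain: CoarseChain, lo: int, hi: int) -> np.ndarray:
    return np.nonzero((chain.bead_res >= lo) & (chain.bead_res <= hi))[0]


def _spanning_free_bonds(chain: CoarseChain) -> list[int]:
    """Backbone cut positions k (between residue k and k+1) that no base
    pair spans; cutting there detaches a complete suffix."""
    n = chain.n_res
    spanned = np.zeros(n + 1, dtype=bool)
    for p in chain.ss.pairs:
        spanned[p.i:p.j] = True  # spans bonds k for i <= k < j
    return [k for k in range(1, n) if not spanned[k]]


#: taper weights for flanking unpaired residues of a junction move,
#: by distance (in residues) from the helix
TAPER_WEIGHTS = (0.7, 0.45, 0.2)

DEFAULT_MOVE_WEIGHTS = {"bead": 0.35, "crank": 0.12, "subtree": 0.25,
                        "pinned": 0.05, "taper": 0.23}


def build_move_catalog(chain: CoarseChain, weights=None) -> dict:
    """Static move catalog; see module docstring for the move classes."""
    weights = dict(weights or DEFAULT_MOVE_WEIGHTS)
    weights.setdefault("taper", 0.0)
    n = chain.n_beads
    # entry: (kind, bead set, a1, a2, amplitude scale, weights, full_terms)
    entries: list[tuple] = []

    def ent(kind, mv, a1=-1, a2=-1, scale=1.0, wts=None, full=False):
        if wts is None:
            wts = np.ones(len(mv))
        entries.append((kind, np.asarray(mv, dtype=np.int64), a1, a2,
                        scale, np.asarray(wts, float), full))

    free = np.nonzero(chain.group_id == -1)[0]
    for b in free:
        ent(_kernels.K_BEAD, [b])

    nres = chain.n_res
    for (lo, hi) in chain.topology.loops:
        mv = _residue_beads(chain, lo, hi)
        if len(mv) == 0:
            continue
        left = chain.bead_index(lo - 1, S) if lo > 1 else -1
        right = chain.bead_index(hi + 1, P) if hi < nres else -1
        if left >= 0 and right >= 0:
            ent(_kernels.K_CRANK, mv, left, right)
        elif left >= 0 or right >= 0:
            ent(_kernels.K_SUBTREE, mv, max(left, right))

    seen: set[frozenset] = set()

    def add_subtree(lo, hi):
        """Move the smaller of [lo..hi] and its complement."""
        inside = _residue_beads(chain, lo, hi)
        if len(inside) == 0 or len(inside) == n:
            return
        if len(inside) <= n - len(inside):
            mv = inside
            anchor = (chain.bead_index(lo - 1, S) if lo > 1
                      else chain.bead_index(hi + 1, P))
        else:
            mv = np.nonzero((chain.bead_res < lo) | (chain.bead_res > hi))[0]
            anchor = (chain.bead_index(lo, P) if lo > 1
                      else chain.bead_index(hi, S))
        key = frozenset(mv.tolist())
        if key in seen:
            return
        seen.add(key)
        ent(_kernels.K_SUBTREE, mv, anchor)

    # helix subtrees (valid when no pair crosses the outer span)
    for h in chain.topology.helices:
        lo, hi = h.outer
        crossed = any((p.i < lo <= p.j <= hi) or (lo <= p.i <= hi < p.j)
                      for p in chain.ss.pairs
                      if not (lo <= p.i and p.j <= hi) and not (p.j < lo or p.i > hi))
        if not crossed:
            add_subtree(lo, hi)
    # suffix cuts at unspanned backbone bonds
    for k in _spanning_free_bonds(chain):
        add_subtree(k + 1, nres)

    # per-helix rigid moves (the only global relaxation channel for
    # pseudoknot helices, which belong to no valid subtree):
    #   - small rotation/translation about the centroid (pinned class)
    #   - crankshaft about the axis through the helix's two external
    #     backbone anchors, which strains only the two remaining
    #     boundary bonds and so reorients the helix much faster
    helix_by_gid = {chain.group_names.index(h.name): h
                    for h in chain.topology.helices}
    partner = chain.ss.partner()
    gids = sorted(set(int(g) for g in chain.group_id if g >= 0))
    for g in gids:
        mv = np.nonzero(chain.group_id == g)[0]
        ent(_kernels.K_PINNED, mv)
        h = helix_by_gid.get(g)
        if h is None:
            continue
        before = h.strand1[0] - 1
        after = h.strand2[1] + 1
        if before >= 1 and after <= nres:
            a1 = chain.bead_index(before, S)
            a2 = chain.bead_index(after, P)
            if chain.group_id[a1] != g and chain.group_id[a2] != g:
                # reduced amplitude: helix reorientation against 2 bonds
                ent(_kernels.K_CRANK, mv, a1, a2, 0.25)
        # tapered junction move: the helix rotates as a rigid body while
        # flanking unpaired residues follow with decaying fractions of the
        # rotation, spreading the boundary strain over the linkers
        t_idx = list(mv)
        t_w = [1.0] * len(mv)
        for end, step in ((h.strand1[0], -1), (h.strand1[1], +1),
                          (h.strand2[0], -1), (h.strand2[1], +1)):
            res = end
            for w in TAPER_WEIGHTS:
                res += step
                if res < 1 or res > nres or res in partner:
                    break
                for bidx in np.nonzero(chain.bead_res == res)[0]:
                    if bidx not in t_idx:
                        t_idx.append(int(bidx))
                        t_w.append(w)
        ent(_kernels.K_TAPER, t_idx, wts=t_w, full=True)

    # tandem taper moves: directly stacked helices (0-nt junctions, e.g.
    # a coaxial P4/P6 step) reorient as one core, since rotating either
    # alone fully strains the shared junction bond
    def _taper_core(core_helices):
        t_idx, t_w = [], []
        for hh in core_helices:
            for bidx in chain.helix_bead_indices(hh.name):
                t_idx.append(int(bidx))
                t_w.append(1.0)
        ends = []
        for hh in core_helices:
            ends += [(hh.strand1[0], -1), (hh.strand1[1], +1),
                     (hh.strand2[0], -1), (hh.strand2[1], +1)]
        for end, step in ends:
            res = end
            for w in TAPER_WEIGHTS:
                res += step
                if res < 1 or res > nres or res in partner:
                    break
                for bidx in np.nonzero(chain.bead_res == res)[0]:
                    if int(bidx) not in t_idx:
                        t_idx.append(int(bidx))
                        t_w.append(w)
        ent(_kernels.K_TAPER, t_idx, wts=t_w, full=True)

    helices = chain.topology.helices
    for a in helices:
        for b in helices:
            if a.name >= b.name:
                continue
            se_a = {a.strand1[0], a.strand1[1], a.strand2[0], a.strand2[1]}
            se_b = {b.strand1[0], b.strand1[1], b.strand2[0], b.strand2[1]}
            if any(abs(x - y) == 1 for x in se_a for y in se_b):
                _taper_core((a, b))

    # sort by class, flatten
    entries.sort(key=lambda t: t[0])
    kinds = np.array([t[0] for t in entries], dtype=np.int64)
    ent_scale = np.array([t[4] for t in entries], dtype=np.float64)
    nc = _kernels.N_CLASSES
    class_start = np.zeros(nc, dtype=np.int64)
    class_count = np.zeros(nc, dtype=np.int64)
    for c in range(nc):
        idx = np.nonzero(kinds == c)[0]
        class_start[c] = idx[0] if len(idx) else 0
        class_count[c] = len(idx)

    probs = np.array([weights["bead"], weights["crank"], weights["subtree"],
                      weights["pinned"], weights["taper"]], float)
    probs[class_count == 0] = 0.0
    if probs.sum() <= 0:
        raise ValueError("no usable move class")
    class_cum = np.cumsum(probs / probs.sum())

    mv_off = np.zeros(len(entries) + 1, dtype=np.int64)
    for e, (_, mv, *_rest) in enumerate(entries):
        mv_off[e + 1] = mv_off[e] + len(mv)
    mv_idx = np.concatenate([t[1] for t in entries]).astype(np.int64)
    mv_w = np.concatenate([t[5] for t in entries]).astype(np.float64)
    ent_a1 = np.array([t[2] for t in entries], dtype=np.int64)
    ent_a2 = np.array([t[3] for t in entries], dtype=np.int64)

    # boundary term lists per entry (terms straddling the moved set)
    def mixed_lists(term_beads: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        offs = np.zeros(len(entries) + 1, dtype=np.int64)
        chunks = []
        if term_beads.size == 0:
            return np.zeros(0, dtype=np.int64), offs
        width = term_beads.shape[1]
        mask = np.zeros(n, dtype=bool)
        for e, t in enumerate(entries):
            mv, full = t[1], t[6]
            mask[mv] = True
            inside = mask[term_beads].sum(axis=1)
            if full:
                hit = np.nonzero(inside > 0)[0]
            else:
                hit = np.nonzero((inside > 0) & (inside < width))[0]
            chunks.append(hit.astype(np.int64))
            offs[e + 1] = offs[e] + len(hit)
            mask[mv] = False
        return (np.concatenate(chunks) if chunks else np.zeros(0, np.int64)), offs

    return {
        "entries": entries,
        "kinds": kinds, "class_start": class_start,
        "class_count": class_count, "class_cum": class_cum,
        "mv_idx": mv_idx, "mv_w": mv_w, "mv_off": mv_off,
        "ent_a1": ent_a1, "ent_a2": ent_a2, "ent_scale": ent_scale,
        "mixed_lists": mixed_lists,
        "max_set": int(max(len(t[1]) for t in entries)),
    }


def build_system(
    chain: CoarseChain,
    restraints: RestraintSet | None = None,
    move_weights=None,
) -> System:
    p = chain.params
    noe_rows = list(chain.internal_noe)
    dih_rows = []
    rg_on, rg_target, rg_k = 0, 0.0, 0.0
    if restraints is not None:
        noe_rows += list(restraints.noe)
        dih_rows += [(q, math.radians(phi0), k)
                     for q, phi0, k in restraints.dihedral]
        if restraints.rg is not None:
            rg_on, (rg_target, rg_k) = 1, restraints.rg

    dih = np.vstack([chain.dihedrals] + [np.array([q for q, _, _ in dih_rows],
                                                  dtype=np.int64).reshape(-1, 4)]) \
        if dih_rows else chain.dihedrals
    dih_phi0 = np.concatenate([chain.dihedral_phi0,
                               np.array([f for _, f, _ in dih_rows])])
    dih_k = np.concatenate([chain.dihedral_k,
                            np.array([k for _, _, k in dih_rows])])

    noe = np.array(noe_rows, dtype=float).reshape(-1, 7)
    arrays = {
        "radii": chain.radii(),
        "group_id": chain.group_id.astype(np.int64),
        "excl": _exclusion_table(chain),
        "bond_i": chain.bonds[:, 0], "bond_j": chain.bonds[:, 1],
        "bond_r0": chain.bond_r0, "bond_k": chain.bond_k,
        "ang_a": chain.angles[:, 0], "ang_b": chain.angles[:, 1],
        "ang_c": chain.angles[:, 2],
        "ang_th0": chain.angle_theta0, "ang_k": chain.angle_k,
        "dih": np.ascontiguousarray(dih, dtype=np.int64),
        "dih_phi0": dih_phi0, "dih_k": dih_k,
        "noe_i": noe[:, 0].astype(np.int64), "noe_j": noe[:, 1].astype(np.int64),
        "noe_rmin": noe[:, 2], "noe_rmax": noe[:, 3],
        "noe_kmin": noe[:, 4], "noe_kmax": noe[:, 5], "noe_fmax": noe[:, 6],
        "att_i": chain.attraction_pairs[:, 0],
        "att_j": chain.attraction_pairs[:, 1],
        "att_eps": np.full(len(chain.attraction_pairs), p.pair_attraction_eps),
        "att_ron": p.pair_attraction_r_on, "att_roff": p.pair_attraction_r_off,
        "k_ev": p.k_ev,
        "rg_on": rg_on, "rg_target": rg_target, "rg_k": rg_k,
    }
    cat = build_move_catalog(chain, weights=move_weights)
    term_b = np.column_stack([arrays["bond_i"], arrays["bond_j"]])
    term_a = np.column_stack([arrays["ang_a"], arrays["ang_b"], arrays["ang_c"]])
    term_d = arrays["dih"]
    term_n = np.column_stack([arrays["noe_i"], arrays["noe_j"]])
    term_t = np.column_stack([arrays["att_i"], arrays["att_j"]]) \
        if len(chain.attraction_pairs) else np.zeros((0, 2), np.int64)
    ml = cat.pop("mixed_lists")
    cat["eb_idx"], cat["eb_off"] = ml(term_b)
    cat["ea_idx"], cat["ea_off"] = ml(term_a)
    cat["ed_idx"], cat["ed_off"] = ml(term_d)
    cat["en_idx"], cat["en_off"] = ml(term_n)
    cat["et_idx"], cat["et_off"] = ml(term_t)
    return System(chain=chain, restraints=restraints, arrays=arrays,
                  catalog=cat, n_beads=chain.n_beads)


# ---------------------------------------------------------------------------
# Monte Carlo drivers


@dataclass
class SamplerConfig:
    temperatures: tuple = field(default_factory=exponential_ladder)
    total_steps: int = 100_000          # MC moves per replica
    steps_per_exchange: int = 500
    record_interval: int | None = None  # default: each exchange interval
    seed: int = 0
    equilibration_fraction: float = 0.01
    store_frame_stride: int | None = None  # in recorded frames; None = off
    amp_bead: float = 0.7               # Å
    amp_crank: float = 1.2              # rad
    amp_subtree: float = 1.0            # rad
    amp_pinned_rot: float = 0.10        # rad
    amp_pinned_trans: float = 0.4       # Å
    amp_taper: float = 0.30             # rad
    move_weights: dict | None = None

    def __post_init__(self):
        temps = tuple(float(t) for t in self.temperatures)
        if any(b <= a for a, b in zip(temps, temps[1:])):
            raise ValueError("temperature ladder must be strictly increasing")
        self.temperatures = temps

    def snapshot(self) -> dict:
        return dataclasses.asdict(self)


@dataclass
class TrajectoryEnsemble:
    """Recorded 300 K (bottom-slot) series of an MC / REMD run."""

    config: dict
    n_frames: int
    equilibration: int                      # frames to discard
    observables: dict                       # name -> (n_frames, ...) array
    frames: np.ndarray | None               # (F, n_beads, 3) float32 or None
    frame_stride: int | None
    frame_replica: np.ndarray               # replica id per recorded frame
    temperature: float
    exchange_attempts: np.ndarray           # per neighbor pair
    exchange_accepts: np.ndarray
    seed: int

    @property
    def exchange_rates(self) -> np.ndarray:
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(self.exchange_attempts > 0,
                            self.exchange_accepts / self.exchange_attempts, np.nan)

    def production(self, name: str) -> np.ndarray:
        """Post-equilibration series of a recorded observable."""
        return self.observables[name][self.equilibration:]

    def production_frames(self) -> np.ndarray:
        if self.frames is None:
            raise ValueError("run did not store coordinate frames")
        skip = 0
        if self.frame_stride:
            skip = self.equilibration // self.frame_stride
        return self.frames[skip:]


def _kernel_args(system: System):
    a, c = system.arrays, system.catalog
    return a, c


def _run_block(system, coords, mask, rg_sums, n_steps, rt, seed, old_buf,
               acc, config, class_cum=None):
    a, c = system.arrays, system.catalog
    _kernels.run_block(
        coords, a["radii"], a["group_id"], a["excl"], mask,
        a["bond_i"], a["bond_j"], a["bond_r0"], a["bond_k"],
        a["ang_a"], a["ang_b"], a["ang_c"], a["ang_th0"], a["ang_k"],
        a["dih"], a["dih_phi0"], a["dih_k"],
        a["noe_i"], a["noe_j"], a["noe_rmin"], a["noe_rmax"],
        a["noe_kmin"], a["noe_kmax"], a["noe_fmax"],
        a["att_i"], a["att_j"], a["att_eps"], a["att_ron"], a["att_roff"],
        a["k_ev"], a["rg_on"], a["rg_target"], a["rg_k"], rg_sums,
        c["kinds"], c["ent_a1"], c["ent_a2"], c["ent_scale"],
        c["mv_idx"], c["mv_w"], c["mv_off"],
        c["eb_idx"], c["eb_off"], c["ea_idx"], c["ea_off"],
        c["ed_idx"], c["ed_off"], c["en_idx"], c["en_off"],
        c["et_idx"], c["et_off"],
        c["class_start"], c["class_count"],
        class_cum if class_cum is not None else c["class_cum"],
        config.amp_bead, config.amp_crank, config.amp_subtree,
        config.amp_pinned_rot, config.amp_pinned_trans, config.amp_taper,
        n_steps, rt, seed, old_buf, acc,
    )


def _rg_sums(coords) -> np.ndarray:
    return np.array([coords[:, 0].sum(), coords[:, 1].sum(),
                     coords[:, 2].sum(), (coords**2).sum()])


def mc_step(system: System, coords: np.ndarray, temperature: float,
            seed: int, config: SamplerConfig | None = None,
            move_class: str | None = None) -> tuple[bool, np.ndarray]:
    """Single Metropolis MC step (test / inspection utility).

    Returns (accepted, coords); ``coords`` is modified in place.
    """
    config = config or SamplerConfig()
    mask = np.zeros(system.n_beads, dtype=np.int8)
    old = np.zeros((system.catalog["max_set"], 3))
    acc = np.zeros(_kernels.N_CLASSES, dtype=np.int64)
    cum = None
    if move_class is not None:
        order = ["bead", "crank", "subtree", "pinned", "taper"]
        cum = np.zeros(_kernels.N_CLASSES)
        cum[order.index(move_class):] = 1.0
        if system.catalog["class_count"][order.index(move_class)] == 0:
            raise ValueError(f"no moves of class {move_class!r}")
    rg_sums = _rg_sums(coords)
    _run_block(system, coords, mask, rg_sums, 1, R_KCAL * temperature,
               int(seed) & 0x7FFFFFFF, old, acc, config, class_cum=cum)
    return bool(acc.sum()), coords


def remd_run(
    chain: CoarseChain,
    restraints: RestraintSet | None,
    config: SamplerConfig,
    observers: dict | None = None,
    start_coords: np.ndarray | None = None,
    progress: bool = False,
) -> TrajectoryEnsemble:
    """Replica-exchange MC run; records the bottom-temperature series.

    ``observers`` maps name -> callable(coords) returning a float or a
    fixed-shape array, evaluated at every recording interval on the
    replica currently at the lowest temperature.
    """
    system = build_system(chain, restraints, move_weights=config.move_weights)
    temps = config.temperatures
    n_rep = len(temps)
    rts = [R_KCAL * t for t in temps]
    betas = [1.0 / rt for rt in rts]

    rec = config.record_interval or config.steps_per_exchange
    if config.steps_per_exchange % rec:
        raise ValueError("record_interval must divide steps_per_exchange")
    exch_every = config.steps_per_exchange // rec
    n_blocks = config.total_steps // rec

    base = start_coords if start_coords is not None else chain.coords
    states = [np.array(base, dtype=float) for _ in range(n_rep)]
    rg_sums = [_rg_sums(s) for s in states]
    slot_state = list(range(n_rep))  # temperature slot -> state index

    seedseq = np.random.SeedSequence(config.seed)
    rep_seeds = [child.generate_state(n_blocks + 1).astype(np.uint64)
                 for child in seedseq.spawn(n_rep)]
    swap_rng = np.random.default_rng(seedseq.spawn(1)[0])

    mask = np.zeros(system.n_beads, dtype=np.int8)
    old = np.zeros((system.catalog["max_set"], 3))
    acc = np.zeros(_kernels.N_CLASSES, dtype=np.int64)

    observers = observers or {}
    obs_out: dict[str, list] = {name: [] for name in observers}
    frames: list[np.ndarray] = []
    frame_replica: list[int] = []
    ex_att = np.zeros(n_rep - 1, dtype=np.int64)
    ex_acc = np.zeros(n_rep - 1, dtype=np.int64)
    parity = 0
    n_recorded = 0

    for block in range(n_blocks):
        for slot in range(n_rep):
            st = slot_state[slot]
            seed = int(rep_seeds[st][block] & 0x7FFFFFFF)
            _run_block(system, states[st], mask, rg_sums[st], rec, rts[slot],
                       seed, old, acc, config)
        # record bottom-temperature slot
        coords0 = states[slot_state[0]]
        for name, fn in observers.items():
            obs_out[name].append(fn(coords0))
        if config.store_frame_stride and n_recorded % config.store_frame_stride == 0:
            frames.append(coords0.astype(np.float32).copy())
        frame_replica.append(slot_state[0])
        n_recorded += 1

        if (block + 1) % exch_every == 0 and n_rep > 1:
            energies = [system.energy(states[slot_state[slot]])[0]
                        for slot in range(n_rep)]
            if not all(np.isfinite(energies)):
                raise RuntimeError(
                    f"non-finite energy mid-run at block {block}: {energies}"
                )
            for k in range(parity, n_rep - 1, 2):
                ex_att[k] += 1
                arg = (betas[k] - betas[k + 1]) * (energies[k] - energies[k + 1])
                if arg >= 0 or swap_rng.random() < math.exp(max(arg, -50.0)):
                    slot_state[k], slot_state[k + 1] = (slot_state[k + 1],
                                                        slot_state[k])
                    energies[k], energies[k + 1] = energies[k + 1], energies[k]
                    ex_acc[k] += 1
            parity ^= 1
        if progress and (block + 1) % max(1, n_blocks // 20) == 0:
            print(f"  block {block + 1}/{n_blocks}", flush=True)

    observables = {name: np.asarray(vals) for name, vals in obs_out.items()}
    n_frames = n_recorded
    equil = int(config.equilibration_fraction * n_frames)
    return TrajectoryEnsemble(
        config=config.snapshot(), n_frames=n_frames, equilibration=equil,
        observables=observables,
        frames=np.array(frames) if frames else None,
        frame_stride=config.store_frame_stride,
        frame_replica=np.array(frame_replica),
        temperature=temps[0],
        exchange_attempts=ex_att, exchange_accepts=ex_acc, seed=config.seed,
    )


def fold_in_restraints(
    chain: CoarseChain,
    restraints: RestraintSet,
    seed: int = 0,
    n_moves: int = 80_000,
    boost: float = 10.0,
    temperature: float = 320.0,
) -> np.ndarray:
    """Assemble a restrained motif before production sampling.

    Restrained ensembles are meant to start with the restraints
    satisfied (the original study starts them from the native fold).
    Without native coordinates, this runs a single-temperature MC stage
    with the NOE constants scaled by ``boost`` so the weak printed
    constants do not have to fight the chain entropy during assembly,
    and returns the final coordinates as the production starting point.
    """
    strong = RestraintSet(
        noe=[(i, j, rmin, rmax, kmin * boost, kmax * boost, fmax * boost)
             for (i, j, rmin, rmax, kmin, kmax, fmax) in restraints.noe],
        dihedral=list(restraints.dihedral),
        rg=restraints.rg,
        label=f"{restraints.label}-fold-in",
    )
    system = build_system(chain, strong)
    coords = chain.coords.astype(float).copy()
    mask = np.zeros(system.n_beads, dtype=np.int8)
    old = np.zeros((system.catalog["max_set"], 3))
    acc = np.zeros(_kernels.N_CLASSES, dtype=np.int64)
    rg_sums = _rg_sums(coords)
    seeds = np.random.SeedSequence(seed).generate_state(
        max(1, n_moves // 5000)).astype(np.uint64)
    done = 0
    for s in seeds:
        step = min(5000, n_moves - done)
        _run_block(system, coords, mask, rg_sums, step, R_KCAL * temperature,
                   int(s & 0x7FFFFFFF), old, acc, SamplerConfig())
        done += step
    return coords


def relax_chain(chain: CoarseChain, n_moves: int = 50_000, seed: int = 0) -> bool:
    """Anneal the extended build layout into a bonded, clash-free start.

    Runs plain 300 K MC (sterics on throughout, so pseudoknot closure
    cannot thread through helices) and writes the result back to
    ``chain.coords``.  Returns True when all bonds are within 1 Å of their
    rest length and the worst steric overlap is < 0.8 Å.
    """
    # pinned-helix moves weighted up: pseudoknot helices can only close
    # their stretched boundary bonds through rigid-body translations
    weights = {"bead": 0.3, "crank": 0.1, "subtree": 0.25, "pinned": 0.2,
               "taper": 0.15}
    system = build_system(chain, move_weights=weights)
    relax_cfg = SamplerConfig(amp_pinned_trans=1.2, amp_pinned_rot=0.15)
    coords = chain.coords.astype(float).copy()
    mask = np.zeros(system.n_beads, dtype=np.int8)
    old = np.zeros((system.catalog["max_set"], 3))
    acc = np.zeros(_kernels.N_CLASSES, dtype=np.int64)
    rg_sums = _rg_sums(coords)
    seeds = np.random.SeedSequence(seed).generate_state(
        max(1, n_moves // 5000)).astype(np.uint64)
    done = 0
    for s in seeds:
        step = min(5000, n_moves - done)
        _run_block(system, coords, mask, rg_sums, step, R_KCAL * 300.0,
                   int(s & 0x7FFFFFFF), old, acc, relax_cfg)
        done += step
    chain.coords = coords
    return _relaxed_ok(chain, system)


def _relaxed_ok(chain: CoarseChain, system: System) -> bool:
    coords = chain.coords
    d = np.linalg.norm(coords[chain.bonds[:, 0]] - coords[chain.bonds[:, 1]],
                       axis=1)
    if np.max(np.abs(d - chain.bond_r0)) > 1.0:
        return False
    # worst pairwise overlap among non-excluded beads
    a = system.arrays
    radii, group_id, excl = a["radii"], a["group_id"], a["excl"]
    n = len(coords)
    worst = 0.0
    for i in range(n):
        delta = coords[i + 1:] - coords[i]
        dist = np.linalg.norm(delta, axis=1)
        sig = radii[i] + radii[i + 1:]
        over = sig - dist
        if len(over) == 0:
            continue
        js = np.nonzero(over > worst)[0] + i + 1
        for j in js:
            if group_id[i] >= 0 and group_id[i] == group_id[j]:
                continue
            if j in excl[i]:
                continue
            worst = max(worst, sig[j - i - 1] - dist[j - i - 1])
    return worst < 0.8


# ---------------------------------------------------------------------------
# frame-level measurements


def radius_of_gyration(frame: np.ndarray, selection=None) -> float:
    """Mass-uniform R_g (Å) over a bead selection (default: all beads)."""
    frame = np.asarray(frame, float)
    if selection is not None:
        selection = np.asarray(selection)
        if selection.size == 0:
            raise ValueError("empty bead selection")
        frame = frame[selection]
    return geometry.radius_of_gyration(frame)


def rmsd_p_beads(frame: np.ndarray, reference: np.ndarray,
                 chain: CoarseChain) -> float:
    """Superposition RMSD over P beads only."""
    sel = chain.beads_of_type(P)
    a = np.asarray(frame, float)[sel]
    b = np.asarray(reference, float)[sel]
    return geometry.kabsch_rmsd(a, b)
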