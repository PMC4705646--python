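"""Contact probabilities and conformational free energies.

The central statistic: the free-energy cost topological constraints place
on forming a tertiary contact,

    dG_topo = -RT ln( P / (1 - P) ),   T = 300 K,

where P is the equilibrium probability that the sugar-bead distance
d_ij < 14 Å for the defining residue sets (at least ``min_pairs`` such
(i, j) combinations; 1 for residue-residue contacts, 2 for TL/TLR and
J6/P3 interactions).  Cooperativity between contacts is the conditional
difference dd G_coop(x, y) = dG_topo(x | y) - dG_topo(x), and absolute
folding free energies follow from the reference-transfer relation
dG_fold = dG_fold_ref - dG_topo_ref + dG_topo.

Unsampled (P = 0) or always-formed (P = 1) contacts yield one-sided
bounds from the pseudocount 1/(N+1); bounds are flagged and never mixed
silently with values.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .builder import CoarseChain
from .forcefield import R_KCAL

DEFAULT_CUTOFF = 14.0  # Å; roughly the distance across a canonical base pair
DEFAULT_T = 300.0


@dataclass
class ContactDefinition:
    set_i: tuple
    set_j: tuple
    cutoff: float = DEFAULT_CUTOFF
    min_pairs: int = 1
    name: str = ""

    def __post_init__(self):
        self.set_i = tuple(self.set_i)
        self.set_j = tuple(self.set_j)
        if set(self.set_i) & set(self.set_j):
            raise ValueError("contact residue sets must be disjoint")
        if self.cutoff <= 0:
            raise ValueError("cutoff must be positive")
        if self.min_pairs < 1:
            raise ValueError("min_pairs must be >= 1")


@dataclass
class FreeEnergyResult:
    p: float
    n_frames: int
    n_contact_frames: int
    dg: float | None             # kcal/mol at T; None when p in {0, 1}
    bound: float | None          # one-sided bound when dg is None
    ci: tuple | None             # block-bootstrap CI on dg
    temperature: float = DEFAULT_T
    conditioning: str = "unrestrained"
    name: str = ""

    @property
    def is_bound(self) -> bool:
        return self.dg is None

    def value_or_bound(self) -> float:
        return self.dg if self.dg is not None else self.bound


# ---------------------------------------------------------------------------
# closed-form pieces


def dg_topo(p: float, temperature: float = DEFAULT_T) -> float:
    """Eq.-style logit free energy -RT ln(p/(1-p)), kcal/mol."""
    if not 0.0 < p < 1.0:
        raise ValueError(
            "p in {0,1}: contact unsampled or always formed; use "
            "dg_topo_bound for the pseudocount bound"
        )
    return -R_KCAL * temperature * math.log(p / (1.0 - p))


def dg_topo_bound(n_frames: int, formed: bool,
                  temperature: float = DEFAULT_T) -> float:
    """One-sided bound for p in {0, 1} using pseudocount 1/(N+1)."""
    p = 1.0 - 1.0 / (n_frames + 1) if formed else 1.0 / (n_frames + 1)
    return dg_topo(p, temperature)


def ddg_coop(dg_conditional: float, dg_unconditional: float) -> float:
    """Cooperativity: negative values mean conditional stabilization."""
    for v in (dg_conditional, dg_unconditional):
        if not math.isfinite(v):
            raise ValueError("cooperativity requires finite free energies")
    return dg_conditional - dg_unconditional


@dataclass
class FoldEnergyParams:
    """Reference-transfer constants for absolute TL/TLR folding energies.

    ``dg_ref_fold`` is the experimentally measured folding free energy of
    the isolated tethered reference system (-0.3 kcal/mol); ``dg_ref_topo``
    is its simulated topological penalty (2.9 kcal/mol).  Their difference
    is the architecture-independent dG_other.
    """

    dg_ref_fold: float = -0.3
    dg_ref_topo: float = 2.9


def dg_fold(dg_topo_value: float, params: FoldEnergyParams | None = None) -> float:
    params = params or FoldEnergyParams()
    return params.dg_ref_fold - params.dg_ref_topo + dg_topo_value


def fjc_pivot_penalty(n_pivots_a: int, n_pivots_b: int,
                      temperature: float = DEFAULT_T) -> float:
    """Gaussian-chain estimate of the dG_topo advantage of fewer pivots.

    For ideal chains the end-to-end contact probability scales as
    n^(-3/2), so a path with ``n_pivots_a`` flexible pivots is favored
    over one with ``n_pivots_b`` by -RT (3/2) ln(n_b / n_a).
    """
    if min(n_pivots_a, n_pivots_b) < 1:
        raise ValueError("pivot counts must be >= 1")
    return -R_KCAL * temperature * 1.5 * math.log(n_pivots_b / n_pivots_a)


# ---------------------------------------------------------------------------
# contact probabilities from ensembles


def contact_mask(chain: CoarseChain, frames: np.ndarray,
                 cdef: ContactDefinition) -> np.ndarray:
    """Boolean per-frame indicator of the contact over stored frames."""
    si = chain.s_beads_of(cdef.set_i)
    sj = chain.s_beads_of(cdef.set_j)
    frames = np.asarray(frames, float)
    out = np.empty(len(frames), dtype=bool)
    for k, coords in enumerate(frames):
        d = np.linalg.norm(coords[si][:, None, :] - coords[sj][None, :, :],
                           axis=-1)
        out[k] = int((d < cdef.cutoff).sum()) >= cdef.min_pairs
    return out


def make_contact_observer(chain: CoarseChain, cdef: ContactDefinition):
    si = chain.s_beads_of(cdef.set_i)
    sj = chain.s_beads_of(cdef.set_j)

    def obs(coords):
        d = np.linalg.norm(coords[si][:, None, :] - coords[sj][None, :, :],
                           axis=-1)
        return float((d < cdef.cutoff).sum() >= cdef.min_pairs)

    return obs


def contact_probability_from_mask(
    mask: np.ndarray,
    condition: np.ndarray | None = None,
    n_blocks: int = 50,
    n_boot: int = 1000,
    seed: int = 0,
    temperature: float = DEFAULT_T,
    conditioning: str = "unrestrained",
    name: str = "",
) -> FreeEnergyResult:
    """Contact probability + dG_topo with a block-bootstrap CI.

    The bootstrap resamples contiguous frame blocks (correlation-aware);
    when the point estimate is 0 or 1 the result carries a pseudocount
    bound instead of a value.
    """
    mask = np.asarray(mask, dtype=bool)
    if condition is not None:
        condition = np.asarray(condition, dtype=bool)
        if len(condition) != len(mask):
            raise ValueError("condition mask not aligned to frames")
        mask = mask[condition]
    n = len(mask)
    if n == 0:
        raise ValueError("zero frames after masking/conditioning")
    hits = int(mask.sum())
    p = hits / n

    ci = None
    if 0 < hits < n:
        rng = np.random.default_rng(seed)
        nb = min(n_blocks, n)
        blocks = np.array_split(mask, nb)
        block_sums = np.array([b.sum() for b in blocks])
        block_lens = np.array([len(b) for b in blocks])
        pick = rng.integers(0, nb, size=(n_boot, nb))
        ps = block_sums[pick].sum(axis=1) / block_lens[pick].sum(axis=1)
        # pseudocount keeps resampled logits finite
        ps = np.clip(ps, 1.0 / (n + 1), 1.0 - 1.0 / (n + 1))
        dgs = -R_KCAL * temperature * np.log(ps / (1.0 - ps))
        ci = (float(np.percentile(dgs, 2.5)), float(np.percentile(dgs, 97.5)))
        return FreeEnergyResult(p, n, hits, dg_topo(p, temperature), None, ci,
                                temperature, conditioning, name)
    bound = dg_topo_bound(n, formed=hits == n, temperature=temperature)
    return FreeEnergyResult(p, n, hits, None, bound, None, temperature,
                            conditioning, name)


def contact_probability(
    traj,
    chain: CoarseChain,
    cdef: ContactDefinition,
    condition: np.ndarray | None = None,
    **kw,
) -> FreeEnergyResult:
    """Contact probability from a trajectory's stored production frames."""
    mask = contact_mask(chain, traj.production_frames(), cdef)
    return contact_probability_from_mask(mask, condition=condition,
                                         name=cdef.name, **kw)


# ---------------------------------------------------------------------------
# matrices / maps


def region_contact(chain: CoarseChain, a: str, b: str,
                   min_pairs: int = 2, cutoff: float = DEFAULT_CUTOFF,
                   name: str | None = None) -> ContactDefinition:
    return ContactDefinition(chain.region(a), chain.region(b), cutoff,
                             min_pairs, name or f"{a}/{b}")


def tl_tlr_matrix(
    chain: CoarseChain,
    traj,
    loops,
    receptors,
    native_pairs=(("L2", "J8"), ("L9", "J5")),
    min_pairs: int = 2,
    cutoff: float = DEFAULT_CUTOFF,
    seed: int = 0,
) -> pd.DataFrame:
    """dG_topo for every tetraloop/receptor combination (Figure-style
    matrix); native pairs are flagged."""
    frames = traj.production_frames()
    rows = []
    native = {tuple(p) for p in native_pairs}
    for tl in loops:
        for tlr in receptors:
            cdef = region_contact(chain, tl, tlr, min_pairs, cutoff)
            res = contact_probability_from_mask(
                contact_mask(chain, frames, cdef), seed=seed, name=cdef.name)
            rows.append({
                "TL": tl, "TLR": tlr, "native": (tl, tlr) in native,
                "p": res.p, "dG_topo": res.value_or_bound(),
                "is_bound": res.is_bound,
                "ci_low": res.ci[0] if res.ci else np.nan,
                "ci_high": res.ci[1] if res.ci else np.nan,
                "N": res.n_frames,
            })
    return pd.DataFrame(rows)


def pairwise_dg_map(
    chain: CoarseChain,
    traj,
    row_regions,
    residues=None,
    min_pairs: int = 1,
    cutoff: float = DEFAULT_CUTOFF,
    seed: int = 0,
) -> pd.DataFrame:
    """Residue-resolved dG_topo heat-map table (region rows vs residues)."""
    frames = traj.production_frames()
    residues = residues or list(range(1, chain.n_res + 1))
    rows = []
    for region in row_regions:
        rset = set(chain.region(region))
        for res in residues:
            if res in rset:
                continue
            cdef = ContactDefinition(tuple(sorted(rset)), (res,), cutoff,
                                     min_pairs, name=f"{region}/{res}")
            r = contact_probability_from_mask(
                contact_mask(chain, frames, cdef), n_boot=0 or 200, seed=seed)
            rows.append({"region": region, "residue": res, "p": r.p,
                         "dG_topo": r.value_or_bound(), "is_bound": r.is_bound})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# P4/P6 stacking proxy


def detect_p4p6_stacking(
    coords: np.ndarray,
    chain: CoarseChain,
    helix_a: str = "P4",
    helix_b: str = "P6",
    beta_min: float = 150.0,
    gap_max: float = 7.0,
) -> bool:
    """Coaxial-stacking proxy of triple-helix formation.

    True iff the interhelical bend beta_h(P4, P6) exceeds ``beta_min``
    (with 5'-strand reference frames, coaxial stacking is anti-aligned,
    beta ~ 180) and the centroids of the two facing helix-end base pairs
    are closer than ``gap_max`` Å.  Thresholds are configurable stand-ins
    for the original stacking criteria.
    """
    from .euler import euler_angles, helix_frame

    fa = helix_frame(chain, coords, helix_a)
    fb = helix_frame(chain, coords, helix_b)
    beta = euler_angles(fa, fb)[1]
    if beta <= beta_min:
        return False
    return _facing_gap(coords, chain, helix_a, helix_b) < gap_max


def _facing_gap(coords, chain, helix_a, helix_b) -> float:
    ha = chain.topology.helix_by_name(helix_a)
    hb = chain.topology.helix_by_name(helix_b)

    def end_centroids(h):
        out = []
        for pr in (h.pairs[0], h.pairs[-1]):
            beads = [chain.bead_index(pr.i, t) for t in (0, 1, 2)]
            beads += [chain.bead_index(pr.j, t) for t in (0, 1, 2)]
            out.append(coords[beads].mean(axis=0))
        return out

    ca = end_centroids(ha)
    cb = end_centroids(hb)
    return min(float(np.linalg.norm(a - b)) for a in ca for b in cb)


def make_stacking_observer(chain: CoarseChain, **kw):
    def obs(coords):
        return float(detect_p4p6_stacking(coords, chain, **kw))

    return obs
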