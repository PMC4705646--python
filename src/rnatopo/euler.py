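"""Interhelical Euler angles and fraction-of-conformational-space statistics.

For each helix a right-handed orthonormal frame is fixed: z along the
best-fit helix axis oriented 5'->3' of the reference strand, x toward the
reference 5' sugar bead projected perpendicular to z, y = z cross x.  The
relative rotation between two helix frames is decomposed in the ZYZ
(twist-bend-twist) convention into (alpha_h, beta_h, gamma_h) with
alpha_h, gamma_h in [-180, 180) and beta_h in [0, 180].

Discretizing the angles on a regular grid gives a finite conformational
space; the fraction of occupied bins (F_samp, and joint 2x/3x variants for
pseudoknotted junctions) measures how strongly topological constraints
limit interhelical orientation.  Note the statistic is the raw occupied
fraction of the (alpha, beta, gamma) grid: no sin(beta) volume correction
is applied, and the same convention must be used for any reference
constant it is compared against.

The absolute angle values depend on this frame convention; the fraction
and mutual-information statistics are convention-robust (a change of
convention only relabels bins).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from . import geometry
from .builder import CoarseChain, S

_GIMBAL_TOL = 1e-9


@dataclass
class HelixFrame:
    origin: np.ndarray
    axes: np.ndarray            # columns x, y, z (frame -> lab)
    helix: str = ""
    reference_strand: int = 1

    def __post_init__(self):
        r = self.axes
        if not np.allclose(r.T @ r, np.eye(3), atol=1e-9):
            raise ValueError("frame axes must be orthonormal")
        if np.linalg.det(r) < 0:
            raise ValueError("frame must be right-handed")


@dataclass
class EulerSeries:
    """Per-frame (alpha_h, beta_h, gamma_h) in degrees for one helix pair."""

    angles: np.ndarray          # (N, 3)
    pair: tuple = ("A", "B")
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.angles = np.asarray(self.angles, float).reshape(-1, 3)

    def __len__(self) -> int:
        return len(self.angles)


# ---------------------------------------------------------------------------
# frames and decomposition


def helix_frame(
    chain: CoarseChain,
    coords: np.ndarray,
    helix: str,
    reference_strand: int = 1,
) -> HelixFrame:
    """Orthonormal frame of a helix in one conformation.

    Requires >= 2 base pairs (the axis of a 1-bp helix is undefined).
    """
    h = chain.topology.helix_by_name(helix)
    if h.n_pairs < 2:
        raise ValueError(f"helix {helix} has {h.n_pairs} bp; axis undefined")
    coords = np.asarray(coords, float)
    s_i = np.array([chain.bead_index(p.i, S) for p in h.pairs])
    s_j = np.array([chain.bead_index(p.j, S) for p in h.pairs])

    # the helix axis is found by superposing the ideal A-form template
    # onto the current sugar beads (exact for built helices, which are
    # rigid template copies; a best-fit helical axis for mapped ones)
    t1, t2 = _template_s_cache(h.n_pairs)
    tmpl = np.vstack([t1, t2])
    cur = np.vstack([coords[s_i], coords[s_j]])
    rot, trans = geometry.kabsch_transform(tmpl, cur)
    center = rot @ tmpl.mean(axis=0) + trans
    z = rot @ np.array([0.0, 0.0, 1.0])
    if reference_strand == 2:
        z = -z
        ref5_s = coords[s_j[-1]]
    else:
        ref5_s = coords[s_i[0]]
    x = ref5_s - center
    x = x - np.dot(x, z) * z
    nx = np.linalg.norm(x)
    if nx < 1e-9:
        # degenerate: reference sugar on the axis; fall back to any normal
        x = np.array([1.0, 0.0, 0.0]) - z[0] * z
        nx = np.linalg.norm(x)
    x = x / nx
    y = np.cross(z, x)
    return HelixFrame(origin=center, axes=np.column_stack([x, y, z]),
                      helix=helix, reference_strand=reference_strand)


_S_CACHE: dict = {}


def _template_s_cache(n_bp: int):
    if n_bp not in _S_CACHE:
        from . import geometry as g

        s1, s2 = g.aform_duplex(n_bp)
        # strand2 beads in pair order (template strand2 is listed 5'->3')
        _S_CACHE[n_bp] = (s1[:, 1].copy(), s2[::-1, 1].copy())
    return _S_CACHE[n_bp]


def euler_angles(frame_a: HelixFrame | np.ndarray,
                 frame_b: HelixFrame | np.ndarray) -> tuple[float, float, float]:
    """ZYZ decomposition of the rotation taking frame A into frame B.

    Returns (alpha_h, beta_h, gamma_h) in degrees; at the gimbal locus
    (beta = 0 or 180) gamma := 0 and the full twist is assigned to alpha.
    """
    ra = frame_a.axes if isinstance(frame_a, HelixFrame) else np.asarray(frame_a)
    rb = frame_b.axes if isinstance(frame_b, HelixFrame) else np.asarray(frame_b)
    r = ra.T @ rb
    return decompose_zyz(r)


def decompose_zyz(r: np.ndarray) -> tuple[float, float, float]:
    cb = min(1.0, max(-1.0, r[2, 2]))
    beta = math.degrees(math.acos(cb))
    sb2 = r[0, 2] ** 2 + r[1, 2] ** 2
    if sb2 < _GIMBAL_TOL:
        gamma = 0.0
        if cb > 0:
            alpha = math.degrees(math.atan2(r[1, 0], r[0, 0]))
        else:
            # beta = 180: R = Rz(alpha - gamma) Ry(pi); assign all to alpha
            alpha = math.degrees(math.atan2(-r[1, 0], -r[0, 0]))
    else:
        alpha = math.degrees(math.atan2(r[1, 2], r[0, 2]))
        gamma = math.degrees(math.atan2(r[2, 1], -r[2, 0]))
    if alpha >= 180.0:
        alpha -= 360.0
    if gamma >= 180.0:
        gamma -= 360.0
    return alpha, beta, gamma


def recompose_zyz(alpha: float, beta: float, gamma: float) -> np.ndarray:
    """Inverse of :func:`decompose_zyz` (degrees in, matrix out)."""
    a, b, g = (math.radians(v) for v in (alpha, beta, gamma))

    def rz(t):
        return np.array([[math.cos(t), -math.sin(t), 0],
                         [math.sin(t), math.cos(t), 0],
                         [0, 0, 1.0]])

    ry = np.array([[math.cos(b), 0, math.sin(b)],
                   [0, 1.0, 0],
                   [-math.sin(b), 0, math.cos(b)]])
    return rz(a) @ ry @ rz(g)


def euler_series(
    chain: CoarseChain,
    frames: np.ndarray,
    helix_a: str,
    helix_b: str,
    reference_strands: tuple[int, int] = (1, 1),
) -> EulerSeries:
    """Euler-angle series for a helix pair over stored coordinate frames."""
    out = np.empty((len(frames), 3))
    for k, coords in enumerate(frames):
        fa = helix_frame(chain, coords, helix_a, reference_strands[0])
        fb = helix_frame(chain, coords, helix_b, reference_strands[1])
        out[k] = euler_angles(fa, fb)
    return EulerSeries(out, pair=(helix_a, helix_b),
                       meta={"reference_strands": reference_strands})


def decompose_zyz_batch(r: np.ndarray) -> np.ndarray:
    """Vectorized ZYZ decomposition for an (F, 3, 3) rotation stack."""
    r = np.asarray(r, float)
    cb = np.clip(r[:, 2, 2], -1.0, 1.0)
    beta = np.degrees(np.arccos(cb))
    sb2 = r[:, 0, 2] ** 2 + r[:, 1, 2] ** 2
    alpha = np.degrees(np.arctan2(r[:, 1, 2], r[:, 0, 2]))
    gamma = np.degrees(np.arctan2(r[:, 2, 1], -r[:, 2, 0]))
    gim = sb2 < _GIMBAL_TOL
    if np.any(gim):
        pos = gim & (cb > 0)
        neg = gim & (cb <= 0)
        alpha = np.where(pos, np.degrees(np.arctan2(r[:, 1, 0], r[:, 0, 0])),
                         alpha)
        alpha = np.where(neg, np.degrees(np.arctan2(-r[:, 1, 0], -r[:, 0, 0])),
                         alpha)
        gamma = np.where(gim, 0.0, gamma)
    alpha = np.where(alpha >= 180.0, alpha - 360.0, alpha)
    gamma = np.where(gamma >= 180.0, gamma - 360.0, gamma)
    return np.column_stack([alpha, beta, gamma])


class OrientationRecorder:
    """Cheap per-frame recorder for interhelical Euler-angle series.

    During sampling only the sugar-bead coordinates of the involved
    helices are stored (a few hundred bytes per frame); helix frames and
    ZYZ angles are computed afterwards with batched linear algebra.
    """

    def __init__(self, chain: CoarseChain, helices: list[str],
                 reference_strands: dict | None = None):
        self.chain = chain
        self.helices = list(helices)
        self.ref = reference_strands or {}
        sel: list[int] = []
        self._slices = {}
        for name in self.helices:
            h = chain.topology.helix_by_name(name)
            if h.n_pairs < 2:
                raise ValueError(f"helix {name} has <2 bp; axis undefined")
            beads = [chain.bead_index(p.i, S) for p in h.pairs]
            beads += [chain.bead_index(p.j, S) for p in h.pairs]
            self._slices[name] = slice(len(sel), len(sel) + len(beads))
            sel.extend(beads)
        self.selection = np.array(sel, dtype=np.int64)

    def observer(self):
        selection = self.selection

        def obs(coords):
            return coords[selection].astype(np.float32)

        return obs

    def _frames(self, stack: np.ndarray, name: str) -> np.ndarray:
        """Batched helix frames: (F, 3, 3) axes column matrices."""
        h = self.chain.topology.helix_by_name(name)
        t1, t2 = _template_s_cache(h.n_pairs)
        tmpl = np.vstack([t1, t2])
        tc = tmpl - tmpl.mean(axis=0)
        cur = stack[:, self._slices[name], :].astype(float)
        cc = cur - cur.mean(axis=1, keepdims=True)
        hmat = np.einsum("ki,fkj->fij", tc, cc)
        u, s, vt = np.linalg.svd(hmat)
        det = np.linalg.det(np.einsum("fij,fjk->fik",
                                      np.transpose(vt, (0, 2, 1)),
                                      np.transpose(u, (0, 2, 1))))
        flip = np.ones((len(cur), 3))
        flip[:, 2] = det
        rot = np.einsum("fij,fj,fkj->fik", np.transpose(vt, (0, 2, 1)), flip, u)
        z = rot[:, :, 2]
        ref_strand = self.ref.get(name, 1)
        n_bp = h.n_pairs
        if ref_strand == 2:
            z = -z
            ref5 = cur[:, 2 * n_bp - 1, :]
        else:
            ref5 = cur[:, 0, :]
        center = cur.mean(axis=1)
        x = ref5 - center
        x = x - (x * z).sum(axis=1, keepdims=True) * z
        x /= np.linalg.norm(x, axis=1, keepdims=True)
        y = np.cross(z, x)
        return np.stack([x, y, z], axis=2)

    def series(self, stack: np.ndarray, helix_a: str, helix_b: str) -> EulerSeries:
        fa = self._frames(stack, helix_a)
        fb = self._frames(stack, helix_b)
        rel = np.einsum("fji,fjk->fik", fa, fb)
        return EulerSeries(decompose_zyz_batch(rel), pair=(helix_a, helix_b))


def make_euler_observer(chain: CoarseChain, helix_a: str, helix_b: str,
                        reference_strands=(1, 1)):
    """Per-frame observer returning (alpha, beta, gamma) for a helix pair."""

    def obs(coords):
        fa = helix_frame(chain, coords, helix_a, reference_strands[0])
        fb = helix_frame(chain, coords, helix_b, reference_strands[1])
        return np.array(euler_angles(fa, fb))

    return obs


# ---------------------------------------------------------------------------
# binning and fractions


def _check_width(bin_width: float) -> None:
    if 360.0 % bin_width or 180.0 % bin_width:
        raise ValueError(f"bin width {bin_width} must divide 360 and 180 evenly")


def n_bins(bin_width: float) -> int:
    """Cells of the (alpha, beta, gamma) grid at the given width (deg)."""
    _check_width(bin_width)
    w = bin_width
    return int(round((360 / w) * (180 / w) * (360 / w)))


def bin_indices(angles: np.ndarray, bin_width: float) -> np.ndarray:
    """Linear grid-cell index per frame; edge samples go to the higher bin,
    the single point beta = 180 belongs to the last beta bin."""
    _check_width(bin_width)
    a = np.asarray(angles, float).reshape(-1, 3)
    w = bin_width
    na, nb = int(360 // w), int(180 // w)
    ia = np.floor((a[:, 0] + 180.0) / w).astype(np.int64)
    ib = np.floor(a[:, 1] / w).astype(np.int64)
    ig = np.floor((a[:, 2] + 180.0) / w).astype(np.int64)
    ia = np.clip(ia, 0, na - 1)
    ib = np.clip(ib, 0, nb - 1)
    ig = np.clip(ig, 0, na - 1)
    return (ia * nb + ib) * na + ig


def fraction_sampled(series: EulerSeries | np.ndarray,
                     bin_width: float = 10.0) -> float:
    """Occupied-bin fraction of the single-pair orientation grid."""
    angles = series.angles if isinstance(series, EulerSeries) else series
    if len(angles) == 0:
        raise ValueError("empty Euler series")
    occ = len(np.unique(bin_indices(angles, bin_width)))
    return occ / n_bins(bin_width)


def fraction_joint(series_list, bin_width: float = 30.0) -> float:
    """Fraction of joint k x (alpha, beta, gamma) combinations sampled.

    ``k = len(series_list)`` in {1, 2, 3}; all series must be frame-aligned.
    """
    k = len(series_list)
    if k not in (1, 2, 3):
        raise ValueError("joint fraction defined for 1-3 series")
    lengths = {len(s) for s in series_list}
    if len(lengths) != 1:
        raise ValueError("misaligned series (different frame counts)")
    if lengths == {0}:
        raise ValueError("empty Euler series")
    base = n_bins(bin_width)
    combined = np.zeros(next(iter(lengths)), dtype=np.int64)
    for s in series_list:
        angles = s.angles if isinstance(s, EulerSeries) else s
        combined = combined * base + bin_indices(angles, bin_width)
    occ = len(np.unique(combined))
    return occ / base**k


def reference_subsample_size(
    k: int,
    n_ref: int = 499_000,
    k_ref: int = 3,
    bin_width: float = 60.0,
) -> int:
    """Subsample size keeping N_conf / N_bin constant across junction orders.

    The reference density is ``n_ref`` conformations on the k_ref-fold
    joint grid; the matched size for a k-fold junction is rounded up.
    """
    base = n_bins(bin_width)
    return math.ceil(n_ref * base**k / base**k_ref)


def fraction_norm(
    series_list,
    f_trna: float | None,
    n_conf: int,
    seed: int = 0,
    bin_width: float = 60.0,
) -> dict:
    """Normalized fraction F_norm = F*_samp / F_trna.

    F*_samp is the joint fraction on a random subsample of ``n_conf``
    frames (matching the reference N_conf/N_bin density); ``f_trna`` is the
    reference molecule's fraction and must be supplied by the user (it is
    an external constant, never defaulted).
    """
    if f_trna is None:
        raise ValueError(
            "F_trna must be supplied (reference tRNA fraction; this package "
            "does not ship a default)"
        )
    pool = len(series_list[0])
    if n_conf > pool:
        raise ValueError(f"subsample {n_conf} exceeds pool of {pool} frames")
    rng = np.random.default_rng(seed)
    pick = rng.choice(pool, size=n_conf, replace=False)
    sub = [EulerSeries((s.angles if isinstance(s, EulerSeries) else s)[pick])
           for s in series_list]
    f_star = fraction_joint(sub, bin_width=bin_width)
    return {"f_star_samp": f_star, "f_norm": f_star / f_trna,
            "n_conf": n_conf, "subsample_seed": seed}


def series_to_tsv(series: EulerSeries) -> str:
    lines = ["frame\talpha\tbeta\tgamma"]
    for k, (a, b, g) in enumerate(series.angles):
        lines.append(f"{k}\t{a:.3f}\t{b:.3f}\t{g:.3f}")
    return "\n".join(lines) + "\n"
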