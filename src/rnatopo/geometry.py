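"""Geometric primitives: ideal A-form template, superposition, gyration.

The A-form duplex template is generated from idealized fiber-like
cylindrical parameters (rise, twist, per-bead radius and phase).  The
template fixes both the rigid-body geometry of every helix and the
equilibrium values of the bonded terms of the coarse-grained energy
function (bond lengths and backbone angles are *measured* from the
template, keeping the model self-consistent).
"""

from __future__ import annotations

import numpy as np

# idealized A-form helical parameters (per base-pair step)
RISE = 2.81  # Å
TWIST = 32.7  # degrees

# cylindrical placement of the three beads of a paired residue:
# (radius Å, phase offset from the pair bisector deg, z offset Å)
_R_S, _PHI_S, _Z_S = 9.4, 33.5, 0.0     # sugar bead (C1' position)
_R_B, _PHI_B, _Z_B = 8.0, 30.0, 0.0     # base bead (glycosidic N)
_R_P, _PHI_P, _Z_P = 9.7, 17.15, -1.405  # phosphate, between S(k-1) and S(k)


def _cyl(r: float, phi_deg: float, z: float) -> np.ndarray:
    phi = np.deg2rad(phi_deg)
    return np.array([r * np.cos(phi), r * np.sin(phi), z])


def aform_duplex(n_bp: int) -> tuple[np.ndarray, np.ndarray]:
    """Bead coordinates for an ideal A-form duplex of ``n_bp`` pairs.

    Returns ``(strand1, strand2)`` each of shape (n_bp, 3, 3): per residue
    the P, S, B bead positions.  Strand 1 runs 5'->3' with the helix axis
    (+z); strand 2 is the antiparallel complement, listed 5'->3' as well
    (i.e. from pair index n_bp-1 down to 0 it pairs strand1 reversed).
    """
    if n_bp < 1:
        raise ValueError("helix needs >= 1 base pair")
    s1 = np.empty((n_bp, 3, 3))
    s2 = np.empty((n_bp, 3, 3))
    for k in range(n_bp):
        theta = k * TWIST
        z = k * RISE
        # strand 1: phases +, backbone advancing with +z
        s1[k, 1] = _cyl(_R_S, theta + _PHI_S, z + _Z_S)
        s1[k, 2] = _cyl(_R_B, theta + _PHI_B, z + _Z_B)
        s1[k, 0] = _cyl(_R_P, theta + _PHI_S - _PHI_P + 0.0, z + _Z_P)
        # strand 2: mirrored phases, backbone advancing with -z
        s2[k, 1] = _cyl(_R_S, theta - _PHI_S, z - _Z_S)
        s2[k, 2] = _cyl(_R_B, theta - _PHI_B, z - _Z_B)
        s2[k, 0] = _cyl(_R_P, theta - _PHI_S + _PHI_P, z - _Z_P)
    # reorder strand2 5'->3' (descending pair index)
    return s1, s2[::-1].copy()


def template_bond_lengths() -> dict[str, float]:
    """Equilibrium bond lengths measured from the template (Å)."""
    s1, _ = aform_duplex(4)
    ps = float(np.linalg.norm(s1[1, 0] - s1[1, 1]))       # P(i)-S(i)
    sp = float(np.linalg.norm(s1[1, 1] - s1[2, 0]))       # S(i)-P(i+1)
    sb = float(np.linalg.norm(s1[1, 1] - s1[1, 2]))       # S(i)-B(i)
    return {"PS": ps, "SP": sp, "SB": sb}


def template_backbone_angles() -> dict[str, float]:
    """Equilibrium backbone angles measured from the template (degrees)."""
    s1, _ = aform_duplex(5)

    def ang(a, b, c):
        u, v = a - b, c - b
        cos = np.dot(u, v) / (np.linalg.norm(u) * np.linalg.norm(v))
        return float(np.degrees(np.arccos(np.clip(cos, -1, 1))))

    psp = ang(s1[1, 0], s1[1, 1], s1[2, 0])  # P(i)-S(i)-P(i+1)
    sps = ang(s1[1, 1], s1[2, 0], s1[2, 1])  # S(i)-P(i+1)-S(i+1)
    return {"PSP": psp, "SPS": sps}


def dihedral(p0, p1, p2, p3) -> float:
    """Signed dihedral angle in degrees for four points."""
    b0, b1, b2 = p1 - p0, p2 - p1, p3 - p2
    n1 = np.cross(b0, b1)
    n2 = np.cross(b1, b2)
    m1 = np.cross(n1, b1 / np.linalg.norm(b1))
    x = np.dot(n1, n2)
    y = np.dot(m1, n2)
    return float(np.degrees(np.arctan2(y, x)))


def radius_of_gyration(coords: np.ndarray) -> float:
    """Mass-uniform radius of gyration of a coordinate set (Å)."""
    coords = np.asarray(coords, dtype=float)
    if coords.ndim != 2 or len(coords) < 2:
        raise ValueError("radius of gyration needs >= 2 beads")
    c = coords - coords.mean(axis=0)
    return float(np.sqrt((c * c).sum() / len(coords)))


def kabsch_rmsd(a: np.ndarray, b: np.ndarray) -> float:
    """Least-squares superposition RMSD between two point sets."""
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    if a.shape != b.shape:
        raise ValueError(f"point-count mismatch {a.shape} vs {b.shape}")
    a0 = a - a.mean(axis=0)
    b0 = b - b.mean(axis=0)
    h = a0.T @ b0
    u, s, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(u @ vt))
    s = s.copy()
    s[-1] *= d
    msd = (np.sum(a0 * a0) + np.sum(b0 * b0) - 2.0 * s.sum()) / len(a)
    return float(np.sqrt(max(msd, 0.0)))


def kabsch_transform(a: np.ndarray, b: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Optimal rigid transform (R, t) minimizing ||R a + t - b||."""
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    ca, cb = a.mean(axis=0), b.mean(axis=0)
    h = (a - ca).T @ (b - cb)
    u, s, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    r = vt.T @ np.diag([1.0, 1.0, d]) @ u.T
    return r, cb - r @ ca


def rotation_about_axis(axis: np.ndarray, angle_rad: float) -> np.ndarray:
    """Rotation matrix about a (normalized) axis, Rodrigues form."""
    axis = np.asarray(axis, float)
    axis = axis / np.linalg.norm(axis)
    k = np.array([
        [0, -axis[2], axis[1]],
        [axis[2], 0, -axis[0]],
        [-axis[1], axis[0], 0],
    ])
    return np.eye(3) + np.sin(angle_rad) * k + (1 - np.cos(angle_rad)) * (k @ k)
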