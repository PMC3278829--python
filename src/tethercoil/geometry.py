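"""Internal-coordinate backbone geometry.

Bond lengths and angles follow the Engh & Huber restraint set for a trans
polypeptide backbone. Chains are built atom-by-atom with the NeRF (natural
extension reference frame) construction: each new atom is placed from three
previously placed atoms by a bond length, a bond angle and a torsion.

All interface angles are degrees; the dihedral sign convention is the
standard IUPAC one (cis = 0, trans = 180, right-handed rotation positive).
"""

from __future__ import annotations

import math

import numpy as np

# Engh-Huber backbone restraints (Å, degrees)
BOND_N_CA = 1.458
BOND_CA_C = 1.525
BOND_C_N = 1.329
BOND_C_O = 1.231
BOND_CA_CB = 1.530

ANGLE_N_CA_C = 111.2
ANGLE_CA_C_N = 116.2
ANGLE_C_N_CA = 121.7
ANGLE_CA_C_O = 120.8
ANGLE_N_CA_CB = 109.5

#: trans peptide bond; cis-proline is not modelled
OMEGA_TRANS = 180.0

#: improper torsion C-N-CA-CB fixing the L-configuration at CA
#: (measured on CCD ideal residue coordinates)
IMPROPER_C_N_CA_CB = -120.0


def place_atom(a, b, c, bond: float, angle_deg: float, torsion_deg: float):
    """Place atom d bonded to c with ``|cd| = bond``, angle(b,c,d) and
    torsion(a,b,c,d) as given.  Inputs and output are 3-tuples of floats;
    kept scalar (no ndarray) because this sits in the innermost build loop.
    """
    ang = math.radians(angle_deg)
    tor = math.radians(torsion_deg)
    # local displacement in the (bc, m, n) frame
    d2x = -bond * math.cos(ang)
    d2y = bond * math.sin(ang) * math.cos(tor)
    d2z = bond * math.sin(ang) * math.sin(tor)

    bcx, bcy, bcz = c[0] - b[0], c[1] - b[1], c[2] - b[2]
    r = math.sqrt(bcx * bcx + bcy * bcy + bcz * bcz)
    bcx, bcy, bcz = bcx / r, bcy / r, bcz / r

    abx, aby, abz = b[0] - a[0], b[1] - a[1], b[2] - a[2]
    # n = ab x bc, normalised
    nx = aby * bcz - abz * bcy
    ny = abz * bcx - abx * bcz
    nz = abx * bcy - aby * bcx
    r = math.sqrt(nx * nx + ny * ny + nz * nz)
    nx, ny, nz = nx / r, ny / r, nz / r
    # m = n x bc
    mx = ny * bcz - nz * bcy
    my = nz * bcx - nx * bcz
    mz = nx * bcy - ny * bcx

    return (
        c[0] + bcx * d2x + mx * d2y + nx * d2z,
        c[1] + bcy * d2x + my * d2y + ny * d2z,
        c[2] + bcz * d2x + mz * d2y + nz * d2z,
    )


def dihedral(p0, p1, p2, p3) -> float:
    """Signed dihedral angle p0-p1-p2-p3 in degrees, IUPAC convention."""
    p0 = np.asarray(p0, dtype=float)
    p1 = np.asarray(p1, dtype=float)
    p2 = np.asarray(p2, dtype=float)
    p3 = np.asarray(p3, dtype=float)
    b0 = p0 - p1
    b1 = p2 - p1
    b2 = p3 - p2
    b1 = b1 / np.linalg.norm(b1)
    v = b0 - np.dot(b0, b1) * b1
    w = b2 - np.dot(b2, b1) * b1
    x = np.dot(v, w)
    y = np.dot(np.cross(b1, v), w)
    return float(np.degrees(np.arctan2(y, x)))


def bond_angle(a, b, c) -> float:
    """Bond angle a-b-c in degrees."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    c = np.asarray(c, dtype=float)
    u = a - b
    v = c - b
    cosang = np.dot(u, v) / (np.linalg.norm(u) * np.linalg.norm(v))
    return float(np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0))))


def wrap_angle(angle_deg: float) -> float:
    """Wrap an angle into (-180, 180]."""
    a = (angle_deg + 180.0) % 360.0 - 180.0
    return 180.0 if a == -180.0 else a


def random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Uniform random proper rotation matrix (via QR of a Gaussian matrix)."""
    m = rng.normal(size=(3, 3))
    q, r = np.linalg.qr(m)
    q *= np.sign(np.diag(r))
    if np.linalg.det(q) < 0:
        q[:, 0] = -q[:, 0]
    return q
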