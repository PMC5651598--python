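"""Low-level 3D geometry: signed dihedral angles and internal-coordinate placement.

The dihedral convention is IUPAC: for a bonded chain A-B-C-D, the torsion is
the signed angle between the plane through A,B,C and the plane through B,C,D,
measured looking down the B->C axis, positive for a right-handed (clockwise)
rotation of the far bond relative to the near bond.  Values are reported in
radians in the half-open interval [-pi, pi); the anti-periplanar arrangement
is canonically -pi.
"""

from __future__ import annotations

import math

import numpy as np

__all__ = ["dihedral", "nerf_place", "wrap_angle", "UNDEFINED"]

#: Sentinel for an undefined angle.  Torsion matrices use NaN so that whole
#: arrays of angles can be handled with vectorized numpy operations.
UNDEFINED = math.nan

# Two triples are treated as degenerate (collinear) when the cross product of
# the bond vectors is shorter than this fraction of the bond-length product.
_COLLINEAR_TOL = 1e-9


def wrap_angle(t: float) -> float:
    """Wrap an angle in radians to the canonical interval [-pi, pi)."""
    w = math.remainder(t, 2.0 * math.pi)  # (-pi, pi], ties to even
    return -math.pi if w >= math.pi else w


def dihedral(a, b, c, d) -> float:
    """Signed torsion angle of the atom chain a-b-c-d, in [-pi, pi).

    Returns NaN (undefined) when either atom triple is collinear, i.e. the
    planes are not determined.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    c = np.asarray(c, dtype=float)
    d = np.asarray(d, dtype=float)

    b0 = a - b
    axis = c - b
    b2 = d - c
    norm = np.linalg.norm(axis)
    if norm < _COLLINEAR_TOL:
        return UNDEFINED
    axis = axis / norm

    # components of the outer bonds perpendicular to the rotation axis
    v = b0 - np.dot(b0, axis) * axis
    w = b2 - np.dot(b2, axis) * axis
    nv = np.linalg.norm(v)
    nw = np.linalg.norm(w)
    if nv < _COLLINEAR_TOL * max(1.0, np.linalg.norm(b0)) or nw < _COLLINEAR_TOL * max(
        1.0, np.linalg.norm(b2)
    ):
        return UNDEFINED

    x = float(np.dot(v, w))
    y = float(np.dot(np.cross(axis, v), w))
    ang = math.atan2(y, x)
    return -math.pi if ang >= math.pi else ang


def nerf_place(a, b, c, bond_len: float, bond_angle_deg: float, torsion_deg: float):
    """Place atom d from the reference frame a-b-c (natural-extension placement).

    The returned point d satisfies, up to floating point error:
    ``|c - d| == bond_len``, ``angle(b, c, d) == bond_angle_deg`` and
    ``dihedral(a, b, c, d) == torsion_deg``.

    Raises ``ValueError`` if a, b, c are (nearly) collinear, since then the
    torsion reference plane is undefined.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    c = np.asarray(c, dtype=float)

    theta = math.radians(bond_angle_deg)
    phi = math.radians(torsion_deg)

    bc = c - b
    bc_hat = bc / np.linalg.norm(bc)
    n = np.cross(b - a, bc_hat)
    n_norm = np.linalg.norm(n)
    if n_norm < 1e-9:
        raise ValueError("collinear reference frame: torsion plane undefined")
    n_hat = n / n_norm
    m_hat = np.cross(n_hat, bc_hat)

    d_local = bond_len * np.array(
        [-math.cos(theta), math.sin(theta) * math.cos(phi), math.sin(theta) * math.sin(phi)]
    )
    return c + d_local[0] * bc_hat + d_local[1] * m_hat + d_local[2] * n_hat
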