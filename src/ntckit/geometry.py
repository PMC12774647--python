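"""Exact vector geometry for nucleic-acid backbone analysis.

Distances, planar angles, torsion angles (IUPAC sign convention),
least-squares rigid-body superposition, and internal-coordinate atom
placement (the NeRF construction used to build chains from bond
lengths, bond angles and torsions).

Conventions
-----------
* Lengths in angstroms, angles in degrees.
* Torsions are reported in the half-open interval (-180, +180].
* A torsion is positive when, looking from the second atom toward the
  third, the far bond rotates clockwise from the near bond.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "GeometryError",
    "SuperpositionResult",
    "wrap_angle",
    "angular_difference",
    "distance",
    "planar_angle",
    "dihedral",
    "superpose",
    "place_atom",
]

#: Cross products with a norm below this are treated as degenerate.
DEGENERACY_TOL = 1e-10


class GeometryError(ValueError):
    """Raised for degenerate geometric configurations."""


def wrap_angle(angle_deg: float) -> float:
    """Wrap an angle in degrees into (-180, +180]."""
    a = float(angle_deg) % 360.0
    if a > 180.0:
        a -= 360.0
    # map -180 exactly to +180 so the interval is half-open
    if a <= -180.0:
        a += 360.0
    return a


def angular_difference(a_deg: float, b_deg: float) -> float:
    """Signed wrapped difference a - b in degrees, in (-180, +180]."""
    return wrap_angle(float(a_deg) - float(b_deg))


def distance(p1, p2) -> float:
    """Euclidean distance between two points."""
    return float(np.linalg.norm(np.asarray(p2, dtype=float) - np.asarray(p1, dtype=float)))


def planar_angle(p1, p2, p3) -> float:
    """Interior angle at ``p2`` of the triangle p1-p2-p3, in [0, 180] degrees."""
    v1 = np.asarray(p1, dtype=float) - np.asarray(p2, dtype=float)
    v2 = np.asarray(p3, dtype=float) - np.asarray(p2, dtype=float)
    n1 = np.linalg.norm(v1)
    n2 = np.linalg.norm(v2)
    if n1 < DEGENERACY_TOL or n2 < DEGENERACY_TOL:
        raise GeometryError("planar angle undefined: coincident points")
    cosang = np.clip(np.dot(v1, v2) / (n1 * n2), -1.0, 1.0)
    return float(np.degrees(np.arccos(cosang)))


def dihedral(p1, p2, p3, p4) -> float:
    """Torsion angle p1-p2-p3-p4 in degrees, IUPAC sign convention.

    Positive when, viewed from ``p2`` toward ``p3``, the bond p3->p4
    rotates clockwise from the bond p1->p2. Result in (-180, +180].
    """
    p1 = np.asarray(p1, dtype=float)
    p2 = np.asarray(p2, dtype=float)
    p3 = np.asarray(p3, dtype=float)
    p4 = np.asarray(p4, dtype=float)
    b1 = p2 - p1
    b2 = p3 - p2
    b3 = p4 - p3
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    if np.linalg.norm(n1) < DEGENERACY_TOL or np.linalg.norm(n2) < DEGENERACY_TOL:
        raise GeometryError("torsion undefined: colinear or zero-length bond vectors")
    b2n = b2 / np.linalg.norm(b2)
    x = float(np.dot(n1, n2))
    y = float(np.dot(np.cross(n1, n2), b2n))
    return wrap_angle(np.degrees(np.arctan2(y, x)))


@dataclass(frozen=True)
class SuperpositionResult:
    """Optimal rigid-body superposition of one point set onto another.

    Applying ``rotation @ x + translation`` to each moving point
    minimises the RMSD to the corresponding fixed point.
    """

    rotation: np.ndarray  # 3x3 proper rotation, det = +1
    translation: np.ndarray  # 3-vector, angstroms
    rmsd: float  # angstroms, >= 0

    def transform(self, coords: np.ndarray) -> np.ndarray:
        coords = np.asarray(coords, dtype=float)
        return coords @ self.rotation.T + self.translation


def superpose(moving: np.ndarray, fixed: np.ndarray) -> SuperpositionResult:
    """Least-squares superposition of ``moving`` onto ``fixed`` (Kabsch).

    Correspondence is positional: moving[i] pairs with fixed[i].
    The rotation is constrained to be proper (no reflection) via the
    SVD determinant correction.
    """
    moving = np.asarray(moving, dtype=float)
    fixed = np.asarray(fixed, dtype=float)
    if moving.shape != fixed.shape or moving.ndim != 2 or moving.shape[1] != 3:
        raise GeometryError("superpose expects two N x 3 arrays of equal shape")
    n = moving.shape[0]
    if n < 3:
        raise GeometryError("superpose requires at least 3 points")
    mc = moving.mean(axis=0)
    fc = fixed.mean(axis=0)
    a = moving - mc
    b = fixed - fc
    h = a.T @ b
    if np.linalg.matrix_rank(h) < 2:
        raise GeometryError("superpose: rank-deficient configuration")
    u, s, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    corr = np.diag([1.0, 1.0, d])
    rot = vt.T @ corr @ u.T
    trans = fc - rot @ mc
    moved = a @ rot.T + fc
    rmsd = float(np.sqrt(np.mean(np.sum((moved - fixed) ** 2, axis=1))))
    return SuperpositionResult(rotation=rot, translation=trans, rmsd=rmsd)


def place_atom(p1, p2, p3, bond: float, angle: float, torsion: float) -> np.ndarray:
    """Place a fourth atom from three reference atoms and internal coordinates.

    Returns the point ``p4`` with |p4 - p3| = ``bond`` (angstroms),
    planar_angle(p2, p3, p4) = ``angle`` (degrees) and
    dihedral(p1, p2, p3, p4) = ``torsion`` (degrees). This is the
    standard natural-extension reference frame (NeRF) construction.
    """
    p1 = np.asarray(p1, dtype=float)
    p2 = np.asarray(p2, dtype=float)
    p3 = np.asarray(p3, dtype=float)
    if not bond > 0:
        raise GeometryError("bond length must be positive")
    if not 0.0 < angle < 180.0:
        raise GeometryError("bond angle must lie strictly between 0 and 180 degrees")
    bc = p3 - p2
    nbc = np.linalg.norm(bc)
    ab = p2 - p1
    if nbc < DEGENERACY_TOL or np.linalg.norm(ab) < DEGENERACY_TOL:
        raise GeometryError("place_atom: degenerate reference frame")
    bc = bc / nbc
    n = np.cross(ab, bc)
    nn = np.linalg.norm(n)
    if nn < DEGENERACY_TOL:
        raise GeometryError("place_atom: colinear reference atoms")
    n = n / nn
    m = np.cross(n, bc)
    ang = np.radians(angle)
    tor = np.radians(torsion)
    # local displacement in the frame (bc, m, n)
    d = bond * np.array([-np.cos(ang), np.sin(ang) * np.cos(tor), np.sin(ang) * np.sin(tor)])
    frame = np.column_stack([bc, m, n])
    return p3 + frame @ d
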