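"""Rigid-transform algebra and superposition utilities.

A :class:`RigidTransform` is a proper rotation plus a translation acting on
3D points in ångström, the "frame" attached to each residue's N–Cα–C atoms.
All operations broadcast over leading batch dimensions so a whole chain's
frames are a single object. Angles cross the API boundary in degrees.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.transform import Rotation

__all__ = [
    "RigidTransform", "AtomCoordinates", "DegenerateFrameError",
    "rigid_from_three_points", "compose", "invert", "apply",
    "kabsch_superpose", "dihedral", "mirror",
]

#: sine of the enclosed angle below which three points cannot define a frame
FRAME_DEGENERACY_TOL = 1e-6


class DegenerateFrameError(ValueError):
    """Raised when collinear or coincident points cannot define a frame."""


@dataclass
class RigidTransform:
    """Rotation (3×3, proper orthonormal) plus translation (Å).

    Both fields may carry leading batch dimensions: ``rotation`` is
    ``(..., 3, 3)`` and ``translation`` ``(..., 3)``.
    """

    rotation: np.ndarray
    translation: np.ndarray

    def __post_init__(self):
        self.rotation = np.asarray(self.rotation, dtype=np.float64)
        self.translation = np.asarray(self.translation, dtype=np.float64)

    @classmethod
    def identity(cls, batch_shape: tuple = ()) -> "RigidTransform":
        rot = np.broadcast_to(np.eye(3), (*batch_shape, 3, 3)).copy()
        return cls(rot, np.zeros((*batch_shape, 3)))

    @property
    def batch_shape(self) -> tuple:
        return self.rotation.shape[:-2]

    def __getitem__(self, idx) -> "RigidTransform":
        return RigidTransform(self.rotation[idx], self.translation[idx])

    def is_orthonormal(self, tol: float = 1e-6) -> bool:
        rtr = np.swapaxes(self.rotation, -1, -2) @ self.rotation
        eye = np.broadcast_to(np.eye(3), rtr.shape)
        return (
            np.allclose(rtr, eye, atol=tol)
            and np.allclose(np.linalg.det(self.rotation), 1.0, atol=tol)
        )


@dataclass
class AtomCoordinates:
    """Atom positions (Å) with an existence/resolved mask.

    Masked-out atoms never influence any loss or metric.
    """

    positions: np.ndarray  # (..., N, 3)
    mask: np.ndarray       # (..., N) bool

    def __post_init__(self):
        self.positions = np.asarray(self.positions, dtype=np.float64)
        self.mask = np.asarray(self.mask, dtype=bool)


def rigid_from_three_points(x1, x2, x3, tol: float = FRAME_DEGENERACY_TOL) -> RigidTransform:
    """Gram–Schmidt frame from three points (batched over leading dims).

    The frame's origin is ``x2``, its first axis points along ``x3 − x2``
    and its second axis is the orthogonalized component of ``x1 − x2`` —
    the convention for a residue frame built from (N, CA, C) with CA at the
    origin and C on the +x axis. Right-handed by construction.
    """
    x1, x2, x3 = (np.asarray(x, dtype=np.float64) for x in (x1, x2, x3))
    v1 = x3 - x2
    v2 = x1 - x2
    n1 = np.linalg.norm(v1, axis=-1, keepdims=True)
    n2 = np.linalg.norm(v2, axis=-1, keepdims=True)
    if np.any(n1 < tol) or np.any(n2 < tol):
        raise DegenerateFrameError("coincident points cannot define a frame")
    e1 = v1 / n1
    u = v2 - (v2 * e1).sum(-1, keepdims=True) * e1
    nu = np.linalg.norm(u, axis=-1, keepdims=True)
    # nu / |v2| is the sine of the angle enclosed at x2
    if np.any(nu / n2 < tol):
        raise DegenerateFrameError("collinear points cannot define a frame")
    e2 = u / nu
    e3 = np.cross(e1, e2)
    rotation = np.stack([e1, e2, e3], axis=-1)  # columns are the axes
    return RigidTransform(rotation, x2)


def compose(a: RigidTransform, b: RigidTransform) -> RigidTransform:
    """(a ∘ b)(x) == a(b(x))."""
    rot = a.rotation @ b.rotation
    trans = np.squeeze(a.rotation @ b.translation[..., None], -1) + a.translation
    return RigidTransform(rot, trans)


def invert(t: RigidTransform) -> RigidTransform:
    rot = np.swapaxes(t.rotation, -1, -2)
    trans = -np.squeeze(rot @ t.translation[..., None], -1)
    return RigidTransform(rot, trans)


def apply(t: RigidTransform, points: np.ndarray) -> np.ndarray:
    """y = R·x + t, rowwise over the last-but-one axis."""
    points = np.asarray(points, dtype=np.float64)
    return points @ np.swapaxes(t.rotation, -1, -2) + t.translation[..., None, :]


class InsufficientPointsError(ValueError):
    """Raised when fewer than three effective atoms are available."""


def kabsch_superpose(moving: AtomCoordinates, fixed: AtomCoordinates,
                     weights: np.ndarray | None = None) -> tuple[RigidTransform, float]:
    """Weighted least-squares superposition of ``moving`` onto ``fixed``.

    Returns the proper rigid transform T minimizing the weighted RMSD of
    ``apply(T, moving)`` against ``fixed`` (reflections are never returned),
    together with that RMSD in Å. Masks of the two sets are intersected.
    """
    if moving.positions.shape != fixed.positions.shape:
        raise ValueError("coordinate sets must have equal shapes")
    mask = moving.mask & fixed.mask
    n = moving.positions.shape[-2]
    w = np.ones(n) if weights is None else np.asarray(weights, dtype=np.float64)
    if np.any(w < 0):
        raise ValueError("weights must be nonnegative")
    w = np.where(mask, w, 0.0)
    eff = w > 0
    if eff.sum() < 3:
        raise InsufficientPointsError("need >= 3 effective atoms to superpose")
    x = moving.positions[eff]
    y = fixed.positions[eff]
    we = w[eff]
    cx = (we[:, None] * x).sum(0) / we.sum()
    cy = (we[:, None] * y).sum(0) / we.sum()
    if np.linalg.matrix_rank(np.vstack([x - cx, y - cy]), tol=1e-9) < 2:
        raise InsufficientPointsError("effective atoms are collinear")
    rot, _ = Rotation.align_vectors(y - cy, x - cx, weights=we)
    r = rot.as_matrix()
    t = cy - r @ cx
    transform = RigidTransform(r, t)
    moved = apply(transform, x)
    rmsd = float(np.sqrt((we * ((moved - y) ** 2).sum(-1)).sum() / we.sum()))
    return transform, rmsd


def dihedral(p1, p2, p3, p4) -> np.ndarray:
    """Signed torsion angle in degrees, in (−180, 180]. Batched.

    Sign convention: looking down the p2→p3 bond, a clockwise rotation of
    p4 relative to p1 is positive. Mirror reflection negates the angle.
    """
    p1, p2, p3, p4 = (np.asarray(p, dtype=np.float64) for p in (p1, p2, p3, p4))
    b1 = p2 - p1
    b2 = p3 - p2
    b3 = p4 - p3
    for b in (b1, b2, b3):
        if np.any(np.linalg.norm(b, axis=-1) < 1e-9):
            raise DegenerateFrameError("coincident consecutive points in dihedral")
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    if np.any(np.linalg.norm(n1, axis=-1) < 1e-9) or np.any(np.linalg.norm(n2, axis=-1) < 1e-9):
        raise DegenerateFrameError("collinear triple in dihedral")
    b2n = b2 / np.linalg.norm(b2, axis=-1, keepdims=True)
    x = (n1 * n2).sum(-1)
    y = (np.cross(n1, n2) * b2n).sum(-1)
    ang = np.degrees(np.arctan2(y, x))
    # map -180 exactly to +180 so the range is (-180, 180]
    return np.where(np.isclose(ang, -180.0), 180.0, ang)


def place_atom(a, b, c, bond: float, angle_deg: float, torsion_deg: float) -> np.ndarray:
    """Place atom d from internal coordinates: |d−c| = bond, angle(b,c,d),
    torsion(a,b,c,d) — the natural-extension-of-reference-frame step."""
    a, b, c = (np.asarray(x, dtype=np.float64) for x in (a, b, c))
    angle = np.radians(angle_deg)
    torsion = np.radians(torsion_deg)
    bc = c - b
    bc = bc / np.linalg.norm(bc)
    ab = b - a
    n = np.cross(ab, bc)
    norm_n = np.linalg.norm(n)
    if norm_n < 1e-9:
        raise DegenerateFrameError("collinear reference atoms in placement")
    n = n / norm_n
    m = np.cross(n, bc)
    d = np.array([
        -bond * np.cos(angle),
        bond * np.sin(angle) * np.cos(torsion),
        bond * np.sin(angle) * np.sin(torsion),
    ])
    return c + d[0] * bc + d[1] * m + d[2] * n


def mirror(coords: AtomCoordinates) -> AtomCoordinates:
    """Reflect through the z=0 plane; preserves all pairwise distances."""
    pos = coords.positions.copy()
    pos[..., 2] *= -1.0
    return AtomCoordinates(pos, coords.mask.copy())
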