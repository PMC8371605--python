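"""Structure module: residue gas, invariant point attention, all-atom build.

The backbone is a "residue gas": one rigid frame per residue, free-floating
with respect to the global frame, with no chain constraint enforced at any
point — consecutive frames may drift apart during refinement, which lets
every part of the chain refine locally at once. Invariant point attention
(IPA) updates the per-residue single representation using 3D query/key/value
points expressed in each residue's local frame and compared in the global
frame, which makes the update invariant to global rigid motion; the frame
update that follows is applied in each residue's local frame, making the
whole iteration equivariant.

Side chains are driven by up to four χ torsions per residue; all-atom
coordinates are produced by posing each residue's ideal-geometry template in
its backbone frame and rotating the atoms downstream of each χ axis.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.transform import Rotation

from . import geometry, nn
from .chemistry import (
    IDEAL_CA_C, IDEAL_N_CA, IDEAL_N_CA_C, Protein, residue_template,
    MAX_ATOMS,
)
from .config import ModelConfig
from .geometry import RigidTransform
from .nn import ParamStore, Tensor

__all__ = [
    "ResidueGas", "TorsionSet", "StructurePrediction", "FrameTensors",
    "init_residue_gas", "invariant_point_attention", "backbone_update",
    "torsion_head", "build_all_atom", "extract_torsions",
    "structure_module_forward", "ideal_backbone_local",
]


@dataclass
class ResidueGas:
    """N_res independent rigid frames (no chain constraint)."""

    frames: RigidTransform
    history: list = field(default_factory=list)

    @property
    def n_res(self) -> int:
        return self.frames.rotation.shape[0]


@dataclass
class TorsionSet:
    """Per-residue χ angles (degrees) with a validity mask by residue type."""

    angles: np.ndarray   # (N_res, 4) in (-180, 180]
    mask: np.ndarray     # (N_res, 4) bool

    def __post_init__(self):
        self.angles = np.asarray(self.angles, dtype=np.float64)
        self.mask = np.asarray(self.mask, dtype=bool)

    def sincos(self) -> np.ndarray:
        rad = np.radians(self.angles)
        return np.stack([np.sin(rad), np.cos(rad)], axis=-1)


@dataclass
class StructurePrediction:
    """Full model output: atoms, frames, torsions and confidence."""

    protein: Protein
    frames: RigidTransform
    torsions: TorsionSet
    plddt: np.ndarray           # (N_res,) in [0, 100]
    pae: np.ndarray | None = None   # (N_res, N_res, B) probabilities
    ptm: float | None = None
    trajectory: list | None = None  # per-iteration frames

    @property
    def mean_plddt(self) -> float:
        return float(self.plddt.mean())


def init_residue_gas(n_res: int) -> ResidueGas:
    """All rotations identity, all positions at the origin."""
    if n_res < 1:
        raise ValueError("n_res must be >= 1")
    return ResidueGas(RigidTransform.identity((n_res,)))


# -- differentiable frames --------------------------------------------------

@dataclass
class FrameTensors:
    """Autodiff twin of a batch of rigid frames."""

    rot: Tensor    # (N, 3, 3)
    trans: Tensor  # (N, 3)

    @classmethod
    def identity(cls, n: int) -> "FrameTensors":
        return cls(
            nn.astensor(np.broadcast_to(np.eye(3), (n, 3, 3)).copy()),
            nn.astensor(np.zeros((n, 3))),
        )

    @classmethod
    def from_rigid(cls, t: RigidTransform) -> "FrameTensors":
        return cls(nn.astensor(t.rotation), nn.astensor(t.translation))

    def to_rigid(self) -> RigidTransform:
        return RigidTransform(self.rot.data.copy(), self.trans.data.copy())

    def apply(self, points: Tensor) -> Tensor:
        """Local -> global for points of shape (N, P, 3)."""
        return points @ self.rot.swapaxes(-1, -2) + self.trans.reshape(
            self.trans.shape[0], 1, 3
        )

    def apply_inverse(self, points: Tensor) -> Tensor:
        """Global -> local for points of shape (N, P, 3)."""
        return (points - self.trans.reshape(self.trans.shape[0], 1, 3)) @ self.rot

    def detach_rot(self) -> "FrameTensors":
        return FrameTensors(self.rot.detach(), self.trans)


def quat_rotation(qvec: Tensor) -> Tensor:
    """Rotation matrices from non-normalized quaternions (1, a, b, c).

    The real part is fixed to 1, so the zero vector is exactly the identity
    rotation and small outputs parameterize small rotations.
    """
    n = qvec.shape[0]
    a, b, c = qvec[:, 0], qvec[:, 1], qvec[:, 2]
    one = nn.astensor(np.ones(n))
    norm2 = one + a * a + b * b + c * c
    w = one
    rows = [
        [w * w + a * a - b * b - c * c, 2 * (a * b - w * c), 2 * (a * c + w * b)],
        [2 * (a * b + w * c), w * w - a * a + b * b - c * c, 2 * (b * c - w * a)],
        [2 * (a * c - w * b), 2 * (b * c + w * a), w * w - a * a - b * b + c * c],
    ]
    mat = nn.stack([nn.stack(r, axis=-1) for r in rows], axis=-2)  # (n,3,3)
    return mat / norm2.reshape(n, 1, 1)


# -- invariant point attention ----------------------------------------------

def invariant_point_attention(
    store: ParamStore, p: str, single: Tensor, z: Tensor, frames: FrameTensors,
    cfg: ModelConfig, return_weights: bool = False,
):
    """IPA update of the single representation.

    Logits per head combine (i) scalar query·key affinity, (ii) a pair-bias
    projection from the pair representation and (iii) a learned nonnegative
    per-head weight γ times the negative squared distances between query and
    key points expressed in the global frame. The output concatenates the
    attended scalar values, attended pair values, and the attended value
    points mapped back into each residue's local frame (plus their norms).
    Invariant to any global rigid motion of the frames.
    """
    n, c_s = single.shape
    h = cfg.ipa_heads
    d = c_s // h
    pq = cfg.ipa_query_points
    pv = cfg.ipa_value_points

    q = nn.linear(store, f"{p}.q", single, c_s, h * d, bias=False).reshape(n, h, d)
    k = nn.linear(store, f"{p}.k", single, c_s, h * d, bias=False).reshape(n, h, d)
    v = nn.linear(store, f"{p}.v", single, c_s, h * d, bias=False).reshape(n, h, d)

    qp = nn.linear(store, f"{p}.q_pts", single, c_s, h * pq * 3, bias=False).reshape(n, h * pq, 3)
    kp = nn.linear(store, f"{p}.k_pts", single, c_s, h * pq * 3, bias=False).reshape(n, h * pq, 3)
    vp = nn.linear(store, f"{p}.v_pts", single, c_s, h * pv * 3, bias=False).reshape(n, h * pv, 3)
    gq = frames.apply(qp).reshape(n, h, pq, 3)
    gk = frames.apply(kp).reshape(n, h, pq, 3)
    gv = frames.apply(vp)  # (n, h*pv, 3)

    bias = nn.linear(store, f"{p}.pair_bias", z, cfg.c_z, h, bias=False)  # (n,n,h)

    diff = gq.reshape(n, 1, h, pq, 3) - gk.reshape(1, n, h, pq, 3)
    d2 = (diff * diff).sum(axis=-1).sum(axis=-1)  # (n, n, h)

    gamma = nn.softplus(store.get(f"{p}.gamma", (h,), "zeros"))
    w_c = np.sqrt(2.0 / (9.0 * pq))
    w_l = np.sqrt(1.0 / 3.0)

    qk = (q.swapaxes(0, 1) @ k.swapaxes(0, 1).swapaxes(-1, -2))  # (h, n, n)
    logits = (
        qk.transpose((1, 2, 0)) * (1.0 / np.sqrt(d))
        + bias
        - d2 * gamma.reshape(1, 1, h) * (w_c / 2.0)
    ) * w_l
    attn = nn.softmax(logits, axis=1)  # normalize over keys j; (i, j, h)

    at = attn.transpose((2, 0, 1))  # (h, i, j)
    o_scalar = (at @ v.swapaxes(0, 1)).swapaxes(0, 1).reshape(n, h * d)
    # attended pair values: sum_j attn[i,j,h] * z[i,j,:]
    o_pair = (attn.swapaxes(1, 2).reshape(n, h, n) @ z).reshape(n, h * cfg.c_z)
    # attended global points, then back to each residue's local frame
    gv_heads = gv.reshape(n, h, pv * 3).swapaxes(0, 1)          # (h, n, pv*3)
    o_pts = (at @ gv_heads).swapaxes(0, 1).reshape(n, h * pv, 3)  # global
    o_pts_local = frames.apply_inverse(o_pts)                    # (n, h*pv, 3)
    parts = [o_scalar, o_pair, o_pts_local.reshape(n, h * pv * 3)]
    if cfg.ipa_point_norms:
        norms = nn.sqrt((o_pts_local * o_pts_local).sum(axis=-1) + 1e-8)
        parts.append(norms)
    concat = nn.concatenate(parts, axis=-1)
    d_concat = concat.shape[-1]
    update = nn.linear(store, f"{p}.out", concat, d_concat, c_s, init="zeros")
    if return_weights:
        return update, attn.data
    return update


def backbone_update(store: ParamStore, p: str, single: Tensor,
                    frames: FrameTensors, cfg: ModelConfig) -> FrameTensors:
    """Predict 6 numbers per residue — a local-frame translation and the
    vector part of a quaternion (1, a, b, c) — and compose each frame with
    its local update. Zero prediction leaves the frames unchanged."""
    n, c_s = single.shape
    upd = nn.linear(store, f"{p}.upd", single, c_s, 6, init="zeros")
    trans_local = upd[:, 3:] * cfg.trans_scale
    rot_local = quat_rotation(upd[:, :3])
    new_rot = frames.rot @ rot_local
    new_trans = (
        (trans_local.reshape(n, 1, 3) @ frames.rot.swapaxes(-1, -2)).reshape(n, 3)
        + frames.trans
    )
    return FrameTensors(new_rot, new_trans)


def torsion_head(store: ParamStore, single: Tensor, cfg: ModelConfig) -> Tensor:
    """Small per-residue network predicting (sin, cos) for each of 4 χ slots;
    the 2-vectors are normalized so scaling the raw output is irrelevant."""
    n, c_s = single.shape
    hidden = nn.relu(nn.linear(store, "torsion.in", single, c_s, c_s, init="relu"))
    raw = nn.linear(store, "torsion.out", hidden, c_s, 8).reshape(n, 4, 2)
    norm = nn.sqrt((raw * raw).sum(axis=-1, keepdims=True) + 1e-8)
    return raw / norm


def sincos_to_torsion_set(sincos: np.ndarray, sequence: str) -> TorsionSet:
    angles = np.degrees(np.arctan2(sincos[..., 0], sincos[..., 1]))
    mask = np.stack([residue_template(r).chi_valid for r in sequence])
    return TorsionSet(angles, mask)


def ideal_backbone_local() -> np.ndarray:
    """Ideal local positions of (N, CA, C) in the backbone frame."""
    ang = np.radians(IDEAL_N_CA_C)
    return np.array([
        [IDEAL_N_CA * np.cos(ang), IDEAL_N_CA * np.sin(ang), 0.0],
        [0.0, 0.0, 0.0],
        [IDEAL_CA_C, 0.0, 0.0],
    ])


def backbone_atoms(frames: FrameTensors) -> Tensor:
    """Differentiable (N, 3 atoms, 3) global positions of N, CA, C."""
    n = frames.trans.shape[0]
    pts = nn.astensor(np.broadcast_to(ideal_backbone_local(), (n, 3, 3)).copy())
    return frames.apply(pts)


def build_all_atom(sequence: str, gas: ResidueGas | RigidTransform,
                   torsions: TorsionSet) -> Protein:
    """Place all heavy atoms from backbone frames and χ torsions.

    Each residue's ideal-geometry template is posed in its frame; for every
    valid χ slot the atoms downstream of the rotation axis are rotated so
    the dihedral equals the requested angle. Re-extracting torsions from the
    built structure returns the inputs exactly.
    """
    frames = gas.frames if isinstance(gas, ResidueGas) else gas
    n = len(sequence)
    positions = np.zeros((n, MAX_ATOMS, 3))
    mask = np.zeros((n, MAX_ATOMS), dtype=bool)
    for i, res1 in enumerate(sequence):
        tmpl = residue_template(res1)  # raises for unknown residue types
        coords = tmpl.local_coords.copy()
        slot = 0
        for idx, moving in zip(tmpl.chi_indices, tmpl.chi_moving):
            while not tmpl.chi_valid[slot]:
                slot += 1
            if torsions.mask[i, slot]:
                delta = np.radians(torsions.angles[i, slot] - tmpl.ideal_chi[slot])
                b, c = coords[idx[1]], coords[idx[2]]
                axis = c - b
                axis = axis / np.linalg.norm(axis)
                rot = Rotation.from_rotvec(axis * delta).as_matrix()
                coords[moving] = (coords[moving] - c) @ rot.T + c
            slot += 1
        na = len(tmpl.atom_names)
        positions[i, :na] = geometry.apply(frames[i], coords)
        mask[i, :na] = True
    # the carbonyl O depends on the backbone ψ torsion (it belongs to the
    # next peptide plane): re-place it trans to the next residue's N
    from .chemistry import IDEAL_C_O, IDEAL_CA_C_O

    for i in range(n - 1):
        ti = residue_template(sequence[i])
        tn = residue_template(sequence[i + 1])
        n_i = positions[i, ti.atom_index("N")]
        ca_i = positions[i, ti.atom_index("CA")]
        c_i = positions[i, ti.atom_index("C")]
        n_next = positions[i + 1, tn.atom_index("N")]
        try:
            psi = float(geometry.dihedral(n_i, ca_i, c_i, n_next))
            positions[i, ti.atom_index("O")] = geometry.place_atom(
                n_i, ca_i, c_i, IDEAL_C_O, IDEAL_CA_C_O, psi - 180.0
            )
        except geometry.DegenerateFrameError:
            pass  # keep the template O for degenerate inter-residue geometry
    return Protein(sequence, positions, mask)


def extract_torsions(protein: Protein) -> TorsionSet:
    """χ dihedrals measured from atom coordinates; slots with missing atoms
    or non-rotatable chemistry are masked out."""
    n = len(protein)
    angles = np.zeros((n, 4))
    mask = np.zeros((n, 4), dtype=bool)
    for i, res1 in enumerate(protein.sequence):
        tmpl = residue_template(res1)
        slot = 0
        for idx in tmpl.chi_indices:
            while not tmpl.chi_valid[slot]:
                slot += 1
            if all(protein.atom_mask[i, a] for a in idx):
                pts = [protein.atom_positions[i, a] for a in idx]
                angles[i, slot] = float(geometry.dihedral(*pts))
                mask[i, slot] = True
            slot += 1
    return TorsionSet(angles, mask)


# -- the full structure module ----------------------------------------------

def structure_module_forward(
    store: ParamStore, single: Tensor, z: Tensor, cfg: ModelConfig,
    n_iter: int | None = None, initial_frames: FrameTensors | None = None,
):
    """Iterate (IPA -> transition -> frame update) ``n_iter`` times with
    shared weights, starting from the trivial residue gas (identity frames
    at the origin) unless ``initial_frames`` injects a different start.

    Returns a dict with the final single representation, per-iteration
    frames (the trajectory), and the normalized torsion (sin, cos) output.
    No chain constraint is enforced at any point.
    """
    n_iter = cfg.n_struct_iter if n_iter is None else n_iter
    if n_iter < 1:
        raise ValueError("n_iter must be >= 1")
    n, _ = single.shape
    s = nn.layer_norm(
        single,
        store.get("sm.ln_in.scale", (cfg.c_s,), "ones"),
        store.get("sm.ln_in.offset", (cfg.c_s,), "zeros"),
    )
    s = nn.linear(store, "sm.proj_in", s, cfg.c_s, cfg.c_s)
    frames = initial_frames if initial_frames is not None else FrameTensors.identity(n)
    trajectory: list[FrameTensors] = []
    for _ in range(n_iter):
        s = s + invariant_point_attention(store, "sm.ipa", s, z, frames, cfg)
        s = nn.layer_norm(
            s,
            store.get("sm.ln_ipa.scale", (cfg.c_s,), "ones"),
            store.get("sm.ln_ipa.offset", (cfg.c_s,), "zeros"),
        )
        hidden = nn.relu(nn.linear(store, "sm.trans_in", s, cfg.c_s, cfg.c_s, init="relu"))
        s = s + nn.linear(store, "sm.trans_out", hidden, cfg.c_s, cfg.c_s, init="zeros")
        s = nn.layer_norm(
            s,
            store.get("sm.ln_trans.scale", (cfg.c_s,), "ones"),
            store.get("sm.ln_trans.offset", (cfg.c_s,), "zeros"),
        )
        frames = backbone_update(store, "sm.bb", s, frames, cfg)
        trajectory.append(frames)
        if cfg.stop_rot_gradient:
            # stop gradients through rotations between iterations for
            # stability; the translation path stays differentiable
            frames = frames.detach_rot()
    sincos = torsion_head(store, s, cfg)
    return {
        "single": s,
        "frames": trajectory[-1],
        "trajectory": trajectory,
        "torsion_sincos": sincos,
        "backbone_atoms": backbone_atoms(trajectory[-1]),
    }
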