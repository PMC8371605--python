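"""Training losses and confidence heads.

FAPE (frame-aligned point error) is the main structural loss: every
predicted atom is expressed in the local coordinates of every predicted
frame, the corresponding true atom in the corresponding true frame, and the
N_frames × N_atoms local-coordinate distances are penalized with a clamped
L1. Because local frames are chiral, FAPE distinguishes a structure from
its mirror image — it is invariant to global rigid motion but not to
reflection.

Auxiliary heads: distogram (binned Cβ–Cβ distances, cross-entropy),
BERT-style masked-MSA reconstruction, per-residue binned lDDT-Cα (whose
expectation is the pLDDT confidence), side-chain torsion loss on the unit
circle, a pairwise aligned-error head from which pTM is computed, and a
flat-bottom stereochemical violation penalty used during fine-tuning.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import nn
from .chemistry import (
    IDEAL_C_N, IDEAL_CA_C_N, IDEAL_C_N_CA, Protein, SD_C_N, SD_CA_C_N,
    SD_C_N_CA, VDW_RADII, residue_template,
)
from .config import ModelConfig
from .geometry import RigidTransform
from .nn import ParamStore, Tensor
from .structure import FrameTensors, TorsionSet

__all__ = [
    "FapeConfig", "DistogramTarget", "fape", "distogram_head",
    "distogram_target", "distogram_loss", "masked_msa_head",
    "masked_msa_loss", "plddt_head", "plddt_from_logits", "plddt_loss",
    "pae_head", "ptm_from_pae", "torsion_loss", "violation_loss",
    "bond_violation_tensor", "tm_d0",
]


@dataclass
class FapeConfig:
    d_clamp: float = 10.0  # Å
    scale: float = 10.0    # Å, length normalization Z

    def __post_init__(self):
        if self.d_clamp <= 0 or self.scale <= 0:
            raise ValueError("FAPE constants must be positive")


def _as_frames(frames) -> FrameTensors:
    if isinstance(frames, FrameTensors):
        return frames
    if isinstance(frames, RigidTransform):
        return FrameTensors.from_rigid(frames)
    raise TypeError(f"cannot interpret {type(frames)} as frames")


def fape(pred_frames, pred_atoms, true_frames, true_atoms,
         cfg: FapeConfig | None = None,
         frame_mask: np.ndarray | None = None,
         atom_mask: np.ndarray | None = None,
         eps: float = 1e-8) -> Tensor:
    """Frame-aligned point error.

    For every frame k and atom i the predicted and true atom are expressed
    in the local coordinates of the predicted and true frame k respectively;
    the loss is the mean over valid (k, i) of ``min(d_ki, d_clamp) / Z``.
    Differentiable when predictions are tensors; returns a scalar Tensor.
    """
    cfg = cfg or FapeConfig()
    pf = _as_frames(pred_frames)
    tf = _as_frames(true_frames)
    pa = nn.astensor(pred_atoms)
    ta = np.asarray(true_atoms.data if isinstance(true_atoms, Tensor) else true_atoms,
                    dtype=np.float64)
    if pa.ndim != 2 or ta.ndim != 2:
        raise ValueError("atoms must be (N_atoms, 3)")
    k = pf.trans.shape[0]
    a = pa.shape[0]
    fm = np.ones(k, bool) if frame_mask is None else np.asarray(frame_mask, bool)
    am = np.ones(a, bool) if atom_mask is None else np.asarray(atom_mask, bool)
    valid = np.outer(fm, am)
    if not valid.any():
        raise ValueError("no valid (frame, atom) pairs for FAPE")

    # predicted atoms in predicted local frames: (K, A, 3)
    diff_p = pa.reshape(1, a, 3) - pf.trans.reshape(k, 1, 3)
    local_p = diff_p @ pf.rot
    diff_t = ta[None, :, :] - tf.trans.data[:, None, :]
    local_t = diff_t @ tf.rot.data

    delta = local_p - nn.astensor(local_t)
    d = nn.sqrt((delta * delta).sum(axis=-1) + eps)
    clamped = nn.clamp_max(d, cfg.d_clamp)
    w = valid.astype(float)
    return (clamped * w).sum() / float(w.sum()) / cfg.scale


# -- distogram --------------------------------------------------------------

@dataclass
class DistogramTarget:
    edges: np.ndarray       # (B-1,) strictly increasing bin edges, Å
    true_bins: np.ndarray   # (N, N) bin index per residue pair
    mask: np.ndarray        # (N, N) valid pairs

    def __post_init__(self):
        if not np.all(np.diff(self.edges) > 0):
            raise ValueError("bin edges must be strictly increasing")


def cbeta_coordinates(protein: Protein) -> tuple[np.ndarray, np.ndarray]:
    """Cβ positions (Cα for glycine) and their mask."""
    n = len(protein)
    pos = np.zeros((n, 3))
    mask = np.zeros(n, bool)
    for i, r in enumerate(protein.sequence):
        tmpl = residue_template(r)
        name = "CB" if r != "G" else "CA"
        k = tmpl.atom_index(name)
        pos[i] = protein.atom_positions[i, k]
        mask[i] = protein.atom_mask[i, k]
    return pos, mask


def distogram_target(true: Protein, cfg: ModelConfig) -> DistogramTarget:
    pos, mask = cbeta_coordinates(true)
    d = np.linalg.norm(pos[:, None] - pos[None], axis=-1)
    edges = np.linspace(cfg.distogram_min_dist, cfg.distogram_max_dist,
                        cfg.distogram_bins - 1)
    bins = np.searchsorted(edges, d)
    return DistogramTarget(edges, bins, np.outer(mask, mask))


def distogram_head(store: ParamStore, z: Tensor, cfg: ModelConfig) -> Tensor:
    """Symmetrized per-pair logits over distance bins."""
    logits = nn.linear(store, "distogram", z, cfg.c_z, cfg.distogram_bins)
    return logits + logits.swapaxes(0, 1)


def distogram_loss(logits: Tensor, target: DistogramTarget,
                   exclude_diagonal: bool = True) -> Tensor:
    mask = target.mask.copy()
    if exclude_diagonal:
        np.fill_diagonal(mask, False)
    return nn.cross_entropy(logits, target.true_bins, mask)


# -- masked MSA -------------------------------------------------------------

def masked_msa_head(store: ParamStore, m: Tensor, cfg: ModelConfig) -> Tensor:
    from .msa import N_OUTPUT_CLASSES

    return nn.linear(store, "masked_msa", m, cfg.c_m, N_OUTPUT_CLASSES)


def masked_msa_loss(logits: Tensor, masked) -> Tensor:
    """Cross-entropy over residue classes at the corrupted positions only.

    Empty targets yield a zero loss (nothing was corrupted).
    """
    if len(masked.target_classes) == 0:
        import warnings

        warnings.warn("masked-MSA loss with no targets; returning 0")
        return nn.Tensor(0.0)
    rows, cols = masked.target_positions.T
    picked = logits[rows, cols]
    return nn.cross_entropy(picked, masked.target_classes)


# -- pLDDT ------------------------------------------------------------------

def plddt_head(store: ParamStore, single: Tensor, cfg: ModelConfig) -> Tensor:
    c = single.shape[-1]
    hidden = nn.relu(nn.linear(store, "plddt.in", single, c, c, init="relu"))
    return nn.linear(store, "plddt.out", hidden, c, cfg.plddt_bins)


def plddt_bin_centers(n_bins: int) -> np.ndarray:
    width = 100.0 / n_bins
    return (np.arange(n_bins) + 0.5) * width


def plddt_from_logits(logits: Tensor | np.ndarray, n_bins: int | None = None) -> np.ndarray:
    """pLDDT = expectation of the lDDT-Cα bin centers, in [0, 100]."""
    data = logits.data if isinstance(logits, Tensor) else np.asarray(logits)
    n_bins = data.shape[-1] if n_bins is None else n_bins
    e = np.exp(data - data.max(-1, keepdims=True))
    p = e / e.sum(-1, keepdims=True)
    return p @ plddt_bin_centers(n_bins)


def plddt_loss(logits: Tensor, true_lddt_per_res: np.ndarray,
               cfg: ModelConfig) -> Tensor:
    width = 100.0 / cfg.plddt_bins
    bins = np.clip((true_lddt_per_res / width).astype(int), 0, cfg.plddt_bins - 1)
    return nn.cross_entropy(logits, bins)


# -- pairwise error head and pTM --------------------------------------------

def pae_head(store: ParamStore, z: Tensor, cfg: ModelConfig) -> Tensor:
    """Per ordered pair, logits over aligned-error bins."""
    return nn.linear(store, "pae", z, cfg.c_z, cfg.pae_bins)


def tm_d0(n_res: int) -> float:
    """Standard TM-score length normalization, floored for short chains."""
    if n_res < 1:
        raise ValueError("n_res must be >= 1")
    val = 1.24 * np.cbrt(max(n_res - 15, 0)) - 1.8 if n_res > 15 else 0.0
    return max(float(val), 0.5)


def ptm_from_pae(pae_logits: Tensor | np.ndarray, n_res: int,
                 cfg: ModelConfig) -> float:
    """pTM = max over alignment residue i of the mean over j of the expected
    TM kernel 1 / (1 + (e_ij / d0)^2) under the predicted error bins."""
    if n_res < 1:
        raise ValueError("n_res must be >= 1")
    data = pae_logits.data if isinstance(pae_logits, Tensor) else np.asarray(pae_logits)
    e = np.exp(data - data.max(-1, keepdims=True))
    p = e / e.sum(-1, keepdims=True)  # (N, N, B)
    width = cfg.pae_max_dist / cfg.pae_bins
    # representative error of each bin is its lower edge, so a prediction
    # concentrated in the zero-error bin scores a kernel of exactly 1
    errors = np.arange(cfg.pae_bins) * width
    kernel = 1.0 / (1.0 + (errors / tm_d0(n_res)) ** 2)
    f = p @ kernel                     # (N, N)
    return float(f.mean(axis=1).max())


# -- torsions ---------------------------------------------------------------

def torsion_loss(pred_sincos: Tensor, true: TorsionSet, sequence: str) -> Tensor:
    """Mean squared chordal distance on the unit circle between predicted
    and true (sin, cos); χ slots with a 180°-symmetric terminal group are
    scored against the nearer of the two symmetry images."""
    from .chemistry import CHI_PI_PERIODIC, one_to_three

    mask = true.mask.astype(float)
    if mask.sum() == 0:
        return nn.Tensor(0.0)
    t = true.sincos()
    d_direct = ((pred_sincos - t) ** 2).sum(axis=-1)      # (N, 4)
    d_flip = ((pred_sincos + t) ** 2).sum(axis=-1)        # 180° image
    sym = np.zeros_like(mask)
    for i, r in enumerate(sequence):
        for slot in CHI_PI_PERIODIC.get(one_to_three(r), []):
            sym[i, slot] = 1.0
    use_flip = sym * (d_flip.data < d_direct.data)
    d = d_direct * (1.0 - use_flip) + d_flip * use_flip
    return (d * mask).sum() / float(mask.sum())


# -- stereochemical violations ----------------------------------------------

def _angle(a, b, c) -> np.ndarray:
    v1 = a - b
    v2 = c - b
    cosang = (v1 * v2).sum(-1) / (
        np.linalg.norm(v1, axis=-1) * np.linalg.norm(v2, axis=-1)
    )
    return np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0)))


def violation_loss(protein: Protein, tol_factor: float = 12.0,
                   clash_overlap: float = 1.5) -> dict:
    """Flat-bottom penalties on peptide-bond geometry and steric clashes.

    Returns a per-term breakdown: ``bond`` (C–N length), ``angle``
    (CA–C–N and C–N–CA), ``clash`` (non-bonded heavy atoms closer than the
    sum of van der Waals radii minus the overlap allowance), and ``total``.
    Zero inside tolerance, linear outside.
    """
    n = len(protein)
    bond_pen, bond_cnt = 0.0, 0
    angle_pen, angle_cnt = 0.0, 0
    for i in range(n - 1):
        ti = residue_template(protein.sequence[i])
        tj = residue_template(protein.sequence[i + 1])
        ic, jn = ti.atom_index("C"), tj.atom_index("N")
        ica, jca = ti.atom_index("CA"), tj.atom_index("CA")
        if not (protein.atom_mask[i, ic] and protein.atom_mask[i + 1, jn]):
            continue
        c = protein.atom_positions[i, ic]
        nn_ = protein.atom_positions[i + 1, jn]
        d = float(np.linalg.norm(c - nn_))
        bond_pen += max(0.0, abs(d - IDEAL_C_N) - tol_factor * SD_C_N)
        bond_cnt += 1
        if protein.atom_mask[i, ica]:
            ang = float(_angle(protein.atom_positions[i, ica], c, nn_))
            angle_pen += max(0.0, abs(ang - IDEAL_CA_C_N) - tol_factor * SD_CA_C_N)
            angle_cnt += 1
        if protein.atom_mask[i + 1, jca]:
            ang = float(_angle(c, nn_, protein.atom_positions[i + 1, jca]))
            angle_pen += max(0.0, abs(ang - IDEAL_C_N_CA) - tol_factor * SD_C_N_CA)
            angle_cnt += 1

    # non-bonded clashes between residues (peptide C-N pair excluded)
    flat_pos, flat_res, flat_elem = [], [], []
    flat_name = []
    for i, r in enumerate(protein.sequence):
        tmpl = residue_template(r)
        for k, name in enumerate(tmpl.atom_names):
            if protein.atom_mask[i, k]:
                flat_pos.append(protein.atom_positions[i, k])
                flat_res.append(i)
                flat_elem.append(tmpl.elements[k])
                flat_name.append(name)
    flat_pos = np.asarray(flat_pos)
    flat_res = np.asarray(flat_res)
    radii = np.array([VDW_RADII.get(e, 1.7) for e in flat_elem])
    clash_pen, clash_cnt = 0.0, 0
    m = len(flat_pos)
    if m:
        d = np.linalg.norm(flat_pos[:, None] - flat_pos[None], axis=-1)
        cutoff = radii[:, None] + radii[None, :] - clash_overlap
        different = flat_res[:, None] != flat_res[None, :]
        peptide = np.zeros((m, m), bool)
        for a in range(m):
            for b in range(m):
                if (
                    flat_res[b] == flat_res[a] + 1
                    and flat_name[a] == "C"
                    and flat_name[b] == "N"
                ):
                    peptide[a, b] = peptide[b, a] = True
        upper = np.triu(different & ~peptide, k=1)
        excess = np.where(upper, np.maximum(0.0, cutoff - d), 0.0)
        clash_pen = float(excess.sum())
        clash_cnt = int(upper.sum())

    report = {
        "bond": bond_pen / max(bond_cnt, 1),
        "angle": angle_pen / max(angle_cnt, 1),
        "clash": clash_pen / max(clash_cnt, 1),
    }
    report["total"] = sum(report.values())
    return report


def bond_violation_tensor(backbone_atoms: Tensor, tol_factor: float = 12.0) -> Tensor:
    """Differentiable peptide C–N bond-length penalty for fine-tuning.

    ``backbone_atoms`` is the (N, 3, 3) tensor of (N, CA, C) positions.
    """
    n = backbone_atoms.shape[0]
    if n < 2:
        return nn.Tensor(0.0)
    c = backbone_atoms[:-1, 2]
    nxt = backbone_atoms[1:, 0]
    d = nn.sqrt(((c - nxt) ** 2).sum(axis=-1) + 1e-10)
    tol = tol_factor * SD_C_N
    over = nn.relu(d - (IDEAL_C_N + tol)) + nn.relu((IDEAL_C_N - tol) - d)
    return over.mean()
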