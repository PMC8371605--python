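"""Full-model assembly: recycling, prediction, probing and toy training.

``MiniFold`` wires the pieces together: MSA featurization → Evoformer trunk
→ structure module → confidence heads, with the whole pipeline applied
recursively ("recycling"): after each pass the final pair representation,
the first row of the MSA representation and a binned embedding of the
predicted inter-residue distances are re-injected into the next pass's
inputs. Training applies the loss to every recycling iteration's outputs
(with re-injected features detached); inference returns the final pass.

The training harness is deliberately desk-scale: single-example batches,
contiguous cropping, inverse-cluster-size sampling, and an adaptive-moment
optimizer, sufficient to overfit toy proteins and exercise every loss term.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import evoformer, losses, nn
from .chemistry import Protein, residue_template, MAX_ATOMS
from .config import ModelConfig
from .msa import MaskedMsa, Msa, initial_representations, mask_msa, subsample_clusters
from .nn import ParamStore, Tensor
from .structure import (
    FrameTensors, StructurePrediction, TorsionSet, build_all_atom,
    extract_torsions, ideal_backbone_local, sincos_to_torsion_set,
    structure_module_forward,
)

__all__ = [
    "MiniFold", "run_model", "select_best", "intermediate_trajectory",
    "TrainExample", "train_toy", "TrainingDivergedError",
]


class TrainingDivergedError(RuntimeError):
    """Raised when the training loss becomes non-finite."""


def protein_from_backbone(sequence: str, backbone: np.ndarray,
                          bfactors: np.ndarray | None = None) -> Protein:
    """A backbone-only Protein from (N_res, 3, 3) N/CA/C positions."""
    n = len(sequence)
    pos = np.zeros((n, MAX_ATOMS, 3))
    mask = np.zeros((n, MAX_ATOMS), bool)
    for i, r in enumerate(sequence):
        tmpl = residue_template(r)
        for k, name in enumerate(("N", "CA", "C")):
            a = tmpl.atom_index(name)
            pos[i, a] = backbone[i, k]
            mask[i, a] = True
    return Protein(sequence, pos, mask, bfactors)


_CB_LOCAL = np.array([-0.526, -0.777, -1.211])  # ideal Cβ in the backbone frame


def _distance_bin_features(frames: FrameTensors, cfg: ModelConfig) -> np.ndarray:
    """One-hot binned pseudo-Cβ distances from predicted frames (detached)."""
    rot = frames.rot.data
    trans = frames.trans.data
    cb = trans + _CB_LOCAL @ np.swapaxes(rot, -1, -2)
    d = np.linalg.norm(cb[:, None] - cb[None], axis=-1)
    edges = np.linspace(cfg.recycle_min_dist, cfg.recycle_max_dist,
                        cfg.recycle_bins - 1)
    return np.eye(cfg.recycle_bins)[np.searchsorted(edges, d)]


class MiniFold:
    """The assembled model. Parameters are created lazily on first use and
    live in a single named :class:`ParamStore`."""

    def __init__(self, config: ModelConfig | None = None, seed: int = 0):
        self.config = config or ModelConfig.toy()
        self.store = ParamStore(seed)

    # -- persistence -------------------------------------------------------
    def save_weights(self, path) -> None:
        self.store.save(path)

    def load_weights(self, path) -> None:
        self.store.load(path)

    # -- forward -----------------------------------------------------------
    def prepare_msa(self, msa: Msa, seed: int = 0) -> Msa:
        """Subsample cluster centres when the alignment is deeper than the
        configured number of clusters (the query is always kept)."""
        if msa.n_seq <= self.config.n_clusters:
            return msa
        centres, _ = subsample_clusters(msa, self.config.n_clusters, seed=seed)
        return msa.subset(centres.tolist())

    def forward(self, msa_input: Msa | MaskedMsa, n_recycle: int | None = None,
                collect_intermediates: bool = False) -> dict:
        """One full inference pass including recycling.

        Returns a dict of Tensors: trunk outputs, per-recycle structure
        outputs, and all head logits for the final pass.
        """
        cfg = self.config
        store = self.store
        n_recycle = cfg.n_recycle if n_recycle is None else n_recycle
        if n_recycle < 1:
            raise ValueError("n_recycle must be >= 1")

        prev = None
        per_recycle = []
        for cycle in range(n_recycle):
            m, z = initial_representations(msa_input, store, cfg)
            n_res = z.shape[0]
            if prev is not None:
                if cfg.recycle_pair:
                    z = z + nn.linear(
                        store, "recycle.pair",
                        _ln(store, "recycle.ln_pair", prev["pair"].detach(), cfg.c_z),
                        cfg.c_z, cfg.c_z, init="zeros",
                    )
                if cfg.recycle_dist:
                    feats = _distance_bin_features(prev["frames"], cfg)
                    z = z + nn.linear(store, "recycle.dist", nn.astensor(feats),
                                      cfg.recycle_bins, cfg.c_z, init="zeros")
                if cfg.recycle_msa:
                    row = nn.linear(
                        store, "recycle.msa",
                        _ln(store, "recycle.ln_msa", prev["msa_row"].detach(), cfg.c_m),
                        cfg.c_m, cfg.c_m, init="zeros",
                    ).reshape(1, n_res, cfg.c_m)
                    if m.shape[0] > 1:
                        pad = nn.astensor(np.zeros((m.shape[0] - 1, n_res, cfg.c_m)))
                        row = nn.concatenate([row, pad], axis=0)
                    m = m + row

            result = evoformer.evoformer_stack(
                store, m, z, cfg, collect_intermediates=collect_intermediates
            )
            if collect_intermediates:
                m_out, z_out, single, inter = result
            else:
                m_out, z_out, single = result
                inter = None
            sm = structure_module_forward(store, single, z_out, cfg)
            out = {
                "msa": m_out, "pair": z_out, "single_trunk": single,
                "single": sm["single"], "frames": sm["frames"],
                "sm_trajectory": sm["trajectory"],
                "torsion_sincos": sm["torsion_sincos"],
                "backbone_atoms": sm["backbone_atoms"],
                "msa_row": m_out[0],
                "block_intermediates": inter,
            }
            per_recycle.append(out)
            prev = out

        final = dict(per_recycle[-1])
        final["per_recycle"] = per_recycle
        final["distogram_logits"] = losses.distogram_head(store, final["pair"], cfg)
        final["masked_msa_logits"] = losses.masked_msa_head(store, final["msa"], cfg)
        final["plddt_logits"] = losses.plddt_head(store, final["single"], cfg)
        final["pae_logits"] = losses.pae_head(store, final["pair"], cfg)
        return final

    def predict(self, msa: Msa, n_recycle: int | None = None,
                seed: int = 0) -> StructurePrediction:
        """End-to-end prediction with confidence."""
        msa_used = self.prepare_msa(msa, seed=seed)
        out = self.forward(msa_used, n_recycle=n_recycle)
        cfg = self.config
        sequence = msa.query
        frames = out["frames"].to_rigid()
        sincos = out["torsion_sincos"].data
        torsions = sincos_to_torsion_set(sincos, sequence)
        plddt = losses.plddt_from_logits(out["plddt_logits"])
        protein = build_all_atom(sequence, frames, torsions)
        protein.bfactors = plddt
        pae_logits = out["pae_logits"].data
        e = np.exp(pae_logits - pae_logits.max(-1, keepdims=True))
        return StructurePrediction(
            protein=protein,
            frames=frames,
            torsions=torsions,
            plddt=plddt,
            pae=e / e.sum(-1, keepdims=True),
            ptm=losses.ptm_from_pae(out["pae_logits"], len(sequence), cfg),
            trajectory=[f.to_rigid() for f in out["sm_trajectory"]],
        )


def _ln(store: ParamStore, name: str, x: Tensor, width: int) -> Tensor:
    return nn.layer_norm(
        x,
        store.get(f"{name}.scale", (width,), "ones"),
        store.get(f"{name}.offset", (width,), "zeros"),
    )


def run_model(msa: Msa, config: ModelConfig, weights=None,
              n_recycle: int | None = None, seed: int = 0) -> StructurePrediction:
    """Convenience wrapper: build a model, optionally load weights, predict."""
    model = MiniFold(config, seed=seed)
    if weights is not None:
        model.load_weights(weights)
    return model.predict(msa, n_recycle=n_recycle, seed=seed)


def select_best(predictions: list[StructurePrediction],
                criterion: str = "plddt") -> StructurePrediction:
    """Pick the prediction with the highest confidence (mean pLDDT by
    default, pTM optionally); ties resolve to the first candidate."""
    if not predictions:
        raise ValueError("empty prediction list")
    if criterion == "plddt":
        scores = [p.mean_plddt for p in predictions]
    elif criterion == "ptm":
        scores = [p.ptm for p in predictions]
    else:
        raise ValueError(f"unknown criterion {criterion!r}")
    return predictions[int(np.argmax(scores))]


def intermediate_trajectory(msa: Msa, model: MiniFold,
                            probe_store: ParamStore | None = None,
                            n_recycle: int | None = None) -> list:
    """Apply a structure module to every Evoformer block's intermediate
    output, giving one structure per block per recycling iteration
    (n_blocks × n_recycle in total; 192 at the full-scale defaults).

    With ``probe_store`` unset the main model's structure-module weights are
    used, so the final entry coincides with the main prediction's frames.
    """
    cfg = model.config
    store = model.store
    msa_used = model.prepare_msa(msa)
    out = model.forward(msa_used, n_recycle=n_recycle, collect_intermediates=True)
    sm_store = probe_store or store
    trajectory = []
    for cycle_out in out["per_recycle"]:
        for m_b, z_b in cycle_out["block_intermediates"]:
            single_b = evoformer.single_representation(store, m_b, cfg)
            sm = structure_module_forward(sm_store, single_b, z_b, cfg)
            trajectory.append(sm["frames"].to_rigid())
    return trajectory


# -- training ----------------------------------------------------------------

@dataclass
class TrainExample:
    msa: Msa
    structure: Protein
    cluster_size: int = 1


def _crop(example: TrainExample, crop_size: int, rng) -> TrainExample:
    n = len(example.structure)
    if n <= crop_size:
        return example
    start = int(rng.integers(0, n - crop_size + 1))
    sl = slice(start, start + crop_size)
    msa = Msa(
        [s[sl] for s in example.msa.sequences],
        example.msa.deletions[:, sl],
        example.msa.descriptions,
    )
    prot = Protein(
        example.structure.sequence[sl],
        example.structure.atom_positions[sl],
        example.structure.atom_mask[sl],
    )
    return TrainExample(msa, prot, example.cluster_size)


def compute_losses(outputs: dict, target: Protein, masked: MaskedMsa,
                   cfg: ModelConfig) -> dict:
    """All loss terms for one forward pass, as scalar Tensors.

    FAPE is averaged over the structure module's iterations and over
    recycling passes (the final loss is applied to every recycle).
    """
    from . import metrics

    true_frames = target.backbone_frames()
    bb = np.stack([
        target.backbone("N").positions,
        target.backbone("CA").positions,
        target.backbone("C").positions,
    ], axis=1)  # (N, 3, 3)
    bb_mask = (
        target.backbone("N").mask & target.backbone("CA").mask & target.backbone("C").mask
    )
    true_atoms = bb.reshape(-1, 3)
    atom_mask = np.repeat(bb_mask, 3)
    fape_cfg = losses.FapeConfig(cfg.fape_clamp, cfg.fape_scale)

    terms: dict[str, Tensor] = {}
    fape_terms = []
    for cycle_out in outputs["per_recycle"]:
        for frames in cycle_out["sm_trajectory"]:
            from .structure import backbone_atoms

            pred_atoms = backbone_atoms(frames).reshape(-1, 3)
            fape_terms.append(losses.fape(
                frames, pred_atoms, true_frames, true_atoms,
                fape_cfg, frame_mask=bb_mask, atom_mask=atom_mask,
            ))
    total_fape = fape_terms[0]
    for t in fape_terms[1:]:
        total_fape = total_fape + t
    terms["fape"] = total_fape / float(len(fape_terms))

    terms["distogram"] = losses.distogram_loss(
        outputs["distogram_logits"], losses.distogram_target(target, cfg)
    )
    terms["masked_msa"] = losses.masked_msa_loss(outputs["masked_msa_logits"], masked)
    terms["torsion"] = losses.torsion_loss(
        outputs["torsion_sincos"], extract_torsions(target), target.sequence
    )

    pred_bb = outputs["backbone_atoms"].data
    pred_prot = protein_from_backbone(target.sequence, pred_bb)
    try:
        _, per_res = metrics.lddt(pred_prot, target, mode="ca")
        per_res = np.nan_to_num(per_res, nan=50.0)
        terms["plddt"] = losses.plddt_loss(outputs["plddt_logits"], per_res, cfg)
    except ValueError:
        terms["plddt"] = nn.Tensor(0.0)

    if cfg.loss_weights.get("violation", 0.0) > 0:
        terms["violation"] = losses.bond_violation_tensor(outputs["backbone_atoms"])
    return terms


def train_toy(dataset: list[TrainExample], config: ModelConfig | None = None,
              seed: int = 0, n_steps: int = 500,
              callback=None) -> tuple[MiniFold, list[dict]]:
    """Gradient-based minimization of the weighted loss sum on toy configs.

    Examples are sampled in inverse proportion to their cluster size and
    cropped to ``config.crop_size`` contiguous residues. Emits one flat
    named-scalar log entry per step. Raises
    :class:`TrainingDivergedError` on non-finite loss.
    """
    if not dataset:
        raise ValueError("empty dataset")
    cfg = config or ModelConfig.toy()
    rng = np.random.default_rng(seed)
    model = MiniFold(cfg, seed=int(rng.integers(2**31)))

    weights = np.array([1.0 / ex.cluster_size for ex in dataset])
    weights = weights / weights.sum()

    opt = None
    logs: list[dict] = []
    for step in range(n_steps):
        ex = dataset[int(rng.choice(len(dataset), p=weights))]
        ex = _crop(ex, cfg.crop_size, rng)
        masked = mask_msa(ex.msa, cfg.mask_fraction, cfg.mutate_fraction,
                          seed=int(rng.integers(2**31)))
        outputs = model.forward(masked)
        terms = compute_losses(outputs, ex.structure, masked, cfg)
        total = None
        entry = {}
        for name, t in terms.items():
            w = cfg.loss_weights.get(name, 0.0)
            entry[name] = float(t.data)
            contrib = t * w
            total = contrib if total is None else total + contrib
        entry["total"] = float(total.data)
        if not np.isfinite(entry["total"]):
            raise TrainingDivergedError(
                f"non-finite loss at step {step}: {entry}"
            )
        model.store.zero_grad()
        total.backward()
        if opt is None:
            opt = nn.Adam(model.store, lr=cfg.learning_rate)
        # cosine decay to a tenth of the base rate over the run
        frac = step / max(n_steps - 1, 1)
        opt.lr = cfg.learning_rate * (0.1 + 0.45 * (1 + np.cos(np.pi * frac)))
        opt.step()
        entry["step"] = step
        logs.append(entry)
        if callback is not None and callback(step, model, entry):
            break
    return model, logs
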