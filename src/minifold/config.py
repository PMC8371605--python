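"""Model configuration.

One dataclass holds every tunable dimension, count and loss constant.
``ModelConfig()`` gives supplement-style full-scale defaults (48 blocks,
c_m=256, c_z=128, 4 recycles); :meth:`ModelConfig.toy` gives a desk-scale
configuration that trains on a CPU in minutes.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field


@dataclass
class ModelConfig:
    # representation widths
    c_m: int = 256            # MSA representation channels
    c_z: int = 128            # pair representation channels
    c_s: int = 384            # single representation channels

    # Evoformer trunk
    n_blocks: int = 48
    msa_heads: int = 8
    pair_heads: int = 4
    transition_factor: int = 4
    rel_pos_clip: int = 32    # |i-j| clipped to this for relative-position features

    # MSA featurization
    n_clusters: int = 128
    mask_fraction: float = 0.12     # BERT-style corruption: share replaced by MASK
    mutate_fraction: float = 0.03   # share replaced by a random residue

    # structure module
    n_struct_iter: int = 8    # shared-weight IPA/update iterations
    ipa_heads: int = 8
    ipa_query_points: int = 4
    ipa_value_points: int = 8
    trans_scale: float = 10.0  # Å per unit of predicted translation
    stop_rot_gradient: bool = True
    ipa_point_norms: bool = True  # include attended-point norms in IPA output

    # recycling
    n_recycle: int = 4
    recycle_pair: bool = True
    recycle_msa: bool = True
    recycle_dist: bool = True
    recycle_bins: int = 15
    recycle_min_dist: float = 3.0   # Å, first distance-bin edge
    recycle_max_dist: float = 21.0

    # heads / losses
    fape_clamp: float = 10.0  # Å
    fape_scale: float = 10.0  # Å (length normalization Z)
    distogram_bins: int = 64
    distogram_min_dist: float = 2.0
    distogram_max_dist: float = 22.0
    plddt_bins: int = 50
    pae_bins: int = 64
    pae_max_dist: float = 32.0
    loss_weights: dict = field(default_factory=lambda: {
        "fape": 1.0,
        "distogram": 0.3,
        "masked_msa": 0.3,
        "torsion": 0.3,
        "plddt": 0.01,
        "violation": 0.0,   # switched on in the fine-tune config
    })

    # training
    crop_size: int = 256
    learning_rate: float = 1e-3

    @classmethod
    def toy(cls, **overrides) -> "ModelConfig":
        """Desk-scale configuration used by the tests and demos."""
        base = dict(
            c_m=32, c_z=16, c_s=32,
            n_blocks=2, msa_heads=4, pair_heads=2,
            n_clusters=8,
            n_struct_iter=4, ipa_heads=2, ipa_query_points=2, ipa_value_points=2,
            n_recycle=2, recycle_bins=15,
            distogram_bins=16, plddt_bins=10, pae_bins=16,
            crop_size=64, learning_rate=3e-3,
        )
        base.update(overrides)
        return cls(**base)

    @classmethod
    def finetune(cls, **overrides) -> "ModelConfig":
        cfg = cls.toy(**overrides)
        cfg.loss_weights = dict(cfg.loss_weights, violation=0.1)
        return cfg

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2)

    @classmethod
    def from_json(cls, text: str) -> "ModelConfig":
        return cls(**json.loads(text))
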