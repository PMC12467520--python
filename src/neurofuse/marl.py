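"""Multimodal aware representation learning.

Each modality embedding passes through one shared encoder (a single
parameter set reused across modalities, capturing modality-invariant
structure) and its own private encoder (modality-specific structure).
A sigmoid gate computed from the concatenated pair mixes the two as a
convex combination, f_m = g ⊙ s_m + (1 - g) ⊙ p_m; the five fused
vectors are concatenated and projected through a ReLU linear head into
the subject-level fusion embedding.

All parameters are autodiff Tensors so the module trains jointly with
the downstream population-graph classifier.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .autodiff import Tensor, concat
from .core_io import ValidationError

__all__ = ["MODALITIES", "FeatureBundle", "MarlParams", "gate_fuse", "marl_fuse"]

MODALITIES = ("smri", "fmri", "ho", "ez", "aal")


@dataclass
class FeatureBundle:
    """Ordered map modality -> (batch, d) embedding matrix."""

    features: dict[str, np.ndarray]
    modalities: tuple[str, ...] = MODALITIES

    def __post_init__(self):
        missing = [m for m in self.modalities if m not in self.features]
        if missing:
            raise ValidationError(f"feature bundle missing modalities: {missing}")
        shapes = {np.asarray(self.features[m]).shape for m in self.modalities}
        if len(shapes) != 1:
            raise ValidationError(f"modalities disagree on (batch, d): {shapes}")

    @property
    def batch_size(self) -> int:
        return np.asarray(self.features[self.modalities[0]]).shape[0]

    @property
    def dim(self) -> int:
        return np.asarray(self.features[self.modalities[0]]).shape[1]

    def concatenated(self) -> np.ndarray:
        """Raw concatenation across modalities (diagnostic export)."""
        return np.concatenate([np.asarray(self.features[m]) for m in self.modalities],
                              axis=1)


def _mlp_params(rng: np.random.Generator, d_in: int, d_hidden: int, d_out: int,
                tag: str) -> dict[str, Tensor]:
    return {
        f"{tag}_w1": Tensor.param(rng.normal(0, np.sqrt(2 / d_in), (d_in, d_hidden))),
        f"{tag}_b1": Tensor.param(np.zeros(d_hidden)),
        f"{tag}_w2": Tensor.param(rng.normal(0, np.sqrt(2 / d_hidden), (d_hidden, d_out))),
        f"{tag}_b2": Tensor.param(np.zeros(d_out)),
    }


def _mlp(x: Tensor, params: dict[str, Tensor], tag: str) -> Tensor:
    h = (x @ params[f"{tag}_w1"] + params[f"{tag}_b1"]).relu()
    return h @ params[f"{tag}_w2"] + params[f"{tag}_b2"]


@dataclass
class MarlParams:
    """One shared encoder, per-modality private encoders, gate, fusion head."""

    dim: int
    fusion_dim: int = 64
    modalities: tuple[str, ...] = MODALITIES
    scalar_gate: bool = False
    tensors: dict[str, Tensor] = field(default_factory=dict)

    @classmethod
    def init(cls, dim: int, fusion_dim: int = 64,
             modalities: tuple[str, ...] = MODALITIES,
             scalar_gate: bool = False, seed: int = 0) -> "MarlParams":
        rng = np.random.default_rng(seed)
        t: dict[str, Tensor] = {}
        t.update(_mlp_params(rng, dim, dim, dim, "shared"))
        for m in modalities:
            t.update(_mlp_params(rng, dim, dim, dim, f"private_{m}"))
        gate_out = 1 if scalar_gate else dim
        t["gate_w"] = Tensor.param(rng.normal(0, np.sqrt(1 / (2 * dim)), (2 * dim, gate_out)))
        t["gate_b"] = Tensor.param(np.zeros(gate_out))
        cat = dim * len(modalities)
        t["fuse_w"] = Tensor.param(rng.normal(0, np.sqrt(2 / cat), (cat, fusion_dim)))
        t["fuse_b"] = Tensor.param(np.zeros(fusion_dim))
        return cls(dim=dim, fusion_dim=fusion_dim, modalities=modalities,
                   scalar_gate=scalar_gate, tensors=t)

    def parameters(self) -> list[Tensor]:
        return list(self.tensors.values())

    def weight_matrices(self) -> list[Tensor]:
        """2D weights entering the L2 penalty (biases excluded)."""
        return [t for k, t in self.tensors.items() if t.data.ndim == 2]


def gate_fuse(s: Tensor, p: Tensor, gate_w: Tensor, gate_b: Tensor) -> Tensor:
    """Convex gated mixture of shared and private embeddings."""
    if s.shape != p.shape:
        raise ValidationError(f"shared/private shape mismatch: {s.shape} vs {p.shape}")
    g = (concat([s, p], axis=1) @ gate_w + gate_b).sigmoid()
    return g * s + (1.0 - g) * p


def marl_fuse(bundle: FeatureBundle, params: MarlParams,
              enabled: bool = True) -> Tensor:
    """Fuse a feature bundle into (batch, fusion_dim) subject embeddings.

    With ``enabled=False`` the module degrades to plain concatenation
    followed by the linear head (the fusion-ablation variant).
    """
    if bundle.modalities != params.modalities:
        raise ValidationError(
            f"bundle modalities {bundle.modalities} do not match "
            f"parameters {params.modalities}")
    fused = []
    for m in params.modalities:
        x = Tensor(np.asarray(bundle.features[m], dtype=np.float64))
        if enabled:
            s = _mlp(x, params.tensors, "shared")
            p = _mlp(x, params.tensors, f"private_{m}")
            fused.append(gate_fuse(s, p, params.tensors["gate_w"],
                                   params.tensors["gate_b"]))
        else:
            fused.append(x)
    stacked = concat(fused, axis=1)
    return (stacked @ params.tensors["fuse_w"] + params.tensors["fuse_b"]).relu()
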