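"""Adaptive convolutional feature extraction from 3D volumes.

A stack of 3D convolution blocks, each refined by squeeze-excitation
style channel attention and a CBAM-style spatial attention map, with an
identity residual skip around the attention pair. Adaptive average
pooling and a projection head turn the final feature maps into a
fixed-width per-subject embedding.

The extractor runs as a seeded, randomly initialised forward pass: it
serves as the volumetric feature stage whose outputs feed the trainable
fusion and population-graph classifier downstream.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .core_io import ConfigError, ValidationError

__all__ = ["AcfeParams", "AcfeNetwork", "channel_attention", "spatial_attention"]

# keep the im2col buffer bounded; larger batches are processed in chunks
_MAX_COL_BYTES = 128 * 1024 ** 2


@dataclass
class AcfeParams:
    """Architecture hyperparameters for the volumetric extractor."""

    n_blocks: int = 3
    channels: tuple[int, ...] = (8, 16, 32)
    kernel: int = 3
    reduction_ratio: int = 8
    spatial_kernel: int = 7
    pooled_grid: int = 4
    out_dim: int = 64
    use_channel_attn: bool = True
    use_spatial_attn: bool = True
    use_residual: bool = True

    def __post_init__(self):
        if len(self.channels) != self.n_blocks:
            raise ConfigError("channels must list one width per block")
        for c in self.channels:
            if c % self.reduction_ratio != 0:
                raise ConfigError(
                    f"reduction ratio {self.reduction_ratio} must divide channels {c}")
        if self.out_dim < 1:
            raise ConfigError("out_dim must be >= 1")


def _conv3d(x: np.ndarray, w: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Shape-preserving 3D convolution. x: (B,C,D,H,W); w: (O,C,k,k,k)."""
    k = w.shape[-1]
    pad = k // 2
    xp = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad), (pad, pad)))
    win = sliding_window_view(xp, (k, k, k), axis=(2, 3, 4))
    # chunk the batch so the window view is realized in bounded memory
    per_item = win[0].size * 8
    chunk = max(1, _MAX_COL_BYTES // max(per_item, 1))
    outs = []
    for i in range(0, x.shape[0], chunk):
        outs.append(np.einsum("bcdhwxyz,ocxyz->bodhw", win[i:i + chunk], w,
                              optimize=True))
    out = np.concatenate(outs, axis=0)
    return out + b[None, :, None, None, None]


def channel_attention(f: np.ndarray, w1: np.ndarray, w2: np.ndarray
                      ) -> tuple[np.ndarray, np.ndarray]:
    """Squeeze-excitation channel reweighting.

    The channel descriptor is the spatial mean of each feature channel;
    two dense layers with a ReLU bottleneck and a sigmoid produce one
    weight per channel, which rescales the feature map.

    Returns ``(s, f_tilde)`` with ``s`` in (0,1) of shape (B, C).
    """
    z = f.mean(axis=(2, 3, 4))                      # B x C
    hidden = np.maximum(z @ w1.T, 0.0)              # B x C/r
    s = 1.0 / (1.0 + np.exp(-(hidden @ w2.T)))      # B x C
    return s, f * s[:, :, None, None, None]


def spatial_attention(f: np.ndarray, w: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Spatial attention: channel mean/max maps -> conv -> sigmoid gate."""
    f_avg = f.mean(axis=1, keepdims=True)
    f_max = f.max(axis=1, keepdims=True)
    stacked = np.concatenate([f_avg, f_max], axis=1)   # B x 2 x D x H x W
    m = 1.0 / (1.0 + np.exp(-_conv3d(stacked, w, b)))  # B x 1 x ...
    return f * m


def _avg_pool2(x: np.ndarray) -> np.ndarray:
    """2x downsampling by mean over non-overlapping 2^3 cells (odd tails dropped)."""
    b, c, d, h, w = x.shape
    d2, h2, w2 = d // 2, h // 2, w // 2
    x = x[:, :, :d2 * 2, :h2 * 2, :w2 * 2]
    return x.reshape(b, c, d2, 2, h2, 2, w2, 2).mean(axis=(3, 5, 7))


def _adaptive_avg_pool(x: np.ndarray, grid: int) -> np.ndarray:
    """Adaptive average pooling to a (grid, grid, grid) output."""
    b, c, d, h, w = x.shape
    out = np.empty((b, c, grid, grid, grid))
    bounds = [np.linspace(0, size, grid + 1).astype(int) for size in (d, h, w)]
    for i in range(grid):
        for j in range(grid):
            for k in range(grid):
                cell = x[:, :, bounds[0][i]:max(bounds[0][i + 1], bounds[0][i] + 1),
                         bounds[1][j]:max(bounds[1][j + 1], bounds[1][j] + 1),
                         bounds[2][k]:max(bounds[2][k + 1], bounds[2][k] + 1)]
                out[:, :, i, j, k] = cell.mean(axis=(2, 3, 4))
    return out


@dataclass
class AcfeNetwork:
    """Seeded instantiation of the extractor; weights He-initialised."""

    params: AcfeParams
    weights: dict = field(default_factory=dict)

    @classmethod
    def init(cls, params: AcfeParams, seed: int = 0) -> "AcfeNetwork":
        rng = np.random.default_rng(seed)
        w: dict[str, np.ndarray] = {}
        c_in = 1
        k = params.kernel
        for i, c_out in enumerate(params.channels):
            fan_in = c_in * k ** 3
            w[f"conv{i}_w"] = rng.normal(0, np.sqrt(2 / fan_in), (c_out, c_in, k, k, k))
            w[f"conv{i}_b"] = np.zeros(c_out)
            cr = c_out // params.reduction_ratio
            w[f"ca{i}_w1"] = rng.normal(0, np.sqrt(2 / c_out), (cr, c_out))
            w[f"ca{i}_w2"] = rng.normal(0, np.sqrt(2 / max(cr, 1)), (c_out, cr))
            sk = params.spatial_kernel
            w[f"sa{i}_w"] = rng.normal(0, np.sqrt(2 / (2 * sk ** 3)), (1, 2, sk, sk, sk))
            w[f"sa{i}_b"] = np.zeros(1)
            c_in = c_out
        flat = params.channels[-1] * params.pooled_grid ** 3
        w["head_w"] = rng.normal(0, np.sqrt(2 / flat), (params.out_dim, flat))
        w["head_b"] = np.zeros(params.out_dim)
        return cls(params=params, weights=w)

    def save(self, path) -> None:
        """Checkpoint all weights to a single .npz archive."""
        np.savez(path, **self.weights)

    @classmethod
    def load(cls, path, params: AcfeParams) -> "AcfeNetwork":
        with np.load(path) as archive:
            return cls(params=params, weights={k: archive[k] for k in archive.files})

    def n_layers(self) -> int:
        """Count of active computational layers (ablation structure audit)."""
        per_block = 1 + int(self.params.use_channel_attn) \
            + int(self.params.use_spatial_attn) + int(self.params.use_residual)
        return self.params.n_blocks * per_block + 1  # + projection head

    def forward(self, volumes: np.ndarray) -> np.ndarray:
        """Map a (B, D, H, W) volume batch to a (B, out_dim) embedding."""
        volumes = np.asarray(volumes, dtype=np.float64)
        if volumes.ndim != 4:
            raise ValidationError("expected a batch of 3D volumes (B, D, H, W)")
        p = self.params
        x = volumes[:, None]                          # B x 1 x D x H x W
        for i in range(p.n_blocks):
            x = _conv3d(x, self.weights[f"conv{i}_w"], self.weights[f"conv{i}_b"])
            identity = x
            if p.use_channel_attn:
                _, x = channel_attention(x, self.weights[f"ca{i}_w1"],
                                         self.weights[f"ca{i}_w2"])
            if p.use_spatial_attn:
                x = spatial_attention(x, self.weights[f"sa{i}_w"],
                                      self.weights[f"sa{i}_b"])
            if p.use_residual:
                x = x + identity
            if i < p.n_blocks - 1 and min(x.shape[2:]) >= 2:
                x = _avg_pool2(x)
        x = _adaptive_avg_pool(x, p.pooled_grid)
        flat = x.reshape(x.shape[0], -1)
        return np.maximum(flat @ self.weights["head_w"].T + self.weights["head_b"], 0.0)


def extract_embeddings(network: AcfeNetwork, volumes: np.ndarray,
                       batch_size: int = 32) -> np.ndarray:
    """Run the extractor over subjects in batches; shapes must agree."""
    shapes = {np.asarray(v).shape for v in volumes}
    if len(shapes) > 1:
        raise ValidationError(f"heterogeneous volume shapes in batch: {shapes}")
    volumes = np.asarray(volumes, dtype=np.float64)
    outs = [network.forward(volumes[i:i + batch_size])
            for i in range(0, len(volumes), batch_size)]
    return np.concatenate(outs, axis=0)
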