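"""Phenotype-aware population graph and attention-pruned transductive classifier.

Subjects become nodes of one graph; edges join pairs whose feature
vectors — fused imaging embedding concatenated with encoded phenotypes
(site/sex one-hot, age/IQ z-scored), each block L2-normalised — have
absolute cosine similarity above a threshold. A two-layer graph
attention network classifies nodes transductively: between the layers,
dynamic attention-based graph pruning ranks the directed edges by their
layer-1 attention coefficients and keeps only the top p%, re-inserting a
self-loop per node so no node loses its own message. The loss is masked
binary cross-entropy plus an L2 penalty on the weight matrices.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .autodiff import Tensor, concat, gather_rows, make_scatter, segment_sum
from .core_io import SubjectRecord, ValidationError, get_logger

__all__ = [
    "PopulationGraph", "DagpState", "GatParams",
    "pairwise_similarity", "encode_phenotypes", "build_population_graph",
    "gat_forward_with_dagp", "compute_loss", "prune_top_p",
]

_EPS = 1e-7


# --------------------------------------------------------------------------
# Graph construction
# --------------------------------------------------------------------------

def pairwise_similarity(x_u: np.ndarray, x_v: np.ndarray) -> float:
    """Absolute cosine similarity in [0, 1]; zero vectors map to 0."""
    x_u = np.asarray(x_u, dtype=np.float64)
    x_v = np.asarray(x_v, dtype=np.float64)
    nu, nv = np.linalg.norm(x_u), np.linalg.norm(x_v)
    if nu == 0 or nv == 0:
        get_logger().warning("zero vector in similarity; returning 0")
        return 0.0
    return float(abs(x_u @ x_v) / (nu * nv))


def encode_phenotypes(records: Sequence[SubjectRecord]) -> np.ndarray:
    """Site/sex one-hot plus z-scored age and IQ, one row per subject."""
    sites = sorted({r.site for r in records})
    sexes = sorted({r.sex for r in records})
    rows = []
    ages = np.array([r.age for r in records], dtype=np.float64)
    iqs = np.array([r.iq for r in records], dtype=np.float64)

    def z(v: np.ndarray) -> np.ndarray:
        sd = v.std()
        return (v - v.mean()) / sd if sd > 0 else np.zeros_like(v)

    z_age, z_iq = z(ages), z(iqs)
    for i, r in enumerate(records):
        row = np.zeros(len(sites) + len(sexes) + 2)
        row[sites.index(r.site)] = 1.0
        row[len(sites) + sexes.index(r.sex)] = 1.0
        row[-2], row[-1] = z_age[i], z_iq[i]
        rows.append(row)
    return np.asarray(rows)


@dataclass
class PopulationGraph:
    """All subjects in one graph; folds are realised as index masks."""

    x: np.ndarray                  # n_subjects x feature width
    adjacency: np.ndarray          # n x n {0,1}, symmetric, zero diagonal
    labels: np.ndarray             # n, {0,1}
    subject_ids: list[str]

    def __post_init__(self):
        n = len(self.labels)
        if self.adjacency.shape != (n, n) or self.x.shape[0] != n:
            raise ValidationError("population graph arrays disagree on subject count")
        if not np.array_equal(self.adjacency, self.adjacency.T):
            raise ValidationError("population adjacency must be symmetric")
        if np.any(np.diag(self.adjacency) != 0):
            raise ValidationError("population adjacency diagonal must be zero")

    @property
    def n_nodes(self) -> int:
        return len(self.labels)

    def directed_edges(self) -> tuple[np.ndarray, np.ndarray]:
        """Both directions of every undirected edge, excluding self-loops."""
        src, dst = np.nonzero(self.adjacency)
        return src, dst


def _block_normalize(block: np.ndarray) -> np.ndarray:
    norms = np.linalg.norm(block, axis=1, keepdims=True)
    norms[norms == 0] = 1.0
    return block / norms


def build_population_graph(records: Sequence[SubjectRecord],
                           fused: np.ndarray, th: float = 0.5,
                           mode: str = "both") -> PopulationGraph:
    """Binarize absolute cosine similarity of subject vectors at `th`.

    The node vector concatenates the L2-normalised fused embedding with
    the L2-normalised encoded phenotype block so neither dominates the
    cosine; ``mode`` restricts to one block for the ablation variants.
    """
    fused = np.asarray(fused, dtype=np.float64)
    if fused.shape[0] != len(records):
        raise ValidationError("need exactly one fused row per subject record")
    blocks = []
    if mode in ("both", "features"):
        blocks.append(_block_normalize(fused))
    if mode in ("both", "phenotypes"):
        blocks.append(_block_normalize(encode_phenotypes(records)))
    x = np.concatenate(blocks, axis=1)
    norms = np.linalg.norm(x, axis=1)
    safe = np.where(norms == 0, 1.0, norms)
    sim = np.abs((x / safe[:, None]) @ (x / safe[:, None]).T)
    sim[norms == 0, :] = 0.0
    sim[:, norms == 0] = 0.0
    a = (sim > th).astype(np.float64)
    np.fill_diagonal(a, 0.0)
    if a.sum() == 0:
        get_logger().warning("similarity threshold %.3f produced an empty edge set", th)
    return PopulationGraph(x=x, adjacency=a,
                           labels=np.array([r.label for r in records]),
                           subject_ids=[r.subject_id for r in records])


# --------------------------------------------------------------------------
# GAT + dynamic attention-based pruning
# --------------------------------------------------------------------------

@dataclass
class GatParams:
    """Two attention layers (multi-head then single-head) and a logit head."""

    in_dim: int
    hidden: int = 64          # total layer-1 width, split across heads
    heads: int = 4
    out_dim: int = 16
    leaky_slope: float = 0.2
    dropout: float = 0.5
    tensors: dict[str, Tensor] = field(default_factory=dict)

    @classmethod
    def init(cls, in_dim: int, hidden: int = 64, heads: int = 4,
             out_dim: int = 16, leaky_slope: float = 0.2, dropout: float = 0.5,
             seed: int = 0) -> "GatParams":
        if hidden % heads != 0:
            raise ValidationError("hidden width must be divisible by head count")
        rng = np.random.default_rng(seed)
        per_head = hidden // heads
        t = {
            "w1": Tensor.param(rng.normal(0, np.sqrt(2 / in_dim), (in_dim, hidden))),
            "a1_src": Tensor.param(rng.normal(0, np.sqrt(1 / per_head), (heads, per_head))),
            "a1_dst": Tensor.param(rng.normal(0, np.sqrt(1 / per_head), (heads, per_head))),
            "w2": Tensor.param(rng.normal(0, np.sqrt(2 / hidden), (hidden, out_dim))),
            "a2_src": Tensor.param(rng.normal(0, np.sqrt(1 / out_dim), (1, out_dim))),
            "a2_dst": Tensor.param(rng.normal(0, np.sqrt(1 / out_dim), (1, out_dim))),
            "w_out": Tensor.param(rng.normal(0, np.sqrt(2 / out_dim), (out_dim, 1))),
            "b_out": Tensor.param(np.zeros(1)),
        }
        return cls(in_dim=in_dim, hidden=hidden, heads=heads, out_dim=out_dim,
                   leaky_slope=leaky_slope, dropout=dropout, tensors=t)

    def parameters(self) -> list[Tensor]:
        return list(self.tensors.values())

    def weight_matrices(self) -> list[Tensor]:
        return [self.tensors[k] for k in ("w1", "w2", "w_out")]


@dataclass
class DagpState:
    """Attention coefficients and the pruned edge set of one forward pass."""

    attention: np.ndarray          # mean over heads, one value per directed edge
    src: np.ndarray
    dst: np.ndarray
    kept: np.ndarray               # indices into (src, dst) retained by pruning
    prune_percent: float
    z1: np.ndarray                 # layer-1 embeddings
    z2: np.ndarray                 # layer-2 embeddings


def _with_self_loops(src: np.ndarray, dst: np.ndarray, n: int
                     ) -> tuple[np.ndarray, np.ndarray]:
    loops = np.arange(n)
    return np.concatenate([src, loops]), np.concatenate([dst, loops])


def _attention_layer(x: Tensor, src: np.ndarray, dst: np.ndarray, n: int,
                     w: Tensor, a_src: Tensor, a_dst: Tensor, heads: int,
                     slope: float, dropout: float,
                     rng: np.random.Generator | None) -> tuple[Tensor, np.ndarray]:
    """One multi-head attention layer on an explicit directed edge list.

    Returns the (n, heads*per_head) output and the per-edge attention
    coefficients averaged over heads (detached, for pruning decisions).
    """
    s_src = make_scatter(src, n)
    s_dst = make_scatter(dst, n)
    h = (x @ w).reshape(n, heads, -1)                     # n x heads x f
    e_src = (h * a_src).sum(axis=2)                       # n x heads
    e_dst = (h * a_dst).sum(axis=2)
    logits = (gather_rows(e_src, src, s_src)
              + gather_rows(e_dst, dst, s_dst)).leaky_relu(slope)
    # softmax over each destination's in-neighbourhood; the max shift is a
    # per-segment constant and does not alter the softmax or its gradient
    shift = np.full((n, logits.data.shape[1]), -np.inf)
    np.maximum.at(shift, dst, logits.data)
    z = (logits - Tensor(shift[dst])).exp()
    denom = segment_sum(z, dst, n, s_dst)
    att = z / gather_rows(denom, dst, s_dst)              # E x heads
    if rng is not None and dropout > 0:
        mask = (rng.random(att.data.shape) >= dropout) / (1 - dropout)
        att = att * Tensor(mask)
    msgs = att.reshape(att.data.shape[0], heads, 1) * gather_rows(h, src, s_src)
    out = segment_sum(msgs, dst, n, s_dst).reshape(n, -1)
    return out, att.data.mean(axis=1)


def prune_top_p(attention: np.ndarray, src: np.ndarray, dst: np.ndarray,
                p: float) -> np.ndarray:
    """Indices of the top-p% directed edges by attention weight.

    Retains exactly ceil(p/100 * E) edges. Ties break toward higher
    attention first, then lower (source, target) index, so the selection
    is fully deterministic.
    """
    n_edges = len(src)
    keep = int(np.ceil(p / 100.0 * n_edges))
    order = np.lexsort((dst, src, -attention))
    return np.sort(order[:keep])


def gat_forward_with_dagp(graph: PopulationGraph, params: GatParams,
                          prune_percent: float = 70.0,
                          rng: np.random.Generator | None = None,
                          x: Tensor | None = None) -> tuple[Tensor, DagpState]:
    """Full forward pass: attention layer, prune, attention layer, sigmoid.

    ``rng`` enables dropout (training / Monte Carlo passes); ``None``
    gives the deterministic evaluation forward. ``x`` overrides the
    graph's static node features with a differentiable tensor so the
    upstream fusion module trains jointly.
    """
    n = graph.n_nodes
    src, dst = graph.directed_edges()
    if x is None:
        x = Tensor(graph.x)
    src1, dst1 = _with_self_loops(src, dst, n)
    z1, att_full = _attention_layer(
        x, src1, dst1, n, params.tensors["w1"], params.tensors["a1_src"],
        params.tensors["a1_dst"], params.heads, params.leaky_slope,
        params.dropout, rng)
    z1 = z1.relu()
    # rank only the real (non-self) directed edges; self-loops are re-inserted
    att_edges = att_full[:len(src)]
    kept = prune_top_p(att_edges, src, dst, prune_percent)
    src2, dst2 = _with_self_loops(src[kept], dst[kept], n)
    z1_in = z1
    if rng is not None and params.dropout > 0:
        mask = (rng.random(z1.data.shape) >= params.dropout) / (1 - params.dropout)
        z1_in = z1 * Tensor(mask)
    z2, _ = _attention_layer(
        z1_in, src2, dst2, n, params.tensors["w2"], params.tensors["a2_src"],
        params.tensors["a2_dst"], 1, params.leaky_slope, params.dropout, rng)
    z2 = z2.relu()
    logits = z2 @ params.tensors["w_out"] + params.tensors["b_out"]
    y_hat = logits.sigmoid().reshape(n)
    state = DagpState(attention=att_edges, src=src, dst=dst, kept=kept,
                      prune_percent=prune_percent, z1=z1.data, z2=z2.data)
    return y_hat, state


def compute_loss(y: np.ndarray, y_hat: Tensor,
                 weights: Sequence[Tensor] = (), lam: float = 0.0,
                 mask: np.ndarray | None = None) -> Tensor:
    """Masked binary cross-entropy plus lambda * sum of squared weights."""
    y = np.asarray(y, dtype=np.float64)
    if mask is None:
        mask = np.ones(len(y), dtype=bool)
    idx = np.nonzero(np.asarray(mask))[0]
    p = gather_rows(y_hat, idx).clip(_EPS, 1.0 - _EPS)
    yt = Tensor(y[idx])
    bce = -(yt * p.log() + (1.0 - yt) * (1.0 - p).log()).sum()
    if lam > 0 and weights:
        reg = None
        for w in weights:
            term = (w * w).sum()
            reg = term if reg is None else reg + term
        return bce + lam * reg
    return bce
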