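"""Per-subject brain graphs from ROI time series, and edge-sensitive pooling.

Graph construction follows the bilateral-homolog convention: every right
hemisphere region is linked to its left homolog, every region is linked
to an appended average-signal node (guarding against scanner/site level
offsets), and a top-K functional-connectivity kNN term densifies the
graph. Node features are each region's Pearson correlation profile.

The edge-sensitive pooling mechanism (ESPM) scores each node with a
sigmoid importance coefficient alpha from a spectral graph convolution,
scores each undirected edge as the sum of its endpoint coefficients,
prunes edges at the mean edge score while preserving all nodes, and mean
pools a second convolution on the sparsified graph into a fixed-width
per-atlas embedding.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core_io import AtlasSpec, BrainGraph, FeatureError, ValidationError

__all__ = [
    "EspmParams", "EdgeScoreTable", "EspmNetwork",
    "build_atlas_graph", "node_importance", "prune_edges", "espm_embed",
    "graph_to_edgelist",
]


@dataclass
class EspmParams:
    """Widths of the pooling mechanism's two convolutions and its head."""

    in_dim: int                      # node feature width (= node count here)
    hidden: int = 32
    post_hidden: int = 32
    out_dim: int = 64

    def __post_init__(self):
        if min(self.in_dim, self.hidden, self.post_hidden, self.out_dim) < 1:
            raise ValidationError("ESPM widths must be >= 1")


@dataclass
class EdgeScoreTable:
    """Scores e_ij = alpha_i + alpha_j for each undirected edge (i < j)."""

    edges: np.ndarray        # E x 2 int, i < j
    scores: np.ndarray       # E
    mean_score: float
    retained: np.ndarray     # E bool


def build_atlas_graph(ts: np.ndarray, atlas: AtlasSpec, knn_k: int = 10,
                      subject_id: str = "") -> BrainGraph:
    """Construct one subject's brain graph from an ROI time-series matrix."""
    ts = np.asarray(ts, dtype=np.float64)
    if ts.shape[0] != atlas.n_regions:
        raise ValidationError(
            f"time series has {ts.shape[0]} rows, atlas {atlas.name} defines "
            f"{atlas.n_regions} regions")
    if atlas.has_average_node:
        series = np.vstack([ts, ts.mean(axis=0, keepdims=True)])
    else:
        series = ts
    if np.any(series.std(axis=1) == 0):
        bad = np.where(series.std(axis=1) == 0)[0].tolist()
        raise FeatureError(
            f"constant time series at rows {bad}: correlation undefined. "
            "Check ROI extraction; constant series usually mean an empty mask.")
    corr = np.corrcoef(series)
    m = series.shape[0]
    a = np.zeros((m, m))
    for left, right in atlas.homolog_pairs:
        a[left, right] = a[right, left] = 1.0
    if atlas.has_average_node:
        a[:-1, -1] = a[-1, :-1] = 1.0
    if knn_k > 0:
        strength = np.abs(corr)
        np.fill_diagonal(strength, -np.inf)
        k = min(knn_k, m - 1)
        nbrs = np.argsort(-strength, axis=1, kind="stable")[:, :k]
        rows = np.repeat(np.arange(m), k)
        a[rows, nbrs.ravel()] = 1.0
        a = np.maximum(a, a.T)       # symmetrize the kNN term
    np.fill_diagonal(a, 0.0)
    return BrainGraph(X=corr, A=a, atlas=atlas, subject_id=subject_id)


def _normalized_adjacency(a: np.ndarray) -> np.ndarray:
    """Symmetric normalisation with self-loops: D^-1/2 (A + I) D^-1/2."""
    a_hat = a + np.eye(a.shape[0])
    d = a_hat.sum(axis=1)
    d_inv_sqrt = 1.0 / np.sqrt(d)
    return a_hat * d_inv_sqrt[:, None] * d_inv_sqrt[None, :]


def node_importance(g: BrainGraph, w_conv: np.ndarray, w_score: np.ndarray
                    ) -> np.ndarray:
    """Per-node importance alpha = sigmoid(H w), H = ReLU(A_hat X W)."""
    a_hat = _normalized_adjacency(g.A)
    h = np.maximum(a_hat @ g.X @ w_conv, 0.0)
    return 1.0 / (1.0 + np.exp(-(h @ w_score)))


def _undirected_edges(a: np.ndarray) -> np.ndarray:
    i, j = np.nonzero(np.triu(a, k=1))
    return np.stack([i, j], axis=1)


def prune_edges(g: BrainGraph, alpha: np.ndarray
                ) -> tuple[np.ndarray, EdgeScoreTable]:
    """Drop edges whose score alpha_i + alpha_j does not exceed the mean score.

    Self-loops are never scored (they exist only inside the normalised
    propagation matrix). If no edge strictly exceeds the mean — possible
    only when all scores are equal — every edge is retained so the graph
    never degenerates to an empty edge set. All nodes are preserved.
    """
    alpha = np.asarray(alpha, dtype=np.float64)
    if alpha.shape[0] != g.n_nodes:
        raise ValidationError("alpha length must equal node count")
    edges = _undirected_edges(g.A)
    if len(edges) == 0:
        return g.A.copy(), EdgeScoreTable(edges, np.array([]), float("nan"),
                                          np.array([], dtype=bool))
    scores = alpha[edges[:, 0]] + alpha[edges[:, 1]]
    mean_score = float(scores.mean())
    retained = scores > mean_score
    if not retained.any():
        retained = np.ones_like(retained)
    a_pruned = np.zeros_like(g.A)
    kept = edges[retained]
    a_pruned[kept[:, 0], kept[:, 1]] = 1.0
    a_pruned[kept[:, 1], kept[:, 0]] = 1.0
    return a_pruned, EdgeScoreTable(edges, scores, mean_score, retained)


@dataclass
class EspmNetwork:
    """Seeded parameter set applying the pooling mechanism to one atlas."""

    params: EspmParams
    weights: dict = field(default_factory=dict)

    @classmethod
    def init(cls, params: EspmParams, seed: int = 0) -> "EspmNetwork":
        rng = np.random.default_rng(seed)
        m, h, h2, d = params.in_dim, params.hidden, params.post_hidden, params.out_dim
        w = {
            "conv1_w": rng.normal(0, np.sqrt(2 / m), (m, h)),
            "score_w": rng.normal(0, np.sqrt(1 / h), h),
            "conv2_w": rng.normal(0, np.sqrt(2 / m), (m, h2)),
            "head_w": rng.normal(0, np.sqrt(2 / h2), (h2, d)),
        }
        return cls(params=params, weights=w)

    def importance(self, g: BrainGraph) -> np.ndarray:
        return node_importance(g, self.weights["conv1_w"], self.weights["score_w"])

    def embed(self, g: BrainGraph, prune: bool = True
              ) -> tuple[np.ndarray, np.ndarray]:
        """Return (embedding, alpha) for one brain graph."""
        alpha = self.importance(g)
        a_used = prune_edges(g, alpha)[0] if prune else g.A
        emb = espm_embed(g.X, a_used, alpha,
                         self.weights["conv2_w"], self.weights["head_w"])
        return emb, alpha


def graph_to_edgelist(g: BrainGraph, path=None):
    """Undirected edge list (source/target labels) as a DataFrame or CSV."""
    import pandas as pd

    labels = list(g.atlas.region_labels)
    if g.atlas.has_average_node:
        labels.append("__average__")
    edges = _undirected_edges(g.A)
    df = pd.DataFrame({"source": [labels[i] for i in edges[:, 0]],
                       "target": [labels[j] for j in edges[:, 1]]})
    if path is not None:
        df.to_csv(path, index=False)
    return df


def espm_embed(x: np.ndarray, a_pruned: np.ndarray, alpha: np.ndarray,
               w_conv: np.ndarray, w_head: np.ndarray) -> np.ndarray:
    """Recalibrate nodes by alpha, convolve on the pruned graph, mean pool."""
    x_prime = x * np.asarray(alpha)[:, None]
    h = np.maximum(_normalized_adjacency(a_pruned) @ x_prime @ w_conv, 0.0)
    return h.mean(axis=0) @ w_head
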