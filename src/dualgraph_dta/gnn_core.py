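"""Graph encoders: GATv2 (reference) plus GAT and GCN ablation variants.

Attention scoring
-----------------
For an edge j -> i with node states h_i, h_j and edge feature e_ij, the
unnormalised score in the two supported modes is::

    gatv2_canonical : a^T LeakyReLU(W1 [h_i || h_j || e_ij] + b1) / sqrt(d_k)
    as_printed_linear: (w1^T [h_i || h_j || e_ij] + b1) / sqrt(d_k)

with d_k the dimension of the concatenated vector. Coefficients alpha_ij are
the softmax of the scores over each node i's in-neighbourhood (self-loops
included by default so degree-0 nodes keep their state). The GAT variant
applies its shared transform first and scores with
LeakyReLU(a^T [W h_i || W h_j || e_ij]) -- a *static* attention whose
neighbour ranking cannot depend on the query node. The GCN variant drops
attention entirely and uses symmetric-normalised equal-weight aggregation
D^-1/2 (A+I) D^-1/2.

Message passing (all variants): h'_i = sigma(sum_j alpha_ij W2 h_j).

Multi-head handling: heads are concatenated on all but the last layer and
averaged on the last (standard GAT-family convention). Readout is a mean
pool over nodes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .autodiff import (
    SegmentContext,
    Tensor,
    as_tensor,
    concat,
    gather_rows,
    gather_rows_ctx,
    glorot,
    parameter,
    segment_mean,
    segment_softmax,
    segment_softmax_ctx,
    segment_sum,
    segment_sum_ctx,
)

VARIANTS = ("gatv2", "gat", "gcn")
SCORE_MODES = ("gatv2_canonical", "as_printed_linear")
ACTIVATIONS = ("elu", "relu", "identity")


def _apply_activation(t: Tensor, name: str) -> Tensor:
    if name == "elu":
        return t.elu()
    if name == "relu":
        return t.relu()
    if name == "identity":
        return t
    raise ValueError(f"unknown activation {name!r}")


def add_self_loops(
    edge_index: np.ndarray, edge_feats: np.ndarray, num_nodes: int
) -> tuple[np.ndarray, np.ndarray]:
    """Append (i, i) edges with zero edge features."""
    loops = np.stack([np.arange(num_nodes), np.arange(num_nodes)], axis=1).astype(np.intp)
    n_edges = len(np.asarray(edge_index).reshape(-1, 2))
    edge_index = np.concatenate([np.asarray(edge_index, dtype=np.intp).reshape(-1, 2), loops])
    fe = 0
    if edge_feats is not None:
        ef = np.asarray(edge_feats, dtype=np.float64)
        if ef.ndim != 2:
            ef = ef.reshape(n_edges, -1) if ef.size else ef.reshape(n_edges, 0)
        fe = ef.shape[1]
    if fe == 0:
        return edge_index, np.zeros((len(edge_index), 0))
    edge_feats = np.concatenate([ef, np.zeros((num_nodes, fe))])
    return edge_index, edge_feats


# ---------------------------------------------------------------------------
# single-head parameter container (functional surface)
# ---------------------------------------------------------------------------

@dataclass
class AttentionLayerParams:
    """Learnable tensors of one attention head.

    ``W1``/``a``/``b1`` parameterise the score, ``W2`` the message transform.
    For the GAT variant ``W1`` is the shared endpoint transform (F, dh) and
    ``a`` has length 2*dh + edge_dim; for GATv2 ``W1`` is (2F + edge_dim, dh)
    and ``a`` has length dh. ``d_k`` defaults to the concatenated dimension.
    """

    W1: np.ndarray
    a: np.ndarray
    b1: np.ndarray
    W2: np.ndarray
    d_k: float
    n_heads: int = 1
    leak: float = 0.2
    variant: str = "gatv2"
    score_mode: str = "gatv2_canonical"

    def __post_init__(self) -> None:
        if self.variant not in VARIANTS:
            raise ValueError(f"variant must be one of {VARIANTS}")
        if self.score_mode not in SCORE_MODES:
            raise ValueError(f"score_mode must be one of {SCORE_MODES}")
        if self.d_k <= 0:
            raise ValueError("d_k must be positive")


def _edge_scores(
    h: Tensor,
    edge_index: np.ndarray,
    edge_feats: np.ndarray,
    W1: Tensor,
    a: Tensor,
    b1: Tensor,
    d_k: float,
    leak: float,
    variant: str,
    score_mode: str,
    ctx: SegmentContext | None = None,
) -> Tensor:
    """Unnormalised attention score per edge (1-D Tensor).

    The concatenated transform W1 [h_i || h_j || e_ij] is evaluated in
    decomposed form (row blocks of W1 applied to h once per node, gathered
    per edge) -- algebraically identical but far cheaper on large edge sets.
    """
    src, dst = edge_index[:, 0], edge_index[:, 1]
    fe = np.asarray(edge_feats, dtype=np.float64).reshape(len(edge_index), -1)
    ef = as_tensor(fe)
    f = h.shape[1]

    def _at_dst(x: Tensor) -> Tensor:
        return gather_rows_ctx(x, ctx) if ctx is not None else gather_rows(x, dst)

    if variant == "gatv2":
        W_i, W_j = W1[:f], W1[f : 2 * f]
        pre = _at_dst(h @ W_i) + gather_rows(h @ W_j, src) + b1
        if fe.shape[1]:
            pre = pre + ef @ W1[2 * f :]
        if score_mode == "as_printed_linear":
            s = pre  # W1 is a single column here; LeakyReLU and a are dropped
        else:
            s = pre.leaky_relu(leak) @ a
        return s.reshape(-1) / np.sqrt(d_k)
    if variant == "gat":
        hw = h @ W1
        dh = hw.shape[1]
        a_i, a_j = a[:dh], a[dh : 2 * dh]
        pre = _at_dst(hw @ a_i) + gather_rows(hw @ a_j, src) + b1
        if fe.shape[1]:
            pre = pre + ef @ a[2 * dh :]
        s = pre.leaky_relu(leak)
        return s.reshape(-1) / np.sqrt(d_k)
    raise ValueError("attention scores are undefined for the gcn variant")


def attention_coefficients(
    h: np.ndarray,
    edges: np.ndarray,
    edge_feats: np.ndarray | None,
    params: AttentionLayerParams,
    self_loops: bool = True,
) -> tuple[np.ndarray, np.ndarray]:
    """Normalised attention coefficients for one head.

    Returns ``(edge_index_used, alpha)`` where ``edge_index_used`` includes
    the appended self-loops when ``self_loops`` is true. For every node i the
    coefficients over its incoming edges sum to 1.
    """
    h_t = as_tensor(np.asarray(h, dtype=np.float64))
    n = h_t.shape[0]
    edges = np.asarray(edges, dtype=np.intp).reshape(-1, 2)
    if edge_feats is None:
        edge_feats = np.zeros((len(edges), 0))
    if self_loops:
        edges, edge_feats = add_self_loops(edges, edge_feats, n)
    a_col = as_tensor(np.asarray(params.a, dtype=np.float64).reshape(-1, 1))
    scores = _edge_scores(
        h_t, edges, edge_feats,
        as_tensor(params.W1), a_col, as_tensor(params.b1),
        params.d_k, params.leak, params.variant, params.score_mode,
    )
    alpha = segment_softmax(scores, edges[:, 1], n)
    return edges, alpha.data


def message_passing_update(
    h: np.ndarray,
    edge_index: np.ndarray,
    alpha: np.ndarray,
    params: AttentionLayerParams,
    activation: str = "identity",
) -> np.ndarray:
    """h'_i = sigma(sum_{j in N(i)} alpha_ij W2 h_j) for one head."""
    edge_index = np.asarray(edge_index, dtype=np.intp).reshape(-1, 2)
    if len(alpha) != len(edge_index):
        raise ValueError("alpha / edge_index length mismatch")
    h_t = as_tensor(np.asarray(h, dtype=np.float64))
    n = h_t.shape[0]
    msg = gather_rows(h_t @ as_tensor(params.W2), edge_index[:, 0])
    weighted = msg * as_tensor(np.asarray(alpha).reshape(-1, 1))
    out = segment_sum(weighted, edge_index[:, 1], n)
    return _apply_activation(out, activation).data


def gcn_update(
    h: np.ndarray,
    edge_index: np.ndarray,
    params: AttentionLayerParams,
    activation: str = "identity",
    self_loops: bool = True,
) -> np.ndarray:
    """Symmetric-normalised graph convolution: sigma(D~^-1/2 (A+I) D~^-1/2 H W)."""
    h_t = as_tensor(np.asarray(h, dtype=np.float64))
    n = h_t.shape[0]
    edge_index = np.asarray(edge_index, dtype=np.intp).reshape(-1, 2)
    if self_loops:
        edge_index, _ = add_self_loops(edge_index, None, n)
    deg = np.bincount(edge_index[:, 1], minlength=n).astype(np.float64)
    norm = 1.0 / np.sqrt(deg[edge_index[:, 0]] * deg[edge_index[:, 1]])
    msg = gather_rows(h_t @ as_tensor(params.W2), edge_index[:, 0])
    out = segment_sum(msg * as_tensor(norm.reshape(-1, 1)), edge_index[:, 1], n)
    return _apply_activation(out, activation).data


# ---------------------------------------------------------------------------
# multi-head layers and the 3-layer encoder
# ---------------------------------------------------------------------------

@dataclass
class GraphEncoderConfig:
    """Structural choices of a graph encoder stack."""

    n_layers: int = 3
    hidden_dim: int = 512
    variant: str = "gatv2"
    score_mode: str = "gatv2_canonical"
    n_heads: int = 4
    leak: float = 0.2
    activation: str = "elu"
    readout: str = "mean"
    dropout: float = 0.0

    def __post_init__(self) -> None:
        if self.n_layers < 1 or self.hidden_dim < 1:
            raise ValueError("n_layers and hidden_dim must be positive")
        if self.variant not in VARIANTS:
            raise ValueError(f"variant must be one of {VARIANTS}")
        if self.score_mode not in SCORE_MODES:
            raise ValueError(f"score_mode must be one of {SCORE_MODES}")
        if self.readout != "mean":
            raise ValueError("only mean readout is supported")
        if self.variant != "gcn" and self.hidden_dim % self.n_heads:
            raise ValueError("hidden_dim must be divisible by n_heads")


class _AttentionLayer:
    """One multi-head attention layer (GATv2 or GAT form)."""

    def __init__(
        self,
        in_dim: int,
        head_dim: int,
        n_heads: int,
        edge_dim: int,
        cfg: GraphEncoderConfig,
        concat_heads: bool,
        rng: np.random.Generator,
    ):
        self.cfg = cfg
        self.n_heads = n_heads
        self.head_dim = head_dim
        self.concat_heads = concat_heads
        self.edge_dim = edge_dim
        z_dim = 2 * in_dim + edge_dim
        self.d_k = float(z_dim)
        self.heads = []
        for _ in range(n_heads):
            if cfg.variant == "gatv2":
                score_cols = 1 if cfg.score_mode == "as_printed_linear" else head_dim
                W1 = glorot(rng, (z_dim, score_cols))
                a = glorot(rng, (score_cols, 1))
                b1 = parameter(np.zeros(score_cols))
            else:  # gat
                W1 = glorot(rng, (in_dim, head_dim))
                a = glorot(rng, (2 * head_dim + edge_dim, 1))
                b1 = parameter(np.zeros(1))
            W2 = glorot(rng, (in_dim, head_dim))
            self.heads.append({"W1": W1, "a": a, "b1": b1, "W2": W2})

    def parameters(self) -> list[Tensor]:
        return [p for h in self.heads for p in h.values()]

    def forward(
        self,
        h: Tensor,
        edge_index: np.ndarray,
        edge_feats: np.ndarray,
        num_nodes: int,
        ctx: SegmentContext | None = None,
    ) -> Tensor:
        outs = []
        for hd in self.heads:
            scores = _edge_scores(
                h, edge_index, edge_feats, hd["W1"], hd["a"], hd["b1"],
                self.d_k, self.cfg.leak, self.cfg.variant, self.cfg.score_mode,
                ctx=ctx,
            )
            alpha = (segment_softmax_ctx(scores, ctx) if ctx is not None
                     else segment_softmax(scores, edge_index[:, 1], num_nodes))
            msg = gather_rows(h @ hd["W2"], edge_index[:, 0]) * alpha.reshape(-1, 1)
            outs.append(segment_sum_ctx(msg, ctx) if ctx is not None
                        else segment_sum(msg, edge_index[:, 1], num_nodes))
        if self.concat_heads:
            out = concat(outs, axis=1)
        else:
            out = outs[0]
            for o in outs[1:]:
                out = out + o
            out = out / float(len(outs))
        return _apply_activation(out, self.cfg.activation)


class _GCNLayer:
    def __init__(self, in_dim: int, out_dim: int, cfg: GraphEncoderConfig,
                 rng: np.random.Generator):
        self.cfg = cfg
        self.W = glorot(rng, (in_dim, out_dim))

    def parameters(self) -> list[Tensor]:
        return [self.W]

    def forward(self, h: Tensor, edge_index: np.ndarray, edge_feats: np.ndarray,
                num_nodes: int, ctx: SegmentContext | None = None) -> Tensor:
        deg = np.bincount(edge_index[:, 1], minlength=num_nodes).astype(np.float64)
        norm = 1.0 / np.sqrt(deg[edge_index[:, 0]] * deg[edge_index[:, 1]])
        msg = gather_rows(h @ self.W, edge_index[:, 0]) * as_tensor(norm.reshape(-1, 1))
        out = (segment_sum_ctx(msg, ctx) if ctx is not None
               else segment_sum(msg, edge_index[:, 1], num_nodes))
        return _apply_activation(out, self.cfg.activation)


class GraphEncoder:
    """n-layer graph encoder with mean-pool readout.

    ``encode_batch`` operates on a disjoint union of graphs: node features
    stacked, edge indices offset, plus a per-node graph id used for pooling.
    Self-loops are added here (zero edge features) before any layer runs.
    """

    def __init__(self, in_dim: int, edge_dim: int, config: GraphEncoderConfig,
                 rng: np.random.Generator):
        self.config = config
        self.in_dim = in_dim
        self.edge_dim = edge_dim
        self.layers: list[_AttentionLayer | _GCNLayer] = []
        dim = in_dim
        for layer_idx in range(config.n_layers):
            last = layer_idx == config.n_layers - 1
            if config.variant == "gcn":
                self.layers.append(_GCNLayer(dim, config.hidden_dim, config, rng))
                dim = config.hidden_dim
            else:
                if last:
                    head_dim, concat_heads = config.hidden_dim, False
                else:
                    head_dim, concat_heads = config.hidden_dim // config.n_heads, True
                self.layers.append(
                    _AttentionLayer(dim, head_dim, config.n_heads, edge_dim, config,
                                    concat_heads, rng)
                )
                dim = head_dim * config.n_heads if concat_heads else head_dim
        self.out_dim = dim

    def parameters(self) -> list[Tensor]:
        return [p for layer in self.layers for p in layer.parameters()]

    def encode_batch(
        self,
        node_features: Tensor | np.ndarray,
        edge_index: np.ndarray,
        edge_feats: np.ndarray | None,
        graph_ids: np.ndarray,
        n_graphs: int,
        rng: np.random.Generator | None = None,
        training: bool = False,
    ) -> Tensor:
        h = as_tensor(node_features)
        num_nodes = h.shape[0]
        if num_nodes == 0:
            raise ValueError("cannot encode an empty graph batch")
        if edge_feats is None:
            edge_feats = np.zeros((len(edge_index), 0))
        edge_index, edge_feats = add_self_loops(edge_index, edge_feats, num_nodes)
        # sort edges by destination once: all dst-side segment ops then run
        # on the contiguous fast path
        order = np.argsort(edge_index[:, 1], kind="stable")
        edge_index = edge_index[order]
        edge_feats = edge_feats[order]
        ctx = SegmentContext(edge_index[:, 1], num_nodes)
        for layer in self.layers:
            h = layer.forward(h, edge_index, edge_feats, num_nodes, ctx=ctx)
            if training and self.config.dropout > 0 and rng is not None:
                keep = (rng.random(h.shape) >= self.config.dropout) / (1 - self.config.dropout)
                h = h * as_tensor(keep)
        return segment_mean(h, graph_ids, n_graphs)


def encode_graph(graph, encoder: GraphEncoder) -> np.ndarray:
    """Graph-level vector for a single MolecularGraph / ProteinGraph."""
    if graph.num_nodes == 0:
        raise ValueError("cannot encode an empty graph")
    edge_feats = getattr(graph, "edge_features", None)
    if edge_feats is None:
        w = getattr(graph, "edge_weights", None)
        edge_feats = None if w is None else np.asarray(w).reshape(-1, 1)
    out = encoder.encode_batch(
        np.asarray(graph.node_features, dtype=np.float64),
        np.asarray(graph.edge_index, dtype=np.intp).reshape(-1, 2),
        edge_feats,
        np.zeros(graph.num_nodes, dtype=np.intp),
        1,
    )
    return out.data[0]


__all__ = [
    "VARIANTS",
    "SCORE_MODES",
    "AttentionLayerParams",
    "GraphEncoderConfig",
    "GraphEncoder",
    "add_self_loops",
    "attention_coefficients",
    "message_passing_update",
    "gcn_update",
    "encode_graph",
]
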