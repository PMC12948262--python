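"""Attention coefficients, message passing, GCN aggregation, graph encoding."""

import numpy as np
import pytest

from dualgraph_dta.drug_graph import build_molecular_graph
from dualgraph_dta.gnn_core import (
    AttentionLayerParams,
    GraphEncoder,
    GraphEncoderConfig,
    add_self_loops,
    attention_coefficients,
    encode_graph,
    gcn_update,
    message_passing_update,
)


def _single_head_params(f, dh=4, edge_dim=0, variant="gatv2",
                        score_mode="gatv2_canonical", seed=0):
    rng = np.random.default_rng(seed)
    z = 2 * f + edge_dim
    if variant == "gatv2":
        cols = 1 if score_mode == "as_printed_linear" else dh
        W1 = rng.normal(size=(z, cols))
        a = rng.normal(size=cols)
        b1 = rng.normal(size=cols)
    else:
        W1 = rng.normal(size=(f, dh))
        a = rng.normal(size=2 * dh + edge_dim)
        b1 = rng.normal(size=1)
    return AttentionLayerParams(W1=W1, a=a, b1=b1, W2=rng.normal(size=(f, dh)),
                                d_k=float(z), variant=variant, score_mode=score_mode)


# ---------------------------------------------------------------------------
# attention coefficients
# ---------------------------------------------------------------------------

def test_single_neighbour_gets_full_attention(rng):
    h = rng.normal(size=(2, 3))
    params = _single_head_params(3)
    edges, alpha = attention_coefficients(h, [(0, 1)], None, params, self_loops=False)
    assert alpha[0] == pytest.approx(1.0)


def test_identical_neighbours_share_attention_equally():
    h = np.array([[0.5, -1.0], [2.0, 0.3], [2.0, 0.3]])  # nodes 1, 2 identical
    params = _single_head_params(2)
    edges, alpha = attention_coefficients(
        h, [(1, 0), (2, 0)], None, params, self_loops=False
    )
    np.testing.assert_allclose(alpha, [0.5, 0.5], atol=1e-12)


@pytest.mark.parametrize("score_mode", ["gatv2_canonical", "as_printed_linear"])
def test_path_graph_matches_scalar_oracle(score_mode):
    """Explicit per-edge arithmetic reproduction of the score + softmax."""
    f, dh = 2, 3
    h = np.array([[1.0, 2.0], [0.5, -1.0], [-2.0, 0.25]])
    edges = [(0, 1), (2, 1)]  # node 1 receives from both ends of the path
    params = _single_head_params(f, dh, score_mode=score_mode, seed=3)
    _, alpha = attention_coefficients(h, edges, None, params, self_loops=False)

    def leaky(x):
        return np.where(x > 0, x, 0.2 * x)

    scores = []
    for src, dst in edges:
        z = np.concatenate([h[dst], h[src]])
        if score_mode == "as_printed_linear":
            s = float((z @ params.W1 + params.b1)[0])
        else:
            s = float(leaky(z @ params.W1 + params.b1) @ params.a)
        scores.append(s / np.sqrt(params.d_k))
    e = np.exp(np.array(scores) - max(scores))
    np.testing.assert_allclose(alpha, e / e.sum(), atol=1e-12)


def test_attention_includes_edge_features_in_score():
    f = 2
    h = np.ones((3, f))
    edge_feats = np.array([[1.0], [0.1]])  # distinct 1-D edge features
    params = _single_head_params(f, edge_dim=1, seed=5)
    _, alpha = attention_coefficients(
        h, [(1, 0), (2, 0)], edge_feats, params, self_loops=False
    )
    assert abs(alpha[0] - alpha[1]) > 1e-6  # identical nodes, differing edges


def test_self_loops_added_when_requested(rng):
    h = rng.normal(size=(3, 2))
    params = _single_head_params(2)
    edges, alpha = attention_coefficients(h, [(0, 1)], None, params, self_loops=True)
    assert len(edges) == 4  # 1 real edge + 3 self-loops
    # normalisation holds for every node
    sums = np.zeros(3)
    np.add.at(sums, edges[:, 1], alpha)
    np.testing.assert_allclose(sums, 1.0, atol=1e-9)


# ---------------------------------------------------------------------------
# message passing
# ---------------------------------------------------------------------------

def test_self_loop_identity_fixed_point(rng):
    h = rng.normal(size=(3, 4))
    params = _single_head_params(4, dh=4)
    params.W2 = np.eye(4)
    edges = [(i, i) for i in range(3)]
    out = message_passing_update(h, edges, np.ones(3), params, activation="identity")
    np.testing.assert_allclose(out, h, atol=1e-12)


def test_single_neighbour_copies_its_state(rng):
    h = rng.normal(size=(2, 4))
    params = _single_head_params(4, dh=4)
    params.W2 = np.eye(4)
    out = message_passing_update(h, [(1, 0)], np.array([1.0]), params,
                                 activation="identity")
    np.testing.assert_allclose(out[0], h[1], atol=1e-12)


def test_weighted_sum_matches_brute_force(rng):
    h = rng.normal(size=(3, 3))
    params = _single_head_params(3, dh=2, seed=1)
    edges = [(0, 2), (1, 2), (2, 2)]
    alpha = np.array([0.2, 0.5, 0.3])
    out = message_passing_update(h, edges, alpha, params, activation="identity")
    expected = 0.2 * h[0] @ params.W2 + 0.5 * h[1] @ params.W2 + 0.3 * h[2] @ params.W2
    np.testing.assert_allclose(out[2], expected, atol=1e-10)


def test_alpha_edge_mismatch_is_error(rng):
    params = _single_head_params(2)
    with pytest.raises(ValueError):
        message_passing_update(np.ones((2, 2)), [(0, 1)], np.ones(3), params)


# ---------------------------------------------------------------------------
# GCN aggregation
# ---------------------------------------------------------------------------

def test_gcn_isolated_node_identity():
    params = _single_head_params(3, dh=3)
    params.W2 = np.eye(3)
    h = np.array([[1.0, -2.0, 0.5]])
    out = gcn_update(h, np.zeros((0, 2), dtype=int), params, activation="identity")
    np.testing.assert_allclose(out, h, atol=1e-12)


def test_gcn_symmetric_nodes_get_equal_outputs():
    params = _single_head_params(2, dh=2, seed=2)
    h = np.array([[1.0, 2.0], [1.0, 2.0]])
    out = gcn_update(h, [(0, 1), (1, 0)], params, activation="identity")
    np.testing.assert_allclose(out[0], out[1], atol=1e-12)


def test_gcn_matches_dense_normalised_adjacency(rng):
    n, f, o = 4, 3, 2
    h = rng.normal(size=(n, f))
    params = _single_head_params(f, dh=o, seed=7)
    edges = [(0, 1), (1, 0), (1, 2), (2, 1), (2, 3), (3, 2)]
    out = gcn_update(h, edges, params, activation="identity")
    A = np.zeros((n, n))
    for i, j in edges:
        A[j, i] = 1  # aggregation at dst
    A += np.eye(n)
    d = A.sum(axis=1)
    A_hat = A / np.sqrt(np.outer(d, d))
    np.testing.assert_allclose(out, A_hat @ h @ params.W2, atol=1e-10)


def test_gcn_equals_uniform_attention_on_regular_graph(rng):
    """With zeroed score parameters GATv2 attention becomes uniform; on a
    degree-regular graph that coincides with GCN's symmetric normalisation."""
    n, f = 6, 3
    h = rng.normal(size=(n, f))
    ring = [(i, (i + 1) % n) for i in range(n)] + [((i + 1) % n, i) for i in range(n)]
    params = _single_head_params(f, dh=f, seed=9)
    params.W1 = np.zeros_like(params.W1)
    params.a = np.zeros_like(params.a)
    params.b1 = np.zeros_like(params.b1)
    edges_aug, alpha = attention_coefficients(h, ring, None, params, self_loops=True)
    att_out = message_passing_update(h, edges_aug, alpha, params, activation="identity")
    gcn_out = gcn_update(h, ring, params, activation="identity")
    np.testing.assert_allclose(att_out, gcn_out, atol=1e-6)


# ---------------------------------------------------------------------------
# graph-level encoding
# ---------------------------------------------------------------------------

def test_softmax_normalisation_on_random_graphs(rng):
    for _ in range(20):
        n = int(rng.integers(2, 30))
        f = 3
        h = rng.normal(size=(n, f))
        n_edges = int(rng.integers(1, n * 2))
        edges = rng.integers(0, n, size=(n_edges, 2))
        edges = edges[edges[:, 0] != edges[:, 1]]
        params = _single_head_params(f, seed=int(rng.integers(1000)))
        eaug, alpha = attention_coefficients(h, edges.reshape(-1, 2), None, params)
        sums = np.zeros(n)
        np.add.at(sums, eaug[:, 1], alpha)
        np.testing.assert_allclose(sums, 1.0, atol=1e-6)


def test_permutation_invariant_encoding(atom_provider, rng):
    g = build_molecular_graph("CC(=O)Oc1ccccc1", atom_provider)
    encoder = GraphEncoder(
        atom_provider.dim, 6,
        GraphEncoderConfig(hidden_dim=8, n_heads=2), np.random.default_rng(0),
    )
    out1 = encode_graph(g, encoder)
    perm = rng.permutation(g.num_nodes)
    inv = np.argsort(perm)
    g.node_features = g.node_features[perm]
    g.edge_index = np.array([(inv[s], inv[d]) for s, d in g.edge_index])
    out2 = encode_graph(g, encoder)
    np.testing.assert_allclose(out1, out2, atol=1e-5)


def test_isomorphic_smiles_orders_encode_equally(atom_provider):
    encoder = GraphEncoder(
        atom_provider.dim, 6,
        GraphEncoderConfig(hidden_dim=8, n_heads=2), np.random.default_rng(1),
    )
    ga = build_molecular_graph("CCO", atom_provider)
    gb = build_molecular_graph("OCC", atom_provider)
    np.testing.assert_allclose(encode_graph(ga, encoder), encode_graph(gb, encoder),
                               atol=1e-5)


def test_single_node_identity_composition(rng):
    """Identity-configured layers pass a single node's feature through."""
    dim = 5
    encoder = GraphEncoder(
        dim, 0,
        GraphEncoderConfig(hidden_dim=dim, n_heads=1, activation="identity"),
        np.random.default_rng(0),
    )
    for layer in encoder.layers:
        layer.heads[0]["W2"].data = np.eye(dim)

    class OneNode:
        num_nodes = 1
        node_features = rng.normal(size=(1, dim))
        edge_index = np.zeros((0, 2), dtype=int)
        edge_features = np.zeros((0, 0))

    out = encode_graph(OneNode(), encoder)
    np.testing.assert_allclose(out, OneNode.node_features[0], atol=1e-10)


def test_empty_graph_is_error(atom_provider):
    encoder = GraphEncoder(4, 0, GraphEncoderConfig(hidden_dim=4, n_heads=1),
                           np.random.default_rng(0))

    class Empty:
        num_nodes = 0
        node_features = np.zeros((0, 4))
        edge_index = np.zeros((0, 2), dtype=int)
        edge_features = None

    with pytest.raises(ValueError):
        encode_graph(Empty(), encoder)


def test_config_validation():
    with pytest.raises(ValueError):
        GraphEncoderConfig(hidden_dim=10, n_heads=4)  # not divisible
    with pytest.raises(ValueError):
        GraphEncoderConfig(variant="transformer")
    with pytest.raises(ValueError):
        AttentionLayerParams(W1=np.eye(2), a=np.ones(2), b1=np.zeros(2),
                             W2=np.eye(2), d_k=-1.0)
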