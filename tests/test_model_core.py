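import numpy as np
import pytest

from epitopegnn.autodiff import Tensor
from epitopegnn.graph_builder import assemble_graph
from epitopegnn.model_core import (
    ModalityBundle,
    ModelConfig,
    ModelParams,
    additive_attention,
    forward,
    fuse_nodes,
    graph_norm_adjs,
    load_checkpoint,
    multiscale_gcn_layer,
    project_modality,
    residual_combine,
    save_checkpoint,
)

CFG = ModelConfig(seq_dim=20, if_dim=12, proj_dim=16, gcn_dim=16,
                  mlp_hidden=(16, 8), seed=0)


@pytest.fixture
def params():
    return ModelParams(CFG)


def random_instance(seed, n=12):
    rng = np.random.default_rng(seed)
    bundle = ModalityBundle(
        seq_emb=rng.normal(size=(n, CFG.seq_dim)),
        if_emb=rng.normal(size=(n, CFG.if_dim)),
        dssp_feats=rng.normal(size=(n, CFG.dssp_dim)),
    )
    graph = assemble_graph(rng.normal(size=(n, 3)) * 4)
    return bundle, graph


# ---- modality projection -------------------------------------------------

def test_projection_matches_straightline_oracle(params):
    rng = np.random.default_rng(1)
    X = rng.normal(size=(5, CFG.dssp_dim))
    f = params.fusion["dssp"]
    out = project_modality(X, f, CFG.layernorm_eps).data
    # independent step-by-step computation
    h = X @ f.lin.W.data + f.lin.b.data
    mu = h.mean(axis=1, keepdims=True)
    var = ((h - mu) ** 2).mean(axis=1, keepdims=True)
    ln = (h - mu) / np.sqrt(var + CFG.layernorm_eps)
    expect = np.maximum(ln * f.gamma.data + f.beta.data, 0.0)
    np.testing.assert_allclose(out, expect, atol=1e-6)


def test_projection_zero_weights_zero_output(params):
    f = params.fusion["dssp"]
    f.lin.W.data[:] = 0.0
    f.lin.b.data[:] = 0.0
    out = project_modality(np.random.default_rng(0).normal(size=(4, CFG.dssp_dim)), f)
    np.testing.assert_array_equal(out.data, 0.0)


def test_projection_output_nonnegative(params):
    rng = np.random.default_rng(2)
    out = project_modality(rng.normal(size=(6, CFG.seq_dim)),
                           params.fusion["seq"])
    assert (out.data >= 0).all()


def test_fuse_block_order_and_equivariance(params):
    bundle, _ = random_instance(3, n=6)
    X0 = fuse_nodes(bundle, params).data
    assert X0.shape == (6, CFG.fused_dim)
    p = CFG.proj_dim
    np.testing.assert_allclose(
        X0[:, :p], project_modality(bundle.seq_emb, params.fusion["seq"]).data
    )
    np.testing.assert_allclose(
        X0[:, 2 * p:],
        project_modality(bundle.dssp_feats, params.fusion["dssp"]).data,
    )
    # row-wise op: permuting residues permutes rows identically
    perm = np.array([3, 1, 5, 0, 2, 4])
    permuted = ModalityBundle(bundle.seq_emb[perm], bundle.if_emb[perm],
                              bundle.dssp_feats[perm])
    np.testing.assert_allclose(fuse_nodes(permuted, params).data, X0[perm])


def test_fuse_mismatched_rows_error():
    with pytest.raises(ValueError, match="equal residue counts"):
        ModalityBundle(np.zeros((3, 4)), np.zeros((2, 4)), np.zeros((3, 14)))


# ---- additive attention --------------------------------------------------

def test_attention_single_residue(params):
    X = Tensor(np.random.default_rng(0).normal(size=(1, CFG.fused_dim)))
    a, Z, per_res = additive_attention(X, params.attention)
    np.testing.assert_allclose(a.data, [1.0])
    np.testing.assert_allclose(Z.data, X.data[0])
    np.testing.assert_allclose(per_res.data, np.hstack([X.data, X.data]))


def test_attention_constant_scores_uniform(params):
    params.attention.V.data[:] = 0.0  # all e_i equal (zero)
    rng = np.random.default_rng(1)
    X = Tensor(rng.normal(size=(7, CFG.fused_dim)))
    a, Z, _ = additive_attention(X, params.attention)
    np.testing.assert_allclose(a.data, np.full(7, 1 / 7))
    np.testing.assert_allclose(Z.data, X.data.mean(axis=0))


def test_attention_matches_direct_evaluation(params):
    rng = np.random.default_rng(2)
    X = rng.normal(size=(6, CFG.fused_dim))
    a, Z, _ = additive_attention(Tensor(X), params.attention)
    e = (np.tanh(X @ params.attention.W.data) @ params.attention.V.data)[:, 0]
    expect_a = np.exp(e - e.max())
    expect_a /= expect_a.sum()
    np.testing.assert_allclose(a.data, expect_a, atol=1e-6)
    np.testing.assert_allclose(Z.data, expect_a @ X, atol=1e-6)
    assert a.data.sum() == pytest.approx(1.0, abs=1e-8)


def test_attention_shift_invariance(params):
    # adding a constant to every attention energy leaves weights unchanged:
    # equivalent direct check on the softmax of shifted energies
    rng = np.random.default_rng(3)
    X = rng.normal(size=(5, CFG.fused_dim))
    a, _, _ = additive_attention(Tensor(X), params.attention)
    e = (np.tanh(X @ params.attention.W.data) @ params.attention.V.data)[:, 0]
    shifted = np.exp((e + 123.4) - (e + 123.4).max())
    shifted /= shifted.sum()
    np.testing.assert_allclose(a.data, shifted, atol=1e-10)


# ---- multi-scale GCN -----------------------------------------------------

def test_gcn_single_node_identity(params):
    d = CFG.fused_dim
    layer = params.gcn1
    for k in (1, 2, 3):
        layer.W_k[k].data = np.eye(d, CFG.gcn_dim)
    layer.fuse.W.data = np.vstack([np.eye(CFG.gcn_dim)] * 3) / 3.0
    layer.fuse.b.data[:] = 0.0
    x = np.abs(np.random.default_rng(0).normal(size=(1, d)))
    adjs = {k: np.ones((1, 1)) for k in (1, 2, 3)}
    out = multiscale_gcn_layer(Tensor(x), adjs, layer)
    np.testing.assert_allclose(out.data, np.maximum(x[:, :CFG.gcn_dim], 0.0),
                               atol=1e-12)


def test_gcn_identical_features_identical_rows(params):
    # ring graph (2-regular): every node sees the same neighborhood stats
    n, d = 8, CFG.fused_dim
    adj = np.zeros((n, n), dtype=int)
    for i in range(n):
        adj[i, (i + 1) % n] = adj[(i + 1) % n, i] = 1
    from epitopegnn.graph_builder import khop_adjacency, normalized_adjacency

    adjs = {k: normalized_adjacency(khop_adjacency(adj, k)) for k in (1, 2, 3)}
    x = np.tile(np.random.default_rng(1).normal(size=(1, d)), (n, 1))
    out = multiscale_gcn_layer(Tensor(x), adjs, params.gcn1).data
    np.testing.assert_allclose(out, np.tile(out[:1], (n, 1)), atol=1e-10)


def test_gcn_matches_dense_oracle(params):
    rng = np.random.default_rng(4)
    n = 12
    graph = assemble_graph(rng.normal(size=(n, 3)) * 4)
    adjs = graph_norm_adjs(graph)
    H = rng.normal(size=(n, CFG.fused_dim))
    out = multiscale_gcn_layer(Tensor(H), adjs, params.gcn1).data
    # independent dense computation per kernel
    pieces = []
    for k in (1, 2, 3):
        a = graph.multi_adj[k].astype(float)
        deg = a.sum(1)
        ahat = a / np.sqrt(np.outer(deg, deg))
        pieces.append(np.maximum(ahat @ H @ params.gcn1.W_k[k].data, 0.0))
    fused = np.concatenate(pieces, axis=1)
    expect = np.maximum(
        fused @ params.gcn1.fuse.W.data + params.gcn1.fuse.b.data, 0.0
    )
    np.testing.assert_allclose(out, expect, atol=1e-5)


def test_gcn_size_mismatch_error(params):
    adjs = {k: np.ones((3, 3)) / 3 for k in (1, 2, 3)}
    with pytest.raises(ValueError, match="mismatch"):
        multiscale_gcn_layer(Tensor(np.zeros((4, CFG.fused_dim))), adjs,
                             params.gcn1)


def test_gcn_permutation_equivariance(params):
    rng = np.random.default_rng(5)
    n = 10
    graph = assemble_graph(rng.normal(size=(n, 3)) * 4)
    H = rng.normal(size=(n, CFG.fused_dim))
    out = multiscale_gcn_layer(Tensor(H), graph_norm_adjs(graph),
                               params.gcn1).data
    perm = rng.permutation(n)
    adjs_p = {
        k: graph_norm_adjs(graph)[k][np.ix_(perm, perm)] for k in (1, 2, 3)
    }
    out_p = multiscale_gcn_layer(Tensor(H[perm]), adjs_p, params.gcn1).data
    np.testing.assert_allclose(out_p, out[perm], atol=1e-10)


# ---- residual mix --------------------------------------------------------

def test_residual_limits_and_symmetry():
    rng = np.random.default_rng(6)
    H0 = Tensor(rng.normal(size=(4, 3)))
    Hd = Tensor(rng.normal(size=(4, 3)))
    near_one = residual_combine(H0, Hd, Tensor(np.array(50.0))).data
    np.testing.assert_allclose(near_one, H0.data, atol=1e-12)
    near_zero = residual_combine(H0, Hd, Tensor(np.array(-50.0))).data
    np.testing.assert_allclose(near_zero, Hd.data, atol=1e-12)
    zero = residual_combine(H0, Tensor(-H0.data), Tensor(np.array(0.0))).data
    np.testing.assert_allclose(zero, 0.0, atol=1e-12)


def test_residual_convex_bounds():
    rng = np.random.default_rng(7)
    H0, Hd = rng.normal(size=(5, 4)), rng.normal(size=(5, 4))
    for theta in (-3.0, -0.5, 0.0, 1.2, 4.0):
        out = residual_combine(Tensor(H0), Tensor(Hd),
                               Tensor(np.array(theta))).data
        lo, hi = np.minimum(H0, Hd), np.maximum(H0, Hd)
        assert np.all(out >= lo - 1e-12) and np.all(out <= hi + 1e-12)


# ---- full forward --------------------------------------------------------

def test_forward_probabilities_in_open_interval(params):
    bundle, graph = random_instance(8)
    p = forward(bundle, graph, params).data
    assert p.shape == (bundle.n_residues,)
    assert (p > 0).all() and (p < 1).all()


def test_forward_permutation_equivariance(params):
    bundle, graph = random_instance(9, n=10)
    p = forward(bundle, graph, params).data
    rng = np.random.default_rng(0)
    perm = rng.permutation(10)
    bundle_p = ModalityBundle(bundle.seq_emb[perm], bundle.if_emb[perm],
                              bundle.dssp_feats[perm])
    graph_p = assemble_graph(np.zeros((10, 3)))  # placeholder, replaced below
    graph_p.n_nodes = 10
    graph_p.union_adj = graph.union_adj[np.ix_(perm, perm)]
    graph_p.multi_adj = {
        k: graph.multi_adj[k][np.ix_(perm, perm)] for k in (1, 2, 3)
    }
    p_perm = forward(bundle_p, graph_p, params).data
    np.testing.assert_allclose(p_perm, p[perm], atol=1e-10)


def test_forward_duplicate_isolated_nodes_identical(params):
    rng = np.random.default_rng(10)
    row_seq = rng.normal(size=CFG.seq_dim)
    row_if = rng.normal(size=CFG.if_dim)
    row_d = rng.normal(size=CFG.dssp_dim)
    n = 4
    bundle = ModalityBundle(np.tile(row_seq, (n, 1)), np.tile(row_if, (n, 1)),
                            np.tile(row_d, (n, 1)))
    from epitopegnn.graph_builder import ProteinGraph

    eye = np.eye(n, dtype=np.int8)
    graph = ProteinGraph(n_nodes=n, edges_seq=set(), edges_radius=set(),
                         edges_knn=set(),
                         union_adj=np.zeros((n, n), dtype=np.int8),
                         multi_adj={1: eye, 2: eye, 3: eye})
    p = forward(bundle, graph, params).data
    np.testing.assert_allclose(p, p[0], atol=1e-12)


def test_forward_deterministic_in_inference(params):
    bundle, graph = random_instance(11)
    p1 = forward(bundle, graph, params).data
    p2 = forward(bundle, graph, params).data
    np.testing.assert_array_equal(p1, p2)


def test_gradient_reaches_every_parameter(params):
    from epitopegnn.training import bce_loss

    bundle, graph = random_instance(12, n=9)
    labels = np.random.default_rng(1).integers(0, 2, size=9)
    probs = forward(bundle, graph, params, mode="train",
                    dropout_rng=np.random.default_rng(0))
    bce_loss(probs, labels).backward()
    for name, t in params.named_parameters():
        assert t.grad is not None and not np.allclose(t.grad, 0.0), name


def test_checkpoint_roundtrip(tmp_path, params):
    bundle, graph = random_instance(13)
    p_before = forward(bundle, graph, params).data
    path = tmp_path / "model.npz"
    save_checkpoint(params, path)
    restored = load_checkpoint(path)
    assert restored.config == params.config
    p_after = forward(bundle, graph, restored).data
    np.testing.assert_array_equal(p_before, p_after)


def test_lambda_initialized_at_half(params):
    assert params.lam == pytest.approx(0.5)
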