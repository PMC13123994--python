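"""The dual-branch epitope network.

Per-residue inputs come in three modalities — sequence-language embeddings,
inverse-folding embeddings, and the 14-dim structural descriptor.  Each is
projected to a common width (linear → layer norm → ReLU) and concatenated
into the node matrix X₀.  Two branches then run in parallel:

* an additive-attention branch producing a softmax-weighted global context
  vector Z, broadcast back so residue i carries [xᵢ | Z];
* a two-layer multi-scale GCN over the residue graph, each layer applying
  three parallel symmetric-normalized convolutions over the 1-, 2- and
  3-hop adjacencies, fused by a linear map; a learnable convex residual
  λ·H₀ + (1−λ)·H_deep guards against over-smoothing.

The branch outputs are concatenated per residue and an MLP head emits one
sigmoid probability per residue.
"""

from __future__ import annotations

import dataclasses
import json

import numpy as np

from .autodiff import Adam, Tensor, concat, glorot_uniform
from .graph_builder import ProteinGraph, normalized_adjacency

__all__ = [
    "ModelConfig",
    "ModalityBundle",
    "ModelParams",
    "project_modality",
    "fuse_nodes",
    "additive_attention",
    "multiscale_gcn_layer",
    "residual_combine",
    "forward",
    "save_checkpoint",
    "load_checkpoint",
]


@dataclasses.dataclass(frozen=True)
class ModelConfig:
    seq_dim: int = 2560
    if_dim: int = 512
    dssp_dim: int = 14
    proj_dim: int = 256       # per-modality projection width
    gcn_dim: int = 256        # hidden width d1 of the GCN branch
    mlp_hidden: tuple = (256, 64)
    dropout: float = 0.3
    layernorm_eps: float = 1e-5
    seed: int = 0

    @property
    def fused_dim(self) -> int:
        return 3 * self.proj_dim


@dataclasses.dataclass
class ModalityBundle:
    seq_emb: np.ndarray   # N × seq_dim
    if_emb: np.ndarray    # N × if_dim
    dssp_feats: np.ndarray  # N × 14

    def __post_init__(self):
        self.seq_emb = np.asarray(self.seq_emb, dtype=float)
        self.if_emb = np.asarray(self.if_emb, dtype=float)
        self.dssp_feats = np.asarray(self.dssp_feats, dtype=float)
        n = self.seq_emb.shape[0]
        if self.if_emb.shape[0] != n or self.dssp_feats.shape[0] != n:
            raise ValueError("modalities must have equal residue counts")
        for m in (self.seq_emb, self.if_emb, self.dssp_feats):
            if not np.all(np.isfinite(m)):
                raise ValueError("non-finite entries in modality matrix")

    @property
    def n_residues(self) -> int:
        return self.seq_emb.shape[0]


class _Linear:
    def __init__(self, rng, d_in, d_out):
        self.W = glorot_uniform(rng, d_in, d_out)
        self.b = Tensor(np.zeros(d_out), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        return x @ self.W + self.b

    def params(self):
        return [self.W, self.b]


class _FusionParams:
    """Projection + layer norm parameters for one modality."""

    def __init__(self, rng, d_in, d_out):
        self.lin = _Linear(rng, d_in, d_out)
        self.gamma = Tensor(np.ones(d_out), requires_grad=True)
        self.beta = Tensor(np.zeros(d_out), requires_grad=True)

    def params(self):
        return self.lin.params() + [self.gamma, self.beta]


class _AttentionParams:
    def __init__(self, rng, d):
        self.W = glorot_uniform(rng, d, d)
        self.V = glorot_uniform(rng, d, 1, shape=(d, 1))

    def params(self):
        return [self.W, self.V]


class _GcnLayerParams:
    def __init__(self, rng, d_in, d_out):
        self.W_k = {k: glorot_uniform(rng, d_in, d_out) for k in (1, 2, 3)}
        self.fuse = _Linear(rng, 3 * d_out, d_out)

    def params(self):
        return [self.W_k[k] for k in (1, 2, 3)] + self.fuse.params()


class ModelParams:
    """All trainable tensors of the network, built from a seeded RNG."""

    def __init__(self, config: ModelConfig):
        self.config = config
        rng = np.random.default_rng(config.seed)
        p = config.proj_dim
        self.fusion = {
            "seq": _FusionParams(rng, config.seq_dim, p),
            "if": _FusionParams(rng, config.if_dim, p),
            "dssp": _FusionParams(rng, config.dssp_dim, p),
        }
        d0 = config.fused_dim
        d1 = config.gcn_dim
        self.attention = _AttentionParams(rng, d0)
        self.gcn1 = _GcnLayerParams(rng, d0, d1)
        self.gcn2 = _GcnLayerParams(rng, d1, d1)
        self.residual_proj = _Linear(rng, d0, d1)
        self.theta = Tensor(np.zeros(()), requires_grad=True)  # λ = σ(θ) = 0.5
        mlp_in = 2 * d0 + d1
        widths = [mlp_in, *config.mlp_hidden, 1]
        self.mlp = [
            _Linear(rng, a, b) for a, b in zip(widths[:-1], widths[1:])
        ]

    @property
    def lam(self) -> float:
        return float(Tensor(self.theta.data).sigmoid().data)

    def parameters(self):
        out = []
        for f in self.fusion.values():
            out += f.params()
        out += self.attention.params()
        out += self.gcn1.params() + self.gcn2.params()
        out += self.residual_proj.params()
        out.append(self.theta)
        for lin in self.mlp:
            out += lin.params()
        return out

    def named_parameters(self):
        names = []
        for mod, f in self.fusion.items():
            names += [f"fusion.{mod}.W", f"fusion.{mod}.b",
                      f"fusion.{mod}.gamma", f"fusion.{mod}.beta"]
        names += ["attention.W", "attention.V"]
        for layer in ("gcn1", "gcn2"):
            names += [f"{layer}.W1", f"{layer}.W2", f"{layer}.W3",
                      f"{layer}.fuse.W", f"{layer}.fuse.b"]
        names += ["residual_proj.W", "residual_proj.b", "theta"]
        for i in range(len(self.mlp)):
            names += [f"mlp.{i}.W", f"mlp.{i}.b"]
        return list(zip(names, self.parameters()))


def project_modality(X, params: _FusionParams,
                     eps: float = 1e-5) -> Tensor:
    """ReLU(LayerNorm(X W₀ + b₀)) — rows are residues."""
    X = X if isinstance(X, Tensor) else Tensor(X)
    return params.lin(X).layer_norm(params.gamma, params.beta, eps).relu()


def fuse_nodes(bundle: ModalityBundle, params: ModelParams) -> Tensor:
    """Concatenate the three projected modalities: N × 3·proj_dim."""
    eps = params.config.layernorm_eps
    blocks = [
        project_modality(bundle.seq_emb, params.fusion["seq"], eps),
        project_modality(bundle.if_emb, params.fusion["if"], eps),
        project_modality(bundle.dssp_feats, params.fusion["dssp"], eps),
    ]
    return concat(blocks, axis=1)


def additive_attention(X: Tensor, params: _AttentionParams):
    """Additive attention: eᵢ = Vᵀ tanh(W xᵢ), a = softmax(e), Z = Σ aᵢxᵢ.

    Returns (a, Z, per_residue_out) where per_residue_out row i is
    [xᵢ | Z] — the global context broadcast to every residue.
    """
    X = X if isinstance(X, Tensor) else Tensor(X)
    n = X.shape[0]
    e = (X @ params.W).tanh() @ params.V          # N × 1
    a = e.reshape(n).softmax_vec()                # N
    Z = a.reshape(1, n) @ X                       # 1 × d
    ones = Tensor(np.ones((n, 1)))
    per_residue = concat([X, ones @ Z], axis=1)   # N × 2d
    return a, Z.reshape(X.shape[1]), per_residue


def multiscale_gcn_layer(H: Tensor, norm_adjs: dict,
                         params: _GcnLayerParams) -> Tensor:
    """One multi-scale graph convolution layer.

    For each scale k: H⁽ᵏ⁾ = ReLU(Âₖ H Wₖ) with Âₖ the symmetric-normalized
    k-hop adjacency (self-loops included); the three scales are concatenated
    and fused by a linear map + ReLU.
    """
    H = H if isinstance(H, Tensor) else Tensor(H)
    outs = []
    for k in (1, 2, 3):
        A = norm_adjs[k]
        if A.shape[0] != H.shape[0]:
            raise ValueError("adjacency/feature size mismatch")
        outs.append((Tensor(A) @ (H @ params.W_k[k])).relu())
    return params.fuse(concat(outs, axis=1)).relu()


def residual_combine(H0: Tensor, H_deep: Tensor, theta: Tensor) -> Tensor:
    """Convex mix λ·H₀ + (1−λ)·H_deep with λ = σ(θ) ∈ (0, 1)."""
    lam = theta.sigmoid()
    return lam * H0 + (1.0 - lam) * H_deep


def graph_norm_adjs(graph: ProteinGraph) -> dict:
    return {k: normalized_adjacency(graph.multi_adj[k]) for k in (1, 2, 3)}


def forward(bundle: ModalityBundle, graph: ProteinGraph,
            params: ModelParams, mode: str = "infer",
            dropout_rng: np.random.Generator | None = None) -> Tensor:
    """Full forward pass → per-residue probabilities in (0, 1), shape (N,)."""
    if bundle.n_residues != graph.n_nodes:
        raise ValueError("bundle and graph disagree on residue count")
    cfg = params.config
    X0 = fuse_nodes(bundle, params)

    _, _, branch_a = additive_attention(X0, params.attention)

    adjs = graph_norm_adjs(graph)
    H1 = multiscale_gcn_layer(X0, adjs, params.gcn1)
    H2 = multiscale_gcn_layer(H1, adjs, params.gcn2)
    H0m = params.residual_proj(X0)
    branch_b = residual_combine(H0m, H2, params.theta)

    h = concat([branch_a, branch_b], axis=1)
    train = mode == "train"
    if train and dropout_rng is None:
        dropout_rng = np.random.default_rng(cfg.seed)
    for i, lin in enumerate(params.mlp):
        h = lin(h)
        if i < len(params.mlp) - 1:
            h = h.relu()
            if train and cfg.dropout > 0:
                keep = 1.0 - cfg.dropout
                mask = dropout_rng.binomial(1, keep, size=h.shape) / keep
                h = h * Tensor(mask)
    return h.reshape(h.shape[0]).sigmoid()


def save_checkpoint(params: ModelParams, path) -> None:
    """Single-file archive: named tensors + JSON config."""
    arrays = {name: t.data for name, t in params.named_parameters()}
    arrays["__config__"] = np.frombuffer(
        json.dumps(dataclasses.asdict(params.config)).encode(), dtype=np.uint8
    )
    np.savez(path, **arrays)


def load_checkpoint(path) -> ModelParams:
    with np.load(path) as archive:
        cfg_raw = json.loads(archive["__config__"].tobytes().decode())
        cfg_raw["mlp_hidden"] = tuple(cfg_raw["mlp_hidden"])
        params = ModelParams(ModelConfig(**cfg_raw))
        for name, t in params.named_parameters():
            t.data = np.array(archive[name], dtype=float)
    return params
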