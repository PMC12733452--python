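"""The four segmentation networks: U-Net, DeepLab variant, GAT, SGNN.

All models consume NHWC unit-interval images and emit a per-pixel tumor
probability map of the same spatial size through a 1x1 sigmoid head.  The
graph models turn a convolutional feature grid into a node graph whose edges
come from cosine similarity between node features — dense for the GAT,
restricted to each node's top-k most similar neighbors for the SGNN — and
refine node embeddings with multi-head attention:

    e_ij = LeakyReLU(a_k^T [W_k h_i || W_k h_j])        (attention logits)
    alpha_ij = softmax_j(e_ij)                          (normalized over N(i))
    h'_i = ||_k sigma( sum_j alpha_ij^k W_k h_j )       (head concatenation)

Self-loops are always included in N(i), the LeakyReLU slope is 0.2 and the
hidden-layer sigma is an ELU (identity before the decoder), all standard GAT
practice.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import _nn as nn
from ._nn import (
    BatchNorm,
    Conv2D,
    ConvBNReLU,
    ConvTranspose2x2,
    Dense,
    Module,
    Tensor,
)

# ---------------------------------------------------------------------------
# Declarative specs
# ---------------------------------------------------------------------------

ARCHITECTURES = ("unet", "deeplab", "gat", "sgnn")


@dataclass
class ModelSpec:
    """Declarative description of a segmentation network."""

    architecture: str = "unet"
    input_size: tuple = (256, 256, 3)
    base_width: int = 64
    depth: int = 4
    aspp_rates: tuple = (6, 12, 18)
    heads: int = 8
    head_dim: int = 8  # F' per attention head
    attention_layers: int = 2
    top_k: int | None = 8  # neighbor budget for the sgnn
    graph_grid: tuple = (16, 16)
    stem_width: int = 32
    seed: int = 0

    def __post_init__(self):
        if self.architecture not in ARCHITECTURES:
            raise ValueError(
                f"unknown architecture {self.architecture!r}; choose from {ARCHITECTURES}"
            )
        if self.heads < 1:
            raise ValueError("heads must be >= 1")


@dataclass
class Graph:
    """Node features plus neighbor structure with cosine-similarity weights.

    `neighbors[i]` lists the retained neighbor indices of node i (self-loop
    included); `weights` carries the matching similarities.
    """

    node_features: np.ndarray  # (N, F)
    neighbors: np.ndarray  # (N, m) int
    weights: np.ndarray  # (N, m) float
    construction: str  # dense_cosine | topk_cosine
    k: int | None = None


@dataclass
class GraphAttentionParams:
    """Per-head linear maps W (K,F',F) and attention vectors a (K,2F')."""

    W: np.ndarray
    a: np.ndarray
    negative_slope: float = 0.2
    activation: str = "elu"  # elu | identity

    @property
    def heads(self) -> int:
        return self.W.shape[0]

    @property
    def out_dim(self) -> int:
        return self.W.shape[1]


# ---------------------------------------------------------------------------
# Graph construction and attention
# ---------------------------------------------------------------------------


def build_graph_from_features(feature_grid: np.ndarray, mode: str = "dense_cosine", k: int | None = None) -> Graph:
    """Build the spatial-location graph from an (h, w, F) feature grid.

    Nodes are grid cells in row-major order; edge weights are cosine
    similarities (zero-norm vectors get similarity 0).  Dense mode keeps all
    pairs; top-k mode keeps, per node, the k most similar other nodes plus
    the self-loop, ties broken by node index.
    """
    h, w, f = feature_grid.shape
    n = h * w
    if n < 2:
        raise ValueError("need at least 2 nodes")
    feats = feature_grid.reshape(n, f).astype(np.float32)
    norms = np.linalg.norm(feats, axis=1)
    if not norms.any():
        raise ValueError("degenerate features: all node feature vectors are zero")
    safe = np.where(norms > 0, norms, 1.0)
    unit = feats / safe[:, None]
    sim = unit @ unit.T
    sim[norms == 0, :] = 0.0
    sim[:, norms == 0] = 0.0
    np.fill_diagonal(sim, 1.0)

    if mode == "dense_cosine":
        neighbors = np.broadcast_to(np.arange(n), (n, n)).copy()
        return Graph(feats, neighbors, sim.copy(), "dense_cosine")
    if mode == "topk_cosine":
        if k is None or not 1 <= k <= n - 1:
            raise ValueError(f"topk_cosine requires 1 <= k <= {n - 1}")
        s = sim.copy()
        np.fill_diagonal(s, -np.inf)  # self handled separately
        # stable top-k: sort by (-similarity, index)
        order = np.lexsort((np.broadcast_to(np.arange(n), (n, n)), -s), axis=1)
        top = np.sort(order[:, :k], axis=1)
        neighbors = np.concatenate([np.arange(n)[:, None], top], axis=1)
        weights = np.take_along_axis(sim, neighbors, axis=1)
        return Graph(feats, neighbors, weights, "topk_cosine", k=k)
    raise ValueError(f"unknown graph construction {mode!r}")


def _attention_forward(h: nn.Tensor, neighbors: np.ndarray, W: nn.Tensor, a: nn.Tensor,
                       negative_slope: float, activation: str) -> nn.Tensor:
    """Differentiable multi-head attention over a fixed neighbor structure.

    h: (N,F) tensor; W: (K,F',F); a: (K,2F').  Returns (N, K*F').
    """
    n_nodes, m = neighbors.shape
    K, fprime, _ = W.shape
    # dense graphs keep every neighbor in index order: pure-matmul fast path
    dense = m == n_nodes and np.array_equal(neighbors[0], np.arange(n_nodes))
    outs = []
    for kh in range(K):
        # W_k h: (N,F) @ (F,F')^T -> (N,F')
        Wk = _slice_head(W, kh)
        ak = _slice_head(a, kh)
        Wh = nn.matmul(h, _transpose(Wk))
        a_src = nn.matmul(Wh, nn.reshape(_slice_vec(ak, 0, fprime), (fprime, 1)))  # (N,1)
        a_dst = nn.matmul(Wh, nn.reshape(_slice_vec(ak, fprime, 2 * fprime), (fprime, 1)))
        if dense:
            e = nn.leaky_relu(
                nn.add(a_src, nn.reshape(a_dst, (1, n_nodes))), negative_slope
            )  # (N,N)
            alpha = nn.softmax(e, axis=1)
            agg = nn.matmul(alpha, Wh)  # (N,F')
        else:
            dst_j = nn.gather_rows(a_dst, neighbors)  # (N,m,1)
            e = nn.leaky_relu(nn.add(nn.reshape(a_src, (n_nodes, 1, 1)), dst_j), negative_slope)
            alpha = nn.softmax(nn.reshape(e, (n_nodes, m)), axis=1)
            Wh_j = nn.gather_rows(Wh, neighbors)  # (N,m,F')
            agg = nn.tsum(nn.mul(nn.reshape(alpha, (n_nodes, m, 1)), Wh_j), axis=1)  # (N,F')
        outs.append(nn.elu(agg) if activation == "elu" else agg)
    return nn.concat(outs, axis=1)


def _slice_head(t: nn.Tensor, k: int) -> nn.Tensor:
    """Differentiable slice t[k] along the leading (head) axis."""
    shape = t.shape

    def backward(g):
        full = np.zeros(shape, dtype=np.float32)
        full[k] = g
        return (full,)

    return nn._result(t.data[k], (t,), backward)


def _slice_vec(t: nn.Tensor, start: int, stop: int) -> nn.Tensor:
    shape = t.shape

    def backward(g):
        full = np.zeros(shape, dtype=np.float32)
        full[start:stop] = g
        return (full,)

    return nn._result(t.data[start:stop], (t,), backward)


def _transpose(t: nn.Tensor) -> nn.Tensor:
    return nn._result(t.data.T.copy(), (t,), lambda g: (g.T.copy(),))


def gat_attention(graph: Graph, params: GraphAttentionParams) -> np.ndarray:
    """Run one multi-head graph-attention layer; returns (N, K*F') features.

    Per head, attention logits are scored by a^T[W h_i || W h_j] through a
    LeakyReLU, softmax-normalized over each node's neighbor set (rows sum to
    one), and used to average the transformed neighbor features.
    """
    if graph.neighbors.shape[1] == 0:
        raise ValueError("node with empty neighbor set: cannot normalize attention")
    h = nn.Tensor(graph.node_features)
    W = nn.Tensor(np.asarray(params.W, dtype=np.float32))
    a = nn.Tensor(np.asarray(params.a, dtype=np.float32))
    out = _attention_forward(h, graph.neighbors, W, a, params.negative_slope, params.activation)
    return out.data


def attention_rowsums(graph: Graph, params: GraphAttentionParams) -> np.ndarray:
    """Per-head attention row sums (should all be 1)."""
    h = graph.node_features
    sums = []
    for kh in range(params.heads):
        Wh = h @ params.W[kh].T
        fprime = params.out_dim
        a_src = Wh @ params.a[kh][:fprime]
        a_dst = Wh @ params.a[kh][fprime:]
        e = a_src[:, None] + a_dst[graph.neighbors]
        e = np.where(e > 0, e, params.negative_slope * e)
        e = e - e.max(axis=1, keepdims=True)
        al = np.exp(e)
        al /= al.sum(axis=1, keepdims=True)
        sums.append(al.sum(axis=1))
    return np.stack(sums)


# ---------------------------------------------------------------------------
# Model graphs
# ---------------------------------------------------------------------------


class ModelGraph(Module):
    """A realized trainable network with the common output contract."""

    spec: ModelSpec

    def predict(self, images: np.ndarray, batch_size: int = 8) -> np.ndarray:
        """Probability maps for a (N,H,W,C) stack, eval mode, no gradients."""
        outs = []
        for i in range(0, len(images), batch_size):
            outs.append(self(nn.Tensor(images[i : i + batch_size]), training=False).data)
        return np.concatenate(outs, axis=0)

    def parameter_shapes(self) -> dict:
        return {name: list(p.shape) for name, p in self.named_parameters()}


def _check_divisible(spec: ModelSpec):
    h, w, _ = spec.input_size
    f = 2**spec.depth
    if h % f or w % f:
        raise ValueError(f"input size {h}x{w} not divisible by 2^depth = {f}")


class UNet(ModelGraph):
    """Symmetric encoder-decoder with skip concatenation.

    Encoder: `depth` stages of two 3x3 conv(+BN+ReLU) then 2x2 max-pool,
    channels doubling from base_width; bottleneck at base_width * 2^depth;
    decoder mirrors with 2x2 transposed convolutions and skip concatenation;
    1x1 sigmoid head.
    """

    def __init__(self, spec: ModelSpec):
        _check_divisible(spec)
        self.spec = spec
        rng = np.random.default_rng(spec.seed)
        cin = spec.input_size[2]
        w = spec.base_width
        self.enc = []
        for d in range(spec.depth):
            cout = w * 2**d
            self.enc.append([ConvBNReLU(cin, cout, rng=rng), ConvBNReLU(cout, cout, rng=rng)])
            cin = cout
        bw = w * 2**spec.depth
        self.bottleneck = [ConvBNReLU(cin, bw, rng=rng), ConvBNReLU(bw, bw, rng=rng)]
        self.ups = []
        self.dec = []
        cin = bw
        for d in reversed(range(spec.depth)):
            cout = w * 2**d
            self.ups.append(ConvTranspose2x2(cin, cout, rng=rng))
            self.dec.append([ConvBNReLU(2 * cout, cout, rng=rng), ConvBNReLU(cout, cout, rng=rng)])
            cin = cout
        self.head = Conv2D(cin, 1, k=1, rng=rng)

    def named_parameters(self, prefix: str = ""):
        yield from _walk_nested(self, prefix)

    def named_buffers(self, prefix: str = ""):
        yield from _walk_buffers(self, prefix)

    def __call__(self, x, training=False):
        skips = []
        for block in self.enc:
            for layer in block:
                x = layer(x, training)
            skips.append(x)
            x = nn.maxpool_2x2(x)
        for layer in self.bottleneck:
            x = layer(x, training)
        for up, block, skip in zip(self.ups, self.dec, reversed(skips)):
            x = up(x, training)
            x = nn.concat([skip, x], axis=-1)
            for layer in block:
                x = layer(x, training)
        return nn.sigmoid(self.head(x, training))


def _walk_nested(module: Module, prefix: str = ""):
    """named_parameters that also descends plain lists of lists of modules."""
    for name, val in vars(module).items():
        path = f"{prefix}{name}"
        yield from _emit_params(val, path)


def _emit_params(val, path):
    if isinstance(val, Tensor):
        if val.requires_grad:
            yield path, val
    elif isinstance(val, Module):
        yield from _walk_nested(val, path + ".")
    elif isinstance(val, (list, tuple)):
        for i, item in enumerate(val):
            yield from _emit_params(item, f"{path}.{i}")


def _walk_buffers(module: Module, prefix: str = ""):
    for name, val in vars(module).items():
        path = f"{prefix}{name}"
        yield from _emit_buffers(val, path)


def _emit_buffers(val, path):
    if isinstance(val, dict) and "mean" in val and "var" in val:
        yield path + ".mean", val, "mean"
        yield path + ".var", val, "var"
    elif isinstance(val, Module):
        yield from _walk_buffers(val, path + ".")
    elif isinstance(val, (list, tuple)):
        for i, item in enumerate(val):
            yield from _emit_buffers(item, f"{path}.{i}")


class _SqueezeExcite(Module):
    """Global channel attention: GAP -> dense bottleneck -> sigmoid gate."""

    def __init__(self, c, ratio=8, rng=None):
        hidden = max(1, c // ratio)
        self.fc1 = Dense(c, hidden, rng)
        self.fc2 = Dense(hidden, c, rng)

    def __call__(self, x, training=False):
        s = nn.global_avg_pool(x)  # (N,C)
        gate = nn.sigmoid(self.fc2(nn.relu(self.fc1(s))))
        n, c = gate.shape
        return nn.mul(x, nn.reshape(gate, (n, 1, 1, c)))


class _ResidualBlock(Module):
    """Two 3x3 conv(+BN+ReLU) with additive skip (1x1 projection if needed)."""

    def __init__(self, cin, cout, rng=None):
        self.c1 = ConvBNReLU(cin, cout, rng=rng)
        self.c2 = Conv2D(cout, cout, rng=rng)
        self.bn2 = BatchNorm(cout)
        self.proj = Conv2D(cin, cout, k=1, rng=rng) if cin != cout else None

    def __call__(self, x, training=False):
        y = self.bn2(self.c2(self.c1(x, training), training), training)
        skip = self.proj(x, training) if self.proj is not None else x
        return nn.relu(nn.add(skip, y))


class DeepLab(ModelGraph):
    """Residual encoder + channel attention + ASPP + transposed-conv decoder.

    Four residual blocks (channels doubling, 2x2 max-pool between), each
    followed by a squeeze-excite channel-attention gate; atrous spatial
    pyramid pooling with one dilated 3x3 branch per rate plus a 1x1 branch
    (256 filters each), concatenated and fused; transposed convolutions back
    to full resolution; 1x1 sigmoid head.
    """

    ASPP_FILTERS = 256

    def __init__(self, spec: ModelSpec):
        _check_divisible(spec)
        if not spec.aspp_rates:
            raise ValueError("aspp_rates must be non-empty")
        self.spec = spec
        rng = np.random.default_rng(spec.seed)
        cin = spec.input_size[2]
        w = spec.base_width
        self.blocks = []
        self.gates = []
        for d in range(4):
            cout = w * 2**d
            self.blocks.append(_ResidualBlock(cin, cout, rng))
            self.gates.append(_SqueezeExcite(cout, rng=rng))
            cin = cout
        filt = min(self.ASPP_FILTERS, 4 * w)
        self.aspp = [ConvBNReLU(cin, filt, k=1, rng=rng)]
        for rate in spec.aspp_rates:
            self.aspp.append(ConvBNReLU(cin, filt, k=3, dilation=rate, rng=rng))
        self.fuse = ConvBNReLU(filt * (len(spec.aspp_rates) + 1), filt, k=1, rng=rng)
        self.ups = []
        c = filt
        for d in reversed(range(4)):
            cout = max(w * 2**d // 2, w // 2)
            self.ups.append(ConvTranspose2x2(c, cout, rng=rng))
            c = cout
        self.head = Conv2D(c, 1, k=1, rng=rng)

    def named_parameters(self, prefix: str = ""):
        yield from _walk_nested(self, prefix)

    def named_buffers(self, prefix: str = ""):
        yield from _walk_buffers(self, prefix)

    def aspp_branch_count(self) -> int:
        return len(self.aspp)

    def __call__(self, x, training=False):
        for block, gate in zip(self.blocks, self.gates):
            x = gate(block(x, training), training)
            x = nn.maxpool_2x2(x)
        x = nn.concat([branch(x, training) for branch in self.aspp], axis=-1)
        x = self.fuse(x, training)
        for up in self.ups:
            x = nn.relu(up(x, training))
        return nn.sigmoid(self.head(x, training))


class _GraphSegmenter(ModelGraph):
    """Shared GAT/SGNN body: conv stem -> graph attention -> deconv decoder.

    The stem downsamples the image to the node grid; a graph is built from
    the stem features per sample (dense cosine edges for the GAT, top-k for
    the SGNN); stacked attention layers refine node embeddings (hidden sigma
    ELU, final layer identity before the decoder); embeddings are reshaped to
    the grid and upsampled by transposed convolutions to the sigmoid head.
    """

    def __init__(self, spec: ModelSpec, sparse: bool):
        self.spec = spec
        self.sparse = sparse
        if sparse and spec.top_k is None:
            raise ValueError("sgnn requires top_k to be set")
        h, w, cin = spec.input_size
        gh, gw = spec.graph_grid
        if h % gh or w % gw or (h // gh) != (w // gw):
            raise ValueError("graph_grid must divide the input size isotropically")
        factor = h // gh
        if factor & (factor - 1):
            raise ValueError("input/graph_grid ratio must be a power of 2")
        self.factor = factor
        rng = np.random.default_rng(spec.seed)
        n_down = factor.bit_length() - 1
        width = spec.heads * spec.head_dim
        self.stem = []
        c = cin
        for i in range(n_down):
            cout = width if i == n_down - 1 else max(spec.stem_width, width // 2)
            self.stem.append(ConvBNReLU(c, cout, rng=rng))
            c = cout
        self.gat_W = []
        self.gat_a = []
        for layer in range(spec.attention_layers):
            fin = c if layer == 0 else width
            Wl = np.stack(
                [
                    nn.glorot_uniform(rng, (spec.head_dim, fin), fin, spec.head_dim)
                    for _ in range(spec.heads)
                ]
            )
            al = np.stack(
                [
                    nn.glorot_uniform(rng, (2 * spec.head_dim,), 2 * spec.head_dim, 1)
                    for _ in range(spec.heads)
                ]
            )
            self.gat_W.append(Tensor(Wl, requires_grad=True))
            self.gat_a.append(Tensor(al, requires_grad=True))
        self.ups = []
        c = width
        for i in range(n_down):
            cout = max(8, c // 2)
            self.ups.append(ConvTranspose2x2(c, cout, rng=rng))
            c = cout
        self.head = Conv2D(c, 1, k=1, rng=rng)

    def named_parameters(self, prefix: str = ""):
        yield from _walk_nested(self, prefix)

    def named_buffers(self, prefix: str = ""):
        yield from _walk_buffers(self, prefix)

    def _neighbors_for(self, feats: np.ndarray) -> np.ndarray:
        gh, gw = self.spec.graph_grid
        grid = feats.reshape(gh, gw, -1)
        mode = "topk_cosine" if self.sparse else "dense_cosine"
        k = self.spec.top_k if self.sparse else None
        try:
            graph = build_graph_from_features(grid, mode, k)
        except ValueError:
            n = gh * gw
            return np.broadcast_to(np.arange(n), (n, n)).copy()
        return graph.neighbors

    def __call__(self, x, training=False):
        for layer in self.stem:
            x = layer(x, training)
            x = nn.maxpool_2x2(x)
        nbatch, gh, gw, c = x.shape
        outs = []
        for b in range(nbatch):
            hb = nn.reshape(_slice_batch(x, b), (gh * gw, c))
            neighbors = self._neighbors_for(hb.data)
            for layer in range(self.spec.attention_layers):
                act = "elu" if layer < self.spec.attention_layers - 1 else "identity"
                hb = _attention_forward(
                    hb, neighbors, self.gat_W[layer], self.gat_a[layer], 0.2, act
                )
            outs.append(nn.reshape(hb, (1, gh, gw, hb.shape[1])))
        x = nn.concat(outs, axis=0) if len(outs) > 1 else outs[0]
        for up in self.ups:
            x = nn.relu(up(x, training))
        return nn.sigmoid(self.head(x, training))


def _slice_batch(t: Tensor, b: int) -> Tensor:
    shape = t.shape

    def backward(g):
        full = np.zeros(shape, dtype=np.float32)
        full[b] = g
        return (full,)

    return nn._result(t.data[b], (t,), backward)


# ---------------------------------------------------------------------------
# Builders and parameter accounting
# ---------------------------------------------------------------------------


def build_unet(spec: ModelSpec) -> ModelGraph:
    if spec.architecture != "unet":
        raise ValueError("spec.architecture must be 'unet'")
    return UNet(spec)


def build_deeplab(spec: ModelSpec) -> ModelGraph:
    if spec.architecture != "deeplab":
        raise ValueError("spec.architecture must be 'deeplab'")
    return DeepLab(spec)


def build_gat_segmenter(spec: ModelSpec) -> ModelGraph:
    return _GraphSegmenter(spec, sparse=False)


def build_sgnn_segmenter(spec: ModelSpec) -> ModelGraph:
    return _GraphSegmenter(spec, sparse=True)


_BUILDERS = {
    "unet": build_unet,
    "deeplab": build_deeplab,
    "gat": build_gat_segmenter,
    "sgnn": build_sgnn_segmenter,
}


def build_model(spec: ModelSpec) -> ModelGraph:
    return _BUILDERS[spec.architecture](spec)


def count_trainable_parameters(model: ModelGraph) -> int:
    """Element count over trainable tensors; BatchNorm scale/shift counted,
    running statistics excluded; frozen (requires_grad=False) tensors skipped."""
    return int(sum(p.data.size for p in model.parameters()))
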