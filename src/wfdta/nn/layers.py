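"""Network layers: dense, 1D convolution, and graph message-passing layers.

Graph layers operate on a batched node-feature tensor plus fixed structural
arrays (sparse adjacency / edge lists / node-to-graph assignment), the
block-diagonal batching convention of graph neural networks.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from scipy import sparse

from . import autodiff as ad
from .autodiff import Tensor


def glorot(rng: np.random.Generator, fan_in: int, fan_out: int, shape=None) -> Tensor:
    """Glorot/Xavier uniform initialization."""
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    shape = shape or (fan_in, fan_out)
    return Tensor(rng.uniform(-limit, limit, size=shape), requires_grad=True)


class Module:
    def parameters(self) -> list[Tensor]:
        params: list[Tensor] = []
        for value in vars(self).values():
            if isinstance(value, Tensor) and value.requires_grad:
                params.append(value)
            elif isinstance(value, Module):
                params.extend(value.parameters())
            elif isinstance(value, (list, tuple)):
                for item in value:
                    if isinstance(item, Tensor) and item.requires_grad:
                        params.append(item)
                    elif isinstance(item, Module):
                        params.extend(item.parameters())
        return params


class Linear(Module):
    def __init__(self, in_dim: int, out_dim: int, rng: np.random.Generator):
        self.weight = glorot(rng, in_dim, out_dim)
        self.bias = Tensor(np.zeros(out_dim), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        return (x @ self.weight) + self.bias


class Conv1d(Module):
    """1-channel 1D convolution over a flat feature vector, flattened output.

    Input is a (batch, length) array; output is a
    (batch, (length - kernel + 1) * filters) tensor — convolution windows
    times filters, ready for a dense layer.
    """

    def __init__(self, kernel: int, filters: int, rng: np.random.Generator):
        self.kernel = kernel
        self.filters = filters
        self.weight = glorot(rng, kernel, filters)
        self.bias = Tensor(np.zeros(filters), requires_grad=True)

    def out_dim(self, length: int) -> int:
        return (length - self.kernel + 1) * self.filters

    def __call__(self, x: np.ndarray) -> Tensor:
        batch, length = x.shape
        t_out = length - self.kernel + 1
        if t_out < 1:
            raise ValueError(f"input length {length} shorter than kernel {self.kernel}")
        windows = sliding_window_view(x, self.kernel, axis=1).reshape(batch * t_out, self.kernel)
        conv = (Tensor(windows) @ self.weight) + self.bias
        return ad.reshape(conv, (batch, t_out * self.filters))


def normalized_adjacency(edge_src: np.ndarray, edge_dst: np.ndarray, num_nodes: int) -> sparse.csr_matrix:
    """Symmetrically normalized adjacency with self-loops, D^-1/2 (A+I) D^-1/2."""
    src = np.concatenate([edge_src, np.arange(num_nodes)])
    dst = np.concatenate([edge_dst, np.arange(num_nodes)])
    a = sparse.coo_matrix((np.ones(src.size), (dst, src)), shape=(num_nodes, num_nodes)).tocsr()
    deg = np.asarray(a.sum(axis=1)).ravel()
    d_inv_sqrt = 1.0 / np.sqrt(np.maximum(deg, 1e-12))
    d = sparse.diags(d_inv_sqrt)
    return (d @ a @ d).tocsr()


def plain_adjacency(edge_src: np.ndarray, edge_dst: np.ndarray, num_nodes: int) -> sparse.csr_matrix:
    return sparse.coo_matrix(
        (np.ones(edge_src.size), (edge_dst, edge_src)), shape=(num_nodes, num_nodes)
    ).tocsr()


class GCNConv(Module):
    """Graph convolution: x' = D^-1/2 (A+I) D^-1/2 x W + b."""

    def __init__(self, in_dim: int, out_dim: int, rng: np.random.Generator):
        self.weight = glorot(rng, in_dim, out_dim)
        self.bias = Tensor(np.zeros(out_dim), requires_grad=True)

    def __call__(self, x: Tensor, adj_norm: sparse.csr_matrix) -> Tensor:
        return ad.spmm(adj_norm, x @ self.weight) + self.bias


class GINConv(Module):
    """Graph isomorphism layer: x' = MLP((1 + eps) x + sum of neighbours)."""

    def __init__(self, in_dim: int, hidden: int, rng: np.random.Generator, eps: float = 0.0):
        self.eps = eps
        self.lin1 = Linear(in_dim, hidden, rng)
        self.lin2 = Linear(hidden, hidden, rng)

    def __call__(self, x: Tensor, adj: sparse.csr_matrix) -> Tensor:
        agg = ad.spmm(adj, x) + (1.0 + self.eps) * x
        return self.lin2(ad.relu(self.lin1(agg)))


class GATConv(Module):
    """Graph attention layer with multi-head additive attention.

    Per head h: scores e_ij = LeakyReLU(a_src . W_h x_i + a_dst . W_h x_j)
    over edges (i -> j) including self-loops, softmax-normalized over each
    target node's incoming edges; head outputs are concatenated.
    """

    def __init__(self, in_dim: int, out_dim: int, heads: int, rng: np.random.Generator):
        self.heads = heads
        self.out_dim = out_dim
        self.weights = [glorot(rng, in_dim, out_dim) for _ in range(heads)]
        self.att_src = [glorot(rng, out_dim, 1, shape=(out_dim, 1)) for _ in range(heads)]
        self.att_dst = [glorot(rng, out_dim, 1, shape=(out_dim, 1)) for _ in range(heads)]
        self.bias = Tensor(np.zeros(heads * out_dim), requires_grad=True)

    def __call__(self, x: Tensor, edge_src: np.ndarray, edge_dst: np.ndarray, num_nodes: int) -> Tensor:
        # self-loops keep isolated atoms (single-heavy-atom drugs) defined
        loops = np.arange(num_nodes)
        src = np.concatenate([edge_src, loops])
        dst = np.concatenate([edge_dst, loops])
        outs = []
        for w, a_s, a_d in zip(self.weights, self.att_src, self.att_dst):
            h = x @ w
            h_src = ad.gather_rows(h, src)
            h_dst = ad.gather_rows(h, dst)
            scores = ad.leaky_relu((h_src @ a_s) + (h_dst @ a_d), slope=0.2)
            alpha = ad.segment_softmax(scores, dst, num_nodes)
            outs.append(ad.segment_sum(alpha * h_src, dst, num_nodes))
        stacked = outs[0] if len(outs) == 1 else ad.concat(outs, axis=1)
        return stacked + self.bias


class Adam:
    """Adam optimizer over a fixed parameter list."""

    def __init__(self, params: list[Tensor], lr: float = 1e-3, betas=(0.9, 0.999), eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in params]
        self.v = [np.zeros_like(p.data) for p in params]
        self._scratch = [np.empty_like(p.data) for p in params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None

    def step(self) -> None:
        self.t += 1
        bc1 = 1 - self.b1**self.t
        bc2 = 1 - self.b2**self.t
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            m, v, s = self.m[i], self.v[i], self._scratch[i]
            # in-place moment updates through a preallocated scratch buffer
            m *= self.b1
            np.multiply(g, 1 - self.b1, out=s)
            m += s
            v *= self.b2
            np.square(g, out=s)
            s *= 1 - self.b2
            v += s
            np.divide(v, bc2, out=s)
            np.sqrt(s, out=s)
            s += self.eps
            s *= bc1 / self.lr
            np.divide(m, s, out=s)
            p.data -= s
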