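"""Graph layer operators: GIN, GAT, ARMA, SGC, and batch normalization.

Each operator is a pure function over a :class:`GraphSignal` (node feature
matrix + directed COO edge list + optional batch assignment) and a parameter
record. Inputs may be plain NumPy arrays or autodiff :class:`Tensor`s; the
output matches the input kind, so the same code path serves both the dense
oracle tests and gradient training.

Update rules:

* GIN:   h'_v = MLP((1 + eps) * h_v + sum_{u in N(v)} h_u)
* GAT:   e_ij = LeakyReLU(a . [W h_i || W h_j]);  a_ij = softmax_j(e_ij);
         h'_i = sigma(sum_j a_ij W h_j)   (self-loops added so N(i) is never empty)
* ARMA:  Xbar(t+1) = sigma(Ltilde Xbar(t) W(t) + X V(t)), mean over K stacks of
         depth T, with Ltilde = D^{-1/2} A D^{-1/2} (the modified Laplacian
         I - L_sym of the graph without self-loops)
* SGC:   S^K X W with S = Dtilde^{-1/2} (A + I) Dtilde^{-1/2}; the task is
         regression so no softmax is applied.
* BN:    per-channel (x - mean) / sqrt(var + eps) * gamma + beta over the
         minibatch of node rows, population variance.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .autodiff import Tensor, scatter_add, sparse_prop, take_rows

__all__ = [
    "GraphSignal", "LinearParams", "GINParams", "GATParams", "ARMAParams",
    "SGCParams", "BatchNormParams", "gin_update", "gat_attention",
    "arma_layer", "sgc_propagate", "batch_norm", "glorot",
]


class ContractError(ValueError):
    """A layer precondition (shape/structure) was violated."""


@dataclass
class GraphSignal:
    """Node features over a (possibly batched) molecular graph."""

    x: Tensor | np.ndarray             # (n, d)
    edge_index: np.ndarray             # (2, E) directed COO
    batch: np.ndarray | None = None    # (n,) graph id per node, non-decreasing

    @property
    def n_nodes(self) -> int:
        return (self.x.data if isinstance(self.x, Tensor) else self.x).shape[0]

    def with_x(self, x) -> "GraphSignal":
        return GraphSignal(x=x, edge_index=self.edge_index, batch=self.batch)


def _as_tensor(x) -> tuple[Tensor, bool]:
    if isinstance(x, Tensor):
        return x, True
    return Tensor(x), False


def _maybe_numpy(out: Tensor, was_tensor: bool):
    return out if was_tensor else out.data


def glorot(rng: np.random.Generator, fan_in: int, fan_out: int) -> Tensor:
    """Glorot/Xavier-uniform initialized trainable weight matrix."""
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return Tensor(rng.uniform(-limit, limit, size=(fan_in, fan_out)),
                  requires_grad=True)


@dataclass
class LinearParams:
    W: Tensor
    b: Tensor | None = None

    def apply(self, x: Tensor) -> Tensor:
        out = x @ self.W
        if self.b is not None:
            out = out + self.b
        return out

    @staticmethod
    def init(rng, d_in, d_out, bias=True) -> "LinearParams":
        b = Tensor(np.zeros(d_out), requires_grad=True) if bias else None
        return LinearParams(W=glorot(rng, d_in, d_out), b=b)


@dataclass
class GINParams:
    """eps plus a two-affine-layer MLP (ReLU between, hidden = output width)."""

    eps: Tensor
    mlp: list[LinearParams]
    activation: str = "relu"  # between MLP affine layers

    @staticmethod
    def init(rng, d_in, d_out) -> "GINParams":
        return GINParams(
            eps=Tensor(0.0, requires_grad=True),
            mlp=[LinearParams.init(rng, d_in, d_out),
                 LinearParams.init(rng, d_out, d_out)],
        )

    def tensors(self) -> list[Tensor]:
        out = [self.eps]
        for lin in self.mlp:
            out.append(lin.W)
            if lin.b is not None:
                out.append(lin.b)
        return out


@dataclass
class GATParams:
    """Shared linear map W and attention vector a = [a_src || a_dst]."""

    W: Tensor
    a_src: Tensor                      # (d_out,) scores the source/neighbor j
    a_dst: Tensor                      # (d_out,) scores the target i
    negative_slope: float = 0.2
    activation: str = "relu"           # sigma in the output rule
    add_self_loops: bool = True

    @staticmethod
    def init(rng, d_in, d_out) -> "GATParams":
        limit = np.sqrt(6.0 / (d_out + 1))
        return GATParams(
            W=glorot(rng, d_in, d_out),
            a_src=Tensor(rng.uniform(-limit, limit, d_out), requires_grad=True),
            a_dst=Tensor(rng.uniform(-limit, limit, d_out), requires_grad=True),
        )

    def tensors(self) -> list[Tensor]:
        return [self.W, self.a_src, self.a_dst]


@dataclass
class ARMAParams:
    """K parallel stacks of T graph-convolutional-skip layers."""

    stacks: list[list[tuple[LinearParams, LinearParams]]]  # [K][T] of (W, V)
    activation: str = "relu"

    @property
    def K(self) -> int:
        return len(self.stacks)

    @property
    def T(self) -> int:
        return len(self.stacks[0]) if self.stacks else 0

    @staticmethod
    def init(rng, d_in, d_out, K=1, T=1) -> "ARMAParams":
        stacks = []
        for _ in range(K):
            stack = []
            for t in range(T):
                w_in = d_in if t == 0 else d_out
                stack.append((LinearParams.init(rng, w_in, d_out, bias=False),
                              LinearParams.init(rng, d_in, d_out, bias=False)))
            stacks.append(stack)
        return ARMAParams(stacks=stacks)

    def tensors(self) -> list[Tensor]:
        out = []
        for stack in self.stacks:
            for w, v in stack:
                out.extend(t for t in (w.W, w.b, v.W, v.b) if t is not None)
        return out


@dataclass
class SGCParams:
    W: Tensor
    K: int = 2

    @staticmethod
    def init(rng, d_in, d_out, K=2) -> "SGCParams":
        return SGCParams(W=glorot(rng, d_in, d_out), K=K)

    def tensors(self) -> list[Tensor]:
        return [self.W]


@dataclass
class BatchNormParams:
    gamma: Tensor
    beta: Tensor
    eps: float = 1e-5
    momentum: float = 0.1
    running_mean: np.ndarray = None
    running_var: np.ndarray = None

    @staticmethod
    def init(width: int) -> "BatchNormParams":
        return BatchNormParams(
            gamma=Tensor(np.ones(width), requires_grad=True),
            beta=Tensor(np.zeros(width), requires_grad=True),
            running_mean=np.zeros(width),
            running_var=np.ones(width),
        )

    def tensors(self) -> list[Tensor]:
        return [self.gamma, self.beta]


def _activate(x: Tensor, name: str) -> Tensor:
    if name == "relu":
        return x.relu()
    if name == "identity":
        return x
    if name == "leaky_relu":
        return x.leaky_relu()
    raise ValueError(f"unknown activation {name!r}")


# -- GIN ----------------------------------------------------------------------

def gin_update(signal: GraphSignal, params: GINParams) -> GraphSignal:
    """One graph-isomorphism-network update; isolated nodes aggregate zero."""
    x, was_tensor = _as_tensor(signal.x)
    n = x.data.shape[0]
    if params.mlp and params.mlp[0].W.data.shape[0] != x.data.shape[1]:
        raise ContractError(
            f"MLP input width {params.mlp[0].W.data.shape[0]} != feature width "
            f"{x.data.shape[1]}")
    src, dst = signal.edge_index
    neighbor_sum = scatter_add(take_rows(x, src), dst, n)
    h = x * (1.0 + params.eps) + neighbor_sum
    for i, lin in enumerate(params.mlp):
        h = lin.apply(h)
        if i < len(params.mlp) - 1:
            h = _activate(h, params.activation)
    return signal.with_x(_maybe_numpy(h, was_tensor))


# -- GAT ----------------------------------------------------------------------

def gat_attention(signal: GraphSignal, params: GATParams):
    """Attention coefficients per directed edge plus the updated signal.

    Returns ``(alpha, edge_index_used, signal')`` where ``alpha[e]`` is the
    normalized attention for edge ``e`` of ``edge_index_used`` (self-loops
    appended when ``params.add_self_loops``); for every target node the
    coefficients over its neighborhood sum to 1.
    """
    x, was_tensor = _as_tensor(signal.x)
    n = x.data.shape[0]
    edge_index = signal.edge_index
    if params.add_self_loops:
        loops = np.arange(n, dtype=np.int64)
        edge_index = np.concatenate([edge_index, np.stack([loops, loops])], axis=1)
    src, dst = edge_index
    if n > 0 and len(np.unique(dst)) < n:
        raise ContractError("GAT requires a non-empty neighborhood for every node; "
                            "enable add_self_loops")

    wh = x @ params.W
    # e_ij = LeakyReLU(a . [W h_i || W h_j]) for target i = dst, neighbor j = src
    score_dst = (wh * params.a_dst.reshape(1, -1)).sum(axis=1, keepdims=True)
    score_src = (wh * params.a_src.reshape(1, -1)).sum(axis=1, keepdims=True)
    e = (take_rows(score_dst, dst) + take_rows(score_src, src)).leaky_relu(
        params.negative_slope)
    # softmax over each target's neighborhood (max-shifted for stability;
    # the shift is constant per segment so it does not enter the gradient)
    shift = np.full(n, -np.inf)
    np.maximum.at(shift, dst, e.data[:, 0])
    e_exp = (e - shift[dst].reshape(-1, 1)).exp()
    denom = scatter_add(e_exp, dst, n)
    alpha = e_exp / take_rows(denom, dst)

    messages = alpha * take_rows(wh, src)
    out = _activate(scatter_add(messages, dst, n), params.activation)
    alpha_out = alpha.reshape(-1) if was_tensor else alpha.data.reshape(-1)
    return alpha_out, edge_index, signal.with_x(_maybe_numpy(out, was_tensor))


# -- spectral operators -------------------------------------------------------

def _symnorm_edge_weights(edge_index: np.ndarray, n: int,
                          add_self_loops: bool) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Edge weights 1/sqrt(d_u d_v) of the symmetric-normalized operator."""
    if add_self_loops:
        loops = np.arange(n, dtype=np.int64)
        edge_index = np.concatenate([edge_index, np.stack([loops, loops])], axis=1)
    src, dst = edge_index
    deg = np.bincount(dst, minlength=n).astype(np.float64)
    inv_sqrt = np.zeros(n)
    nz = deg > 0
    inv_sqrt[nz] = deg[nz] ** -0.5
    return src, dst, inv_sqrt[src] * inv_sqrt[dst]


def arma_layer(signal: GraphSignal, params: ARMAParams) -> GraphSignal:
    """ARMA graph convolution: mean over K stacks of T GCS updates."""
    if params.K < 1 or params.T < 1:
        raise ContractError("ARMA requires K >= 1 and T >= 1")
    x, was_tensor = _as_tensor(signal.x)
    n = x.data.shape[0]
    src, dst, w = _symnorm_edge_weights(signal.edge_index, n, add_self_loops=False)

    outputs = []
    for stack in params.stacks:
        xbar = x
        for w_lin, v_lin in stack:
            propagated = sparse_prop(xbar @ w_lin.W, src, dst, w, n)
            if w_lin.b is not None:
                propagated = propagated + w_lin.b
            xbar = _activate(propagated + v_lin.apply(x), params.activation)
        outputs.append(xbar)
    out = outputs[0]
    for extra in outputs[1:]:
        out = out + extra
    out = out * (1.0 / len(outputs))
    return signal.with_x(_maybe_numpy(out, was_tensor))


def sgc_propagate(signal: GraphSignal, params: SGCParams,
                  K: int | None = None) -> GraphSignal:
    """Simple graph convolution: S^K X W with self-looped normalized adjacency."""
    depth = params.K if K is None else K
    if depth < 0:
        raise ContractError("SGC depth K must be >= 0")
    x, was_tensor = _as_tensor(signal.x)
    n = x.data.shape[0]
    src, dst, w = _symnorm_edge_weights(signal.edge_index, n, add_self_loops=True)
    h = x
    for _ in range(depth):
        h = sparse_prop(h, src, dst, w, n)
    out = h @ params.W
    return signal.with_x(_maybe_numpy(out, was_tensor))


def normalized_adjacency(edge_index: np.ndarray, n: int) -> np.ndarray:
    """Dense S = Dtilde^{-1/2} (A + I) Dtilde^{-1/2} (diagnostic helper)."""
    a_tilde = np.eye(n)
    for u, v in edge_index.T:
        a_tilde[u, v] = 1.0
    deg = a_tilde.sum(axis=1)
    inv_sqrt = np.diag(deg ** -0.5)
    return inv_sqrt @ a_tilde @ inv_sqrt


# -- batch normalization ------------------------------------------------------

def batch_norm(values, gamma, beta, eps: float = 1e-5):
    """Normalize a minibatch per channel, then scale by gamma and shift by beta.

    Uses the population (1/m) variance of the minibatch. ``values`` may be a
    1-D minibatch or an (m, d) matrix of per-node activations.
    """
    x, was_tensor = _as_tensor(values)
    gamma, _ = _as_tensor(gamma)
    beta, _ = _as_tensor(beta)
    mu = x.mean(axis=0, keepdims=True)
    centered = x - mu
    var = (centered * centered).mean(axis=0, keepdims=True)
    x_hat = centered * (var + eps) ** -0.5
    out = x_hat * gamma + beta
    return _maybe_numpy(out, was_tensor)


def batch_norm_inference(values, params: BatchNormParams):
    """Batch norm using stored running statistics (evaluation mode)."""
    x, was_tensor = _as_tensor(values)
    x_hat = (x - params.running_mean.reshape(1, -1)) * \
        (params.running_var.reshape(1, -1) + params.eps) ** -0.5
    out = x_hat * params.gamma + params.beta
    return _maybe_numpy(out, was_tensor)


def batch_norm_train(values, params: BatchNormParams):
    """Batch norm with minibatch statistics; updates running statistics."""
    x, was_tensor = _as_tensor(values)
    mu = x.data.mean(axis=0)
    var = x.data.var(axis=0)
    m = params.momentum
    params.running_mean = (1 - m) * params.running_mean + m * mu
    params.running_var = (1 - m) * params.running_var + m * var
    out = batch_norm(x, params.gamma, params.beta, eps=params.eps)
    return _maybe_numpy(out, was_tensor)
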