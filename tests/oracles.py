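"""Dense brute-force reference implementations of the layer update rules.

These recompute each operator with straightforward dense matrix loops so the
sparse scatter-based implementations can be checked against independent
arithmetic. They share only the parameter arrays, never the code paths.
"""

import numpy as np


def _leaky_relu(x, slope=0.2):
    return np.where(x > 0, x, slope * x)


def _relu(x):
    return np.maximum(x, 0.0)


def dense_gin(h: np.ndarray, adj: np.ndarray, eps: float,
              mlp_weights: list[tuple[np.ndarray, np.ndarray]]) -> np.ndarray:
    """MLP((1 + eps) H + A H) with ReLU between the MLP affine layers."""
    out = (1.0 + eps) * h + adj @ h
    for i, (w, b) in enumerate(mlp_weights):
        out = out @ w + b
        if i < len(mlp_weights) - 1:
            out = _relu(out)
    return out


def dense_gat(h: np.ndarray, adj: np.ndarray, w: np.ndarray,
              a_src: np.ndarray, a_dst: np.ndarray,
              slope: float = 0.2) -> tuple[np.ndarray, np.ndarray]:
    """Per-pair attention matrix and updated features, self-loops included."""
    n = h.shape[0]
    adj = adj + np.eye(n)
    wh = h @ w
    alpha = np.zeros((n, n))
    for i in range(n):
        neighbors = np.flatnonzero(adj[i])
        scores = np.array([_leaky_relu(wh[i] @ a_dst + wh[j] @ a_src, slope)
                           for j in neighbors])
        weights = np.exp(scores - scores.max())
        alpha[i, neighbors] = weights / weights.sum()
    return alpha, _relu(alpha @ wh)


def dense_modified_laplacian(adj: np.ndarray) -> np.ndarray:
    """Ltilde = I - L_sym = D^{-1/2} A D^{-1/2} (zero rows for isolates)."""
    deg = adj.sum(axis=1)
    inv_sqrt = np.zeros_like(deg)
    inv_sqrt[deg > 0] = deg[deg > 0] ** -0.5
    return np.diag(inv_sqrt) @ adj @ np.diag(inv_sqrt)


def dense_arma(h: np.ndarray, adj: np.ndarray,
               stacks: list[list[tuple[np.ndarray, np.ndarray]]],
               activation=_relu) -> np.ndarray:
    """Mean over K stacks of T updates Xbar <- sigma(Lt Xbar W + X V)."""
    laplacian = dense_modified_laplacian(adj)
    outputs = []
    for stack in stacks:
        xbar = h
        for w, v in stack:
            xbar = activation(laplacian @ xbar @ w + h @ v)
        outputs.append(xbar)
    return np.mean(outputs, axis=0)


def dense_sgc_operator(adj: np.ndarray) -> np.ndarray:
    """S = Dt^{-1/2} (A + I) Dt^{-1/2}."""
    a_tilde = adj + np.eye(adj.shape[0])
    inv_sqrt = np.diag(a_tilde.sum(axis=1) ** -0.5)
    return inv_sqrt @ a_tilde @ inv_sqrt

def dense_sgc(h: np.ndarray, adj: np.ndarray, w: np.ndarray,
              k: int) -> np.ndarray:
    return np.linalg.matrix_power(dense_sgc_operator(adj), k) @ h @ w
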