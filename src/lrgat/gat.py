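"""GATv2 attention layers and link-scorer training, implemented in numpy.

The scorer is a small graph attention network in the GATv2 form: the
un-normalised attention score between a node *m* and a neighbour *n* is

    l(h_m, h_n) = b^T LeakyReLU(O [h_m || h_n])

(the nonlinearity sits inside and the attention vector outside, so the
attention is a genuine function of both endpoints), normalised with a
max-stabilised softmax over the in-neighbourhood and used to aggregate
transformed neighbour features, sigma(sum_n alpha_mn O h_n).

Training minimises binary cross-entropy (the Bernoulli negative
log-likelihood) on edge scores sigma(<emb_l, emb_r>), with curated
ligand-receptor pairs as the positive class and shuffled pairings as the
negative class.  Gradients are derived analytically and checked against
numerical differentiation in the test suite.  A final forward pass yields
two-dimensional embeddings for every node.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np

__all__ = [
    "GATConfig",
    "GATv2Layer",
    "GATv2Network",
    "gat_score",
    "gat_attention",
    "gat_aggregate",
    "train_link_scorer",
    "TrainResult",
]


def _leaky_relu(x: np.ndarray, slope: float) -> np.ndarray:
    return np.where(x >= 0, x, slope * x)


def _leaky_relu_grad(x: np.ndarray, slope: float) -> np.ndarray:
    return np.where(x >= 0, 1.0, slope)


def _elu(x: np.ndarray) -> np.ndarray:
    return np.where(x > 0, x, np.expm1(np.minimum(x, 0.0)))


def _elu_grad(x: np.ndarray) -> np.ndarray:
    return np.where(x > 0, 1.0, np.exp(np.minimum(x, 0.0)))


def _sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x, dtype=float)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def gat_score(
    h_m: np.ndarray, h_n: np.ndarray, O: np.ndarray, b: np.ndarray,
    slope: float = 0.2,
) -> float:
    """Un-normalised GATv2 attention score for one (node, neighbour) pair."""
    h_m, h_n = np.asarray(h_m, float), np.asarray(h_n, float)
    if O.shape[1] != h_m.size or O.shape[1] != h_n.size:
        raise ValueError(
            f"O maps dim {O.shape[1]} but got features of dim "
            f"{h_m.size} and {h_n.size}"
        )
    if b.size != 2 * O.shape[0]:
        raise ValueError(f"b has {b.size} entries, expected {2 * O.shape[0]}")
    u = np.concatenate([O @ h_m, O @ h_n])
    return float(b @ _leaky_relu(u, slope))


def gat_attention(scores: np.ndarray) -> np.ndarray:
    """Max-stabilised softmax over one neighbourhood's raw scores."""
    scores = np.asarray(scores, float)
    if scores.size == 0:
        raise ValueError("empty neighbourhood")
    e = np.exp(scores - scores.max())
    return e / e.sum()


def gat_aggregate(
    alpha: np.ndarray,
    neighbor_features: np.ndarray,
    O: np.ndarray,
    activation: Callable[[np.ndarray], np.ndarray] = _elu,
) -> np.ndarray:
    """Attention-weighted aggregation sigma(sum_n alpha_n O h_n)."""
    z = (np.asarray(alpha, float)[:, None] * (neighbor_features @ O.T)).sum(axis=0)
    return activation(z)


@dataclass
class GATConfig:
    feature_dim: int = 8      # d: input feature dimension after SVD reduction
    hidden_dim: int = 16      # d' of the hidden layer
    out_dim: int = 2          # final embedding dimension
    n_layers: int = 2
    leaky_slope: float = 0.2
    residual: bool = True
    input_skip: bool = True
    learning_rate: float = 0.01
    epochs: int = 200
    seed: int = 0

    def layer_dims(self) -> list[tuple[int, int]]:
        dims = [self.feature_dim] + [self.hidden_dim] * (self.n_layers - 1) + [self.out_dim]
        return list(zip(dims[:-1], dims[1:]))


class GATv2Layer:
    """One single-head GATv2 layer with analytic backprop.

    Parameters ``O`` (d' x d) and ``b`` (2d') follow the attention form in
    the module docstring.  ``edges`` are (dst, src) index arrays: node
    ``dst`` attends over its in-neighbours ``src`` (self-loops are added
    by the network so no neighbourhood is empty).
    """

    def __init__(self, d_in: int, d_out: int, slope: float, rng: np.random.Generator,
                 out_scale: float = 1.0, final: bool = False, residual: bool = True):
        limit = np.sqrt(6.0 / (d_in + d_out))
        self.O = rng.uniform(-limit, limit, size=(d_out, d_in)) * out_scale
        self.b = np.zeros(2 * d_out)
        # residual projection: out += R h_in. Because the same R applies to
        # every node, the inner-product decoder picks up a positive
        # semi-definite term h_m^T R^T R h_n, so nodes with aligned input
        # features score together regardless of where training pushed the
        # attention pathway.
        self.R: np.ndarray | None = (
            rng.uniform(-limit, limit, size=(d_out, d_in)) * out_scale
            if residual else None
        )
        self.slope = slope
        self.final = final  # identity activation on the last layer
        self._cache: dict | None = None

    def forward(self, H: np.ndarray, dst: np.ndarray, src: np.ndarray) -> np.ndarray:
        N = H.shape[0]
        S = H @ self.O.T  # N x d'
        u = np.concatenate([S[dst], S[src]], axis=1)  # E x 2d'
        g = _leaky_relu(u, self.slope)
        e = g @ self.b
        emax = np.full(N, -np.inf)
        np.maximum.at(emax, dst, e)
        ex = np.exp(e - emax[dst])
        denom = np.zeros(N)
        np.add.at(denom, dst, ex)
        alpha = ex / denom[dst]
        Z = np.zeros_like(S)
        np.add.at(Z, dst, alpha[:, None] * S[src])
        if self.R is not None:
            Z = Z + H @ self.R.T
        out = Z if self.final else _elu(Z)
        self._cache = dict(H=H, S=S, u=u, g=g, alpha=alpha, Z=Z, dst=dst, src=src)
        return out

    def attention_weights(self) -> tuple[np.ndarray, np.ndarray]:
        """(dst indices, alpha) from the most recent forward pass."""
        if self._cache is None:
            raise RuntimeError("no forward pass cached")
        return self._cache["dst"], self._cache["alpha"]

    def backward(
        self, dOut: np.ndarray
    ) -> tuple[np.ndarray, list[np.ndarray]]:
        c = self._cache
        if c is None:
            raise RuntimeError("forward must run before backward")
        H, S, u, g, alpha, Z = c["H"], c["S"], c["u"], c["g"], c["alpha"], c["Z"]
        dst, src = c["dst"], c["src"]
        N, d_out = S.shape
        dZ = dOut if self.final else dOut * _elu_grad(Z)
        # aggregation: Z[m] = sum_k alpha_k S[src_k]
        dalpha = np.einsum("ed,ed->e", dZ[dst], S[src])
        dS = np.zeros_like(S)
        np.add.at(dS, src, alpha[:, None] * dZ[dst])
        # softmax over each dst segment
        t = np.zeros(N)
        np.add.at(t, dst, alpha * dalpha)
        de = alpha * (dalpha - t[dst])
        # attention score e = b . leaky_relu(u)
        db = g.T @ de
        du = (de[:, None] * self.b) * _leaky_relu_grad(u, self.slope)
        np.add.at(dS, dst, du[:, :d_out])
        np.add.at(dS, src, du[:, d_out:])
        dO = dS.T @ H
        dH = dS @ self.O
        grads = [dO, db]
        if self.R is not None:
            grads.append(dZ.T @ H)
            dH = dH + dZ @ self.R
        return dH, grads


class GATv2Network:
    """Stack of GATv2 layers (ELU between layers, identity output).

    The final layer's weight initialisation is scaled down so initial
    embeddings -- and hence initial edge scores -- start near zero.

    ``input_skip`` adds a learned projection of the raw input features to
    the final embedding (``emb = GAT(H) + P H``).  Because the same
    projection applies to every node, the inner-product decoder acquires
    the positive semi-definite term ``h_m^T P^T P h_n``: nodes whose
    input features point the same way score together by construction,
    which lets feature similarity generalise to node pairs the
    supervision never saw.
    """

    def __init__(self, config: GATConfig):
        self.config = config
        rng = np.random.default_rng(config.seed)
        dims = config.layer_dims()
        self.layers = [
            GATv2Layer(
                d_in, d_out, config.leaky_slope, rng,
                out_scale=0.1 if i == len(dims) - 1 else 1.0,
                final=i == len(dims) - 1,
                residual=config.residual,
            )
            for i, (d_in, d_out) in enumerate(dims)
        ]
        if config.input_skip:
            limit = np.sqrt(6.0 / (config.feature_dim + config.out_dim))
            self.P = 0.1 * rng.uniform(
                -limit, limit, size=(config.out_dim, config.feature_dim)
            )
        else:
            self.P = None
        self._H0: np.ndarray | None = None

    @staticmethod
    def with_self_loops(
        n_nodes: int, edges: Sequence[tuple[int, int]]
    ) -> tuple[np.ndarray, np.ndarray]:
        """(dst, src) arrays for directed edges src->dst plus self-loops."""
        dst = np.array([j for _, j in edges] + list(range(n_nodes)), dtype=int)
        src = np.array([i for i, _ in edges] + list(range(n_nodes)), dtype=int)
        return dst, src

    def forward(self, H: np.ndarray, dst: np.ndarray, src: np.ndarray) -> np.ndarray:
        self._H0 = H
        out = H
        for layer in self.layers:
            out = layer.forward(out, dst, src)
        if self.P is not None:
            out = out + H @ self.P.T
        return out

    def backward(self, dEmb: np.ndarray) -> list[list[np.ndarray]]:
        grads: list[list[np.ndarray]] = []
        d = dEmb
        for layer in reversed(self.layers):
            d, layer_grads = layer.backward(d)
            grads.append(layer_grads)
        grads = list(reversed(grads))
        if self.P is not None:
            if self._H0 is None:
                raise RuntimeError("forward must run before backward")
            grads.append([dEmb.T @ self._H0])
        return grads

    def parameters(self) -> list[np.ndarray]:
        out: list[np.ndarray] = []
        for layer in self.layers:
            out.extend([layer.O, layer.b])
            if layer.R is not None:
                out.append(layer.R)
        if self.P is not None:
            out.append(self.P)
        return out


@dataclass
class TrainResult:
    embeddings: np.ndarray  # nodes x out_dim
    loss_history: np.ndarray
    network: GATv2Network


def _bce_loss_and_grad(
    emb: np.ndarray, pairs: np.ndarray, labels: np.ndarray
) -> tuple[float, np.ndarray]:
    i, j = pairs[:, 0], pairs[:, 1]
    s = np.einsum("kd,kd->k", emb[i], emb[j])
    p = _sigmoid(s)
    eps = 1e-12
    loss = -np.mean(labels * np.log(p + eps) + (1 - labels) * np.log(1 - p + eps))
    ds = (p - labels) / len(labels)
    dEmb = np.zeros_like(emb)
    np.add.at(dEmb, i, ds[:, None] * emb[j])
    np.add.at(dEmb, j, ds[:, None] * emb[i])
    return float(loss), dEmb


def train_link_scorer(
    node_features: np.ndarray,
    edges: Sequence[tuple[int, int]],
    positive_pairs: Sequence[tuple[int, int]],
    negative_pairs: Sequence[tuple[int, int]],
    config: GATConfig | None = None,
) -> TrainResult:
    """Train the GATv2 link scorer and return final node embeddings.

    ``edges`` are directed (src, dst) message-passing edges over the
    inference graph; ``positive_pairs``/``negative_pairs`` are node-index
    pairs supervising the inner-product edge score.  Optimisation is Adam
    on the analytic gradients; the loss history is returned so callers can
    verify training actually reduced the objective.
    """
    config = config or GATConfig()
    if len(positive_pairs) == 0:
        raise ValueError("at least one positive pair is required")
    if node_features.shape[1] != config.feature_dim:
        raise ValueError(
            f"features have dim {node_features.shape[1]}, "
            f"config expects {config.feature_dim}"
        )
    n = node_features.shape[0]
    dst, src = GATv2Network.with_self_loops(n, edges)
    pairs = np.array(list(positive_pairs) + list(negative_pairs), dtype=int)
    labels = np.array([1.0] * len(positive_pairs) + [0.0] * len(negative_pairs))

    net = GATv2Network(config)
    params = net.parameters()
    m_t = [np.zeros_like(p) for p in params]
    v_t = [np.zeros_like(p) for p in params]
    beta1, beta2, eps = 0.9, 0.999, 1e-8
    losses = np.empty(config.epochs + 1)
    for epoch in range(config.epochs + 1):
        emb = net.forward(node_features, dst, src)
        loss, dEmb = _bce_loss_and_grad(emb, pairs, labels)
        if not np.isfinite(loss):
            raise FloatingPointError(
                f"non-finite training loss at epoch {epoch}: {loss}"
            )
        losses[epoch] = loss
        if epoch == config.epochs or config.learning_rate == 0.0:
            if config.learning_rate == 0.0:
                losses[epoch:] = loss
                break
            continue
        grads = net.backward(dEmb)
        flat = [g for layer_grads in grads for g in layer_grads]
        t = epoch + 1
        for k, (p, g) in enumerate(zip(params, flat)):
            m_t[k] = beta1 * m_t[k] + (1 - beta1) * g
            v_t[k] = beta2 * v_t[k] + (1 - beta2) * g * g
            mhat = m_t[k] / (1 - beta1**t)
            vhat = v_t[k] / (1 - beta2**t)
            p -= config.learning_rate * mhat / (np.sqrt(vhat) + eps)
    emb = net.forward(node_features, dst, src)
    return TrainResult(embeddings=emb, loss_history=losses, network=net)
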