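"""Unsupervised GraphSAGE node embedding, implemented from scratch in numpy.

The model is the inductive sample-and-aggregate scheme: for each layer k,
a node v aggregates the representations of a fixed-size sample of its
neighbors N(v),

    h_N(v)^k = f^k({h_u^{k-1} : u in N(v)})                 (aggregate)
    h_v^k    = sigma(W^k . [h_v^{k-1} || h_N(v)^k])          (transform)
    h_v^k    = h_v^k / ||h_v^k||_2                           (normalize)

with f either the elementwise mean or a max-pooling aggregator
max(sigma(W_pool h_u)), and sigma = ReLU inside layers. The final-layer
output z_v = h_v^K is the node embedding.

Training is unsupervised: positive (target, context) pairs are co-visits
on uniform random walks, and the objective is the negative-sampling loss

    J(z_u) = -log s(z_u . z_v) - sum_{q=1..Q} log s(-z_u . z_{v_q})

with s the logistic sigmoid and v_q drawn uniformly over all nodes
(redrawn if equal to u or v). Minibatch gradients (batch_size pairs per
step) are applied with Adam; dropout acts on the input of each W^k during
training only. Neighborhoods are resampled every step; at inference the
full neighborhood is used, so embeddings are deterministic given weights.

Gradients are hand-derived and checked against finite differences in the
test suite; no autodiff framework is involved.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .connectivity import BrainGraph

__all__ = [
    "SageConfig",
    "LayerParams",
    "NodeEmbeddings",
    "WalkPairSet",
    "sample_neighbors",
    "aggregate_mean",
    "aggregate_pool",
    "forward_layer",
    "generate_walk_pairs",
    "unsupervised_loss",
    "train_embeddings",
    "write_embeddings",
    "read_embeddings",
]

logger = logging.getLogger(__name__)

_ADAM_B1, _ADAM_B2, _ADAM_EPS = 0.9, 0.999, 1e-8


@dataclass(frozen=True)
class SageConfig:
    """Hyperparameters of the two-layer unsupervised GraphSAGE run.

    Defaults: hidden layers 200/100 neurons, neighbor fan-outs 50 (1-hop)
    and 10 (2-hop), 10 walks of length 5 per node, batch size 10, learning
    rate 0.01, 100 epochs, dropout 0.15, Q = 5 negatives per positive pair.
    """

    layer_sizes: tuple[int, ...] = (200, 100)
    fanouts: tuple[int, ...] = (50, 10)
    walks_per_node: int = 10
    walk_length: int = 5
    batch_size: int = 10
    learning_rate: float = 0.01
    epochs: int = 100
    dropout: float = 0.15
    negatives_q: int = 5
    aggregator: str = "mean"
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.layer_sizes) != len(self.fanouts):
            raise ValueError("layer_sizes and fanouts must have equal length")
        if len(self.layer_sizes) < 1:
            raise ValueError("need at least one layer")
        if not (0.0 <= self.dropout < 1.0):
            raise ValueError(f"dropout must lie in [0, 1), got {self.dropout}")
        for name in ("walks_per_node", "walk_length", "batch_size", "epochs", "negatives_q"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if any(s < 1 for s in self.layer_sizes) or any(f < 1 for f in self.fanouts):
            raise ValueError("layer sizes and fanouts must be >= 1")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if self.aggregator not in ("mean", "pool"):
            raise ValueError(f"aggregator must be 'mean' or 'pool', got {self.aggregator!r}")

    @property
    def n_layers(self) -> int:
        return len(self.layer_sizes)


def _relu(x: np.ndarray) -> np.ndarray:
    return np.maximum(x, 0.0)


@dataclass
class LayerParams:
    """Weights of one sample-and-aggregate layer.

    ``W`` maps the concatenated (self || neighborhood) vector, of dimension
    2 x d_in, to the layer's output dimension. ``pool_W`` (d_in x d_in) is
    the pre-pooling transform of the max-pool aggregator; unused for mean.
    """

    W: np.ndarray
    pool_W: np.ndarray | None = None
    sigma: Callable[[np.ndarray], np.ndarray] = _relu

    def __post_init__(self) -> None:
        if self.W.ndim != 2 or self.W.shape[1] % 2 != 0:
            raise ValueError("W must be 2-D with an even input dimension (self || neigh)")


@dataclass
class NodeEmbeddings:
    """Final-layer embeddings z_v, one unit-norm row per ROI."""

    z: np.ndarray
    roi_ids: list[str]
    epoch_losses: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.z.ndim != 2 or self.z.shape[0] != len(self.roi_ids):
            raise ValueError("embedding matrix rows must match roi_ids")


@dataclass
class WalkPairSet:
    """Skip-gram style (target, context) pairs from uniform random walks."""

    pairs: np.ndarray  # (n_pairs, 2) int array, columns (u, v), u != v
    n_nodes: int  # negative distribution P_n is uniform over range(n_nodes)

    def __post_init__(self) -> None:
        if self.pairs.ndim != 2 or self.pairs.shape[1] != 2:
            raise ValueError("pairs must be an (n, 2) array")
        if np.any(self.pairs[:, 0] == self.pairs[:, 1]):
            raise ValueError("context must differ from target")


def sample_neighbors(
    graph: BrainGraph,
    node: int,
    fanout: int,
    rng: np.random.Generator,
    exact: bool = False,
) -> np.ndarray:
    """Draw ``fanout`` neighbors of ``node`` uniformly with replacement.

    An isolated node falls back to ``fanout`` copies of itself so the
    aggregator never sees an empty set. With ``exact=True`` the full
    neighborhood is returned unsampled (used at inference and in tests).
    """
    nbrs = graph.neighbors(node)  # raises KeyError for unknown node
    if len(nbrs) == 0:
        nbrs = np.array([node], dtype=np.int64)
    if exact:
        return nbrs.copy()
    return nbrs[rng.integers(0, len(nbrs), size=fanout)]


def aggregate_mean(neighbor_vectors: Sequence[np.ndarray] | np.ndarray) -> np.ndarray:
    """Elementwise mean of the (sampled) neighbor representations."""
    arr = np.asarray(neighbor_vectors, dtype=float)
    if arr.ndim != 2 or arr.shape[0] == 0:
        raise ValueError("need a non-empty list of equal-length vectors")
    return arr.mean(axis=0)


def aggregate_pool(
    neighbor_vectors: Sequence[np.ndarray] | np.ndarray,
    pool_W: np.ndarray | None = None,
    sigma: Callable[[np.ndarray], np.ndarray] | None = None,
) -> np.ndarray:
    """Elementwise max of sigma(pool_W . h_u) over the neighbor set."""
    arr = np.asarray(neighbor_vectors, dtype=float)
    if arr.ndim != 2 or arr.shape[0] == 0:
        raise ValueError("need a non-empty list of equal-length vectors")
    if pool_W is not None:
        if pool_W.shape[1] != arr.shape[1]:
            raise ValueError(
                f"pool_W expects dimension {pool_W.shape[1]}, vectors have {arr.shape[1]}"
            )
        arr = arr @ pool_W.T
    if sigma is not None:
        arr = sigma(arr)
    return arr.max(axis=0)


def _normalize_rows(a: np.ndarray, warn: bool = True) -> tuple[np.ndarray, np.ndarray]:
    """L2-normalize rows; all-zero rows are left zero (with a warning)."""
    norms = np.linalg.norm(a, axis=-1, keepdims=True)
    zero = norms.squeeze(-1) == 0.0
    if np.any(zero):
        # transient zero rows during training are routine (dead ReLU units
        # revived by later updates); only warn in the single-node API
        logger.log(
            logging.WARNING if warn else logging.DEBUG,
            "%d zero vector(s) left unnormalized",
            int(np.sum(zero)),
        )
    safe = np.where(norms == 0.0, 1.0, norms)
    return a / safe, norms.squeeze(-1)


def forward_layer(
    h_self: np.ndarray, h_neigh: np.ndarray, params: LayerParams
) -> np.ndarray:
    """One layer for one node: sigma(W . [h_self || h_neigh]), L2-normalized."""
    h_self = np.asarray(h_self, dtype=float)
    h_neigh = np.asarray(h_neigh, dtype=float)
    if not (np.all(np.isfinite(h_self)) and np.all(np.isfinite(h_neigh))):
        raise FloatingPointError("non-finite layer input")
    concat = np.concatenate([h_self, h_neigh])
    if concat.shape[0] != params.W.shape[1]:
        raise ValueError(
            f"W expects input dimension {params.W.shape[1]}, got {concat.shape[0]}"
        )
    out = params.sigma(params.W @ concat)
    normed, _ = _normalize_rows(out[None, :])
    return normed[0]


def generate_walk_pairs(
    graph: BrainGraph,
    walks_per_node: int,
    walk_length: int,
    rng: np.random.Generator,
) -> WalkPairSet:
    """Uniform random walks from every node; pairs = (start, later visit).

    ``walks_per_node`` walks of ``walk_length`` nodes each are started from
    every node in ascending index order; a walk truncates at a dead end.
    Every non-start visit v != u on a walk yields one (u, v) pair.
    """
    if graph.n_edges == 0:
        raise ValueError("cannot walk on an edgeless graph")
    pairs: list[tuple[int, int]] = []
    for start in range(graph.n_nodes):
        for _ in range(walks_per_node):
            current = start
            for _ in range(walk_length - 1):
                nbrs = graph.neighbors(current)
                if len(nbrs) == 0:
                    break
                current = int(nbrs[rng.integers(0, len(nbrs))])
                if current != start:
                    pairs.append((start, current))
    return WalkPairSet(
        pairs=np.array(pairs, dtype=np.int64).reshape(-1, 2), n_nodes=graph.n_nodes
    )


def _log_sigmoid(x: np.ndarray | float) -> np.ndarray | float:
    # log s(x) = -log(1 + e^{-x}), computed stably
    return -np.logaddexp(0.0, -np.asarray(x, dtype=float))


def unsupervised_loss(
    z_u: np.ndarray, z_v: np.ndarray, z_negs: Sequence[np.ndarray] | np.ndarray
) -> float:
    """Negative-sampling loss for one positive pair and its Q negatives.

    -log s(z_u . z_v) - sum over negatives of log s(-z_u . z_n); always >= 0.
    """
    z_u = np.asarray(z_u, dtype=float)
    z_v = np.asarray(z_v, dtype=float)
    negs = np.asarray(z_negs, dtype=float)
    if negs.ndim == 1:
        negs = negs.reshape(0, z_u.shape[0]) if negs.size == 0 else negs[None, :]
    if negs.shape[0] == 0:
        raise ValueError("need at least one negative sample")
    pos = -_log_sigmoid(float(z_u @ z_v))
    neg = -np.sum(_log_sigmoid(-(negs @ z_u)))
    return float(pos + neg)


# ---------------------------------------------------------------------------
# minibatch training
# ---------------------------------------------------------------------------


class _AdamState:
    def __init__(self, shapes: list[tuple[int, ...]]) -> None:
        self.m = [np.zeros(s) for s in shapes]
        self.v = [np.zeros(s) for s in shapes]
        self.t = 0

    def step(self, params: list[np.ndarray], grads: list[np.ndarray], lr: float) -> None:
        self.t += 1
        for p, g, m, v in zip(params, grads, self.m, self.v):
            m *= _ADAM_B1
            m += (1 - _ADAM_B1) * g
            v *= _ADAM_B2
            v += (1 - _ADAM_B2) * g * g
            mhat = m / (1 - _ADAM_B1**self.t)
            vhat = v / (1 - _ADAM_B2**self.t)
            p -= lr * mhat / (np.sqrt(vhat) + _ADAM_EPS)


def _glorot(rng: np.random.Generator, n_out: int, n_in: int) -> np.ndarray:
    limit = np.sqrt(6.0 / (n_in + n_out))
    return rng.uniform(-limit, limit, size=(n_out, n_in))


def _padded_neighbors(graph: BrainGraph) -> tuple[np.ndarray, np.ndarray]:
    """(n, max_deg) padded neighbor table and per-node degrees.

    Isolated nodes get a single self entry (the sampling self-fallback).
    """
    lists = []
    for v in range(graph.n_nodes):
        nbrs = graph.neighbors(v)
        lists.append(nbrs if len(nbrs) else np.array([v], dtype=np.int64))
    deg = np.array([len(l) for l in lists], dtype=np.int64)
    table = np.zeros((graph.n_nodes, int(deg.max())), dtype=np.int64)
    for v, l in enumerate(lists):
        table[v, : len(l)] = l
    return table, deg


def _sample_all(
    table: np.ndarray, deg: np.ndarray, fanout: int, rng: np.random.Generator
) -> np.ndarray:
    """(n, fanout) uniform-with-replacement neighbor sample for every node."""
    n = table.shape[0]
    cols = (rng.random((n, fanout)) * deg[:, None]).astype(np.int64)
    return table[np.arange(n)[:, None], cols]


class _Trainer:
    """Full-graph forward/backward per minibatch step.

    All node representations are recomputed each step with freshly sampled
    neighborhoods; only the rows reached by the batch carry gradient. For
    ROI graphs (hundreds of nodes) this is cheaper and simpler than
    per-batch computation-graph pruning.
    """

    def __init__(self, graph: BrainGraph, config: SageConfig, rng: np.random.Generator):
        self.graph = graph
        self.cfg = config
        self.rng = rng
        self.table, self.deg = _padded_neighbors(graph)
        self.n = graph.n_nodes
        dims = [graph.features.shape[1], *config.layer_sizes]
        self.W = [_glorot(rng, dims[k + 1], 2 * dims[k]) for k in range(config.n_layers)]
        self.pool_W = (
            [_glorot(rng, dims[k], dims[k]) for k in range(config.n_layers)]
            if config.aggregator == "pool"
            else [None] * config.n_layers
        )
        shapes = [w.shape for w in self.W] + [
            p.shape for p in self.pool_W if p is not None
        ]
        self.adam = _AdamState(shapes)
        # layer k aggregates over the (K - k)-hop sample: the outermost
        # layer uses fanouts[0] (1-hop), the innermost fanouts[-1]
        self.layer_fanouts = list(reversed(config.fanouts))
        # exact (unsampled) neighborhood-averaging matrix, used at inference
        m_exact = np.zeros((self.n, self.n))
        rows = np.repeat(np.arange(self.n), self.deg)
        cols = np.concatenate([self.table[v, : self.deg[v]] for v in range(self.n)])
        np.add.at(m_exact, (rows, cols), 1.0)
        self.m_exact = m_exact / self.deg[:, None]

    # -- forward -----------------------------------------------------------

    def forward(self, train: bool) -> tuple[np.ndarray, list[dict]]:
        cfg = self.cfg
        h = self.graph.features.astype(float)
        caches: list[dict] = []
        keep = 1.0 - cfg.dropout
        for k in range(cfg.n_layers):
            cache: dict = {"h_in": h}
            if train:
                s_idx = _sample_all(self.table, self.deg, self.layer_fanouts[k], self.rng)
            else:
                s_idx = None  # exact neighborhoods at inference
            if cfg.aggregator == "mean":
                if s_idx is None:
                    m = self.m_exact
                else:
                    m = np.zeros((self.n, self.n))
                    np.add.at(
                        m,
                        (np.repeat(np.arange(self.n), s_idx.shape[1]), s_idx.ravel()),
                        1.0 / s_idx.shape[1],
                    )
                neigh = m @ h
                cache["m"] = m
            else:  # pool
                t = _relu(h @ self.pool_W[k].T)
                cache["t_pos"] = t > 0
                if s_idx is None:
                    neigh = np.empty_like(t)
                    amax_global = np.empty((self.n, t.shape[1]), dtype=np.int64)
                    for v in range(self.n):
                        nb = self.table[v, : self.deg[v]]
                        g = t[nb]
                        a = g.argmax(axis=0)
                        neigh[v] = g[a, np.arange(t.shape[1])]
                        amax_global[v] = nb[a]
                    cache["amax_nodes"] = amax_global
                else:
                    g = t[s_idx]  # (n, fanout, d)
                    a = g.argmax(axis=1)
                    neigh = np.take_along_axis(g, a[:, None, :], axis=1)[:, 0, :]
                    cache["amax_nodes"] = np.take_along_axis(s_idx, a, axis=1)
            c = np.concatenate([h, neigh], axis=1)
            if train and cfg.dropout > 0.0:
                mask = (self.rng.random(c.shape) < keep) / keep
                c = c * mask
                cache["drop"] = mask
            p = c @ self.W[k].T
            a_out = _relu(p)
            h_out, norms = _normalize_rows(a_out, warn=False)
            cache.update(c=c, p_pos=p > 0, h_out=h_out, norms=norms)
            caches.append(cache)
            h = h_out
        return h, caches

    # -- backward ----------------------------------------------------------

    def backward(self, dZ: np.ndarray, caches: list[dict]) -> list[np.ndarray]:
        cfg = self.cfg
        dW = [np.zeros_like(w) for w in self.W]
        dPool = [None if p is None else np.zeros_like(p) for p in self.pool_W]
        dh = dZ
        for k in reversed(range(cfg.n_layers)):
            cache = caches[k]
            h_out, norms = cache["h_out"], cache["norms"]
            # through row normalization: d a = (d h - h (h . d h)) / ||a||
            dot = np.sum(h_out * dh, axis=1, keepdims=True)
            safe = np.where(norms == 0.0, 1.0, norms)[:, None]
            da = (dh - h_out * dot) / safe
            da[norms == 0.0] = 0.0
            dp = da * cache["p_pos"]
            dW[k] += dp.T @ cache["c"]
            dc = dp @ self.W[k]
            if "drop" in cache:
                dc = dc * cache["drop"]
            d_in = cache["h_in"].shape[1]
            dh_self, dneigh = dc[:, :d_in], dc[:, d_in:]
            if cfg.aggregator == "mean":
                dh = dh_self + cache["m"].T @ dneigh
            else:
                h_in = cache["h_in"]
                dt = np.zeros((self.n, d_in))
                np.add.at(
                    dt,
                    (cache["amax_nodes"], np.arange(d_in)[None, :]),
                    dneigh,
                )
                dt *= cache["t_pos"]
                dPool[k] += dt.T @ h_in
                dh = dh_self + dt @ self.pool_W[k]
        return dW + [g for g in dPool if g is not None]

    # -- loss --------------------------------------------------------------

    def batch_loss_grad(
        self, z: np.ndarray, u: np.ndarray, v: np.ndarray, negs: np.ndarray
    ) -> tuple[float, np.ndarray]:
        b = len(u)
        zu, zv = z[u], z[v]
        pos = np.sum(zu * zv, axis=1)  # (b,)
        zneg = z[negs]  # (b, q, d)
        neg = np.einsum("bd,bqd->bq", zu, zneg)
        loss = float(np.mean(-_log_sigmoid(pos) - np.sum(_log_sigmoid(-neg), axis=1)))
        g_pos = -_sigmoid(-pos) / b  # d loss / d (zu.zv)
        g_neg = _sigmoid(neg) / b  # d loss / d (zu.zn)
        dz = np.zeros_like(z)
        du = g_pos[:, None] * zv + np.einsum("bq,bqd->bd", g_neg, zneg)
        np.add.at(dz, u, du)
        np.add.at(dz, v, g_pos[:, None] * zu)
        np.add.at(dz, negs.ravel(), (g_neg[:, :, None] * zu[:, None, :]).reshape(-1, z.shape[1]))
        return loss, dz

    def params(self) -> list[np.ndarray]:
        return self.W + [p for p in self.pool_W if p is not None]


def _sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x, dtype=float)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    e = np.exp(x[~pos])
    out[~pos] = e / (1.0 + e)
    return out


def _draw_negatives(
    rng: np.random.Generator, u: np.ndarray, v: np.ndarray, q: int, n_nodes: int
) -> np.ndarray:
    """(b, q) uniform negatives, redrawn where they collide with u or v."""
    negs = rng.integers(0, n_nodes, size=(len(u), q))
    if n_nodes <= 2:
        return negs  # nothing else to draw
    while True:
        bad = (negs == u[:, None]) | (negs == v[:, None])
        if not bad.any():
            return negs
        negs[bad] = rng.integers(0, n_nodes, size=int(bad.sum()))


def train_embeddings(graph: BrainGraph, config: SageConfig) -> NodeEmbeddings:
    """Train the unsupervised model and return final-layer embeddings.

    Deterministic given ``config.seed``; the per-epoch mean minibatch loss
    is attached as ``epoch_losses``.
    """
    if graph.features.shape[0] != graph.n_nodes:
        raise ValueError("graph features missing or misshapen")
    rng = np.random.default_rng(config.seed)
    trainer = _Trainer(graph, config, rng)
    walk_set = generate_walk_pairs(graph, config.walks_per_node, config.walk_length, rng)
    pairs = walk_set.pairs
    if len(pairs) == 0:
        raise ValueError("random walks produced no training pairs")
    epoch_losses = np.empty(config.epochs)
    for epoch in range(config.epochs):
        order = rng.permutation(len(pairs))
        losses = []
        for start in range(0, len(order), config.batch_size):
            batch = pairs[order[start : start + config.batch_size]]
            u, v = batch[:, 0], batch[:, 1]
            negs = _draw_negatives(rng, u, v, config.negatives_q, graph.n_nodes)
            z, caches = trainer.forward(train=True)
            loss, dz = trainer.batch_loss_grad(z, u, v, negs)
            if not np.isfinite(loss):
                raise FloatingPointError(
                    f"non-finite loss at epoch {epoch}, step {start // config.batch_size}"
                )
            grads = trainer.backward(dz, caches)
            trainer.adam.step(trainer.params(), grads, config.learning_rate)
            losses.append(loss)
        epoch_losses[epoch] = float(np.mean(losses))
    z, _ = trainer.forward(train=False)
    return NodeEmbeddings(z=z, roi_ids=list(graph.roi_ids), epoch_losses=epoch_losses)


def write_embeddings(emb: NodeEmbeddings, out_dir: str | Path) -> Path:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    path = out / "embeddings.tsv"
    df = pd.DataFrame(emb.z, columns=[f"dim{j}" for j in range(emb.z.shape[1])])
    df.insert(0, "roi_id", emb.roi_ids)
    df.to_csv(path, sep="\t", index=False, float_format="%.9g")
    if emb.epoch_losses is not None:
        log = pd.DataFrame(
            {"epoch": np.arange(len(emb.epoch_losses)), "mean_loss": emb.epoch_losses}
        )
        log.to_csv(out / "training_log.tsv", sep="\t", index=False, float_format="%.9g")
    return path


def read_embeddings(path: str | Path) -> NodeEmbeddings:
    df = pd.read_csv(path, sep="\t")
    roi_ids = df["roi_id"].astype(str).tolist()
    z = df.drop(columns=["roi_id"]).to_numpy(dtype=float)
    return NodeEmbeddings(z=z, roi_ids=roi_ids)
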