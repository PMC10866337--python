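"""NumPy implementation of the directed bond-level message-passing encoder
and the feed-forward regression head, with hand-written backpropagation.

Messages live on directed arcs.  Each arc ``v->w`` is initialized from the
concatenated source-atom and bond features; during each of ``depth`` update
rounds it aggregates the messages of arcs incoming to ``v`` *excluding its
own reverse arc* ``w->v`` (the defining property of the directed MPNN).
Final atom states combine the atom's own features with its incident
messages, and the graph embedding is the mean (or sum) over atoms.

With ``depth = 0`` no arc messages are formed at all, so the embedding
depends only on atom features.

The forward pass stores the per-round intermediates; ``encoder_backward``
replays them in reverse.  Gradients are exact (verified against finite
differences in the test suite), and everything is deterministic given the
seeds.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Dict, List, Optional, Tuple

import numpy as np

from .errors import ShapeError
from .featurize import GraphBatch

__all__ = [
    "EncoderParams",
    "HeadParams",
    "init_encoder",
    "init_head",
    "encoder_forward",
    "encoder_backward",
    "head_forward",
    "head_backward",
    "Adam",
    "make_lr_schedule",
]


def _glorot(rng: np.random.Generator, fan_in: int, fan_out: int) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=(fan_in, fan_out))


@dataclass
class EncoderParams:
    """Weights of one D-MPNN encoder.

    The message-update weight matrix is shared across depth iterations.
    """

    W_i: np.ndarray  # (atom_width + bond_width, hidden) input projection
    b_i: np.ndarray
    W_h: np.ndarray  # (hidden, hidden) message update
    W_o: np.ndarray  # (atom_width + hidden, hidden) atom aggregation
    b_o: np.ndarray
    depth: int = 3
    hidden: int = 300
    seed: int = 0

    @property
    def atom_width(self) -> int:
        return self.W_o.shape[0] - self.hidden

    @property
    def bond_width(self) -> int:
        return self.W_i.shape[0] - self.atom_width

    def arrays(self, prefix: str) -> Dict[str, np.ndarray]:
        return {
            f"{prefix}.W_i": self.W_i,
            f"{prefix}.b_i": self.b_i,
            f"{prefix}.W_h": self.W_h,
            f"{prefix}.W_o": self.W_o,
            f"{prefix}.b_o": self.b_o,
        }


@dataclass
class HeadParams:
    """Feed-forward network mapping the concatenated embeddings (plus
    optional molecular extras) to the two targets (ddG, ddH)."""

    weights: List[np.ndarray]
    biases: List[np.ndarray]
    activation: str = "relu"

    @property
    def input_dim(self) -> int:
        return self.weights[0].shape[0]

    @property
    def output_dim(self) -> int:
        return self.weights[-1].shape[1]

    def arrays(self, prefix: str) -> Dict[str, np.ndarray]:
        out = {}
        for k, (w, b) in enumerate(zip(self.weights, self.biases)):
            out[f"{prefix}.W{k}"] = w
            out[f"{prefix}.b{k}"] = b
        return out


def init_encoder(
    atom_width: int, bond_width: int, hidden: int, depth: int, seed: int
) -> EncoderParams:
    rng = np.random.default_rng(seed)
    return EncoderParams(
        W_i=_glorot(rng, atom_width + bond_width, hidden),
        b_i=np.zeros(hidden),
        W_h=_glorot(rng, hidden, hidden),
        W_o=_glorot(rng, atom_width + hidden, hidden),
        b_o=np.zeros(hidden),
        depth=depth,
        hidden=hidden,
        seed=seed,
    )


def init_head(
    input_dim: int, hidden_sizes: Tuple[int, ...], output_dim: int, seed: int
) -> HeadParams:
    rng = np.random.default_rng(seed)
    sizes = [input_dim, *hidden_sizes, output_dim]
    return HeadParams(
        weights=[_glorot(rng, a, b) for a, b in zip(sizes[:-1], sizes[1:])],
        biases=[np.zeros(b) for b in sizes[1:]],
    )


def _segment_sum(values: np.ndarray, index: np.ndarray, n: int) -> np.ndarray:
    out = np.zeros((n, values.shape[1]))
    np.add.at(out, index, values)
    return out


def encoder_forward(
    batch: GraphBatch,
    params: EncoderParams,
    readout: str = "mean",
    dropout: float = 0.0,
    rng: Optional[np.random.Generator] = None,
    want_cache: bool = False,
):
    """Encode a batch of graphs into (n_graphs, hidden) embeddings."""
    fa = batch.atom_features.shape[1]
    fb = batch.arc_features.shape[1]
    if fa + fb != params.W_i.shape[0]:
        raise ShapeError(
            f"graph widths ({fa} atom + {fb} bond) do not match encoder input "
            f"dimension {params.W_i.shape[0]}"
        )
    n_atoms = batch.n_atoms
    cache: Dict = {"batch": batch, "readout": readout}

    if params.depth >= 1 and batch.arc_src.size:
        inp = np.concatenate(
            [batch.atom_features[batch.arc_src], batch.arc_features], axis=1
        )
        z0 = inp @ params.W_i + params.b_i
        h = np.maximum(z0, 0.0)
        masks = [z0 > 0]
        ms: List[np.ndarray] = []
        for _ in range(params.depth):
            incoming = _segment_sum(h, batch.arc_dst, n_atoms)
            m = incoming[batch.arc_src] - h[batch.rev]
            z = z0 + m @ params.W_h
            h = np.maximum(z, 0.0)
            masks.append(z > 0)
            ms.append(m)
        agg = _segment_sum(h, batch.arc_dst, n_atoms)
        cache.update(inp=inp, masks=masks, ms=ms, hs_final=h)
    else:
        agg = np.zeros((n_atoms, params.hidden))
        cache.update(inp=None, masks=[], ms=[], hs_final=None)

    atom_in = np.concatenate([batch.atom_features, agg], axis=1)
    q = atom_in @ params.W_o + params.b_o
    ha = np.maximum(q, 0.0)
    drop_mask = None
    if dropout > 0.0 and rng is not None:
        drop_mask = (rng.random(ha.shape) >= dropout) / (1.0 - dropout)
        ha = ha * drop_mask
    cache.update(atom_in=atom_in, q_mask=q > 0, drop_mask=drop_mask)

    pooled = _segment_sum(ha, batch.atom_graph_id, batch.n_graphs)
    if readout == "mean":
        pooled = pooled / batch.atom_counts[:, None]
    elif readout != "sum":
        raise ValueError(f"unknown readout {readout!r}")
    if want_cache:
        return pooled, cache
    return pooled


def encoder_backward(
    d_emb: np.ndarray, cache: Dict, params: EncoderParams
) -> Dict[str, np.ndarray]:
    """Gradients of a scalar loss w.r.t. the encoder weights, given the
    gradient w.r.t. the embeddings and the forward cache."""
    batch: GraphBatch = cache["batch"]
    d_ha = d_emb[batch.atom_graph_id]
    if cache["readout"] == "mean":
        d_ha = d_ha / batch.atom_counts[batch.atom_graph_id][:, None]
    if cache["drop_mask"] is not None:
        d_ha = d_ha * cache["drop_mask"]
    d_q = d_ha * cache["q_mask"]
    grads = {
        "W_o": cache["atom_in"].T @ d_q,
        "b_o": d_q.sum(axis=0),
        "W_i": np.zeros_like(params.W_i),
        "b_i": np.zeros_like(params.b_i),
        "W_h": np.zeros_like(params.W_h),
    }
    if cache["inp"] is None:
        return grads

    hidden = params.hidden
    fa = batch.atom_features.shape[1]
    d_atom_in = d_q @ params.W_o.T
    d_agg = d_atom_in[:, fa:]
    d_h = d_agg[batch.arc_dst]  # grad on final arc states

    d_z0 = np.zeros((batch.arc_src.size, hidden))
    masks = cache["masks"]
    ms = cache["ms"]
    for t in range(params.depth, 0, -1):
        d_z = d_h * masks[t]
        d_z0 += d_z
        grads["W_h"] += ms[t - 1].T @ d_z
        d_m = d_z @ params.W_h.T
        g_atom = _segment_sum(d_m, batch.arc_src, batch.n_atoms)
        d_h = g_atom[batch.arc_dst] - d_m[batch.rev]
    d_z0 += d_h * masks[0]
    grads["W_i"] = cache["inp"].T @ d_z0
    grads["b_i"] = d_z0.sum(axis=0)
    return grads


def head_forward(
    x: np.ndarray,
    head: HeadParams,
    dropout: float = 0.0,
    rng: Optional[np.random.Generator] = None,
    want_cache: bool = False,
):
    if x.shape[1] != head.input_dim:
        raise ShapeError(
            f"head expects input width {head.input_dim}, got {x.shape[1]}"
        )
    cache = {"xs": [x], "masks": [], "drops": []}
    out = x
    last = len(head.weights) - 1
    for k, (w, b) in enumerate(zip(head.weights, head.biases)):
        z = out @ w + b
        if k < last:
            mask = z > 0
            out = np.maximum(z, 0.0)
            drop = None
            if dropout > 0.0 and rng is not None:
                drop = (rng.random(out.shape) >= dropout) / (1.0 - dropout)
                out = out * drop
            cache["masks"].append(mask)
            cache["drops"].append(drop)
            cache["xs"].append(out)
        else:
            out = z
    if want_cache:
        return out, cache
    return out


def head_backward(
    d_out: np.ndarray, cache: Dict, head: HeadParams
) -> Tuple[Dict[str, np.ndarray], np.ndarray]:
    """Returns (weight gradients, gradient w.r.t. the head input)."""
    grads: Dict[str, np.ndarray] = {}
    d = d_out
    last = len(head.weights) - 1
    for k in range(last, -1, -1):
        x = cache["xs"][k]
        grads[f"W{k}"] = x.T @ d
        grads[f"b{k}"] = d.sum(axis=0)
        d = d @ head.weights[k].T
        if k > 0:
            if cache["drops"][k - 1] is not None:
                d = d * cache["drops"][k - 1]
            d = d * cache["masks"][k - 1]
    return grads, d


class Adam:
    """Adaptive-moment gradient descent over a named parameter dict.

    Parameter arrays are updated in place, so dataclass views stay current.
    """

    def __init__(
        self,
        params: Dict[str, np.ndarray],
        beta1: float = 0.9,
        beta2: float = 0.999,
        eps: float = 1e-8,
    ):
        self.params = params
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.t = 0

    def step(self, grads: Dict[str, np.ndarray], lr: float) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for k, p in self.params.items():
            g = grads[k]
            self.m[k] = b1 * self.m[k] + (1 - b1) * g
            self.v[k] = b2 * self.v[k] + (1 - b2) * g * g
            m_hat = self.m[k] / (1 - b1 ** self.t)
            v_hat = self.v[k] / (1 - b2 ** self.t)
            p -= lr * m_hat / (np.sqrt(v_hat) + self.eps)


def make_lr_schedule(
    steps_per_epoch: int,
    max_epochs: int,
    warmup_epochs: float = 2.0,
    init_lr: float = 1e-4,
    max_lr: float = 1e-3,
    final_lr: float = 1e-4,
) -> Callable[[int], float]:
    """Noam-style schedule: linear warmup to ``max_lr`` followed by an
    exponential decay toward ``final_lr`` at the last step."""
    total = max(1, steps_per_epoch * max_epochs)
    warmup = max(1, int(round(steps_per_epoch * min(warmup_epochs, max_epochs))))
    if warmup >= total:
        warmup = max(1, total // 2)
    gamma = (final_lr / max_lr) ** (1.0 / max(1, total - warmup))

    def lr_at(step: int) -> float:
        if step < warmup:
            return init_lr + (max_lr - init_lr) * step / warmup
        return max_lr * gamma ** (step - warmup)

    return lr_at
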