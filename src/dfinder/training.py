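"""End-to-end optimization with Bayesian Personalized Ranking (BPR) loss.

BPR is a pairwise ranking loss: for a drug D with an observed partner food
F_i and an unobserved food F_j, the loss ``-ln sigmoid(y(D,F_i) - y(D,F_j))``
pushes observed interactions above unobserved ones.  The total objective

    L = - sum_triples ln sigmoid(y_pos - y_neg) + lambda * ||theta0||^2

regularizes only the layer-0 topology embeddings; gradients flow through
propagation, the attribute DNN, fusion and scoring jointly, and are applied
with a mini-batch Adam optimizer.  Negatives are resampled every epoch, one
per positive.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace as dc_replace
from typing import TYPE_CHECKING, Sequence

import numpy as np

from .graph import BipartiteDFIGraph

if TYPE_CHECKING:  # pragma: no cover
    from .model import DFinder, DFinderResults, ModelParams


@dataclass(frozen=True)
class BPRTriple:
    """(drug, observed food, unobserved food) ranking triple."""

    drug: str
    pos_food: str
    neg_food: str


@dataclass(frozen=True)
class TrainConfig:
    """Hyperparameters of a training run.

    lam is the L2 strength on the layer-0 embeddings (Eq.-style
    ``lambda * ||theta0||^2``); ``negative_ratio`` negatives are drawn per
    positive each epoch.  A single root ``seed`` drives initialization,
    shuffling and negative sampling.
    """

    learning_rate: float = 1e-3
    batch_size: int = 1024
    epochs: int = 400
    lam: float = 1e-4
    seed: int = 0
    negative_ratio: int = 1
    log_every: int = 0  # 0 = silent

    def __post_init__(self) -> None:
        if self.lam < 0:
            raise ValueError("lam must be >= 0")
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")

    def replace(self, **kwargs) -> "TrainConfig":
        return dc_replace(self, **kwargs)

    def to_dict(self) -> dict:
        return {
            "learning_rate": self.learning_rate,
            "batch_size": self.batch_size,
            "epochs": self.epochs,
            "lam": self.lam,
            "seed": self.seed,
            "negative_ratio": self.negative_ratio,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "TrainConfig":
        return cls(**{k: v for k, v in d.items() if k in cls.__dataclass_fields__})


# ---------------------------------------------------------------------------
# triple sampling
# ---------------------------------------------------------------------------


def sample_triples(
    graph: BipartiteDFIGraph,
    batch_size: int,
    seed: int | np.random.Generator = 0,
) -> list[BPRTriple]:
    """Draw ``batch_size`` BPR triples from the training graph.

    Positives are drawn uniformly from the observed edges; each positive is
    paired with one negative food drawn uniformly from the foods NOT linked
    to that drug.  A drug adjacent to every food cannot yield a negative:
    its positives are skipped with a warning.
    """
    rng = (
        seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    )
    edges = sorted(graph.edges)
    N = graph.n_foods
    picks = rng.integers(0, len(edges), size=batch_size)
    triples: list[BPRTriple] = []
    for e in picks:
        d, f_pos = edges[e]
        nbrs = graph.neighbors_of_drug[d]
        if len(nbrs) >= N:
            warnings.warn(
                f"drug {d!r} is adjacent to every food; skipping its positives"
            )
            continue
        while True:
            f_neg = graph.food_ids[int(rng.integers(0, N))]
            if f_neg not in nbrs:
                break
        triples.append(BPRTriple(d, f_pos, f_neg))
    return triples


# ---------------------------------------------------------------------------
# loss
# ---------------------------------------------------------------------------


def _log_sigmoid(x: np.ndarray) -> np.ndarray:
    # numerically stable ln sigma(x) = -softplus(-x)
    return np.where(x >= 0, -np.log1p(np.exp(-x)), x - np.log1p(np.exp(x)))


def bpr_loss(
    pos_scores: Sequence[float],
    neg_scores: Sequence[float],
    theta0: np.ndarray | None = None,
    lam: float = 0.0,
) -> float:
    """BPR objective ``-sum ln sigmoid(y_pos - y_neg) + lam * ||theta0||^2``.

    Score lists are paired by triple; the L2 term covers the layer-0
    embeddings only.
    """
    pos = np.asarray(pos_scores, dtype=float)
    neg = np.asarray(neg_scores, dtype=float)
    if pos.shape != neg.shape:
        raise ValueError("pos_scores and neg_scores must have equal length")
    loss = float(-_log_sigmoid(pos - neg).sum())
    if theta0 is not None and lam > 0:
        loss += lam * float(np.sum(theta0 * theta0))
    return loss


# ---------------------------------------------------------------------------
# gradients (hand-written reverse mode, verified by finite differences)
# ---------------------------------------------------------------------------


def loss_and_grads(
    model: "DFinder",
    params: "ModelParams",
    d_idx: np.ndarray,
    pos_idx: np.ndarray,
    neg_idx: np.ndarray,
    lam: float,
):
    """Full-model BPR loss and gradients for one batch of index triples.

    ``d_idx`` are stacked drug indices, ``pos_idx``/``neg_idx`` stacked food
    indices (i.e. already offset by M).  Returns ``(loss, grads)`` with
    ``grads`` a list aligned with ``params.arrays()``.
    """
    from .model import attribute_backward, propagate_combined

    Z, (T, dnn_cache) = model.forward(params, return_cache=True)
    s_pos = np.sum(Z[d_idx] * Z[pos_idx], axis=1)
    s_neg = np.sum(Z[d_idx] * Z[neg_idx], axis=1)
    margin = s_pos - s_neg
    loss = float(-_log_sigmoid(margin).sum())
    loss += lam * float(np.sum(params.theta0 * params.theta0))

    # d/dm of -ln sigma(m) is sigma(m) - 1
    c = 1.0 / (1.0 + np.exp(-margin)) - 1.0
    dZ = np.zeros_like(Z)
    np.add.at(dZ, d_idx, c[:, None] * (Z[pos_idx] - Z[neg_idx]))
    np.add.at(dZ, pos_idx, c[:, None] * Z[d_idx])
    np.add.at(dZ, neg_idx, -c[:, None] * Z[d_idx])

    d_topo = params.d_topo
    dT = dZ[:, :d_topo]
    # the combined propagation operator is symmetric: adjoint == forward
    dtheta0 = propagate_combined(dT, model.S, params.K)
    dtheta0 += 2.0 * lam * params.theta0
    grads = [dtheta0]
    if params.dnn_weights is not None:
        dA = dZ[:, d_topo:]
        for gW, gb in attribute_backward(
            dA, dnn_cache, params.dnn_weights, model.relu_output
        ):
            grads.extend([gW, gb])
    return loss, grads


# ---------------------------------------------------------------------------
# Adam
# ---------------------------------------------------------------------------


class Adam:
    """Mini-batch Adam with per-array first/second moment estimates."""

    def __init__(
        self,
        arrays: Sequence[np.ndarray],
        lr: float = 1e-3,
        beta1: float = 0.9,
        beta2: float = 0.999,
        eps: float = 1e-8,
    ) -> None:
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(a) for a in arrays]
        self.v = [np.zeros_like(a) for a in arrays]
        self.t = 0

    def step(self, arrays: Sequence[np.ndarray], grads: Sequence[np.ndarray]) -> None:
        self.t += 1
        b1t = 1.0 - self.beta1**self.t
        b2t = 1.0 - self.beta2**self.t
        for a, g, m, v in zip(arrays, grads, self.m, self.v):
            m *= self.beta1
            m += (1.0 - self.beta1) * g
            v *= self.beta2
            v += (1.0 - self.beta2) * g * g
            a -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)


# ---------------------------------------------------------------------------
# training loop
# ---------------------------------------------------------------------------


def train(model: "DFinder", config: TrainConfig) -> "DFinderResults":
    """Train ``model`` end-to-end; returns a results object.

    Each epoch shuffles all training edges, pairs every positive with
    ``negative_ratio`` freshly drawn uniform negatives, and applies Adam
    per mini-batch on the summed BPR loss.  Fully determined by
    ``config.seed``.
    """
    from .model import DFinderResults

    g = model.graph
    rng = np.random.default_rng(config.seed)
    params = model.init_params(seed=int(rng.integers(0, 2**31 - 1)))
    arrays = params.arrays()
    opt = Adam(arrays, lr=config.learning_rate)

    edges = sorted(g.edges)
    M, N = g.n_drugs, g.n_foods
    d_all = np.array([g.drug_index[d] for d, _ in edges])
    f_all = np.array([g.food_index[f] + M for _, f in edges])
    # boolean adjacency for fast negative rejection
    adj = np.zeros((M, N), dtype=bool)
    for d, f in edges:
        adj[g.drug_index[d], g.food_index[f]] = True
    full_rows = adj.all(axis=1)
    if full_rows.any():
        warnings.warn(
            f"{int(full_rows.sum())} drugs are adjacent to every food; "
            "their positives are skipped"
        )

    loss_history: list[float] = []
    n_edges = len(edges)
    batch = min(config.batch_size, n_edges)
    for epoch in range(config.epochs):
        order = rng.permutation(n_edges)
        if config.negative_ratio != 1:
            order = np.repeat(order, config.negative_ratio)
        keep = ~full_rows[d_all[order]]
        order = order[keep]
        # fresh uniform negatives, rejecting observed edges
        neg = rng.integers(0, N, size=len(order))
        bad = adj[d_all[order], neg]
        while bad.any():
            neg[bad] = rng.integers(0, N, size=int(bad.sum()))
            bad = adj[d_all[order], neg]
        epoch_loss = 0.0
        for start in range(0, len(order), batch):
            sl = order[start : start + batch]
            loss, grads = loss_and_grads(
                model,
                params,
                d_all[sl],
                f_all[sl],
                neg[start : start + batch] + M,
                config.lam,
            )
            if not np.isfinite(loss):
                raise FloatingPointError(
                    f"non-finite loss at epoch {epoch}: {loss!r}; "
                    "try a smaller learning rate"
                )
            opt.step(arrays, grads)
            epoch_loss += loss
        loss_history.append(epoch_loss)
        if config.log_every and (epoch + 1) % config.log_every == 0:
            print(f"epoch {epoch + 1:>5d}  loss {epoch_loss:.4f}")

    return DFinderResults(model, params, config, loss_history)
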