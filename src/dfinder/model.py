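"""The DFinder model: bipartite link prediction by fusing graph-topology
embeddings with compressed structural-similarity attribute features.

Architecture
------------
*Topology branch.*  Every node carries a trainable layer-0 embedding
``theta0``.  Embeddings are propagated over the bipartite interaction graph
by a simplified graph convolution — a pure weighted-sum neighbor
aggregation with symmetric degree normalization ``1/sqrt(|N_D||N_F|)`` and
no feature transformation or nonlinearity (the LightGCN simplification).
After ``K`` propagation steps the per-layer embeddings are averaged to give
the topology feature ``T`` of each node.

*Attribute branch.*  Each node's structural similarity profile (SSP) row is
compressed by a three-layer fully connected network (panel width -> 1024 ->
512 -> 64 by default, ReLU after every layer) into a 64-dimensional
attribute feature ``A``.

*Fusion and scoring.*  The final node representation is the concatenation
``Z = (T || A)`` and the interaction score of a (drug, food) pair is the
inner product of their fused representations.

Everything is trained end-to-end against a Bayesian Personalized Ranking
loss (see :mod:`dfinder.training`); gradients here are computed by
hand-written reverse-mode passes, which keeps the whole model dependency-
light and makes finite-difference verification straightforward.

The public surface follows the Model/Results convention: build a
:class:`DFinder` from a graph (and optionally an SSP matrix), call
``fit()``, and read estimates and predictions off the returned
:class:`DFinderResults`.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import scipy.sparse as sp

from .exceptions import LeakageError
from .graph import BipartiteDFIGraph, Edge
from .ssp import SSPMatrix

# ---------------------------------------------------------------------------
# parameters
# ---------------------------------------------------------------------------


@dataclass
class ModelParams:
    """Trainable parameters.

    ``theta0`` stacks the layer-0 embeddings of all drugs then all foods,
    one row per node; it is the only block that the BPR loss L2-regularizes.
    ``dnn_weights`` is a list of ``(W, b)`` pairs for the attribute network,
    or ``None`` for a topology-only model.  ``K`` is the number of
    propagation layers.
    """

    theta0: np.ndarray
    dnn_weights: list[tuple[np.ndarray, np.ndarray]] | None
    K: int

    @property
    def d_topo(self) -> int:
        return self.theta0.shape[1]

    def copy(self) -> "ModelParams":
        dnn = (
            None
            if self.dnn_weights is None
            else [(W.copy(), b.copy()) for W, b in self.dnn_weights]
        )
        return ModelParams(self.theta0.copy(), dnn, self.K)

    def arrays(self) -> list[np.ndarray]:
        """Flat list of parameter arrays (theta0 first), for optimizers."""
        out = [self.theta0]
        if self.dnn_weights is not None:
            for W, b in self.dnn_weights:
                out.extend([W, b])
        return out


# ---------------------------------------------------------------------------
# topology branch
# ---------------------------------------------------------------------------


def normalized_adjacency(graph: BipartiteDFIGraph) -> sp.csr_matrix:
    """Symmetric-normalized stacked adjacency of the bipartite graph.

    Entry ``(D, F)`` (and its transpose) is ``1/sqrt(|N_D| |N_F|)``; drugs
    occupy rows ``0..M-1`` and foods rows ``M..M+N-1``.  No self-loops:
    isolated nodes simply receive the zero vector at layers >= 1.  The
    operator is symmetric with spectral norm <= 1, so repeated propagation
    cannot blow up embedding scale.
    """
    M, N = graph.n_drugs, graph.n_foods
    rows, cols, vals = [], [], []
    for d, f in graph.edges:
        i = graph.drug_index[d]
        j = graph.food_index[f] + M
        w = 1.0 / np.sqrt(graph.drug_degree(d) * graph.food_degree(f))
        rows.extend([i, j])
        cols.extend([j, i])
        vals.extend([w, w])
    return sp.csr_matrix((vals, (rows, cols)), shape=(M + N, M + N))


def propagate(theta0: np.ndarray, S: sp.spmatrix, K: int) -> list[np.ndarray]:
    """Layer embeddings ``[T^(0), ..., T^(K)]`` with ``T^(l+1) = S T^(l)``."""
    if K < 0:
        raise ValueError(f"K must be >= 0, got {K}")
    layers = [np.asarray(theta0, dtype=float)]
    for _ in range(K):
        layers.append(S @ layers[-1])
    return layers


def combine_layers(layers: Sequence[np.ndarray]) -> np.ndarray:
    """Mean over propagation layers: ``T = 1/(K+1) sum_k T^(k)``."""
    return np.mean(np.stack(layers, axis=0), axis=0)


def propagate_combined(theta: np.ndarray, S: sp.spmatrix, K: int) -> np.ndarray:
    """Apply the combined propagation operator ``1/(K+1) sum_k S^k``.

    The operator is symmetric, so it is its own adjoint: the same routine
    maps layer-0 embeddings forward and back-propagates gradients onto them.
    """
    acc = np.array(theta, dtype=float)
    cur = acc.copy()
    for _ in range(K):
        cur = S @ cur
        acc += cur
    return acc / (K + 1)


# ---------------------------------------------------------------------------
# attribute branch
# ---------------------------------------------------------------------------


def attribute_forward(
    X: np.ndarray,
    weights: Sequence[tuple[np.ndarray, np.ndarray]],
    relu_output: bool = True,
    return_cache: bool = False,
):
    """Forward pass of the attribute DNN: affine + ReLU per layer.

    ``X`` holds one SSP row per node; the row width must equal the first
    weight matrix's input width.  ReLU follows every layer including the
    output by default (``relu_output=False`` gives a linear last layer).
    """
    X = np.asarray(X, dtype=float)
    if X.shape[1] != weights[0][0].shape[0]:
        raise ValueError(
            f"attribute width {X.shape[1]} does not match DNN input width "
            f"{weights[0][0].shape[0]}"
        )
    H = X
    pre: list[np.ndarray] = []
    acts: list[np.ndarray] = [X]
    n_layers = len(weights)
    for l, (W, b) in enumerate(weights):
        Zl = H @ W + b
        pre.append(Zl)
        if l < n_layers - 1 or relu_output:
            H = np.maximum(Zl, 0.0)
        else:
            H = Zl
        acts.append(H)
    if return_cache:
        return H, (pre, acts)
    return H


def attribute_backward(
    dA: np.ndarray,
    cache: tuple[list[np.ndarray], list[np.ndarray]],
    weights: Sequence[tuple[np.ndarray, np.ndarray]],
    relu_output: bool = True,
) -> list[tuple[np.ndarray, np.ndarray]]:
    """Gradients of the DNN weights given the gradient at its output."""
    pre, acts = cache
    n_layers = len(weights)
    dH = np.asarray(dA, dtype=float)
    grads: list[tuple[np.ndarray, np.ndarray]] = [None] * n_layers  # type: ignore
    for l in range(n_layers - 1, -1, -1):
        if l < n_layers - 1 or relu_output:
            dZ = dH * (pre[l] > 0)
        else:
            dZ = dH
        grads[l] = (acts[l].T @ dZ, dZ.sum(axis=0))
        dH = dZ @ weights[l][0].T
    return grads


# ---------------------------------------------------------------------------
# fusion and scoring
# ---------------------------------------------------------------------------


def fuse(T: np.ndarray, A: np.ndarray | None) -> np.ndarray:
    """Concatenate topology and attribute features, topology first."""
    if A is None:
        return np.asarray(T, dtype=float)
    return np.concatenate([T, A], axis=-1)


def score(z_drug: np.ndarray, z_food: np.ndarray) -> float | np.ndarray:
    """Interaction score: inner product of fused representations."""
    z_drug = np.asarray(z_drug, dtype=float)
    z_food = np.asarray(z_food, dtype=float)
    if z_drug.shape[-1] != z_food.shape[-1]:
        raise ValueError(
            f"dimension mismatch: {z_drug.shape[-1]} vs {z_food.shape[-1]}"
        )
    return np.sum(z_drug * z_food, axis=-1)


# ---------------------------------------------------------------------------
# the Model object
# ---------------------------------------------------------------------------


class DFinder:
    """Drug-food interaction prediction model.

    Parameters
    ----------
    graph
        The *training* interaction network.  Its edges drive both
        propagation and the positive pairs of the BPR loss, so held-out
        test edges must already be removed.
    ssp
        Structural similarity profiles covering every node of ``graph``
        (drugs and foods share the panel space).  ``None`` gives a
        topology-only model (no attribute branch).
    K
        Number of propagation layers (default 3).
    d_topo
        Dimension of the layer-0 topology embeddings (default 64).
    hidden_dims, attr_dim
        Attribute-DNN hidden widths and output width (defaults 1024/512
        and 64, the widths used with a 2159-drug reference panel).
    relu_output
        Apply ReLU after the final DNN layer as well (default True).

    Examples
    --------
    >>> model = DFinder(train_graph, ssp, K=3, d_topo=64)
    >>> res = model.fit(epochs=400, seed=0)
    >>> res.predict_pairs([("D1", "F7")])
    """

    def __init__(
        self,
        graph: BipartiteDFIGraph,
        ssp: SSPMatrix | None = None,
        K: int = 3,
        d_topo: int = 64,
        hidden_dims: tuple[int, ...] = (1024, 512),
        attr_dim: int = 64,
        relu_output: bool = True,
    ) -> None:
        if not 0 <= K <= 8:
            raise ValueError(f"K must be in 0..8, got {K}")
        if d_topo <= 0:
            raise ValueError(f"d_topo must be positive, got {d_topo}")
        self.graph = graph
        self.K = K
        self.d_topo = d_topo
        self.hidden_dims = tuple(hidden_dims)
        self.attr_dim = attr_dim
        self.relu_output = relu_output
        self.S = normalized_adjacency(graph)
        self.node_order = list(graph.drug_ids) + list(graph.food_ids)
        if ssp is not None:
            self.X: np.ndarray | None = ssp.aligned_to(self.node_order)
        else:
            self.X = None

    # -- initialization ---------------------------------------------------

    def init_params(self, seed: int = 0) -> ModelParams:
        """Seeded parameter initialization.

        Layer-0 embeddings are zero-mean Gaussian with std 0.1; DNN weights
        use scaled-Gaussian (He) initialization with a small positive bias
        (0.01) so ReLU units start active and pre-activations avoid the
        exact kink at zero.
        """
        rng = np.random.default_rng(seed)
        n_nodes = self.graph.n_drugs + self.graph.n_foods
        theta0 = rng.normal(0.0, 0.1, size=(n_nodes, self.d_topo))
        dnn = None
        if self.X is not None:
            widths = [self.X.shape[1], *self.hidden_dims, self.attr_dim]
            dnn = []
            for fan_in, fan_out in zip(widths[:-1], widths[1:]):
                W = rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(fan_in, fan_out))
                dnn.append((W, np.full(fan_out, 0.01)))
        return ModelParams(theta0, dnn, self.K)

    # -- forward ----------------------------------------------------------

    def forward(self, params: ModelParams, return_cache: bool = False):
        """Fused representations ``Z`` for all nodes (drugs stacked first)."""
        T = propagate_combined(params.theta0, self.S, params.K)
        if params.dnn_weights is None:
            Z = T
            cache = (T, None)
        else:
            A, dnn_cache = attribute_forward(
                self.X, params.dnn_weights, self.relu_output, return_cache=True
            )
            Z = fuse(T, A)
            cache = (T, dnn_cache)
        if return_cache:
            return Z, cache
        return Z

    # -- fitting ----------------------------------------------------------

    def fit(self, config=None, **kwargs) -> "DFinderResults":
        """Train end-to-end with BPR loss and mini-batch Adam.

        ``config`` is a :class:`dfinder.training.TrainConfig`; keyword
        arguments override individual fields.  Returns a
        :class:`DFinderResults`.
        """
        from .training import TrainConfig, train

        if config is None:
            config = TrainConfig(**kwargs)
        elif kwargs:
            config = config.replace(**kwargs)
        return train(self, config)


class DFinderResults:
    """Fitted-model results: parameter estimates, training diagnostics and
    prediction helpers."""

    def __init__(
        self,
        model: DFinder,
        params: ModelParams,
        config,
        loss_history: list[float],
    ) -> None:
        self.model = model
        self.params = params
        self.config = config
        self.loss_history = list(loss_history)
        self._Z: np.ndarray | None = None

    @property
    def embeddings(self) -> np.ndarray:
        """Fused node representations, one row per node (drugs first)."""
        if self._Z is None:
            self._Z = self.model.forward(self.params)
        return self._Z

    def predict_pairs(self, pairs: Sequence[Edge]) -> np.ndarray:
        """Interaction scores for (drug_id, food_id) pairs."""
        Z = self.embeddings
        g = self.model.graph
        M = g.n_drugs
        di = np.array([g.drug_index[d] for d, _ in pairs])
        fi = np.array([g.food_index[f] + M for _, f in pairs])
        return np.sum(Z[di] * Z[fi], axis=1)

    def score_matrix(self) -> np.ndarray:
        """Full M x N matrix of interaction scores."""
        Z = self.embeddings
        M = self.model.graph.n_drugs
        return Z[:M] @ Z[M:].T

    def check_no_leakage(self, test_edges: Iterable[Edge] = ()) -> None:
        leaked = set(test_edges) & self.model.graph.edges
        if leaked:
            raise LeakageError(
                f"{len(leaked)} test edges present in the propagation graph"
            )

    def summary(self) -> str:
        """Human-readable fit summary."""
        g = self.model.graph
        lines = [
            "DFinder results",
            "=" * 46,
            f"{'drugs (M)':<28}{g.n_drugs:>18}",
            f"{'food constituents (N)':<28}{g.n_foods:>18}",
            f"{'training edges':<28}{g.n_edges:>18}",
            f"{'propagation layers K':<28}{self.params.K:>18}",
            f"{'topology dim d_topo':<28}{self.params.d_topo:>18}",
            f"{'attribute branch':<28}"
            f"{('on (' + str(self.model.X.shape[1]) + ' -> ' + str(self.model.attr_dim) + ')') if self.model.X is not None else 'off':>18}",
            f"{'epochs':<28}{len(self.loss_history):>18}",
            f"{'initial BPR loss':<28}{self.loss_history[0]:>18.4f}",
            f"{'final BPR loss':<28}{self.loss_history[-1]:>18.4f}",
            "=" * 46,
        ]
        return "\n".join(lines)

    # -- checkpointing ----------------------------------------------------

    def save(self, path: str | Path) -> None:
        """Serialize parameters + config into a single ``.npz`` container."""
        arrays = {"theta0": self.params.theta0, "K": np.array(self.params.K)}
        if self.params.dnn_weights is not None:
            for l, (W, b) in enumerate(self.params.dnn_weights):
                arrays[f"W{l}"] = W
                arrays[f"b{l}"] = b
        arrays["n_dnn_layers"] = np.array(
            0 if self.params.dnn_weights is None else len(self.params.dnn_weights)
        )
        arrays["config_json"] = np.frombuffer(
            json.dumps(self.config.to_dict()).encode(), dtype=np.uint8
        )
        arrays["loss_history"] = np.array(self.loss_history)
        np.savez(path, **arrays)

    @staticmethod
    def load_params(path: str | Path) -> tuple[ModelParams, dict, list[float]]:
        """Load (params, config dict, loss history) from a checkpoint."""
        with np.load(path) as data:
            n_layers = int(data["n_dnn_layers"])
            dnn = (
                [(data[f"W{l}"], data[f"b{l}"]) for l in range(n_layers)]
                if n_layers
                else None
            )
            params = ModelParams(data["theta0"], dnn, int(data["K"]))
            cfg = json.loads(bytes(data["config_json"]).decode())
            hist = [float(x) for x in data["loss_history"]]
        return params, cfg, hist
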