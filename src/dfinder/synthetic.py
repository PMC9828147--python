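"""Synthetic DFI fixtures: bipartite graphs with planted low-rank latent
structure and attribute vectors correlated with the latents.

The generator emulates the statistical shape of a real DFI network — a
sparse bipartite graph whose edges are driven by low-dimensional node
latents — together with SSP-like bounded attribute vectors carrying a
tunable amount of information about those latents.  Every stage of the
pipeline (splitting, training, evaluation, baselines) is therefore testable
offline, and parameter recovery is measurable because the ground truth is
known.

Model: drug latents ``u_i`` and food latents ``v_j`` have i.i.d. standard
Gaussian entries (unit variance, dimension ``d_lat``); an edge (i, j) is an
independent Bernoulli draw with probability ``sigmoid(u_i . v_j + b)``,
where the scalar bias ``b`` is calibrated by bisection so the expected
density matches the requested target.  Unit-variance latents give the inner
product a standard deviation of ``sqrt(d_lat)``, i.e. a strong planted
signal: the Bayes-optimal ranking of pairs by ``u . v`` attains a high
AUROC, so a learner's recovery performance is interpretable.

Attributes: each node's row is the logistic squashing of a noisy fixed
random projection of its latent, ``sigmoid(latent @ P + noise)``, with
``P`` shared by drugs and foods and i.i.d. Gaussian noise of standard
deviation ``noise_sd`` — bounded, SSP-like vectors whose information
content about the edges shrinks as ``noise_sd`` grows (at ``noise_sd``
around 10 the sigmoid saturates on noise and the rows become essentially
uninformative).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .graph import BipartiteDFIGraph
from .ssp import SSPMatrix


@dataclass
class LatentModel:
    """Ground-truth latents of a generated fixture."""

    U: np.ndarray  # (M, d_lat) drug latents
    V: np.ndarray  # (N, d_lat) food latents
    bias: float
    seed: int

    @property
    def d_lat(self) -> int:
        return self.U.shape[1]

    def edge_probabilities(self) -> np.ndarray:
        logits = self.U @ self.V.T + self.bias
        return 1.0 / (1.0 + np.exp(-logits))


def _calibrate_bias(logits: np.ndarray, target: float) -> float:
    """Bisection on the bias so that mean sigmoid(logits + b) == target."""
    lo, hi = -50.0, 50.0

    def mean_p(b: float) -> float:
        return float((1.0 / (1.0 + np.exp(-(logits + b)))).mean())

    if not mean_p(lo) < target < mean_p(hi):
        raise ValueError(f"target density {target} not attainable")
    for _ in range(200):
        mid = (lo + hi) / 2.0
        if mean_p(mid) < target:
            lo = mid
        else:
            hi = mid
    return (lo + hi) / 2.0


def generate_graph(
    M: int,
    N: int,
    d_lat: int = 8,
    target_density: float = 0.059,
    seed: int = 0,
) -> tuple[BipartiteDFIGraph, LatentModel]:
    """Generate a bipartite graph with planted low-rank structure.

    Node ids are ``D000..`` and ``F000..``.  The default density 0.059
    mirrors a curated DFI network; 0.025 mirrors a larger text-mined one.
    """
    if M < 2 or N < 2:
        raise ValueError("M and N must be >= 2")
    if not 0.0 < target_density < 0.5:
        raise ValueError(f"target_density must be in (0, 0.5), got {target_density}")
    rng = np.random.default_rng(seed)
    U = rng.normal(size=(M, d_lat))
    V = rng.normal(size=(N, d_lat))
    logits = U @ V.T
    b = _calibrate_bias(logits, target_density)
    P = 1.0 / (1.0 + np.exp(-(logits + b)))
    E = rng.random((M, N)) < P
    width_d = max(3, len(str(M - 1)))
    width_f = max(3, len(str(N - 1)))
    drugs = [f"D{i:0{width_d}d}" for i in range(M)]
    foods = [f"F{j:0{width_f}d}" for j in range(N)]
    edges = [(drugs[i], foods[j]) for i, j in np.argwhere(E)]
    graph = BipartiteDFIGraph(drugs, foods, edges)
    return graph, LatentModel(U=U, V=V, bias=b, seed=seed)


def generate_attributes(
    latents: LatentModel,
    node_ids: list[str],
    ssp_dim: int = 256,
    noise_sd: float = 0.1,
    seed: int = 0,
) -> SSPMatrix:
    """SSP-like attribute matrix correlated with the planted latents.

    ``node_ids`` must list drugs first then foods (the stacked node order of
    the graph the latents generated).  Rows are
    ``sigmoid(latent @ P + noise)`` with a shared fixed random projection
    ``P`` of shape (d_lat, ssp_dim); the squashing bounds every entry in
    [0, 1] and large ``noise_sd`` saturates the rows into noise.
    """
    if ssp_dim < latents.d_lat:
        raise ValueError("ssp_dim must be >= d_lat")
    M, N = latents.U.shape[0], latents.V.shape[0]
    if len(node_ids) != M + N:
        raise ValueError(f"expected {M + N} node ids, got {len(node_ids)}")
    rng = np.random.default_rng(seed)
    proj = rng.normal(size=(latents.d_lat, ssp_dim)) / np.sqrt(latents.d_lat)
    L = np.vstack([latents.U, latents.V])
    logits = L @ proj
    if noise_sd > 0:
        logits = logits + rng.normal(scale=noise_sd, size=logits.shape)
    values = 1.0 / (1.0 + np.exp(-logits))
    ref_ids = [f"ref{r:04d}" for r in range(ssp_dim)]
    return SSPMatrix(node_ids=list(node_ids), reference_ids=ref_ids, values=values)


def generate_fixture(
    M: int = 100,
    N: int = 120,
    d_lat: int = 8,
    target_density: float = 0.059,
    ssp_dim: int = 256,
    noise_sd: float = 0.1,
    seed: int = 0,
) -> tuple[BipartiteDFIGraph, SSPMatrix, LatentModel]:
    """Graph + attributes + ground truth in one call (one root seed)."""
    rng = np.random.default_rng(seed)
    g_seed, a_seed = (int(s) for s in rng.integers(0, 2**31 - 1, size=2))
    graph, latents = generate_graph(M, N, d_lat, target_density, seed=g_seed)
    node_ids = list(graph.drug_ids) + list(graph.food_ids)
    ssp = generate_attributes(latents, node_ids, ssp_dim, noise_sd, seed=a_seed)
    return graph, ssp, latents


def write_fixture_dir(
    out_dir: str | Path,
    graph: BipartiteDFIGraph,
    ssp: SSPMatrix,
    latents: LatentModel,
) -> None:
    """Write edge list, SSP matrix and ground-truth latents as TSV files."""
    from .graph import save_edge_list

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    save_edge_list(graph, out / "edges.tsv")
    ssp.to_tsv(out / "ssp.tsv")
    node_ids = list(graph.drug_ids) + list(graph.food_ids)
    L = np.vstack([latents.U, latents.V])
    with open(out / "latents.tsv", "w") as fh:
        fh.write("node_id\t" + "\t".join(f"z{k}" for k in range(L.shape[1])) + "\n")
        fh.write(f"#bias\t{latents.bias}\n")
        for nid, row in zip(node_ids, L):
            fh.write(nid + "\t" + "\t".join(f"{x:.6g}" for x in row) + "\n")
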