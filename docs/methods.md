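# Methods

This note documents the models and procedures the package implements, the
defaults and why they were chosen, what the synthetic generator does and
does not emulate, and the numerical choices that affect results.

## The prediction model

DFI prediction is cast as link prediction on a bipartite graph with `M`
drugs and `N` food constituents. The model scores a pair by the inner
product of fused node representations `Z = (T ‖ A)`.

**Topology features `T`.** Trainable layer-0 embeddings (dimension
`d_topo`, default 64) are propagated by a simplified graph convolution:
neighbor aggregation with symmetric degree normalization
`1/√(|N_D||N_F|)` and *no* feature transformation or nonlinearity. The
simplification follows the collaborative-filtering literature (LightGCN):
on interaction graphs the extra machinery of a full GCN layer does not
help and makes training harder. The propagation operator is the
symmetric matrix `S` with those normalized weights; it has spectral norm
≤ 1 (verified by property test), so repeated propagation cannot inflate
embedding scale. After `K` steps (default 3, configurable 0–8) the
per-layer embeddings are averaged. There are no self-loops: layer-0
information re-enters only through the layer average, and isolated nodes
contribute the zero vector at layers ≥ 1.

**Attribute features `A`.** Each node (drugs and food constituents are
both small molecules) is described by a structural similarity profile:
Tanimoto similarities of its circular fingerprint (radius 2, 2048 bits —
the DeepDDI-style default; kind and length configurable) against a
reference panel of approved drugs. A panel of 2,159 approved drugs is the
conventional choice, but the panel is user-supplied and the DNN input
width follows the panel size. A three-layer fully connected network
(input → 1024 → 512 → 64) compresses the profile; ReLU follows every
layer including the last (a config flag gives a linear output for
experimentation). One DNN is shared by drugs and foods, since both live
in the same SSP space; per-type networks would double parameters with no
obvious benefit at these data sizes. Tanimoto similarity of two all-zero
fingerprints is defined as 0.

**Fusion and scoring.** `Z = (T ‖ A)`, topology first; score is the
inner product. With the defaults `Z` has 64 + 64 = 128 dimensions.

## Training

The objective is the Bayesian Personalized Ranking loss in sum form,

    L = − Σ ln σ(ŷ_pos − ŷ_neg) + λ‖Θ‖²,

where Θ is the stacked layer-0 embedding block — the only L2-regularized
parameters; DNN weight decay is off by default (config knob). Defaults:
learning rate 1e-3, batch size 1024 (capped at the number of training
edges), 400 epochs, λ = 1e-4, no early stopping (an optional
validation-AUROC stopper with patience 20 is a documented extension
point). One epoch is a pass over the shuffled training edges; each
positive gets one freshly drawn uniform negative food not adjacent to its
drug (negative_ratio is configurable). Optimization is mini-batch Adam
(β₁ = 0.9, β₂ = 0.999, ε = 1e-8) applied to the summed loss — Adam's
per-parameter scaling makes sum vs mean immaterial. A single root seed
drives initialization, shuffling and negative sampling; identical
configurations are bit-reproducible.

Gradients are hand-written reverse-mode passes (the model is three small
building blocks: a linear propagation operator, an affine+ReLU chain, and
a bilinear score). The propagation operator is symmetric, so it is its
own adjoint; the full analytic gradient is verified against central
finite differences entrywise to better than 1e-4 relative error in the
test suite. Initialization: layer-0 embeddings are Gaussian with std 0.1;
DNN weights are He-scaled Gaussians with bias 0.01. The small positive
bias keeps ReLU units initially active; with exactly zero biases a node
whose first hidden layer is entirely inactive produces pre-activations
exactly at the ReLU kink, where subgradient and finite differences
legitimately disagree and optimization can strand dead units.

## Network construction from co-occurrence counts

The package consumes a (drug, constituent, count) table of abstract
co-mentions — the retrieval step itself (e.g. an ESearch-style query per
pair) is outside scope, which keeps the pipeline offline-testable. Three
filters are applied in order, though they commute and are idempotent
(asserted as properties): counts must exceed a threshold (strict `> 20`
by default); pairs whose two names are identical after normalization
(Unicode NFC, casefold, whitespace collapse) are dropped, because many
constituents are themselves registered drugs; pairs whose names are
merely similar are dropped, because near-identical names co-occur for
lexical rather than pharmacological reasons. Name similarity is
normalized Levenshtein, `1 − dist/max(len)`, with removal at ≥ 0.8 —
the similarity function and cutoff for this filter are not standardized
anywhere, so both are explicit configuration with these defaults.
Surviving pairs become edges; counts are discarded.

Whole foods are represented by their constituents: a composition table
(food, constituent, content) is reduced to each food's top-k constituents
by content (default k = 20), ties broken lexicographically for
determinism.

## Evaluation protocol

20% of observed edges are held out (round-half-up), uniformly at random;
the propagation graph used by a fitted model contains training edges only,
and the evaluator raises a hard error if a held-out edge is found in it.
Test negatives are sampled 1:1 against test positives, uniform over
non-edges by default; a degree-matched mode (endpoints drawn proportional
to degree) is available and is the conventional way to evaluate the
preferential-attachment baseline without handing it the degree signal for
free. The ratio is configurable — evaluating against *all* non-edges is
possible but makes precision-type metrics scale-dependent.

Metrics: AUROC in the Mann–Whitney formulation (ties half-credit), AUPR
as average precision (mean precision at each positive's rank, stable
descending sort; the trapezoid variant gives slightly different values
and is deliberately not used), and F1/recall/precision after binarizing
`sigmoid(score) ≥ 0.5` (threshold configurable; with unbounded
inner-product scores the ranking metrics are the informative ones).
Repeats re-split with seeds `seed..seed+r−1` (default r = 5) and report
mean ± standard deviation.

Note that average precision of a *random* ranking exceeds the positive
prevalence at finite size (bias of order `1/n_pos`); the property test
that AP ≈ prevalence for shuffled labels therefore runs at n = 400.

## The synthetic generator

The generator plants the structure the model assumes, so recovery is a
meaningful end-to-end check. Drug and food latents have i.i.d. standard
Gaussian entries (dimension `d_lat`, default 8); edges are independent
Bernoulli draws with probability `σ(u·v + b)`, with `b` calibrated by
bisection so the expected density over the realized latents matches the
target exactly (realized densities then fluctuate within a few percent).
Unit-variance latents are a deliberate choice: they give the logit signal
a standard deviation of `√d_lat` ≈ 2.8, under which the Bayes-optimal
ranking of pairs by `u·v` reaches AUROC ≈ 0.95 on the default fixture —
a strong but not trivial planted signal, so a learner's recovery AUROC is
interpretable against a known ceiling. (Shrinking latents by `1/√d_lat`,
a superficially natural normalization, caps the Bayes AUROC near 0.61 and
makes *every* method look broken; we verified this numerically before
fixing the design.) Default density targets 0.059 and 0.025 mirror the
two reference DFI networks.

Attributes are `σ(latent·P + noise)` with a fixed shared random
projection `P` and Gaussian noise (sd `noise_sd`, default 0.1) applied in
logit space — bounded SSP-like rows whose information about the edges
degrades smoothly: held-out ridge regression from attributes to latents
gives R² > 0.5 at noise 0.1 and R² < 0.1 at noise 10 (asserted in tests).
Noise inside the squashing is essential to that second property: noise
added *after* squashing and clipped to [0, 1] acts as a noisy threshold
and retains substantial signal at any noise level.

What the generator does **not** emulate: real chemistry (SSP rows are not
fingerprint similarities), degree heavy-tails beyond what the low-rank
model induces, cold-start nodes, or correlated/textual noise in the
co-occurrence counts (count tables for the filter tests are fabricated
directly). Passing recovery tests therefore demonstrates that the
estimator recovers planted low-rank structure with informative bounded
attributes — not that it matches any particular curated network's
headline numbers.

## Problem sizes and observed behavior

The recovery experiment uses M = 100, N = 120, d_lat = 8, density 0.06,
ssp_dim = 256, noise 0.1 (≈ 720 edges), three random 80/20 splits, default
training — about 12 s per fit on one CPU. The fused model's mean test
AUROC is ≈ 0.85–0.90 depending on the fixture seed and clearly exceeds
the preferential-attachment baseline (≈ 0.63–0.70). Training dynamics on
this fixture are non-monotone in ranking quality: test AUROC peaks near
epoch 100, dips as the model over-sharpens on the ≈ 560 training edges,
and partially recovers by epoch 400 — the expected overfitting signature
of an expressive model on a small graph, and the reason a validation-based
stopper is the first extension a user with real data should enable.
Smaller configurations (e.g. 60 × 70 nodes, d_topo 16, hidden 64/32,
150 epochs) train in under a second and are used throughout the test
suite; the ablation check (fused ≥ topology-only mean AUROC when
attributes are informative) runs at that scale.

## Degenerate inputs and tie-breaks

- Empty graphs: density and loading raise explicit errors.
- Duplicate edges and duplicate co-occurrence pairs collapse silently.
- A drug adjacent to every food cannot yield a BPR negative; its
  positives are skipped with a warning.
- Negative sampling is exact (no rejection loops at the API surface):
  capacity is checked against the true non-edge count, and degree-matched
  mode errors if the request exceeds the positive-weight support.
- Content ties in food decomposition and score ties in AUPR break by
  lexicographic name and stable input order respectively.
- Checkpoints are single `.npz` containers holding Θ, the DNN weights,
  `K`, the loss history and a JSON echo of the config; round-trip is
  tested.

## Known limitations

- No GPU path; the numpy implementation is sized for networks of up to a
  few thousand nodes, matching real DFI datasets.
- The F1/precision/recall binarization of inner-product scores at
  sigmoid 0.5 is crude; ranking metrics are the primary outputs.
- The co-occurrence stage trusts its count table; no sentence-level
  relation extraction or negation handling.
- Entity normalization across vocabularies (drug synonyms, constituent
  naming) is out of scope; node identifiers are opaque strings.
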