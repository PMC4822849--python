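# Methods

## Scoring model

`fiprank` ranks genes by a random walk with restart (RWR) on an undirected
gene network. Writing `W` for the fused edge-weight matrix, `D` for the
diagonal matrix of its column sums and `e` for the restart prior, the score
vector is the fixed point of `q ← d·(W D⁻¹)·q + (1−d)·e`, solved in closed
form as

    Q = (1 − d) (I − d · W D⁻¹)⁻¹ e.

`M = W D⁻¹` is column-stochastic on nodes with positive degree, so on a
connected network a prior summing to one yields scores summing to one
(the Neumann series telescopes: `1ᵀ M^k e = 1` for every k). The model is
linear in `e`; rankings are therefore invariant to positive rescaling of the
prior, which is why the prior's default normalization (sum to 1) is a
convenience, not a modelling choice.

Two solvers are provided and cross-checked: a sparse LU solve of
`(I − d·M) Q = (1−d)·e` (default; the systems here are small) and the power
iteration from `q⁰ = e`, which converges geometrically at rate `d`. They
agree to well below 1e-8 at the tolerances used.

Degenerate cases: `d = 0` returns the prior exactly. `d = 1` is rejected
(singular system). Isolated nodes have no degree to normalize by; their
transition column is left zero, so they retain exactly their restart mass
`(1−d)·e_i` — the continuous limit of a vanishing degree — and are flagged
in the log rather than treated as errors.

## Edge weights

Each network edge carries `w = α·S′ + β·P′ + γ·F′` with coefficients in
[0, 1]; the all-zero combination is rejected as degenerate. Defaults
(α, β, γ) = (0.8, 0.5, 0.9) are the grid-search optimum from the thrombosis
application the method originates from; the grid-search utility re-derives
optima for other data.

**Interaction credibility S.** From per-pair literature co-occurrence counts
the weighted score is `C_ij = v_d·n_doc + v_p·n_para + v_s·n_sent`
(defaults 1, 2, 0.2), and

    S(i,j) = C_ij^t · (C_ij · C·· / (C_i· · C·j))^(1−t),   t = 0.6,

where the marginals `C_i·`, `C··` are always recomputed from the table
(never stored). The first factor measures evidence volume, the second the
pair's specificity; `t` interpolates between them, with `S = C_ij` at t = 1.
`S = 0` whenever `C_ij = 0`; a positive `C_ij` with a zero marginal is an
inconsistent table and errors. A sentence co-mention implies a paragraph and
a document co-mention, so `n_sent ≤ n_para ≤ n_doc` is enforced at load.
When the input network already carries an edge confidence (e.g. a combined
interaction score), that confidence, rescaled by its maximum to [0, 1], can
stand in for S directly.

**Co-expression P.** Sample Pearson correlation of the two gene rows over
the pooled control + disease samples (a single pooled `h` with the (h−1)
denominator; computing per group and averaging is *not* done — the pooled
form is what a single correlation over "all samples" means). Zero-variance
(flat) genes make the correlation undefined; they occur in practice, so the
value is set to 0 with a warning rather than erroring.

**Functional similarity F.** `F(i,j) = Σ_f 1/|Gene(f)|` over the GO terms
annotated to both genes — a flat shared-term sum; no ontology-hierarchy
semantics (Resnik/Lin-style measures are out of scope by design).

**Sign and scale decisions.** Propagation requires nonnegative weights, but
Pearson is signed and the literature on this fusion is silent about sign.
The default transform is `abs` (strong negative co-expression counts as
strong association); `clip0` and `raw` are offered for sensitivity analysis.
Similarly, S and F are unbounded count-derived scores while P is bounded;
by default each channel is min-max rescaled to [0, 1] over the network's
edges (`component_norm="minmax"`) so that α, β, γ act as comparable
importances; `"none"` reproduces the literal unscaled fusion. A constant
channel min-max rescales to zero — a channel with no variation carries no
information either way.

## Prior

`e_i = |Σ_control x_iy − Σ_disease x_iy|` over the harmonized expression
matrix. Note this uses group *sums*, not means, so with unbalanced groups a
gene flat at a high level acquires prior mass; the generator uses balanced
groups and real analyses should prefer balanced designs or pre-centered
data.

## Universe harmonization

The analysis universe is the intersection of network nodes and expression
genes after case normalization (symbols stored upper-case). Seeds outside
the universe are dropped and logged — mirroring how curated disease-gene
lists typically shrink when intersected with a network and a platform — and
candidates are the universe minus the surviving seeds. Duplicate expression
rows (multiple probes per gene) collapse by the arithmetic mean by default
(`max` optional); duplicate edges keep the maximum confidence; self-loops
are dropped.

## Validation harness

Because Q depends only on the prior and W — never on seed labels — removing
a seed does not change any score. LOOCV therefore needs a single
propagation: each seed in turn is ranked among candidates ∪ {itself}
(remaining seeds are excluded from the negative pool), giving rank `r_k`
among `n` genes. The pooled AUC uses the Mann–Whitney form

    AUC = 1 − mean((r_k − 1)/(n − 1)),

and a threshold-sweep ROC curve is emitted for plotting (FPR approximated
by the normalized rank, TPR by the empirical CDF of test-gene ranks). This
construction is a declared design choice — standard for rank-based
prioritization evaluation — not something the fused-weights literature
pins down. k-fold CV partitions seeds by a seeded shuffle and ranks each
fold as in LOOCV; with fold mates excluded from each other's negatives it
coincides with LOOCV for every k, and the machinery is retained for API
fidelity and determinism checks.

Grid search sweeps (α, β, γ) at step 0.1 by default and
d ∈ {0.1, 0.3, 0.5, 0.7, 0.9}, in two modes: `two_stage` (coefficients
swept at the default d, then d swept for the best combination — the
published procedure) and `joint`. Channels are computed once and only the
fusion + solve repeats per point, so per-point LOOCV AUC is cheap and on by
default. Selection: highest LOOCV AUC, ties broken by top-50 seed count,
then top-100, then lexicographically smallest coefficients for determinism.
The degenerate (0, 0, 0) point is skipped.

Ablations: (1) per-edge Pearson values reassigned from the pool of observed
values (permutation or bootstrap; applied to the transformed channel, which
is equivalent for a permutation since min-max bounds are order statistics of
the same pool), W re-fused, top-k seed counts recorded per repetition;
(2) S replaced by 1 on every edge and LOOCV re-run. Both are directional
checks: on data where the ablated channel is informative they should not
improve performance.

## Synthetic benchmark

The generator emulates the statistical structure the method assumes, on one
gene universe:

* **Network** — preferential-attachment backbone (attachment 3, giving mean
  degree ≈ 6 at n = 500, comparable edge density to curated interaction
  networks); a planted module of 30 genes whose internal edge probability is
  boosted to ~5× background; stray components (rare) are bridged so
  propagation behavior is not conflated with generator artifacts.
* **Expression** — Gaussian noise (SD 1) for 20 control + 20 disease
  samples; module genes share a latent factor (loading 0.7, within-module
  Pearson ≈ 0.33) and gain a one-SD shift in disease samples. One latent
  factor is the simplest mechanism giving tunable within-module correlation;
  no full covariance model is attempted.
* **Annotations** — each gene draws ~3 of 150 background terms; module
  genes are additionally annotated to each of 5 module terms with
  probability 0.5, inflating shared-term sums inside the module.
* **Co-occurrence** — per pair, document counts are Binomial(300, rate)
  with rate 0.08 on edges, 3× that on module-internal edges, and 0.01 on a
  sample of non-edges (as many as there are edges; W never sees non-edges,
  they only shape the marginals); paragraph and sentence counts are
  binomial thinnings (0.6, 0.4) of the document counts, so the containment
  hierarchy holds by construction. Counts are drawn per pair rather than by
  simulating individual documents — the per-pair marginal distribution is
  the same and the cost is linear in pairs. The module-internal rate boost
  exists so that the credibility channel is genuinely informative about the
  module (without it S separates edges from non-edges only, which the
  edge-restricted W cannot use).
* **Truth split** — 15 module genes are revealed as seeds; the other 15 are
  the hidden truth used only by evaluation.

Everything is deterministic given `rng_seed`. The `null()` condition
switches every module-specific signal off (no shift, no latent factor, no
density or co-occurrence boost, no term enrichment, equal co-occurrence
rates) while keeping the module labels, and calibrates to LOOCV AUC
0.5 ± 0.05 averaged over replicates.

What passing on this benchmark does *not* show: robustness to microarray
normalization artifacts, probe-level structure, batch effects, hub bias in
curated networks, or annotation incompleteness — none of which the
generator emulates. Results on it demonstrate correctness of the machinery
and the directional behavior of the channels, not real-data performance.

## Problem sizes and numerics

Tests and the acceptance script run at the generator's default scale
(500 genes, ≈1500–2500 edges) with 10–50 replicates per stochastic claim;
solver cross-checks use random networks up to 500 nodes. The direct solver
is exact to machine precision; the iterative solver's tolerance (1e-10
default, 1e-13 in cross-checks) leaves agreement far below the 1e-8 bound
asserted. Ties in rankings receive average ranks with lexicographic
secondary order so every output is deterministic.

## Known limitations

* The prior uses group sums (see above) and is sensitive to group imbalance.
* Min-max channel scaling depends on the network's edge set; adding edges
  can rescale all weights (rank effects are usually negligible but real).
* The shuffle ablation permutes transformed channel values; under the `raw`
  transform with replacement this differs slightly from resampling raw
  correlations first.
* k-fold CV adds no information beyond LOOCV here (scores are label-free);
  it exists for protocol compatibility.
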