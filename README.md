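# fiprank

Disease-gene prioritization by network propagation with restart over a
protein-interaction network whose edge weights fuse three similarity
channels. Given a set of *seed* genes already known to be associated with a
disease and an expression study with control and disease groups, `fiprank`
ranks every other gene in the network by disease relevance — the
guilt-by-association setting used, for example, to nominate candidate genes
for venous thromboembolism from whole-blood expression profiles.

## The model

Scores solve a random walk with restart on the gene network:

```
Q = (1 − d) · (I − d · W D⁻¹)⁻¹ · e
```

* `e` — restart prior: per gene, the absolute difference between its summed
  expression in control vs. disease samples (normalized to sum to 1);
* `W` — symmetric edge-weight matrix, `w_ij = α·S(i,j) + β·P(i,j) + γ·F(i,j)`
  on network edges and 0 elsewhere;
* `D` — diagonal of column sums of `W`, so `W D⁻¹` is column-stochastic and
  score mass is conserved;
* `d ∈ [0, 1)` — diffusion weight (default 0.9); `1 − d` is the restart
  probability.

The three channels are:

* **S(i,j)** — interaction credibility from weighted literature co-occurrence
  counts: `C_ij = v_d·n_doc + v_p·n_para + v_s·n_sent` (defaults 1, 2, 0.2)
  and `S = C_ij^t (C_ij C·· / (C_i· C·_j))^(1−t)` with `t = 0.6`; or, when the
  network ships precomputed confidences, those rescaled to [0, 1];
* **P(i,j)** — Pearson correlation of the two expression rows over the pooled
  samples (by default its absolute value, so strong negative co-expression
  counts as strong association);
* **F(i,j)** — shared functional significance: `Σ 1/|Gene(f)|` over GO terms
  `f` annotated to both genes.

Default coefficients `α = 0.8, β = 0.5, γ = 0.9` are the optimum reported for
the thrombosis application this method was developed on; a grid-search
utility re-derives such optima on any dataset. The validation harness
provides LOOCV/k-fold seed recovery with rank-based ROC/AUC, top-k seed
counts, and two ablations (shuffled Pearson values; unit credibility).
A synthetic planted-module benchmark generator makes the whole pipeline
testable without any external downloads.

## Worked example

```python
import fiprank as fr

bench = fr.generate_benchmark(fr.BenchmarkSpec(rng_seed=42))
scored = fr.score_genes(bench.network, bench.expression, bench.annotations,
                        bench.cooccurrence, bench.seeds)
ranking = fr.rank_genes(scored.q, scored.seeds, scored.candidates)
print(ranking.entries.head(5).to_string(index=False))
cv = fr.cv_from_scores(scored.q, scored.seeds, scored.candidates)
print(f"LOOCV AUC: {cv.auc:.4f}")
print("seeds in top 50:", fr.topk_seed_count(ranking, 50))
```

prints

```
 rank  gene        q  is_seed
  1.0 G0001 0.011437    False
  2.0 G0002 0.011095    False
  3.0 G0006 0.010820    False
  4.0 G0003 0.010605    False
  5.0 G0024 0.008959    False
LOOCV AUC: 0.9138
seeds in top 50: 9
```

The benchmark plants a 30-gene disease module in a 500-gene scale-free
network (15 module genes revealed as seeds); `q` is each gene's propagated
disease-relevance score. The AUC of 0.91 says that a held-out seed gene
almost always outranks a random candidate; 9 of the 15 seeds land in the
top 50 of the full ranking, and 11 of the 15 *hidden* module genes appear in
the top 100 — the guilt-by-association signal the method is built to
exploit.

The same workflow is available from the shell:

```
fiprank simulate --outdir bench/
fiprank rank --network bench/network.tsv --expression bench/expression.tsv \
    --groups bench/groups.tsv --annotations bench/annotations.tsv \
    --cooccurrence bench/cooccurrence.tsv --seeds bench/seeds.txt \
    --out ranking.tsv
fiprank validate ... --mode loocv --out cv.tsv
fiprank gridsearch ... --out grid.tsv
```

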