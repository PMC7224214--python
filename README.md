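# crminfer

Bayesian inference of cooperative **cis-regulatory modules (CRMs)** from
binary TF–gene binding events and gene expression data.

Transcription factors rarely act alone: context-specific combinations of
TFs co-bind promoters and enhancers and jointly drive transcription.
Genome-wide binding assays (ChIP-seq peaks mapped to genes, ATAC-seq motif
scans, curated databases) tell us *which* TFs can bind near a gene, but not
which combination is actually functional in a given cell state. `crminfer`
integrates a binary binding matrix with an expression matrix from the same
context and infers, for every gene, the posterior probability that each
candidate TF combination regulates it — together with latent TF activities,
signed regulation strengths, and a probabilistic TF–gene network. It is
aimed at computational biologists doing regulatory-network inference who
have gene-level binding indicators and a matched expression compendium.

## Model

Expression relative to baseline is multiplicative in TF activities, hence
linear after a log transform. With `y[n,m]` the log-transformed, per-gene
mean-centered expression of gene *n* in sample *m*:

```
y[n,m] = Σ_t a[n,t] · b[c_n,t] · x[t,m] + r[n] + e[n,m]
```

- `B = [b_{k,t}]` — candidate CRM matrix: each row a unique TF combination
  observed in the binding data, plus an all-zero *background* row for genes
  regulated by no candidate;
- `c_n` — index of the module assigned to gene *n*, uniform prior over the
  modules *compatible* with the gene's observed bindings (module TF set ⊆
  bound TF set);
- `x[t,m] ~ N(0, σ²_x)` — latent activity of TF *t* in sample *m*;
- `a[n,t] ~ N(0, σ²_a)` if TF *t* is in the gene's module (positive =
  activation, negative = repression), structurally 0 otherwise;
- `r[n] ~ N(0, σ²_r)` — baseline residual left by imperfect centering;
- `e[n,m] ~ N(0, σ²_e)` with a conjugate inverse-gamma(α, β) prior on σ²_e.

All full conditionals are closed-form (Gaussian / inverse-gamma /
categorical), and a multi-chain Gibbs sampler cycles through them. When a
gene's module is resampled, its strength vector is integrated out
analytically (the score of module *k* is the marginal likelihood
`y_n − r_n ~ N(0, σ²_a X_kᵀX_k + σ²_e I)`) and then redrawn as a block — a
collapsed move that crosses module sizes freely. Convergence is monitored
with the potential scale reduction factor over sign-invariant scalars, and
post-convergence sampling frequencies of modules are the posterior
regulation probabilities: calls use a 0.85 cutoff, CRMs are ranked by
target count, and `P(t → n)` sums the frequencies of modules containing
TF *t*.

The package also ships a synthetic-network generator (ground-truth modules,
strong/weak regulators, configurable expression noise and binding
false-positive/false-negative corruption) and an evaluation harness
(exact-match CRM precision/recall, target-gene AUC, TF–gene edge
F-measure), so the whole pipeline is testable without external data.

## Worked example

```
$ crminfer simulate --out sim --n-genes 40 --n-tfs 8 --n-targets 20 \
      --n-samples 20 --module-size 2 3 --noise-var 0.2 --fp-rate 0.1 --seed 7
simulated 40 genes x 8 TFs (20 targets, SNR 12.26 dB) -> sim

$ crminfer infer --binding sim/binding.tsv --expr sim/expression.tsv \
      --out run --pseudocount 0 --max-subset-size 3 --seed 7
40 genes, 8 TFs, 20 samples, 45 candidate modules
converged after 650 sweeps -> run

$ crminfer evaluate --run run --truth sim --out eval
CRM precision 0.889 recall 0.400; target AUC 1.000; edge F 0.854
```

The simulator drew 20 regulated genes (modules of 2–3 TFs), added Gaussian
expression noise (realized signal-to-noise ratio 12.26 dB) and corrupted
the binding prior with 10% spurious edges. Inference enumerated 45
candidate modules (observed binding patterns and their sub-patterns up to 3
TFs), ran 3 chains until the maximum PSRF dropped below 1.1 (650 sweeps),
then pooled 1000 sweeps per chain. Scoring against the generator's truth:
of the genes called at the 0.85 posterior cutoff, 88.9% were assigned
exactly their true TF combination (precision); 40% of all regulated genes
were confidently and exactly recovered (recall); ranking genes by posterior
probability of being regulated separates targets from background perfectly
(AUC 1.0); and thresholded TF–gene edges reach an F-measure of 0.854.

`run/` contains the ranked module list (`modules_ranked.tsv`), the
gene × module posterior frequencies (`module_gene_posterior.tsv`), the
TF–gene network (`tf_gene_network.tsv`), convergence diagnostics, and a
`config.json` snapshot that makes the run exactly replayable.

The same pipeline is available as a library:

```python
from crminfer import (benchmark_config, simulate_truth, add_noise,
                      perturb_bindings, to_expression_table,
                      log_transform_normalize, enumerate_candidates,
                      build_compatibility, Hyperparameters, ChainConfig,
                      run, evaluate_run)
```

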