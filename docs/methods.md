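# Methods

## Model

Gene expression is modeled relative to each gene's baseline. In the
original multiplicative form, expression of gene *n* in sample *m* is a
product of TF activities raised to regulation-strength powers; taking
natural logarithms gives the linear observation model

    y[n,m] = Σ_t a[n,t] · b[c_n,t] · x[t,m] + r[n] + e[n,m]

over the log-transformed, per-gene mean-centered expression matrix `Y`.
The base of the logarithm is a free choice (any fixed base rescales `a·x`
jointly); natural log is used throughout. Mean-centering per gene removes
the baseline for steady-state data; for time-course data a `--baseline-column`
option references each gene to a chosen sample first and the rows are then
re-centered, so the model's zero-mean residual assumption holds either way.
The sampled residual `r[n]` absorbs whatever the centering leaves behind.

Assumptions worth keeping in mind:

- binding is gene-level and binary — the model does not use peak heights,
  distances, or enhancer–gene maps;
- each gene is regulated by exactly one candidate module (possibly the
  background module); cooperative combinations are modeled, overlapping
  simultaneous modules are not;
- noise is i.i.d. Gaussian on the log scale with one global variance
  `σ²_e`, sampled with a conjugate inverse-gamma prior;
- TF activities are exchangeable across samples (no time-series
  structure).

## Candidate modules

Candidates are derived from the binding table. The default list is the set
of distinct non-zero gene binding patterns, plus the all-zero background
row; rows can be filtered by minimum module size (`min_tfs`) and by the
number of genes whose pattern contains the row (`min_gene_support`; both
default to 1). The matrix is ordered background first, then
lexicographically by member TF indices, which makes outputs deterministic.

When the binding prior is noisy, a gene's observed pattern may be a strict
superset of the combination that actually regulates it, and the pattern
itself is then the *wrong* candidate. `max_subset_size` therefore enables
enumeration of all sub-patterns of each observed pattern up to that size.
This is the recommended setting whenever false-positive binding edges are
expected (it is what the benchmark protocol uses, with the bound set to
the largest module size the generator produces); it grows K substantially,
so the sampler's assignment step is engineered to scale with the number of
*compatible* (gene, module) pairs rather than with K × N.

A module is compatible with a gene when every module TF binds the gene.
Assignments are sampled only over compatible modules, which keeps every
inferred network edge supported by the binding prior. A gene with no
non-background compatible module deterministically stays background.

## Gibbs sampler

All conditionals are conjugate. One systematic sweep updates, in order:

1. **Activities** `x[t,m]`: Gaussian, precision `1/σ²_x + Σ_n w_n²/σ²_e`
   with `w_n = a[n,t]·b[c_n,t]`; the M samples of one TF are conditionally
   independent and updated as a vector.
2. **Strengths** `a[n,t]` for active entries: scalar Gaussian conditionals,
   independent across genes for fixed *t*.
3. **Baselines** `r[n]`: Gaussian, precision `1/σ²_r + M/σ²_e`.
4. **Assignments** `c_n`: the default move integrates the gene's strength
   vector out analytically under its prior, scoring module *k* by the
   marginal likelihood `z ~ N(0, σ²_a·X_kᵀX_k + σ²_e·I)` with
   `z = y_n − r_n`, then redraws the strength vector from its exact
   multivariate conditional. This blocked/collapsed move mixes freely
   across nested modules of different sizes.
5. **Noise variance**: inverse-gamma with shape `α + NM/2` and scale
   `β + SSE/2`.

The residual matrix `E = Y − (A∘B_C)X − R` is carried incrementally
through all updates (tests assert agreement with recomputation to 1e-8).

An alternative assignment move, `score_on_current_strengths`, reproduces
the behavior of samplers that condition the module score on the current
strength values instead of marginalizing: strengths then persist for every
TF appearing in any of the gene's candidate modules (out-of-module entries
refresh from the prior, having no likelihood term), and candidates are
scored by the likelihood under those values. Both moves leave the same
stationary distribution invariant, but the conditioned variant crosses
between nested modules only through rare prior draws; its finite-run
sampling frequencies therefore concentrate on modules whose regulators are
currently well-fitted. It is retained for parity experiments; the
marginalized move is the default and is the one validated against
enumeration oracles.

### Numerical choices

- Module marginals are evaluated in the q-dimensional dual form
  (`q` = module size): Cholesky of `I_q + (σ²_a/σ²_e)·X_k X_kᵀ` with a
  1e-10 jitter, giving O(q²M) per score instead of O(M³). The same matrix
  over `σ²_a` is the strength conditional's precision, so its factors are
  reused for the blocked redraw.
- Assignment probabilities use log-sum-exp; the categorical draw is
  Gumbel-max, vectorized over genes via padded compatible-index matrices.
- Modules of equal size are batched through stacked (LAPACK-vectorized)
  Cholesky/inverse calls once per sweep.
- Non-finite values anywhere in a sweep abort with the offending block
  named.

### Initialization and convergence

Each chain starts from an independent draw: assignments uniform over
compatible sets, strengths and activities from their priors, the baseline
set to the per-gene mean leftover (so initial residuals have zero mean per
gene — exact by construction), and `σ²_e` from its prior.

Convergence is declared when the maximum potential scale reduction factor
(PSRF, within- vs between-chain variance) over monitored scalars falls
below 1.1, checked every 50 sweeps on the second half of the burn-in
history. Because the likelihood is invariant under jointly flipping the
sign of one TF's activities and strengths, raw `x` and `a` values are not
comparable across chains; the monitored scalars are `|x[t,m]|` and each
gene's active `Σ|a|`, which are invariant under that symmetry. Defaults:
3 chains, burn-in cap 5000 sweeps, 1000 collected sweeps per chain pooled
across chains. A run that hits the cap returns results flagged
non-converged (CLI exit code 3).

A known slow-mixing mode: a TF used by a single gene sits on a continuous
`a·x` scale ridge pinned only by the priors, and its `|x|` trace can keep
the PSRF above threshold long after module assignments have stabilized.
This is mostly a small-problem artifact — with many genes per TF the ridge
is well-pinned — and is why some tiny test fixtures cap the burn-in and
assert on assignments rather than on full convergence.

## Hyperparameters

| parameter | default | role / rationale |
|---|---|---|
| σ²_x | 1.0 | prior variance of TF activities; unit scale matches centered log expression |
| σ²_a | 1.0 | prior variance of regulation strengths; also sets the complexity penalty of larger modules in the marginal score |
| σ²_r | 0.1 | baseline residuals only absorb centering error, so a small variance |
| α, β | 1.0, 1.0 | weak inverse-gamma prior on σ²_e |
| cutoff | 0.85 | posterior sampling frequency needed to call a gene a module's target |
| edge cutoff | 0.85 | same threshold for TF–gene edges, separately configurable |
| PSRF threshold | 1.1 | standard "near 1" convergence bar |

All are exposed through the library and CLI.

## Synthetic data generator

`simulate_truth` draws a ground-truth network: `n_targets` of `n_genes`
genes each get one module of TFs (size uniform over `module_size_range`,
members drawn without replacement from `n_tfs` TFs). Each module contains
at least `n_strong_per_module` strong regulators with `|a| = 2 + |N(0,1)|`
and random sign; the remaining members are weak, `a ~ N(0,1)` truncated to
`weak_range` in absolute value. Activities are i.i.d. standard normal;
clean log expression is `A·X` with zero baseline. `add_noise` adds i.i.d.
Gaussian noise and reports the realized SNR in dB;
`perturb_bindings` corrupts the true edge set by deleting
`round(fn_rate·|E|)` true edges and adding `round(fp_rate·|E|)` absent
pairs — both rates are fractions of the true edge count, the convention
under which "adding 30% false positives" grows the edge list by 30%.
`to_expression_table` exponentiates, so simulated data enter the pipeline
through the same log-transform path as real data.

What the generator does *not* emulate: correlated TF activities,
count-based measurement noise (overdispersion, dropout), genes regulated
by more than one module, TF self-regulation, and binding priors whose
errors are biased rather than uniform. Passing the recovery tests
therefore demonstrates correctness of the inference under the model's own
assumptions, not robustness to everything real data can do.

## Benchmark protocol

The CRM-recovery study fixes: 160 genes, 20 TFs, 80 target genes, modules
of 2–6 TFs, 30% false-positive binding perturbation, expression noise
variance 0.5, three independently drawn networks, default chains, exact
TF-set match at the 0.85 cutoff. Two generator details are genuinely open
and are pinned in `benchmark_config` as the package's own choices:

- **Samples M = 40** — a typical expression-compendium size, and enough
  data that a weak regulator's contribution is resolvable against the
  marginal score's complexity penalty (~½·log(1 + σ²_a·M/σ²_e) per extra
  module dimension).
- **Weak strengths |a| ∈ [0.5, 2]** — "weak but non-zero" is taken to mean
  every weak regulator carries a real, in-principle-detectable signal. If
  weak strengths are allowed down to ~0.1, a module containing such a TF
  is statistically indistinguishable from the sub-module without it at any
  realistic M, the posterior legitimately splits between the two, and no
  sampler can (or should) call the full module with 85% confidence. The
  identifiability threshold is roughly `|a|² > σ²_e·log(1+σ²_a·M/σ²_e)/M`,
  ≈ 0.21 at these settings.

Inference on the benchmark enumerates sub-patterns (`max_subset_size=6`)
because 30% spurious binding edges corrupt roughly half of the target
genes' patterns, and without sub-pattern candidates those genes' true
modules are not in the candidate list at all.

One behavior of the exact collapsed sampler on this benchmark is worth
stating: confident calls are almost always exactly right, so CRM precision
runs close to 1 while recall is set by how many genes clear the 0.85
confidence bar. Samplers that condition on current strengths instead of
marginalizing tend to trade precision for recall here (confident superset
calls on corruption-affected genes); the flag above reproduces that regime
for comparison.

The binding-robustness study uses sparser networks (100 genes, 50 targets,
1–3 regulators per gene — median two, as in the common in-silico network
benchmarks) and sweeps false-negative rates 5–50% and false-positive rates
5–100%, one axis at a time, scoring thresholded TF–gene edges by
F-measure. False negatives physically remove edges from every candidate,
so edge recall — and hence F — is capped near `1 − fn_rate`; false
positives are largely rejected by the marginal score's complexity penalty,
so that axis stays nearly flat.

Problem sizes in the test suite (3 networks for the recovery study, one
network per robustness condition, 80-gene networks for the degradation
sweep, 2000-sweep burn-in caps on the zero-noise runs) were chosen to keep
the full suite under ten minutes on a single CPU while leaving the
Monte-Carlo error well inside the asserted tolerances.

## Evaluation

- **CRM identification**: a called (gene, module) pair is a true positive
  only if the called TF set *exactly* equals the gene's true module
  (strictest definition; a Jaccard partial-credit average is reported
  alongside). Precision divides by called pairs, recall by true target
  genes; background is excluded on both sides.
- **Target-gene AUC**: genes scored by `1 − freq[background]`,
  Mann–Whitney AUC against true target labels (ties count ½).
- **Edge F-measure**: TF–gene probabilities thresholded at the edge
  cutoff, compared to true edges; `F = 2PR/(P+R)`, defined as 0 when
  `P = R = 0`.
- CRM ranking ties break toward the smaller module, then lexicographic TF
  ids — deterministic outputs.

## Degenerate inputs and edge cases

- All-zero binding matrix: candidate enumeration warns and returns the
  background-only set; inference degenerates to per-gene noise fitting.
- Zero expression values with pseudocount 0: rejected with instructions to
  set a positive pseudocount (default 1.0 for count-like data; 0 is fine
  for strictly positive inputs).
- `fp_rate` requests exceeding the available non-edges: capped with a
  warning.
- Constant monitored scalar across chains: PSRF 1 by convention; chains
  stuck at different constants: +∞.

## Limitations

- One module per gene; no overlapping or combinatorially interacting
  modules.
- A single global noise variance; per-gene variances would be a
  straightforward extension but are not implemented.
- Sign of (a, x) pairs is not identifiable; only products, module
  assignments and fitted expression are interpretable. Posterior means of
  `X` and `A` are reported but should be read with that symmetry in mind.
- The candidate set is limited to observed patterns (and optionally their
  sub-patterns); a TF combination never observed in the binding data
  cannot be discovered.
- Sub-pattern enumeration is exponential in pattern size; the
  `max_subset_size` bound keeps it manageable but dense binding rows
  (many TFs per gene) will still inflate K quickly.
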