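# Methods

## Model

A catalog is an N×M matrix V of non-negative integer counts; row V^n holds
sample n's mutations over the M = 96 SBS categories (any M ≥ 2 is accepted).
Mutations are modeled as iid draws given the sample's latent cluster:

* cluster: c^n ~ Categorical(w), w ∈ Δ^{L−1};
* signature per mutation: z ~ Categorical(π^{c^n}), π^ℓ ∈ Δ^{K−1};
* category per mutation: o ~ Categorical(e_z), e_i ∈ Δ^{M−1}.

Because mutation order is irrelevant, the per-sample likelihood given a
cluster is the multinomial-mixture product f(V, π, e) = ∏_j (Σ_i π_i
e_i(j))^{V_j}, and the data likelihood is ∏_n Σ_ℓ w_ℓ f(V^n, π^ℓ, e).
Exposures are tied per cluster, not per sample: the free-parameter count
(L−1) + L(K−1) + K(M−1) does not grow with N, which is what makes maximum
likelihood well posed when samples carry only a handful of mutations.
A sample with zero mutations has likelihood 1 under every cluster; it is
retained and its posterior equals w.

## EM

The E-step computes responsibilities f^{n,ℓ} ∝ w_ℓ f(V^n, π^ℓ, e) in log
space and pools three expectation tables: expected emissions E_i(j), expected
per-cluster signature usage A_i^ℓ, and expected occupancy W_ℓ. The M-step
normalizes each table (rows of e, rows of π, and w respectively). After every
E-step, Σ_i E_i(j) equals the column totals of V and Σ_ℓ W_ℓ = N — these
conservation identities are asserted in the tests, as is the monotonicity of
the log-likelihood. In refitting mode e is set to the supplied signature
matrix and the e-update is skipped; only w and π are learned (and only their
(L−1) + L(K−1) parameters are counted in the BIC — fixed signatures are not
estimated).

Implementation notes:

* Duplicate count rows are collapsed to unique rows with multiplicities
  before training (panel catalogs repeat sparse rows often); the pooled
  statistics are mathematically identical, and an equality test enforces it.
* Count matrices with ≥ 32 categories and < 25% fill are held in CSR form;
  the two per-iteration matmuls then scale with the number of nonzeros.
* Per-category mixture probabilities that are positive are floored at 1e-300
  before the log; an *exact* zero with a positive count is a structural
  impossibility and yields −inf (an error where a finite answer is required,
  naming the offending sample or category).
* A cluster or signature whose pooled expectation is entirely zero keeps its
  previous parameters, with a warning, instead of dividing 0/0.

## Training protocol

Training runs R = 10 random restarts (5 per grid cell during model
selection); restart r draws w, the rows of π, and — in de-novo mode — the
rows of e from symmetric Dirichlet(1) using a generator seeded `seed + r`,
and the restart with the highest final log-likelihood wins. Each restart is
capped at 1000 EM iterations and stops early when the absolute
log-likelihood gain falls below `tol = 1e-6` or the relative gain below
`rel_tol = 1e-8`. The relative threshold is the operative one on cohort-scale
data (|loglik| ~ 1e5): at 1e-8 the fits converge in roughly 400–700
iterations, and tightening it further changes the log-likelihood by less
than one nat — far below any BIC margin or recovery threshold — while
roughly doubling the run time. Results are bit-reproducible for a fixed
seed.

Hyperparameters are selected by minimising BIC = size·log(n) − 2·loglik over
an (L, K) grid, where n is the **total mutation count** (mutations are the
iid units of the likelihood). Ties break towards smaller K, then smaller L.

## Inference

Per-sample exposures are either the best cluster's exposure row (hard) or
the posterior-weighted average Σ_ℓ f^{n,ℓ} π^ℓ (soft). Hard assignment is the
default for reporting clusters, soft for exposures; both are exposed, on a
relative (rows sum to 1) or count scale (rows sum to the sample's mutation
total). Posterior argmax ties break to the lowest cluster index.

## Synthetic data

`default_base_model()` is a fixed, documented stand-in for a rich
cohort-trained model: 10 clusters, 6 signatures, 96 categories, pinned to an
internal seed. Signatures are sparse Dirichlet(0.05) draws (pairwise cosine
< 0.4 — well separated, as SBS signatures largely are); cluster priors are a
moderately even Dirichlet(5) draw. Exposure rows emulate the "few dominant
processes" structure of real cohorts: the first four signatures are majors,
and each cluster puts ~99% of its mass on a distinct dominant subset of 2–3
majors (weights jittered around (0.68, 0.32) / (0.42, 0.33, 0.25)), with the
remainder spread as background — 0.002 on non-dominant majors and 0.0002 on
the two rare signatures. The small but non-zero background guarantees that
restricting a cluster to any signature subset never leaves an all-zero
exposure row.

Ground truths are subsampled from the base: clusters drawn without
replacement with probabilities w (priors renormalized), then K signatures
drawn without replacement with probabilities p_k = Σ_ℓ w_ℓ π^ℓ_k, exposure
rows restricted to the chosen signatures and renormalized (no
re-sparsification). With the default base the four majors are selected with
probability ≈ 0.99, so the subsampled truths stay well separated — the
regime in which parameter recovery is a meaningful test.

Per-sample mutation budgets are resampled uniformly with replacement from
`default_panel_budgets()`, a fixed list of 500 negative-binomial (r = 2)
totals clipped to ≥ 1 with mean ≈ 7 — emulating the overdispersed totals of
targeted-panel cohorts — or drawn Poisson(mean) for rich-data scenarios.

What the generator does *not* emulate: trinucleotide-context territory
differences between genome/exome/panel, sequencing error, signatures outside
the base set, and intra-cluster exposure heterogeneity. Passing the recovery
tests therefore demonstrates correctness of the estimation machinery under
the model's own assumptions, not performance on real cohorts.

## Downsampling

Poisson thinning keeps, per sample, a uniform without-replacement subset of
size min(Poisson(d), T_i) of its mutations (a multivariate hypergeometric
draw over the category counts). Region restriction keeps per-mutation records
whose 1-based position falls in a BED interval (0-based half-open: kept iff
start < pos ≤ end).

## Evaluation metrics

RE is the L1 distance between the row-normalized full profile and its
reconstruction E_d·S from exposures inferred on sparse data; ERE is the L1
distance between those exposures and row-normalized "true" exposures obtained
by NNLS on the full data. Both lie in [0, 2] per sample; the mean over
evaluable samples is reported, with zero-count or zero-exposure rows skipped.
Signature matching uses cosine similarity, either best-match (repeats
allowed) or a maximum-total-cosine one-to-one assignment; ties break to the
lower reference index. AMI uses the max-entropy normalization.

## Study-scale checks

The acceptance suite runs the pipeline at the scale the model targets:
5000 samples at ~7 mutations each (~34k mutations). Parameter recovery fits
the true (L, K) with 10 restarts and requires mean one-to-one cosine ≥ 0.97
over signatures and cluster exposure rows. BIC recovery runs the grid
L ∈ [L−2, L+2], K ∈ [2, 6] with 5 restarts per cell for true L = 5..9 and
requires ≥ 4 of 5 exact selections. The 5000-sample scale matters for the
BIC check specifically: the penalty for a fourth signature grows like
(L + M − 1)·log n while its likelihood evidence grows linearly in n, and at
2000 samples the penalty can win even when the signature is real (observed:
a true (7, 4) scored below (5, 3) at N = 2000 but above it at N = 5000).

The refitting benchmark mirrors the downsampling study design: 3 clusters
with *overlapping* Dirichlet(1) exposure rows over 4 well-separated
signatures (cohort refitting data are not crisply clustered), 300 samples at
Poisson(100) mutations, thinned to d = 6; the model is refit with the true
signatures on one half and evaluated on the other, against per-sample NNLS
on the same sparse counts. Aggregated over 10 seeds, soft inference ≤ hard
inference < NNLS on both mean RE and mean ERE. With crisply separated
clusters the soft/hard gap inverts (hedging across clusters costs accuracy
when posteriors are confident) — the overlapping-exposure design is the
regime the soft scheme is for.

## Known limitations

* The likelihood is non-convex; restarts mitigate but do not eliminate local
  maxima, and near-duplicate cluster exposure rows are not identifiable at
  panel sparsity.
* The model assumes exposures are constant within a cluster; real cohorts
  interpolate between cluster archetypes.
* BIC model selection is consistent but conservative at small mutation
  totals (see above); expect underestimated K below a few thousand samples
  of panel data.
* Catalog files are fixed to the canonical SBS-96 layout; other category
  systems are supported in memory but not by the readers.
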