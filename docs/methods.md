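# Methods

## Model and inference

`otutopics` fits latent Dirichlet allocation to a sample × taxon count table
under the document–sample analogy: samples are documents, genus-level taxa
are the vocabulary, and every count unit is one token.  Topic mixtures θ_d
and topic-taxon distributions φ_k carry symmetric Dirichlet priors with
concentrations α and β.  Inference is collapsed Gibbs sampling: θ and φ are
integrated out analytically and the chain moves over token-level topic
assignments with the standard conditional
p(z = k | ·) ∝ (n_dk + α)(n_kw + β)/(n_k + Vβ), the current token excluded
from all counts.

Assumptions worth stating: counts are exchangeable within a sample (no
spatial or temporal structure), samples are independent given the topics, and
raw counts enter the multinomial likelihood directly — no rarefaction or
normalisation, which would break that likelihood.  Token order inside a
document is fixed to ascending taxon index; the collapsed model is
exchangeable over token order, so this only pins down the sweep sequence for
reproducibility.

The per-iteration trace records the collapsed joint log P(w, z | α, β) as a
sum of Dirichlet-multinomial normalisers over documents and topics; it is
invariant under topic relabeling and is the quantity enumerated exactly in
the sampler-correctness tests.

### Estimators

Point estimates are the smoothed posterior means
θ̂_dk = (n_dk + α)/(n_d + Kα) and φ̂_kw = (n_kw + β)/(n_k + Vβ), averaged
over post-burn-in states taken every `sample_lag` iterations (the first
post-burn-in state is always retained).  Averaging reduces Monte-Carlo
variance relative to a single final state; note that averaging across states
is only meaningful within one chain, where label switching is rare on
well-separated data.  Topic labels are arbitrary across chains and folds, and
no alignment is attempted — all cross-run comparisons in the package use
permutation-invariant quantities (perplexity, likelihood) or explicit
best-permutation matching in the tests.

### Parameters and defaults

| parameter | default | meaning |
|---|---|---|
| K | chosen by CV | number of topics / sub-communities |
| α | 50/K | Dirichlet concentration on θ (Griffiths–Steyvers convention) |
| β | 0.1 | Dirichlet concentration on φ |
| n_iter / burn_in / sample_lag | 2000 / 1000 / 10 | sweep schedule |
| presence threshold | 0.05 | θ̂ cutoff for a topic to count as observed |
| φ display threshold | 0.01 | cutoff defining a topic's dominant taxa |

The 0.05 and 0.01 cutoffs are applied strictly (an entry exactly at the
threshold is *not* retained), matching the display convention that points
with probability *no more than* the cutoff are hidden.

A caution on α at small K: with the 50/K convention the smoothing floor of
θ̂ is α/(n_d + Kα); at K = 4 and 200 counts per sample this floor sits at
exactly 0.05, the presence cutoff, making presence calls for truly absent
topics a coin flip on sampler noise.  Analyses at small K with moderate
sequencing depth should use a smaller α; the validation suite uses α = 1,
which also matches the synthetic generator's mixing prior.

### Randomness and reproducibility

The sweep kernels are numba-compiled and draw from numba's global MT19937,
seeded once at the start of every operation; sweeps visit tokens in
document-major order.  Identical (corpus, hyperparameters, schedule, seed)
therefore give bit-identical assignments, estimates and output files —
checked at byte level on whole pipeline runs.  Per-(K, fold)
cross-validation seeds are derived from the master seed through
`numpy.random.SeedSequence([master, K, fold])`, so cells are independent
chains yet fully reproducible.

## Preprocessing

Default pipeline order: drop samples with fewer than `min_taxa` (2) detected
taxa → drop taxa present in fewer than `min_prevalence` (2) samples → drop
taxa with mean per-sample relative abundance below 1e-4 → optional
vocabulary selection by corpus-level tf-idf, score(w) = total count ×
ln(D/df(w)).  This order guarantees nonzero sample totals before any
relative-abundance arithmetic.  Filters only delete rows/columns, never edit
surviving counts, and are idempotent.  The tf-idf variant is the
corpus-level one used for LDA vocabulary pruning (a taxon present in every
sample scores 0 and is the first to go under `min_score`); per-document
averaging is a documented alternative not implemented.  Thresholds are
strict on the tf-idf side (score > value kept) to make edge cases
deterministic.

## Model selection

Folds partition *samples* (the exchangeable unit), never tokens; test-set
sizes differ by at most one.  For each candidate K and fold, the model is fit
on the training samples with the vocabulary unchanged, θ for test samples is
re-estimated by fold-in (Gibbs with φ̂ fixed, conditional ∝ (n_dk + α)φ_kw;
first half of the fold-in sweeps discarded as burn-in, smoothed θ averaged
over the rest), and held-out perplexity exp(−mean per-token log-likelihood)
is recorded, with held-out log-likelihood = −ln(perplexity) × test tokens.
Test taxa unseen in training still receive β mass through the smoothed φ̂,
keeping perplexity finite and comparable across K.

Selection rules: `min_mean_perplexity` (default; ties to the smaller K) and
`one_sd` (smallest K within one standard deviation of the minimum).  On data
with well-separated topics the perplexity curve typically drops steeply up
to the generating K and then *plateaus*; the minimum rule may then land
anywhere on the plateau, and reading the elbow (or using `one_sd`) is the
better scientific practice.  Both metrics are reported so either rule can be
applied after the fact.

## Quetelet Index

A topic is observed in a sample when θ̂_dk > 0.05.  For topic k and group g,
QI_kg = f(k | g)/f(k | all) − 1 on those presence calls.  Properties used as
test invariants: group frequencies weighted by group size average to the
overall frequency (so a topic's indices cannot all be strictly positive);
QI ∈ [−1, N/support − 1]; QI is invariant to sample order and group
renaming.  A topic present nowhere has an undefined index, reported as
missing — never as 0.  An alternate continuous-mass mode (mean θ in group /
mean θ overall − 1) is deliberately not the default: the presence-frequency
reading follows the index's classical definition on observation frequencies.

An optional permutation test shuffles status labels jointly across topics
(preserving inter-topic correlation) and reports two-sided
p = (1 + #{|QI*| ≥ |QI|})/(1 + n_perm).

## Topic interaction and map

Dominant-taxon sets (φ̂ > 0.01) are compared by Jaccard overlap (0 when both
sets are empty).  Inter-topic distance is the square root of the
Jensen–Shannon divergence, base 2 — a true metric on [0, 1], computed via
`scipy.spatial.distance.jensenshannon` and cross-checked in the tests
against an independent entropy computation.  The 2-D map uses classical
(Torgerson) MDS — double-center −½D², take the top two eigenpairs, scale by
√eigenvalue — implemented directly because the deterministic classical
variant (not iterative SMACOF) is required for reproducibility.  Axis signs
are fixed by making each axis's first nonzero loading positive; negative
eigenvalues beyond tolerance (non-Euclidean input) are recorded as a warning
in the output metadata, and alternates for both the overlap statistic and
the distance can be swapped in because the choices are recorded with the
outputs.

## Synthetic data

The generator draws directly from the model above (`generate_corpus`) or
with a planted label association (`generate_labeled_corpus`): samples are
assigned to groups round-robin, and a group's enriched topic has its
Dirichlet concentration scaled by a multiplier before θ is drawn, so
enriched data remain inside the model family.  Defaults: α = 1 (uniform on
the mixture simplex), β = 0.1, 1000 counts per sample (a realistic
genus-level depth); presets `oral-like` (40 × 90) and `gut-like`
(150 × 180) mirror typical oral and gut study shapes.

What the generator does *not* emulate: zero inflation, compositional
artifacts, sequencing error, or phylogenetic correlation between taxa.
Passing tests on synthetic data therefore demonstrate correctness of the
inference machinery under the model's own assumptions, not robustness to the
ways real microbiome data violate them.

## Validation problem sizes

The validation suite works at sizes chosen to make each property sharply
testable while keeping the whole suite fast: exact-enumeration checks on
corpora of ≤ 6 tokens (64 assignments, 200k sweeps); parameter recovery at
K=3, V=30, D=100, 200 counts/sample with well-separated topics (generator
β = 0.01), requiring best-permutation mean total-variation error < 0.1;
model-selection sanity at D=120 over five replicate seeds; Quetelet
validation at K=4, D=100 with a 20× planted enrichment, where the computed
indices must equal an independent contingency tabulation exactly.

## Known limitations

- Single-chain inference; no convergence diagnostics beyond the likelihood
  trace, and no hyperparameter optimisation (fixed-point α/β updates are out
  of scope).
- Perplexity-based selection is flat beyond the true K on separable data;
  the default rule can overshoot (see Model selection).
- The Quetelet Index is a descriptive association measure on thresholded
  presence calls; it adjusts for no covariates and its permutation p-values
  are companions, not a replacement for a regression framework.
- BIOM support is limited to BIOM TSV exports; binary/JSON dialects are out
  of scope.
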