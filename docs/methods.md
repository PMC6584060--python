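# Methods

## Data model

The unit of analysis is a features × samples matrix of methylation beta values
β ∈ [0, 1] with opaque string IDs for CpG probes and samples, paired with a
label per sample in {allergic, sensitized, neither}. "Neither" samples (no
sensitization, no allergy) carry no information for the two-class problem and
are removed before any split; a skin-prick test performs the equivalent triage
clinically. Values are assumed pre-normalized; the loader rejects out-of-bound
values, duplicate IDs, and missing cells (optional per-feature mean imputation
is available behind a flag, default off, since missingness handling is
dataset-specific and defaults should fail loudly).

## Fold geometry

Each fold partitions the cohort into train / cross-validation / hidden sets of
fixed even sizes (default 40/10/8 on 58 samples) with exactly half of each set
from each class. Hidden sets across folds are drawn per class from a shuffled
queue consumed without replacement and reshuffled on exhaustion; with
n_folds × hidden_size ≥ n this constructively guarantees that every sample is
hidden at least once, which is the property the whole "hidden accuracy"
scoring rests on. The remaining samples of a fold are split randomly (per
class) into train and cross-validation. A pigeonhole check rejects infeasible
requests up front and names the minimum feasible fold count.

Seeding: a single master seed is fanned out to child seeds by hashing a token
path (stage, fold index, feature set, …). Consequences worth knowing: adding
folds or repeats never perturbs earlier ones, and partial CLI re-runs match
full runs bit for bit.

## Moderated t ranking

With ~20 training samples per class, per-CpG variances are noisy, so features
are ranked by the empirical-Bayes moderated t: the pooled two-sample variance
s²_g (d_g = n₁+n₂−2 df) is shrunk toward a prior s₀² with weight d₀,

  s̃²_g = (d₀ s₀² + d_g s²_g) / (d₀ + d_g),  t̃_g = Δ̄_g / (s̃_g √(1/n₁+1/n₂)),

where (d₀, s₀²) solve the method-of-moments equations on log s²_g (trigamma
inversion by bisection on d₀ ∈ (10⁻², 10⁶]; if the excess variance of
log s²_g is non-positive the fit degenerates to d₀ = +∞ and all variances
equal s₀²). The implementation is validated in the test suite against
Bioconductor limma's `lmFit`+`eBayes` on the same matrix (agreement to ~1e-9
on t, d₀ and s₀²). Statistics are always computed on the training cohort
only. Ranking is by |t̃| descending (residual df are constant across features,
so this matches ordering by moderated p-value); ties break by feature ID for
determinism.

Per-fold top-K lists (K = 99 by default) are merged into a unique pool
ordered by (occurrence count across lists desc, mean 1-based position asc,
feature ID). The order is cosmetic — every pooled feature is subsequently
evaluated on its own — but is fixed exactly so runs are reproducible.

## Classifier families and the accuracy score

Four families are fitted per (fold, feature set): CART decision tree (Gini,
minimum leaf 2), L2 logistic regression (C = 1), an RBF network, and an MLP
with two hidden layers of ten logistic units. The RBF network is built
in-repo: k-means (2 centers per class) on the training rows, Gaussian basis
functions with widths set to the within-cluster RMS distance (floored at
10⁻³), and a logistic output layer on the activations — the construction
mirrors classic RBF-network practice. The MLP uses full-batch SGD, constant
learning rate 0.3, momentum 0.2, 500 epochs, and **no early stopping**: on
near-separable one-dimensional inputs the loss sits on a plateau for tens of
epochs before dropping, and tolerance-based stopping would freeze the network
at chance level. All fits are deterministic given the derived child seed.

Per fold, the family with the highest cross-validation accuracy is selected;
exact ties resolve by the fixed preference MLP > LR > DT > RBF. Only the
selected model is scored on the hidden cohort (accuracy at the 0.5 probability
threshold, ties to allergic; AUROC by the Mann-Whitney rank formulation with
half-credit ties). The *accuracy score* of a feature set is its mean hidden
accuracy across folds. Hidden samples are provably untouched by fitting and
selection (disjointness is asserted at evaluation time).

## Screening and sequential forward selection

All pooled singletons are scored; those at or above the screen threshold
(default 0.75) form the shortlist. The forward search then extends each of the
top-`beam` (default 25) sets of size s−1 by every shortlist feature not
already present, deduplicates unordered sets, keeps at most `cap_per_size`
(default 200) candidates ranked by parent score, and scores each from scratch
with fresh per-fold retraining. Every size up to `max_size` (default 12) is
evaluated; a perfect score never short-circuits the search, so the per-size
summary (best score, top-5 mean score and AUROC) is always complete. With an
unlimited beam and cap the search provably reduces to exhaustive enumeration,
which the test suite checks on a four-feature shortlist.

## Ensembles

Members (feature sets, ordered by accuracy score, ties by ID) vote on each
hidden sample; odd sizes 1–101 are evaluated by default, and exact ties under
even sizes default to the allergic class. The steady-state value is the mean
accuracy over sizes at or above a convergence size (default 29, exposed in
config because the plateau onset is dataset-specific). For independent members
with individual accuracy above chance the vote accuracy rises with size
(Condorcet behavior); the test suite demonstrates the effect with 31
independently planted features of ~0.7 individual accuracy.

## Validation and signature extraction

A candidate signature is re-evaluated over `n_repeats` (default 200)
independent random reallocations of the samples into balanced 40/10/8
cohorts, each with fresh per-fold family selection. The summary reports the
mean hidden accuracy and AUROC and a Student-t 95% CI, mean ± t₀.₉₇₅,ₙ₋₁·sd/√n
on the percent scale; with zero variance the interval degenerates to a point.
A t-interval was chosen because the per-repeat accuracies are a mean of
exchangeable repeated evaluations and the interval is symmetric and standard;
the CI width empirically shrinks like 1/√n, which the tests verify at a
doubling of n.

The signature report tallies how often each CpG occurs across the "top"
classifiers — by default all sets reaching one of the two best distinct
accuracy scores, a config knob (`signature_score_levels`) since any fixed
count is dataset-specific — and maps the union to gene symbols from the
annotation table. Pseudogene groups listed in the annotation are counted as a
single gene; the merge is table-driven, never hard-coded.

## Synthetic data generator

Values are inverse-logit transforms of Gaussians: feature g has baseline
logit-mean μ_g ~ N(0, 1.5) (spanning low/intermediate/high methylation and
producing the U-shaped beta marginal typical of arrays), and sample values
logit⁻¹(μ_g + ε), ε ~ N(0, noise_sd). Planted features add ±effect_delta to
the allergic class on the logit scale, alternating sign so both hyper- and
hypo-methylated markers occur. The logit-normal choice keeps effects linear on
the M-value scale while guaranteeing values strictly inside (0, 1). Defaults:
29 samples per class (the cohort size of the motivating two-class design),
5,000 features (desk scale; the generator handles full-array sizes),
noise_sd 0.5 and effect_delta 1.0 — a moderate, realistic per-CpG shift.
Planted indices come from a child RNG stream separate from the value stream,
so generation with effect_delta = 0 is bit-identical to all-null generation
under the same seed.

What the generator does **not** emulate: probe-type chemistry effects, batch
effects, cell-composition confounding, and spatial correlation among CpGs.
Passing tests therefore demonstrate the pipeline's statistical mechanics
(ranking recovery, selection behavior, ensemble gains, CI calibration) — not
performance claims about any real cohort.

## Numerical choices and degenerate inputs

- Zero mean difference yields t̃ = 0 exactly regardless of variance.
- Features with zero pooled variance get finite t̃ through the shrunken
  variance whenever s₀² > 0.
- The `prior_df` override (0 → ordinary pooled t, +∞ → fully pooled
  variances) exists for analysis and testing.
- k-means center counts are capped at the number of distinct training points
  per class; RBF widths are floored to avoid singular bases.
- Constant features make trees vacuous (majority/tie prediction) rather than
  erroring.
- All TSV artifacts are written with 17-significant-digit floats and read
  back with exact round-trip parsing, so write∘read is the identity.

## Problem sizes in the shipped tests

The test suite and demo configs run the pipeline at reduced scale — thousands
of features, shortlists of tens, forward selection to size 3, reduced MLP
epoch budgets — chosen so the full suite exercises every stage end to end in
a few minutes on one core. All sizes are ordinary config parameters; the
pipeline runs unchanged at the full defaults (636-candidate screens,
12-feature search, 101-member ensembles, 200 reallocations), which is a
multi-hour workload.

## Known limitations

- The search is greedy/beam-restricted; a smaller perfect signature may exist
  outside the explored frontier (exhaustive search over all subsets is
  intractable by design).
- Family selection by cross-validation accuracy on 10 samples is coarse; ties
  are common and the fixed preference order matters in practice.
- The four family definitions leave genuine freedom (tree pruning, RBF
  construction details, MLP epoch schedule); the defaults here follow common
  Weka conventions and are all exposed in `ModelConfig`.
- No covariate stratification (age, sex) in fold construction.
- Gene mapping is annotation-table-driven only; no enrichment analysis is
  included.
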