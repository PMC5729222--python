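# Methods

## Model and assumptions

Each class (healthy, diseased) is modelled by a single Dirichlet-multinomial
(DM) distribution over taxon read counts. The DM arises by drawing a
sample's taxon proportions from a Dirichlet with concentrations
α = (α₁, …, α_T) and then drawing N reads multinomially, giving

    log P(s | α) = log N! − Σ_t log s_t!
                 + log Γ(A) − log Γ(A + N)
                 + Σ_t [log Γ(α_t + s_t) − log Γ(α_t)],    A = Σ_t α_t.

We use the composition/overdispersion parameterization common in microbiome
statistics: π_t = α_t / A (expected proportion of taxon t, Σπ_t = 1) and
θ = 1/(1 + A) ∈ (0, 1). θ measures extra-multinomial between-sample
variation: the variance of a taxon's proportion at depth N is
π_t(1−π_t)[θ + (1−θ)/N], so θ → 0 recovers the multinomial and larger θ
more heterogeneous communities. Typical stool 16S data sit around
θ ≈ 0.005–0.05.

Assumptions worth keeping in mind: one DM component per class (no mixture
structure within a class); taxa interact only through the shared Dirichlet
(no pairwise correlation structure beyond compositional coupling); and
sequencing depth N is treated as fixed per sample and uninformative about
class. Depths are never rarefied — the likelihood conditions on each
sample's own N, so unequal depths are handled natively.

## Maximum-likelihood fitting

`fit_dm` maximizes the DM log-likelihood over α for one class's rows.

* **Initializer** — method of moments: π⁰ is the pooled proportion vector;
  θ⁰ comes from the ANOVA-style moment estimator contrasting between-sample
  and within-sample mean squares of proportions (clipped to
  [10⁻⁶, 1−10⁻⁶]).
* **Updates** — Newton–Raphson on α. The Hessian is diagonal plus rank one,
  so the Newton step is closed-form via Sherman–Morrison. Whenever the
  Newton candidate leaves the positive orthant or lowers the likelihood,
  the iteration falls back to the monotone fixed-point update
  α_t ← α_t · Σᵢ[ψ(α_t+s_it) − ψ(α_t)] / Σᵢ[ψ(A+Nᵢ) − ψ(A)].
  In practice Newton accepts after the first iteration or two and
  convergence takes well under ten iterations.
* **Convergence** — |Δ log L| < 10⁻⁸ or 500 iterations. The returned
  log-likelihood is never below the initializer's (only improving steps are
  accepted) and the gradient is numerically zero at interior optima.
* **Boundary** — θ estimates are clamped to [10⁻¹⁰, 1−10⁻¹⁰]. A fit ending
  below θ = 10⁻⁷ is a boundary solution (the data are
  multinomial-compatible and the θ-MLE sits at 0, e.g. identical rows); it
  is returned with `converged=False` and parameters clamped inside (0, 1).
* **Unseen taxa** — a taxon with zero total count in a class's training
  rows would get α_t → 0 and assign −∞ log-likelihood to any test sample
  containing it. Its concentration is floored at ε = 0.5 / (total reads in
  the class), the minimal intervention that keeps every test likelihood
  finite while leaving observed taxa essentially untouched.
* All likelihood arithmetic is in log space with log-gamma/digamma
  functions; no factorial is ever evaluated directly.

The fit is validated in the tests against a brute-force Pólya-urn
enumeration of the pmf (exact for small T, N) and a grid-search check that
no (π, θ) grid point beats the returned optimum.

## Posterior classification

`posterior` applies Bayes' rule with the per-class DM likelihoods and a
class prior, normalizing via log-sum-exp so that arbitrarily deep samples
(log-likelihoods of order −10⁵) remain exact. The prior is either the
empirical class frequency of the training labels or a user-supplied pair of
probabilities (e.g. a published disease prevalence); degenerate priors
containing exactly 0 or 1 are rejected. The scalar score used for ranking
and ROC analysis is the diseased-class posterior probability. Only binary
classification is exposed; the internal machinery keeps the class dimension
general.

## Taxon ranking

Each taxon's abundance is compared between classes with a two-sided
Mann-Whitney U test on raw counts (a `rank_on_proportions` flag rank-tests
relative abundances instead, which matters when depths differ strongly and
systematically between classes). The exact null distribution is used when
both groups have ≤ 12 samples and the pooled values are tie-free; otherwise
the normal approximation with tie and continuity correction. A taxon with
identical values in all samples gets P = 1. No multiple-testing correction
is applied: the P values only order the taxa, and each candidate set is
re-evaluated by cross-validation anyway. Ties in P are broken toward the
larger absolute difference in mean relative abundance, then column order,
so rankings are deterministic.

## Signature-taxon selection

Candidates are the taxa with P strictly below the threshold (default 0.5).
For k = 1 … candidate_count the top-k taxa are kept individually and all
remaining taxa merged into a single "other" column; the merge preserves
every sample's total read count exactly, and when k covers all taxa a
structurally zero "other" column is still appended so fitted models always
have k+1 columns. Each round is scored by leave-one-out cross-validation:
the held-out sample is scored by DM fits on the remaining samples (the
other class's fit is cached and the held-out class refitted warm-started;
empirical priors are recomputed within each fold excluding the held-out
sample; a fold whose fit degenerates falls back to the method-of-moments
estimate with a logged warning). The best round is the smallest k attaining
the maximal AUC — a parsimony tie-break, since AUC ties across nested
candidate sets are common when separation saturates. Final per-class
parameters are refitted on all training rows reduced to the winning
columns.

By default the ranking is computed once on the full training set and the
LOOCV only re-estimates DM parameters per fold. This mirrors the method's
natural order (rank, then cross-validate) but leaks the held-out sample
into the *feature choice*, which matters for honest error estimation on
weak signals: on null data (identical class parameters, 20 taxa, 30
samples per class) the best-round LOOCV AUC has median ≈ 0.66–0.68 rather
than 0.5 — partly this leakage, partly the maximum over ~10 correlated
rounds, which is itself a selection. The acceptance script computes this
null figure (`null_best_auc_median`) so the bias is visible rather than
hidden; a strict `rerank_per_fold=True` mode re-ranks taxa inside every
fold and removes the leakage component (the max-over-rounds optimism
remains). With a fixed candidate set the LOOCV AUC is unbiased to slightly
pessimistic, as leave-one-out estimates generally are. Treat the selection
trace's best AUC as a model-selection criterion, not an unbiased estimate
of generalization AUC; for the latter, score an untouched test set with
`predict`.

## Prediction on new samples

New tables are mapped to the model by taxon *name*: signature taxa are
matched by name (absent ones contribute zero counts), all unmatched taxa
are summed into the "other" column, and a table sharing no names with the
training taxa is rejected as a likely taxonomy-level mismatch. Hard calls
take the posterior argmax, with exact ties called diseased and flagged.
The positive ("diseased") class is the lexicographically second label
unless named explicitly; it is recorded in the model file so AUC signs are
unambiguous. Models serialize to a versioned JSON document (signature
taxa, per-class π/θ, prior, threshold, selection trace, input hash, seed,
package version) whose float fields use shortest round-trip repr, making
training byte-deterministic for fixed inputs.

## ROC and AUC

Two independent AUC routes are maintained deliberately: the trapezoidal
integral of the threshold-swept ROC curve (anchored at (0,0) and (1,1) so
constant scores are well defined) and the midrank formula
(Σ ranks_pos − n₁(n₁+1)/2)/(n₁n₀). With ties counting 0.5 per
positive-negative pair the two agree to machine precision, which the tests
check against a brute-force all-pairs count.

## Synthetic data

`simulate` draws labelled two-class datasets by the same
Dirichlet-then-multinomial process the classifier assumes, with the ground
truth (compositions, overdispersions, signal-taxon indices, seed) returned
alongside the table. Defaults model a modest 16S case-control study:
20 taxa, 25 samples per class, θ = 0.01 for both classes, and per-sample
depths log-normal around a geometric mean of 2000 reads (σ = 0.3),
emulating uneven library sizes; a fixed integer depth is available where
exact row totals are wanted. `planted_spec` places signal as balanced
high/low swaps (taxon 0 at proportion 0.25 healthy / 0.05 diseased, taxon 1
the reverse) so that the non-signal taxa have *identical* compositions in
both classes — without the swap, compositional renormalization would make
every taxon a signal taxon. `null_spec` uses identical parameters in both
classes. Because the generator matches the model family exactly, passing
tests demonstrate correctness of the machinery, not robustness to the ways
real data deviate (taxon correlations, mixture structure within a class,
mis-assigned reads); the strong planted signal (≈4σ separation per signal
taxon at these settings) makes selection essentially deterministic, which
the tests exploit.

## Problem sizes and numerical choices in the test suite

Parameter-recovery runs use T = 10, θ = 0.01, 200 samples at depth 5000
(median L1 error of π̂ ≈ 0.015, median relative error of θ̂ ≈ 3–6%);
selection behaviour is measured over 20 simulation seeds for planted and
null conditions; pmf oracles enumerate all count vectors with T ≤ 3,
N ≤ 6. Exhaustive checks (pmf normalization, AUC route agreement,
depth conservation) use tolerances 10⁻¹⁰–10⁻¹², estimator checks the
tolerances a moment's calculation of the sampling noise suggests.

## Known limitations

Single DM per class (no within-class substructure); binary labels only;
rank-once selection inflates the best-round cross-validated AUC on weak or
null signals (see above); the Mann-Whitney ranking ignores covariates such
as age or sex; and maximum-likelihood point estimates ignore parameter
uncertainty — a fully Bayesian treatment over (π, θ) would propagate it
but is not implemented.
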