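# Methods

## Data model

Three kinds of expression signature flow through the package, all
unitless per-gene changes versus a control:

- **Perturbation signatures** x ∈ ℝᵖ: mean expression change after
  knocking down (proxy for inhibition) or overexpressing (proxy for
  activation) one gene in one cell line.  Raw profiles arrive one per
  (replicate, time point, dose); aggregation takes a single unweighted
  pooled mean over all profiles of a (perturbed gene, cell line) pair.
  Pooling in one mean rather than nesting (mean over replicates, then
  over times, then doses) is a deliberate simplification: the two differ
  only for unbalanced group sizes, and the flat mean is reproducible
  without knowing the nesting.
- **Disease signatures** z ∈ ℝ^q: per-gene mean over the patient-specific
  differential-expression profiles of a disease (consumed as given; the
  differential-expression method that produced them is out of scope).
  Disease signatures exist in two restrictions: the full gene universe
  feeds disease–disease similarity, and the d-gene restriction to genes
  shared with the perturbation data feeds scoring.  Gene matching is
  exact, case-sensitive symbol intersection; no alias resolution.
- **Labels** y_{m,i} ∈ {0,1}: curated target–disease associations,
  separately for inhibitory (knockdown) and activatory (overexpression)
  modes.  Pairs absent from the curation are treated as negatives.

## Disease graph

S_{ij} is the cosine similarity of full-gene disease signatures.  Because
signatures are signed, S can contain negative entries, which would make
the degree normalization K^{−1/2} ill-defined; negative entries are
clamped to zero before computing K_{ll} = Σ_m S_{lm} (self-similarity
included, so degrees are strictly positive for any nonzero signature) and
Lₛ = K^{−1/2}(K − S)K^{−1/2}.  The unclamped S is retained for reporting.
Clamping, rather than shifting or taking absolute values, preserves the
intended semantics that only *similar* diseases share weights;
anti-correlated diseases are simply uncoupled.  Lₛ is symmetric PSD with
eigenvalues in [0, 2].

## Trans-disease model

The model is linear per disease, fₘ(x) = wₘᵀx, with the joint objective

    Σₘ Σᵢ log(1 + exp(−ỹ_{m,i} wₘᵀxᵢ)) + λₛ·½Tr(W Lₛ Wᵀ) + λᵣ·½Tr(W Wᵀ),

ỹ = 2y − 1.  Writing the loss with ±1 labels is the standard logistic
convention; the {0,1} form would make negative pairs constant in W.
There is deliberately no intercept: scores are comparable across targets
within a disease, which is all ranking evaluation needs.

The objective is convex (logistic loss plus two PSD quadratics).  It is
minimized by full-batch gradient descent,

    ∇ = Xᵀ(σ(XW) − Y) + λᵣW + λₛW Lₛ,

with backtracking: the step is halved whenever it would increase the
objective, so the objective trace is monotone non-increasing and the
fixed-step instability of a huge λₛ is handled automatically.  Defaults:
zeros initialization (deterministic; `small_random` exists for tests),
learning rate 0.05, relative-change tolerance 1e−7, 5000 iteration cap.
λₛ = λᵣ = 0.1 by default; `select_hyperparameters` searches a grid
(default {0, 0.01, 0.1, 1, 10}²) by inner 3-fold pair-level CV.

An optional binary *observation mask* restricts the loss (and CV folds)
to a subset of pairs.  With real curated data the mask is all-ones —
unknown pairs are negatives, exactly the printed loss.  The mask exists
for partially observed learning sets, in particular the synthetic
generator below.

One model is fitted per perturbation mode and per cell line (a
concatenated fit is possible by stacking inputs).  Diseases without any
positive occupy columns and learn only through the Laplacian coupling.

Prediction scores are σ(wₘᵀx) ∈ (0,1), monotone in fₘ, so rankings and
AUCs are unaffected by the squashing.

## Inverse signature scoring

Pearson correlation between each perturbation signature and each disease
signature on their common genes; candidates are ranked ascending in r
(most negative first) and the score exported for ROC evaluation is −r.
Zero-variance vectors raise rather than silently scoring 0; affected
pairs are excluded with a logged count.  Ties break lexicographically on
(target, disease) for deterministic output.

## Tensor completion

Perturbational compendia measure only some (perturbed gene, cell line)
combinations.  The data form a third-order tensor T (perturbed gene ×
measured gene × cell line) with an observation mask, and missing fibers
are imputed from a rank-R CP decomposition fitted to observed entries by
EM-style alternating least squares: impute missing entries with the
current reconstruction, run one exact unmasked ALS sweep (normal
equations via Khatri–Rao products, with a 1e−12 ridge for rank-deficient
Gram matrices), repeat.  The masked relative residual is monotone
non-increasing; iteration stops when its change falls below 1e−8
(relative) or after 500 sweeps, with a warning carrying the final
residual otherwise.  Initialization is seeded random normal scaled by the
observed standard deviation.  Observed entries always pass through
imputation bit-exactly.  The default rank (3) can be replaced by
`select_rank`, which holds out 10% of observed entries and minimizes
held-out RMSE over a user grid.  A slice with no observed entry at all is
an error: no information constrains its factor row.

## SNP baseline

For each (gene, disease), association P values over all SNPs and studies
are averaged arithmetically; the score is −log₁₀(mean P), with 0 for
genes lacking any record (continuous with P = 1).  Base 10 is the GWAS
convention; the base only rescales scores, so rankings and AUCs are
base-invariant.  The baseline is direction-blind: the same profile is
used against inhibitory and activatory gold standards.

## Evaluation

AUC follows the Mann–Whitney convention, P(score⁺ > score⁻) + ½P(tie),
computed from the ROC curve (scikit-learn backend); the test suite checks
it against brute-force pair counting.  Cross-validation splits
(target, disease) *pairs* — matching an evaluation over all pairs — into
k = 5 folds; a target-grouped split would be the stricter probe of
generalization to unseen targets and can be emulated by masking rows.
Test-fold positives are set to 0 in the training labels but their targets
stay in X, so they remain scoreable; folds are re-drawn (up to 10 seeds)
if a test fold lacks both classes, and in degenerate regimes where folds
are single pairs (leave-one-pair-out) per-fold AUCs are skipped in favor
of the pooled AUC over all test pairs.  Per-cell-line evaluation repeats
the procedure independently on each cell line's signatures.

## Synthetic data

The generator produces data *from the model's own assumptions* so that
recovery is a meaningful test of the implementation, at desk scale:

- Diseases fall into `n_clusters` clusters; each cluster has a random
  unit direction c, and z = c + σu with isotropic u and
  σ² = (1 − ρ)/ρ, making the expected within-cluster cosine ≈ ρ
  (default 0.8).
- True weights are w*ₘ = s·(cluster direction of disease m), features
  are standard normal, labels are drawn y ~ Bernoulli(σ(w*ᵀx)) and then
  thinned to `positives_per_disease` (default 5) curated positives.
  Thinning is a *deletion*: the kept positives are the drawn positives
  with the highest generative probability — curated gold standards
  favor the strongest, best-studied responders — and the thinned-out
  drawn positives leave the learning set via the observation mask.
  Relabelling them as negatives would instead plant a large population
  of adversarial negatives (true positives marked 0) that no
  intercept-free linear model can separate, and recovery of w* would be
  impossible by construction rather than hard; deletion keeps the
  generator faithful to the model the package fits.
- Signal strength s defaults to 3.0, spreading σ(w*ᵀx) over (0, 1)
  without saturation — strong but realistic separability for a
  transcriptome-derived predictor.
- The tensor generator plants seeded CP factors plus Gaussian noise and
  Bernoulli missingness; the SNP generator gives true pairs
  P = 10^−U(3,8) (genome-wide-significant range) over a U(0.05, 1)
  background covering 10% of null pairs.

What the generator does **not** emulate: transcriptomic covariance
(genes are independent), batch/platform effects, heavy-tailed expression
changes, shared targets inducing label correlations beyond the cluster
structure, and non-random curation of negatives.  Passing recovery tests
therefore demonstrates correctness of the estimation machinery under the
model's assumptions, not expected performance on real compendia.

Reference conditions used by the acceptance script and the deepest
tests: N = 200 targets, M = 12 diseases in 3 clusters, d = 50 genes,
within-cluster cosine 0.8, 5 positives per disease, seeds 0–19.  These
sizes keep a full 20-seed, 5-fold cross-validated run under a minute
while leaving each disease's label count (5) realistically scarce.

## Repositioning summary

Given known associations, predicted scores and a user-supplied
disease→class map (e.g. ICD-11 chapters), the summary counts predicted
*new* associations of already-known targets by (from-class, to-class).
The cut is top-k per disease (default 20) or an absolute score
threshold; known pairs never count.  Each counted prediction contributes
exactly once (conservation); a target known in several classes is
attributed to its lexicographically first known disease's class, a
deterministic convention that matters only for multi-class targets.

## Known limitations

- The trans-disease model is linear and intercept-free; base-rate
  information cannot be expressed, only relative ranking within a
  disease.
- EM-ALS for masked CP is guaranteed monotone but not globally optimal;
  poorly conditioned or high-noise tensors can stall at the iteration
  cap (reported via warning with the final residual).
- Hyperparameter selection maximizes pair-level inner-CV AUC, which
  inherits the optimism of pair-level splitting for targets seen in
  training.
- Per-cell-line fitting ignores information shared across cell lines;
  tensor completion is the only cross-cell-line coupling provided.
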