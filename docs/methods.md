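# Methods

This note records the models implemented in `omibench`, the conventions and
numerical choices taken where the methods' usual descriptions leave them
open, and what the synthetic benchmark does and does not demonstrate.

## Data model and preprocessing

A study is a set of per-source `samples × features` matrices aligned to one
sample order (the label file's order is canonical), a label per sample in
{−1, +1}, and optionally a cluster/family id. Internally a label of 0 marks
a sample whose status is hidden from fitting; only the toolkit sets 0s
(during hold-out masking), never the user, which keeps test labels out of
every fitting path by construction. Features are z-scored per source before
graph or kernel construction, always with statistics computed on training
samples only; correlation and RBF distances are scale-sensitive and omics
platforms differ by orders of magnitude, so unscaled integration would let
one source dominate silently. Zero-variance features are dropped (or, with
externally supplied statistics, passed through with unit sd). Loading is
strict — non-numeric or missing cells are errors — with an opt-in
column-median imputation for processed matrices with scattered missingness.

## Sample-similarity graphs

`W_ij = max(corr(x_i·, x_j·), 0)` between the feature profiles of samples i
and j (Pearson by default; Spearman available at O(n² log n)). Negative
correlations are truncated because edge weights are connection strengths
and must be non-negative. The diagonal is forced to 0: a self-correlation
of 1 on every node would dominate the degree matrix and shrink all
propagated scores uniformly. The Laplacian is `L = D − W`,
`D = diag(row sums)`; for symmetric W it is PSD and
`fᵀLf = Σ_{i<j} w_ij (f_i − f_j)²`.

Graphs are transductive: test samples are nodes with label 0. Their
*features* participate in graph construction (that is the point of
semi-supervised propagation); their labels never do.

## Graph semi-supervised learning

Single network: `f = (I + cL)⁻¹y`, computed by a dense LU solve, never an
explicit inverse. Classification uses the median cut-off: a node is +1 iff
its score is strictly closer to the median score of +1-labelled nodes than
to that of −1-labelled nodes; exact ties go to −1 (an arbitrary but fixed
convention).

Multiple networks: bounding every per-network smoothness `fᵀL_k f` by a
common γ and dualising gives

    min_α  yᵀ(I + Σ_k α_k L_k)⁻¹ y   s.t.  α ≥ 0, Σ α_k ≤ c,

with `f = (I + Σα_k L_k)⁻¹y` at the optimum. Note the minimax character:
the weight goes to networks whose smoothness constraint *binds* — a
worst-case-robust combination, not a signal-seeking one. A consequence
worth knowing: if one source is pure noise with edges as strong as the
informative source's, the noise network binds and receives the weight.
In realistic omics regimes a pure-noise source has many features, its
pairwise correlations concentrate near zero, its network is weak, and the
informative network correctly dominates (this is the regime of the
reference study below).

The solver is SLSQP on the simplex with the analytic gradient
`∂/∂α_k = −uᵀL_k u`, `u = A⁻¹y`, initialised at the uniform feasible point
c/m, with vertex restarts if it stalls and a projected-gradient polish
(monotone by construction) on the best candidate. Objective tolerance
1e−9.

Well-posedness guard: the dual objective is only meaningful while
`A = I + Σα_k L_k ≻ 0`. Symmetric Laplacians are PSD, so any feasible α is
safe. *Sharpened* Laplacians (below) can have indefinite symmetric parts,
in which case the objective is unbounded past the singularity of A and the
optimiser would otherwise chase it into numerical collapse. We therefore
add the linear constraint `Σ α_k ν_k ≤ 0.99`, where ν_k is the magnitude of
the most negative eigenvalue of the (symmetrised) L_k — a conservative
sufficient condition keeping the smallest eigenvalue of A above 0.01. It is
inactive whenever all networks are PSD.

`c` is tuned by repeated stratified k-fold cross-validation (defaults
k = 5, 5 repeats — the repeat count is a package choice) over the grid
{0.001, 0.005, 0.01, 0.05, 0.1, 0.25, 0.5, 1, 1.5, 5, 10, 25, 50, 100},
ties broken toward the smaller (smoother-toward-loss) value. Stratified
folds avoid single-class folds at small n. The benchmark adapters default
to fixed `c = 1` so that large run counts stay tractable; `c="auto"`
switches the tuning on.

## Graph sharpening

Reading `w_ij` as the strength of the edge *from node j to node i*,
sharpening zeroes (i) edges from unlabelled senders into labelled
receivers and (ii) edges between oppositely labelled nodes, leaving an
asymmetric, sparser matrix. Labelled nodes keep all their outgoing
influence on same-label and unlabelled nodes. The multi-network solution
becomes `f = [I + ½Σα_k(L_k + L_kᵀ)]⁻¹y`, i.e. the symmetric machinery
applied to `(L_k + L_kᵀ)/2` — the only reading under which that expression
is the stationary point of the integration objective, and the one we use
for the α optimisation as well. Sharpening is recomputed for every
train/test split, since the labelled set changes.

Sharpened symmetrised Laplacians are where the PD guard above matters:
`fᵀ(D−W)f = ½Σw_ij(f_i−f_j)² + ½Σ_i(d_i^out−d_i^in)f_i²` can be negative
when in- and out-degrees diverge, which sharpening causes by design.

Observed behaviour, consistent with the method's reputation: on the
reference study the sharpened integrator ranks test samples well
(AUC ≈ 0.7–0.8) while the median cut-off decodes that ranking poorly
(accuracy near 0.5) — the sharpened score distribution is shifted relative
to the labelled nodes' medians. We report both metrics rather than
repairing the cut-off, since the median rule is part of the method.

## Composite association network

Over the labelled (training) nodes, the target network T takes one of
three values determined by the class counts. The printed three-level
scheme assigns `(n₊/n)²` to negative–negative pairs, `(n₋/n)²` to
positive–positive pairs and `+n₊n₋/n²` to mixed pairs. Two properties of
that scheme are worth stating plainly: for balanced classes it is constant
(the regression then has no signal, every fitted α is ~0 and the uniform
fallback fires), and for unbalanced classes the projection of a
same-class-elevated weight matrix onto it is non-positive — so under this
target the fitted weights do not track source informativeness. We
implement it verbatim as the default (`convention="printed"`) and provide
`convention="attraction"` — same-label pairs positive
(`(n_opposite/n)²`), mixed pairs `−n₊n₋/n²` — which rewards networks whose
strong edges connect same-label pairs. The benchmark experiments use the
attraction convention; the printed one remains available for fidelity.

Weights solve the normal equations `α = (ΩᵀΩ)⁻¹Ωᵀvec(T)` with
`Ω = [1, vec(W₁), …, vec(W_m)]`; vec() stacks the full symmetric matrix,
both triangles and the diagonal (a convention that affects only constant
factors). The fitted bias α₀ is reported and discarded. Negative α_i are
zeroed; if all are ≤ 0 the uniform fallback `α_i = 1/m` is used and
flagged. A near-singular normal matrix (duplicated or collinear sources —
common with redundant omics layers) falls back to a ridge-regularised
solve (λ = 1e−8) with a warning. The regression sees only
training-node submatrices (T is undefined for unlabelled nodes); the
fitted α then combines the *full* matrices — the only leakage-free
reading. Propagation uses the method's fixed `c = 1` and the median
cut-off.

## Bayesian network classifier

Per source: features pass a pooled two-sample t-test at the
Bonferroni-corrected 0.05 level (the t-test is the appropriate association
test for the continuous matrices this package consumes; if nothing passes,
the single smallest-p feature is kept so the source still yields a score).
Each sample's source score is the sum of its training-standardised values
over selected features, signed by the class-mean difference — a stated
construction of this package, since "a score" is all the method's usual
description pins down. Scores are discretised at the training quartiles
(4 bins, linear-interpolation quantiles; values equal to an edge fall in
the lower bin; test scores use the training edges and clamp into the outer
bins). The structured variant adds an undirected dependence edge between
two source variables when their within-class Pearson correlation, averaged
over the two classes, exceeds 0.3 in absolute value ("conditional on y" is
implemented as this within-class average); the simple variant forces the
empty edge set. Likelihoods are estimated per connected component — joint
tables over dependent blocks, univariate tables for isolated variables —
with a Laplace pseudocount of 1 in every cell, which guarantees finite
posterior odds for all bin patterns; the known failure mode this prevents
is the frequent infinite odds of structured models at small n. Components
of more than 3 variables warn (table size 4^k). Classification:
`Odd_post = Odd_prior · Π (ratios) > 1 → +1`, ties to −1.

## Multiple-kernel SVM

Kernels: linear `⟨x_i, x_j⟩` and RBF `exp(−σ‖x_i − x_j‖²)` (unit
diagonal). σ defaults to the median-squared-distance heuristic; a 5-fold
CV grid search over that heuristic × 2^{−4..4} is available, as is a C grid
{0.01, 0.1, 1, 10, 100}. The benchmark adapters default to the median
heuristic and C = 1 for tractability.

The joint problem — 1-norm soft-margin SVM over `K = Σμ_i K_i`, μ ≥ 0,
`trace(Σμ_i K_i) = c` — is solved in its QCQP dual form

    max_{α,t} 2αᵀe − ct   s.t.  t ≥ (1/r_i)αᵀdiag(y)K_i diag(y)α,
                                 r_i = trace(K_i), αᵀy = 0, 0 ≤ α ≤ C,

by scipy's trust-constr interior-point method with analytic gradients and
Hessians. KKT stationarity in t identifies the kernel weights with the
quadratic constraints' Lagrange multipliers and gives `Σμ_i r_i = c`
automatically; we rescale the recovered multipliers to satisfy the trace
budget exactly and also expose the sum-normalised μ. `c` defaults to the
training-set size (making the normalised weights sum to one). Kernels get
a 1e−8 diagonal jitter against near-singularity.

Decision values use the standard dual expansion
`f(x) = Σα_i y_i K(x_i, x) + b` — the label enters through `y_i`, as the
dual requires. Default bias is `b = −(max_{y=−1} w·x_i + min_{y=+1}
w·x_i)/2`, the margin-midpoint convention (exact under hard-margin
conditions); `bias="paper"` reproduces the double-max variant that appears
in some write-ups and that we regard as a typo. `f = 0` classifies −1.

## RVM and AdaBoost-RVM

The RVM score is `Y(x) = Σ_i w_i k(x, x_i)` over training samples (no bias
term), with `P(y=1|x) = σ(Y)`. Training is sparse Bayesian learning:
independent Gaussian priors `w_i ~ N(0, a_i⁻¹)`, posterior mode by
Newton/IRLS under the logistic likelihood (Laplace approximation), and
type-II updates `a_i ← γ_i / w_i²`, `γ_i = 1 − a_iΣ_ii`. Weights with
`a_i > 1e9` are pruned; the survivors are the relevance vectors.
Convergence at max |Δ log a| < 1e−3 or 500 outer iterations (non-
convergence returns the best iterate with a warning and `converged=False`).
These settings are this package's commitments; the method's literature
leaves them open.

Multi-source integration fits one model per source kernel and averages the
per-source probabilities; `p̄ > 0.5 → +1` (0.5 exactly → −1).

AdaBoost: sample weights start at 1/N; each round draws
`round(fraction·N)` training samples *without replacement with selection
probability proportional to the current weights* (the natural reading of
boosting by resampling), fits an RVM on the subsample, and computes the
weighted error ε_t over the FULL training set — the weights are defined on
all N samples, so that is where Σw_i over misclassifications lives. Rounds
with ε_t ≥ 0.5 are skipped (weights untouched); otherwise the learner is
stored with `α_t = ½ln((1−ε_t)/ε_t)`, weights are multiplied by `e^{±α_t}`
and renormalised to sum 1. The ensemble score is `Σ_t α_t h_t(x)` with
h_t the round's ±1 prediction; probabilities are the sigmoid of that
score. If every round is skipped, a single RVM on the full training set is
the fallback (warned). The (fraction, iterations) grid
{0.2, 0.4, 0.6, 0.8} × {1, 5, 10, 20, 30} is tunable by 5-fold CV with
ties toward the cheaper model; the benchmark adapters default to
(0.4, 10), the regime reported to work well on a few hundred samples.
Whether boosting should happen per source or on a combined kernel is not
settled anywhere we know of; per source mirrors the per-source RVM design
and is what we do.

## Evaluation protocol

Accuracy `(tp+tn)/n`, `F1 = 2tp/(2tp+fp+fn)`, sensitivity `tp/P`,
specificity `tn/N`; AUC by the rank-based estimator
(concordant + ½·tied)/(P·N). Repeated hold-out: stratified 75/25 splits
(stratification is a package choice that prevents empty-class test sets at
small n), 200 runs by default, each algorithm receiving the study with
test labels masked to 0. Leave-cluster-out: training clusters drawn
without replacement (default 12 of 17), no cluster straddles the split;
splits without both classes on both sides are redrawn with a retry limit.
Means over runs carry percentile-bootstrap 95% CIs (2000 resamples of the
per-run metric values — the run is the bootstrap unit — under a fixed
seed). Algorithm failures in a run are logged and excluded for that
algorithm, with counts reported. Imbalance experiments subsample the
largest sub-study with an exact positive:negative integer ratio, without
replacement (maximising size; fixing total n instead would be the other
defensible convention).

## Synthetic generator and the reference study

Each source is Gaussian noise (sd `noise_sd`) with the first
`n_informative` features' class means shifted ±Δ/2 (Δ in sd units).
Optional family structure adds a per-cluster random intercept
(sd = noise_sd/2) shared across sources. Labels are exact to the requested
balance within one sample; everything is reproducible from the seed.

The reference two-source study used by the experiments and the acceptance
script: n = 150, balanced; an informative source of 100 features with 20
informative at Δ = 1.5; a pure-noise source of 1000 features. The noise
dimensionality matters and was chosen to match the omics regime the
methods target (hundreds to thousands of features per layer): with few
noise features, random sample correlations are as strong as the signal
correlations and the minimax graph combination provably concentrates on
the noise network (see above) — an intrinsic property of that method, not
an implementation artifact. The label-permuted control redraws an
independent permutation per run; a single shared permutation would leave
all runs correlated through the fixed label/graph pairing and its mean
AUC would not concentrate at 0.5.

What the generator does not emulate: feature–feature correlation
structure within a source, heavy tails, batch effects, discrete genotypes
(continuous matrices stand in for all layers), and missingness. Passing
benchmarks here demonstrates correct mechanics and sensible relative
behaviour, not performance on real cohorts.

## Numerical conventions collected

- Linear systems: dense LU solves; residual tolerance 1e−8.
- Simplex optimisation: SLSQP + projected-gradient polish, objective
  tolerance 1e−9; PD margin 0.01 for indefinite (sharpened) Laplacians.
- QCQP: trust-constr, gtol 1e−10; kernel jitter 1e−8.
- Ties: median cut-off → −1; `Odd_post = 1` → −1; `p̄ = 0.5` → −1;
  `f = 0` → −1; CV grids break ties toward the smaller / cheaper setting.
- Quantiles: linear interpolation; bin boundaries belong to the lower bin.
- RVM: prune threshold 1e9, outer tolerance 1e−3, max 500 iterations;
  ε_t floored at 1e−10 when a round is error-free.

## Known limitations

- The printed composite-network target is retained verbatim but is
  uninformative for balanced classes; use the attraction convention when
  the weights themselves are of interest.
- The minimax multi-network combination is not robust to adversarially
  strong noise networks (low-dimensional pure-noise sources).
- Dense O(n³) solves throughout; fine for cohort-scale n (≤ ~1000), not
  for biobank-scale graphs.
- The Bayesian classifier's score construction and its t-test filter are
  stand-ins for source-specific association tests (e.g. SNP trend tests),
  which are out of scope for continuous matrices.
- RVM training is the computational bottleneck; the benchmark defaults
  (fixed hyperparameters, median-heuristic σ) trade tuning for run count.
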