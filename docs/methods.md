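# Methods

## Setting and model

Data are N units with features x_n ∈ R^p and M label columns y_n^m ∈
{1..G}, one per annotator; optionally some units also carry a ground-truth
label. Each annotator's labels are treated as a complete, noisy labeling
of the same underlying classes. Per annotator we fit a Gaussian
discriminant classifier by maximizing the joint likelihood

    ∏_n τ_{m,y_nm} φ(x_n; μ_{m,y_nm}, Σ_{m,y_nm}),

so priors are class frequencies n_g/N, means are class sample means, and
covariances are ML estimates under one of 14 constraints obtained by
eigendecomposing Σ_g = λ_g D_g A_g D_gᵀ and forcing volume λ, shape A
(diagonal, det 1) and orientation D to be equal or variable across
classes, with diagonal and spherical specializations. All ML denominators
are n_g (or N), never n_g − 1: BIC, defined here as 2ℓ − k·log N and
maximized, requires the likelihood at its maximum. The free-parameter
count k is (G−1) priors + G·p means + the standard covariance-parameter
count of the model (EII: 1, …, VVV: G·p(p+1)/2).

The ensemble classifier stacks the M fitted base learners by convex
parameter averaging: τ̂_g = Σ_m w_m τ̂_mg and likewise for means and
covariances, then classifies by the MAP rule with log-sum-exp
stabilization. Averaging operates on realized parameter values only, so
base learners selected by BIC may carry different covariance models, and
the stacked covariances are generally class-specific even when every base
learner imposed across-class equality — that equality is deliberately not
re-imposed.

## Estimation of the 14 covariance models

Closed forms exist and are used for EII, VII, EEI, EVI, VVI, EEE, EEV and
VVV, and also for EVV (shape-orientation matrices C_g = W_g /
det(W_g)^{1/p}, common volume λ = Σ_g det(W_g)^{1/p} / N, with W_g the
class scatter). The remaining models alternate coordinate-wise exact
updates of volume and shape with, where the orientation is shared (VEE via
the shared det-normalized matrix; EVE/VVE via an explicit D), a
majorize-minimize step over the orthogonal group: the quadratic objective
Σ_g tr(D A_g⁻¹ Dᵀ S_g) becomes concave after subtracting its largest
Hessian eigenvalue (‖D‖_F² is constant on the group), so each MM step
minimizes a linear functional, solved by an SVD. VEV fixes D_g at the
eigenvectors of W_g (eigenvalues descending) and runs a small fixed point
over (λ_g, A). Outer loops monitor the profile deviance Σ_g [tr(W_g
Σ_g⁻¹) + n_g log det Σ_g] with relative tolerance 1e-8 and a 200-iteration
cap. The test suite checks every model against a multi-start Nelder-Mead
maximizer over an explicit (λ, A, D) parameterization; the dedicated fits
must match or beat it within 1e-4 log-likelihood.

Numerical choices: covariance estimates are symmetrized; estimates whose
smallest eigenvalue falls below 1e-10 receive a ridge ε·I with ε = 1e-8 ·
trace(Σ̂)/p, and raise a singular-fit error if still degenerate (so
genuinely rank-deficient classes fail loudly rather than silently). BIC
ties break toward fewer free parameters, then canonical model-code order.
MAP ties resolve to the lowest class index. Labels are 1..G integers
throughout the package, internally and externally; the sentinel −1 marks
"no reference label" in majority-vote bookkeeping. Using one labeling
convention end-to-end, rather than converting to 0-based indices at the
I/O boundary, removes an entire class of off-by-one defects at the cost of
slightly un-Pythonic indexing in a few loops.

## Weighting strategies

All strategies return weights on the M-simplex together with the raw
scores that produced them.

* **PGT** counts, on the subset with known truth, how often each annotator
  matches it, then rescales: w_m = s_m / Σ s_m. Default truth subset in
  the simulation: 10% of the training units.
* **EN** splits a fixed mass across declared tiers, equally within a tier;
  default 80% of the mass to experts.
* **E** is 1/M.
* **MV** scores agreement with per-unit majority labels. A unit whose top
  vote count is tied is a deadlock and awards no points; with an agreement
  threshold t the top count must additionally reach ceil(t·M). The
  simulation default t = 5/7 demands five of seven annotators. A zero
  score total (every unit deadlocked or below threshold) falls back to
  equal weights with a warning: a medical annotator panel should degrade
  to democracy, not drop members.
* **ItAlg1/ItAlg2** initialize estimated labels by plain majority vote
  (deadlocks resolve to the lowest tied class), then alternate: score
  annotators against the current labels, rescale to weights, re-stack the
  fixed base learners, relabel by MAP. ItAlg1 scores hard agreement
  counts; ItAlg2 scores the annotator's own base-learner posterior at the
  estimated label, *gated by agreement* — an annotator whose label
  disagrees earns nothing however confident it was. This gated form is the
  only reading consistent with the worked single-observation example in
  which the disagreeing annotator scores 0; the ungated alternative
  (posterior credit regardless of agreement) is noted but not implemented.
  The loop stops when labels repeat on consecutive iterations (converged)
  or after max_iter = 100 sweeps; if the label sequence revisits an
  earlier state without converging (a cycle the update rule does not
  exclude), the visited state with the highest ensemble mixture
  log-likelihood is returned flagged non-converged. max_iter = 0 returns
  the weights scored against the initial majority-vote labels.

## Synthetic study conditions

The simulator reproduces the validation conditions: G = 3 equiprobable
bivariate Gaussians, N = 150, stratified 100/50 train/test split,
S = 50 repetitions, M = 7 annotators (4 experts, 3 novices). Scenario 1
fixes means (2,2), (0,0), (−2,−2) with identity covariances; Scenario 2
keeps the means but draws class-wise random PD covariances (eigenvalues
uniform on [0.5, 2], Haar-random orientation via QR), giving each class a
different correlation pattern. Annotator labels are Dirichlet-multinomial:
p ~ Dir(α_m(g)) given true class g, then one multinomial draw. The
concentration profiles are not printed anywhere authoritative, so they are
package defaults chosen once: experts α = 8 on the true class and 1
elsewhere (mean correct-label probability 0.8), novices α = 3.5 and 1.5
(mean ≈ 0.54). Consequences: the ground-truth benchmark row of the
simulation (which does not involve the annotators) is quantitatively
reproducible, while base-learner and ensemble accuracy levels are
reproducible only qualitatively — ensembles beat every single base
learner, experts outrank novices in the data-driven scores — and the
tests assert exactly that. Per-repetition seeds derive from the master
seed through `numpy.random.SeedSequence([master, rep])`, so every strategy
within a repetition sees identical data and reruns are bit-identical.

What the simulator does not emulate: annotator correlations (labels are
independent given the truth, as the stacking model itself assumes),
instance-difficulty effects (noise depends only on the true class), class
imbalance, and non-Gaussian features. Passing tests therefore certify the
procedure under its own generative assumptions, not robustness to their
violation.

## Evaluation metrics

Accuracy is averaged over repetitions with the (S−1)-denominator standard
deviation. Mean recovery error is the mean over classes of the *plain*
Euclidean norm ‖μ_g − μ̂_g‖ (not squared): under Scenario 1 with ~33
training points per class the per-class error is Rayleigh with mean
√(π/(2n_g)) ≈ 0.217, which matches the reported benchmark magnitude,
whereas the squared version (≈ 0.06) does not — that closed form settles
the norm-vs-squared-norm ambiguity and doubles as a test oracle.
Covariance recovery error is the mean over classes of the Frobenius norm
of Σ_g − Σ̂_g, taken literally; classes are matched by label index (labels
are shared and supervised, so no permutation search is needed). The
reported ground-truth covariance error for the pooled model is roughly
half the Wishart-fluctuation expectation of this literal formula,
suggesting an unstated normalization upstream; the literal definition is
kept and that single number is not asserted anywhere. Binary-collapse
metrics map a declared positive set of classes (for the lesion data:
adenoma + serrated adenoma = "malignant") onto a 2×2 confusion matrix and
report sensitivity, NPV, specificity and precision, with zero-denominator
ratios reported as missing. The agreement matrix gives, per annotator and
true class, the fraction of units labeled correctly, plus overall
per-annotator accuracy.

## Problem sizes and defaults

The shipped study sizes are the study conditions themselves (S = 50,
N = 150, M = 7); the acceptance script runs them in seconds. The
numerical-maximizer cross-check uses five fixed two-class toys at p = 2,
where the orientation manifold is a single angle per class and a generic
optimizer is trustworthy. Iterative-fit tolerances (1e-8 relative, 200
iterations) are far inside the 1e-4 oracle-agreement band. The real-data
protocol (76 lesions, 50 random 50/26 stratified splits, pooled-covariance
base learners) is implemented end-to-end but requires the publicly
downloadable colonoscopy dataset, which cannot be redistributed here; its
tests fail with instructions until `data/gastro_prepared.csv` is supplied.

## Known limitations

Base learners require every class to appear in every annotator's labels;
an annotator who never uses a class is rejected rather than smoothed.
Parameter averaging is known to trade estimation fidelity for predictive
robustness: stacked covariances absorb between-annotator disagreement and
overestimate spread, so recovery errors for ensembles exceed those of good
individual annotators even when accuracy improves. The iterative schemes
fix the base learners throughout, as specified, so they cannot correct a
base learner that is itself badly wrong. The MM orientation step
guarantees monotone deviance decrease but, like all the alternating fits,
only a local maximum; the oracle tests bound the practical gap.
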