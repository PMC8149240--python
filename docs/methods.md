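# Methods

## Problem setting

The package targets small two-class clinical tabular datasets with class
imbalance up to roughly 4:1, a mix of informative and irrelevant numeric
features, and sporadically missing entries. The positive class is defined
as the minority class of the raw data — the convention a screening
application needs for TP/FN to mean what clinicians expect. On an exact
tie in class counts the lexicographically larger label string is positive;
the choice only fixes which side of the confusion table is which.

## Preprocessing

The chain is fixed: impute → oversample → normalize → split.

* **Mean imputation** uses the global per-feature mean of observed values,
  not class-conditional means. Class-conditional imputation would leak
  label information into the features before the train/test split.
* **SMOTE.** Each minority instance `p` contributes `multiplier − 1`
  synthetic instances `p + u(q − p)`, `q` uniform over `p`'s `k = 5`
  nearest minority neighbours (Euclidean, on imputed raw values — before
  normalization, so neighbourhoods reflect the original measurement
  scales), `u ~ U(0,1)`. When no multiplier is given it is derived from
  the majority:minority ratio: 1 below 1.5, otherwise the ratio rounded
  half-up. This rule is deliberately coarse — it equalizes classes to
  within rounding rather than exactly, which matches how oversampling is
  typically applied to these datasets; callers can override it.
* **Min-max normalization** maps each feature to [0, 1] via
  `a' = (a − min)/(max − min)`. A constant feature has a zero denominator;
  it maps to 0 (any constant in [0, 1] would do — 0 keeps the map
  idempotent and deterministic). Parameters are fitted on one dataset and
  serializable, so test data is transformed with training-set parameters.
* **Stratified splitting** draws the train size as
  `round_half_up(fraction · n)` and apportions per-class counts by
  largest remainder, so every class count is within one instance of its
  ideal share. Half-up rounding is used everywhere sizes are derived
  (249.6 → 250).

## Wrapper fitness

A candidate subset is scored by the mean accuracy of an RBF-kernel SVM
(C = 1, inverse-dimension-scaled kernel width) over stratified 5-fold
cross-validation on the training set restricted to the masked-in
features. Cross-validation rather than a single holdout keeps the wrapper
from overfitting one split; resubstitution accuracy would saturate at 1
for expressive kernels and make subsets indistinguishable. The fold
assignment is frozen per evaluator, making fitness a pure function of the
mask; evaluations are cached by mask bits, which both bounds the real
search cost (at most `2^m − 1` cross-validations regardless of how long
the swarms run) and guarantees selectors see consistent values. The empty
mask scores 0 without training. Subset comparison is lexicographic:
higher accuracy, then fewer features, then the incumbent stands — the
cardinality tie-break makes the selection well defined when many subsets
tie at high accuracy, which on separable data is the rule, not the
exception.

## Binary encoding

All three metaheuristics search the continuous unit box and decode a
position to a mask by thresholding at 0.5 (boundary inclusive). A decode
with no bits set switches on the single largest component, so every agent
always corresponds to a trainable subset. One shared encoding keeps the
three search traces comparable.

## Cat swarm optimization

Each iteration, `round(MR·N)` cats trace and the rest seek; the
assignment is re-randomized every iteration. Seeking builds `SMP`
candidates (one being the unmodified position when the
self-position-consideration flag is up, drawn per cat per iteration with
probability 1/2), each perturbing a random `CDC` fraction of dimensions
by ±`SRD`, and keeps one candidate with probability proportional to
relative fitness (uniform on a complete tie). Tracing updates velocity by
`v ← v + r·c·(best − x)`, `r ~ U(0,1)` per dimension, clamps to
±`v_max`, and moves. Defaults `N = 20`, 50 iterations, `SMP = 5`,
`SRD = 0.2`, `CDC = 0.8`, `MR = 0.3`, `c = 2`, `v_max = 1` are the
conventional settings for the algorithm family. Within an iteration cats
move first and the elitist best is refreshed afterwards from the
population.

## Krill herd

The velocity is the exact three-term sum `dx/dt = N_i + F_i + RD_i`;
setting any term's speed parameter to zero disables precisely that term.

* **Induced motion** `N ← N_max·α + w_n·N`, where α sums a local
  attraction/repulsion term over neighbours within the sensing distance
  (mean herd distance / 5) and a target term toward the best krill with
  gain `2(t/T + ε)`. Objective differences are normalized by the herd's
  worst-minus-best spread, directions by distance, so α is scale-free.
* **Foraging** `F ← V_f·β + w_f·F`, with β the pull toward the
  objective-weighted food centroid (weights `1/objective`, floored at
  10⁻¹²; gain `2(1 − t/T)`) plus the krill's own best-seen position. The
  food position's objective is evaluated through the same fitness
  function on its decoded mask.
* **Diffusion** `RD = RD_max·(1 − t/T)·δ`, `δ ~ U(−1, 1)` per dimension.

The position step is `Δx = C_t·m·(N + F + RD)` for the m-dimensional
unit box. The minimized objective is `1 − accuracy`. Defaults:
`V_f = 0.02`, `N_max = 0.01`, `RD_max = 0.005` (midpoint of its
admissible [0.002, 0.01] band, which the configuration loader enforces),
`w_n = w_f = 0.5`, `C_t = 0.5`, `N = 20`, 50 iterations. The genetic
operators some krill-herd variants bolt on are deliberately omitted.

## Bacterial foraging

Triple loop: `N_ed` elimination-dispersal events over `N_re` reproduction
steps over `N_c` chemotactic steps. A chemotactic step tumbles along a
random unit direction (uniform components, normalized; zero draws
re-drawn), moves by step length `L`, then swims in the same direction
while the objective improves, up to `N_s` moves. The chemotactic
objective is `1 − accuracy` plus the cell-to-cell swarming potential
`J_cc(θ) = Σ[−d_a·exp(−w_a‖θ−θⁱ‖²)] + Σ[h_r·exp(−w_r‖θ−θⁱ‖²)]`
(switchable; on by default). The swarming term is excluded from reported
fitness, which is always pure SVM accuracy, so results are comparable
across selectors. Health is the running sum of evaluated objectives over
a chemotactic pass; reproduction keeps the healthiest half and duplicates
each survivor in place with health reset; elimination-dispersal redraws
each bacterium uniformly with probability `P_ed`. Defaults `S = 20`,
`N_c = 10`, `N_s = 4`, `N_re = 4`, `N_ed = 2`, `P_ed = 0.25`, `L = 0.1`,
`d_a = h_r = 0.1`, `w_a = 0.2`, `w_r = 10` follow the classical
formulation of the algorithm.

All three selectors keep a best-ever (elitist) mask under the shared
comparison rule and report a per-step best-fitness trace, which is
monotone non-decreasing by construction.

## BPNN and conjugate-gradient training

One sigmoid hidden layer with `2·n_input` units and a single sigmoid
output; weights initialized uniformly in `±1/√fan_in` from the seeded
generator. Training minimizes mean binary cross-entropy (squared error
available) by Polak–Ribière nonlinear conjugate gradient: backpropagated
gradients, restart to steepest descent when β < 0 or every
n-parameters iterations, and a backtracking line search from step 1
halving until the Armijo condition (c = 10⁻⁴) holds — hence the
non-increasing loss trace. Cross-entropy is computed in the logit domain
(`log(1+e^z) − yz`) for stability. Training stops at 100 iterations or
when the gradient norm drops below the tolerance, default 10⁻⁷ — in a
line-search CG method the natural role for a "learning parameter" of that
magnitude, since CG has no fixed step size for it to be. Prediction
thresholds the output probability at 0.5, boundary mapped to the positive
class.

## Stacking

The meta-dataset holds, per base-stage test instance, the three base
classifiers' predictions in the fixed order (CSO, KH, BFO) plus the true
label. Meta features are hard 0/1 labels by default — the base
classifiers' "classification results" — with output probabilities behind
a flag. The meta split is 80/20, stratified by true label, half-up train
size; the super learner is a 3-input / 6-hidden BPNN trained as above.
Note the super learner trains on predictions for base-test instances, so
base metrics (computed on the full 40% test set) and super-learner
metrics (computed on the held-out 20% of meta rows) are not measured on
identical instances; `evaluate_bases_on_meta_test` additionally reports
base metrics on exactly the super learner's evaluation rows for a
like-for-like comparison. Cross-validated stacking in the van der Laan
sense is out of scope.

Every pipeline stage derives its seed from the master seed through named
substreams (CRC-mixed `SeedSequence`), so one integer reproduces the
entire report bit for bit.

## Metrics

Accuracy, sensitivity, specificity and precision are percentages rounded
half-up to two decimals via exact decimal arithmetic; the F-score is a
ratio to two decimals. A zero denominator yields an explicit `None`
marker — reporting 0 or 100 there would fabricate a number. Relabeling
the positive class swaps sensitivity with specificity and turns precision
into negative predictive value; this symmetry is property-tested.

## Synthetic benchmark

The generator plants `m_informative` features whose class-1 mean is
shifted by `shift` within-class standard deviations, `m_noise` standard
normal features, labels at a fixed majority:minority ratio, and
missing-completely-at-random cells. Under this model the wrapper-fitness
optimum is the informative subset (possibly padded by ties), which makes
selector recovery exactly checkable: the fixed benchmark —
n = 600, imbalance 2:1, 3 informative at shift 3.0, 7 noise, 5% missing —
keeps the mask space at 2¹⁰, small enough to enumerate exhaustively as an
independent oracle while large enough that random search without
structure would not reliably find the optimum basin.

What the benchmark does **not** emulate: correlated features, non-Gaussian
marginals, informative-feature redundancy, label noise, and
missingness-not-at-random. Passing the recovery tests therefore shows the
search and plumbing are correct, not that the method attains any
particular accuracy on real clinical data; published headline accuracies
on external datasets depend on download-specific preprocessing and
unstated seeds and are not desk-reproducible claims.

## Problem sizes and numerical choices

The test suite and the acceptance script run the fixed benchmark for
recovery (exhaustive 2¹⁰ oracle plus 10 seeded runs per selector, shared
fitness cache), a reduced 80-instance / 5-feature dataset for the
20-run elitism sweep, and a reduced-iteration pipeline configuration for
the determinism and end-to-end checks — sizes chosen so a full pass
completes in well under a minute on one CPU while still exercising every
operator. Numerical tie-breaks are documented where they occur: mask
decode boundary inclusive at 0.5, prediction boundary to the positive
class, constant features normalized to 0, selection-probability fallback
to uniform on complete fitness ties, and incumbent-wins comparison
stability. Gradient correctness is asserted against central finite
differences in norm-relative terms (< 10⁻⁶), the standard robust
comparison when individual components pass near zero.

## Known limitations

* The SMOTE multiplier rule equalizes classes only to within rounding of
  the class ratio; heavily imbalanced data may remain mildly imbalanced.
* Wrapper fitness refits an SVM per fold per subset; for feature counts
  far beyond ~20 the exhaustive-oracle testing strategy no longer applies
  and runtimes grow with the mask-space coverage of the swarms.
* The stacked design reuses base-test instances for super-learner
  training by construction; see the stacking note above.
* Only numeric features and binary labels are supported; categorical
  encodings and multi-class extensions are out of scope.
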