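# Methods

`trtequate` implements a Monte-Carlo study of test equating for tests built
from *testlets* — bundles of items sharing a stimulus — under the
non-equivalent-groups-with-anchor-test (NEAT) design with concurrent
calibration. Two model pairs are compared on identical data: the
two-parameter logistic model (2PLM) against its testlet extension (2PTM)
for dichotomous items, and the graded response model (GRM) against the
graded response testlet model (GRTM) for five-category items.

## Models

For item *j* with discrimination `a_j > 0` and difficulty `b_j`, examinee
*i* with trait `θ_i`:

    2PLM:  P(y_ij = 1) = logistic(a_j (θ_i − b_j))
    2PTM:  P(y_ij = 1) = logistic(a_j (θ_i − b_j − γ_id(j)))

where `d(j)` is the testlet containing *j* and `γ_id ~ N(0, σ²_d)` is the
person-by-testlet random effect capturing local item dependence (LID); its
variance `σ²_d` is the *testlet effect*. The graded models replace the
single difficulty by ordered category boundaries `b_j1 < … < b_j,K−1`:

    P*_jx(θ) = logistic(a_j (θ − b_jx [− γ_id(j)]))
    P_jx(θ)  = P*_jx(θ) − P*_j,x+1(θ),      P*_j0 = 1, P*_jK = 0

No `D = 1.7` scaling constant is used anywhere: the response functions are
pure logistic, and generation and estimation share that metric. Setting
every `γ` to zero collapses each testlet model onto its classical
counterpart exactly; the test suite asserts this to machine precision.

## Synthetic data

Each form has 60 items: 20 locally independent non-anchor items, 20
non-anchor testlet items (4 testlets of 5 or 2 of 10), 10 anchor testlet
items (2 testlets of 5 or 1 of 10), and 10 independent anchor items. The
anchor block (items and testlet variances) is drawn once and shared
verbatim by the base and new forms — an internal anchor.

True parameters are drawn by **rejection sampling**, never clipping
(clipping would put point masses at the bounds): `a = exp(z)`, `z ~ N(0,1)`
accepted in (0, 2.5) for non-anchor and (1, 2) for anchor items;
difficulties and category boundaries `~ N(0,1)` accepted in (−3, 3), the
four boundaries of a graded item sorted into increasing order (the sorted
truncated-normal choice reproduces the order and spread of the published
polytomous parameter set, whose column means are ≈ −0.96, −0.27, 0.29,
1.05). Testlet variances are drawn per testlet from U(0.1, 0.5),
U(0.6, 1.0) or U(1.1, 2.0) for low / moderate / high LID.

Base-group abilities are N(0, 1) — matching the difficulty scale — and the
new group is N(shift, 1). The shift is not pinned by any published value;
the package default is **+0.5**, exposed as `new_form_mean_shift`.

Response generation **always** uses the testlet model (testlet effects
exist in every generating condition); fitting the classical family to such
data is the misspecification under study. Dichotomous items code 1 when
the model probability exceeds a U(0,1) draw; graded items locate the draw
in the cumulative category partition (codes 0–4).

The published item-parameter tables for both studies ship as TSV fixtures
(checksummed at load). Their printed anchor blocks differ between forms,
so `load_printed_forms` / `printed_form_pair` use the reference form's
anchor rows for both sides when a linked NEAT pair is required; tied
category boundaries produced by the tables' two-decimal rounding are
nudged apart by 1e−6. Note that the printed discriminations (mean 1.51
dichotomous, 1.10 polytomous) are substantially higher than draws from the
stated truncated lognormal (mean ≈ 0.94); study runs default to
`form_source="sampled"` (the stated distributions) with
`form_source="printed"` available.

## Calibration

Estimation is multiple-group marginal-maximum-likelihood EM with fixed
rectangular quadrature for θ (default 21 points on [−5, 5]) — not MCMC.
The base group is fixed at N(0, 1) for identification; the new group's
mean and variance are free and updated in closed form from posterior
moments. Anchor items occupy a single column of the stacked two-group
matrix, so one shared parameter set links the forms (concurrent
calibration); no post-hoc transformation is involved.

For the testlet families each random effect is written `γ = s_d z`,
`z ~ N(0,1)` on an 11-point Gauss–Hermite grid. Because every item loads
on θ plus at most one testlet effect — with the 2PTM/GRTM constraint that
the γ slope equals the item's `a` — the conditional likelihood factors
over testlets given θ, and integration costs (θ nodes) × (z nodes) per
testlet instead of growing exponentially with the number of testlets
(bifactor dimension reduction). `s_d` is a structural parameter of the
item response surface under this standardised-grid parameterisation, so
the E-step grids never move and the procedure is a genuine ECM.

The M-step is one batched Fisher-scoring pass over all items (graded
parameterisation with log-slope and log-increments; the dichotomous case
is its K = 2 special case), with per-item step halving so the expected
complete-data log-likelihood never decreases, followed by a safeguarded
1-D Newton update of each `s_d` on [0, 3] and the group-moment update.
Every conditional step is ascent-safe, so the marginal log-likelihood is
non-decreasing across cycles up to round-off; fits record the full
likelihood path and the test suite asserts ascent with a 1e−6 allowance.

Numerical choices: probabilities are clamped to [1e−12, 1 − 1e−12] inside
logarithms only, never in returned probabilities; slopes are kept in
[0.05, 8] and boundaries in [−7, 7] during updates; `σ̂²` reaching the 0
boundary is reported as 0 (a legitimate boundary MLE under low LID), which
is why `s_d` is optimised on the bounded interval directly rather than on
a log scale. Starting values: `a = 1`, boundaries at the logits of the
observed cumulative category frequencies, `σ² = 0.5`; in study runs the
testlet fit starts from the classical fit of the same data. A testlet with
fewer than two calibrated items is treated as locally independent — a
one-item testlet's random-effect variance is not identified (the marginal
likelihood has a flat (a, σ²) ridge) — and an item with zero observed
response variance is excluded from the fit and flagged.

Convergence is declared when the largest absolute parameter change falls
below `convergence_tol` (default 1e−4, cap 500 cycles). Study runs use
1e−3: the resulting parameter differences (≲ 0.02, dominated by σ̂²) are
two orders of magnitude below the Monte-Carlo spread of the error
statistics they feed.

Ability estimates are **EAP** scores — posterior means of θ under the
person's group prior with testlet effects integrated out. (Whether the
original tables used EAP, MAP or ML scoring is not stated anywhere; EAP is
the package's choice and is config-exposed.) An all-missing person scores
at the group prior mean and is flagged.

The calibrator is an sklearn-style estimator (`ConcurrentCalibrator`, with
`fit`/`predict`, `get_params`/`set_params` and fitted attributes), and the
EM solution has been cross-checked against direct L-BFGS maximisation of
the identical quadrature likelihood (agreement to 1e−4 per parameter on a
12-item problem with one strong testlet).

## Error statistics and aggregation

Over R replications with estimate `λ̂_r` of truth `λ`:

    Bias = mean(λ̂_r − λ)
    SEE  = sqrt(mean((λ̂_r − mean(λ̂))²))
    RMSE = sqrt(mean((λ̂_r − λ)²))

all with divisor R, so `RMSE² = Bias² + SEE²` holds exactly per parameter
and is asserted property-wide. Item statistics are computed per item over
replications and then averaged, unweighted and signed, across the items in
scope; the default scope is the new form's non-anchor testlet items
(whether the published tables included the shared anchor testlets is not
recoverable; `include_anchor_testlets` flips the choice). Ability
statistics pool the new-group examinees within each replication and
average the per-replication values. Bias is never sign-flipped.

## Study runner

A condition is one cell of the factorial design (2 fitted families × 3
effect levels × 2 testlet lengths × 2 group sizes per study; the
dichotomous grid alone has 12 generating conditions). The form pair is
drawn once per condition and reused across replications (consistent with
publishing a single parameter set per study; `resample_forms` redraws per
replication). Both families are fitted to the *same* generated data within
a replication — a paired design that removes shared Monte-Carlo noise from
model contrasts. Seeds derive from
`SeedSequence([master_seed, condition_index, replication_index])`, so any
replication reproduces bit-identically in isolation and results are
independent of execution order. Replication-level fit failures are logged,
counted in the manifest and excluded from summaries without aborting the
run.

The default replication count is 500; desk-scale runs (the acceptance
script, the test suite) use 100 replications for the dichotomous headline
condition, 30 for the polytomous one and 30 for effect-level sweeps —
enough that the Monte-Carlo standard error of a condition cell is an order
of magnitude below the differences of interest.

## What the generator does and does not emulate

It emulates: the NEAT two-form layout with an internal anchor, unequal
group means, per-testlet random effects at three LID levels, truncated
parameter distributions, structural missingness of non-administered items.
It does not emulate: real-data features such as guessing, speededness,
item drift or DIF, mixed-format tests, or examinee misfit. Passing tests
therefore certify the pipeline's internal correctness and the model-world
behaviour of the estimators, not robustness to those real-data phenomena.

## Known limitations and observed discrepancies

* A correctly implemented MML pipeline under the stated generating process
  does **not** reproduce several previously published condition cells, and
  two diagnostics in the package show why. First,
  `eap_rmse_floor` computes the information floor of a form: simulating
  locally independent responses from the *true* published dichotomous
  parameters and scoring with true-parameter EAP already yields ability
  RMSE ≈ 0.23 on the new form (the test suite asserts 0.21–0.25), so
  ability-RMSE values near 0.18 are unreachable in the pure-logistic
  metric for any pipeline that adds testlet noise and estimation error on
  top. Second, the direction of the discrimination bias under a
  misspecified classical fit depends on each testlet's share of the test:
  with the design's many small testlets the headline runs find *negative*
  (attenuated) testlet-item discrimination bias, while a test with half
  its items in one strong testlet shows the often-reported *inflation*
  (both asserted in the suite). The package implements the per-testlet
  random-effect model exactly as defined and reports what that model
  yields; the acceptance checks that encode previously published cell
  values for discrimination RMSE, difficulty bias and dichotomous ability
  RMSE therefore fail honestly, with the computed values written by
  `scripts/acceptance.py`.
* The published polytomous discrimination table prints Bias > RMSE in
  several cells, which no per-item aggregation can produce (RMSE ≥ |Bias|
  is an algebraic identity); the package enforces the identity and the
  suite asserts it on study output.
* Standard errors of item estimates are not computed; separate-calibration
  linking (Stocking–Lord, Haebara) and 3PL/nominal/partial-credit families
  are out of scope.
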