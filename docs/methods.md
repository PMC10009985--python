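# Methods

## Scope and data model

The package analyses paired stated-choice data: each respondent answers a
series of choice tasks, each task pitting two hypothetical rural job
profiles against each other. One *observation* is one respondent-task
(the study layout is 352 respondents × 16 tasks = 5,632 observations,
11,264 rows in long format). The attribute schema fixes the design-matrix
contract used everywhere: columns in schema order, one numeric column for
the linear salary attribute (ETB/month; levels 9,056 / 11,320 / 13,584 /
15,848) and one 0/1 dummy per non-reference level of each binary
attribute (references: basic housing, inadequate supply, two service
years, unsupportive management, heavy workload). The USD conversion
(1 USD = 41 ETB) is metadata only; all computation is in ETB.

## Design construction

The target instrument is a fractional-factorial paired design: 24 tasks
(48 profiles from the 128-profile full factorial) in 3 blocks of 8, two
blocks per respondent. The generator that produced the original
instrument is not recoverable; only its criteria are — level balance,
orthogonality, minimal within-task overlap, utility balance. We therefore
search directly over those criteria:

* initialise each attribute column over the 48 profile slots as a
  shuffled, exactly (or maximally) balanced level assignment;
* propose swaps of two slots within one attribute column — these moves
  leave level counts invariant, so level balance is optimal throughout
  and never traded off;
* accept a move iff it does not increase the penalty
  `w₁·mean squared off-diagonal column correlation + w₂·mean overlap +
  w₃·mean (P_A − 0.5)²` (equal weights by default, utility balance under
  a supplied prior coefficient vector, default zero — no pilot priors are
  assumed);
* reject any move that would pair a profile with itself.

The best penalty is non-increasing by construction and the whole search
is a pure function of (schema, seed). Blocking is greedy: tasks are
assigned (in seeded random order) to the unfilled block whose per-block
level counts they unbalance least. Block assignment to respondents is a
uniform seeded draw of 2 distinct blocks out of 3. Typical output at the
default 4,000 iterations: max |column correlation| ≈ 0.08, mean overlap
≈ 0.3, exact level balance.

## Synthetic respondents

The simulator is the study-conditions generator, not a tuning knob. Its
presets are the published preference structure: a mixed-logit process
with means (0.0002371, 0.28, 1.01, 0.47, 0.44, 0.45) and SDs
(0, 0.65, 1.13, 0.98, 0.74, 0.01) in the column order above; a
three-class process with the published class coefficient vectors and
shares (0.298, 0.417, 0.285); and the homogeneous special case. Random
coefficients are independent normals — only per-attribute SDs are
published, so no correlation structure is assumed. Covariates mimic the
sample: sex Bernoulli(0.75 male), age a rounded normal(24, 1.3) clipped
to 21–28. The optional interaction process shifts the service-year
coefficient additively for the "young" (≤ 24) dummy; the published source
gives only the direction, so the magnitude is configurable (tests use
+0.5, large enough to be detectable at n = 2,000 without being
dominant). Class membership is independent of covariates by default — the
true dependence in the study is unknown.

Choices follow random utility: `U = x'β + Gumbel`, the maximum wins,
equivalently `P(A) = logistic((x_A − x_B)'β)`. Gumbel noise is generated
as `−log(−log(u))` from seeded uniforms so that identical seeds give
bit-identical datasets on any platform. One master seed spawns child
seeds for covariates, preferences, block assignment and noise through
`numpy.random.SeedSequence`, so every stage is separately reproducible.

What the simulator deliberately omits: response styles, attribute
non-attendance, straight-lining, item nonresponse, scale heterogeneity.
Passing parameter-recovery tests therefore shows the estimators are
correct under the maintained model, not that the model is right for any
particular real sample.

## Estimators

**Conditional logit.** For two-alternative tasks the conditional logit
reduces to a binary logit on encoded differences `Δx = x_A − x_B` with no
intercept. We maximise by Newton's method with step halving from β = 0,
stopping when the gradient max-norm falls below 1e-6; the covariance is
the inverse observed information. The fit is flagged (not raised) as
non-converged on iteration exhaustion or when final utilities exceed ±25
— the signature of separation, where the MLE is infinite. A weighted
variant serves as the latent-class M-step. Cross-check: statsmodels'
binary logit on the same differences agrees to 4 decimals (test-only
dependency).

**Halton draws.** Standard radical-inverse sequences with distinct prime
bases (2, 3, 5, 7, 11, …) per random coefficient, first 50 elements
discarded, no scrambling by default (random-shift scrambling behind a
flag). For n respondents and R draws the sequence of length n·R is
partitioned across respondents, and draws map to standard normals via the
inverse normal CDF.

**Mixed logit.** Panel simulated maximum likelihood: per respondent, the
product of logit probabilities over their 16 tasks is averaged across the
R draws, logged and summed. The analytic gradient (means and SDs) is
supplied to BFGS. Columns are internally standardised so the salary
coefficient (per-ETB scale, ~1e-4) optimises on the same footing as the
dummies; estimates, SEs and the covariance are mapped back to raw units.
Starting values are the conditional-logit fit with SDs at 0.5 (scaled).
SD parameters are unconstrained and reported as magnitudes. Standard
errors come from the inverse numerical Hessian (central differences of
the analytic gradient). Salary is a fixed (non-random) coefficient by
default, matching a published specification that reports no salary SD.
The default R = 2000; verification runs use R = 200, at which doubling R
moves the simulated log-likelihood by well under 0.5% (measured on the
study-scale fixture).

**Latent class.** EM: the E-step computes posterior class probabilities
from current shares and per-class panel likelihoods; the M-step runs a
fully converged weighted Newton conditional logit per class and updates
shares as posterior means, so the observed log-likelihood is
non-decreasing (asserted in tests). Restarts perturb the pooled
conditional-logit solution (seeded, SD 0.75 in standardised units); the
best log-likelihood wins. A restart that collapses a class
(share < 1e-4) is discarded; if all collapse, a flagged single-class
fallback is returned. Label switching is resolved by sorting classes on
descending salary coefficient, then share. Class SEs are conditional
(inverse information of the weighted logit at the final posteriors),
ignoring share uncertainty. `select_classes` fits each C and picks the
AIC minimiser, with AIC = 2k − 2LL and k = 6C + (C − 1).

**Interactions.** Attribute × respondent-dummy columns
(`Δx_attr · dummy`) appended to the difference matrix, fitted as a
conditional logit with Wald z-tests; rank-deficient interaction sets
raise, naming the columns.

## Post-estimation

* **WTA**: `β_k / β_salary`, refused when |β_salary| < 1e-12. Intervals
  by the delta method (first-order ratio variance) or Krinsky–Robb
  (default 10,000 seeded multivariate-normal parameter draws, percentile
  interval).
* **Relative importance**: per class, salary range `|β_salary|·6792`,
  binary range `|β_k|`; normalised by the class maximum; pooled scores
  are share-weighted normalised scores (the alternative — pooling raw
  ranges — changes little and is not exposed; normalised pooling keeps
  the [0, 1] scale exact).
* **Uptake change**: `Δ% = 100·(logistic(β'Δx) − 0.5)/0.5` with Δx a
  single-attribute move, evaluated at the mixed-logit means. This point
  formula at mean coefficients (no integration over the random
  coefficients) exactly reproduces the published uptake table from the
  published coefficient means, which is why it is the default; intervals
  again delta or Krinsky–Robb.

The package ships the published estimates as ready-made result objects
(`reference_mixl_result`, `reference_lcm_result`) with diagonal
covariances at the printed standard errors — parameter covariances were
never published, so intervals computed from these presets are
approximations, while point statistics are exact.

## Verification problem sizes and numerical choices

The test suite verifies recovery at the study scale: mixed logit at 352
respondents with R = 200 draws (all means and SDs within 3 SE of truth),
latent class at 2,000 respondents (shares within Monte-Carlo error; AIC
selects 3 classes on the canonical fixture), conditional logit RMSE
shrinking from 352 to 4,000 respondents. Closed-form anchors pin the
implementations: null log-likelihood N·ln ½ (−3903.80 at N = 5,632),
Halton base-2 prefix (0.5, 0.25, 0.75), zero-SD mixed logit equal to the
conditional logit to 1e-10, single-class EM equal to the conditional
logit to 1e-6, analytic gradients against central differences.

Known limitations: AIC class selection sits on a knife edge at n = 2,000
— on some data draws a 4-class fit beats the true 3-class structure by a
~2-point AIC margin, the well-known finite-sample tendency of AIC to
over-select mixture components; BIC would penalise harder but AIC is the
criterion this pipeline mirrors. Simulated-likelihood SEs inherit
simulation noise at small R; the workload SD (true 0.01) is correctly
estimated as indistinguishable from zero, and its magnitude-reported
estimate is upward-biased as any |N(0, σ²)| is. Krinsky–Robb intervals
from the reference presets ignore the unpublished parameter covariances.
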