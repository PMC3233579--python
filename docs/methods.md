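# Methods

## Allocation model

The package tracks a two-arm trial as running per-arm totals and
per-arm, per-factor, per-level counts of categorical prognostic factors.
Two imbalance measures drive the two-way minimizer:

* `D1 = |N_T − N_C|`, the arm-size imbalance;
* `D2 = Σ_k w_k · d(p_{T,k·}, p_{C,k·})`, a weighted sum over factors of a
  distance between the two arms' level-proportion distributions.

**Distribution distance.** The default `d` is the L1 distance
`Σ_l |p_{T,kl} − p_{C,kl}|`, which reduces to `2|p_T − p_C|` for binary
factors and is bounded by 2. A max-over-levels alternative is provided.
The choice is deliberately low-stakes: the allocation rules are purely
comparison-based, so any strictly increasing transform of the distance —
and more generally any monotone re-expression of `D1` or `D2` — produces
identical allocation decisions. This invariance is asserted in the test
suite (cubing `D1`, exponentiating `D2`).

**Factor weights** default to 1 per factor and are user-configurable;
no reweighting is applied internally.

**Burn-in.** Level proportions are undefined while an arm is empty, so
the trial starts under simple randomization and switches to two-way
minimization once both arms contain at least one subject (threshold
configurable). This is the weakest condition that makes `D2`
well-defined; with fair-coin burn-in it is typically over after two or
three subjects.

**Accrual function.** Rule A1 is selected with probability
`π(D1) = 1 − (1 − q)^D1`, the canonical geometric form that is zero at
`D1 = 0`, strictly increasing, and tends to 1 — so size-corrective moves
become near-certain if the arm totals drift apart. The tuning default
`q = 0.05` is the value the sweep experiments identify as a good
efficiency/predictability compromise; the sweep itself
(`evaluation.q_sweep`) treats `q = 0` as the pure covariate-adaptive
boundary (rule A2 always).

**Ties** — in rule A1, rule A2 and the Pocock–Simon comparators — fall
to a fair coin drawn from the caller's RNG stream. Imbalance differences
are rationals with denominators bounded by the arm totals, so a tie
threshold of 1e−12 is many orders of magnitude below the granularity of
genuine differences and classifies only exact ties.

## Comparator schemes

* *Simple randomization*: fair coin per subject.
* *Permuted blocks* (size 4 by default): each complete block holds
  exactly half per arm in uniform random order; a truncated final block
  simply stops (no forced completion beyond the block).
* *Stratified randomization*: permuted blocks run independently within
  each full cross-classification stratum. With many strata and few
  subjects most strata never complete a block, and behavior approaches
  simple randomization — the known failure mode with many
  factors/levels.
* *Deterministic / biased-coin Pocock–Simon minimization*: the marginal
  score of a hypothetical placement is the sum over factors of
  `|n_{T,k,l(k)} − n_{C,k,l(k)}|` at the subject's own levels, using raw
  counts (defined from the first subject) with equal factor weights; the
  score-minimizing arm is chosen with probability 1 (deterministic) or
  0.7 (biased coin).

## Simulation model

Each replicate draws a fresh cohort: binary factors get a non-reference
prevalence from Uniform(0.2, 0.8) (redrawn per replicate, so results
average over prevalence configurations); polytomous factors are
equiprobable. Non-reference level effects are Uniform(0, 2β̄), mean β̄
(a centered alternative Uniform(β̄−c, β̄+c) is available); the reference
level's effect is zero by definition. Responses are
`y_i ~ Normal(α·1[arm=T] + Σ_k β_{k,x_ik}, 1)`.

β̄ defaults to 1.0 for the headline tables. The choice is immaterial
there: the factor effects lie in the column span of the adjusted
regression, so the treatment estimate — hence bias, variance and
rejection rate — is algebraically invariant to the drawn β values (and
likewise shifts exactly by α under a nonzero treatment effect). The
suite asserts this invariance; β̄ only matters for the unadjusted
analyses below.

Randomness is organized as one master seed → per-replicate child
streams → per-trial (cohort, allocation) sub-streams. Profiles and
response noise come from the cohort stream, every allocator coin from
the allocation stream; allocation remains strictly sequential (subject
i's arm depends only on the preceding assignments and subject i's own
profile, verified by prefix replay). Sharing a master seed across
allocators therefore pairs them on identical cohorts, which is how the
method-comparison experiments isolate allocation-driven differences.

## Analysis

The per-trial analysis regresses the response on an intercept, the
treatment indicator, and one dummy per non-reference factor level, all
entered regardless of factor dimension. The treatment coefficient, its
model variance `σ̂²[(X'X)^{-1}]_tt` with `σ̂² = RSS/(n−p)`, and the
two-sided t-test at significance 0.05 are recorded. The solver is a
direct normal-equations Cholesky solve (the matrices are tiny and
well-conditioned after degenerate columns are removed), cross-checked in
the tests against statsmodels OLS and an explicit matrix-inversion
solve. Levels unobserved in a cohort produce zero-variance dummies:
these are dropped and the fit flagged degenerate. Replicates whose
subjects all land in one arm (possible only for simple randomization at
tiny n) are excluded from aggregation with a logged count. A numerically
perfect fit (RSS at rounding level, e.g. a constant response) reports a
zero estimate and p-value 1 rather than a 0/0 t-statistic.

**Analysis pairing in the evaluation.** Schemes that force-balance the
prognostic factors (stratified, deterministic, biased-coin, two-way) are
analysed with the covariate-adjusted regression; simple and block
randomization get the conventional unadjusted two-sample comparison.
The pairing matters: under universal adjustment, power is exactly flat
in β̄ for every scheme (see the invariance above), and the
characteristic collapse of the non-balancing schemes as prognostic
effects grow appears only under their unadjusted analysis, where the
unexplained covariate variation `Var(Σ_k β_k x_k)` inflates the residual
variance. Both analyses are valid tests of the null (allocation is
response-independent), so type I error stays calibrated either way. An
`adjust` flag overrides the pairing per study.

## Evaluation metrics

Per design × scheme cell, over (by default) 10,000 replicates: bias
(mean estimate − α), empirical variance of the estimates, mean of the
model variance estimates (their agreement is the variance-accuracy
claim), rejection rate (type I error under α = 0, power otherwise), and
two predictability indices pooled as ratios of sums: Predictability-I,
the probability the next allocation differs from the previous subject's
arm; Predictability-II, the probability of going to the currently
smaller arm, conditioned on the arm totals differing. Subjects facing
equal totals have no smaller arm and are excluded from the denominator
by default (`tie_mode="half"` counts them 1/2; exclusion is used for
reported indices). Binomial Monte-Carlo standard errors accompany every
rate.

## Problem sizes and tolerances in the test suite

The acceptance tests compare recomputed operating characteristics with
their published values: rates checked at ±0.015 (type I error, 10,000
replicates) or ±0.03 (powers, 5,000 replicates — ~4 binomial SEs);
variances at ±5% relative and bias within 3 MC SEs of zero at 10,000
replicates; the qualitative sweep/comparison orderings at 5,000
replicates with explicit MC-error slack. `scripts/acceptance.py` always
runs the full 10,000 replicates per cell.

## What the generator does and does not emulate

The simulator reproduces the study conditions: sequential recruitment,
independent categorical covariates with the stated prevalence model,
homoscedastic normal responses that are linear in treatment and factor
dummies, and no missingness or dropout. It does not model correlated or
continuous covariates, non-normal/binary/survival outcomes, unequal
target allocation ratios, more than two arms, or time trends in
recruitment — so passing tests certify the allocation and analysis
machinery under these idealized conditions, not robustness to such
departures.

## Known limitations

* Two arms with 1:1 target allocation only.
* The real-time `allocate` CLI persists allocator bookkeeping (pending
  permuted blocks, RNG state) in the state JSON; editing that file by
  hand breaks reproducibility guarantees.
* The Pocock–Simon comparators implement the unweighted
  sum-of-absolute-marginal-differences criterion only.
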