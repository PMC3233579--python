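# twowaymin

Treatment allocation for small two-arm clinical trials: an implementation
of **two-way minimization** — a covariate-adaptive randomization scheme
that stochastically alternates between balancing the arm sizes and
balancing the distributions of prognostic factors — together with five
comparator schemes (simple, permuted-block, stratified, deterministic and
biased-coin Pocock–Simon minimization) and a Monte-Carlo engine that
evaluates them on type I error, power, bias, variance accuracy and
allocation predictability.

It is aimed at trial statisticians who need a real-time allocator for a
small trial with prognostic factors to balance, and at methodologists who
want to benchmark allocation schemes by simulation.

## The method

At any point in the trial let `N_T`, `N_C` be the arm totals and, for
prognostic factor `k` with levels `l`, let `p_{T,kl}`, `p_{C,kl}` be the
within-arm level proportions. Two imbalances are tracked:

```
D1 = |N_T − N_C|                      (arm-size imbalance)
D2 = Σ_k w_k Σ_l |p_{T,kl} − p_{C,kl}|   (covariate-distribution imbalance)
```

After a burn-in of simple randomization (until both arms are nonempty),
each new subject is allocated by one of two rules, chosen by a Bernoulli
draw with probability `π(D1) = 1 − (1 − q)^D1`:

* **A1** (probability `π`): assign to the smaller arm — treatment-adaptive;
* **A2** (probability `1 − π`): assign to the arm that minimizes the
  prospective `D2` if the subject joined it — covariate-adaptive.

Ties fall to a fair coin. Because `π(0) = 0`, a perfectly size-balanced
trial allocates purely on covariates; as `D1` grows, corrective size
moves become increasingly likely. The tuning parameter `q` (default 0.05)
trades statistical efficiency (larger `q`) against allocation
predictability (smaller `q`). Since both rules only *compare* imbalances,
any strictly increasing transform of `D1` or `D2` yields identical
allocations.

Analysis is a multiple linear regression of the response on the treatment
indicator plus dummy codes of the force-balanced factors; the treatment
coefficient, its model variance and a two-sided t-test are reported.

## Worked example

```python
from twowaymin import AllocatorConfig, TrialDesign, run_study

design = TrialDesign(
    n=40, factors="three_binary", treatment_effect=1.0,
    allocator=AllocatorConfig(method="two_way", q=0.05),
    replicates=10_000, seed=7,
)
res = run_study(design)
print(f"power        {res.rejection_rate:.4f} (MC SE {res.rejection_se:.4f})")
print(f"variance     {res.empirical_variance:.4f} / model {res.mean_estimated_variance:.4f}")
print(f"bias         {res.bias:+.4f}")
print(f"predictability I/II  {res.predictability_i:.3f} / {res.predictability_ii:.3f}")
```

prints

```
power        0.8645 (MC SE 0.0034)
variance     0.0986 / model 0.1020
bias         -0.0007
predictability I/II  0.510 / 0.556
```

i.e. with 40 subjects, three binary prognostic factors and a true effect
of 1.0, the two-way minimizer delivers ~87% power, an essentially
unbiased estimate whose model-based variance matches the empirical
sampling variance, and next-allocation predictability close to the coin-
flip 0.5 — the combination that makes the scheme attractive for small
trials.

The command-line interface mirrors the library. Real-time allocation of
recruited subjects from a CSV:

```bash
twowaymin allocate subjects.csv --config trial.yaml --out allocated.csv
```

where `trial.yaml` names the scheme, its parameters, the seed and each
factor's ordered level labels; the run emits the allocations and a state
JSON for resuming the trial at the next recruit. `twowaymin simulate`,
`twowaymin compare` and `twowaymin sweep` drive the simulation engine
from design YAMLs to tidy CSV reports.

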