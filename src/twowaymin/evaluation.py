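"""Monte-Carlo evaluation of allocation schemes.

Runs replicated simulated trials under a design, fits each with the
adjusted regression, and aggregates the operating characteristics used
to judge an allocation scheme:

* bias — mean treatment-effect estimate minus the true effect;
* empirical variance of the estimates across replicates, alongside the
  mean of the model-based variance estimates (their agreement is the
  variance-accuracy check);
* rejection rate — fraction of replicates with two-sided p < 0.05,
  i.e. the type I error rate when the true effect is zero and the
  power otherwise;
* Predictability-I — the probability that a subject is allocated to
  the arm opposite the previous subject's;
* Predictability-II — among allocations made while the arm totals
  differed, the probability of going to the smaller arm.

Both predictability indices are pooled as ratios of sums over all
subjects and replicates.  Subjects who faced equal arm totals have no
"smaller" arm; by default they are excluded from Predictability-II's
denominator (``tie_mode="half"`` counts them as 1/2 instead).

Each scheme is paired with its natural analysis: the four schemes that
force-balance the prognostic factors (stratified, deterministic and
biased-coin minimization, two-way) are analysed with the
covariate-adjusted regression, while simple and block randomization —
which balance nothing — get the unadjusted two-sample comparison.  With
adjustment everywhere, power would be exactly flat in the prognostic
effect size (the design distribution does not depend on it); the
degradation of the non-balancing schemes as prognostic effects grow
only appears under their conventional unadjusted analysis.  Pass
``adjust=True``/``False`` to override the pairing.

Replicates whose treatment indicator is constant (every subject in one
arm — impossible after burn-in for the adaptive schemes, possible for
simple randomization at tiny n) are excluded with a logged count.

Monte-Carlo standard errors accompany every rate so that comparisons
between schemes or tuning values can be made noise-aware.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .allocators import AllocatorConfig
from .analysis import FitError, analyze_trial
from .simulate import TrialDesign, TrialRecord, simulate_trial

logger = logging.getLogger(__name__)

SIGNIFICANCE_LEVEL = 0.05

#: Schemes that force-balance covariates and are therefore analysed with
#: the covariate-adjusted regression by default.
ADJUSTED_METHODS = frozenset(
    {"stratified", "deterministic_minimization", "biased_coin_minimization", "two_way"}
)

METRIC_COLUMNS = [
    "method",
    "n",
    "scenario",
    "treatment_effect",
    "mean_prognostic_effect",
    "q",
    "adjusted",
    "replicates",
    "excluded_replicates",
    "bias",
    "bias_se",
    "empirical_variance",
    "mean_estimated_variance",
    "rejection_rate",
    "rejection_se",
    "predictability_i",
    "predictability_ii",
    "mean_final_d1",
    "mean_final_d2",
    "seed",
]


@dataclass(frozen=True)
class StudyResult:
    """Aggregated metrics for one design x allocator cell."""

    design: TrialDesign
    adjusted: bool
    replicates: int
    excluded_replicates: int
    bias: float
    empirical_variance: float
    mean_estimated_variance: float
    rejection_rate: float
    predictability_i: float
    predictability_ii: float
    mean_final_d1: float
    mean_final_d2: float

    @property
    def bias_se(self) -> float:
        m = self.replicates - self.excluded_replicates
        return float(np.sqrt(self.empirical_variance / m)) if m > 1 else float("nan")

    @property
    def rejection_se(self) -> float:
        m = self.replicates - self.excluded_replicates
        r = self.rejection_rate
        return float(np.sqrt(r * (1.0 - r) / m)) if m > 0 else float("nan")

    def row(self) -> dict:
        d = self.design
        scenario = d.factors if isinstance(d.factors, str) else str(d.spec.levels)
        return {
            "method": d.allocator.method,
            "n": d.n,
            "scenario": scenario,
            "treatment_effect": d.treatment_effect,
            "mean_prognostic_effect": d.mean_prognostic_effect,
            "q": d.allocator.q if d.allocator.method == "two_way" else float("nan"),
            "adjusted": self.adjusted,
            "replicates": self.replicates,
            "excluded_replicates": self.excluded_replicates,
            "bias": self.bias,
            "bias_se": self.bias_se,
            "empirical_variance": self.empirical_variance,
            "mean_estimated_variance": self.mean_estimated_variance,
            "rejection_rate": self.rejection_rate,
            "rejection_se": self.rejection_se,
            "predictability_i": self.predictability_i,
            "predictability_ii": self.predictability_ii,
            "mean_final_d1": self.mean_final_d1,
            "mean_final_d2": self.mean_final_d2,
            "seed": d.seed,
        }


def predictability_indices(
    records: Sequence[TrialRecord], tie_mode: str = "exclude"
) -> tuple[float, float]:
    """Pooled (Predictability-I, Predictability-II) over trial records."""
    if tie_mode not in ("exclude", "half"):
        raise ValueError(f"tie_mode must be 'exclude' or 'half', got {tie_mode!r}")
    switches = 0
    transitions = 0
    smaller_hits = 0.0
    smaller_total = 0
    for rec in records:
        if rec.n < 2:
            raise ValueError("predictability needs at least 2 subjects per trial")
        switches += int(rec.switched[1:].sum())
        transitions += rec.n - 1
        defined = rec.prev_diff
        smaller_hits += float(rec.to_smaller[defined].sum())
        smaller_total += int(defined.sum())
        if tie_mode == "half":
            ties = rec.n - int(defined.sum())
            smaller_hits += 0.5 * ties
            smaller_total += ties
    p1 = switches / transitions if transitions else float("nan")
    p2 = smaller_hits / smaller_total if smaller_total else float("nan")
    return p1, p2


def run_study(
    design: TrialDesign,
    tie_mode: str = "exclude",
    allocator_kwargs: dict | None = None,
    significance: float = SIGNIFICANCE_LEVEL,
    adjust: bool | None = None,
) -> StudyResult:
    """Simulate and analyse ``design.replicates`` independent trials.

    Each replicate runs under its own child stream spawned from the
    design's master seed, so results are bit-reproducible and, for a
    shared seed, different allocators face identical cohorts.
    ``adjust=None`` selects the scheme's natural analysis (see the
    module docstring).
    """
    if adjust is None:
        adjust = design.allocator.method in ADJUSTED_METHODS
    master = np.random.SeedSequence(design.seed)
    children = master.spawn(design.replicates)
    estimates: list[float] = []
    variances: list[float] = []
    p_values: list[float] = []
    records: list[TrialRecord] = []
    final_d1: list[float] = []
    final_d2: list[float] = []
    excluded = 0
    for child in children:
        record = simulate_trial(design, child, allocator_kwargs=allocator_kwargs)
        records.append(record)
        final_d1.append(float(record.final_d1))
        final_d2.append(record.final_d2)
        try:
            fit = analyze_trial(record, adjust=adjust)
        except FitError as err:
            excluded += 1
            logger.debug("replicate excluded: %s", err)
            continue
        estimates.append(fit.estimate)
        variances.append(fit.variance_estimate)
        p_values.append(fit.p_value)

    if not estimates:
        raise RuntimeError("every replicate was excluded; the study is empty")
    if excluded:
        logger.info(
            "excluded %d of %d replicates (treatment arm degenerate)",
            excluded,
            design.replicates,
        )
    est = np.asarray(estimates)
    p1, p2 = predictability_indices(records, tie_mode=tie_mode)
    return StudyResult(
        design=design,
        adjusted=adjust,
        replicates=design.replicates,
        excluded_replicates=excluded,
        bias=float(est.mean() - design.treatment_effect),
        empirical_variance=float(est.var(ddof=1)) if len(est) > 1 else float("nan"),
        mean_estimated_variance=float(np.mean(variances)),
        rejection_rate=float(np.mean(np.asarray(p_values) < significance)),
        predictability_i=p1,
        predictability_ii=p2,
        mean_final_d1=float(np.mean(final_d1)),
        mean_final_d2=float(np.nanmean(final_d2)),
    )


def _as_table(results: Sequence[StudyResult]) -> pd.DataFrame:
    return pd.DataFrame([r.row() for r in results], columns=METRIC_COLUMNS)


def q_sweep(design: TrialDesign, q_grid: Sequence[float]) -> pd.DataFrame:
    """One study per tuning value ``q``; ``q = 0`` runs the pure
    covariate-adaptive boundary (rule A2 on every post-burn-in step)."""
    if design.allocator.method != "two_way":
        raise ValueError("q_sweep only applies to the two-way minimizer")
    results = []
    for q in q_grid:
        if q == 0:
            cfg = design.allocator
            kwargs = {"rule_override": "A2"}
        elif 0 < q < 1:
            cfg = replace(design.allocator, q=float(q))
            kwargs = None
        else:
            raise ValueError(f"q must lie in [0, 1), got {q}")
        res = run_study(replace(design, allocator=cfg), allocator_kwargs=kwargs)
        row = res.row()
        row["q"] = float(q)
        results.append(row)
    return pd.DataFrame(results, columns=METRIC_COLUMNS)


def method_comparison(
    design: TrialDesign,
    methods: Sequence[str | AllocatorConfig] | None = None,
    adjust: bool | None = None,
) -> pd.DataFrame:
    """One study per allocation scheme under common cohorts.

    All schemes run from the same master seed; because cohort and
    allocation randomness live on separate child streams, every scheme
    sees the identical sequence of subjects, prognostic effects and
    response noise, so metric differences are allocation-driven.
    """
    if methods is None:
        methods = [
            "simple",
            "block",
            "stratified",
            "deterministic_minimization",
            "biased_coin_minimization",
            "two_way",
        ]
    results = []
    for method in methods:
        cfg = (
            method
            if isinstance(method, AllocatorConfig)
            else replace(design.allocator, method=method)
        )
        results.append(run_study(replace(design, allocator=cfg), adjust=adjust))
    return _as_table(results)
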