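"""Synthetic small-trial generator.

A simulated trial recruits ``n`` subjects sequentially.  Each subject's
categorical prognostic profile is drawn from per-factor level
probabilities; the chosen allocator assigns an arm against the running
trial state; and the response is drawn from a unit-variance normal whose
mean is the treatment effect (if treated) plus the sum of the subject's
prognostic-factor effects.

Study conditions (the defaults):

* binary factors: the probability of the non-reference level is drawn
  fresh each replicate from Uniform(0.2, 0.8);
* polytomous factors: all levels equiprobable;
* non-reference level effects drawn from Uniform(0, 2 * beta_bar), so
  their mean equals ``beta_bar``, the average prognostic effect; the
  reference level's effect is 0 by definition;
* responses ``y_i ~ Normal(alpha * 1[arm=T] + sum_k beta_{k, x_ik}, 1)``.

Randomness is split into two child streams per trial: a *cohort* stream
(prevalences, effects, profiles, response noise) and an *allocation*
stream (every coin the allocator flips).  Trials simulated from the same
seed therefore share their cohort across different allocators, which is
what the method-comparison experiments rely on.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .allocators import AllocatorConfig, make_allocator
from .state import (
    CONTROL,
    TREATMENT,
    FactorSpec,
    SubjectProfile,
    TrialState,
    overall_distribution_imbalance,
    total_imbalance,
)

#: Named factor scenarios studied in the evaluation experiments.
SCENARIOS: dict[str, FactorSpec] = {
    "three_binary": FactorSpec((2, 2, 2)),
    "six_binary": FactorSpec((2, 2, 2, 2, 2, 2)),
    "three_polytomous": FactorSpec((5, 4, 3)),
}


def resolve_factors(factors: FactorSpec | str) -> FactorSpec:
    if isinstance(factors, FactorSpec):
        return factors
    try:
        return SCENARIOS[factors]
    except KeyError:
        raise ValueError(
            f"unknown factor scenario {factors!r}; expected one of {sorted(SCENARIOS)} "
            "or an explicit FactorSpec"
        ) from None


@dataclass(frozen=True)
class TrialDesign:
    """Everything that determines a simulation scenario.

    Parameters
    ----------
    n
        Subjects per trial.
    factors
        A :class:`FactorSpec` or a scenario name from :data:`SCENARIOS`.
    treatment_effect
        True treatment effect ``alpha`` on the response scale.
    mean_prognostic_effect
        Average effect ``beta_bar`` of the prognostic factors; each
        non-reference level effect is Uniform(0, 2*beta_bar) unless
        ``effect_halfwidth`` selects the centered alternative
        Uniform(beta_bar - c, beta_bar + c).
    allocator
        The allocation scheme configuration.
    prevalences
        Optional fixed per-factor level probabilities; by default binary
        prevalences are redrawn each replicate and polytomous levels are
        equiprobable.
    """

    n: int = 20
    factors: FactorSpec | str = "three_binary"
    treatment_effect: float = 0.0
    mean_prognostic_effect: float = 1.0
    allocator: AllocatorConfig = field(default_factory=AllocatorConfig)
    replicates: int = 10_000
    seed: int = 0
    effect_halfwidth: float | None = None
    prevalences: tuple[tuple[float, ...], ...] | None = None

    def __post_init__(self) -> None:
        if self.n < 2:
            raise ValueError("a trial needs at least 2 subjects")
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")
        if self.mean_prognostic_effect < 0:
            raise ValueError("mean_prognostic_effect must be nonnegative")

    @property
    def spec(self) -> FactorSpec:
        return resolve_factors(self.factors)


@dataclass
class TrialRecord:
    """One completed simulated trial.

    ``prev_diff[i]`` flags that the arm totals differed just before
    subject ``i`` was allocated, and ``to_smaller[i]`` that the subject
    went to the then-smaller arm (meaningful only where ``prev_diff``).
    ``switched[i]`` flags that subject ``i``'s arm differs from subject
    ``i-1``'s (undefined at ``i = 0``).
    """

    spec: FactorSpec
    profiles: np.ndarray  # (n, K) int level indices
    arms: np.ndarray  # (n,) '<U1' labels
    responses: np.ndarray  # (n,) float
    prevalences: list[np.ndarray]
    effects: np.ndarray  # (K, max_levels) float, reference column zero
    prev_diff: np.ndarray  # (n,) bool
    to_smaller: np.ndarray  # (n,) bool
    switched: np.ndarray  # (n,) bool; switched[0] is always False
    final_d1: int
    final_d2: float

    @property
    def n(self) -> int:
        return len(self.arms)

    @property
    def treatment_indicator(self) -> np.ndarray:
        return (self.arms == TREATMENT).astype(np.float64)

    def final_state(self) -> TrialState:
        """Rebuild the end-of-trial state from the stored allocations."""
        state = TrialState(self.spec)
        for row, arm in zip(self.profiles, self.arms):
            state.update(SubjectProfile(tuple(int(v) for v in row)), str(arm))
        return state


def draw_prevalences(
    spec: FactorSpec, rng: np.random.Generator
) -> list[np.ndarray]:
    """Per-factor level probabilities for one replicate.

    Binary factors get a fresh non-reference prevalence from
    Uniform(0.2, 0.8); polytomous factors are equiprobable.
    """
    prevalences = []
    for L in spec.levels:
        if L == 2:
            p = rng.uniform(0.2, 0.8)
            prevalences.append(np.array([1.0 - p, p]))
        else:
            prevalences.append(np.full(L, 1.0 / L))
    return prevalences


def draw_effects(
    spec: FactorSpec,
    mean_effect: float,
    rng: np.random.Generator,
    halfwidth: float | None = None,
) -> np.ndarray:
    """Per-level prognostic effects for one replicate.

    Returns a ``(K, max_levels)`` array whose reference column (level 0)
    is zero.  Non-reference effects are Uniform(0, 2*mean_effect), or
    Uniform(mean_effect - halfwidth, mean_effect + halfwidth) when a
    halfwidth is given; either way their mean is ``mean_effect``.
    """
    if halfwidth is None:
        low, high = 0.0, 2.0 * mean_effect
    else:
        low, high = mean_effect - halfwidth, mean_effect + halfwidth
    effects = np.zeros((spec.n_factors, spec.max_levels))
    for k, L in enumerate(spec.levels):
        if high > low:
            effects[k, 1:L] = rng.uniform(low, high, size=L - 1)
        else:
            effects[k, 1:L] = low  # degenerate interval (e.g. mean_effect = 0)
    return effects


def _draw_profiles(
    n: int, prevalences: Sequence[np.ndarray], rng: np.random.Generator
) -> np.ndarray:
    """Draw an (n, K) matrix of level indices, one column per factor."""
    cols = []
    for probs in prevalences:
        cum = np.cumsum(probs)
        cum[-1] = 1.0  # guard against round-off in the last bin
        cols.append(np.searchsorted(cum, rng.random(n), side="right"))
    return np.column_stack(cols).astype(np.int64)


def simulate_trial(
    design: TrialDesign,
    seed: int | np.random.SeedSequence | None = None,
    allocator_kwargs: dict | None = None,
) -> TrialRecord:
    """Simulate one trial under ``design``; fully determined by the seed.

    ``allocator_kwargs`` are forwarded to the allocator constructor
    (e.g. ``rule_override`` for the two-way minimizer).
    """
    if seed is None:
        seed = design.seed
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    cohort_rng, alloc_rng = (np.random.default_rng(s) for s in ss.spawn(2))

    spec = design.spec
    n = design.n
    if design.prevalences is not None:
        prevalences = [np.asarray(p, dtype=float) for p in design.prevalences]
    else:
        prevalences = draw_prevalences(spec, cohort_rng)
    effects = draw_effects(
        spec, design.mean_prognostic_effect, cohort_rng, design.effect_halfwidth
    )
    profiles = _draw_profiles(n, prevalences, cohort_rng)
    noise = cohort_rng.standard_normal(n)

    allocator = make_allocator(spec, design.allocator, **(allocator_kwargs or {}))
    state = TrialState(spec)
    arms = np.empty(n, dtype="<U1")
    prev_diff = np.zeros(n, dtype=bool)
    to_smaller = np.zeros(n, dtype=bool)
    for i in range(n):
        profile = SubjectProfile(tuple(int(v) for v in profiles[i]))
        n_t, n_c = int(state.totals[0]), int(state.totals[1])
        arm = allocator.assign(state, profile, alloc_rng)
        if n_t != n_c:
            prev_diff[i] = True
            smaller = TREATMENT if n_t < n_c else CONTROL
            to_smaller[i] = arm == smaller
        arms[i] = arm
        state.update(profile, arm)

    treat = (arms == TREATMENT).astype(np.float64)
    factor_idx = np.arange(spec.n_factors)[:, None]
    lin_pred = design.treatment_effect * treat + effects[factor_idx, profiles.T].sum(axis=0)
    responses = lin_pred + noise

    switched = np.zeros(n, dtype=bool)
    switched[1:] = arms[1:] != arms[:-1]
    final_d1 = total_imbalance(state)
    final_d2 = (
        overall_distribution_imbalance(state) if state.burned_in() else float("nan")
    )
    return TrialRecord(
        spec=spec,
        profiles=profiles,
        arms=arms,
        responses=responses,
        prevalences=prevalences,
        effects=effects,
        prev_diff=prev_diff,
        to_smaller=to_smaller,
        switched=switched,
        final_d1=final_d1,
        final_d2=final_d2,
    )
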