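"""The six treatment-allocation schemes.

Every allocator shares one contract: given the trial's running
:class:`~twowaymin.state.TrialState`, the new subject's profile, and a
NumPy random generator, :meth:`~Allocator.assign` returns an arm label
(``"T"`` or ``"C"``).  Allocators that need private bookkeeping beyond
the shared state (pending permuted blocks, per-stratum blocks) hold it
on the instance, so a fresh allocator plus a fixed seed reproduces an
allocation sequence exactly.

Schemes
-------
``simple``
    Fair coin per subject, state-independent.
``block``
    Permuted blocks: every complete block of ``block_size`` consecutive
    subjects contains exactly half per arm, in uniform random order.
``stratified``
    Permuted blocks run independently within each cross-classification
    stratum of the subject's factor levels.
``deterministic_minimization``
    Pocock–Simon: assign to the arm minimizing the marginal
    covariate-imbalance score; fair coin on ties.
``biased_coin_minimization``
    As above, but the score-minimizing arm is chosen only with a fixed
    coin probability (0.7 by default).
``two_way``
    Two-way minimization: after a burn-in of simple randomization
    (until both arms are nonempty), a Bernoulli draw with probability
    ``pi(D1) = 1 - (1-q)^D1`` selects between rule A1 — minimize the
    arm-size imbalance D1 — and rule A2 — minimize the prospective
    covariate-distribution imbalance D2.  Larger arm-size imbalance
    makes corrective A1 steps more likely; at D1 = 0 the decision is
    purely covariate-adaptive.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np

from .state import (
    CONTROL,
    TIE_TOLERANCE,
    TREATMENT,
    FactorSpec,
    SubjectProfile,
    TrialState,
    arm_index,
    prospective_imbalance,
    total_imbalance,
)

METHODS = (
    "simple",
    "block",
    "stratified",
    "deterministic_minimization",
    "biased_coin_minimization",
    "two_way",
)


def accrual_probability(d1: int, q: float) -> float:
    """Geometric accrual probability ``pi(D1) = 1 - (1 - q)**D1``.

    Equals 0 at ``D1 = 0``, is strictly increasing in ``D1`` and tends
    to 1 as ``D1`` grows; ``q`` in (0, 1) governs the accrual rate.
    """
    if not 0.0 < q < 1.0:
        raise ValueError(f"tuning parameter q must lie strictly in (0, 1), got {q}")
    if d1 < 0:
        raise ValueError("D1 is an absolute difference and cannot be negative")
    return 1.0 - (1.0 - q) ** d1


@dataclass(frozen=True)
class AllocatorConfig:
    """Configuration selecting an allocation scheme and its parameters."""

    method: str = "two_way"
    block_size: int = 4
    coin_probability: float = 0.7
    q: float = 0.05
    burn_in: int = 1  # minimum subjects per arm before two-way kicks in
    distance: str = "l1"

    def __post_init__(self) -> None:
        if self.method not in METHODS:
            raise ValueError(f"unknown method {self.method!r}; expected one of {METHODS}")
        if self.method in ("block", "stratified"):
            if self.block_size <= 0 or self.block_size % 2:
                raise ValueError(f"block_size must be a positive even integer, got {self.block_size}")
        if self.method == "biased_coin_minimization" and not 0.5 < self.coin_probability <= 1.0:
            raise ValueError(
                f"coin_probability must lie in (0.5, 1], got {self.coin_probability}"
            )
        if self.method == "two_way":
            accrual_probability(0, self.q)  # validates q
            if self.burn_in < 1:
                raise ValueError("burn_in must be >= 1 subject per arm")


def _coin(rng: np.random.Generator) -> str:
    return TREATMENT if rng.random() < 0.5 else CONTROL


class Allocator:
    """Base class: stateless fair-coin (simple randomization)."""

    def __init__(self, spec: FactorSpec, config: AllocatorConfig):
        self.spec = spec
        self.config = config

    def assign(
        self, state: TrialState, profile: SubjectProfile, rng: np.random.Generator
    ) -> str:
        raise NotImplementedError

    # Bookkeeping beyond the shared TrialState (pending blocks), for
    # suspending and resuming a real trial between subjects.
    def export_state(self) -> dict:
        return {}

    def restore_state(self, data: dict) -> None:
        if data:
            raise ValueError(f"{type(self).__name__} carries no internal state")


class SimpleRandomizer(Allocator):
    def assign(self, state, profile, rng) -> str:
        return _coin(rng)


class BlockRandomizer(Allocator):
    """Permuted-block randomization; an incomplete final block simply stops."""

    def __init__(self, spec, config):
        super().__init__(spec, config)
        self._pending: list[str] = []

    def _new_block(self, rng: np.random.Generator) -> list[str]:
        half = self.config.block_size // 2
        block = [TREATMENT] * half + [CONTROL] * half
        order = rng.permutation(self.config.block_size)
        return [block[i] for i in order]

    def assign(self, state, profile, rng) -> str:
        if not self._pending:
            self._pending = self._new_block(rng)
        return self._pending.pop(0)

    def export_state(self) -> dict:
        return {"pending": list(self._pending)}

    def restore_state(self, data: dict) -> None:
        self._pending = list(data.get("pending", []))


class StratifiedRandomizer(BlockRandomizer):
    """Permuted blocks run independently within each covariate stratum.

    The stratum is the full cross-classification cell of the subject's
    factor levels, so with many factors or levels most strata hold very
    few subjects and balance degrades toward simple randomization.
    """

    def __init__(self, spec, config):
        super().__init__(spec, config)
        self._strata: dict[tuple[int, ...], list[str]] = {}

    def assign(self, state, profile, rng) -> str:
        key = profile.levels
        pending = self._strata.get(key)
        if not pending:
            pending = self._strata[key] = self._new_block(rng)
        return pending.pop(0)

    def export_state(self) -> dict:
        return {
            "strata": {
                ",".join(map(str, key)): list(block)
                for key, block in self._strata.items()
            }
        }

    def restore_state(self, data: dict) -> None:
        self._strata = {
            tuple(int(v) for v in key.split(",")): list(block)
            for key, block in data.get("strata", {}).items()
        }


def marginal_imbalance_score(
    state: TrialState, profile: SubjectProfile, arm: str
) -> int:
    """Pocock–Simon marginal imbalance score of a hypothetical placement.

    Sum over factors of ``|n_T,k,l(k) - n_C,k,l(k)|`` at the subject's own
    levels ``l(k)``, after placing the subject in ``arm``.  Raw counts, not
    proportions, so the score is defined from the very first subject.
    """
    profile.validate(state.spec)
    a = arm_index(arm)
    sign = 1 if a == 0 else -1
    score = 0
    counts = state.counts
    for k, l in enumerate(profile.levels):
        score += abs(int(counts[0, k, l]) - int(counts[1, k, l]) + sign)
    return score


class DeterministicMinimizer(Allocator):
    """Pocock–Simon minimization choosing the score-minimizing arm with
    probability 1 (fair coin on ties)."""

    coin_probability = 1.0

    def assign(self, state, profile, rng) -> str:
        s_t = marginal_imbalance_score(state, profile, TREATMENT)
        s_c = marginal_imbalance_score(state, profile, CONTROL)
        if abs(s_t - s_c) < TIE_TOLERANCE:
            return _coin(rng)
        best = TREATMENT if s_t < s_c else CONTROL
        p = self.coin_probability
        if p >= 1.0:
            return best
        return best if rng.random() < p else (CONTROL if best == TREATMENT else TREATMENT)


class BiasedCoinMinimizer(DeterministicMinimizer):
    """Pocock–Simon minimization with a biased coin: the score-minimizing
    arm is chosen with probability ``coin_probability``.

    The explicit ``coin_probability`` argument overrides the config and
    accepts the limiting values 1.0 (deterministic minimization) and 0.5
    (simple randomization) for reduction checks.
    """

    def __init__(self, spec, config, coin_probability: float | None = None):
        super().__init__(spec, config)
        p = config.coin_probability if coin_probability is None else coin_probability
        if not 0.5 <= p <= 1.0:
            raise ValueError(f"coin probability must lie in [0.5, 1], got {p}")
        self.coin_probability = p


class TwoWayMinimizer(Allocator):
    """Two-way minimization.

    Parameters beyond the config are test hooks: ``rule_override`` forces
    every post-burn-in decision through rule A1 (``"A1"``) or rule A2
    (``"A2"``); ``d1_transform`` / ``d2_transform`` apply strictly
    increasing transforms before comparison, which must not change any
    decision (the rules are purely comparison-based).
    """

    def __init__(
        self,
        spec,
        config,
        rule_override: str | None = None,
        d1_transform: Callable[[float], float] | None = None,
        d2_transform: Callable[[float], float] | None = None,
    ):
        super().__init__(spec, config)
        if rule_override not in (None, "A1", "A2"):
            raise ValueError("rule_override must be None, 'A1' or 'A2'")
        self.rule_override = rule_override
        self.d1_transform = d1_transform or (lambda x: x)
        self.d2_transform = d2_transform or (lambda x: x)

    def rule_a1(self, state: TrialState, rng: np.random.Generator) -> str:
        """Minimize arm-size imbalance: allocate to the smaller arm."""
        f = self.d1_transform
        n_t, n_c = f(float(state.totals[0])), f(float(state.totals[1]))
        if abs(n_t - n_c) < TIE_TOLERANCE:
            return _coin(rng)
        return TREATMENT if n_t < n_c else CONTROL

    def rule_a2(
        self, state: TrialState, profile: SubjectProfile, rng: np.random.Generator
    ) -> str:
        """Minimize prospective covariate-distribution imbalance."""
        dist = self.config.distance
        f = self.d2_transform
        d_t = f(prospective_imbalance(state, profile, TREATMENT, distance=dist))
        d_c = f(prospective_imbalance(state, profile, CONTROL, distance=dist))
        if abs(d_t - d_c) < TIE_TOLERANCE:
            return _coin(rng)
        return TREATMENT if d_t < d_c else CONTROL

    def assign(self, state, profile, rng) -> str:
        if not state.burned_in(self.config.burn_in):
            return _coin(rng)
        if self.rule_override == "A1":
            return self.rule_a1(state, rng)
        if self.rule_override == "A2":
            return self.rule_a2(state, profile, rng)
        pi = accrual_probability(total_imbalance(state), self.config.q)
        if rng.random() < pi:
            return self.rule_a1(state, rng)
        return self.rule_a2(state, profile, rng)


_CLASSES = {
    "simple": SimpleRandomizer,
    "block": BlockRandomizer,
    "stratified": StratifiedRandomizer,
    "deterministic_minimization": DeterministicMinimizer,
    "biased_coin_minimization": BiasedCoinMinimizer,
    "two_way": TwoWayMinimizer,
}


def make_allocator(spec: FactorSpec, config: AllocatorConfig, **kwargs) -> Allocator:
    """Instantiate the allocator named by ``config.method``."""
    return _CLASSES[config.method](spec, config, **kwargs)
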