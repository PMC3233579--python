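"""Trial state and imbalance measures.

A two-arm trial is tracked as running per-arm totals and per-arm,
per-factor, per-level counts of categorical prognostic factors.  Two
imbalance measures drive covariate-adaptive allocation:

* ``D1`` — the absolute difference in the numbers of subjects allocated
  to the two arms (:func:`total_imbalance`);
* ``D2`` — a weighted sum over prognostic factors of a distance between
  the two arms' level-proportion distributions
  (:func:`overall_distribution_imbalance`).

The per-factor distance defaults to the L1 distance
``sum_l |p_T,kl - p_C,kl|``; a max-over-levels alternative is available.
Because allocation rules only ever *compare* imbalances, any strictly
increasing transform of the distance yields identical decisions, so the
exact functional form is not critical.

Proportions are undefined while an arm is empty; imbalance functions
raise :class:`BurnInError` in that case, signalling that the initial
simple-randomization phase has not yet completed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

TREATMENT = "T"
CONTROL = "C"
ARMS = (TREATMENT, CONTROL)
_ARM_INDEX = {TREATMENT: 0, CONTROL: 1}

#: Differences in imbalance below this are treated as exact ties.  Imbalance
#: differences are rationals with denominators bounded by the arm totals, so
#: their granularity is many orders of magnitude above this.
TIE_TOLERANCE = 1e-12


class BurnInError(RuntimeError):
    """Raised when a proportion-based imbalance is requested while an arm
    is still empty (the burn-in phase has not completed)."""


def arm_index(arm: str) -> int:
    """Map an arm label (``"T"`` or ``"C"``) to its internal index."""
    try:
        return _ARM_INDEX[arm]
    except KeyError:
        raise ValueError(f"unknown arm label {arm!r}; expected one of {ARMS}") from None


def other_arm(arm: str) -> str:
    return CONTROL if arm == TREATMENT else TREATMENT


@dataclass(frozen=True)
class FactorSpec:
    """Structure of the prognostic factors to be balanced.

    Parameters
    ----------
    levels
        Number of levels per factor, each >= 2.  Level index 0 is the
        designated reference level.
    weights
        Nonnegative weight per factor in the weighted sum defining the
        overall distribution imbalance.  Defaults to 1 for every factor.
    """

    levels: tuple[int, ...]
    weights: tuple[float, ...] = ()

    def __post_init__(self) -> None:
        levels = tuple(int(l) for l in self.levels)
        object.__setattr__(self, "levels", levels)
        if not levels:
            raise ValueError("at least one prognostic factor is required")
        if any(l < 2 for l in levels):
            raise ValueError(f"every factor needs >= 2 levels, got {levels}")
        weights = tuple(float(w) for w in (self.weights or (1.0,) * len(levels)))
        object.__setattr__(self, "weights", weights)
        if len(weights) != len(levels):
            raise ValueError("weights length must equal the number of factors")
        if any(w < 0 for w in weights):
            raise ValueError("weights must be nonnegative")
        if not any(w > 0 for w in weights):
            raise ValueError("at least one weight must be positive")

    @property
    def n_factors(self) -> int:
        return len(self.levels)

    @property
    def max_levels(self) -> int:
        return max(self.levels)


@dataclass(frozen=True)
class SubjectProfile:
    """One subject's vector of categorical factor levels (0-based;
    level 0 is the reference level of each factor)."""

    levels: tuple[int, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "levels", tuple(int(l) for l in self.levels))

    def validate(self, spec: FactorSpec) -> None:
        if len(self.levels) != spec.n_factors:
            raise ValueError(
                f"profile has {len(self.levels)} factors, spec has {spec.n_factors}"
            )
        for k, (l, L) in enumerate(zip(self.levels, spec.levels)):
            if not 0 <= l < L:
                raise ValueError(
                    f"factor {k}: level {l} outside the valid range [0, {L - 1}]"
                )


class TrialState:
    """Running allocation state of a two-arm trial.

    Attributes
    ----------
    spec
        The factor structure being balanced.
    totals
        ``(2,)`` integer array of per-arm subject totals ``(N_T, N_C)``.
    counts
        ``(2, K, max_levels)`` integer array; ``counts[a, k, l]`` is the
        number of subjects in arm ``a`` whose factor ``k`` is at level
        ``l``.  Entries beyond a factor's level count stay zero.
    history
        Ordered list of ``(subject_index, arm_label)`` assignments.
    """

    def __init__(self, spec: FactorSpec):
        self.spec = spec
        self.totals = np.zeros(2, dtype=np.int64)
        self.counts = np.zeros((2, spec.n_factors, spec.max_levels), dtype=np.int64)
        self.history: list[tuple[int, str]] = []

    def update(self, profile: SubjectProfile, arm: str) -> "TrialState":
        """Record one allocation in place; returns ``self`` for chaining."""
        profile.validate(self.spec)
        a = arm_index(arm)
        self.totals[a] += 1
        for k, l in enumerate(profile.levels):
            self.counts[a, k, l] += 1
        self.history.append((len(self.history), arm))
        return self

    def copy(self) -> "TrialState":
        new = TrialState.__new__(TrialState)
        new.spec = self.spec
        new.totals = self.totals.copy()
        new.counts = self.counts.copy()
        new.history = list(self.history)
        return new

    @property
    def n_subjects(self) -> int:
        return int(self.totals.sum())

    def burned_in(self, min_per_arm: int = 1) -> bool:
        """True once both arms hold at least ``min_per_arm`` subjects."""
        return bool(self.totals.min() >= min_per_arm)

    # -- serialization ------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "levels": list(self.spec.levels),
            "weights": list(self.spec.weights),
            "totals": self.totals.tolist(),
            "counts": self.counts.tolist(),
            "history": [[i, arm] for i, arm in self.history],
        }

    @classmethod
    def from_dict(cls, data: dict) -> "TrialState":
        spec = FactorSpec(tuple(data["levels"]), tuple(data["weights"]))
        state = cls(spec)
        state.totals = np.asarray(data["totals"], dtype=np.int64)
        state.counts = np.asarray(data["counts"], dtype=np.int64)
        state.history = [(int(i), str(arm)) for i, arm in data["history"]]
        if state.counts.shape != (2, spec.n_factors, spec.max_levels):
            raise ValueError("count tensor shape inconsistent with factor spec")
        return state

    def to_json(self) -> str:
        return json.dumps(self.to_dict())

    @classmethod
    def from_json(cls, text: str) -> "TrialState":
        return cls.from_dict(json.loads(text))


# ---------------------------------------------------------------------------
# Imbalance measures
# ---------------------------------------------------------------------------

def total_imbalance(state: TrialState) -> int:
    """Arm-size imbalance ``D1 = |N_T - N_C|``."""
    return int(abs(state.totals[0] - state.totals[1]))


def factor_distribution(state: TrialState, arm: str, factor: int) -> np.ndarray:
    """Level proportions of one factor within one arm; entries sum to 1."""
    a = arm_index(arm)
    total = state.totals[a]
    if total == 0:
        raise BurnInError(
            f"arm {arm!r} is empty; distribution imbalance is undefined before burn-in"
        )
    L = state.spec.levels[factor]
    return state.counts[a, factor, :L] / total


def factor_imbalance(state: TrialState, factor: int, distance: str = "l1") -> float:
    """Distance between the two arms' level distributions of one factor.

    ``distance="l1"`` (default) gives ``sum_l |p_T,kl - p_C,kl|``, bounded
    by 2; ``distance="max"`` gives ``max_l |p_T,kl - p_C,kl|``.
    """
    p_t = factor_distribution(state, TREATMENT, factor)
    p_c = factor_distribution(state, CONTROL, factor)
    diff = np.abs(p_t - p_c)
    if distance == "l1":
        return float(diff.sum())
    if distance == "max":
        return float(diff.max())
    raise ValueError(f"unknown distance {distance!r}; expected 'l1' or 'max'")


def overall_distribution_imbalance(
    state: TrialState, spec: FactorSpec | None = None, distance: str = "l1"
) -> float:
    """Covariate-distribution imbalance ``D2 = sum_k w_k D_k``."""
    spec = spec or state.spec
    return float(
        sum(
            w * factor_imbalance(state, k, distance)
            for k, w in enumerate(spec.weights)
        )
    )


def prospective_imbalance(
    state: TrialState,
    profile: SubjectProfile,
    arm: str,
    spec: FactorSpec | None = None,
    distance: str = "l1",
) -> float:
    """``D2`` of the hypothetical state with ``profile`` added to ``arm``.

    The input state is left untouched.
    """
    spec = spec or state.spec
    profile.validate(spec)
    a = arm_index(arm)
    totals = state.totals.astype(np.float64)
    totals[a] += 1
    if totals.min() == 0:
        raise BurnInError(
            "an arm would still be empty; prospective imbalance is undefined"
        )
    d2 = 0.0
    counts = state.counts
    for k, w in enumerate(spec.weights):
        L = spec.levels[k]
        c_t = counts[0, k, :L].astype(np.float64)
        c_c = counts[1, k, :L].astype(np.float64)
        if a == 0:
            c_t = c_t.copy()
            c_t[profile.levels[k]] += 1
        else:
            c_c = c_c.copy()
            c_c[profile.levels[k]] += 1
        diff = np.abs(c_t / totals[0] - c_c / totals[1])
        d2 += w * (diff.sum() if distance == "l1" else diff.max())
    return float(d2)


def replay(
    spec: FactorSpec, assignments: Iterable[tuple[SubjectProfile, str]]
) -> TrialState:
    """Build a state from scratch by replaying (profile, arm) pairs."""
    state = TrialState(spec)
    for profile, arm in assignments:
        state.update(profile, arm)
    return state
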