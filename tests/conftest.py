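import numpy as np
import pytest

from twowaymin import CONTROL, TREATMENT, FactorSpec, SubjectProfile, TrialState


@pytest.fixture
def spec1b() -> FactorSpec:
    return FactorSpec((2,))


@pytest.fixture
def spec3b() -> FactorSpec:
    return FactorSpec((2, 2, 2))


@pytest.fixture
def spec_poly() -> FactorSpec:
    return FactorSpec((5, 4, 3))


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20260920)


def build_state(spec: FactorSpec, assignments) -> TrialState:
    """Build a state from (levels-tuple, arm) pairs."""
    state = TrialState(spec)
    for levels, arm in assignments:
        state.update(SubjectProfile(levels), arm)
    return state


def random_assignments(spec: FactorSpec, n: int, rng: np.random.Generator):
    """n random (levels, arm) pairs for the given factor structure."""
    out = []
    for _ in range(n):
        levels = tuple(int(rng.integers(L)) for L in spec.levels)
        arm = TREATMENT if rng.random() < 0.5 else CONTROL
        out.append((levels, arm))
    return out
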