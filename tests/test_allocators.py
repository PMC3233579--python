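"""The six allocation schemes and their defining behaviors."""

import numpy as np
import pytest

from twowaymin import (
    CONTROL,
    TREATMENT,
    AllocatorConfig,
    BiasedCoinMinimizer,
    BlockRandomizer,
    DeterministicMinimizer,
    SimpleRandomizer,
    StratifiedRandomizer,
    SubjectProfile,
    TrialState,
    TwoWayMinimizer,
    accrual_probability,
    make_allocator,
    marginal_imbalance_score,
)
from twowaymin.simulate import TrialDesign, simulate_trial

from conftest import build_state, random_assignments


# -- geometric accrual function -------------------------------------------

def test_accrual_probability_properties():
    for q in (0.01, 0.05, 0.5, 0.99):
        assert accrual_probability(0, q) == 0.0
    assert accrual_probability(1, 0.05) == pytest.approx(0.05)
    assert accrual_probability(14, 0.05) == pytest.approx(1 - 0.95**14)  # ~0.5123
    values = [accrual_probability(d, 0.05) for d in range(50)]
    assert all(b > a for a, b in zip(values, values[1:]))  # strictly increasing
    assert accrual_probability(1000, 0.05) == pytest.approx(1.0)  # limit


@pytest.mark.parametrize("q", [0.0, 1.0, -0.1, 1.5])
def test_accrual_probability_rejects_bad_q(q):
    with pytest.raises(ValueError):
        accrual_probability(3, q)


def test_allocator_config_validation():
    with pytest.raises(ValueError):
        AllocatorConfig(method="block", block_size=5)
    with pytest.raises(ValueError):
        AllocatorConfig(method="biased_coin_minimization", coin_probability=0.5)
    with pytest.raises(ValueError):
        AllocatorConfig(method="two_way", q=1.5)
    with pytest.raises(ValueError):
        AllocatorConfig(method="nonsense")
    assert AllocatorConfig().q == 0.05  # study default


# -- two-way minimization --------------------------------------------------

def test_rule_a1_sends_subject_to_smaller_arm(spec1b, rng):
    state = build_state(
        spec1b, [((0,), TREATMENT)] * 2 + [((0,), CONTROL)] * 5
    )
    allocator = TwoWayMinimizer(spec1b, AllocatorConfig(), rule_override="A1")
    assert allocator.assign(state, SubjectProfile((0,)), rng) == TREATMENT


def test_rule_a2_minimizes_prospective_distribution_imbalance(spec1b, rng):
    # T holds one level-0 subject, C one level-1 subject; a level-1 arrival
    # equalizes the distributions only if placed in T.
    state = build_state(spec1b, [((0,), TREATMENT), ((1,), CONTROL)])
    allocator = TwoWayMinimizer(spec1b, AllocatorConfig(), rule_override="A2")
    assert allocator.assign(state, SubjectProfile((1,)), rng) == TREATMENT


def test_equal_arms_make_decision_purely_covariate_adaptive(spec1b):
    # pi(D1=0) = 0, so the Bernoulli draw can never select rule A1
    state = build_state(spec1b, [((0,), TREATMENT), ((1,), CONTROL)])
    allocator = TwoWayMinimizer(spec1b, AllocatorConfig())
    for seed in range(20):
        rng_full = np.random.default_rng(seed)
        rng_a2 = np.random.default_rng(seed)
        rng_a2.random()  # the consumed Bernoulli draw
        got = allocator.assign(state, SubjectProfile((1,)), rng_full)
        want = allocator.rule_a2(state, SubjectProfile((1,)), rng_a2)
        assert got == want == TREATMENT


def test_burn_in_uses_fair_coin_until_both_arms_filled(spec3b):
    arms = []
    allocator = TwoWayMinimizer(spec3b, AllocatorConfig())
    for seed in range(400):
        state = TrialState(spec3b)
        arms.append(
            allocator.assign(state, SubjectProfile((0, 0, 0)), np.random.default_rng(seed))
        )
    frac_t = np.mean([a == TREATMENT for a in arms])
    assert 0.4 < frac_t < 0.6


def test_forcing_rule_a1_keeps_final_arm_difference_at_most_one():
    design = TrialDesign(n=21, factors="three_binary", replicates=1, seed=33)
    for seed in range(30):
        rec = simulate_trial(design, seed, allocator_kwargs={"rule_override": "A1"})
        assert rec.final_d1 <= 1


def test_monotone_transforms_leave_decisions_unchanged():
    design = TrialDesign(n=30, factors="three_polytomous", replicates=1, seed=0)
    transformed = {
        "d1_transform": lambda x: x**3,
        "d2_transform": np.exp,
    }
    for seed in range(25):
        plain = simulate_trial(design, seed)
        warped = simulate_trial(design, seed, allocator_kwargs=transformed)
        assert np.array_equal(plain.arms, warped.arms)


def test_two_way_has_no_structural_arm_preference(spec1b, rng):
    # mirror the state (swap arm contents): deterministic decisions mirror too
    cfg = AllocatorConfig()
    state = build_state(spec1b, [((0,), TREATMENT)] * 2 + [((1,), CONTROL)] * 5)
    mirror = build_state(spec1b, [((0,), CONTROL)] * 2 + [((1,), TREATMENT)] * 5)
    a1 = TwoWayMinimizer(spec1b, cfg, rule_override="A1")
    assert a1.assign(state, SubjectProfile((0,)), rng) == TREATMENT
    assert a1.assign(mirror, SubjectProfile((0,)), rng) == CONTROL
    a2 = TwoWayMinimizer(spec1b, cfg, rule_override="A2")
    profile = SubjectProfile((1,))
    assert a2.assign(state, profile, rng) != a2.assign(mirror, profile, rng)


# -- simple randomization --------------------------------------------------

def test_simple_randomization_is_a_fair_independent_coin(spec1b, rng):
    allocator = SimpleRandomizer(spec1b, AllocatorConfig(method="simple"))
    state = TrialState(spec1b)
    arms = [allocator.assign(state, SubjectProfile((0,)), rng) for _ in range(10_000)]
    frac_t = np.mean([a == TREATMENT for a in arms])
    switches = np.mean([a != b for a, b in zip(arms, arms[1:])])
    assert frac_t == pytest.approx(0.5, abs=0.02)
    assert switches == pytest.approx(0.5, abs=0.02)
    # reproducible under a fixed seed
    rerun = [
        allocator.assign(state, SubjectProfile((0,)), np.random.default_rng(1))
        for _ in range(5)
    ]
    assert rerun == [rerun[0]] * 5


# -- permuted blocks -------------------------------------------------------

def test_block_randomization_counting_invariants(spec1b, rng):
    cfg = AllocatorConfig(method="block", block_size=4)
    allocator = BlockRandomizer(spec1b, cfg)
    state = TrialState(spec1b)
    arms = []
    for _ in range(20):
        arm = allocator.assign(state, SubjectProfile((0,)), rng)
        state.update(SubjectProfile((0,)), arm)
        arms.append(arm)
    blocks = [arms[i : i + 4] for i in range(0, 20, 4)]
    for block in blocks:
        assert block.count(TREATMENT) == 2  # exactly half per complete block
    assert abs(arms.count(TREATMENT) - arms.count(CONTROL)) == 0  # n=20: 5 blocks


def test_block_completion_is_forced(spec1b, rng):
    cfg = AllocatorConfig(method="block", block_size=4)
    allocator = BlockRandomizer(spec1b, cfg)
    allocator.restore_state({"pending": ["T", "T", "C", "C"]})
    state = TrialState(spec1b)
    seen = [allocator.assign(state, SubjectProfile((0,)), rng) for _ in range(4)]
    assert seen == [TREATMENT, TREATMENT, CONTROL, CONTROL]


# -- stratified randomization ----------------------------------------------

def test_stratified_blocks_run_independently_per_stratum(spec1b, rng):
    cfg = AllocatorConfig(method="stratified", block_size=4)
    allocator = StratifiedRandomizer(spec1b, cfg)
    allocator.restore_state({"strata": {"0": ["T", "T", "C", "C"]}})
    state = TrialState(spec1b)
    # two same-stratum subjects follow the stratum's block order
    assert allocator.assign(state, SubjectProfile((0,)), rng) == TREATMENT
    assert allocator.assign(state, SubjectProfile((0,)), rng) == TREATMENT
    # a subject in another stratum starts a fresh block there and does not
    # consume from the first stratum's
    allocator.assign(state, SubjectProfile((1,)), rng)
    assert allocator.export_state()["strata"]["0"] == ["C", "C"]


def test_many_strata_degrade_balance_toward_simple_randomization(spec_poly):
    # 5*4*3 = 60 strata with n=20: most hold <= 1 subject, so arm totals drift
    strat = TrialDesign(
        n=20, factors="three_polytomous",
        allocator=AllocatorConfig(method="stratified"), replicates=1, seed=0,
    )
    block = TrialDesign(
        n=20, factors="three_polytomous",
        allocator=AllocatorConfig(method="block"), replicates=1, seed=0,
    )
    d1_strat = np.mean([simulate_trial(strat, s).final_d1 for s in range(200)])
    d1_block = np.mean([simulate_trial(block, s).final_d1 for s in range(200)])
    assert d1_block == 0.0
    assert d1_strat > 1.0


# -- Pocock-Simon minimization --------------------------------------------

def test_marginal_score_on_empty_state_counts_one_per_factor(spec1b, spec3b, rng):
    empty1 = TrialState(spec1b)
    assert marginal_imbalance_score(empty1, SubjectProfile((0,)), TREATMENT) == 1
    assert marginal_imbalance_score(empty1, SubjectProfile((0,)), CONTROL) == 1
    empty3 = TrialState(spec3b)
    assert marginal_imbalance_score(empty3, SubjectProfile((0, 1, 0)), TREATMENT) == 3


def test_marginal_score_matches_brute_force_recount(spec3b, rng):
    for trial in range(20):
        state = build_state(spec3b, random_assignments(spec3b, 5, rng))
        levels = tuple(int(rng.integers(2)) for _ in range(3))
        profile = SubjectProfile(levels)
        for arm in (TREATMENT, CONTROL):
            # independent recount: tally hypothetical counts from history
            hypothetical = state.copy().update(profile, arm)
            expected = sum(
                abs(int(hypothetical.counts[0, k, l]) - int(hypothetical.counts[1, k, l]))
                for k, l in enumerate(levels)
            )
            assert marginal_imbalance_score(state, profile, arm) == expected


def test_deterministic_minimization_is_deterministic_off_ties(spec1b, rng):
    # T-heavy state at the subject's level: score favors C
    state = build_state(spec1b, [((0,), TREATMENT)] * 3 + [((0,), CONTROL)])
    allocator = DeterministicMinimizer(spec1b, AllocatorConfig(method="deterministic_minimization"))
    for seed in range(10):
        assert allocator.assign(state, SubjectProfile((0,)), np.random.default_rng(seed)) == CONTROL


def test_deterministic_minimization_balances_identical_profiles_in_pairs(spec3b):
    # identical profiles from an empty state: every odd arrival ties (coin),
    # and every even arrival is forced opposite its predecessor, so the
    # sequence is a chain of balanced pairs
    allocator = DeterministicMinimizer(spec3b, AllocatorConfig(method="deterministic_minimization"))
    rng = np.random.default_rng(4)
    state = TrialState(spec3b)
    profile = SubjectProfile((0, 1, 0))
    arms = []
    for _ in range(10):
        arm = allocator.assign(state, profile, rng)
        state.update(profile, arm)
        arms.append(arm)
    for i in range(0, 10, 2):
        assert arms[i + 1] != arms[i]


def test_tie_is_a_fair_coin(spec1b):
    allocator = DeterministicMinimizer(spec1b, AllocatorConfig(method="deterministic_minimization"))
    state = TrialState(spec1b)  # empty: both hypothetical scores equal 1
    arms = [
        allocator.assign(state, SubjectProfile((0,)), np.random.default_rng(s))
        for s in range(2000)
    ]
    assert np.mean([a == TREATMENT for a in arms]) == pytest.approx(0.5, abs=0.04)


def test_biased_coin_reduces_to_deterministic_at_p_one(spec3b, rng):
    cfg = AllocatorConfig(method="biased_coin_minimization")
    det = DeterministicMinimizer(spec3b, cfg)
    coin1 = BiasedCoinMinimizer(spec3b, cfg, coin_probability=1.0)
    for seed in range(30):
        state = build_state(spec3b, random_assignments(spec3b, 7, np.random.default_rng(seed)))
        profile = SubjectProfile(tuple(int(v) for v in np.random.default_rng(seed).integers(2, size=3)))
        assert det.assign(state, profile, np.random.default_rng(seed)) == coin1.assign(
            state, profile, np.random.default_rng(seed)
        )


def test_biased_coin_reduces_to_simple_at_p_half(spec1b):
    # heavily unbalanced state, yet p=0.5 ignores the scores entirely
    state = build_state(spec1b, [((0,), TREATMENT)] * 6 + [((0,), CONTROL)])
    half = BiasedCoinMinimizer(spec1b, AllocatorConfig(method="biased_coin_minimization"), coin_probability=0.5)
    arms = [
        half.assign(state, SubjectProfile((0,)), np.random.default_rng(s))
        for s in range(3000)
    ]
    assert np.mean([a == TREATMENT for a in arms]) == pytest.approx(0.5, abs=0.03)


def test_biased_coin_follows_minimizing_arm_at_its_coin_rate(spec1b):
    state = build_state(spec1b, [((0,), TREATMENT)] * 3 + [((0,), CONTROL)])
    allocator = BiasedCoinMinimizer(spec1b, AllocatorConfig(method="biased_coin_minimization", coin_probability=0.7))
    arms = [
        allocator.assign(state, SubjectProfile((0,)), np.random.default_rng(s))
        for s in range(4000)
    ]
    assert np.mean([a == CONTROL for a in arms]) == pytest.approx(0.7, abs=0.025)


# -- shared contract -------------------------------------------------------

@pytest.mark.parametrize(
    "method",
    ["simple", "block", "stratified", "deterministic_minimization",
     "biased_coin_minimization", "two_way"],
)
def test_every_allocator_is_reproducible_under_a_fixed_seed(method):
    design = TrialDesign(
        n=24, factors="three_binary", allocator=AllocatorConfig(method=method),
        replicates=1, seed=99,
    )
    first = simulate_trial(design, 123)
    second = simulate_trial(design, 123)
    assert np.array_equal(first.arms, second.arms)
    assert np.array_equal(first.responses, second.responses)


def test_make_allocator_dispatch(spec3b):
    for method, cls in [
        ("simple", SimpleRandomizer),
        ("block", BlockRandomizer),
        ("stratified", StratifiedRandomizer),
        ("deterministic_minimization", DeterministicMinimizer),
        ("biased_coin_minimization", BiasedCoinMinimizer),
        ("two_way", TwoWayMinimizer),
    ]:
        assert isinstance(make_allocator(spec3b, AllocatorConfig(method=method)), cls)
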