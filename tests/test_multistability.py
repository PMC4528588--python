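"""Bistability decisions, necessary condition, and multistability witnesses."""

import numpy as np
import pytest

from phosphorelay import (
    DegenerateParameters,
    build_unorthodox,
    check_necessary_condition,
    construct_multistable_params,
    construct_shared_rr_witness,
    find_steady_states_numeric,
    is_bistable,
    sample_parameters,
)
from phosphorelay.multistability import UNORTHODOX_WITNESS


def test_unit_parameters_are_monostable(unit_params):
    assert not is_bistable(unit_params)


def test_witness_is_bistable_and_satisfies_necessary_condition(core_witness):
    assert is_bistable(core_witness)
    assert check_necessary_condition(core_witness)


def test_necessary_condition_is_strict(unit_params):
    assert not check_necessary_condition(unit_params)  # k1 == k3
    assert check_necessary_condition(unit_params.with_rates(k3=2.0))


def test_zero_rate_is_degenerate_not_false(unit_params):
    with pytest.raises(DegenerateParameters):
        is_bistable(unit_params.with_rates(k2=0.0))


def test_bistability_implies_k3_greater_k1(core_network, rng):
    """Implication audit on random parameters: no bistable set violates it."""
    n_bistable = 0
    for _ in range(3000):
        p = sample_parameters(core_network, rng)
        try:
            if is_bistable(p):
                n_bistable += 1
                assert check_necessary_condition(p)
        except DegenerateParameters:
            pass
    assert n_bistable > 0  # the audit actually exercised bistable sets


@pytest.mark.parametrize("n", [1, 2, 3])
def test_constructed_witness_attains_2n_plus_1_states(n):
    rep = construct_multistable_params(n, seed=0)
    assert rep.n_positive == 2 * n + 1
    assert rep.n_stable == n + 1
    assert rep.n_unstable == n
    assert rep.n_marginal == 0
    # stability alternates along increasing free-Hpt concentration
    labels = [s.stability for s in rep.witness_states]
    assert labels == ["stable" if i % 2 == 0 else "unstable" for i in range(2 * n + 1)]


def test_witness_respects_upper_bound_never_exceeds(rng):
    """No sampled shared-Hpt parameter set exceeds the 2n+1 bound."""
    from phosphorelay import build_shared_hpt, find_steady_states

    for n in (1, 2):
        net = build_shared_hpt(n)
        for _ in range(50):
            p = sample_parameters(net, rng)
            assert len(find_steady_states(net, p, classify=False)) <= 2 * n + 1


@pytest.mark.parametrize(
    "module_sizes,expected",
    [([1], 3), ([2], 5), ([1, 1], 9)],
)
def test_shared_rr_witness_counts(module_sizes, expected):
    rep = construct_shared_rr_witness(module_sizes, seed=0)
    assert rep.n_positive == expected
    if module_sizes == [1, 1]:
        # stable states combine combinatorially: 2 stable per module
        assert rep.n_stable == 4


def test_regular_relay_is_always_monostable(relay_network, rng):
    for i in range(150):
        p = sample_parameters(relay_network, rng)
        states = find_steady_states_numeric(
            relay_network, p, n_starts=12, seed=i, classify=False
        )
        assert len(states) == 1


def test_relay_without_phosphate_source_rests_unphosphorylated(relay_network, rng):
    """With no autophosphorylation, all phosphate drains via RR_P hydrolysis."""
    p = sample_parameters(relay_network, rng).with_rates(
        ka=0.0, krt2=0.0, krt3=0.0, khy_rec=0.0
    )
    states = find_steady_states_numeric(relay_network, p, n_starts=20, seed=0)
    assert len(states) == 1
    expect = p.unphosphorylated_state(relay_network)
    assert np.allclose(states[0].concentrations, expect, atol=1e-7)


def test_unorthodox_witness_is_multistable():
    net = build_unorthodox()
    states = find_steady_states_numeric(net, UNORTHODOX_WITNESS, n_starts=80, seed=0)
    assert len(states) >= 3
    assert [s.stability for s in states].count("stable") >= 2


def test_folds_shift_monotonically_with_k3_over_k1_ratio(core_network, core_witness):
    """Raising the k3/k1 ratio keeps bistability, moving the window to
    lower input (regression on the recorded fold direction)."""
    from phosphorelay import detect_hysteresis, sweep_input

    rho0 = core_witness.rates["k3"] / core_witness.rates["k1"]
    grid = np.logspace(-2.2, 0, 60)
    lower_folds = []
    for factor in (1.0, 1.5, 2.0):
        branches = sweep_input(core_network, core_witness, rho0 * factor, grid, "Hpt_P")
        hys = detect_hysteresis(branches)
        assert hys.bistable
        lower_folds.append(hys.fold_down)
    assert lower_folds[0] > lower_folds[1] > lower_folds[2]
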