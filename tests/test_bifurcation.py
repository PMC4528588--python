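"""Bifurcation sweeps, hysteresis and quasi-static integration."""

import numpy as np
import pytest

from phosphorelay import (
    detect_hysteresis,
    find_steady_states,
    simulate_to_steady_state,
    state_composition,
    sweep_input,
)


@pytest.fixture(scope="module")
def core_sweep(request):
    from phosphorelay import bistable_core_params, build_core_hybrid

    net = build_core_hybrid()
    p = bistable_core_params()
    rho = p.rates["k3"] / p.rates["k1"]
    grid = np.logspace(np.log10(0.0701) - 1.2, np.log10(0.0701) + 1.2, 41)
    branches = sweep_input(net, p, rho, grid, "Hpt_P")
    return net, p, rho, grid, branches


def test_sweep_produces_s_shaped_diagram(core_sweep):
    net, p, rho, grid, branches = core_sweep
    stable = [b for b in branches if b.is_stable]
    unstable = [b for b in branches if not b.is_stable]
    assert len(stable) == 2 and len(unstable) == 1
    # the unstable branch lies between the stable ones where they coexist
    mid = unstable[0]
    for s, y in zip(mid.input_values, mid.output_values):
        lows = [yy for b in stable for ss, yy in zip(b.input_values, b.output_values) if ss == s]
        assert min(lows) < y < max(lows)
    # all output fractions in [0, 1]
    for b in branches:
        assert all(0.0 <= y <= 1.0 for y in b.output_values)


def test_branch_count_matches_root_count(core_sweep):
    net, p, rho, grid, branches = core_sweep
    for s in grid[::8]:
        p_s = p.with_rates(k1=float(s), k3=float(rho * s))
        n_roots = len(find_steady_states(net, p_s, classify=False))
        n_points = sum(s in b.input_values for b in branches)
        assert n_points == n_roots


def test_hysteresis_integration_agrees_with_polynomial_folds(core_sweep):
    net, p, rho, grid, branches = core_sweep
    hys = detect_hysteresis(
        branches, net, p, rho, "Hpt_P", cross_validate=True
    )
    assert hys.bistable and hys.width > 0
    up_jump, down_jump = hys.integration_folds
    # jumps register within one grid step of the branch-structure folds
    step = np.diff(np.log(grid)).max()
    assert abs(np.log(up_jump) - np.log(hys.fold_up)) <= 1.5 * step
    assert abs(np.log(down_jump) - np.log(hys.fold_down)) <= 1.5 * step


def test_monostable_sweep_has_no_hysteresis(unit_params):
    from phosphorelay import build_core_hybrid

    net = build_core_hybrid()
    grid = np.logspace(-2, 0, 10)
    branches = sweep_input(net, unit_params, 1.0, grid, "Hpt_P")
    hys = detect_hysteresis(branches)
    assert not hys.bistable
    assert hys.width == 0.0
    assert hys.fold_up is None and hys.fold_down is None


def test_output_vanishes_without_input(core_witness):
    from phosphorelay import build_core_hybrid

    net = build_core_hybrid()
    rho = core_witness.rates["k3"] / core_witness.rates["k1"]
    tiny = 1e-8
    p_s = core_witness.with_rates(k1=tiny, k3=rho * tiny)
    states = find_steady_states(net, p_s)
    assert len(states) == 1
    assert states[0]["Hpt_P"] / core_witness.totals["Hpt"] < 1e-3


def test_state_composition_fractions(core_sweep):
    net, p, rho, grid, _ = core_sweep
    comp = state_composition(net, p, rho, grid, branch_selector="upper")
    total = sum(comp.fractions[m] for m in ("OO", "PO", "OP", "PP"))
    assert np.allclose(total, 1.0, rtol=1e-8)
    # the doubly phosphorylated state populates only above the threshold
    pp = comp.fractions["PP"]
    assert pp[0] < 0.05 and pp[-1] > 0.3
    lower = state_composition(net, p, rho, grid, branch_selector="lower")
    assert lower.fractions["PP"][0] < 0.05


def test_two_initial_conditions_reach_the_two_stable_states(core_sweep):
    net, p, rho, grid, _ = core_sweep
    states = find_steady_states(net, p)
    assert [s.stability for s in states] == ["stable", "unstable", "stable"]
    lo_h, mid, hi_h = states
    for target, offset in ((lo_h, -0.05), (hi_h, +0.05)):
        x0 = np.asarray(mid.concentrations).copy()
        i_hpt = net.index("Hpt")
        i_hptp = net.index("Hpt_P")
        x0[i_hpt] += offset
        x0[i_hptp] -= offset
        end, _ = simulate_to_steady_state(net, p, x0)
        assert end.stability == "stable"
        assert end["Hpt"] == pytest.approx(target["Hpt"], rel=1e-3)


def test_simulation_from_steady_state_converges_immediately(core_sweep):
    net, p, _, _, _ = core_sweep
    st = find_steady_states(net, p)[0]
    end, _ = simulate_to_steady_state(net, p, np.asarray(st.concentrations))
    assert end["Hpt"] == pytest.approx(st["Hpt"], rel=1e-6)


def test_simulation_endpoint_matches_polynomial_root(core_sweep):
    net, p, _, _, _ = core_sweep
    end, _ = simulate_to_steady_state(net, p, p.unphosphorylated_state(net))
    roots_h = [s["Hpt"] for s in find_steady_states(net, p)]
    assert min(abs(end["Hpt"] - r) / r for r in roots_h) < 1e-4
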