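"""Response surfaces, Boolean gates and multi-switch thresholds."""

import numpy as np
import pytest

from phosphorelay import (
    ParameterSet,
    build_shared_rr,
    classify_gate,
    gate_witness,
    multi_switch_thresholds,
    response_surface,
    search_gate_params,
)
from phosphorelay.logic import ResponseSurface
from phosphorelay.multistability import CORE_WITNESS


@pytest.mark.parametrize("label", ["AND", "OR", "ADDER"])
def test_reference_gates_classify_correctly(label):
    network, params, grid, ratios = gate_witness(label)
    surf = response_surface(network, params, grid, grid, ratios=ratios)
    verdict = classify_gate(surf)
    assert verdict.label == label
    if label == "ADDER":
        assert verdict.adder_fit >= 0.95


def test_gate_labels_stable_under_grid_refinement():
    for label in ("AND", "OR"):
        network, params, grid, ratios = gate_witness(label, n_grid=12)
        surf = response_surface(network, params, grid, grid, ratios=ratios)
        assert classify_gate(surf).label == label


def test_surface_symmetric_for_symmetric_parameters():
    network, params, grid, ratios = gate_witness("ADDER")
    surf = response_surface(network, params, grid, grid, ratios=ratios)
    assert np.allclose(surf.output, surf.output.T, rtol=1e-5, atol=1e-8)


def test_surface_monotone_in_each_signal_when_monostable():
    network, params, grid, ratios = gate_witness("ADDER")
    surf = response_surface(network, params, grid, grid, ratios=ratios)
    assert not surf.multivalued
    assert np.all(np.diff(surf.output, axis=0) >= -1e-9)
    assert np.all(np.diff(surf.output, axis=1) >= -1e-9)


def test_flat_zero_surface_is_other():
    grid = np.logspace(-2, 0, 4)
    surf = ResponseSurface(grid, grid, np.zeros((4, 4)), {}, set(), "RR_P")
    assert classify_gate(surf).label == "OTHER"


def test_or_gate_reachable_from_and_base_by_tuning_totals_and_rr_hydrolysis():
    network, and_params, grid, ratios = gate_witness("AND")
    params, verdict = search_gate_params(
        network, and_params, "OR", grid, grid, seed=3, budget=60, ratios=ratios
    )
    assert verdict.label == "OR"
    # the kinetic rates other than RR_P hydrolysis are untouched
    for label, v in and_params.rates.items():
        if label != "khy_rr":
            assert params.rates[label] == v


def test_search_rejects_nonpositive_budget():
    network, and_params, grid, ratios = gate_witness("AND")
    with pytest.raises(ValueError):
        search_gate_params(network, and_params, "OR", grid, grid, budget=0)


def _two_module_params(h2_scale: float) -> ParameterSet:
    """shared_rr([1,1]) with module 2's HK total scaled by h2_scale."""
    w = CORE_WITNESS
    rates = {
        "k1_1": w.rates["k1"], "k1_2": w.rates["k2"], "k1_3": w.rates["k3"],
        "k1_4": w.rates["k4"], "k1_5": w.rates["k5"],
        "k2_1": w.rates["k1"], "k2_2": w.rates["k2"], "k2_3": w.rates["k3"],
        "k2_4": w.rates["k4"], "k2_5": w.rates["k5"],
        "k6_m1": w.rates["k6"], "k6_m2": w.rates["k6"],
        "kt_1": w.rates["k6"] * 1e-4, "kt_2": w.rates["k6"] * 1e-4,
        "khy_rr": 1.0,
    }
    totals = {
        "HK1": w.totals["HK"], "HK2": w.totals["HK"] * h2_scale,
        "Hpt1": w.totals["Hpt"], "Hpt2": w.totals["Hpt"],
        "RR": 1.0,
    }
    return ParameterSet(rates, totals)


def test_identical_modules_switch_together_staggered_modules_apart():
    net = build_shared_rr([1, 1])
    grid = np.logspace(np.log10(0.02), np.log10(0.4), 14)
    same = multi_switch_thresholds(net, _two_module_params(1.0), grid)
    assert same[0] == pytest.approx(same[1])
    staggered = multi_switch_thresholds(net, _two_module_params(0.5), grid)
    assert staggered[1] > staggered[0] * 1.2
    # halving the HK total raises that module's threshold
    assert staggered[0] == pytest.approx(same[0])
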