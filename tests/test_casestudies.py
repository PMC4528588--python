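"""Yeast osmosensing and V. harveyi-like case studies."""

import numpy as np
import pytest

from phosphorelay import (
    build_vharveyi_like,
    build_yeast_osmosensing,
    classify_gate,
    detect_hysteresis,
    find_steady_states,
    response_surface,
    sweep_input,
)

GRID = np.logspace(-3, 0.5, 40)


@pytest.fixture(scope="module")
def yeast():
    return build_yeast_osmosensing()


def test_yeast_species_inventory(yeast):
    assert len(yeast.network.species) == 10
    assert set(yeast.network.proteins) == {"Sln1", "Ypd", "Ssk1", "Skn7"}
    assert yeast.output_species == "Ssk1_P"


def test_yeast_every_rate_has_provenance(yeast):
    assert set(yeast.provenance) == set(yeast.network.rate_labels)
    assert any("measured" in v for v in yeast.provenance.values())
    assert any("assumed" in v for v in yeast.provenance.values())


def test_yeast_defaults_are_bistable_with_hysteresis(yeast):
    states = find_steady_states(yeast.network, yeast.default_params)
    assert len(states) == 3
    branches = sweep_input(
        yeast.network, yeast.default_params, yeast.ratio, GRID, "Ssk1_P"
    )
    hys = detect_hysteresis(branches)
    assert hys.bistable and hys.width > 0


@pytest.mark.parametrize(
    "protein,values", [("Ypd", (1.0, 2.0, 3.0)), ("Skn7", (0.5, 1.5, 2.5))]
)
def test_total_sweeps_give_three_distinct_diagrams(yeast, protein, values):
    curves, lower_folds = [], []
    for v in values:
        p = yeast.default_params.with_totals(**{protein: v})
        branches = sweep_input(yeast.network, p, yeast.ratio, GRID, "Ssk1_P")
        hys = detect_hysteresis(branches)
        assert hys.bistable
        lower_folds.append(hys.fold_down)
        upper = max(branches, key=lambda b: max(b.output_values))
        curves.append(
            {s: y for s, y in zip(upper.input_values, upper.output_values)}
        )
    # diagrams are pairwise distinct
    for i in range(3):
        for j in range(i + 1, 3):
            common = set(curves[i]) & set(curves[j])
            assert max(abs(curves[i][s] - curves[j][s]) for s in common) > 1e-3
    # the lower fold moves monotonically across the listed values
    assert lower_folds == sorted(lower_folds) or lower_folds == sorted(
        lower_folds, reverse=True
    )


def test_yeast_hysteresis_robust_to_ten_percent_perturbation(yeast, rng):
    for _ in range(5):
        factors = {
            k: v * (1 + rng.uniform(-0.1, 0.1))
            for k, v in yeast.default_params.rates.items()
        }
        p = yeast.default_params.with_rates(**factors)
        branches = sweep_input(yeast.network, p, yeast.ratio, GRID, "Ssk1_P")
        hys = detect_hysteresis(branches)
        assert hys.bistable and hys.width > 0


def test_yeast_reverse_transfer_flag(yeast):
    without = build_yeast_osmosensing(include_ssk1_reverse=False)
    assert "kr_ssk1" not in without.network.rate_labels
    assert "kr_ssk1" in yeast.network.rate_labels


def test_vharveyi_defaults_implement_adder():
    model = build_vharveyi_like()
    grid = np.logspace(-3, -1, 8)
    surf = response_surface(
        model.network, model.default_params, grid, grid,
        output_species=model.output_species, ratios=(model.ratio, model.ratio),
    )
    verdict = classify_gate(surf)
    assert verdict.label == "ADDER"
    assert verdict.adder_fit >= 0.95
    # symmetric defaults give a symmetric surface
    assert np.allclose(surf.output, surf.output.T, rtol=1e-5, atol=1e-8)


def test_three_hk_variant_is_buildable():
    from phosphorelay import build_shared_rr

    net = build_shared_rr([3])
    assert sum(1 for s in net.species if s.role == "hk_state") == 12
    assert {"Hpt1", "RR"} <= set(net.proteins)
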