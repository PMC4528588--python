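"""Network builders, conservation structure and mass-action kinetics."""

import numpy as np
import pytest
from scipy.integrate import solve_ivp

from phosphorelay import (
    ParameterSet,
    build_core_hybrid,
    build_full_hybrid,
    build_regular_relay,
    build_shared_hpt,
    build_shared_rr,
    build_unorthodox,
    hk_state_cycles,
    mass_action_jacobian,
    mass_action_rhs,
    sample_parameters,
)


def test_core_hybrid_composition(core_network):
    assert sorted(core_network.species_names) == sorted(
        ["OO", "PO", "OP", "PP", "Hpt", "Hpt_P"]
    )
    assert [r.rate_label for r in core_network.reactions] == [
        "k1", "k2", "k3", "k4", "k5", "k6",
    ]
    # HK states enumerate the four phospho-patterns in fixed order
    hk = [s for s in core_network.species if s.protein == "HK"]
    assert ["".join(s.phospho_pattern) for s in hk] == ["OO", "PO", "OP", "PP"]


def test_core_reaction_graph_has_exactly_the_two_feedback_loops(core_network):
    cycles = {frozenset(c) for c in hk_state_cycles(core_network)}
    assert cycles == {
        frozenset({"OO", "PO", "OP"}),
        frozenset({"PO", "OP", "PP"}),
    }


def test_conservation_laws_span_one_vector_per_protein(core_network):
    laws = dict(core_network.conservation_laws())
    assert set(laws) == {"HK", "Hpt"}
    S = core_network.stoichiometric_matrix()
    for v in laws.values():
        assert np.allclose(v @ S, 0.0)


@pytest.mark.parametrize(
    "builder,n_species,n_conservation",
    [
        (build_regular_relay, 8, 4),
        (build_unorthodox, 10, 2),
        (lambda: build_shared_hpt(3), 14, 4),
        (lambda: build_shared_rr([1, 1]), 14, 5),
    ],
)
def test_builder_species_and_conservation_counts(builder, n_species, n_conservation):
    net = builder()
    assert len(net.species) == n_species
    assert len(net.conservation_laws()) == n_conservation


def test_shared_hpt_reaction_count_formula():
    for n in (1, 2, 3, 4):
        net = build_shared_hpt(n)
        assert len(net.species) == 4 * n + 2
        assert len(net.reactions) == 5 * n + 1
    with pytest.raises(ValueError):
        build_shared_hpt(0)


def test_full_hybrid_restriction_reproduces_core(core_network):
    restricted = build_full_hybrid(
        include_rr=False,
        include_reverse_transfer=False,
        include_rec_hydrolysis=False,
        include_rr_hydrolysis=False,
    )
    assert set(restricted.species_names) == set(core_network.species_names)
    assert {(r.reactants, r.products, r.rate_label) for r in restricted.reactions} == {
        (r.reactants, r.products, r.rate_label) for r in core_network.reactions
    }


def test_rec_hydrolysis_only_on_aspartate_sites():
    net = build_full_hybrid()
    first_order = {
        (r.reactants[0], r.products[0]) for r in net.reactions if r.order == 1
    }
    assert ("OP", "OO") in first_order and ("PP", "PO") in first_order
    # no hydrolysis from the His site (PO -> OO) and none from Hpt_P
    assert ("PO", "OO") not in first_order
    assert ("Hpt_P", "Hpt") not in first_order


def test_unorthodox_enumerates_eight_states():
    net = build_unorthodox()
    hk = [s for s in net.species if s.protein == "HK"]
    assert len(hk) == 8
    assert {len(s.phospho_pattern) for s in hk} == {3}
    # every reaction conserves the HK total
    S = net.stoichiometric_matrix()
    v = np.array([1.0 if s.protein == "HK" else 0.0 for s in net.species])
    assert np.allclose(v @ S, 0.0)


def test_rhs_single_active_reaction(core_network, unit_params):
    rhs = mass_action_rhs(core_network, unit_params)
    x = np.zeros(6)
    x[core_network.index("OO")] = 1.0
    x[core_network.index("Hpt")] = 1.0
    dx = rhs(x)
    expect = np.zeros(6)
    expect[core_network.index("OO")] = -1.0
    expect[core_network.index("PO")] = 1.0
    assert np.allclose(dx, expect)


def test_rhs_missing_rate_raises(core_network):
    incomplete = ParameterSet({"k1": 1.0}, {"HK": 1.0, "Hpt": 1.0})
    with pytest.raises(KeyError):
        mass_action_rhs(core_network, incomplete)


@pytest.mark.parametrize("builder", [build_core_hybrid, build_regular_relay, build_unorthodox])
def test_trajectories_conserve_totals_and_stay_nonnegative(builder, rng):
    net = builder()
    params = sample_parameters(net, rng)
    rhs = mass_action_rhs(net, params)
    jac = mass_action_jacobian(net, params)
    x0 = params.unphosphorylated_state(net)
    sol = solve_ivp(
        lambda t, y: rhs(y), (0, 50.0), x0, method="LSODA",
        jac=lambda t, y: jac(y), rtol=1e-9, atol=1e-12,
    )
    assert sol.success
    assert np.min(sol.y) > -1e-8
    for prot, v in net.conservation_laws():
        totals = v @ sol.y
        assert np.allclose(totals, params.totals[prot], rtol=1e-7)


def test_jacobian_matches_finite_differences(core_network, core_witness, rng):
    jac = mass_action_jacobian(core_network, core_witness)
    rhs = mass_action_rhs(core_network, core_witness)
    x = rng.uniform(0.1, 1.0, 6)
    J = jac(x)
    eps = 1e-7
    for j in range(6):
        dx = np.zeros(6)
        dx[j] = eps
        col = (rhs(x + dx) - rhs(x - dx)) / (2 * eps)
        assert np.allclose(J[:, j], col, rtol=1e-5, atol=1e-8)
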