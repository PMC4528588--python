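"""Polynomial elimination, root enumeration and stability classification."""

import numpy as np
import pytest
import sympy as sp

from phosphorelay import (
    DegenerateParameters,
    UnsupportedArchitecture,
    build_regular_relay,
    build_shared_hpt,
    classify_stability,
    derive_polynomial,
    find_steady_states,
    find_steady_states_numeric,
    numeric_elimination,
    positive_roots,
    reconstruct_state,
    sample_parameters,
)
from phosphorelay.casestudies import build_yeast_osmosensing

H_STAR = 0.6572981061383758  # unique positive root of 2h^3 + h^2 - 1


def test_core_polynomial_is_cubic_and_proportional_to_reference(core_network, unit_params):
    poly = derive_polynomial(core_network)
    assert poly.degree == 3
    c = poly.numeric_coefficients(unit_params)
    # at unit parameters the eliminated polynomial is proportional to
    # 2h^3 + h^2 - 1 (obtained by hand substitution)
    ref = np.array([-1.0, 0.0, 1.0, 2.0])
    scale = c[0] / ref[0]
    assert np.allclose(c, scale * ref, atol=1e-12)


def test_unit_parameter_root_and_back_substitution(core_network, unit_params):
    poly = derive_polynomial(core_network)
    roots = positive_roots(poly, unit_params)
    assert roots == pytest.approx([H_STAR], rel=1e-10)
    st = reconstruct_state(poly, roots[0], unit_params)
    assert st["Hpt_P"] == pytest.approx(1.0 - H_STAR, rel=1e-9)
    # elimination formula for the doubly-phosphorylatable state:
    # [OP] = k6 (T - h) / (k3 + k4 h)
    assert st["OP"] == pytest.approx((1 - H_STAR) / (1 + H_STAR), rel=1e-9)
    assert st["OO"] + st["PO"] + st["OP"] + st["PP"] == pytest.approx(1.0, rel=1e-9)


def test_degree_law_shared_hpt():
    for n in (1, 2, 3):
        assert derive_polynomial(build_shared_hpt(n)).degree == 2 * n + 1


def test_unsupported_architectures_raise():
    with pytest.raises(UnsupportedArchitecture):
        derive_polynomial(build_regular_relay())
    with pytest.raises(UnsupportedArchitecture):
        numeric_elimination(build_regular_relay(), None)


def test_degenerate_parameters_raise(core_network, unit_params):
    poly = derive_polynomial(core_network)
    degenerate = unit_params.with_rates(k5=0.0)
    with pytest.raises(DegenerateParameters):
        positive_roots(poly, degenerate)


def test_bistable_witness_has_three_roots_alternating_stability(
    core_network, core_witness
):
    poly = derive_polynomial(core_network)
    roots = positive_roots(poly, core_witness, certify=True)
    assert len(roots) == 3
    states = [
        classify_stability(core_network, core_witness, reconstruct_state(poly, r, core_witness))
        for r in roots
    ]
    assert [s.stability for s in states] == ["stable", "unstable", "stable"]


def test_root_count_parity_is_odd(core_network, rng):
    """Boundedness and the one-to-one correspondence force an odd count."""
    poly = derive_polynomial(core_network)
    counts = set()
    for _ in range(300):
        p = sample_parameters(core_network, rng)
        counts.add(len(positive_roots(poly, p)))
    assert counts <= {1, 3}
    assert 1 in counts


def test_polynomial_route_matches_numeric_oracle(core_network, shared2_network, rng):
    """Elimination and brute multi-start agree state-by-state."""
    for net in (core_network, shared2_network):
        for i in range(15):
            p = sample_parameters(net, rng)
            a = find_steady_states(net, p, classify=False)
            b = find_steady_states_numeric(net, p, n_starts=80, seed=i, classify=False)
            assert len(a) == len(b)
            for sa, sb in zip(a, b):
                assert np.allclose(
                    sa.concentrations, sb.concentrations,
                    rtol=1e-6, atol=1e-9 * max(p.totals.values()),
                )


def test_reconstruction_satisfies_conservation_and_residual(core_network, core_witness):
    poly = derive_polynomial(core_network)
    from phosphorelay import mass_action_rhs

    rhs = mass_action_rhs(core_network, core_witness)
    for r in positive_roots(poly, core_witness):
        st = reconstruct_state(poly, r, core_witness)
        assert np.max(np.abs(rhs(np.asarray(st.concentrations)))) < 1e-9 * max(
            core_witness.totals.values()
        ) * max(core_witness.rates.values())
        assert st["OO"] + st["PO"] + st["OP"] + st["PP"] == pytest.approx(
            core_witness.totals["HK"], rel=1e-9
        )
        assert st["Hpt"] + st["Hpt_P"] == pytest.approx(
            core_witness.totals["Hpt"], rel=1e-9
        )


def test_symbolic_coefficients_reduce_to_unit_values(core_network):
    """Spot-check the symbolic coefficient expressions at a probe point."""
    poly = derive_polynomial(core_network)
    subs = {s: 1 for s, _, _ in poly.param_symbols}
    vals = [float(sp.Rational(c.subs(subs))) for c in poly.coefficients]
    ref = np.array([-1.0, 0.0, 1.0, 2.0])
    assert np.allclose(vals, vals[0] * ref / ref[0])


def test_yeast_network_supports_numeric_elimination():
    model = build_yeast_osmosensing()
    coeffs, builder = numeric_elimination(model.network, model.default_params)
    states = find_steady_states(model.network, model.default_params)
    assert len(states) == 3
    for st in states:
        x = builder(st["Ypd"])
        assert np.allclose(x, np.asarray(st.concentrations), rtol=1e-6, atol=1e-9)
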