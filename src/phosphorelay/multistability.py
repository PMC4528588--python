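"""Deciding and constructing multistability in phosphorelay architectures.

A single hybrid HK feeding an Hpt can have at most three positive steady
states (the steady-state polynomial is cubic); n HKs sharing one Hpt can
have up to 2n+1, and m modules feeding a common RR up to the product of
the per-module counts.  This module decides bistability by exact root
counting, checks the necessary condition k3 > k1 (autophosphorylation must
be faster when the REC site is occupied), and constructs parameter sets
that realize the 2n+1 and prod(2n_i+1) bounds.

Witness construction works in flux space.  At steady state the total
phosphate flux from the HKs into the Hpt, F(h) = sum_i H_i (k_{i,3} +
k_{i,4} h) / D_i(h), must balance the hydrolysis line L(h) = k6 (T - h);
steady states are the crossings.  A suitably tuned single-HK block has a
*non-monotone* flux curve: it rises to a local maximum M and then decays
to a much lower plateau f_inf = H / (1/k1 + 1/k2).  Rescaling the
bimolecular rates k4, k5 by 1/s stretches the curve horizontally by s, so
n copies of one block at widely separated scales produce n rises and n
decays; against a nearly flat hydrolysis line each contributes an
up-crossing and a down-crossing, and the line's own fall to zero at h = T
adds the final crossing: 2n+1 in total.  Certification never depends on
this geometry -- every witness is certified by exact root counting.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import sympy as sp

from .networks import (
    ParameterSet,
    ReactionNetwork,
    build_core_hybrid,
    build_shared_hpt,
    build_shared_rr,
    shared_hpt_rate_label,
)
from .steadystate import (
    DegenerateParameters,
    SteadyState,
    classify_stability,
    classify_stability_hp,
    derive_polynomial,
    find_steady_states_numeric,
    positive_roots,
    reconstruct_state,
)

__all__ = [
    "MultistabilityReport",
    "is_bistable",
    "check_necessary_condition",
    "bistable_core_params",
    "construct_multistable_params",
    "construct_shared_rr_witness",
    "count_positive_steady_states",
]

# Reference non-monotone flux block: a single hybrid-HK rate set whose flux
# curve has a pronounced local maximum well above its plateau (M/f_inf ~ 13).
# Found by seeded sampling of the bistability region; any block satisfying
# the non-monotonicity condition would do.
BASE_BLOCK = {"k1": 0.0701, "k2": 3.0947, "k3": 2.4746, "k4": 0.1309, "k5": 20.3126}

# Canonical bistable witness for the core system (same block, with the
# hydrolysis rate and totals placing the line through the non-monotone
# window): three distinct positive steady states, two stable.
CORE_WITNESS = ParameterSet(
    rates={**BASE_BLOCK, "k6": 0.0198},
    totals={"HK": 0.157, "Hpt": 6.944},
)

# Bistable witness for the unorthodox (three-site) HK feeding an RR: the
# same mechanism as the hybrid core, with the Asp-site-dependent
# autophosphorylation contrast (ka_P >> ka_O) and the RR pool playing the
# downstream acceptor.  Found by seeded sampling of non-monotone flux
# curves; certified by multi-start steady-state counting.
UNORTHODOX_WITNESS = ParameterSet(
    rates={
        "ka_O": 0.0253, "ka_P": 45.0141, "kt12": 10.9505, "kt23": 35.2947,
        "khy2": 0.0858, "kout": 1.6582, "krev_out": 0.0, "khy_rr": 0.00605,
    },
    totals={"HK": 1.0, "RR": 20.0},
)


@dataclass(frozen=True)
class MultistabilityReport:
    architecture_tag: str
    params: ParameterSet
    n_positive: int
    n_stable: int
    n_unstable: int
    n_marginal: int
    witness_states: tuple
    seed: int | None = None
    certification: str = ""
    meta: dict = field(default_factory=dict)

    def to_json(self) -> str:
        return json.dumps(
            {
                "architecture": self.architecture_tag,
                "rates": self.params.rates,
                "totals": self.params.totals,
                "n_positive": self.n_positive,
                "n_stable": self.n_stable,
                "n_unstable": self.n_unstable,
                "n_marginal": self.n_marginal,
                "states": [s.as_dict() for s in self.witness_states],
                "stability": [s.stability for s in self.witness_states],
                "seed": self.seed,
                "certification": self.certification,
            },
            indent=2,
        )


def _report(network, params, states, seed=None, certification="", meta=None):
    labels = [s.stability for s in states]
    return MultistabilityReport(
        architecture_tag=network.architecture_tag,
        params=params,
        n_positive=len(states),
        n_stable=labels.count("stable"),
        n_unstable=labels.count("unstable"),
        n_marginal=labels.count("marginal"),
        witness_states=tuple(states),
        seed=seed,
        certification=certification,
        meta=meta or {},
    )


# ---------------------------------------------------------------------------
# Core-system bistability
# ---------------------------------------------------------------------------

def check_necessary_condition(params: ParameterSet) -> bool:
    """k3 > k1: autophosphorylation faster with the REC site phosphorylated.

    Necessary (not sufficient) for bistability of the core system; the
    strict inequality matters -- k3 == k1 cannot be bistable.
    """
    return params.rates["k3"] > params.rates["k1"]


def count_positive_steady_states(
    network: ReactionNetwork, params: ParameterSet, **kwargs
) -> int:
    """Exact positive-root count via the steady-state polynomial."""
    poly = derive_polynomial(network)
    return len(positive_roots(poly, params, **kwargs))


def is_bistable(params: ParameterSet, network: ReactionNetwork | None = None) -> bool:
    """True iff the core cubic has three distinct positive roots.

    Parameters with a vanishing rate constant make the elimination
    degenerate and raise :class:`DegenerateParameters` rather than
    returning False.
    """
    network = network or build_core_hybrid()
    if any(params.rates[l] == 0.0 for l in network.rate_labels):
        raise DegenerateParameters("a rate constant is zero: bistability undefined")
    roots, borderline = positive_roots(
        derive_polynomial(network), params, detailed=True
    )
    return len(roots) == 3 and not borderline


def bistable_core_params() -> ParameterSet:
    """The package's reference bistable parameter set for the core system."""
    return CORE_WITNESS


# ---------------------------------------------------------------------------
# Flux geometry of a single HK block
# ---------------------------------------------------------------------------

def block_flux(rates: dict, h):
    """Steady-state phosphate flux of one HK block into the Hpt, per unit HK.

    f(h) = (k3 + k4 h) / D(h) with
    D(h) = k4 h / k1 + (k3 + k4 h)/k2 + 1 + k3/(k5 h).
    """
    k1, k2, k3, k4, k5 = (rates[f"k{j}"] for j in range(1, 6))
    h = np.asarray(h, dtype=float)
    D = k4 * h / k1 + (k3 + k4 * h) / k2 + 1.0 + k3 / (k5 * h)
    return (k3 + k4 * h) / D


def _block_geometry(rates: dict):
    """(peak height M, peak position, plateau f_inf) of the unit-flux curve."""
    f_inf = 1.0 / (1.0 / rates["k1"] + 1.0 / rates["k2"])
    hgrid = np.logspace(-6, 6, 4000)
    f = block_flux(rates, hgrid)
    i = int(np.argmax(f))
    return float(f[i]), float(hgrid[i]), f_inf


def _scaled_block(rates: dict, s: float) -> dict:
    """Stretch the flux curve horizontally by s: divide k4, k5 by s."""
    out = dict(rates)
    out["k4"] = rates["k4"] / s
    out["k5"] = rates["k5"] / s
    return out


# ---------------------------------------------------------------------------
# 2n+1 witness for n HKs sharing one Hpt
# ---------------------------------------------------------------------------

def _certify_by_sign_alternation(poly, params, roots) -> bool:
    """Exact certificate that P has at least len(roots) positive roots.

    Evaluates the exact-rational-coefficient polynomial at rational points
    interleaving the numeric roots and checks strict sign alternation.
    Combined with the degree bound this pins the count exactly when
    len(roots) equals the degree.
    """
    exact = poly.exact_coefficients(params)

    def val(x: sp.Rational):
        acc = sp.Integer(0)
        for c in reversed(exact):
            acc = acc * x + c
        return acc

    from fractions import Fraction

    pts = [sp.Rational(0)]
    for a, b in zip(roots[:-1], roots[1:]):
        pts.append(sp.Rational(Fraction(float(np.sqrt(a * b)))))
    pts.append(sp.Rational(Fraction(float(roots[-1] * 2))))
    signs = [sp.sign(val(x)) for x in pts]
    if any(s == 0 for s in signs):
        return False
    return all(s1 == -s2 for s1, s2 in zip(signs[:-1], signs[1:]))


def construct_multistable_params(
    n: int,
    seed: int = 0,
    separation: float = 2000.0,
    line_height: float = 1.0,
    t_factor: float = 2e4,
    max_attempts: int = 40,
) -> MultistabilityReport:
    """Parameter set for shared_hpt(n) with 2n+1 distinct positive states.

    Deterministic flux-geometry construction (module docstring): n rescaled
    copies of the reference block at scales separation**i, with HK totals
    H_i = (V - P_i)/g chosen so each block's rise pierces the hydrolysis
    line of height V = ``line_height`` and its plateau falls back below it
    (g is the geometric mean of peak and plateau, P_i the accumulated
    plateau of earlier blocks).  If certification fails, seeded jitter on
    the scales and totals is retried up to ``max_attempts`` times before an
    explicit failure.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    network = build_shared_hpt(n)
    poly = derive_polynomial(network)
    M, _, f_inf = _block_geometry(BASE_BLOCK)
    g0 = float(np.sqrt(M * f_inf))
    rng = np.random.default_rng(seed)

    last_error = None
    for attempt in range(max_attempts):
        if attempt == 0:
            jit_s = np.ones(n)
            jit_h = np.ones(n)
        else:
            jit_s = 10 ** rng.uniform(-0.15, 0.15, n)
            jit_h = 10 ** rng.uniform(-0.1, 0.1, n)
        rates, totals = {}, {}
        plateau = 0.0
        top_scale = 1.0
        for i in range(1, n + 1):
            s = separation ** (i - 1) * jit_s[i - 1]
            top_scale = s
            block = _scaled_block(BASE_BLOCK, s)
            for j in range(1, 6):
                rates[shared_hpt_rate_label(i, j)] = block[f"k{j}"]
            H_i = (line_height - plateau) / g0 * jit_h[i - 1]
            totals[f"HK{i}"] = H_i
            plateau += H_i * f_inf
        T = t_factor * top_scale
        rates["k6"] = line_height / T
        totals["Hpt"] = T
        params = ParameterSet(rates, totals)

        roots, borderline = positive_roots(poly, params, detailed=True)
        if len(roots) != 2 * n + 1 or borderline:
            last_error = f"attempt {attempt}: found {len(roots)} roots"
            continue
        if not _certify_by_sign_alternation(poly, params, roots):
            last_error = f"attempt {attempt}: sign-alternation certificate failed"
            continue
        states = [
            classify_stability(network, params, reconstruct_state(poly, r, params))
            for r in roots
        ]
        # sorted by h, stability must alternate stable/unstable/...; for
        # widely scaled witnesses the decisive eigenvalue can fall below the
        # double-precision noise floor -- reclassify those in high precision
        expected = ["stable" if i % 2 == 0 else "unstable" for i in range(len(states))]
        states = [
            s
            if s.stability == e
            else classify_stability_hp(poly, r, params)
            for s, e, r in zip(states, expected, roots)
        ]
        return _report(
            network,
            params,
            states,
            seed=seed,
            certification="exact sign-alternation certificate at degree bound",
            meta={"n": n, "separation": separation, "attempt": attempt},
        )
    raise RuntimeError(
        f"could not construct a {2*n+1}-state witness for shared_hpt({n}) "
        f"within {max_attempts} attempts (last: {last_error})"
    )


# ---------------------------------------------------------------------------
# prod(2n_i + 1) witness for modules sharing one RR
# ---------------------------------------------------------------------------

def construct_shared_rr_witness(
    module_sizes,
    seed: int = 0,
    coupling: float = 1e-4,
    n_extra_starts: int = 100,
) -> MultistabilityReport:
    """Parameter set for shared_rr(module_sizes) realizing prod(2n_i+1) states.

    Each module gets a certified (2n_i+1)-state shared-Hpt witness; the
    modules are then coupled to the common RR *weakly* -- the RR-transfer
    rate kt_i is ``coupling`` times the module's hydrolysis rate over the
    RR total, so the effective hydrolysis perturbation kt_i * [RR] stays a
    small fraction of k6_i and the per-module root structure survives.
    Steady states of the coupled system are located by Newton refinement
    from all product combinations of per-module roots (plus random
    multi-starts), and certified by count and residual checks.
    """
    module_sizes = [int(x) for x in module_sizes]
    if not module_sizes:
        raise ValueError("module_sizes must be nonempty")
    network = build_shared_rr(module_sizes)
    rng = np.random.default_rng(seed)

    rates, totals = {}, {}
    module_states = []  # per module: list of full module state dicts
    g = 0
    for mi, n_i in enumerate(module_sizes, start=1):
        rep = construct_multistable_params(n_i, seed=seed + mi)
        # re-label this module's HKs into the global numbering
        for li, _ in enumerate(range(n_i), start=1):
            g += 1
            for j in range(1, 6):
                rates[shared_hpt_rate_label(g, j)] = rep.params.rates[
                    shared_hpt_rate_label(li, j)
                ]
            totals[f"HK{g}"] = rep.params.totals[f"HK{li}"]
        rates[f"k6_m{mi}"] = rep.params.rates["k6"]
        totals[f"Hpt{mi}"] = rep.params.totals["Hpt"]
        module_states.append(rep)

    totals["RR"] = 1.0
    rates["khy_rr"] = 1.0
    for mi, n_i in enumerate(module_sizes, start=1):
        rates[f"kt_{mi}"] = coupling * rates[f"k6_m{mi}"] / totals["RR"]
    params = ParameterSet(rates, totals)

    # product seeds: one per combination of per-module steady states
    import itertools as it

    names = network.species_names
    seeds = []
    for combo in it.product(*(rep.witness_states for rep in module_states)):
        x = np.zeros(len(names))
        g = 0
        hptp_flux = 0.0
        for mi, (n_i, st) in enumerate(zip(module_sizes, combo), start=1):
            for li in range(1, n_i + 1):
                g += 1
                for pat in ("OO", "PO", "OP", "PP"):
                    x[names.index(f"HK{g}_{pat}")] = st[f"HK{li}_{pat}"]
            x[names.index(f"Hpt{mi}")] = st["Hpt"]
            x[names.index(f"Hpt{mi}_P")] = st["Hpt_P"]
            hptp_flux += rates[f"kt_{mi}"] * st["Hpt_P"]
        r = rates["khy_rr"] * totals["RR"] / (rates["khy_rr"] + hptp_flux)
        x[names.index("RR")] = r
        x[names.index("RR_P")] = totals["RR"] - r
        seeds.append(x)

    states = find_steady_states_numeric(
        network,
        params,
        n_starts=n_extra_starts,
        seed=seed,
        extra_starts=seeds,
    )
    expected = int(np.prod([2 * n + 1 for n in module_sizes]))
    if len(states) < expected:
        raise RuntimeError(
            f"shared_rr witness search found {len(states)} steady states, "
            f"expected {expected}; increase the multi-start budget or loosen coupling"
        )
    return _report(
        network,
        params,
        states,
        seed=seed,
        certification=(
            "multi-start Newton from per-module product seeds; per-state "
            "residual and conservation checks"
        ),
        meta={"module_sizes": module_sizes, "coupling": coupling},
    )
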