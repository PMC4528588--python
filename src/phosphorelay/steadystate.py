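"""Steady-state analysis of phosphorelay networks.

The central object is the univariate steady-state polynomial: for every
architecture with a single Hpt protein, setting the mass-action ODEs to
zero and using the conservation totals eliminates all species in favour of
the free-Hpt concentration h, and positive steady states are in one-to-one
correspondence with the positive roots of a polynomial P(h).  For the core
hybrid-HK system the degree is exactly 3; for n hybrid HKs sharing one Hpt
it is 2n+1.

The elimination exploits the network structure: every bimolecular reaction
involves an Hpt species, so given h (and Hpt_P = T - h) the steady-state
equations of each remaining protein are *linear* in that protein's own
species.  Solving one small linear system per protein expresses every
concentration as a rational function of h; substituting into the Hpt_P
balance and clearing denominators yields P(h).

A multi-start Newton solver on the full ODE system
(:func:`find_steady_states_numeric`) serves as an independent oracle for
the polynomial route, and works for architectures the elimination does not
cover (regular relay, unorthodox HK, multi-module shared-RR systems).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace
from fractions import Fraction

import numpy as np
import sympy as sp
from scipy import optimize

from .networks import (
    ParameterSet,
    ReactionNetwork,
    mass_action_jacobian,
    mass_action_rhs,
)

__all__ = [
    "SteadyState",
    "SteadyStatePolynomial",
    "UnsupportedArchitecture",
    "DegenerateParameters",
    "derive_polynomial",
    "positive_roots",
    "reconstruct_state",
    "find_steady_states_numeric",
    "find_steady_states",
    "classify_stability",
    "polynomial_architecture",
    "reduced_jacobian",
    "steady_states_to_frame",
]

ROOT_DEDUP_RTOL = 1e-7  # roots closer than this (relatively) are fold candidates


class UnsupportedArchitecture(ValueError):
    """The requested analysis route does not apply to this architecture."""


class DegenerateParameters(ValueError):
    """Parameter values make the symbolic elimination break down."""


# ---------------------------------------------------------------------------
# Steady-state container
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SteadyState:
    """Full steady-state concentration vector with stability information."""

    species: tuple
    concentrations: np.ndarray
    stability: str = "unknown"  # stable | unstable | marginal | unknown
    eigenvalues: np.ndarray | None = None

    def __getitem__(self, name: str) -> float:
        return float(self.concentrations[self.species.index(name)])

    def fraction(self, name: str, total: float) -> float:
        return self[name] / total

    def as_dict(self) -> dict:
        return dict(zip(self.species, map(float, self.concentrations)))


def steady_states_to_frame(states, input_id=None):
    """Tabulate steady states: one row per state (CSV-ready)."""
    import pandas as pd

    rows = []
    for s in states:
        row = {} if input_id is None else {"input_id": input_id}
        row.update(s.as_dict())
        row["stability"] = s.stability
        row["leading_eig_real"] = (
            float(np.max(s.eigenvalues.real)) if s.eigenvalues is not None else np.nan
        )
        rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Symbolic elimination
# ---------------------------------------------------------------------------

def _total_symbol(network: ReactionNetwork, protein: str) -> sp.Symbol:
    """Field notation: T for the Hpt total, H (or H_i) for HK totals, R for RR."""
    if protein == "HK":
        return sp.Symbol("H", positive=True)
    if protein.startswith("HK"):
        return sp.Symbol("H" + protein[2:], positive=True)
    if protein == "RR":
        return sp.Symbol("R", positive=True)
    if protein.startswith("Hpt"):
        return sp.Symbol("T" + protein[3:], positive=True)
    return sp.Symbol(protein + "_tot", positive=True)


def polynomial_architecture(network: ReactionNetwork) -> bool:
    """True if the single-Hpt elimination applies to this network.

    Requirements: exactly one protein with hpt/hpt_p species, and every
    bimolecular reaction has an Hpt-protein species among its reactants.
    """
    hpt_proteins = {s.protein for s in network.species if s.role in ("hpt", "hpt_p")}
    if len(hpt_proteins) != 1:
        return False
    hpt_names = {
        s.name for s in network.species if s.protein in hpt_proteins
    }
    for r in network.reactions:
        if r.order == 2 and not any(nm in hpt_names for nm in r.reactants):
            return False
    return True


@dataclass(frozen=True)
class SteadyStatePolynomial:
    """P(h): the steady-state polynomial in the free-Hpt concentration.

    ``coefficients`` are symbolic expressions in the rate and total symbols,
    ordered from the constant term upwards.  ``state_exprs`` maps each
    species name to its steady-state concentration as an expression in h
    (the back-substitution of the elimination).
    """

    network: ReactionNetwork
    variable: sp.Symbol
    coefficients: tuple  # sympy expressions, low -> high degree
    state_exprs: dict
    param_symbols: tuple  # (symbol, kind, key) with kind in {rate, total}
    _lambdas: dict = field(default_factory=dict, repr=False, compare=False)

    @property
    def degree(self) -> int:
        return len(self.coefficients) - 1

    def as_expr(self) -> sp.Expr:
        h = self.variable
        return sp.Add(*(c * h**i for i, c in enumerate(self.coefficients)))

    # -- numeric evaluation -------------------------------------------------
    def _param_values(self, params: ParameterSet):
        vals = []
        for _, kind, key in self.param_symbols:
            src = params.rates if kind == "rate" else params.totals
            if key not in src:
                raise KeyError(f"parameter {key} missing for polynomial evaluation")
            vals.append(float(src[key]))
        return vals

    def _coeff_fn(self):
        if "coeffs" not in self._lambdas:
            syms = [s for s, _, _ in self.param_symbols]
            self._lambdas["coeffs"] = sp.lambdify(
                syms, list(self.coefficients), modules="numpy"
            )
        return self._lambdas["coeffs"]

    def _state_fn(self):
        if "state" not in self._lambdas:
            syms = [self.variable] + [s for s, _, _ in self.param_symbols]
            exprs = [self.state_exprs[s.name] for s in self.network.species]
            self._lambdas["state"] = sp.lambdify(syms, exprs, modules="numpy")
        return self._lambdas["state"]

    def numeric_coefficients(self, params: ParameterSet) -> np.ndarray:
        """Coefficient vector (low -> high) at a numeric parameter set."""
        c = np.asarray(self._coeff_fn()(*self._param_values(params)), dtype=float)
        if not np.all(np.isfinite(c)):
            raise DegenerateParameters(
                "polynomial coefficients are not finite at these parameters "
                "(a rate constant involved in the elimination is zero?)"
            )
        if abs(c[-1]) == 0.0:
            raise DegenerateParameters("leading coefficient vanishes at these parameters")
        return c

    def exact_coefficients(self, params: ParameterSet):
        """Coefficients as exact rationals (floats converted exactly)."""
        subs = {}
        for s, kind, key in self.param_symbols:
            src = params.rates if kind == "rate" else params.totals
            subs[s] = sp.Rational(Fraction(float(src[key])))
        return [sp.Rational(c.subs(subs)) for c in self.coefficients]

    def back_substitute(self, root: float, params: ParameterSet) -> np.ndarray:
        """Full steady-state vector at a root h* (no validation)."""
        vals = self._state_fn()(float(root), *self._param_values(params))
        return np.asarray(vals, dtype=float)


def _cache_key(network: ReactionNetwork):
    return (
        network.architecture_tag,
        tuple(s.name for s in network.species),
        tuple((r.reactants, r.products, r.rate_label) for r in network.reactions),
    )


_POLY_CACHE: dict = {}


def derive_polynomial(network: ReactionNetwork, symbolic: bool = True) -> SteadyStatePolynomial:
    """Eliminate all species in favour of the free-Hpt concentration h.

    Supported architectures are those with a single Hpt through which all
    bimolecular reactions run: hybrid_core, shared_hpt(n), hybrid_full,
    yeast_osmo and single-module shared_rr systems.  Others raise
    :class:`UnsupportedArchitecture` (use the numeric oracle instead).

    The result is cached per network, and its coefficient expressions are
    exact in the rate and total symbols; ``symbolic=False`` merely skips a
    final simplification pass on the coefficients.
    """
    key = _cache_key(network)
    if key in _POLY_CACHE:
        return _POLY_CACHE[key]

    if not polynomial_architecture(network):
        raise UnsupportedArchitecture(
            f"single-Hpt elimination does not apply to {network.architecture_tag}; "
            "use find_steady_states_numeric"
        )

    h = sp.Symbol("h", positive=True)
    hpt_protein = next(
        s.protein for s in network.species if s.role in ("hpt", "hpt_p")
    )
    T = _total_symbol(network, hpt_protein)
    hpt_name = next(s.name for s in network.species if s.role == "hpt")
    hpt_p_name = next(s.name for s in network.species if s.role == "hpt_p")

    rate_syms = {l: sp.Symbol(l, positive=True) for l in network.rate_labels}
    total_syms = {p: _total_symbol(network, p) for p in network.proteins}
    total_syms[hpt_protein] = T

    # symbolic concentrations: Hpt fixed by h and conservation, the rest unknown
    conc = {hpt_name: h, hpt_p_name: T - h}
    unknowns = {}
    for s in network.species:
        if s.protein != hpt_protein:
            unknowns[s.name] = sp.Symbol("x_" + s.name, positive=True)
            conc[s.name] = unknowns[s.name]

    # symbolic RHS per species
    rhs = {s.name: sp.Integer(0) for s in network.species}
    for r in network.reactions:
        flux = rate_syms[r.rate_label]
        for nm in r.reactants:
            flux *= conc[nm]
        for nm in r.reactants:
            rhs[nm] -= flux
        for nm in r.products:
            rhs[nm] += flux

    # per-protein linear solve (equations are linear in the protein's species)
    state_exprs = {hpt_name: h, hpt_p_name: T - h}
    for prot in network.proteins:
        if prot == hpt_protein:
            continue
        members = network.protein_species(prot)
        vars_ = [unknowns[m] for m in members]
        eqs = [sp.Eq(rhs[m], 0) for m in members[1:]]
        eqs.append(sp.Eq(sp.Add(*vars_), total_syms[prot]))
        A, b = sp.linear_eq_to_matrix(eqs, vars_)
        sol = A.LUsolve(b)
        for m, expr in zip(members, sol):
            state_exprs[m] = sp.cancel(expr)

    # Hpt_P balance with everything substituted -> rational function of h
    balance = rhs[hpt_p_name].subs(
        {unknowns[m]: state_exprs[m] for m in unknowns}
    )
    numer, _ = sp.fraction(sp.together(balance))
    poly = sp.Poly(sp.expand(numer), h)
    coeffs = list(reversed(poly.all_coeffs()))  # low -> high
    # trim exact-zero leading terms (Poly already drops them) and normalize
    # the sign so the constant term is positive for positive parameters
    probe = {sym: 1 for sym in itertools.chain(rate_syms.values(), total_syms.values())}
    probe[T] = 2  # keep T - h factors positive at the probe point
    const_val = coeffs[0].subs(probe)
    if const_val.is_number and const_val < 0:
        coeffs = [-c for c in coeffs]
    if symbolic and len(coeffs) <= 6:
        # readable factored form for low degree; factoring the coefficient
        # expressions of large shared systems is prohibitively slow
        coeffs = [sp.factor(c) for c in coeffs]

    param_symbols = tuple(
        [(rate_syms[l], "rate", l) for l in network.rate_labels]
        + [(total_syms[p], "total", p) for p in network.proteins]
    )
    result = SteadyStatePolynomial(
        network=network,
        variable=h,
        coefficients=tuple(coeffs),
        state_exprs=state_exprs,
        param_symbols=param_symbols,
    )
    _POLY_CACHE[key] = result
    return result


# ---------------------------------------------------------------------------
# Root enumeration
# ---------------------------------------------------------------------------

def _polish_root(coeffs_low_high: np.ndarray, r: float) -> float:
    c = coeffs_low_high[::-1]  # high -> low for polyval
    dc = np.polyder(c)
    for _ in range(8):
        p, dp = np.polyval(c, r), np.polyval(dc, r)
        if dp == 0:
            break
        step = p / dp
        r -= step
        if abs(step) <= 1e-15 * max(abs(r), 1.0):
            break
    return r


def positive_roots(
    poly: SteadyStatePolynomial,
    params: ParameterSet,
    tol: float = 1e-9,
    certify: str | bool = "auto",
    detailed: bool = False,
):
    """Sorted positive real roots of P(h) at a numeric parameter set.

    Roots within ``tol`` of zero are dropped; roots closer than a relative
    ``ROOT_DEDUP_RTOL`` to each other are merged and flagged borderline
    (fold candidates).  ``certify`` controls the exact Sturm-sequence count
    on the rational-coefficient polynomial: ``True`` always, ``False``
    never, ``"auto"`` only when the numeric roots look fragile (near-zero,
    near-collision, or large residual at the deduplication scale).
    """
    if tol <= 0:
        raise ValueError("tol must be positive")
    c = poly.numeric_coefficients(params)
    # strip harmless all-zero leading terms before companion-matrix roots
    nz = np.nonzero(c)[0]
    c_trim = c[: nz[-1] + 1]
    raw = np.roots(c_trim[::-1])
    scale = max(abs(r) for r in raw) if len(raw) else 1.0
    real = [
        _polish_root(c_trim, r.real)
        for r in raw
        if abs(r.imag) <= 1e-8 * max(scale, abs(r))
    ]
    pos = sorted(r for r in real if r > tol)

    merged, borderline = [], []
    for r in pos:
        if merged and abs(r - merged[-1]) <= ROOT_DEDUP_RTOL * max(abs(r), abs(merged[-1])):
            borderline.append(0.5 * (r + merged[-1]))
            merged[-1] = 0.5 * (r + merged[-1])
        else:
            merged.append(r)
    fragile = bool(borderline) or any(r < 1e3 * tol for r in merged)

    if certify is True or (certify == "auto" and fragile):
        exact = poly.exact_coefficients(params)
        h = poly.variable
        p_exact = sp.Poly(
            sp.Add(*(cc * h**i for i, cc in enumerate(exact))), h
        )
        n_exact = p_exact.count_roots(0, sp.oo)
        if n_exact != len(merged):
            # trust the exact count; recompute roots to high precision
            rts = [float(r) for r in sp.nroots(p_exact, n=30) if abs(sp.im(r)) < 1e-20]
            merged = sorted(r for r in rts if r > tol)

    if detailed:
        return merged, borderline
    return merged


# ---------------------------------------------------------------------------
# Back-substitution and validation
# ---------------------------------------------------------------------------

def _residual_norm(network, params, x):
    return float(np.max(np.abs(mass_action_rhs(network, params)(x))))


def reconstruct_state(
    poly: SteadyStatePolynomial,
    root: float,
    params: ParameterSet,
    residual_tol: float | None = None,
) -> SteadyState:
    """Map a positive root h* back to the full steady-state vector.

    Validates non-negativity (a negative entry signals a spurious root),
    the conservation totals, and the ODE residual.  A Newton refinement on
    the reduced system is applied if the raw back-substitution residual is
    above tolerance (for extreme rate ratios, float roots lose digits).
    """
    network = poly.network
    x = poly.back_substitute(root, params)
    names = tuple(network.species_names)
    if np.any(x < -1e-9 * max(params.totals.values())):
        bad = {n: v for n, v in zip(names, x) if v < 0}
        raise ValueError(f"spurious root {root}: negative concentrations {bad}")
    x = np.clip(x, 0.0, None)

    tol = residual_tol if residual_tol is not None else 1e-9 * max(params.totals.values())
    if _residual_norm(network, params, x) > tol:
        x_ref = _newton_refine(network, params, x)
        if x_ref is not None and _residual_norm(network, params, x_ref) < _residual_norm(
            network, params, x
        ):
            x = x_ref
    res = _residual_norm(network, params, x)
    if res > max(tol, 1e-7 * _rate_scale(network, params) * max(params.totals.values())):
        raise ValueError(f"root {root}: residual {res} exceeds tolerance")
    return SteadyState(names, x)


def _rate_scale(network, params):
    return max(params.rates[l] for l in network.rate_labels)


# ---------------------------------------------------------------------------
# Reduced coordinates (one species eliminated per conservation law)
# ---------------------------------------------------------------------------

def _reduction_maps(network: ReactionNetwork):
    """Independent species indices and the per-protein dependent species.

    The eliminated (dependent) species of each protein is its fully
    unphosphorylated form -- the first species of the protein in the fixed
    ordering, by construction of the builders.
    """
    dep = {}
    for prot in network.proteins:
        dep[prot] = network.index(network.protein_species(prot)[0])
    dep_idx = set(dep.values())
    indep = [i for i in range(len(network.species)) if i not in dep_idx]
    prot_of = [s.protein for s in network.species]
    return indep, dep, prot_of


def _expand_state(network, params, u, indep, dep, prot_of):
    x = np.zeros(len(network.species))
    for val, i in zip(u, indep):
        x[i] = val
    for prot, d in dep.items():
        others = sum(x[i] for i in indep if prot_of[i] == prot)
        x[d] = params.totals[prot] - others
    return x


def reduced_jacobian(network: ReactionNetwork, params: ParameterSet, x: np.ndarray):
    """Jacobian restricted to the stoichiometric compatibility class.

    Conservation directions are removed by eliminating one species per
    protein; the reduced Jacobian has no structural zero eigenvalues.
    """
    indep, dep, prot_of = _reduction_maps(network)
    J = mass_action_jacobian(network, params)(x)
    dep_idx = list(dep.values())
    Jr = J[np.ix_(indep, indep)].copy()
    for col, j in enumerate(indep):
        for d in dep_idx:
            if prot_of[d] == prot_of[j]:
                Jr[:, col] -= J[np.ix_(indep, [d])].ravel()
    return Jr


def classify_stability(
    network: ReactionNetwork,
    params: ParameterSet,
    state: SteadyState,
    eps: float | None = None,
    rel: float = 1e-6,
) -> SteadyState:
    """Fill in stability from the reduced-Jacobian eigenvalues.

    An eigenvalue counts as negative if Re(lambda) < -eps or
    Re(lambda) < -rel*|lambda| (and symmetrically for positive): the
    relative test keeps genuinely stable slow modes of widely-scaled
    systems from being labelled marginal, while eigenvalues that are zero
    up to noise still yield "marginal" (never silently coerced).  Default
    eps is 1e-8 times the largest rate constant.
    """
    if eps is None:
        eps = 1e-8 * _rate_scale(network, params)
    Jr = reduced_jacobian(network, params, np.asarray(state.concentrations))
    eig = np.linalg.eigvals(Jr)
    re, mag = eig.real, np.abs(eig)
    neg = (re < -eps) | (re < -rel * mag)
    pos = (re > eps) | (re > rel * mag)
    if np.all(neg):
        label = "stable"
    elif np.any(pos):
        label = "unstable"
    else:
        label = "marginal"
    return replace(state, stability=label, eigenvalues=eig)


def classify_stability_hp(
    poly: SteadyStatePolynomial,
    root: float,
    params: ParameterSet,
    dps: int = 50,
    rel: float = 1e-6,
) -> SteadyState:
    """High-precision stability classification for extreme-scale states.

    For witnesses whose concentrations span many decades, the decisive
    reduced-Jacobian eigenvalue can lie below the double-precision noise
    floor (machine epsilon times the Jacobian norm).  This path refines the
    root on the exact-coefficient polynomial, back-substitutes and
    eigen-decomposes entirely in ``dps``-digit arithmetic.
    """
    import mpmath as mp

    network = poly.network
    with mp.workdps(dps):
        exact = poly.exact_coefficients(params)
        cs = [mp.mpf(c.p) / mp.mpf(c.q) for c in exact][::-1]  # high -> low
        scale = max(abs(c) * mp.mpf(float(root)) ** (len(cs) - 1 - i) for i, c in enumerate(cs))
        cs = [c / scale for c in cs]
        dcs = [c * (len(cs) - 1 - i) for i, c in enumerate(cs[:-1])]
        r = mp.mpf(float(root))
        for _ in range(80):
            p_v, dp_v = mp.polyval(cs, r), mp.polyval(dcs, r)
            if dp_v == 0:
                break
            step = p_v / dp_v
            r -= step
            if abs(step) <= mp.mpf(10) ** (-dps + 5) * max(abs(r), mp.mpf(1)):
                break

        if "state_mp" not in poly._lambdas:
            syms = [poly.variable] + [s for s, _, _ in poly.param_symbols]
            exprs = [poly.state_exprs[s.name] for s in network.species]
            poly._lambdas["state_mp"] = sp.lambdify(syms, exprs, modules="mpmath")
        pvals = [mp.mpf(v) for v in poly._param_values(params)]
        xs = poly._lambdas["state_mp"](r, *pvals)
        conc = {s.name: xs[i] for i, s in enumerate(network.species)}

        idx = {s.name: i for i, s in enumerate(network.species)}
        n = len(network.species)
        J = [[mp.mpf(0)] * n for _ in range(n)]
        for rx in network.reactions:
            k = mp.mpf(params.rates[rx.rate_label])
            for pos, nm in enumerate(rx.reactants):
                dv = k
                for q, other in enumerate(rx.reactants):
                    if q != pos:
                        dv *= conc[other]
                for t in rx.reactants:
                    J[idx[t]][idx[nm]] -= dv
                for t in rx.products:
                    J[idx[t]][idx[nm]] += dv
        indep, dep, prot_of = _reduction_maps(network)
        m = len(indep)
        Jr = mp.matrix(m, m)
        for a, ia in enumerate(indep):
            for b, ib in enumerate(indep):
                v = J[ia][ib]
                for d in dep.values():
                    if prot_of[d] == prot_of[ib]:
                        v -= J[ia][d]
                Jr[a, b] = v
        eigs, _ = mp.eig(Jr)
        re = [mp.re(e) for e in eigs]
        mag = [abs(e) for e in eigs]
        thresh = [rel * mg for mg in mag]
        if all(x < -t for x, t in zip(re, thresh)):
            label = "stable"
        elif any(x > t for x, t in zip(re, thresh)):
            label = "unstable"
        else:
            label = "marginal"
        eig_np = np.array([complex(e) for e in eigs])
        x_np = np.array([float(v) for v in xs])
    return SteadyState(tuple(network.species_names), x_np, label, eig_np)


# ---------------------------------------------------------------------------
# Numeric multi-start oracle
# ---------------------------------------------------------------------------

def _newton_refine(network, params, x0, tol=1e-13):
    indep, dep, prot_of = _reduction_maps(network)
    rhs = mass_action_rhs(network, params)
    jac = mass_action_jacobian(network, params)

    def g(u):
        return rhs(_expand_state(network, params, u, indep, dep, prot_of))[indep]

    def gj(u):
        x = _expand_state(network, params, u, indep, dep, prot_of)
        return reduced_jacobian(network, params, x)

    u0 = np.asarray(x0)[indep]
    sol = optimize.root(g, u0, jac=gj, method="hybr", tol=tol)
    if not sol.success:
        return None
    x = _expand_state(network, params, sol.x, indep, dep, prot_of)
    return x


def find_steady_states_numeric(
    network: ReactionNetwork,
    params: ParameterSet,
    n_starts: int = 50,
    seed: int = 0,
    classify: bool = True,
    extra_starts=None,
    dedup_rtol: float = 1e-5,
):
    """Multi-start root finding on the stoichiometric compatibility class.

    Starts are sampled uniformly on the product of per-protein simplices
    (Dirichlet weights times totals), deterministically from ``seed``;
    ``extra_starts`` full-state vectors can seed known candidates.
    Converged, componentwise non-negative, deduplicated solutions are
    returned sorted by the free-Hpt (or first-species) concentration.
    """
    if n_starts < 1:
        raise ValueError("n_starts must be >= 1")
    params.validate_for(network)
    rng = np.random.default_rng(seed)
    indep, dep, prot_of = _reduction_maps(network)
    rhs = mass_action_rhs(network, params)
    jac = mass_action_jacobian(network, params)
    names = tuple(network.species_names)

    def g(u):
        return rhs(_expand_state(network, params, u, indep, dep, prot_of))[indep]

    def gj(u):
        x = _expand_state(network, params, u, indep, dep, prot_of)
        return reduced_jacobian(network, params, x)

    starts = []
    for x in extra_starts or []:
        starts.append(np.asarray(x, dtype=float)[indep])
    for _ in range(n_starts):
        x = np.zeros(len(names))
        for prot in network.proteins:
            members = [network.index(m) for m in network.protein_species(prot)]
            w = rng.dirichlet(np.ones(len(members)))
            for i, m in enumerate(members):
                x[m] = w[i] * params.totals[prot]
        starts.append(x[indep])

    tot_scale = max(params.totals.values())
    res_tol = 1e-9 * tot_scale * max(1.0, _rate_scale(network, params))
    found = []
    for u0 in starts:
        sol = optimize.root(g, u0, jac=gj, method="hybr", tol=1e-13)
        if not sol.success:
            continue
        x = _expand_state(network, params, sol.x, indep, dep, prot_of)
        if np.any(x < -1e-8 * tot_scale):
            continue
        x = np.clip(x, 0.0, None)
        if _residual_norm(network, params, x) > res_tol:
            continue
        # relative per-component comparison: states of widely scaled systems
        # can differ only in their small components
        if any(
            np.allclose(x, y, rtol=dedup_rtol, atol=1e-9 * tot_scale) for y in found
        ):
            continue
        found.append(x)

    if not found:
        import warnings

        warnings.warn("no steady state converged from any start", RuntimeWarning)
    # sort by the free-Hpt concentration (matching the polynomial route),
    # falling back to the first species for Hpt-less architectures
    try:
        key_idx = names.index(
            next(s.name for s in network.species if s.role == "hpt")
        )
    except StopIteration:
        key_idx = 0
    states = [SteadyState(names, x) for x in sorted(found, key=lambda v: v[key_idx])]
    if classify:
        states = [classify_stability(network, params, s) for s in states]
    return states


# ---------------------------------------------------------------------------
# Numeric single-Hpt elimination (fast path for sweeps)
# ---------------------------------------------------------------------------
#
# Same elimination as derive_polynomial, but carried out in floating-point
# polynomial arithmetic in h at a fixed parameter set: per-protein linear
# systems over the field of rational functions of h are solved by Cramer's
# rule with numpy polynomial determinants.  This avoids the symbolic
# expression swell of networks with many reverse-transfer reactions and is
# the route bifurcation sweeps take.

def _polyadd(a, b):
    n = max(len(a), len(b))
    out = np.zeros(n)
    out[: len(a)] += a
    out[: len(b)] += b
    return out


def _polydet(M):
    """Determinant of a matrix of coefficient arrays (cofactor expansion)."""
    k = len(M)
    if k == 1:
        return M[0][0]
    det = np.zeros(1)
    for j in range(k):
        minor = [row[:j] + row[j + 1 :] for row in M[1:]]
        term = np.polynomial.polynomial.polymul(M[0][j], _polydet(minor))
        det = _polyadd(det, term if j % 2 == 0 else -term)
    return det


def numeric_elimination(network: ReactionNetwork, params: ParameterSet):
    """(coeffs low->high, state_builder) for a single-Hpt network.

    ``state_builder(h)`` maps a root to the full concentration vector.
    """
    if not polynomial_architecture(network):
        raise UnsupportedArchitecture(
            f"single-Hpt elimination does not apply to {network.architecture_tag}"
        )
    params.validate_for(network)
    pmul = np.polynomial.polynomial.polymul
    hpt_protein = next(s.protein for s in network.species if s.role in ("hpt", "hpt_p"))
    hpt_name = next(s.name for s in network.species if s.role == "hpt")
    hpt_p_name = next(s.name for s in network.species if s.role == "hpt_p")
    T = params.totals[hpt_protein]
    hpt_poly = {hpt_name: np.array([0.0, 1.0]), hpt_p_name: np.array([T, -1.0])}

    proteins = [p for p in network.proteins if p != hpt_protein]
    members = {p: network.protein_species(p) for p in proteins}
    prot_of = {m: p for p in proteins for m in members[p]}

    # reaction bookkeeping: rate constant, optional member reactant,
    # h-polynomial factor from Hpt reactants
    rx_info = []
    for r in network.reactions:
        k = params.rates[r.rate_label]
        member = None
        hfac = np.array([1.0])
        for nm in r.reactants:
            if nm in hpt_poly:
                hfac = pmul(hfac, hpt_poly[nm])
            else:
                member = nm
        rx_info.append((r, k, member, hfac))

    # per-protein linear systems A(h) x = b(h)
    numerators, denominators = {}, {}
    for p in proteins:
        mem = members[p]
        k = len(mem)
        col = {m: j for j, m in enumerate(mem)}
        A = [[np.zeros(1) for _ in range(k)] for _ in range(k)]
        b = [np.zeros(1) for _ in range(k)]
        # steady-state rows for members[1:]
        for ri, target in enumerate(mem[1:]):
            for r, kc, member, hfac in rx_info:
                if member is None or prot_of.get(member) != p:
                    continue
                net_st = r.products.count(target) - r.reactants.count(target)
                if net_st:
                    A[ri][col[member]] = _polyadd(A[ri][col[member]], net_st * kc * hfac)
        # conservation row
        for j in range(k):
            A[k - 1][j] = np.array([1.0])
        b[k - 1] = np.array([params.totals[p]])
        D = _polydet(A)
        denominators[p] = D
        for m in mem:
            Aj = [
                [b[i] if j == col[m] else A[i][j] for j in range(k)]
                for i in range(k)
            ]
            numerators[m] = _polydet(Aj)

    # Hpt_P balance, multiplied by the product of all protein denominators
    balance = np.zeros(1)
    for r, kc, member, hfac in rx_info:
        nu = r.products.count(hpt_p_name) - r.reactants.count(hpt_p_name)
        if nu == 0:
            continue
        term = nu * kc * hfac
        for p in proteins:
            if member is not None and prot_of.get(member) == p:
                term = pmul(term, numerators[member])
            else:
                term = pmul(term, denominators[p])
        balance = _polyadd(balance, term)
    # trim trailing zeros
    nz = np.nonzero(np.abs(balance) > 0)[0]
    balance = balance[: nz[-1] + 1] if len(nz) else balance

    names = network.species_names

    def state_builder(h):
        x = np.zeros(len(names))
        x[names.index(hpt_name)] = h
        x[names.index(hpt_p_name)] = T - h
        for p in proteins:
            D = np.polynomial.polynomial.polyval(h, denominators[p])
            for m in members[p]:
                x[names.index(m)] = (
                    np.polynomial.polynomial.polyval(h, numerators[m]) / D
                )
        return x

    return balance, state_builder


def find_steady_states(
    network: ReactionNetwork,
    params: ParameterSet,
    classify: bool = True,
    n_starts: int = 50,
    seed: int = 0,
    tol: float = 1e-9,
):
    """All positive steady states, via the polynomial route when available.

    Dispatcher used throughout the package: architectures covered by the
    single-Hpt elimination go through root enumeration of the eliminated
    polynomial plus back-substitution (with Newton refinement and residual
    checks); everything else falls back to the multi-start numeric solver.
    """
    if not polynomial_architecture(network):
        return find_steady_states_numeric(
            network, params, n_starts=n_starts, seed=seed, classify=classify
        )
    coeffs, state_builder = numeric_elimination(network, params)
    T = params.totals[next(s.protein for s in network.species if s.role == "hpt")]
    raw = np.roots(coeffs[::-1])
    scale = max(abs(r) for r in raw) if len(raw) else 1.0
    real = [
        _polish_root(coeffs, r.real)
        for r in raw
        if abs(r.imag) <= 1e-8 * max(scale, abs(r))
    ]
    roots = sorted(r for r in real if tol < r < T)
    merged = []
    for r in roots:
        if merged and abs(r - merged[-1]) <= ROOT_DEDUP_RTOL * max(abs(r), abs(merged[-1])):
            merged[-1] = 0.5 * (r + merged[-1])
        else:
            merged.append(r)
    tot_scale = max(params.totals.values())
    res_tol = 1e-9 * tot_scale * max(1.0, _rate_scale(network, params))
    states = []
    for r in merged:
        x = state_builder(r)
        if np.any(x < -1e-9 * tot_scale):
            continue  # spurious root outside the positive orthant
        x = np.clip(x, 0.0, None)
        if _residual_norm(network, params, x) > res_tol:
            x_ref = _newton_refine(network, params, x)
            if x_ref is None or _residual_norm(network, params, x_ref) > res_tol:
                continue
            x = x_ref
        states.append(SteadyState(tuple(network.species_names), x))
    if classify:
        states = [classify_stability(network, params, s) for s in states]
    return states
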