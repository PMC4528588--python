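"""Two-signal response surfaces and Boolean-logic classification.

Architectures with two independently signalled hybrid HKs feeding shared
downstream components can compute on their two inputs: depending on the
totals and the RR dephosphorylation rate, the steady-state RR output
implements a summation over the signals (an "adder"), a Boolean AND, or a
Boolean OR.  Signal i sets the autophosphorylation rate k{i}_1 of HK i,
with k{i}_3 slaved at a fixed ratio.

Where a grid cell is bistable, the reported surface value is the branch
reached by time integration from the fully unphosphorylated state (the
"signal on from rest" convention); all coexisting stable values are kept
in the multivalued record.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .bifurcation import simulate_to_steady_state
from .networks import ParameterSet, ReactionNetwork
from .steadystate import find_steady_states

__all__ = [
    "ResponseSurface",
    "GateVerdict",
    "response_surface",
    "classify_gate",
    "search_gate_params",
    "multi_switch_thresholds",
    "gate_witness",
    "GATE_BASE_RATES",
    "GATE_RATIO",
    "GATE_SIGNAL_HIGH",
]

# ---------------------------------------------------------------------------
# Reference gate witnesses (two hybrid HKs -> shared Hpt -> one RR)
# ---------------------------------------------------------------------------
#
# One kinetic base implements both Boolean gates: the HK flux feeds a
# bistable Hpt switch whose up-fold sits above the single-signal flux for
# the AND totals and below it for the OR totals -- only the totals and the
# RR_P dephosphorylation rate differ between the two, the tuning freedom
# this architecture offers.  The adder witness lives in a monostable,
# summation-linear regime of the same topology (the case-study defaults).

GATE_RATIO = 211.3  # k{i}_3 / k{i}_1 held fixed for both signals
GATE_SIGNAL_HIGH = 0.0569  # top of the signal grid; low end is 1e-3 of it

GATE_BASE_RATES = {
    "k1_1": GATE_SIGNAL_HIGH * 1e-3, "k1_2": 62.28, "k1_3": GATE_RATIO * GATE_SIGNAL_HIGH * 1e-3,
    "k1_4": 2.010, "k1_5": 60.74,
    "k2_1": GATE_SIGNAL_HIGH * 1e-3, "k2_2": 62.28, "k2_3": GATE_RATIO * GATE_SIGNAL_HIGH * 1e-3,
    "k2_4": 2.010, "k2_5": 60.74,
    "k6_m1": 0.00240, "kt_1": 0.1850, "khy_rr": 2.291,
}

AND_GATE_TOTALS = {"HK1": 0.4163, "HK2": 0.4163, "Hpt1": 2.837, "RR": 1.0}
OR_GATE_TOTALS = {"HK1": 0.6330, "HK2": 0.6330, "Hpt1": 3.096, "RR": 1.0}
OR_GATE_KHY_RR = 0.3200


def gate_witness(label: str, n_grid: int = 8):
    """(network, params, s_grid, ratios) reproducing a reference gate.

    ``label`` is AND, OR or ADDER; the returned signal grid spans three
    decades up to the witness's high-signal level.
    """
    from .casestudies import build_vharveyi_like

    model = build_vharveyi_like()
    network = model.network
    if label == "AND":
        params = ParameterSet(dict(GATE_BASE_RATES), dict(AND_GATE_TOTALS))
        hi, rho = GATE_SIGNAL_HIGH, GATE_RATIO
    elif label == "OR":
        params = ParameterSet(
            {**GATE_BASE_RATES, "khy_rr": OR_GATE_KHY_RR}, dict(OR_GATE_TOTALS)
        )
        hi, rho = GATE_SIGNAL_HIGH, GATE_RATIO
    elif label == "ADDER":
        params = model.default_params
        hi, rho = 0.1, model.ratio
    else:
        raise ValueError(f"unknown gate label {label!r}")
    grid = np.logspace(np.log10(hi) - 3, np.log10(hi), n_grid)
    return network, params, grid, (rho, rho)


@dataclass
class ResponseSurface:
    s1_grid: np.ndarray
    s2_grid: np.ndarray
    output: np.ndarray          # [i, j] = value at (s1_grid[i], s2_grid[j])
    multivalued: dict           # (i, j) -> sorted tuple of stable values
    invalid: set                # cells where no steady state converged
    output_species: str

    def corners(self):
        """(lo,lo), (hi,lo), (lo,hi), (hi,hi) output values."""
        return (
            self.output[0, 0],
            self.output[-1, 0],
            self.output[0, -1],
            self.output[-1, -1],
        )


@dataclass
class GateVerdict:
    label: str  # AND | OR | ADDER | OTHER
    corner_outputs: tuple
    adder_fit: float
    on_threshold: float
    off_threshold: float
    meta: dict = field(default_factory=dict)


def _two_hk_signal_labels(network: ReactionNetwork):
    labels = set(network.rate_labels)
    pairs = [("k1_1", "k1_3"), ("k2_1", "k2_3")]
    if not all(l in labels for pair in pairs for l in pair):
        raise ValueError("network must carry two HKs with k{i}_1 / k{i}_3 rates")
    if "k3_1" in labels:
        raise ValueError("network has more than two HKs")
    return pairs


def response_surface(
    network: ReactionNetwork,
    params: ParameterSet,
    s1_grid,
    s2_grid,
    output_species: str = "RR_P",
    ratios=(35.0, 35.0),
    resolve: str = "simulate",
) -> ResponseSurface:
    """Steady-state output fraction over a two-signal grid.

    Every stable steady state is computed per cell; multivalued cells are
    resolved by integration from rest (``resolve="simulate"``) or by
    taking the lowest stable branch (``resolve="low"``, cheaper and
    equivalent for surfaces reached quasi-statically from zero signal).
    Cells where no steady state is found are marked invalid and carry NaN.
    """
    (l11, l13), (l21, l23) = _two_hk_signal_labels(network)
    s1_grid = np.asarray(s1_grid, dtype=float)
    s2_grid = np.asarray(s2_grid, dtype=float)
    prot = next(s.protein for s in network.species if s.name == output_species)
    total = params.totals[prot]
    out = np.full((len(s1_grid), len(s2_grid)), np.nan)
    multivalued, invalid = {}, set()
    for i, s1 in enumerate(s1_grid):
        for j, s2 in enumerate(s2_grid):
            p = params.with_rates(
                **{
                    l11: s1,
                    l13: ratios[0] * s1,
                    l21: s2,
                    l23: ratios[1] * s2,
                }
            )
            states = [
                st for st in find_steady_states(network, p) if st.stability == "stable"
            ]
            if not states:
                invalid.add((i, j))
                continue
            vals = sorted(st[output_species] / total for st in states)
            if len(vals) > 1:
                multivalued[(i, j)] = tuple(vals)
                if resolve == "simulate":
                    st, _ = simulate_to_steady_state(
                        network, p, p.unphosphorylated_state(network)
                    )
                    out[i, j] = st[output_species] / total
                else:
                    out[i, j] = vals[0]
            else:
                out[i, j] = vals[0]
    return ResponseSurface(s1_grid, s2_grid, out, multivalued, invalid, output_species)


def _isotonic_fit(x, y):
    """1 - SS_res/SS_tot of the best monotone (isotonic) fit of y against x."""
    from sklearn.isotonic import IsotonicRegression

    order = np.argsort(x)
    yhat = IsotonicRegression().fit_transform(x[order], y[order])
    resid = y[order] - yhat
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    if ss_tot == 0:
        return 0.0
    return 1.0 - float(np.sum(resid**2)) / ss_tot


def classify_gate(
    surface: ResponseSurface,
    on_threshold: float = 0.75,
    off_threshold: float = 0.25,
    adder_fit_threshold: float = 0.95,
) -> GateVerdict:
    """Corner-based Boolean classification of a response surface.

    Thresholds are fractions of the maximum achievable output on the
    surface: a corner is ON above ``on_threshold``*max and OFF below
    ``off_threshold``*max.  AND requires (OFF,OFF,OFF,ON) over the
    corners (lo,lo),(hi,lo),(lo,hi),(hi,hi); OR requires (OFF,ON,ON,ON).
    ADDER requires non-Boolean corners and an isotonic fit of the output
    against s1+s2 with R^2 at or above ``adder_fit_threshold``.
    """
    if not 0 < off_threshold < on_threshold < 1:
        raise ValueError("need 0 < off_threshold < on_threshold < 1")
    vals = surface.output[np.isfinite(surface.output)]
    mx = float(vals.max()) if len(vals) else 0.0
    corners = surface.corners()

    S1, S2 = np.meshgrid(surface.s1_grid, surface.s2_grid, indexing="ij")
    mask = np.isfinite(surface.output)
    fit = _isotonic_fit((S1 + S2)[mask].ravel(), surface.output[mask].ravel())

    if mx <= 0:
        return GateVerdict("OTHER", corners, fit, on_threshold, off_threshold)
    on = lambda v: np.isfinite(v) and v >= on_threshold * mx
    off = lambda v: np.isfinite(v) and v <= off_threshold * mx
    ll, hl, lh, hh = corners
    if off(ll) and off(hl) and off(lh) and on(hh):
        label = "AND"
    elif off(ll) and on(hl) and on(lh) and on(hh):
        label = "OR"
    elif fit >= adder_fit_threshold and not (
        all(on(c) or off(c) for c in corners)
    ):
        label = "ADDER"
    else:
        label = "OTHER"
    return GateVerdict(label, corners, fit, on_threshold, off_threshold)


def search_gate_params(
    network: ReactionNetwork,
    base_params: ParameterSet,
    target_label: str,
    s1_grid,
    s2_grid,
    seed: int = 0,
    budget: int = 200,
    ratios=(35.0, 35.0),
    output_species: str = "RR_P",
    **classify_kwargs,
):
    """Randomized search for a parameter set implementing a target gate.

    Only the total concentrations and the RR_P dephosphorylation rate are
    varied around ``base_params`` (the kinetic rates stay fixed) -- the
    tuning freedom that switches this architecture between behaviours.
    Returns (ParameterSet, GateVerdict) on success; raises with the best
    candidate attached after ``budget`` draws.
    """
    if budget < 1:
        raise ValueError("budget must be >= 1")
    rng = np.random.default_rng(seed)
    best = None
    candidates = [base_params]
    for _ in range(budget):
        totals = {
            k: v * 10 ** rng.uniform(-1, 1) for k, v in base_params.totals.items()
        }
        khy = base_params.rates["khy_rr"] * 10 ** rng.uniform(-1.5, 1.5)
        candidates.append(
            ParameterSet({**base_params.rates, "khy_rr": khy}, totals)
        )
    for p in candidates:
        surf = response_surface(
            network, p, s1_grid, s2_grid, output_species, ratios=ratios
        )
        verdict = classify_gate(surf, **classify_kwargs)
        if verdict.label == target_label:
            return p, verdict
        if best is None or verdict.adder_fit > best[1].adder_fit:
            best = (p, verdict)
    err = RuntimeError(
        f"no {target_label} gate found within budget {budget}; "
        f"best candidate labelled {best[1].label}"
    )
    err.best_candidate = best
    raise err


def multi_switch_thresholds(
    network: ReactionNetwork,
    params: ParameterSet,
    input_grid,
    ratios=None,
    jump_fraction: float = 0.1,
):
    """Per-module switching thresholds when all HKs sense one signal.

    Shared-RR systems with m modules implement m bistable switches; with
    every HK driven by the same input, the quasi-static up-sweep of each
    module's phosphorylated-Hpt fraction jumps at that module's fold.
    Returns the sorted list of per-module threshold inputs (the grid point
    where the module output first jumps by more than ``jump_fraction`` of
    its total range).
    """
    sizes = network.meta.get("module_sizes")
    if sizes is None:
        raise ValueError("network must be a shared_rr architecture")
    ratios = ratios or {}
    # one common signal: couple every HK's (k{i}_1, k{i}_3) pair, keeping
    # each HK's own ratio from the base parameter set
    sig = []
    for l1 in network.rate_labels:
        if l1.endswith("_1") and l1.startswith("k") and l1[1].isdigit():
            l3 = l1[:-2] + "_3"
            sig.append((l1, l3, ratios.get(l1, params.rates[l3] / params.rates[l1])))

    grid = np.asarray(input_grid, dtype=float)
    module_out = {mi: [] for mi in range(1, len(sizes) + 1)}
    x = params.unphosphorylated_state(network)
    for s in grid:
        updates = {}
        for l1, l3, rho_i in sig:
            updates[l1] = float(s)
            updates[l3] = float(rho_i * s)
        p_s = params.with_rates(**updates)
        st, _ = simulate_to_steady_state(network, p_s, x)
        x = np.asarray(st.concentrations)
        for mi in module_out:
            module_out[mi].append(st[f"Hpt{mi}_P"] / p_s.totals[f"Hpt{mi}"])
    thresholds = []
    for mi, outputs in module_out.items():
        outputs = np.array(outputs)
        rng_out = outputs.max() - outputs.min()
        jumps = np.abs(np.diff(outputs))
        idx = np.where(jumps > jump_fraction * max(rng_out, 1e-12))[0]
        thresholds.append(float(grid[idx[0] + 1]) if len(idx) else float("nan"))
    return sorted(thresholds)
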