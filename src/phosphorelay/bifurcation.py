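"""Dose-response and bifurcation analysis of phosphorelay models.

The input signal acts by scaling the HK autophosphorylation rates: the
swept parameter s sets the REC-unphosphorylated autophosphorylation rate
(k1), with the REC-phosphorylated rate slaved at a fixed ratio
(k3 = ratio * s).  At each input all steady states are enumerated (via the
steady-state polynomial where the architecture supports it), classified,
and threaded into continuous branches; fold (saddle-node) points appear
where branches are born or die, and the gap between the up-switching and
down-switching folds is the hysteresis width.

Quasi-static time-integration sweeps provide an independent check on the
fold locations: the system is integrated to steady state at each input,
carrying the endpoint forward as the next initial condition, so the jump
of the output marks the fold encountered in that sweep direction.
Steady-state detection follows a small-change criterion: the integration
stops once no phosphorylated-species output changes by more than 1e-5
over a window of 10 time units (the window length is this package's
convention; see docs).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import solve_ivp
from scipy.optimize import linear_sum_assignment

from .networks import ParameterSet, ReactionNetwork, mass_action_jacobian, mass_action_rhs
from .steadystate import SteadyState, classify_stability, find_steady_states

__all__ = [
    "BifurcationBranch",
    "StateComposition",
    "HysteresisResult",
    "ConvergenceError",
    "default_signal_labels",
    "sweep_input",
    "detect_hysteresis",
    "integration_sweep",
    "state_composition",
    "simulate_to_steady_state",
    "phosphorylated_species",
    "branches_to_frame",
]


class ConvergenceError(RuntimeError):
    def __init__(self, msg, trajectory=None):
        super().__init__(msg)
        self.trajectory = trajectory


def phosphorylated_species(network: ReactionNetwork):
    """Names of all species carrying at least one phosphate group."""
    out = []
    for s in network.species:
        if s.role in ("hpt_p", "rr_p", "rec_p") or "P" in s.phospho_pattern:
            out.append(s.name)
    return out


def default_signal_labels(network: ReactionNetwork):
    """(k1-like, k3-like) label pairs driven by the input signal.

    Single-HK networks use (k1, k3); multi-HK networks driven by one
    common signal couple every HK's pair.
    """
    labels = set(network.rate_labels)
    if "k1" in labels and "k3" in labels:
        return [("k1", "k3")]
    pairs = []
    i = 1
    while f"k{i}_1" in labels:
        pairs.append((f"k{i}_1", f"k{i}_3"))
        i += 1
    if not pairs:
        raise ValueError("cannot infer signal-driven rate labels; pass signal_labels")
    return pairs


# ---------------------------------------------------------------------------
# Steady-state sweep and branch threading
# ---------------------------------------------------------------------------

@dataclass
class BifurcationBranch:
    branch_id: int
    input_values: list = field(default_factory=list)
    output_values: list = field(default_factory=list)
    stability: list = field(default_factory=list)
    folds: list = field(default_factory=list)  # inputs where the branch is born/dies

    @property
    def is_stable(self) -> bool:
        return all(s == "stable" for s in self.stability)


@dataclass
class StateComposition:
    input_values: np.ndarray
    fractions: dict  # pattern -> array of fractions of the HK total
    branch: str


@dataclass
class HysteresisResult:
    fold_up: float | None
    fold_down: float | None
    width: float
    bistable: bool
    integration_folds: tuple | None = None  # (up-sweep jump, down-sweep jump)


def _signal_params(params, s, ratio, signal_labels):
    updates = {}
    for prim, coup in signal_labels:
        updates[prim] = float(s)
        updates[coup] = float(ratio * s)
    return params.with_rates(**updates)


def _output_fraction(network, params, state: SteadyState, output_species: str) -> float:
    prot = next(sp.protein for sp in network.species if sp.name == output_species)
    return state[output_species] / params.totals[prot]


def sweep_input(
    network: ReactionNetwork,
    params: ParameterSet,
    ratio: float,
    input_grid,
    output_species: str,
    signal_labels=None,
    **solver_kwargs,
):
    """Sweep the autophosphorylation input; thread steady states into branches.

    At each grid point all steady states are computed and classified; the
    points are then linked across inputs by nearest-neighbour matching in
    output value (optimal assignment).  A branch that fails to find a
    continuation records a fold at that input, as does a branch born
    mid-sweep.  Returns the list of :class:`BifurcationBranch`.
    """
    grid = np.asarray(input_grid, dtype=float)
    if np.any(np.diff(grid) <= 0):
        raise ValueError("input_grid must be strictly increasing")
    signal_labels = signal_labels or default_signal_labels(network)

    branches: list[BifurcationBranch] = []
    open_branches: list[BifurcationBranch] = []
    next_id = 0
    for s in grid:
        p_s = _signal_params(params, s, ratio, signal_labels)
        states = find_steady_states(network, p_s, **solver_kwargs)
        pts = [
            (_output_fraction(network, p_s, st, output_species), st.stability)
            for st in states
        ]
        # optimal matching between open branches and new points
        if open_branches and pts:
            C = np.array(
                [[abs(b.output_values[-1] - y) for y, _ in pts] for b in open_branches]
            )
            rows, cols = linear_sum_assignment(C)
            matched_b, matched_p = set(), set()
            for r, c in zip(rows, cols):
                open_branches[r].input_values.append(float(s))
                open_branches[r].output_values.append(pts[c][0])
                open_branches[r].stability.append(pts[c][1])
                matched_b.add(r)
                matched_p.add(c)
        else:
            matched_b, matched_p = set(), set()
        still_open = []
        for i, b in enumerate(open_branches):
            if i in matched_b:
                still_open.append(b)
            else:
                b.folds.append(float(s))  # branch died entering this input
        open_branches = still_open
        for c, (y, stab) in enumerate(pts):
            if c not in matched_p:
                b = BifurcationBranch(branch_id=next_id)
                next_id += 1
                if branches or open_branches:
                    if s != grid[0]:
                        b.folds.append(float(s))  # born mid-sweep: fold here
                b.input_values.append(float(s))
                b.output_values.append(y)
                b.stability.append(stab)
                branches.append(b)
                open_branches.append(b)
    return branches


def detect_hysteresis(
    branches,
    network: ReactionNetwork | None = None,
    params: ParameterSet | None = None,
    ratio: float | None = None,
    output_species: str | None = None,
    cross_validate: bool = False,
    signal_labels=None,
) -> HysteresisResult:
    """Fold pair and hysteresis width from a swept branch set.

    fold_up is the input where the low stable branch disappears (the
    up-sweep switching threshold), fold_down where the high stable branch
    disappears going down; width = fold_up - fold_down.  A monostable
    sweep yields width 0 with folds undefined (``bistable=False``).  With
    ``cross_validate=True`` the folds are re-measured by quasi-static
    up/down integration sweeps over the same grid.
    """
    by_input: dict = {}
    for b in branches:
        for s, stab in zip(b.input_values, b.stability):
            if stab == "stable":
                by_input[s] = by_input.get(s, 0) + 1
    multi = sorted(s for s, cnt in by_input.items() if cnt >= 2)
    if not multi:
        return HysteresisResult(None, None, 0.0, False)
    fold_down, fold_up = float(multi[0]), float(multi[-1])
    result = HysteresisResult(fold_up, fold_down, fold_up - fold_down, True)
    if cross_validate:
        if network is None or params is None or ratio is None or output_species is None:
            raise ValueError("cross-validation needs network/params/ratio/output_species")
        grid = np.array(sorted({s for b in branches for s in b.input_values}))
        _, _, up_jump = integration_sweep(
            network, params, ratio, grid, output_species, "up", signal_labels=signal_labels
        )
        _, _, down_jump = integration_sweep(
            network, params, ratio, grid, output_species, "down", signal_labels=signal_labels
        )
        result.integration_folds = (up_jump, down_jump)
    return result


def integration_sweep(
    network: ReactionNetwork,
    params: ParameterSet,
    ratio: float,
    input_grid,
    output_species: str,
    direction: str = "up",
    signal_labels=None,
    criterion: float = 1e-5,
    window: float = 10.0,
):
    """Quasi-static sweep by time integration, carrying the state forward.

    Returns (inputs in sweep order, output fractions, jump input): the
    jump input is the grid point with the largest output change from its
    predecessor -- the switching threshold in that direction.
    """
    grid = np.asarray(input_grid, dtype=float)
    order = grid if direction == "up" else grid[::-1]
    signal_labels = signal_labels or default_signal_labels(network)
    x = params.unphosphorylated_state(network)
    if direction == "down":
        # start on the high branch: pre-equilibrate at the largest input
        p_s = _signal_params(params, order[0], ratio, signal_labels)
        st, _ = simulate_to_steady_state(
            network, p_s, x, criterion=criterion, window=window
        )
        x = np.asarray(st.concentrations)
    outputs = []
    for s in order:
        p_s = _signal_params(params, s, ratio, signal_labels)
        st, _ = simulate_to_steady_state(
            network, p_s, x, criterion=criterion, window=window
        )
        x = np.asarray(st.concentrations)
        outputs.append(_output_fraction(network, p_s, st, output_species))
    outputs = np.array(outputs)
    jumps = np.abs(np.diff(outputs))
    jump_input = float(order[1:][int(np.argmax(jumps))]) if len(outputs) > 1 else None
    return order, outputs, jump_input


# ---------------------------------------------------------------------------
# HK state composition along a branch
# ---------------------------------------------------------------------------

def state_composition(
    network: ReactionNetwork,
    params: ParameterSet,
    ratio: float,
    input_grid,
    branch_selector: str = "upper",
    protein: str = "HK",
    output_species: str = "Hpt_P",
    signal_labels=None,
) -> StateComposition:
    """Fractions of the HK phospho-states along one stable branch.

    ``branch_selector`` picks the stable state with the largest ("upper")
    or smallest ("lower") output fraction at each input; a callable
    receives the list of stable states and returns one.  Fractions sum to
    one at every grid point.
    """
    grid = np.asarray(input_grid, dtype=float)
    signal_labels = signal_labels or default_signal_labels(network)
    members = network.protein_species(protein)
    fractions = {m: [] for m in members}
    H = params.totals[protein]
    for s in grid:
        p_s = _signal_params(params, s, ratio, signal_labels)
        stable = [
            st
            for st in find_steady_states(network, p_s)
            if st.stability == "stable"
        ]
        if not stable:
            raise ValueError(f"no stable steady state at input {s}")
        if callable(branch_selector):
            chosen = branch_selector(stable)
        else:
            key = lambda st: _output_fraction(network, p_s, st, output_species)
            chosen = max(stable, key=key) if branch_selector == "upper" else min(stable, key=key)
        if chosen is None:
            raise ValueError(f"branch selector picked no state at input {s}")
        for m in members:
            fractions[m].append(chosen[m] / H)
    return StateComposition(
        grid, {m: np.array(v) for m, v in fractions.items()}, str(branch_selector)
    )


# ---------------------------------------------------------------------------
# Time integration to steady state
# ---------------------------------------------------------------------------

def simulate_to_steady_state(
    network: ReactionNetwork,
    params: ParameterSet,
    x0,
    criterion: float = 1e-5,
    window: float = 10.0,
    max_time: float = 1e7,
    keep_trajectory: bool = False,
):
    """Integrate until every phosphorylated output settles.

    The system is deemed at steady state when the change of every
    phosphorylated-species concentration over one integration window is
    below ``criterion``.  Returns (SteadyState, trajectory); the endpoint
    carries a stability label from the reduced Jacobian.  Raises
    :class:`ConvergenceError` (with the trajectory attached) if
    ``max_time`` is exceeded.
    """
    x0 = np.asarray(x0, dtype=float)
    if np.any(x0 < 0):
        raise ValueError("initial state must be componentwise non-negative")
    rhs = mass_action_rhs(network, params)
    jac = mass_action_jacobian(network, params)
    p_idx = [network.index(n) for n in phosphorylated_species(network)]

    f = lambda t, y: rhs(y)
    jf = lambda t, y: jac(y)
    t, x = 0.0, x0.copy()
    traj_t, traj_x = [0.0], [x0.copy()]
    while t < max_time:
        span = min(window, max_time - t)
        sol = solve_ivp(
            f, (t, t + span), x, method="LSODA", jac=jf, rtol=1e-9, atol=1e-12
        )
        if not sol.success:
            raise ConvergenceError(f"integrator failed at t={t}: {sol.message}")
        x_new = sol.y[:, -1]
        if keep_trajectory:
            traj_t.extend(sol.t[1:].tolist())
            traj_x.extend(sol.y[:, 1:].T)
        change = np.max(np.abs(x_new[p_idx] - x[p_idx]))
        t += span
        x = x_new
        if change < criterion and span == window:
            break
    else:
        raise ConvergenceError(
            f"no steady state within t={max_time}",
            trajectory=(np.array(traj_t), np.array(traj_x)),
        )
    x = np.clip(x, 0.0, None)
    state = classify_stability(
        network, params, SteadyState(tuple(network.species_names), x)
    )
    traj = (np.array(traj_t), np.array(traj_x)) if keep_trajectory else None
    return state, traj


def branches_to_frame(branches):
    """CSV-ready table: input, output fraction, stability, branch id, fold flag."""
    import pandas as pd

    rows = []
    for b in branches:
        for s, y, stab in zip(b.input_values, b.output_values, b.stability):
            rows.append(
                {
                    "input": s,
                    "output_fraction": y,
                    "stability": stab,
                    "branch_id": b.branch_id,
                    "fold_at_input": s in b.folds,
                }
            )
    return pd.DataFrame(rows).sort_values(["branch_id", "input"]).reset_index(drop=True)
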