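"""Mass-action reaction networks for microbial phosphorelays.

Builders for the signalling architectures studied in this package: a
four-protein (regular) phosphorelay, phosphorelays with a hybrid histidine
kinase (HK) carrying an extra receiver (REC) domain, an unorthodox HK
carrying REC and Hpt domains, and component-sharing architectures in which
several hybrid HKs feed a common histidine-phosphotransfer protein (Hpt)
or a common response regulator (RR).

Every network is an explicit list of species and elementary mass-action
reactions.  Phosphotransfer between proteins is bimolecular; transitions
among the internal phospho-states of a multi-domain HK (autophosphorylation,
intramolecular transfer, hydrolysis) are first order.  ATP/ADP and the
external signal are implicit: the signal enters only by scaling the
autophosphorylation rate constants.

Hybrid-HK states are labelled by a two-letter pattern over the His and REC
sites, in the fixed order OO, PO, OP, PP (O = unphosphorylated,
P = phosphorylated); unorthodox HKs use three-letter patterns over
(His1, Asp, His2).  Species ordering within a network is fixed so state
vectors are reproducible.

Core hybrid rate-constant conventions (labels ``k1``..``k6``)::

    R1  OO -> PO              k1   (autophosphorylation, REC site empty)
    R2  PO -> OP              k2   (intramolecular His -> REC transfer)
    R3  OP -> PP              k3   (autophosphorylation, REC site occupied)
    R4  OP + Hpt -> OO + Hpt_P  k4 (phosphotransfer REC -> Hpt)
    R5  PP + Hpt -> PO + Hpt_P  k5
    R6  Hpt_P -> Hpt          k6   (hydrolysis of phosphorylated Hpt)

The full hybrid system adds an RR layer (``k7`` forward, ``k8`` reverse,
``k9`` RR_P hydrolysis), reverse Hpt -> REC transfer (``k10``, ``k11``)
and REC-site hydrolysis (``k12``, ``k13``).  Hydrolysis is only possible
on aspartate-phosphorylated sites (REC, RR); histidine-phosphorylated
species (HK His sites, Hpt) do not hydrolyse, with the single exception of
the core model, where the ``k6`` sink stands in for the removed RR layer.
"""

from __future__ import annotations

import itertools
from collections import Counter
from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "Species",
    "Reaction",
    "ReactionNetwork",
    "ParameterSet",
    "build_core_hybrid",
    "build_full_hybrid",
    "build_regular_relay",
    "build_unorthodox",
    "build_shared_hpt",
    "build_shared_rr",
    "mass_action_rhs",
    "mass_action_jacobian",
    "sample_parameters",
    "hk_state_cycles",
]

HYBRID_PATTERNS = ("OO", "PO", "OP", "PP")


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Species:
    """One chemical species: a protein in a definite phosphorylation state."""

    name: str
    role: str  # hk_state | hpt | hpt_p | rr | rr_p | rec | rec_p
    protein: str
    phospho_pattern: tuple = ()

    def __str__(self) -> str:  # pragma: no cover - repr sugar
        return self.name


@dataclass(frozen=True)
class Reaction:
    """Elementary mass-action reaction; reactants/products are name tuples."""

    reactants: tuple
    products: tuple
    rate_label: str

    @property
    def order(self) -> int:
        return len(self.reactants)

    def __post_init__(self):
        if self.order not in (1, 2):
            raise ValueError(
                f"reaction {self.rate_label}: only first- and second-order "
                f"reactions occur in these networks (got order {self.order})"
            )


@dataclass(frozen=True)
class ReactionNetwork:
    species: tuple
    reactions: tuple
    architecture_tag: str
    # per-architecture metadata (n for shared_hpt, module sizes, flags ...)
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        names = [s.name for s in self.species]
        if len(set(names)) != len(names):
            raise ValueError("species names must be unique within a network")
        known = set(names)
        for r in self.reactions:
            for nm in r.reactants + r.products:
                if nm not in known:
                    raise ValueError(f"reaction {r.rate_label} uses unknown species {nm}")

    # -- indexing helpers ---------------------------------------------------
    @property
    def species_names(self):
        return [s.name for s in self.species]

    def index(self, name: str) -> int:
        return self.species_names.index(name)

    @property
    def proteins(self):
        seen = []
        for s in self.species:
            if s.protein not in seen:
                seen.append(s.protein)
        return seen

    def protein_species(self, protein: str):
        return [s.name for s in self.species if s.protein == protein]

    @property
    def rate_labels(self):
        seen = []
        for r in self.reactions:
            if r.rate_label not in seen:
                seen.append(r.rate_label)
        return seen

    # -- stoichiometry ------------------------------------------------------
    def stoichiometric_matrix(self) -> np.ndarray:
        """Species x reactions stoichiometric matrix S."""
        S = np.zeros((len(self.species), len(self.reactions)))
        idx = {s.name: i for i, s in enumerate(self.species)}
        for j, r in enumerate(self.reactions):
            for nm, cnt in Counter(r.reactants).items():
                S[idx[nm], j] -= cnt
            for nm, cnt in Counter(r.products).items():
                S[idx[nm], j] += cnt
        return S

    def conservation_laws(self):
        """One conservation vector per protein: the sum of its forms.

        Each returned (protein, vector) pair lies in the left null space of
        the stoichiometric matrix -- phosphate moves between proteins but
        protein copy numbers are conserved.
        """
        laws = []
        S = self.stoichiometric_matrix()
        for prot in self.proteins:
            v = np.array([1.0 if s.protein == prot else 0.0 for s in self.species])
            if not np.allclose(v @ S, 0.0):
                raise AssertionError(f"protein {prot} total is not conserved")
            laws.append((prot, v))
        return laws


@dataclass(frozen=True)
class ParameterSet:
    """Rate constants and total protein concentrations.

    Units are nondimensional: 1/time for first-order rates,
    1/(concentration * time) for second-order rates, concentration for
    totals.  Outputs are reported as fractions of totals throughout.
    """

    rates: dict
    totals: dict

    def __post_init__(self):
        for lbl, v in self.rates.items():
            if v < 0:
                raise ValueError(f"rate {lbl} must be >= 0 (got {v})")
        for prot, v in self.totals.items():
            if v <= 0:
                raise ValueError(f"total {prot} must be > 0 (got {v})")

    def validate_for(self, network: ReactionNetwork) -> None:
        missing = [l for l in network.rate_labels if l not in self.rates]
        if missing:
            raise KeyError(f"missing rate constants: {missing}")
        missing_t = [p for p in network.proteins if p not in self.totals]
        if missing_t:
            raise KeyError(f"missing totals for proteins: {missing_t}")

    def with_rates(self, **updates) -> "ParameterSet":
        return replace(self, rates={**self.rates, **updates})

    def with_totals(self, **updates) -> "ParameterSet":
        return replace(self, totals={**self.totals, **updates})

    def unphosphorylated_state(self, network: ReactionNetwork) -> np.ndarray:
        """Initial state with every protein fully unphosphorylated."""
        x = np.zeros(len(network.species))
        for s in network.species:
            phospho = "P" in s.phospho_pattern or s.role in ("hpt_p", "rr_p", "rec_p")
            if not phospho:
                x[network.index(s.name)] = self.totals[s.protein]
        return x


# ---------------------------------------------------------------------------
# Builders
# ---------------------------------------------------------------------------

def _hybrid_species(protein: str, prefix: str = ""):
    return [
        Species(f"{prefix}{p}", "hk_state", protein, tuple(p))
        for p in HYBRID_PATTERNS
    ]


def build_core_hybrid() -> ReactionNetwork:
    """Minimal bistability-capable system: one hybrid HK and one Hpt.

    Six species, six reactions R1..R6 (module docstring).  The core embeds
    two interlinked phosphotransfer loops through the HK states:
    OO->PO->OP->OO (via k1, k2, k4) and PO->OP->PP->PO (via k2, k3, k5).
    """
    species = _hybrid_species("HK") + [
        Species("Hpt", "hpt", "Hpt"),
        Species("Hpt_P", "hpt_p", "Hpt"),
    ]
    reactions = [
        Reaction(("OO",), ("PO",), "k1"),
        Reaction(("PO",), ("OP",), "k2"),
        Reaction(("OP",), ("PP",), "k3"),
        Reaction(("OP", "Hpt"), ("OO", "Hpt_P"), "k4"),
        Reaction(("PP", "Hpt"), ("PO", "Hpt_P"), "k5"),
        Reaction(("Hpt_P",), ("Hpt",), "k6"),
    ]
    return ReactionNetwork(tuple(species), tuple(reactions), "hybrid_core")


def build_full_hybrid(
    include_rr: bool = True,
    include_reverse_transfer: bool = True,
    include_rec_hydrolysis: bool = True,
    include_rr_hydrolysis: bool = True,
) -> ReactionNetwork:
    """Full single hybrid-HK phosphorelay with optional reaction groups.

    With all flags on this is the complete hybrid-HK system (HK states,
    Hpt, RR, reverse transfers and aspartate hydrolyses).  Restricting to
    {no RR, no reverse transfer, no REC hydrolysis} and re-adding the Hpt_P
    hydrolysis sink reproduces the core model.
    """
    species = _hybrid_species("HK") + [
        Species("Hpt", "hpt", "Hpt"),
        Species("Hpt_P", "hpt_p", "Hpt"),
    ]
    reactions = [
        Reaction(("OO",), ("PO",), "k1"),
        Reaction(("PO",), ("OP",), "k2"),
        Reaction(("OP",), ("PP",), "k3"),
        Reaction(("OP", "Hpt"), ("OO", "Hpt_P"), "k4"),
        Reaction(("PP", "Hpt"), ("PO", "Hpt_P"), "k5"),
    ]
    if include_rr:
        species += [Species("RR", "rr", "RR"), Species("RR_P", "rr_p", "RR")]
        reactions += [
            Reaction(("Hpt_P", "RR"), ("Hpt", "RR_P"), "k7"),
            Reaction(("RR_P", "Hpt"), ("RR", "Hpt_P"), "k8"),
        ]
        if include_rr_hydrolysis:
            reactions.append(Reaction(("RR_P",), ("RR",), "k9"))
    else:
        # without a downstream layer the phosphorylated Hpt needs a sink
        reactions.append(Reaction(("Hpt_P",), ("Hpt",), "k6"))
    if include_reverse_transfer:
        # phosphate returns from Hpt to the (aspartate) REC site of the HK
        reactions += [
            Reaction(("Hpt_P", "OO"), ("Hpt", "OP"), "k10"),
            Reaction(("Hpt_P", "PO"), ("Hpt", "PP"), "k11"),
        ]
    if include_rec_hydrolysis:
        reactions += [
            Reaction(("OP",), ("OO",), "k12"),
            Reaction(("PP",), ("PO",), "k13"),
        ]
    tag = "hybrid_full" if include_rr else "hybrid_core"
    return ReactionNetwork(
        tuple(species), tuple(reactions), tag,
        meta={
            "include_rr": include_rr,
            "include_reverse_transfer": include_reverse_transfer,
            "include_rec_hydrolysis": include_rec_hydrolysis,
            "include_rr_hydrolysis": include_rr_hydrolysis,
        },
    )


def build_regular_relay() -> ReactionNetwork:
    """Four-protein phosphorelay with a regular (single-domain) HK.

    HK, REC, Hpt and RR are separate proteins; forward transfers run down
    the relay, reverse transfers act at the REC<->Hpt and Hpt<->RR steps,
    and the aspartate-phosphorylated species (REC_P, RR_P) hydrolyse.
    This architecture cannot be bistable.
    """
    species = [
        Species("HK", "hk_state", "HK", ("O",)),
        Species("HK_P", "hk_state", "HK", ("P",)),
        Species("REC", "rec", "REC"),
        Species("REC_P", "rec_p", "REC"),
        Species("Hpt", "hpt", "Hpt"),
        Species("Hpt_P", "hpt_p", "Hpt"),
        Species("RR", "rr", "RR"),
        Species("RR_P", "rr_p", "RR"),
    ]
    reactions = [
        Reaction(("HK",), ("HK_P",), "ka"),
        Reaction(("HK_P", "REC"), ("HK", "REC_P"), "kt1"),
        Reaction(("REC_P", "Hpt"), ("REC", "Hpt_P"), "kt2"),
        Reaction(("Hpt_P", "RR"), ("Hpt", "RR_P"), "kt3"),
        Reaction(("Hpt_P", "REC"), ("Hpt", "REC_P"), "krt2"),
        Reaction(("RR_P", "Hpt"), ("RR", "Hpt_P"), "krt3"),
        Reaction(("REC_P",), ("REC",), "khy_rec"),
        Reaction(("RR_P",), ("RR",), "khy_rr"),
    ]
    return ReactionNetwork(tuple(species), tuple(reactions), "regular_relay")


def build_unorthodox(
    include_reverse_transfer: bool = True,
    include_rr_hydrolysis: bool = True,
) -> ReactionNetwork:
    """Unorthodox HK: three phosphosites (His1, Asp, His2) -> 8 states.

    Mirrors the hybrid scheme site by site: autophosphorylation only at
    His1 (rate ``ka_O``/``ka_P`` depending on the Asp-site status, the
    analogue of k1/k3), one-way intramolecular transfers His1->Asp
    (``kt12``) and Asp->His2 (``kt23``), hydrolysis only at the Asp site
    (``khy2``), and bimolecular output from His2 to the RR (``kout``,
    reverse ``krev_out``).
    """
    patterns = ["".join(p) for p in itertools.product("OP", repeat=3)]
    species = [Species(p, "hk_state", "HK", tuple(p)) for p in patterns]
    species += [Species("RR", "rr", "RR"), Species("RR_P", "rr_p", "RR")]
    reactions = []
    for p in patterns:
        s1, s2, s3 = p
        if s1 == "O":
            lbl = "ka_O" if s2 == "O" else "ka_P"
            reactions.append(Reaction((p,), ("P" + s2 + s3,), lbl))
        if s1 == "P" and s2 == "O":
            reactions.append(Reaction((p,), ("O" + "P" + s3,), "kt12"))
        if s2 == "P" and s3 == "O":
            reactions.append(Reaction((p,), (s1 + "O" + "P",), "kt23"))
        if s2 == "P":
            reactions.append(Reaction((p,), (s1 + "O" + s3,), "khy2"))
        if s3 == "P":
            reactions.append(
                Reaction((p, "RR"), (s1 + s2 + "O", "RR_P"), "kout")
            )
            if include_reverse_transfer:
                reactions.append(
                    Reaction(("RR_P", s1 + s2 + "O"), ("RR", p), "krev_out")
                )
    if include_rr_hydrolysis:
        reactions.append(Reaction(("RR_P",), ("RR",), "khy_rr"))
    return ReactionNetwork(
        tuple(species), tuple(reactions), "unorthodox_full",
        meta={
            "include_reverse_transfer": include_reverse_transfer,
            "include_rr_hydrolysis": include_rr_hydrolysis,
        },
    )


def shared_hpt_rate_label(i: int, j: int) -> str:
    """Label for rate j of HK i in a multi-HK block (k_{i,j} in figures)."""
    return f"k{i}_{j}"


def _hk_block_reactions(prefix: str, i: int, hpt: str, hpt_p: str):
    lbl = lambda j: shared_hpt_rate_label(i, j)
    return [
        Reaction((f"{prefix}OO",), (f"{prefix}PO",), lbl(1)),
        Reaction((f"{prefix}PO",), (f"{prefix}OP",), lbl(2)),
        Reaction((f"{prefix}OP",), (f"{prefix}PP",), lbl(3)),
        Reaction((f"{prefix}OP", hpt), (f"{prefix}OO", hpt_p), lbl(4)),
        Reaction((f"{prefix}PP", hpt), (f"{prefix}PO", hpt_p), lbl(5)),
    ]


def build_shared_hpt(n: int) -> ReactionNetwork:
    """n hybrid HKs transferring phosphate to one common Hpt.

    HK i carries rates k{i}_1..k{i}_5 (the core scheme); the shared Hpt has
    a single hydrolysis reaction k6.  4n+2 species, 5n+1 reactions.
    """
    if n < 1:
        raise ValueError("build_shared_hpt requires n >= 1")
    species, reactions = [], []
    for i in range(1, n + 1):
        species += _hybrid_species(f"HK{i}", prefix=f"HK{i}_")
        reactions += _hk_block_reactions(f"HK{i}_", i, "Hpt", "Hpt_P")
    species += [Species("Hpt", "hpt", "Hpt"), Species("Hpt_P", "hpt_p", "Hpt")]
    reactions.append(Reaction(("Hpt_P",), ("Hpt",), "k6"))
    return ReactionNetwork(
        tuple(species), tuple(reactions), f"shared_hpt({n})", meta={"n": n}
    )


def build_shared_rr(module_sizes) -> ReactionNetwork:
    """m shared-Hpt modules feeding one common response regulator.

    Module i is a shared-Hpt block of ``module_sizes[i-1]`` hybrid HKs with
    its own Hpt (species ``Hpt{i}``, hydrolysis ``k6_{i}``); each
    phosphorylated Hpt additionally transfers to the common RR
    (``kt_{i}``: Hpt{i}_P + RR -> Hpt{i} + RR_P).  RR_P hydrolyses
    (``khy_rr``).  HKs are numbered globally so each keeps distinct
    k{g}_1..k{g}_5 labels.
    """
    module_sizes = list(module_sizes)
    if not module_sizes or any(int(n) < 1 for n in module_sizes):
        raise ValueError("module_sizes must be a nonempty list of integers >= 1")
    species, reactions = [], []
    g = 0
    for mi, n in enumerate(module_sizes, start=1):
        hpt, hpt_p = f"Hpt{mi}", f"Hpt{mi}_P"
        for _ in range(int(n)):
            g += 1
            species += _hybrid_species(f"HK{g}", prefix=f"HK{g}_")
            reactions += _hk_block_reactions(f"HK{g}_", g, hpt, hpt_p)
        species += [
            Species(hpt, "hpt", f"Hpt{mi}"),
            Species(hpt_p, "hpt_p", f"Hpt{mi}"),
        ]
        reactions.append(Reaction((hpt_p,), (hpt,), f"k6_m{mi}"))
        reactions.append(Reaction((hpt_p, "RR"), (hpt, "RR_P"), f"kt_{mi}"))
    species += [Species("RR", "rr", "RR"), Species("RR_P", "rr_p", "RR")]
    reactions.append(Reaction(("RR_P",), ("RR",), "khy_rr"))
    tag = "shared_rr(" + ",".join(str(int(n)) for n in module_sizes) + ")"
    return ReactionNetwork(
        tuple(species), tuple(reactions), tag,
        meta={"module_sizes": [int(n) for n in module_sizes]},
    )


# ---------------------------------------------------------------------------
# Mass-action kinetics
# ---------------------------------------------------------------------------

def _rate_vector_terms(network: ReactionNetwork, params: ParameterSet):
    """Per-reaction (rate constant, reactant index tuple) pairs."""
    params.validate_for(network)
    idx = {s.name: i for i, s in enumerate(network.species)}
    return [
        (params.rates[r.rate_label], tuple(idx[nm] for nm in r.reactants))
        for r in network.reactions
    ]


def mass_action_rhs(network: ReactionNetwork, params: ParameterSet):
    """Return f with f(x) = S v(x), the mass-action ODE right-hand side."""
    S = network.stoichiometric_matrix()
    terms = _rate_vector_terms(network, params)

    def rhs(x, *_):
        v = np.empty(len(terms))
        for j, (k, ridx) in enumerate(terms):
            val = k
            for i in ridx:
                val *= x[i]
            v[j] = val
        return S @ v

    return rhs


def mass_action_jacobian(network: ReactionNetwork, params: ParameterSet):
    """Analytic Jacobian df/dx of the mass-action right-hand side."""
    S = network.stoichiometric_matrix()
    terms = _rate_vector_terms(network, params)
    nsp = len(network.species)

    def jac(x, *_):
        dv = np.zeros((len(terms), nsp))
        for j, (k, ridx) in enumerate(terms):
            for pos, i in enumerate(ridx):
                val = k
                for q, other in enumerate(ridx):
                    if q != pos:
                        val *= x[other]
                dv[j, i] += val
        return S @ dv

    return jac


# ---------------------------------------------------------------------------
# Parameter sampling and reaction-graph utilities
# ---------------------------------------------------------------------------

def sample_parameters(
    network: ReactionNetwork,
    rng,
    rate_range=(1e-2, 1e2),
    total_range=(0.1, 10.0),
) -> ParameterSet:
    """Random ParameterSet: log-uniform rates and totals.

    The default ranges span four decades of rate ratios and two decades of
    totals -- wide enough to cover biologically plausible regimes without
    committing to units.
    """
    lo, hi = np.log10(rate_range[0]), np.log10(rate_range[1])
    tlo, thi = np.log10(total_range[0]), np.log10(total_range[1])
    rates = {l: float(10 ** rng.uniform(lo, hi)) for l in network.rate_labels}
    totals = {p: float(10 ** rng.uniform(tlo, thi)) for p in network.proteins}
    return ParameterSet(rates, totals)


def hk_state_cycles(network: ReactionNetwork, protein: str = "HK"):
    """Directed simple cycles through one HK's internal states.

    Edges are drawn between the HK states connected by a reaction
    (first-order internal transitions and bimolecular transfers alike); the
    core network has exactly two such cycles, OO-PO-OP and PO-OP-PP.
    """
    import networkx as nx

    states = set(network.protein_species(protein))
    G = nx.DiGraph()
    G.add_nodes_from(states)
    for r in network.reactions:
        src = [nm for nm in r.reactants if nm in states]
        dst = [nm for nm in r.products if nm in states]
        if src and dst and src[0] != dst[0]:
            G.add_edge(src[0], dst[0])
    return [tuple(c) for c in nx.simple_cycles(G)]
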