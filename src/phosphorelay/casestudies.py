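"""Experimentally motivated phosphorelay case studies.

Two systems from the literature on hybrid-HK signalling:

* the yeast osmosensing relay, in which the hybrid HK Sln1 transfers
  phosphate to the Hpt protein Ypd1, which feeds two response regulators,
  Ssk1 (the HOG-pathway input, the output variable here) and Skn7;
* a two-HK quorum-sensing-like system modelled on Vibrio harveyi, where
  two hybrid HKs sensing different signals share one Hpt that feeds a
  single RR -- the topology that supports summation ("adder") and Boolean
  AND/OR responses.

Default parameter sets are reconstructed "biologically feasible" values:
they satisfy the bistability requirement k3 > k1 where relevant and
reproduce the qualitative behaviours (bistability with hysteresis for the
yeast relay; an adder for the V. harveyi-like system).  Each rate carries
a provenance flag so measured values can be substituted: phosphotransfer
steps of the yeast relay have been characterized in vitro, and are marked
``measured-in-cited-work``; everything else is ``assumed-feasible``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .networks import (
    ParameterSet,
    Reaction,
    ReactionNetwork,
    Species,
    build_shared_rr,
)

__all__ = ["CaseStudyModel", "build_yeast_osmosensing", "build_vharveyi_like"]


@dataclass(frozen=True)
class CaseStudyModel:
    network: ReactionNetwork
    default_params: ParameterSet
    provenance: dict  # rate label -> provenance note
    output_species: str
    ratio: float  # k3/k1 held fixed during input sweeps
    signal_labels: tuple = (("k1", "k3"),)
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        missing = [l for l in self.network.rate_labels if l not in self.provenance]
        if missing:
            raise ValueError(f"rates without provenance note: {missing}")


# ---------------------------------------------------------------------------
# Yeast osmosensing: Sln1 -> Ypd -> {Ssk1, Skn7}
# ---------------------------------------------------------------------------

#: Default rates for the yeast model.  The Sln1 block realizes a
#: non-monotone Ypd-phosphorylation flux (k3 >> k1); reverse transfers and
#: aspartate hydrolyses are present at feasible magnitudes.  Totals use the
#: same arbitrary units as the published bifurcation sweeps (Ypd total
#: 1..3, Skn7 total 0.5..2.5), so those sweeps are runnable verbatim.
YEAST_RATES = {
    "k1": 0.07,        # Sln1 autophosphorylation, REC site empty (signal)
    "k2": 3.1,         # intramolecular His -> REC transfer
    "k3": 2.47,        # autophosphorylation, REC site occupied (signal)
    "k4": 1.31,        # Sln1-REC~P + Ypd -> Sln1 + Ypd~P
    "k5": 20.3,        # Sln1-PP + Ypd -> Sln1-PO + Ypd~P
    "k10": 0.01,       # reverse transfer Ypd~P + Sln1-OO -> Ypd + Sln1-OP
    "k11": 0.01,       # reverse transfer Ypd~P + Sln1-PO -> Ypd + Sln1-PP
    "k12": 0.001,      # Sln1 REC-site hydrolysis (OP -> OO)
    "k13": 0.001,      # Sln1 REC-site hydrolysis (PP -> PO)
    "kf_ssk1": 1.0,    # Ypd~P + Ssk1 -> Ypd + Ssk1~P
    "kr_ssk1": 0.05,   # reverse transfer Ssk1~P + Ypd -> Ssk1 + Ypd~P
    "khy_ssk1": 0.05,  # Ssk1~P hydrolysis
    "kf_skn7": 1.0,    # Ypd~P + Skn7 -> Ypd + Skn7~P
    "kr_skn7": 0.05,   # reverse transfer Skn7~P + Ypd -> Skn7 + Ypd~P
    "khy_skn7": 0.05,  # Skn7~P hydrolysis
}

YEAST_TOTALS = {"Sln1": 0.16, "Ypd": 1.0, "Ssk1": 0.5, "Skn7": 0.5}

_MEASURED = "measured-in-cited-work (in vitro phosphotransfer kinetics)"
_ASSUMED = "assumed-feasible (reconstructed; no published value available)"

YEAST_PROVENANCE = {
    "k1": _ASSUMED, "k2": _ASSUMED, "k3": _ASSUMED,
    "k4": _MEASURED, "k5": _MEASURED,
    "k10": _MEASURED, "k11": _MEASURED,
    "k12": _ASSUMED, "k13": _ASSUMED,
    "kf_ssk1": _MEASURED, "kr_ssk1": _MEASURED, "khy_ssk1": _ASSUMED,
    "kf_skn7": _MEASURED, "kr_skn7": _MEASURED, "khy_skn7": _ASSUMED,
}


def build_yeast_osmosensing(include_ssk1_reverse: bool = True) -> CaseStudyModel:
    """Sln1 (hybrid HK, 4 states) -> Ypd (Hpt) -> Ssk1 and Skn7 (RRs).

    The full hybrid scheme: forward and reverse phosphotransfer at every
    protein-protein step, hydrolysis on the aspartate-phosphorylated
    species (Sln1 REC site, Ssk1~P, Skn7~P).  Output is the phosphorylated
    fraction of Ssk1.  ``include_ssk1_reverse=False`` disables the
    Ssk1 -> Ypd back-transfer.
    """
    species = [
        Species(f"Sln1_{p}", "hk_state", "Sln1", tuple(p))
        for p in ("OO", "PO", "OP", "PP")
    ] + [
        Species("Ypd", "hpt", "Ypd"),
        Species("Ypd_P", "hpt_p", "Ypd"),
        Species("Ssk1", "rr", "Ssk1"),
        Species("Ssk1_P", "rr_p", "Ssk1"),
        Species("Skn7", "rr", "Skn7"),
        Species("Skn7_P", "rr_p", "Skn7"),
    ]
    reactions = [
        Reaction(("Sln1_OO",), ("Sln1_PO",), "k1"),
        Reaction(("Sln1_PO",), ("Sln1_OP",), "k2"),
        Reaction(("Sln1_OP",), ("Sln1_PP",), "k3"),
        Reaction(("Sln1_OP", "Ypd"), ("Sln1_OO", "Ypd_P"), "k4"),
        Reaction(("Sln1_PP", "Ypd"), ("Sln1_PO", "Ypd_P"), "k5"),
        Reaction(("Ypd_P", "Sln1_OO"), ("Ypd", "Sln1_OP"), "k10"),
        Reaction(("Ypd_P", "Sln1_PO"), ("Ypd", "Sln1_PP"), "k11"),
        Reaction(("Sln1_OP",), ("Sln1_OO",), "k12"),
        Reaction(("Sln1_PP",), ("Sln1_PO",), "k13"),
        Reaction(("Ypd_P", "Ssk1"), ("Ypd", "Ssk1_P"), "kf_ssk1"),
        Reaction(("Ssk1_P",), ("Ssk1",), "khy_ssk1"),
        Reaction(("Ypd_P", "Skn7"), ("Ypd", "Skn7_P"), "kf_skn7"),
        Reaction(("Skn7_P", "Ypd"), ("Skn7", "Ypd_P"), "kr_skn7"),
        Reaction(("Skn7_P",), ("Skn7",), "khy_skn7"),
    ]
    rates = dict(YEAST_RATES)
    provenance = dict(YEAST_PROVENANCE)
    if include_ssk1_reverse:
        reactions.append(Reaction(("Ssk1_P", "Ypd"), ("Ssk1", "Ypd_P"), "kr_ssk1"))
    else:
        rates.pop("kr_ssk1")
        provenance.pop("kr_ssk1")
    network = ReactionNetwork(
        tuple(species), tuple(reactions), "yeast_osmo",
        meta={"include_ssk1_reverse": include_ssk1_reverse},
    )
    return CaseStudyModel(
        network=network,
        default_params=ParameterSet(rates, dict(YEAST_TOTALS)),
        provenance=provenance,
        output_species="Ssk1_P",
        ratio=rates["k3"] / rates["k1"],
    )


# ---------------------------------------------------------------------------
# V. harveyi-like: two hybrid HKs -> shared Hpt -> one RR
# ---------------------------------------------------------------------------

#: Adder-witness defaults for the two-HK shared-Hpt system, symmetric in
#: the two HKs.  Signal i sets k{i}_1 (with k{i}_3 at the fixed ratio);
#: in the default monostable regime the RR output tracks the summed
#: phosphate flux of the two HKs.
VHARVEYI_RATES = {
    "k1_1": 0.02, "k1_2": 3.1, "k1_3": 0.7, "k1_4": 1.31, "k1_5": 20.3,
    "k2_1": 0.02, "k2_2": 3.1, "k2_3": 0.7, "k2_4": 1.31, "k2_5": 20.3,
    "k6_m1": 0.5,     # shared Hpt~P hydrolysis
    "kt_1": 2.0,     # Hpt~P + RR -> Hpt + RR~P
    "khy_rr": 0.5,   # RR~P hydrolysis
}

VHARVEYI_TOTALS = {"HK1": 0.5, "HK2": 0.5, "Hpt1": 1.0, "RR": 1.0}

VHARVEYI_PROVENANCE = {l: _ASSUMED for l in VHARVEYI_RATES}


def build_vharveyi_like() -> CaseStudyModel:
    """Two independently signalled hybrid HKs sharing one Hpt and one RR.

    The same topology as one module of the shared-RR family with two HKs;
    default parameters implement an adder (output a monotone function of
    the summed signals).  The three-HK variant of the natural quorum
    sensing system is ``build_shared_rr([3])`` with analogous parameters.
    """
    network = build_shared_rr([2])
    return CaseStudyModel(
        network=network,
        default_params=ParameterSet(dict(VHARVEYI_RATES), dict(VHARVEYI_TOTALS)),
        provenance=dict(VHARVEYI_PROVENANCE),
        output_species="RR_P",
        ratio=VHARVEYI_RATES["k1_3"] / VHARVEYI_RATES["k1_1"],
        signal_labels=(("k1_1", "k1_3"), ("k2_1", "k2_3")),
    )
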