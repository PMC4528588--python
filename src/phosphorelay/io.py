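"""Declarative configuration files and model export.

A network plus parameter set round-trips through a YAML document::

    architecture:
      tag: shared_hpt        # which builder to use
      n: 2                   # builder arguments (tag-specific)
    rates:   {k1_1: 0.07, ...}
    totals:  {HK1: 0.16, Hpt: 1.0}

Unknown keys are rejected (fail-fast).  Networks can also be exported to
SBML Level 3 with explicit mass-action kinetic laws, for use in external
simulators; the exporter requires the optional python-libsbml dependency.
"""

from __future__ import annotations

import yaml

from . import casestudies, networks
from .networks import ParameterSet, ReactionNetwork

__all__ = [
    "network_to_config",
    "network_from_config",
    "save_config",
    "load_config",
    "export_sbml",
]

_BUILDER_FLAGS = {
    "core_hybrid": (),
    "full_hybrid": (
        "include_rr",
        "include_reverse_transfer",
        "include_rec_hydrolysis",
        "include_rr_hydrolysis",
    ),
    "regular_relay": (),
    "unorthodox": ("include_reverse_transfer", "include_rr_hydrolysis"),
    "shared_hpt": ("n",),
    "shared_rr": ("module_sizes",),
    "yeast_osmo": ("include_ssk1_reverse",),
    "vharveyi": (),
}


def _build(tag: str, args: dict) -> ReactionNetwork:
    if tag == "core_hybrid":
        return networks.build_core_hybrid()
    if tag == "full_hybrid":
        return networks.build_full_hybrid(**args)
    if tag == "regular_relay":
        return networks.build_regular_relay()
    if tag == "unorthodox":
        return networks.build_unorthodox(**args)
    if tag == "shared_hpt":
        return networks.build_shared_hpt(args["n"])
    if tag == "shared_rr":
        return networks.build_shared_rr(args["module_sizes"])
    if tag == "yeast_osmo":
        return casestudies.build_yeast_osmosensing(**args).network
    if tag == "vharveyi":
        return casestudies.build_vharveyi_like().network
    raise ValueError(f"unknown architecture tag {tag!r}")


def _config_tag(network: ReactionNetwork):
    tag = network.architecture_tag
    if tag == "hybrid_core":
        return "core_hybrid", {}
    if tag == "hybrid_full":
        return "full_hybrid", dict(network.meta)
    if tag == "regular_relay":
        return "regular_relay", {}
    if tag == "unorthodox_full":
        return "unorthodox", dict(network.meta)
    if tag.startswith("shared_hpt("):
        return "shared_hpt", {"n": network.meta["n"]}
    if tag.startswith("shared_rr("):
        return "shared_rr", {"module_sizes": network.meta["module_sizes"]}
    if tag == "yeast_osmo":
        return "yeast_osmo", dict(network.meta)
    raise ValueError(f"cannot serialize architecture {tag!r}")


def network_to_config(network: ReactionNetwork, params: ParameterSet) -> dict:
    tag, args = _config_tag(network)
    return {
        "architecture": {"tag": tag, **args},
        "rates": {k: float(v) for k, v in params.rates.items()},
        "totals": {k: float(v) for k, v in params.totals.items()},
    }


def network_from_config(cfg: dict):
    """(network, params) from a config mapping; unknown keys rejected."""
    extra = set(cfg) - {"architecture", "rates", "totals"}
    if extra:
        raise ValueError(f"unknown config keys: {sorted(extra)}")
    arch = dict(cfg["architecture"])
    tag = arch.pop("tag")
    allowed = _BUILDER_FLAGS.get(tag)
    if allowed is None:
        raise ValueError(f"unknown architecture tag {tag!r}")
    bad = set(arch) - set(allowed)
    if bad:
        raise ValueError(f"unknown architecture options for {tag}: {sorted(bad)}")
    network = _build(tag, arch)
    params = ParameterSet(dict(cfg["rates"]), dict(cfg["totals"]))
    params.validate_for(network)
    return network, params


def save_config(path, network: ReactionNetwork, params: ParameterSet) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(network_to_config(network, params), fh, sort_keys=True)


def load_config(path):
    with open(path) as fh:
        return network_from_config(yaml.safe_load(fh))


# ---------------------------------------------------------------------------
# SBML export
# ---------------------------------------------------------------------------

def export_sbml(network: ReactionNetwork, params: ParameterSet, path: str) -> None:
    """Write the network as an SBML Level 3 model with mass-action kinetics.

    Initial amounts place every protein in its unphosphorylated form at the
    total concentration.  Requires python-libsbml.
    """
    try:
        import libsbml
    except ImportError as e:  # pragma: no cover - optional dependency
        raise ImportError(
            "SBML export requires the optional python-libsbml package"
        ) from e

    params.validate_for(network)
    doc = libsbml.SBMLDocument(3, 2)
    model = doc.createModel()
    model.setId(network.architecture_tag.replace("(", "_").replace(")", "").replace(",", "_"))
    comp = model.createCompartment()
    comp.setId("cell")
    comp.setConstant(True)
    comp.setSize(1.0)
    comp.setSpatialDimensions(3)

    x0 = params.unphosphorylated_state(network)
    sanitize = lambda n: n.replace("(", "_").replace(")", "")
    for i, s in enumerate(network.species):
        sp = model.createSpecies()
        sp.setId(sanitize(s.name))
        sp.setCompartment("cell")
        sp.setInitialConcentration(float(x0[i]))
        sp.setHasOnlySubstanceUnits(False)
        sp.setBoundaryCondition(False)
        sp.setConstant(False)
    for label in network.rate_labels:
        par = model.createParameter()
        par.setId(label)
        par.setValue(float(params.rates[label]))
        par.setConstant(True)
    for j, r in enumerate(network.reactions):
        rx = model.createReaction()
        rx.setId(f"R{j+1}_{r.rate_label}")
        rx.setReversible(False)
        for nm in r.reactants:
            ref = rx.createReactant()
            ref.setSpecies(sanitize(nm))
            ref.setStoichiometry(1.0)
            ref.setConstant(True)
        for nm in r.products:
            ref = rx.createProduct()
            ref.setSpecies(sanitize(nm))
            ref.setStoichiometry(1.0)
            ref.setConstant(True)
        law = rx.createKineticLaw()
        formula = " * ".join([r.rate_label] + [sanitize(nm) for nm in r.reactants])
        law.setMath(libsbml.parseL3Formula(formula))
    if doc.getNumErrors(libsbml.LIBSBML_SEV_ERROR):
        raise RuntimeError(doc.getErrorLog().toString())
    libsbml.writeSBMLToFile(doc, str(path))
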