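"""Serialization, SBML export and reporting.

The network schema is a versioned YAML/JSON document::

    schema_version: 1
    name: zf
    species:
      - {name: Z1, q_plus: 1, q_minus: 0, q_zero: 0, q_inactive: 0,
         roles: [activator], initial: 0.0}
    reactions:
      - {rtype: splicing, reactants: {Z1: 1, Z2: 1}, products: {Z3: 1},
         rates: {eta: 100.0}}
    mu: [10.0, 0.0, 0.0]
    theta: [0.0, 1.0, 0.0]
    actuation: {form: hill_competitive, activators: {Z1: 1.0},
                repressors: {Z3: 1.0}, k_plus: 50.0, k_minus: 0.0,
                K_act: 1.0, K_rep: 1.0, hill_n: 1.0}
    delta: 0.0
    delta0: 0.1
    regulated: {L: 1, k: [], gamma: [1.0], input_gain: 1.0}

Round-tripping is stable: ``load(save(x)) == x`` field by field.  The SBML
export emits an SBML Level 3 core document with one irreversible reaction
per mass-action channel (reversible binding/conversion split into a
forward/backward pair) and the Hill-type actuation as a kinetic law built
from the symbolic rate expression.
"""

from __future__ import annotations

import json
import logging
import xml.etree.ElementTree as ET
from pathlib import Path

import numpy as np
import yaml

from .crn_model import (
    ActuationSpec,
    ControllerNetwork,
    InteinSpecies,
    RegulatedNetwork,
    TypedReaction,
    classify_species,
)

__all__ = ["SchemaError", "SCHEMA_VERSION", "load_network", "save_network", "network_to_dict", "export_sbml", "report"]

log = logging.getLogger("inteinctrl")

SCHEMA_VERSION = 1


class SchemaError(ValueError):
    """A network document violates the schema; the message lists offending keys."""


def network_to_dict(network: ControllerNetwork, regulated: RegulatedNetwork | None = None) -> dict:
    act = network.actuation
    if act.form == "custom_monotone":
        raise SchemaError("actuation: custom_monotone callables cannot be serialized")
    if network.sensing_fns is not None:
        raise SchemaError("sensing_fns: nonlinear sensing callables cannot be serialized")
    doc = {
        "schema_version": SCHEMA_VERSION,
        "name": network.name,
        "species": [
            {
                "name": sp.name,
                "q_plus": int(sp.q_plus),
                "q_minus": int(sp.q_minus),
                "q_zero": int(sp.q_zero),
                "q_inactive": int(sp.q_inactive),
                "roles": sorted(sp.roles),
                "initial": float(sp.initial_amount),
            }
            for sp in network.species
        ],
        "reactions": [
            {
                "rtype": r.rtype,
                "reactants": {k: int(v) for k, v in r.reactants.items()},
                "products": {k: int(v) for k, v in r.products.items()},
                "rates": {k: float(v) for k, v in r.rate_params.items()},
            }
            for r in network.reactions
        ],
        "mu": [float(v) for v in network.mu],
        "theta": [float(v) for v in network.theta],
        "actuation": {
            "form": act.form,
            "activators": {k: float(v) for k, v in act.activators.items()},
            "repressors": {k: float(v) for k, v in act.repressors.items()},
            "k_plus": float(act.k_plus),
            "k_minus": float(act.k_minus),
            "K_act": float(act.K_act),
            "K_rep": float(act.K_rep),
            "hill_n": float(act.hill_n),
        },
        "delta": float(network.delta),
        "delta0": float(network.delta0),
    }
    if regulated is not None:
        doc["regulated"] = {
            "L": int(regulated.L),
            "k": [float(v) for v in regulated.k],
            "gamma": [float(v) for v in regulated.gamma],
            "input_gain": float(regulated.input_gain),
        }
    return doc


def save_network(network: ControllerNetwork, path, regulated: RegulatedNetwork | None = None) -> None:
    path = Path(path)
    doc = network_to_dict(network, regulated)
    if path.suffix in (".yaml", ".yml"):
        path.write_text(yaml.safe_dump(doc, sort_keys=False))
    elif path.suffix == ".json":
        path.write_text(json.dumps(doc, indent=2))
    else:
        raise SchemaError(f"unsupported extension {path.suffix!r}; use .yaml/.yml/.json")


def _dict_to_network(doc: dict):
    errors = []
    if doc.get("schema_version") != SCHEMA_VERSION:
        errors.append(f"schema_version: expected {SCHEMA_VERSION}, got {doc.get('schema_version')!r}")
    for key in ("species", "mu", "theta", "actuation"):
        if key not in doc:
            errors.append(f"{key}: missing")
    if errors:
        raise SchemaError("; ".join(errors))
    try:
        species = [
            InteinSpecies(
                name=s["name"],
                q_plus=int(s.get("q_plus", 0)),
                q_minus=int(s.get("q_minus", 0)),
                q_zero=int(s.get("q_zero", 0)),
                q_inactive=int(s.get("q_inactive", 0)),
                roles=frozenset(s.get("roles", ["inert"])),
                initial_amount=float(s.get("initial", 0.0)),
            )
            for s in doc["species"]
        ]
        reactions = [
            TypedReaction(
                rtype=r["rtype"],
                reactants={k: int(v) for k, v in r.get("reactants", {}).items()},
                products={k: int(v) for k, v in r.get("products", {}).items()},
                rate_params={k: float(v) for k, v in r.get("rates", {}).items()},
            )
            for r in doc.get("reactions", [])
        ]
        a = doc["actuation"]
        act = ActuationSpec(
            form=a.get("form", "hill_activation"),
            activators={k: float(v) for k, v in a.get("activators", {}).items()},
            repressors={k: float(v) for k, v in a.get("repressors", {}).items()},
            k_plus=float(a.get("k_plus", 0.0)),
            k_minus=float(a.get("k_minus", 0.0)),
            K_act=float(a.get("K_act", 1.0)),
            K_rep=float(a.get("K_rep", 1.0)),
            hill_n=float(a.get("hill_n", 1.0)),
        )
        network = ControllerNetwork(
            species=species,
            reactions=reactions,
            mu=doc["mu"],
            theta=doc["theta"],
            actuation=act,
            delta=float(doc.get("delta", 0.0)),
            delta0=float(doc.get("delta0", 0.0)),
            name=doc.get("name", "controller"),
        )
    except (ValueError, KeyError, TypeError) as exc:
        raise SchemaError(str(exc)) from exc
    regulated = None
    if "regulated" in doc:
        r = doc["regulated"]
        try:
            regulated = RegulatedNetwork(
                L=int(r.get("L", 1)),
                k=r.get("k", ()),
                gamma=r.get("gamma", 1.0),
                input_gain=float(r.get("input_gain", 1.0)),
            )
        except ValueError as exc:
            raise SchemaError(f"regulated: {exc}") from exc
    return network, regulated


def load_network(path):
    """Load (ControllerNetwork, RegulatedNetwork | None) from a YAML/JSON document."""
    path = Path(path)
    text = path.read_text()
    doc = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
    if not isinstance(doc, dict):
        raise SchemaError("document must be a mapping")
    net, reg = _dict_to_network(doc)
    log.info("loaded %s (schema_version=%s, M=%d)", path, SCHEMA_VERSION, net.M)
    return net, reg


# ---------------------------------------------------------------------------
# SBML Level 3 export
# ---------------------------------------------------------------------------

SBML_NS = "http://www.sbml.org/sbml/level3/version2/core"
MATHML_NS = "http://www.w3.org/1998/Math/MathML"


def _mathml_node(expr) -> ET.Element:
    """Content-MathML node for a sympy arithmetic expression."""
    import sympy

    q = f"{{{MATHML_NS}}}"
    if isinstance(expr, sympy.Symbol):
        el = ET.Element(q + "ci")
        el.text = expr.name
        return el
    if isinstance(expr, (sympy.Float, sympy.Integer, sympy.Rational)) or expr.is_Number:
        el = ET.Element(q + "cn")
        el.text = repr(float(expr))
        return el
    op = {"Add": "plus", "Mul": "times", "Pow": "power"}.get(expr.func.__name__)
    if op is None:
        raise ValueError(f"cannot encode {expr!r} as content MathML")
    apply_el = ET.Element(q + "apply")
    ET.SubElement(apply_el, q + op)
    for arg in expr.args:
        apply_el.append(_mathml_node(arg))
    return apply_el


def _mathml(expr) -> ET.Element:
    """Content-MathML <math> element for a sympy expression."""
    import sympy

    math = ET.Element(f"{{{MATHML_NS}}}math")
    math.append(_mathml_node(sympy.sympify(expr)))
    return math


def export_sbml(network: ControllerNetwork, regulated: RegulatedNetwork, path) -> None:
    """Write the assembled closed-loop mass-action model as SBML Level 3.

    Reversible binding/conversion channels are split into irreversible
    forward/backward reactions; the actuation of X1 is a production reaction
    whose kinetic law carries the (Hill-type) control action expression.
    """
    import sympy

    ET.register_namespace("", SBML_NS)
    sbml = ET.Element(f"{{{SBML_NS}}}sbml", {"level": "3", "version": "2"})
    model = ET.SubElement(sbml, f"{{{SBML_NS}}}model", {"id": network.name or "model"})
    lc = ET.SubElement(model, f"{{{SBML_NS}}}listOfCompartments")
    ET.SubElement(lc, f"{{{SBML_NS}}}compartment", {"id": "cell", "constant": "true", "size": "1"})

    ls = ET.SubElement(model, f"{{{SBML_NS}}}listOfSpecies")
    plant_names = [f"X{i+1}" for i in range(regulated.L)]
    all_names = network.species_names + plant_names
    init = {**{sp.name: sp.initial_amount for sp in network.species},
            **dict(zip(plant_names, regulated.initial_state()))}
    for nm in all_names:
        ET.SubElement(
            ls, f"{{{SBML_NS}}}species",
            {"id": nm, "compartment": "cell", "initialConcentration": repr(float(init[nm])),
             "hasOnlySubstanceUnits": "false", "boundaryCondition": "false", "constant": "false"},
        )

    lr = ET.SubElement(model, f"{{{SBML_NS}}}listOfReactions")
    syms = {nm: sympy.Symbol(nm, nonnegative=True) for nm in all_names}
    rid = iter(range(1, 10000))

    def add_reaction(reactants: dict, products: dict, rate_expr):
        r = ET.SubElement(lr, f"{{{SBML_NS}}}reaction",
                          {"id": f"r{next(rid)}", "reversible": "false"})
        if reactants:
            lre = ET.SubElement(r, f"{{{SBML_NS}}}listOfReactants")
            for nm, m in reactants.items():
                ET.SubElement(lre, f"{{{SBML_NS}}}speciesReference",
                              {"species": nm, "stoichiometry": str(m), "constant": "true"})
        if products:
            lp = ET.SubElement(r, f"{{{SBML_NS}}}listOfProducts")
            for nm, m in products.items():
                ET.SubElement(lp, f"{{{SBML_NS}}}speciesReference",
                              {"species": nm, "stoichiometry": str(m), "constant": "true"})
        kl = ET.SubElement(r, f"{{{SBML_NS}}}kineticLaw")
        kl.append(_mathml(rate_expr))

    x_L = syms[plant_names[-1]]
    # setpoint / sensing productions
    for i, sp in enumerate(network.species):
        if network.mu[i] > 0:
            add_reaction({}, {sp.name: 1}, sympy.Float(network.mu[i]))
        if network.theta[i] > 0:
            add_reaction({}, {sp.name: 1}, sympy.Float(network.theta[i]) * x_L)
    # typed reactions
    from .crn_model import InteinClass, splicing_rate_multiplier

    for rxn in network.reactions:
        if rxn.rtype in ("binding", "conversion"):
            fwd = sympy.Float(rxn.rate_params["kf"])
            for nm, m in rxn.reactants.items():
                fwd *= syms[nm] ** m
            add_reaction(rxn.reactants, rxn.products, fwd)
            bwd = sympy.Float(rxn.rate_params["kr"])
            for nm, m in rxn.products.items():
                bwd *= syms[nm] ** m
            add_reaction(rxn.products, rxn.reactants, bwd)
        elif rxn.rtype == "splicing":
            classes = {sp.name: classify_species(sp) for sp in network.species}
            cs = [nm for nm in rxn.reactants if classes[nm] is InteinClass.C][0]
            ns = [nm for nm in rxn.reactants if classes[nm] is InteinClass.N][0]
            mult = rxn.rate_params.get(
                "multiplier",
                splicing_rate_multiplier(network.species_by_name(cs), network.species_by_name(ns)),
            )
            add_reaction(rxn.reactants, rxn.products,
                         sympy.Float(rxn.rate_params["eta"] * mult) * syms[cs] * syms[ns])
        elif rxn.rtype == "degradation":
            expr = sympy.Float(rxn.rate_params.get("rate", 0.0))
            for nm, m in rxn.reactants.items():
                expr *= syms[nm] ** m
            add_reaction(rxn.reactants, {}, expr)
    # dilution / degradation
    for i, sp in enumerate(network.species):
        rate = network.delta + (network.delta0 if classify_species(sp) is InteinClass.S else 0.0)
        if rate > 0:
            add_reaction({sp.name: 1}, {}, sympy.Float(rate) * syms[sp.name])
    # actuation: production of X1 with the (Hill-type) control action
    act = network.actuation
    if act.form == "custom_monotone":
        raise SchemaError("custom_monotone actuation cannot be exported to SBML")
    A = sum(sympy.Float(w) * syms[nm] for nm, w in act.activators.items()) / sympy.Float(act.K_act)
    R = (sum(sympy.Float(w) * syms[nm] for nm, w in act.repressors.items()) / sympy.Float(act.K_rep)
         if act.repressors else sympy.Integer(0))
    n = sympy.Float(act.hill_n)
    if act.form == "linear":
        h_plus = sympy.Float(act.k_plus) * A * sympy.Float(act.K_act)
        h_minus = sympy.Float(act.k_minus) * R * sympy.Float(act.K_rep)
    elif act.form == "hill_activation":
        h_plus = sympy.Float(act.k_plus) * A**n / (1 + A**n) / (1 + R**n)
        h_minus = sympy.Float(act.k_minus) * R**n / (1 + R**n)
    else:
        h_plus = sympy.Float(act.k_plus) * A**n / (1 + A**n + R**n)
        h_minus = sympy.Float(act.k_minus) * R**n / (1 + A**n + R**n)
    if act.k_plus > 0 or act.form == "linear":
        add_reaction({}, {"X1": 1}, sympy.Float(regulated.input_gain) * h_plus)
    if act.k_minus > 0:
        add_reaction({"X1": 1}, {}, sympy.Float(regulated.input_gain) * h_minus * syms["X1"])
    # plant chain
    for i in range(regulated.L - 1):
        rate = regulated.rate_factors[i] * regulated.k[i]
        add_reaction({plant_names[i]: 1}, {plant_names[i + 1]: 1}, sympy.Float(rate) * syms[plant_names[i]])
    for i in range(regulated.L):
        add_reaction({plant_names[i]: 1}, {}, sympy.Float(regulated.gamma[i]) * syms[plant_names[i]])

    tree = ET.ElementTree(sbml)
    ET.indent(tree)
    tree.write(path, xml_declaration=True, encoding="unicode")
    log.info("wrote SBML to %s", path)


# ---------------------------------------------------------------------------
# Reporting
# ---------------------------------------------------------------------------


def report(results) -> tuple[str, dict]:
    """Human-readable summary and its machine twin for screening/simulation outputs.

    Accepts a RuleReport, a ChargeReport, a SimulationResult, a sweep
    DataFrame, a dict of any of these, or a list; every number printed in
    the text appears in the returned dict.
    """
    from .crn_model import RuleReport
    from .rpa_screen import ChargeReport
    from .simulate import SimulationResult
    import pandas as pd

    lines: list[str] = []
    payload: dict = {}

    def emit(obj, prefix=""):
        if isinstance(obj, RuleReport):
            d = {"mode": obj.mode, "rules": dict(obj.results),
                 "violations": list(obj.violations),
                 "theorem1_eligible": obj.theorem1_eligible,
                 "theorem2_eligible": obj.theorem2_eligible}
            payload[prefix + "rule_report"] = d
            lines.append(f"Rule check ({obj.mode}):")
            for rule, ok in sorted(obj.results.items()):
                lines.append(f"  {rule:5s} {'pass' if ok else 'FAIL'}")
            for v in obj.violations:
                lines.append(f"  ! {v}")
        elif isinstance(obj, ChargeReport):
            d = obj.as_dict()
            payload[prefix + "charge_report"] = d
            lines.append("Charge report:")
            lines.append(f"  q        = {d['q']}")
            lines.append(f"  mu_eff   = {d['mu_eff']:g}")
            lines.append(f"  theta_eff= {d['theta_eff']:g}")
            sp = d["setpoint"]
            lines.append(f"  setpoint = {sp:g}" if sp is not None else "  setpoint = (implicit)")
            lines.append(f"  eligible = {d['eligible']} (conditional on closed-loop stability)")
            for v in d["diagnostics"]:
                lines.append(f"  ! {v}")
        elif isinstance(obj, SimulationResult):
            d = {"converged": obj.converged,
                 "steady_state": obj.steady_state,
                 "steady_state_refined": obj.steady_state_refined,
                 "final_x_L": obj.final_x_L,
                 "t_end": float(obj.time[-1]),
                 "metadata": dict(obj.metadata)}
            payload[prefix + "simulation"] = d
            lines.append(f"Simulation ({obj.metadata.get('model', '?')} model):")
            lines.append(f"  t_end      = {d['t_end']:g}")
            lines.append(f"  converged  = {d['converged']}")
            if obj.steady_state is not None:
                lines.append(f"  x_L steady = {obj.steady_state:.6g}")
            if obj.steady_state_refined is not None:
                lines.append(f"  x_L refined= {obj.steady_state_refined:.6g}")
        elif isinstance(obj, pd.DataFrame):
            payload[prefix + "sweep"] = {
                "rows": obj.to_dict(orient="records"),
                "disturbance_error": obj.attrs.get("disturbance_error"),
            }
            lines.append("Setpoint sweep:")
            lines.append(obj.to_string(index=False))
            if "disturbance_error" in obj.attrs:
                lines.append(f"  averaged disturbance error = {obj.attrs['disturbance_error']:.4%}")
        elif isinstance(obj, dict):
            for k, v in obj.items():
                emit(v, prefix=f"{k}.")
        elif isinstance(obj, (list, tuple)):
            for i, v in enumerate(obj):
                emit(v, prefix=f"{prefix}{i}.")
        elif obj is None:
            pass
        else:
            payload[prefix + "value"] = obj
            lines.append(f"{prefix}{obj}")

    emit(results)
    return "\n".join(lines), payload
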