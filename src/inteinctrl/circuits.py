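"""Built-in controller circuits, default plants, and a random network factory.

The preset library covers the canonical intein-based integral feedback
designs realizable with common transcription factors:

* ``aif`` -- the basic two-species antithetic motif (production at mu,
  output-driven sensing at theta*x_L, annihilating sequestration).
* ``zf`` -- zinc-finger TF with the Int^C in the AD-DBD linker; splicing
  cleaves off the AD and the leftover DBD competes for the promoter
  (filtered PI behaviour).
* ``intradd`` -- TetR-based TF with the Int^C inside the dimerization
  domain; only the homodimer actuates and all spliced products are inert
  (standalone integrator).
* ``tetr`` -- TetR-based TF with the Int^C between DBD-DD and AD; partially
  spliced dimers still activate while the fully spliced dimer represses
  (PI whose proportional gain switches sign).
* ``gal4`` -- Gal4-based TF with the Int^C between DBD and DD; spliced
  monomers sequester the intact TF but no spliced species touches the
  promoter.
* ``inactive_intein`` -- competing-sequestration design: a mutationally
  inactive Int^N reversibly binds the Int^C-AD without splicing it, forming
  heterodimeric activators; only the free pair actually splices.
* ``box3`` -- an abstract six-species charge network (no intein reading of
  the charges) with three heterodimerizations, exercising the generalized
  charge path.

Default kinetic parameters are not dictated by the circuit structure; the
values below give stable closed loops with clear separation between binding
(fast) and production/dilution (slow) timescales.  Concentrations are in
arbitrary units and time in hours.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .crn_model import (
    ActuationSpec,
    ControllerNetwork,
    InteinSpecies,
    RegulatedNetwork,
    TypedReaction,
)

__all__ = ["CircuitPreset", "PRESET_IDS", "build_preset", "build_regulated", "build_box3", "random_network"]

PRESET_IDS = ("aif", "zf", "intradd", "tetr", "gal4", "inactive_intein", "box3")

#: shared kinetic defaults (h^-1 and a.u.); overridable per preset
DEFAULTS = dict(
    mu1=10.0,      # constitutive setpoint-encoding production
    theta2=1.0,    # output-proportional sensing production
    eta=100.0,     # splicing rate
    a=100.0,       # association rate of reversible binding
    d=10.0,        # dissociation rate
    k_act=50.0,    # maximal actuation rate
    K=1.0,         # actuation dissociation constant
    hill_n=1.0,
    delta=0.0,     # dilution
    delta0=0.1,    # S-class degradation (turnover of spliced products)
)


@dataclass
class CircuitPreset:
    """A named controller network with its default parameters and description."""

    id: str
    network: ControllerNetwork
    default_params: dict = field(default_factory=dict)
    notes: str = ""


#: per-preset deviations from DEFAULTS.  The competing-sequestration design
#: runs without S-class degradation: its dead-Int^N pool species are S-class,
#: so a nonzero delta0 would drain the actuator capacity, while its only
#: accumulating splice product (Z3) is inert and decouples from the loop.
PRESET_DEFAULTS = {"inactive_intein": {"delta0": 0.0}}


def _params(overrides: dict, preset_id: str | None = None) -> dict:
    p = dict(DEFAULTS)
    p.update(PRESET_DEFAULTS.get(preset_id, {}))
    unknown = set(overrides) - set(p) - {"mu4", "pool"}
    if unknown:
        raise TypeError(f"unknown parameters {sorted(unknown)}")
    p.update(overrides)
    return p


def _splice(reactants, products, eta):
    return TypedReaction("splicing", dict(reactants), dict(products), {"eta": eta})


def _bind(reactants, products, a, d):
    return TypedReaction("binding", dict(reactants), dict(products), {"kf": a, "kr": d})


def _build_aif(p):
    species = [
        InteinSpecies("Z1", q_plus=1, roles=frozenset({"activator"})),
        InteinSpecies("Z2", q_minus=1),
    ]
    reactions = [_splice({"Z1": 1, "Z2": 1}, {}, p["eta"])]
    act = ActuationSpec(form="linear", activators={"Z1": 1.0}, k_plus=1.0)
    return ControllerNetwork(
        species, reactions,
        mu=[p["mu1"], 0.0], theta=[0.0, p["theta2"]],
        actuation=act, delta=p["delta"], delta0=p["delta0"], name="aif",
    )


def _build_zf(p):
    species = [
        InteinSpecies("Z1", q_plus=1, roles=frozenset({"activator"})),
        InteinSpecies("Z2", q_minus=1),
        InteinSpecies("Z3", q_zero=1, roles=frozenset({"repressor"})),
    ]
    reactions = [_splice({"Z1": 1, "Z2": 1}, {"Z3": 1}, p["eta"])]
    act = ActuationSpec(
        form="hill_competitive", activators={"Z1": 1.0}, repressors={"Z3": 1.0},
        k_plus=p["k_act"], K_act=p["K"], K_rep=p["K"], hill_n=p["hill_n"],
    )
    return ControllerNetwork(
        species, reactions,
        mu=[p["mu1"], 0.0, 0.0], theta=[0.0, p["theta2"], 0.0],
        actuation=act, delta=p["delta"], delta0=p["delta0"], name="zf",
    )


def _build_intradd(p):
    species = [
        InteinSpecies("Z1", q_plus=1),
        InteinSpecies("Z2", q_minus=1),
        InteinSpecies("Z3", q_zero=1),
        InteinSpecies("Z4", q_plus=2, roles=frozenset({"activator"})),
    ]
    reactions = [
        _bind({"Z1": 2}, {"Z4": 1}, p["a"], p["d"]),
        _splice({"Z1": 1, "Z2": 1}, {"Z3": 1}, p["eta"]),
        _splice({"Z4": 1, "Z2": 1}, {"Z1": 1, "Z3": 1}, p["eta"]),
    ]
    act = ActuationSpec(
        form="hill_activation", activators={"Z4": 1.0},
        k_plus=p["k_act"], K_act=p["K"], hill_n=p["hill_n"],
    )
    return ControllerNetwork(
        species, reactions,
        mu=[p["mu1"], 0.0, 0.0, 0.0], theta=[0.0, p["theta2"], 0.0, 0.0],
        actuation=act, delta=p["delta"], delta0=p["delta0"], name="intradd",
    )


def _tf_dimer_species(z4_roles, z6_roles):
    return [
        InteinSpecies("Z1", q_plus=1),
        InteinSpecies("Z2", q_minus=1),
        InteinSpecies("Z3", q_zero=1),
        InteinSpecies("Z4", q_zero=2, roles=z4_roles),
        InteinSpecies("Z5", q_plus=2, roles=frozenset({"activator"})),
        InteinSpecies("Z6", q_plus=1, q_zero=1, roles=z6_roles),
    ]


def _tf_dimer_reactions(p):
    return [
        _bind({"Z1": 2}, {"Z5": 1}, p["a"], p["d"]),
        _bind({"Z1": 1, "Z3": 1}, {"Z6": 1}, p["a"], p["d"]),
        _bind({"Z3": 2}, {"Z4": 1}, p["a"], p["d"]),
        _splice({"Z1": 1, "Z2": 1}, {"Z3": 1}, p["eta"]),
        _splice({"Z5": 1, "Z2": 1}, {"Z6": 1}, p["eta"]),
        _splice({"Z6": 1, "Z2": 1}, {"Z4": 1}, p["eta"]),
    ]


def _build_tetr(p):
    # the half-spliced dimer Z6 keeps one AD and still activates; the fully
    # spliced dimer Z4 binds the operator without activating -> repressor
    species = _tf_dimer_species(frozenset({"repressor"}), frozenset({"activator"}))
    act = ActuationSpec(
        form="hill_competitive",
        activators={"Z5": 2.0, "Z6": 1.0}, repressors={"Z4": 1.0},
        k_plus=p["k_act"], K_act=p["K"], K_rep=p["K"], hill_n=p["hill_n"],
    )
    return ControllerNetwork(
        species, _tf_dimer_reactions(p),
        mu=[p["mu1"], 0, 0, 0, 0, 0], theta=[0, p["theta2"], 0, 0, 0, 0],
        actuation=act, delta=p["delta"], delta0=p["delta0"], name="tetr",
    )


def _build_gal4(p):
    # spliced species lose the DBD: Z4 and Z6 cannot touch the promoter, but
    # Z3 sequesters intact Z1 through the Z6 heterodimerization
    species = _tf_dimer_species(frozenset({"inert"}), frozenset({"inert"}))
    act = ActuationSpec(
        form="hill_activation", activators={"Z5": 1.0},
        k_plus=p["k_act"], K_act=p["K"], hill_n=p["hill_n"],
    )
    return ControllerNetwork(
        species, _tf_dimer_reactions(p),
        mu=[p["mu1"], 0, 0, 0, 0, 0], theta=[0, p["theta2"], 0, 0, 0, 0],
        actuation=act, delta=p["delta"], delta0=p["delta0"], name="gal4",
    )


def _build_inactive_intein(p):
    """Competing-sequestration controller with a mutationally dead Int^N.

    Z4 (TetR fused to an inactive Int^N) binds Z1 (Int^C-AD) reversibly
    without splicing it; Z1 bound into Z6/Z7/Z8 keeps its active Int^C but
    cannot react with Z2, so only free Z1 splices.  The dead segments add a
    conserved direction (q*) used by the generalized four-state reduction.
    In the ideal dilution-free setting the dead-Int^N pool has no sink, so
    it is supplied as an initial endowment ``pool`` (the delta->0 limit of
    constitutive expression mu4/delta); ``mu4`` > 0 is meaningful when
    delta > 0.
    """
    mu4 = float(p.get("mu4", 0.0))
    pool = float(p.get("pool", 5.0))
    species = [
        InteinSpecies("Z1", q_plus=1),
        InteinSpecies("Z2", q_minus=1),
        InteinSpecies("Z3", q_zero=1),
        InteinSpecies("Z4", q_zero=1, q_inactive=1, initial_amount=pool),
        InteinSpecies("Z5", q_zero=2, q_inactive=2, roles=frozenset({"repressor"})),
        InteinSpecies("Z6", q_plus=1, q_zero=1, q_inactive=1, roles=frozenset({"activator"})),
        InteinSpecies("Z7", q_plus=2, q_zero=2, q_inactive=2, roles=frozenset({"activator"})),
        InteinSpecies("Z8", q_plus=1, q_zero=2, q_inactive=2, roles=frozenset({"activator"})),
    ]
    reactions = [
        _bind({"Z1": 1, "Z4": 1}, {"Z6": 1}, p["a"], p["d"]),
        _bind({"Z4": 2}, {"Z5": 1}, p["a"], p["d"]),
        _bind({"Z1": 1, "Z5": 1}, {"Z8": 1}, p["a"], p["d"]),
        _bind({"Z1": 1, "Z8": 1}, {"Z7": 1}, p["a"], p["d"]),
        _splice({"Z1": 1, "Z2": 1}, {"Z3": 1}, p["eta"]),
    ]
    act = ActuationSpec(
        form="hill_competitive",
        activators={"Z6": 1.0, "Z7": 2.0, "Z8": 1.0}, repressors={"Z5": 1.0},
        k_plus=p["k_act"], K_act=p["K"], K_rep=p["K"], hill_n=p["hill_n"],
    )
    return ControllerNetwork(
        species, reactions,
        mu=[p["mu1"], 0, 0, mu4, 0, 0, 0, 0], theta=[0, p["theta2"], 0, 0, 0, 0, 0, 0],
        actuation=act, delta=p["delta"], delta0=p["delta0"], name="inactive_intein",
    )


def _build_box3(p):
    """Abstract six-species charge network: three heterodimerizations, no conversions."""
    species = [
        InteinSpecies("Z1", q_plus=1, roles=frozenset({"activator"})),
        InteinSpecies("Z2", q_minus=1),
        InteinSpecies("Z3", q_zero=1),
        InteinSpecies("Z4", q_plus=1, q_zero=1),
        InteinSpecies("Z5", q_minus=1, q_zero=1),
        InteinSpecies("Z6", q_zero=2),
    ]
    reactions = [
        _bind({"Z1": 1, "Z3": 1}, {"Z4": 1}, p["a"], p["d"]),
        _bind({"Z2": 1, "Z3": 1}, {"Z5": 1}, p["a"], p["d"]),
        _bind({"Z3": 2}, {"Z6": 1}, p["a"], p["d"]),
        _splice({"Z1": 1, "Z2": 1}, {"Z3": 1}, p["eta"]),
        _splice({"Z1": 1, "Z5": 1}, {"Z3": 2}, p["eta"]),
        _splice({"Z4": 1, "Z2": 1}, {"Z3": 2}, p["eta"]),
        _splice({"Z4": 1, "Z5": 1}, {"Z3": 3}, p["eta"]),
    ]
    act = ActuationSpec(
        form="hill_activation", activators={"Z1": 1.0},
        k_plus=p["k_act"], K_act=p["K"], hill_n=p["hill_n"],
    )
    return ControllerNetwork(
        species, reactions,
        mu=[p["mu1"], 0, 0, 0, 0, 0], theta=[0, p["theta2"], 0, 0, 0, 0],
        actuation=act, delta=p["delta"], delta0=p["delta0"], name="box3",
    )


_BUILDERS = {
    "aif": _build_aif,
    "zf": _build_zf,
    "intradd": _build_intradd,
    "tetr": _build_tetr,
    "gal4": _build_gal4,
    "inactive_intein": _build_inactive_intein,
    "box3": _build_box3,
}

_NOTES = {
    "aif": "basic two-species antithetic motif with annihilating sequestration",
    "zf": "zinc-finger TF, intein in the AD-DBD linker; spliced DBD competes for the promoter",
    "intradd": "intein inside the TetR dimerization domain; spliced products inert",
    "tetr": "intein between TetR and AD; half-spliced dimer activates, fully spliced dimer represses",
    "gal4": "intein between Gal4 DBD and DD; spliced monomer sequesters the intact TF",
    "inactive_intein": "competing sequestration by a mutationally inactive Int^N fused to TetR",
    "box3": "abstract six-species charge network, three heterodimerizations",
}


def build_preset(preset_id: str, **overrides) -> CircuitPreset:
    """Build a named controller circuit with optional parameter overrides.

    Overridable keys: the entries of :data:`DEFAULTS` plus, for
    ``inactive_intein``, ``mu4`` (constitutive dead-Int^N expression) and
    ``pool`` (its initial endowment).
    """
    if preset_id not in _BUILDERS:
        raise KeyError(f"unknown preset {preset_id!r}; choose from {PRESET_IDS}")
    p = _params(overrides, preset_id)
    network = _BUILDERS[preset_id](p)
    return CircuitPreset(id=preset_id, network=network, default_params=p, notes=_NOTES[preset_id])


def build_box3(**overrides) -> ControllerNetwork:
    """The abstract generalized-charge example network."""
    return build_preset("box3", **overrides).network


def build_regulated(L: int = 1, gamma=1.0, k=None, input_gain: float = 1.0) -> RegulatedNetwork:
    """Linear production/conversion chain X1 -> ... -> XL with dilution.

    ``L = 1`` mirrors the experimental plant: the actuated output transcript
    itself is the regulated species.  ``k`` defaults to unit conversion
    rates for L > 1.
    """
    if L < 1:
        raise ValueError("L must be >= 1")
    if k is None:
        k = (1.0,) * (L - 1)
    return RegulatedNetwork(L=L, k=k, gamma=gamma, input_gain=input_gain)


def random_network(
    seed: int,
    M: int = 4,
    n_binding: int | None = None,
    n_conversion: int = 0,
    reducible: bool = True,
) -> ControllerNetwork:
    """Seeded factory of rule-compliant random controller networks.

    Starts from the core triplet Z1 (one active Int^C, setpoint production),
    Z2 (one active Int^N, sensing production), Z3 (neutral spliced product)
    and grows complexes by reversible binding and neutral isomers by
    reversible conversion; every C-class species is given a splicing channel
    with Z2 whose products dissociate into Z1/Z3 monomers, so the emitted
    network is screening-eligible and, with ``reducible=True``, satisfies
    the structural reduction conditions by construction
    (M = 3 + n_binding + n_conversion).
    """
    if M < 2:
        raise ValueError("M must be >= 2")
    rng = np.random.default_rng(seed)
    if n_binding is None:
        n_binding = max(M - 3 - n_conversion, 0)
    if 3 + n_binding + n_conversion != M and reducible:
        raise ValueError("reducible construction requires M = 3 + n_binding + n_conversion")

    eta = rng.uniform(20, 200)
    a = rng.uniform(20, 200)
    d = rng.uniform(10, 50)
    mu1 = rng.uniform(2, 20)
    theta2 = rng.uniform(1, 2)
    # maximal actuation a small multiple of the setpoint demand: the loop
    # then operates deep in actuator saturation, keeping the proportional
    # gain low enough for stable closure on slow 1-2 stage plants; brisk
    # S-class turnover keeps degradation-protected complex pools (which fill
    # at the rate mu1 and stall the transient) small
    k_act = (mu1 / theta2) * rng.uniform(1.3, 2.0)
    delta0 = rng.uniform(0.5, 2.0)

    species = [
        InteinSpecies("Z1", q_plus=1),
        InteinSpecies("Z2", q_minus=1),
        InteinSpecies("Z3", q_zero=1),
    ]
    comp = {"Z1": (1, 0), "Z3": (0, 1)}  # Z1-monomer / neutral-monomer content
    reactions = [_splice({"Z1": 1, "Z2": 1}, {"Z3": 1}, eta)]

    # complexes are dimers of the two monomeric species only: stacking
    # complexes onto complexes creates degradation-protected pools with
    # equilibrium sizes growing geometrically in the binding affinity,
    # which stalls the closed-loop transient for hundreds of hours
    bindable = ["Z1", "Z3"]
    for b in range(n_binding):
        i = rng.integers(len(bindable))
        j = rng.integers(len(bindable))
        na, nb = bindable[i], bindable[j]
        new = f"B{b + 1}"
        c = tuple(np.add(comp[na], comp[nb]))
        species.append(InteinSpecies(new, q_plus=int(c[0]), q_zero=int(c[1])))
        comp[new] = c
        reactants = {na: 2} if na == nb else {na: 1, nb: 1}
        reactions.append(_bind(reactants, {new: 1}, a * rng.uniform(0.5, 2), d * rng.uniform(0.5, 2)))
        n1, n3 = c
        if n1 >= 1:
            prods = {}
            if n1 - 1 > 0:
                prods["Z1"] = n1 - 1
            prods["Z3"] = n3 + 1
            if reducible or rng.random() < 0.7:
                reactions.append(_splice({new: 1, "Z2": 1}, prods, eta))

    for c_i in range(n_conversion):
        new = f"C{c_i + 1}"
        species.append(InteinSpecies(new, q_zero=1))
        reactions.append(
            TypedReaction("conversion", {"Z3": 1}, {new: 1},
                          {"kf": rng.uniform(10, 100), "kr": rng.uniform(10, 100)})
        )

    # actuate through a C-class species that accumulates from Z1 alone
    # (complexes containing spliced monomers would deadlock at zero output:
    # their formation needs splicing, which needs sensing, which needs output)
    candidates = [nm for nm, (n1, n3) in comp.items() if n1 >= 1 and n3 == 0]
    actor = candidates[rng.integers(len(candidates))]
    species = [
        InteinSpecies(sp.name, sp.q_plus, sp.q_minus, sp.q_zero, sp.q_inactive,
                      roles=frozenset({"activator"}) if sp.name == actor else sp.roles,
                      initial_amount=sp.initial_amount)
        for sp in species
    ]
    act = ActuationSpec(form="hill_activation", activators={actor: 1.0}, k_plus=k_act, K_act=1.0)
    mu = np.zeros(len(species))
    theta = np.zeros(len(species))
    mu[0], theta[1] = mu1, theta2
    return ControllerNetwork(
        species, reactions, mu=mu, theta=theta, actuation=act,
        delta=0.0, delta0=delta0, name=f"random-{seed}",
    )
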