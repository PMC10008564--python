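"""Data model for intein-annotated controller reaction networks.

A controller network is a set of protein species annotated with counts of
active split-intein segments (Int^C / Int^N) and of constituent monomers
carrying no active segment.  Species fall into three classes:

* C-class -- at least one active Int^C segment,
* N-class -- at least one active Int^N segment,
* S-class -- no active segments at all.

Reactions are typed (binding, conversion, intein splicing, actuation,
degradation, dilution) and the rule engine in :func:`validate_rules` checks a
network against the structural rules that guarantee robust perfect adaptation
(screening mode ``theorem1``) and, more strictly, eligibility for the
three-effective-species model reduction (mode ``theorem2``).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from enum import Enum
from typing import Callable, Mapping, Sequence

import numpy as np

__all__ = [
    "InteinClass",
    "InteinSpecies",
    "TypedReaction",
    "ActuationSpec",
    "ControllerNetwork",
    "RegulatedNetwork",
    "RuleReport",
    "ODESystem",
    "classify_species",
    "splicing_rate_multiplier",
    "validate_rules",
    "build_ode_rhs",
    "reaction_stoichiometry",
]

ROLES = frozenset({"activator", "repressor", "inert"})

RTYPES = frozenset(
    {
        "setpoint_production",
        "sensing_production",
        "binding",
        "conversion",
        "splicing",
        "actuation_positive",
        "actuation_negative",
        "degradation",
        "dilution",
    }
)

#: reversible channel types (Rule 10): carry forward ``kf`` and backward ``kr``
REVERSIBLE_RTYPES = frozenset({"binding", "conversion"})


class InteinClass(str, Enum):
    """Species class: carries active Int^C (C), active Int^N (N), or neither (S)."""

    C = "C"
    N = "N"
    S = "S"


@dataclass(frozen=True)
class InteinSpecies:
    """A controller species with its intein-segment bookkeeping.

    Parameters
    ----------
    name:
        Unique identifier.
    q_plus, q_minus:
        Number of *active* Int^C / Int^N segments carried by the species.
    q_zero:
        Number of constituent monomers carrying no active intein segment.
    q_inactive:
        Number of *inactive* (e.g. mutationally dead) Int^N segments.  Zero
        for ordinary designs; nonzero entries create an extra conservation
        law exploited by the generalized four-state reduction.
    roles:
        Functional tags in {"activator", "repressor", "inert"} describing
        promoter action.
    initial_amount:
        Initial concentration (deterministic) or copy number (stochastic).
    """

    name: str
    q_plus: int = 0
    q_minus: int = 0
    q_zero: int = 0
    q_inactive: int = 0
    roles: frozenset = frozenset({"inert"})
    initial_amount: float = 0.0

    def __post_init__(self):
        for attr in ("q_plus", "q_minus", "q_zero", "q_inactive"):
            v = getattr(self, attr)
            if not isinstance(v, (int, np.integer)) or v < 0:
                raise ValueError(f"{self.name}: {attr} must be a nonnegative integer, got {v!r}")
        if self.q_plus > 0 and self.q_minus > 0:
            raise ValueError(
                f"{self.name}: species carrying both active Int^C and Int^N "
                "segments would self-splice and are not supported"
            )
        if self.q_plus + self.q_minus + self.q_zero < 1:
            raise ValueError(f"{self.name}: species must contain at least one monomer")
        object.__setattr__(self, "roles", frozenset(self.roles))
        if not self.roles <= ROLES:
            raise ValueError(f"{self.name}: unknown roles {set(self.roles) - ROLES}")

    @property
    def intein_class(self) -> InteinClass:
        return classify_species(self)


def classify_species(species: InteinSpecies) -> InteinClass:
    """Assign the C/N/S class of a species from its active-segment counts."""
    if species.q_plus > 0:
        return InteinClass.C
    if species.q_minus > 0:
        return InteinClass.N
    return InteinClass.S


def splicing_rate_multiplier(zi: InteinSpecies, zj: InteinSpecies) -> int:
    """Integer factor of the splicing propensity between a C- and an N-class species.

    The splicing reaction between ``zi`` (C-class) and ``zj`` (N-class) has
    propensity ``eta * max(q_i^+, q_j^-) * z_i * z_j``.
    """
    if classify_species(zi) is not InteinClass.C:
        raise ValueError(f"{zi.name} is not C-class")
    if classify_species(zj) is not InteinClass.N:
        raise ValueError(f"{zj.name} is not N-class")
    return max(zi.q_plus, zj.q_minus)


@dataclass
class TypedReaction:
    """A reaction labeled with one of the permitted channel types.

    ``reactants`` and ``products`` map species names to stoichiometric
    multiplicities.  ``rate_params`` holds the named rates: ``kf``/``kr`` for
    reversible binding/conversion, ``eta`` (and optionally an explicit
    ``multiplier``) for splicing, ``rate`` for the remaining channels.
    """

    rtype: str
    reactants: dict = field(default_factory=dict)
    products: dict = field(default_factory=dict)
    rate_params: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.rtype not in RTYPES:
            raise ValueError(f"unknown reaction type {self.rtype!r}")
        for bag in (self.reactants, self.products):
            for name, mult in bag.items():
                if not isinstance(mult, (int, np.integer)) or mult < 1:
                    raise ValueError(f"stoichiometric multiplicity of {name} must be a positive integer")
        for k, v in self.rate_params.items():
            if isinstance(v, (int, float)) and v < 0:
                raise ValueError(f"rate parameter {k} must be nonnegative")

    @property
    def reversible(self) -> bool:
        return self.rtype in REVERSIBLE_RTYPES

    def copy(self) -> "TypedReaction":
        return TypedReaction(
            rtype=self.rtype,
            reactants=dict(self.reactants),
            products=dict(self.products),
            rate_params=dict(self.rate_params),
        )


@dataclass
class ActuationSpec:
    """Specification of the control action u = h+(z, x_L) - h-(z, x_L) * x1.

    ``activators`` / ``repressors`` map species names to positive weights
    (e.g. the number of activation domains a complex carries).  Supported
    forms:

    * ``linear`` -- h+ = k_plus * A, h- = k_minus * R;
    * ``hill_activation`` -- h+ = k_plus * A^n / (1 + A^n), optionally
      multiplied by the repression factor 1 / (1 + R^n);
    * ``hill_competitive`` -- activators and repressors compete for the same
      promoter sites: h+ = k_plus * A^n / (1 + A^n + R^n);
    * ``custom_monotone`` -- user-supplied callables ``h_plus_fn(conc, x_L)``
      and ``h_minus_fn(conc, x_L)`` over a name->concentration mapping.

    Here A = sum_i w_i z_i / K_act over activators and R likewise over
    repressors, so h+ is nondecreasing in every activator concentration and
    nonincreasing in every repressor concentration by construction.
    """

    form: str = "hill_activation"
    activators: dict = field(default_factory=dict)
    repressors: dict = field(default_factory=dict)
    k_plus: float = 0.0
    k_minus: float = 0.0
    K_act: float = 1.0
    K_rep: float = 1.0
    hill_n: float = 1.0
    h_plus_fn: Callable | None = None
    h_minus_fn: Callable | None = None

    _FORMS = ("linear", "hill_activation", "hill_competitive", "custom_monotone")

    def __post_init__(self):
        if self.form not in self._FORMS:
            raise ValueError(f"unknown actuation form {self.form!r}")
        if min([self.k_plus, self.k_minus, 0.0]) < 0:
            raise ValueError("actuation rates must be nonnegative")
        for bag in (self.activators, self.repressors):
            for name, w in bag.items():
                if w <= 0:
                    raise ValueError(f"actuation weight of {name} must be positive")
        if self.form == "custom_monotone" and self.h_plus_fn is None and self.h_minus_fn is None:
            raise ValueError("custom_monotone requires h_plus_fn and/or h_minus_fn")

    def _sums(self, conc: Mapping[str, float]) -> tuple[float, float]:
        a = sum(w * max(conc[nm], 0.0) for nm, w in self.activators.items())
        r = sum(w * max(conc[nm], 0.0) for nm, w in self.repressors.items())
        return a / self.K_act, r / self.K_rep

    def h_plus(self, conc: Mapping[str, float], x_L: float = 0.0) -> float:
        if self.form == "custom_monotone":
            return float(self.h_plus_fn(conc, x_L)) if self.h_plus_fn else 0.0
        a, r = self._sums(conc)
        n = self.hill_n
        if self.form == "linear":
            return self.k_plus * a * self.K_act
        if self.form == "hill_activation":
            return self.k_plus * a**n / (1.0 + a**n) / (1.0 + r**n)
        # hill_competitive
        return self.k_plus * a**n / (1.0 + a**n + r**n)

    def h_minus(self, conc: Mapping[str, float], x_L: float = 0.0) -> float:
        if self.form == "custom_monotone":
            return float(self.h_minus_fn(conc, x_L)) if self.h_minus_fn else 0.0
        if self.k_minus == 0.0:
            return 0.0
        a, r = self._sums(conc)
        n = self.hill_n
        if self.form == "linear":
            return self.k_minus * r * self.K_rep
        if self.form == "hill_activation":
            return self.k_minus * r**n / (1.0 + r**n)
        return self.k_minus * r**n / (1.0 + a**n + r**n)

    def u(self, conc: Mapping[str, float], x_L: float, x1: float) -> float:
        return self.h_plus(conc, x_L) - self.h_minus(conc, x_L) * x1


@dataclass
class ControllerNetwork:
    """Controller species, typed reactions, setpoint/sensing vectors and actuation.

    ``mu`` and ``theta`` are the length-M vectors of constitutive and
    output-proportional production rates (the setpoint/sensing reactions
    `0 --mu_i + theta_i x_L--> Z_i`).  ``delta`` is the uniform dilution rate
    applied to every species; ``delta0`` the degradation rate applied
    structurally to S-class species only.  ``sensing_fns`` optionally
    replaces the linear terms ``theta_i * x_L`` by monotone functions
    ``f_i(x_L)`` (nonlinear sensing).
    """

    species: list
    reactions: list
    mu: np.ndarray
    theta: np.ndarray
    actuation: ActuationSpec
    delta: float = 0.0
    delta0: float = 0.0
    sensing_fns: list | None = None
    name: str = "controller"

    def __post_init__(self):
        self.mu = np.asarray(self.mu, dtype=float)
        self.theta = np.asarray(self.theta, dtype=float)
        names = [sp.name for sp in self.species]
        if len(set(names)) != len(names):
            raise ValueError("species names must be unique")
        if self.mu.shape != (self.M,) or self.theta.shape != (self.M,):
            raise ValueError("mu and theta must have one entry per species")
        if np.any(self.mu < 0) or np.any(self.theta < 0):
            raise ValueError("mu and theta must be nonnegative")
        if self.delta < 0 or self.delta0 < 0:
            raise ValueError("delta and delta0 must be nonnegative")
        known = set(names)
        for rxn in self.reactions:
            for nm in list(rxn.reactants) + list(rxn.products):
                if nm not in known:
                    raise ValueError(f"reaction references undeclared species {nm!r}")
        for nm in list(self.actuation.activators) + list(self.actuation.repressors):
            if nm not in known:
                raise ValueError(f"actuation references undeclared species {nm!r}")

    @property
    def M(self) -> int:
        return len(self.species)

    @property
    def species_names(self) -> list:
        return [sp.name for sp in self.species]

    @property
    def species_index(self) -> dict:
        return {sp.name: i for i, sp in enumerate(self.species)}

    def species_by_name(self, name: str) -> InteinSpecies:
        return self.species[self.species_index[name]]

    def classes(self) -> list:
        return [classify_species(sp) for sp in self.species]

    def s_class_mask(self) -> np.ndarray:
        return np.array([c is InteinClass.S for c in self.classes()])

    def initial_state(self) -> np.ndarray:
        return np.array([sp.initial_amount for sp in self.species], dtype=float)

    def with_params(self, **kw) -> "ControllerNetwork":
        """Copy with selected scalar fields (delta, delta0, mu, theta, ...) replaced."""
        new = ControllerNetwork(
            species=list(self.species),
            reactions=[r.copy() for r in self.reactions],
            mu=kw.pop("mu", self.mu.copy()),
            theta=kw.pop("theta", self.theta.copy()),
            actuation=kw.pop(
                "actuation",
                replace(
                    self.actuation,
                    activators=dict(self.actuation.activators),
                    repressors=dict(self.actuation.repressors),
                ),
            ),
            delta=kw.pop("delta", self.delta),
            delta0=kw.pop("delta0", self.delta0),
            sensing_fns=kw.pop("sensing_fns", self.sensing_fns),
            name=kw.pop("name", self.name),
        )
        if kw:
            raise TypeError(f"unknown fields {sorted(kw)}")
        return new

    def scale_reaction_rates(self, factor: float, rtypes=("binding", "conversion")) -> "ControllerNetwork":
        """Copy with kf/kr of the selected (fast) channels multiplied by ``factor``."""
        new = self.with_params()
        for rxn in new.reactions:
            if rxn.rtype in rtypes:
                for k in ("kf", "kr"):
                    if k in rxn.rate_params:
                        rxn.rate_params[k] *= factor
        return new


@dataclass
class RegulatedNetwork:
    """A linear chain X1 -> X2 -> ... -> XL regulated by the controller.

    The controller actuates X1 (production u = h+ - h- x1) and senses XL.
    ``k`` are the stage conversion rates (length L-1), ``gamma`` the
    first-order removal rate per stage (scalar or length L).  ``input_gain``
    multiplies the actuation as a plant-gain disturbance hook (the in-silico
    analogue of transfecting more copies of the output plasmid), and
    ``rate_factors`` multiplicatively perturb individual stage conversions.
    """

    L: int = 1
    k: Sequence = ()
    gamma: Sequence | float = 1.0
    input_gain: float = 1.0
    rate_factors: Sequence | None = None
    initial: Sequence | None = None

    def __post_init__(self):
        if self.L < 1:
            raise ValueError("L must be >= 1")
        self.k = tuple(float(v) for v in self.k)
        if len(self.k) != self.L - 1:
            raise ValueError("need L-1 stage conversion rates")
        if np.isscalar(self.gamma):
            self.gamma = (float(self.gamma),) * self.L
        else:
            self.gamma = tuple(float(v) for v in self.gamma)
        if len(self.gamma) != self.L:
            raise ValueError("need L removal rates")
        if any(v < 0 for v in self.k) or any(v < 0 for v in self.gamma):
            raise ValueError("plant rates must be nonnegative")
        if self.input_gain <= 0:
            raise ValueError("input_gain must be positive")
        if self.rate_factors is None:
            self.rate_factors = (1.0,) * max(self.L - 1, 0)
        self.rate_factors = tuple(float(v) for v in self.rate_factors)

    def with_gain(self, factor: float) -> "RegulatedNetwork":
        return RegulatedNetwork(
            L=self.L, k=self.k, gamma=self.gamma,
            input_gain=self.input_gain * factor,
            rate_factors=self.rate_factors, initial=self.initial,
        )

    def with_rate_factor(self, stage: int, factor: float) -> "RegulatedNetwork":
        rf = list(self.rate_factors)
        rf[stage] *= factor
        return RegulatedNetwork(
            L=self.L, k=self.k, gamma=self.gamma, input_gain=self.input_gain,
            rate_factors=rf, initial=self.initial,
        )

    def initial_state(self) -> np.ndarray:
        if self.initial is None:
            return np.zeros(self.L)
        return np.asarray(self.initial, dtype=float)

    def rhs(self, x: np.ndarray, u: float) -> np.ndarray:
        dx = np.zeros(self.L)
        dx[0] += self.input_gain * u
        for i in range(self.L - 1):
            flux = self.rate_factors[i] * self.k[i] * x[i]
            dx[i] -= flux
            dx[i + 1] += flux
        dx -= np.asarray(self.gamma) * x
        return dx

    def dc_gain(self) -> float:
        """Open-loop steady-state output per unit constant input u."""
        inflow = self.input_gain
        for i in range(self.L - 1):
            ki = self.rate_factors[i] * self.k[i]
            xi = inflow / (ki + self.gamma[i])
            inflow = ki * xi
        return inflow / self.gamma[-1]


# Rule identifiers.  SR1-3 and RR2-8 are reconstructed class/structure checks;
# RR1 and RR9-13 follow the stated setpoint/sensing and reduction rules.
THEOREM1_RULES = ("SR1", "SR2", "SR3", "RR1", "RR2", "RR3", "RR4", "RR5", "RR6", "RR7")
THEOREM2_RULES = THEOREM1_RULES + ("RR9", "RR10", "RR11", "RR12", "RR13")


@dataclass
class RuleReport:
    """Per-rule pass/fail record with offending species/reactions."""

    results: dict
    violations: list
    mode: str

    @property
    def theorem1_eligible(self) -> bool:
        return all(self.results.get(r, True) for r in THEOREM1_RULES)

    @property
    def theorem2_eligible(self) -> bool:
        return self.theorem1_eligible and all(self.results.get(r, True) for r in THEOREM2_RULES)

    @property
    def passed(self) -> bool:
        return self.theorem2_eligible if self.mode == "theorem2" else self.theorem1_eligible

    def failed_rules(self) -> list:
        return [r for r, ok in self.results.items() if not ok]


def reaction_stoichiometry(network: ControllerNetwork, rxn: TypedReaction) -> np.ndarray:
    """Net (products minus reactants) stoichiometry column over the species order."""
    idx = network.species_index
    col = np.zeros(network.M, dtype=int)
    for nm, m in rxn.reactants.items():
        col[idx[nm]] -= m
    for nm, m in rxn.products.items():
        col[idx[nm]] += m
    return col


def _charge_changes(network: ControllerNetwork, rxn: TypedReaction) -> dict:
    col = reaction_stoichiometry(network, rxn)
    qp = np.array([sp.q_plus for sp in network.species])
    qm = np.array([sp.q_minus for sp in network.species])
    q0 = np.array([sp.q_zero for sp in network.species])
    qi = np.array([sp.q_inactive for sp in network.species])
    return {
        "q_plus": int(qp @ col),
        "q_minus": int(qm @ col),
        "q_zero": int(q0 @ col),
        "q_inactive": int(qi @ col),
    }


def validate_rules(network: ControllerNetwork, mode: str = "theorem1") -> RuleReport:
    """Check a controller network against the structural species/reaction rules.

    ``mode='theorem1'`` checks the RPA-screening rules; ``mode='theorem2'``
    additionally checks the model-reduction rules (splicing completeness,
    reversibility and charge conservation of the fast channels, S-class-only
    degradation, uniform dilution, and the max-count splicing multiplier).
    Violations are reported, not raised.
    """
    if mode not in ("theorem1", "theorem2"):
        raise ValueError("mode must be 'theorem1' or 'theorem2'")
    results: dict = {}
    violations: list = []

    def flag(rule: str, ok: bool, msg: str = ""):
        results[rule] = results.get(rule, True) and ok
        if not ok:
            violations.append(f"{rule}: {msg}")

    # Species rules (construction already enforces these; re-checked so that
    # hand-built objects bypassing the constructor are still caught).
    for sp in network.species:
        flag("SR1", sp.q_plus + sp.q_minus + sp.q_zero >= 1, f"{sp.name} has no monomer")
        flag("SR2", not (sp.q_plus > 0 and sp.q_minus > 0), f"{sp.name} carries both active segment types")
        flag("SR3", sp.roles <= ROLES, f"{sp.name} has unknown roles")
    for r in ("SR1", "SR2", "SR3"):
        results.setdefault(r, True)

    # RR1: setpoint/sensing -- at least one mu_i and one theta_i strictly positive.
    has_sensing = bool(np.any(network.theta > 0)) or bool(
        network.sensing_fns is not None and any(f is not None for f in network.sensing_fns)
    )
    flag("RR1", bool(np.any(network.mu > 0)), "no strictly positive mu_i (no setpoint encoding)")
    flag("RR1", has_sensing, "no strictly positive theta_i (no output sensing)")

    classes = {sp.name: classify_species(sp) for sp in network.species}

    for rxn in network.reactions:
        if rxn.rtype == "splicing":
            names = []
            for nm, m in rxn.reactants.items():
                names.extend([nm] * m)
            ok_form = (
                len(names) == 2
                and classes[names[0]] is not classes[names[1]]
                and {classes[n] for n in names} == {InteinClass.C, InteinClass.N}
            )
            flag("RR2", ok_form, f"splicing {rxn.reactants} needs exactly one C- and one N-class reactant")
            if ok_form:
                ch = _charge_changes(network, rxn)
                flag(
                    "RR2",
                    ch["q_plus"] == -1 and ch["q_minus"] == -1,
                    f"splicing {rxn.reactants}->{rxn.products} must inactivate exactly one "
                    f"Int^C and one Int^N (got dq+={ch['q_plus']}, dq-={ch['q_minus']})",
                )
        elif rxn.rtype == "binding":
            n_react = sum(rxn.reactants.values())
            flag("RR3", n_react >= 2 and sum(rxn.products.values()) == 1,
                 f"binding {rxn.reactants}->{rxn.products} must associate >=2 molecules into one complex")
        elif rxn.rtype == "conversion":
            flag("RR4", sum(rxn.reactants.values()) == 1 and sum(rxn.products.values()) == 1,
                 f"conversion {rxn.reactants}->{rxn.products} must be unimolecular on both sides")
        elif rxn.rtype == "degradation":
            for nm in rxn.reactants:
                flag("RR11" if mode == "theorem2" else "RR7",
                     classes[nm] is InteinClass.S,
                     f"degradation of non-S-class species {nm}")
    for r in ("RR2", "RR3", "RR4"):
        results.setdefault(r, True)

    # RR5/RR6: actuation wiring -- species exist with consistent roles, rates >= 0.
    act = network.actuation
    for nm in act.activators:
        flag("RR5", "activator" in network.species_by_name(nm).roles,
             f"{nm} used as actuating activator but not tagged 'activator'")
    for nm in act.repressors:
        flag("RR5", "repressor" in network.species_by_name(nm).roles,
             f"{nm} used as actuating repressor but not tagged 'repressor'")
    results.setdefault("RR5", True)
    flag("RR6", act.k_plus >= 0 and act.k_minus >= 0, "actuation rates must be nonnegative")

    # RR7: controller couples to the plant only via actuation and sensing;
    # in this data model reactions are controller-internal by construction.
    results.setdefault("RR7", True)

    if mode == "theorem2":
        # RR9: every C-class species undergoes splicing with every N-class species.
        c_names = [nm for nm, c in classes.items() if c is InteinClass.C]
        n_names = [nm for nm, c in classes.items() if c is InteinClass.N]
        pairs = set()
        for rxn in network.reactions:
            if rxn.rtype == "splicing":
                cs = [nm for nm in rxn.reactants if classes[nm] is InteinClass.C]
                ns = [nm for nm in rxn.reactants if classes[nm] is InteinClass.N]
                if cs and ns:
                    pairs.add((cs[0], ns[0]))
        for cn in c_names:
            for nn in n_names:
                flag("RR9", (cn, nn) in pairs,
                     f"C-class {cn} has no splicing reaction with N-class {nn}")
        results.setdefault("RR9", True)

        # RR10: binding/conversion reversible and charge-conserving.
        for rxn in network.reactions:
            if rxn.rtype in REVERSIBLE_RTYPES:
                kf = rxn.rate_params.get("kf", 0.0)
                kr = rxn.rate_params.get("kr", 0.0)
                flag("RR10", kf > 0 and kr > 0,
                     f"{rxn.rtype} {rxn.reactants}->{rxn.products} must carry kf > 0 and kr > 0")
                ch = _charge_changes(network, rxn)
                flag("RR10", all(v == 0 for v in ch.values()),
                     f"{rxn.rtype} {rxn.reactants}->{rxn.products} does not conserve segment counts {ch}")
        results.setdefault("RR10", True)

        # RR11: only S-class degrades (structural delta0 is S-class-only by design;
        # explicit degradation reactions checked above).
        results.setdefault("RR11", True)
        # RR12: uniform dilution -- delta is a single network-level rate by design.
        results.setdefault("RR12", True)

        # RR13: splicing multiplier equals max(q_i^+, q_j^-).
        for rxn in network.reactions:
            if rxn.rtype == "splicing" and "multiplier" in rxn.rate_params:
                cs = [nm for nm in rxn.reactants if classes[nm] is InteinClass.C]
                ns = [nm for nm in rxn.reactants if classes[nm] is InteinClass.N]
                if cs and ns:
                    want = splicing_rate_multiplier(
                        network.species_by_name(cs[0]), network.species_by_name(ns[0])
                    )
                    flag("RR13", int(rxn.rate_params["multiplier"]) == want,
                         f"splicing {rxn.reactants}: multiplier {rxn.rate_params['multiplier']} != max rule {want}")
        results.setdefault("RR13", True)

    return RuleReport(results=results, violations=violations, mode=mode)


# ---------------------------------------------------------------------------
# Mass-action right-hand-side assembly
# ---------------------------------------------------------------------------


class ODESystem:
    """Compiled closed-loop vector field over the stacked state (z, x).

    The controller part assembles mass-action fluxes for all typed reactions,
    the setpoint/sensing production ``mu_i + theta_i x_L`` (or the nonlinear
    sensing functions), uniform dilution ``delta`` and S-class degradation
    ``delta0``.  The plant receives the actuation ``u = h+ - h- x1`` on X1.
    """

    def __init__(self, network: ControllerNetwork, regulated: RegulatedNetwork):
        self.network = network
        self.regulated = regulated
        self.M = network.M
        self.L = regulated.L
        self._idx = network.species_index
        self._names = network.species_names
        self._s_mask = network.s_class_mask().astype(float)
        self._compile()

    def _compile(self):
        cols = []
        props = []  # list of (kind, data) evaluated against z
        net = self.network
        for rxn in net.reactions:
            col = reaction_stoichiometry(net, rxn)
            if rxn.rtype in REVERSIBLE_RTYPES:
                kf = rxn.rate_params.get("kf", 0.0)
                kr = rxn.rate_params.get("kr", 0.0)
                r_idx = [(self._idx[nm], m) for nm, m in rxn.reactants.items()]
                p_idx = [(self._idx[nm], m) for nm, m in rxn.products.items()]
                props.append(("rev", (kf, r_idx, kr, p_idx)))
            elif rxn.rtype == "splicing":
                eta = rxn.rate_params.get("eta", 0.0)
                classes = {sp.name: classify_species(sp) for sp in net.species}
                cs = [nm for nm in rxn.reactants if classes[nm] is InteinClass.C]
                ns = [nm for nm in rxn.reactants if classes[nm] is InteinClass.N]
                mult = rxn.rate_params.get("multiplier")
                if mult is None:
                    mult = splicing_rate_multiplier(net.species_by_name(cs[0]), net.species_by_name(ns[0]))
                props.append(("mass", (eta * mult, [(self._idx[cs[0]], 1), (self._idx[ns[0]], 1)])))
            elif rxn.rtype in ("degradation", "dilution"):
                rate = rxn.rate_params.get("rate", 0.0)
                r_idx = [(self._idx[nm], m) for nm, m in rxn.reactants.items()]
                props.append(("mass", (rate, r_idx)))
            elif rxn.rtype in ("setpoint_production", "sensing_production"):
                # encoded through mu/theta; explicit reactions contribute the same way
                rate = rxn.rate_params.get("rate", 0.0)
                if rxn.rtype == "setpoint_production":
                    props.append(("const", rate))
                else:
                    props.append(("sense", rate))
            else:
                raise ValueError(f"reaction type {rxn.rtype!r} cannot be assembled into the ODE")
            cols.append(col)
        self._S = np.array(cols, dtype=float).T if cols else np.zeros((self.M, 0))
        self._props = props

    # -- propensities -------------------------------------------------------

    def reaction_fluxes(self, z: np.ndarray, x_L: float) -> np.ndarray:
        """Net deterministic flux of every typed reaction at state z."""
        zc = np.maximum(z, 0.0)
        out = np.empty(len(self._props))
        for i, (kind, data) in enumerate(self._props):
            if kind == "rev":
                kf, r_idx, kr, p_idx = data
                fwd = kf
                for j, m in r_idx:
                    fwd *= zc[j] ** m
                bwd = kr
                for j, m in p_idx:
                    bwd *= zc[j] ** m
                out[i] = fwd - bwd
            elif kind == "mass":
                rate, r_idx = data
                v = rate
                for j, m in r_idx:
                    v *= zc[j] ** m
                out[i] = v
            elif kind == "const":
                out[i] = data
            else:  # sense
                out[i] = data * x_L
        return out

    def conc(self, z: np.ndarray) -> dict:
        return {nm: z[i] for nm, i in self._idx.items()}

    def control_action(self, z: np.ndarray, x: np.ndarray) -> float:
        x_L = x[-1]
        return self.network.actuation.u(self.conc(z), x_L, x[0])

    def sensing_production(self, x_L: float) -> np.ndarray:
        net = self.network
        if net.sensing_fns is not None:
            out = np.zeros(self.M)
            for i, f in enumerate(net.sensing_fns):
                if f is not None:
                    out[i] = f(x_L)
            return out
        return net.theta * x_L

    def controller_rhs(self, z: np.ndarray, x_L: float) -> np.ndarray:
        net = self.network
        dz = net.mu + self.sensing_production(x_L)
        fluxes = self.reaction_fluxes(z, x_L)
        if self._S.shape[1]:
            dz = dz + self._S @ fluxes
        dz -= net.delta * z
        dz -= net.delta0 * self._s_mask * np.maximum(z, 0.0)
        return dz

    def rhs(self, t: float, y: np.ndarray) -> np.ndarray:
        z = y[: self.M]
        x = y[self.M :]
        u = self.control_action(z, x)
        dz = self.controller_rhs(z, x[-1])
        dx = self.regulated.rhs(x, u)
        return np.concatenate([dz, dx])

    def initial_state(self) -> np.ndarray:
        return np.concatenate([self.network.initial_state(), self.regulated.initial_state()])


def build_ode_rhs(network: ControllerNetwork, regulated: RegulatedNetwork) -> ODESystem:
    """Assemble the closed-loop mass-action vector field over (z, x).

    Returns an :class:`ODESystem` whose ``rhs(t, y)`` is suitable for
    ``scipy.integrate.solve_ivp``; the object also exposes the controller
    part, the reaction fluxes and the control action for reuse by the
    reduction and stochastic simulation layers.
    """
    return ODESystem(network, regulated)
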