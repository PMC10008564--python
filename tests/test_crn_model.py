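"""Unit tests for the species/reaction data model and the rule engine."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from inteinctrl import (
    ActuationSpec,
    ControllerNetwork,
    InteinClass,
    InteinSpecies,
    RegulatedNetwork,
    TypedReaction,
    build_ode_rhs,
    build_preset,
    build_regulated,
    classify_species,
    random_network,
    splicing_rate_multiplier,
    validate_rules,
)
from inteinctrl.crn_model import reaction_stoichiometry


@pytest.mark.parametrize(
    "qp,qm,q0,expected",
    [
        (1, 0, 0, InteinClass.C),
        (0, 1, 0, InteinClass.N),
        (0, 0, 1, InteinClass.S),
        (2, 0, 2, InteinClass.C),
        (0, 3, 1, InteinClass.N),
    ],
)
def test_classify_species(qp, qm, q0, expected):
    sp = InteinSpecies("Z", q_plus=qp, q_minus=qm, q_zero=q0)
    assert classify_species(sp) is expected


def test_species_with_both_active_segments_rejected():
    with pytest.raises(ValueError, match="self-splice"):
        InteinSpecies("Z", q_plus=1, q_minus=1)


@pytest.mark.parametrize(
    "bad",
    [
        dict(q_plus=-1),
        dict(q_zero=-2),
        dict(q_plus=0, q_minus=0, q_zero=0),
        dict(q_plus=1.5, q_zero=0),
    ],
)
def test_species_invariants_rejected(bad):
    kw = dict(q_plus=0, q_minus=0, q_zero=1)
    kw.update(bad)
    with pytest.raises(ValueError):
        InteinSpecies("Z", **kw)


@pytest.mark.parametrize("qp,qm,expected", [(2, 1, 2), (1, 1, 1), (1, 3, 3)])
def test_splicing_rate_multiplier(qp, qm, expected):
    zi = InteinSpecies("A", q_plus=qp)
    zj = InteinSpecies("B", q_minus=qm)
    assert splicing_rate_multiplier(zi, zj) == expected


def test_splicing_rate_multiplier_wrong_classes():
    s = InteinSpecies("S", q_zero=1)
    n = InteinSpecies("N", q_minus=1)
    with pytest.raises(ValueError):
        splicing_rate_multiplier(s, n)
    with pytest.raises(ValueError):
        splicing_rate_multiplier(InteinSpecies("C", q_plus=1), s)


def test_classification_partitions_species(presets):
    for net in presets.values():
        for sp in net.species:
            assert sum(classify_species(sp) is c for c in InteinClass) == 1


# -- rule engine -----------------------------------------------------------


def test_zf_passes_all_reduction_rules(presets):
    report = validate_rules(presets["zf"], mode="theorem2")
    assert report.theorem2_eligible
    assert report.violations == []


def test_inactive_intein_violates_splicing_completeness(presets):
    report = validate_rules(presets["inactive_intein"], mode="theorem2")
    assert report.theorem1_eligible
    assert not report.results["RR9"]
    assert not report.theorem2_eligible


def test_zero_theta_violates_sensing_rule(presets):
    net = presets["zf"].with_params(theta=np.zeros(3))
    report = validate_rules(net)
    assert not report.results["RR1"]
    assert any("theta" in v for v in report.violations)


def test_rule13_multiplier_mismatch_flagged(presets):
    net = presets["zf"].with_params()
    net.reactions[0].rate_params["multiplier"] = 5
    report = validate_rules(net, mode="theorem2")
    assert not report.results["RR13"]


def test_irreversible_binding_flagged(presets):
    net = presets["intradd"].with_params()
    net.reactions[0].rate_params["kr"] = 0.0
    report = validate_rules(net, mode="theorem2")
    assert not report.results["RR10"]


def test_theorem2_implies_theorem1_on_random_networks():
    for seed in range(200):
        net = random_network(seed, M=3 + seed % 4)
        r2 = validate_rules(net, mode="theorem2")
        if r2.theorem2_eligible:
            assert validate_rules(net, mode="theorem1").theorem1_eligible


# -- charge bookkeeping of the reaction channels ---------------------------


def _charge_matrix(net):
    qp = np.array([s.q_plus for s in net.species])
    qm = np.array([s.q_minus for s in net.species])
    q0 = np.array([s.q_zero for s in net.species])
    return qp, qm, q0


def test_fast_channels_conserve_all_segment_counts(presets):
    """Binding/conversion rearrange monomers without touching segment counts."""
    nets = list(presets.values()) + [random_network(s, M=3 + s % 4) for s in range(30)]
    for net in nets:
        qp, qm, q0 = _charge_matrix(net)
        for rxn in net.reactions:
            if rxn.rtype in ("binding", "conversion"):
                col = reaction_stoichiometry(net, rxn)
                assert qp @ col == 0 and qm @ col == 0 and q0 @ col == 0


def test_splicing_inactivates_exactly_one_segment_pair(presets):
    nets = list(presets.values()) + [random_network(s, M=3 + s % 4) for s in range(30)]
    for net in nets:
        qp, qm, _ = _charge_matrix(net)
        for rxn in net.reactions:
            if rxn.rtype == "splicing":
                col = reaction_stoichiometry(net, rxn)
                assert qp @ col == -1 and qm @ col == -1


# -- ODE assembly ----------------------------------------------------------


def test_basic_aif_reproduces_reference_odes():
    """At z1 = z2 = 1, mu = 2, theta = 1, eta = 1, x_L = 3 the two controller
    rates are dz1 = mu - eta z1 z2 = 1 and dz2 = theta x_L - eta z1 z2 = 2."""
    net = build_preset("aif", mu1=2.0, theta2=1.0, eta=1.0, delta0=0.0).network
    ods = build_ode_rhs(net, build_regulated(1))
    dz = ods.controller_rhs(np.array([1.0, 1.0]), 3.0)
    assert dz == pytest.approx([1.0, 2.0])


def test_zero_state_zero_mu_gives_zero_controller_field():
    net = build_preset("aif", mu1=0.0, theta2=1.0).network
    ods = build_ode_rhs(net, build_regulated(1))
    report = validate_rules(net)
    assert not report.results["RR1"]  # no setpoint encoding
    assert np.allclose(ods.controller_rhs(np.zeros(2), 0.0), 0.0)


def _oracle_rhs(net, z, x_L):
    """Brute-force per-reaction accumulation, independent of the compiled path."""
    dz = net.mu + net.theta * x_L
    idx = net.species_index
    for rxn in net.reactions:
        col = reaction_stoichiometry(net, rxn)
        if rxn.rtype in ("binding", "conversion"):
            fwd = rxn.rate_params["kf"]
            for nm, m in rxn.reactants.items():
                fwd *= z[idx[nm]] ** m
            bwd = rxn.rate_params["kr"]
            for nm, m in rxn.products.items():
                bwd *= z[idx[nm]] ** m
            dz = dz + col * (fwd - bwd)
        elif rxn.rtype == "splicing":
            names = list(rxn.reactants)
            sps = [net.species_by_name(n) for n in names]
            ci = next(s for s in sps if s.q_plus > 0)
            ni = next(s for s in sps if s.q_minus > 0)
            mult = max(ci.q_plus, ni.q_minus)
            dz = dz + col * rxn.rate_params["eta"] * mult * z[idx[ci.name]] * z[idx[ni.name]]
    s_mask = net.s_class_mask()
    dz = dz - net.delta * z - net.delta0 * np.where(s_mask, z, 0.0)
    return dz


@pytest.mark.parametrize("pid", ["intradd", "tetr", "inactive_intein"])
def test_rhs_matches_per_reaction_oracle(pid, plant1):
    net = build_preset(pid).network
    ods = build_ode_rhs(net, plant1)
    rng = np.random.default_rng(11)
    for _ in range(5):
        z = rng.uniform(0, 3, net.M)
        x_L = rng.uniform(0, 5)
        assert ods.controller_rhs(z, x_L) == pytest.approx(_oracle_rhs(net, z, x_L), rel=1e-12)


def test_unknown_reaction_type_rejected():
    with pytest.raises(ValueError, match="unknown reaction type"):
        TypedReaction("teleportation", {"Z1": 1}, {})


# -- actuation -------------------------------------------------------------


@settings(max_examples=60, deadline=None, derandomize=True)
@given(
    a1=st.floats(0, 50), a2=st.floats(0, 50), r=st.floats(0, 50),
    da=st.floats(0.01, 10), form=st.sampled_from(["linear", "hill_activation", "hill_competitive"]),
)
def test_actuation_monotone_in_activators_and_repressors(a1, a2, r, da, form):
    spec = ActuationSpec(form=form, activators={"A": 1.0, "B": 2.0}, repressors={"R": 1.0},
                         k_plus=10.0, k_minus=1.0)
    base = {"A": a1, "B": a2, "R": r}
    up = dict(base, A=a1 + da)
    assert spec.h_plus(up) >= spec.h_plus(base) - 1e-12
    rep = dict(base, R=r + da)
    assert spec.h_plus(rep) <= spec.h_plus(base) + 1e-12
    assert spec.h_plus(base) >= 0 and spec.h_minus(base) >= 0


# -- regulated network -----------------------------------------------------


def test_plant_dc_gain_matches_hand_computed_cascade():
    """x1* = u/(k1+g1), x2* = k1 x1*/g2 for the two-stage chain."""
    reg = RegulatedNetwork(L=2, k=(3.0,), gamma=(2.0, 4.0))
    u = 1.0
    x1 = u / (3.0 + 2.0)
    x2 = 3.0 * x1 / 4.0
    assert reg.dc_gain() == pytest.approx(x2)
    # steady state of the ODEs agrees
    x = np.array([x1, x2])
    assert np.allclose(reg.rhs(x, u), 0.0, atol=1e-14)


def test_disturbance_hooks_scale_open_loop_gain():
    reg = build_regulated(2)
    assert reg.with_gain(2.0).dc_gain() == pytest.approx(2.0 * reg.dc_gain())
    # doubling the stage-1 conversion raises the throughput but not 2x (loss split)
    bumped = reg.with_rate_factor(0, 2.0)
    assert bumped.dc_gain() > reg.dc_gain()


def test_plant_validation():
    with pytest.raises(ValueError):
        build_regulated(0)
    with pytest.raises(ValueError):
        RegulatedNetwork(L=2, k=(), gamma=1.0)
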