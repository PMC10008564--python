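"""Structural reduction: ranks, slow manifold, reduced dynamics, effective actions."""

import numpy as np
import pytest
from scipy.integrate import solve_ivp

from inteinctrl import (
    build_preset,
    build_box3,
    check_reduction,
    random_network,
    reduce,
    reduce_generalized,
    simulate_to_steady,
    solve_slow_manifold,
    split_stoichiometry,
)
from inteinctrl.reduction import effective_action, exact_rank


# -- exact rank ------------------------------------------------------------


def test_exact_rank_against_sympy_oracle():
    import sympy

    rng = np.random.default_rng(3)
    mats = [rng.integers(-3, 4, size=(m, n)) for m, n in [(3, 5), (5, 3), (4, 4), (6, 2), (1, 1)]]
    mats.append(np.zeros((3, 3), dtype=int))
    # a rank-deficient matrix with large entries (floating-point rank would need a tolerance)
    mats.append(np.array([[2, 4, 6], [3, 6, 9], [1, 0, 1]]))
    for m in mats:
        assert exact_rank(m) == sympy.Matrix(m.tolist()).rank()


def test_preset_stoichiometry_ranks_match_sympy(presets):
    import sympy

    for net in presets.values():
        split = split_stoichiometry(net)
        if split.p:
            assert exact_rank(split.S_B.T) == sympy.Matrix(split.S_B.tolist()).rank()


# -- stoichiometry split ---------------------------------------------------


def test_tetr_binding_columns(presets):
    """Three dimerizations: 2Z1=Z5, Z1+Z3=Z6, 2Z3=Z4 over species order Z1..Z6."""
    split = split_stoichiometry(presets["tetr"])
    assert split.p == 3
    assert split.n_conversion == 0
    cols = {tuple(split.S_B[:, j]) for j in range(3)}
    assert cols == {
        (-2, 0, 0, 0, 1, 0),
        (-1, 0, -1, 0, 0, 1),
        (0, 0, -2, 1, 0, 0),
    }


def test_zf_has_no_fast_channels(presets):
    split = split_stoichiometry(presets["zf"])
    assert split.p == 0 and split.n_conversion == 0


def test_box3_three_bindings_no_conversions():
    split = split_stoichiometry(build_box3())
    assert split.p == 3 and split.n_conversion == 0


def test_irreversible_binding_rejected(presets):
    net = presets["intradd"].with_params()
    net.reactions[0].rate_params["kr"] = 0.0
    with pytest.raises(ValueError, match="reversible"):
        split_stoichiometry(net)


# -- reduction conditions --------------------------------------------------


def test_intradd_counting_condition(presets):
    v = check_reduction(presets["intradd"])
    assert v.M == 4 and v.p == 1 and v.rank_S_C_extra == 0
    assert v.cond3 and v.reducible


def test_tetr_counting_condition(presets):
    v = check_reduction(presets["tetr"])
    assert v.M == 6 and v.p == 3
    assert v.reducible


def test_inactive_intein_not_reducible(presets):
    v = check_reduction(presets["inactive_intein"])
    assert not v.rules_ok and "RR9" in v.failed_rules
    assert not v.reducible
    with pytest.raises(ValueError, match="not reducible"):
        reduce(presets["inactive_intein"])


def test_box3_full_rank_equals_m_minus_3():
    net = build_box3()
    v = check_reduction(net)
    assert v.cond1 and v.cond3 and v.p + v.rank_S_C_extra == net.M - 3
    # dropping one binding breaks the count: 2 != 3
    net2 = net.with_params()
    net2.reactions = [r for r in net2.reactions if r.rtype != "binding"][:0] + [
        r for r in net2.reactions if not (r.rtype == "binding" and "Z6" in r.products)
    ]
    v2 = check_reduction(net2)
    assert not v2.cond3 and v2.p == 2


# -- slow manifold ---------------------------------------------------------


def test_single_dimerization_quadratic_closed_form(presets):
    """2Z1 <-> Z4 with fixed totals: z1 solves 2(a/d) z1^2 + z1 = z+."""
    net = presets["intradd"]
    red = reduce(net)
    a = net.reactions[0].rate_params["kf"]
    d = net.reactions[0].rate_params["kr"]
    for zp in (0.1, 1.0, 7.3):
        z = solve_slow_manifold(red, [zp, 0.5, 2.0])
        K = a / d
        z1 = (-1 + np.sqrt(1 + 8 * K * zp)) / (4 * K)
        assert z == pytest.approx([z1, 0.5, 2.0, K * z1**2], rel=1e-9)


def test_zero_totals_give_zero_manifold(presets):
    red = reduce(presets["tetr"])
    z = solve_slow_manifold(red, [0.0, 0.0, 0.0])
    assert z == pytest.approx(np.zeros(6), abs=1e-12)


def test_tetr_manifold_matches_fast_subsystem_relaxation(presets):
    """The Newton root agrees with integrating the binding subsystem to equilibrium."""
    net = presets["tetr"]
    red = reduce(net)
    rng = np.random.default_rng(5)
    for _ in range(4):
        z_tot = rng.uniform(0.1, 5.0, 3)
        z = solve_slow_manifold(red, z_tot)
        # oracle: relax the fast subsystem from a feasible monomeric state
        z0 = np.zeros(6)
        z0[0], z0[1], z0[2] = z_tot  # Z1, Z2, Z3 are the pure monomers
        S = red.split.S_fast.astype(float)
        sol = solve_ivp(
            lambda t, zz: S @ red.split.lambda_fast(net, zz),
            (0, 200.0), z0, method="BDF", rtol=1e-12, atol=1e-14,
        )
        assert z == pytest.approx(sol.y[:, -1], rel=1e-6, abs=1e-8)
        assert np.max(np.abs(red.split.lambda_fast(net, z))) < 1e-8


# -- reduced models --------------------------------------------------------


def test_reduced_state_count_is_three_for_reducible_networks(presets):
    for pid in ("zf", "intradd", "tetr", "gal4", "box3"):
        assert reduce(presets[pid]).n_states == 3
    for seed in (2, 9, 23):
        net = random_network(seed, M=4 + seed % 3)
        assert reduce(net).n_states == 3


def test_zf_reduction_is_identity(presets):
    red = reduce(presets["zf"])
    assert np.array_equal(red.Q, np.eye(3, dtype=int))
    z = solve_slow_manifold(red, [1.5, 0.3, 4.0])
    assert z == pytest.approx([1.5, 0.3, 4.0])


def test_generalized_reduction_is_four_dimensional(presets):
    red = reduce_generalized(presets["inactive_intein"])
    assert red.n_states == 4
    assert red.state_names[-1] == "z_star"


def test_generalized_path_requires_inactive_conservation_law(presets):
    with pytest.raises(ValueError, match="use reduce"):
        reduce_generalized(presets["zf"])


def test_generalized_reduced_model_recovers_setpoint(presets, plant1):
    res = simulate_to_steady(presets["inactive_intein"], plant1, model="reduced", t_max=3000)
    assert res.converged
    assert res.steady_state == pytest.approx(10.0, rel=1e-3)


def test_extra_production_vanishes_without_degradation(presets):
    """The z0 gain term is delta0-proportional and needs species holding both
    an active segment and a neutral monomer (Z6 in the TetR circuit)."""
    red0 = reduce(build_preset("tetr", delta0=0.0).network)
    assert red0.extra_production([2.0, 0.5, 3.0]) == 0.0
    red = reduce(presets["tetr"])
    assert red.extra_production([2.0, 0.5, 3.0]) > 0.0
    # the intraDD circuit has no such species: the term vanishes even with delta0 > 0
    red_i = reduce(presets["intradd"])
    assert red_i.extra_production([2.0, 0.5, 3.0]) == 0.0


# -- effective control actions ---------------------------------------------


def test_intradd_action_is_standalone_integrator(presets):
    """U depends on z+ only and increases with it."""
    red = reduce(presets["intradd"])
    for zp in (0.5, 2.0, 10.0):
        vals = [effective_action(red, zp, z0) for z0 in (0.0, 5.0, 10.0)]
        assert max(vals) - min(vals) < 1e-9
    grid = [effective_action(red, zp, 1.0) for zp in (0.5, 1.0, 2.0, 4.0)]
    assert np.all(np.diff(grid) > 0)


@pytest.mark.parametrize("pid", ["zf", "gal4"])
def test_filtered_pi_actions_monotone(pid, presets):
    red = reduce(presets[pid])
    h = 1e-4
    for zp in np.linspace(0.3, 6, 4):
        for z0 in np.linspace(0.3, 6, 4):
            assert effective_action(red, zp + h, z0) > effective_action(red, zp, z0)
            assert effective_action(red, zp, z0 + h) < effective_action(red, zp, z0)


def test_tetr_proportional_gain_switches_sign(presets):
    red = reduce(presets["tetr"])
    h = 1e-4
    signs = []
    for s in np.geomspace(0.02, 10, 20):
        d = effective_action(red, s, s + h) - effective_action(red, s, s)
        signs.append(np.sign(d))
    assert signs[0] > 0 and signs[-1] < 0
    flip = np.flatnonzero(np.diff(signs))
    assert flip.size == 1  # a single switch from + to - along the ray
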