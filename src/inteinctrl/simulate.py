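"""Closed-loop simulation: stiff ODE/DAE integration, SSA, and RPA metrics.

Deterministic runs integrate either the full mass-action model or the
reduced model (three or four totals, with the slow-manifold algebraic
system solved inside the right-hand side by direct substitution).  Steady
states are detected with a trailing-window criterion and refined by an
algebraic fixed-point solve; both are reported.  The stochastic route is an
exact direct-method simulation of the jump process with combinatorial
propensities (a homodimerization of n copies fires at rate kf*n*(n-1)/2).

Protocols mirror the experimental characterization: the setpoint is
titrated through the constitutive production rate mu1, and the disturbance
scales the plant gain (the analogue of transfecting more copies of the
output plasmid) without touching the setpoint parameters mu1 and theta2;
the open-loop control is a non-reactive intein pairing (eta = 0).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp
from scipy.optimize import root

from .crn_model import (
    ControllerNetwork,
    InteinClass,
    ODESystem,
    RegulatedNetwork,
    build_ode_rhs,
    classify_species,
)
from .reduction import ReducedModel, reduce, reduce_generalized
from .rpa_screen import integrated_variable

__all__ = [
    "SimulationResult",
    "RPAMetrics",
    "simulate_ode",
    "disturbance_protocol",
    "setpoint_sweep",
    "ssa",
    "rpa_metrics",
    "integral_residual",
]

STATE_FLOOR = -1e-9  # numerical nonnegativity floor


@dataclass
class SimulationResult:
    """Time grid, trajectories and derived series of one closed-loop run."""

    time: np.ndarray
    states: np.ndarray            # (n_states, n_times)
    state_names: tuple
    x_L: np.ndarray
    u: np.ndarray
    z_I: np.ndarray | None
    converged: bool
    steady_state: float | None        # trailing-window x_L
    steady_state_refined: float | None  # algebraic fixed-point x_L
    metadata: dict = field(default_factory=dict)

    @property
    def final_x_L(self) -> float:
        return float(self.x_L[-1])

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.states.T, columns=list(self.state_names))
        df.insert(0, "time", self.time)
        df["x_L"] = self.x_L
        df["u"] = self.u
        return df


@dataclass
class RPAMetrics:
    """Setpoint and disturbance-rejection errors of converged runs."""

    steady_state: float
    setpoint_error: float
    disturbance_error: float
    converged: bool


def _reduced_model(network: ControllerNetwork) -> ReducedModel:
    if any(sp.q_inactive for sp in network.species):
        return reduce_generalized(network)
    return reduce(network)


def simulate_ode(
    network: ControllerNetwork,
    regulated: RegulatedNetwork,
    t_end: float = 200.0,
    model: str = "full",
    rtol: float = 1e-8,
    atol: float = 1e-10,
    y0: np.ndarray | None = None,
    n_points: int = 400,
    until_steady: bool = False,
    t_max: float = 20000.0,
    window_rel: float = 1e-6,
    method: str = "LSODA",
) -> SimulationResult:
    """Integrate the closed loop; optionally continue until steady state.

    ``model='full'`` integrates all M controller species plus the plant;
    ``model='reduced'`` integrates the reduced totals (solving the
    slow-manifold algebraic system inside the right-hand side).  With
    ``until_steady`` the integration proceeds in windows until the relative
    change of x_L over a trailing window falls below ``window_rel``; the
    result then also carries an algebraic fixed-point refinement.
    """
    if model == "full":
        ods = build_ode_rhs(network, regulated)
        fun = ods.rhs
        y_start = ods.initial_state() if y0 is None else np.asarray(y0, dtype=float)
        names = tuple(network.species_names) + tuple(f"X{i+1}" for i in range(regulated.L))
        n_ctrl = network.M
    elif model == "reduced":
        red = _reduced_model(network)
        fun = red.rhs(regulated)
        y_start = red.initial_state(regulated) if y0 is None else np.asarray(y0, dtype=float)
        names = red.state_names + tuple(f"X{i+1}" for i in range(regulated.L))
        n_ctrl = red.n_states
    else:
        raise ValueError("model must be 'full' or 'reduced'")

    times = [np.array([0.0])]
    ys = [y_start.reshape(-1, 1)]
    converged = False
    t0 = 0.0
    y = y_start
    window = t_end
    while True:
        t_grid = np.linspace(t0, t0 + window, max(int(n_points * window / t_end), 50))
        sol = solve_ivp(fun, (t0, t0 + window), y, method=method, rtol=rtol, atol=atol, t_eval=t_grid, max_step=np.inf)
        if not sol.success:
            break
        times.append(sol.t[1:])
        ys.append(sol.y[:, 1:])
        y = sol.y[:, -1]
        t0 = sol.t[-1]
        if not until_steady:
            converged = _window_converged(np.concatenate(times), np.hstack(ys)[-1], window_rel)
            break
        if _window_converged(np.concatenate(times), np.hstack(ys)[-1], window_rel):
            converged = True
            break
        if t0 >= t_max:
            break

    time = np.concatenate(times)
    states = np.hstack(ys)
    if np.min(states) < STATE_FLOOR * max(1.0, float(np.max(np.abs(states)))) - 1e-6:
        converged = False
    x = states[n_ctrl:, :]
    x_L = x[-1, :]

    # derived series
    u_series = np.empty(time.size)
    z_I = None
    if model == "full":
        ods_u = ods
        for i in range(time.size):
            u_series[i] = ods_u.control_action(states[:n_ctrl, i], x[:, i])
        q, _, _ = integrated_variable(network)
        z_I = q @ states[:n_ctrl, :]
    else:
        for i in range(time.size):
            try:
                z_full = red.solve_manifold(states[:n_ctrl, i])
            except Exception:
                z_full = np.zeros(network.M)
            conc = {sp.name: z_full[j] for j, sp in enumerate(network.species)}
            u_series[i] = network.actuation.u(conc, x[-1, i], x[0, i])
        q, _, _ = integrated_variable(network)
        # z_I = q'z is a linear combination of the totals: q = c' Q when reducible
        Qf = red.Q.astype(float)
        coef, *_ = np.linalg.lstsq(Qf.T, q.astype(float), rcond=None)
        if np.allclose(Qf.T @ coef, q, atol=1e-8):
            z_I = coef @ states[:n_ctrl, :]

    ss = float(x_L[-1]) if converged else None
    ss_ref = None
    if converged:
        try:
            sol_root = root(lambda yy: np.asarray(fun(0.0, yy)), states[:, -1], method="hybr", tol=1e-12)
            if sol_root.success and np.min(sol_root.x) > STATE_FLOOR * max(1.0, float(np.max(np.abs(sol_root.x)))):
                ss_ref = float(sol_root.x[-1])
        except Exception:
            # no finite fixed point (e.g. an inert accumulating species) or
            # the solver probed states off the feasible set; the windowed
            # steady state stands on its own
            ss_ref = None

    return SimulationResult(
        time=time,
        states=states,
        state_names=names,
        x_L=x_L,
        u=u_series,
        z_I=z_I,
        converged=converged,
        steady_state=ss,
        steady_state_refined=ss_ref,
        metadata={
            "model": model,
            "method": method,
            "rtol": rtol,
            "atol": atol,
            "network": network.name,
            "delta": network.delta,
            "delta0": network.delta0,
        },
    )


def _window_converged(time: np.ndarray, x_L: np.ndarray, window_rel: float) -> bool:
    if time[-1] <= 0:
        return False
    mask = time >= 0.9 * time[-1]
    if mask.sum() < 3:
        return False
    seg = x_L[mask]
    ref = max(abs(seg[-1]), 1e-12)
    return bool((seg.max() - seg.min()) / ref < window_rel)


def simulate_to_steady(network, regulated, model="full", **kw) -> SimulationResult:
    kw.setdefault("t_end", 100.0)
    kw.setdefault("t_max", 20000.0)
    return simulate_ode(network, regulated, model=model, until_steady=True, **kw)


def disturbance_protocol(
    network: ControllerNetwork,
    regulated: RegulatedNetwork,
    plasmid2_factor: float,
    model: str = "full",
    **kw,
):
    """Reference and disturbed runs; the disturbance scales the plant gain only."""
    if plasmid2_factor <= 0:
        raise ValueError("plasmid2_factor must be positive")
    ref = simulate_to_steady(network, regulated, model=model, **kw)
    dist = simulate_to_steady(network, regulated.with_gain(plasmid2_factor), model=model, **kw)
    return ref, dist


def setpoint_sweep(
    network: ControllerNetwork,
    regulated: RegulatedNetwork,
    mu1_values,
    plasmid2_factor: float = 2.0,
    model: str = "full",
    **kw,
) -> pd.DataFrame:
    """Titrate the setpoint through mu1 and measure disturbance rejection.

    Returns one row per setpoint with the reference and disturbed steady
    states and their normalized ratio; the sweep-averaged relative
    disturbance error is stored in ``df.attrs['disturbance_error']``.
    """
    mu_idx = int(np.argmax(network.mu))
    rows = []
    for mu1 in mu1_values:
        if mu1 <= 0:
            raise ValueError("mu1 values must be positive")
        mu = network.mu.copy()
        mu[mu_idx] = mu1
        net = network.with_params(mu=mu)
        ref, dist = disturbance_protocol(net, regulated, plasmid2_factor, model=model, **kw)
        ok = ref.converged and dist.converged
        rows.append(
            {
                "mu1": mu1,
                "x_ref": ref.steady_state if ref.converged else np.nan,
                "x_dist": dist.steady_state if dist.converged else np.nan,
                "normalized": (dist.steady_state / ref.steady_state) if ok else np.nan,
                "converged": ok,
            }
        )
    df = pd.DataFrame(rows)
    ok = df["converged"]
    df.attrs["disturbance_error"] = float(np.nanmean(np.abs(df.loc[ok, "normalized"] - 1.0)))
    return df


def rpa_metrics(reference: SimulationResult, disturbed: SimulationResult, setpoint: float) -> RPAMetrics:
    """Setpoint and disturbance errors from a reference/disturbed pair."""
    converged = reference.converged and disturbed.converged
    if not converged:
        return RPAMetrics(steady_state=math.nan, setpoint_error=math.nan, disturbance_error=math.nan, converged=False)
    ss = reference.steady_state
    return RPAMetrics(
        steady_state=ss,
        setpoint_error=abs(ss - setpoint) / abs(setpoint),
        disturbance_error=abs(disturbed.steady_state - ss) / abs(ss),
        converged=True,
    )


def integral_residual(network: ControllerNetwork, regulated: RegulatedNetwork, result: SimulationResult) -> float:
    """Max scaled residual |ż_I - (mu_eff - theta_eff x_L)| along a full-model run."""
    if result.metadata.get("model") != "full":
        raise ValueError("integral residual is defined on full-model trajectories")
    ods = build_ode_rhs(network, regulated)
    q, mu_eff, theta_eff = integrated_variable(network)
    worst = 0.0
    for i in range(result.time.size):
        y = result.states[:, i]
        dz = ods.controller_rhs(y[: network.M], y[-1])
        lhs = float(q @ dz)
        rhs = mu_eff - theta_eff * y[-1]
        scale = max(abs(mu_eff), abs(theta_eff * y[-1]), 1e-12)
        worst = max(worst, abs(lhs - rhs) / scale)
    return worst


# ---------------------------------------------------------------------------
# Stochastic simulation (direct method)
# ---------------------------------------------------------------------------


def _stochastic_channels(network: ControllerNetwork, regulated: RegulatedNetwork):
    """Expand the typed reactions into irreversible jump channels.

    Each channel is (stoich_vector, kind, data); propensities use falling
    factorials for multi-copy reactants.
    """
    M, L = network.M, regulated.L
    n = M + L
    idx = network.species_index
    channels = []

    def add(stoich, rate, reactant_idx):
        channels.append((np.asarray(stoich, dtype=np.int64), float(rate), tuple(reactant_idx)))

    # setpoint / sensing productions
    for i in range(M):
        if network.mu[i] > 0:
            s = np.zeros(n, dtype=np.int64)
            s[i] = 1
            add(s, network.mu[i], ())
        if network.theta[i] > 0:
            s = np.zeros(n, dtype=np.int64)
            s[i] = 1
            add(s, network.theta[i], ((n - 1, 1),))  # proportional to X_L
    # typed reactions
    classes = {sp.name: classify_species(sp) for sp in network.species}
    for rxn in network.reactions:
        col = np.zeros(n, dtype=np.int64)
        for nm, m in rxn.reactants.items():
            col[idx[nm]] -= m
        for nm, m in rxn.products.items():
            col[idx[nm]] += m
        r_idx = tuple((idx[nm], m) for nm, m in rxn.reactants.items())
        if rxn.rtype in ("binding", "conversion"):
            add(col, rxn.rate_params["kf"], r_idx)
            p_idx = tuple((idx[nm], m) for nm, m in rxn.products.items())
            add(-col, rxn.rate_params["kr"], p_idx)
        elif rxn.rtype == "splicing":
            cs = [nm for nm in rxn.reactants if classes[nm] is InteinClass.C]
            ns = [nm for nm in rxn.reactants if classes[nm] is InteinClass.N]
            mult = rxn.rate_params.get("multiplier")
            if mult is None:
                from .crn_model import splicing_rate_multiplier

                mult = splicing_rate_multiplier(network.species_by_name(cs[0]), network.species_by_name(ns[0]))
            add(col, rxn.rate_params["eta"] * mult, r_idx)
        elif rxn.rtype == "degradation":
            add(col, rxn.rate_params.get("rate", 0.0), r_idx)
    # dilution / degradation
    s_mask = network.s_class_mask()
    for i in range(M):
        rate = network.delta + (network.delta0 if s_mask[i] else 0.0)
        if rate > 0:
            s = np.zeros(n, dtype=np.int64)
            s[i] = -1
            add(s, rate, ((i, 1),))
    # plant chain
    for i in range(L - 1):
        s = np.zeros(n, dtype=np.int64)
        s[M + i] = -1
        s[M + i + 1] = 1
        add(s, regulated.rate_factors[i] * regulated.k[i], ((M + i, 1),))
    for i in range(L):
        s = np.zeros(n, dtype=np.int64)
        s[M + i] = -1
        add(s, regulated.gamma[i], ((M + i, 1),))
    return channels


def _ssa_path(network, regulated, channels, t_end, rng, record_dt):
    M, L = network.M, regulated.L
    n = M + L
    state = np.zeros(n, dtype=np.int64)
    state[:M] = np.rint(network.initial_state()).astype(np.int64)
    state[M:] = np.rint(regulated.initial_state()).astype(np.int64)
    act = network.actuation
    names = network.species_names
    gain = regulated.input_gain

    stoichs = [c[0] for c in channels]
    rates = [c[1] for c in channels]
    ridxs = [c[2] for c in channels]
    nch = len(channels)
    props = np.zeros(nch + 1)

    t = 0.0
    rec_t = [0.0]
    rec_x = [state[-1]]
    # time-weighted running sum for the stationary average
    next_rec = record_dt
    while t < t_end:
        for c in range(nch):
            a = rates[c]
            st = state
            for j, m in ridxs[c]:
                v = st[j]
                for k in range(m):
                    a *= max(v - k, 0)
                if m == 2:
                    a *= 0.5
                elif m == 3:
                    a /= 6.0
            props[c] = a
        conc = {nm: float(state[i]) for i, nm in enumerate(names)}
        u = act.h_plus(conc, float(state[-1]))
        hm = act.h_minus(conc, float(state[-1]))
        props[nch] = gain * u  # birth of X1
        a0 = props.sum() + hm * state[M]
        if a0 <= 0:
            t = t_end
            break
        t += rng.exponential(1.0 / a0)
        if t > t_end:
            break
        r = rng.random() * a0
        cum = 0.0
        chosen = None
        for c in range(nch + 1):
            cum += props[c]
            if r < cum:
                chosen = c
                break
        if chosen is None:
            state[M] = max(state[M] - 1, 0)  # h- removal of X1
        elif chosen == nch:
            state[M] += 1
        else:
            state += stoichs[chosen]
            np.maximum(state, 0, out=state)
        while t >= next_rec:
            rec_t.append(next_rec)
            rec_x.append(state[-1])
            next_rec += record_dt
    while next_rec <= t_end + 1e-9:
        rec_t.append(next_rec)
        rec_x.append(state[-1])
        next_rec += record_dt
    return np.asarray(rec_t), np.asarray(rec_x, dtype=float)


def ssa(
    network: ControllerNetwork,
    regulated: RegulatedNetwork,
    t_end: float = 500.0,
    seed: int = 0,
    n_paths: int = 50,
    burn_frac: float = 0.5,
    record_dt: float = 1.0,
    n_boot: int = 1000,
):
    """Exact stochastic simulation ensemble and the stationary mean of X_L.

    Integer copy numbers; combinatorial propensities; splicing uses the
    max-count multiplier.  Returns a dict with the per-path time-averaged
    means (after discarding ``burn_frac`` of each path as burn-in), their
    ensemble mean and a bootstrap standard error, plus the recorded output
    trajectories.
    """
    channels = _stochastic_channels(network, regulated)
    ss = np.random.SeedSequence(seed)
    child_seeds = ss.spawn(n_paths)
    path_means = np.empty(n_paths)
    trajs = []
    for ip in range(n_paths):
        rng = np.random.default_rng(child_seeds[ip])
        rec_t, rec_x = _ssa_path(network, regulated, channels, t_end, rng, record_dt)
        keep = rec_t >= burn_frac * t_end
        path_means[ip] = rec_x[keep].mean()
        trajs.append((rec_t, rec_x))
    boot_rng = np.random.default_rng(np.random.SeedSequence(seed).spawn(n_paths + 1)[-1])
    boots = np.empty(n_boot)
    for b in range(n_boot):
        pick = boot_rng.integers(0, n_paths, n_paths)
        boots[b] = path_means[pick].mean()
    return {
        "mean": float(path_means.mean()),
        "se": float(boots.std(ddof=1)),
        "path_means": path_means,
        "trajectories": trajs,
        "seed": seed,
        "n_paths": n_paths,
        "t_end": t_end,
    }
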