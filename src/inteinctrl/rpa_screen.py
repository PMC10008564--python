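"""Robust-perfect-adaptation screening of intein controller networks.

The screen reads the per-species intein "charges" off the network
annotations, forms q_i = q_i^+ - q_i^-, and — for a network passing the
structural rules — reports the guaranteed setpoint

    lim_{t->inf} x_L(t) = - qᵀμ / qᵀθ,

the integrated variable z_I = qᵀz and its effective rates
μ_eff = qᵀμ, θ_eff = -qᵀθ such that ż_I = μ_eff - θ_eff x_L whenever the
dilution δ is zero (S-class degradation never enters z_I since S-class
species carry q_i = 0).  The guarantee is conditional on closed-loop
stability, which the screen flags but does not decide.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .crn_model import ControllerNetwork, validate_rules

__all__ = ["ChargeReport", "charge_vectors", "rpa_verdict", "integrated_variable", "nonlinear_sensing_hook", "implicit_setpoint"]


@dataclass
class ChargeReport:
    """Charge vectors, effective rates and the guaranteed setpoint."""

    q_plus: np.ndarray
    q_minus: np.ndarray
    q_zero: np.ndarray
    q: np.ndarray
    mu_eff: float
    theta_eff: float
    setpoint: float | None
    eligible: bool
    conditional_on_stability: bool = True
    setpoint_implicit: bool = False
    diagnostics: tuple = ()

    def as_dict(self) -> dict:
        return {
            "q_plus": self.q_plus.tolist(),
            "q_minus": self.q_minus.tolist(),
            "q_zero": self.q_zero.tolist(),
            "q": self.q.tolist(),
            "mu_eff": self.mu_eff,
            "theta_eff": self.theta_eff,
            "setpoint": self.setpoint,
            "eligible": self.eligible,
            "conditional_on_stability": self.conditional_on_stability,
            "setpoint_implicit": self.setpoint_implicit,
            "diagnostics": list(self.diagnostics),
        }


def charge_vectors(network: ControllerNetwork):
    """Read (q⁺, q⁻, q⁰, q) off the species annotations in declaration order."""
    q_plus = np.array([sp.q_plus for sp in network.species], dtype=int)
    q_minus = np.array([sp.q_minus for sp in network.species], dtype=int)
    q_zero = np.array([sp.q_zero for sp in network.species], dtype=int)
    return q_plus, q_minus, q_zero, q_plus - q_minus


def rpa_verdict(network: ControllerNetwork) -> ChargeReport:
    """Decide RPA eligibility and compute the guaranteed setpoint -qᵀμ/qᵀθ.

    Eligibility requires qᵀθ != 0 (net sensing) and a strictly positive
    setpoint.  With nonlinear sensing functions installed the screen still
    reports eligibility but marks the setpoint as implicit (the closed-form
    ratio no longer applies; the steady state solves qᵀμ + qᵀf(x*) = 0).
    """
    q_plus, q_minus, q_zero, q = charge_vectors(network)
    mu_eff = float(q @ network.mu)
    qtheta = float(q @ network.theta)
    theta_eff = -qtheta
    diagnostics = []
    eligible = True
    setpoint: float | None = None
    implicit = network.sensing_fns is not None
    if implicit:
        # the net drift of the integrated variable, g(x) = q'mu + q'f(x),
        # must be strictly decreasing in the output (negative feedback) and
        # cross zero at a positive output level
        xs = np.concatenate([[0.0], np.logspace(-3, 6, 200)])
        g = np.array([mu_eff + float(q @ _sensing_values(network, x)) for x in xs])
        if not np.all(np.diff(g) < 1e-12):
            eligible = False
            diagnostics.append("no net sensing: q'f(x_L) is not strictly decreasing")
        if g[0] <= 0 or g[-1] >= 0:
            eligible = False
            diagnostics.append("no positive root of q'mu + q'f(x) (implicit setpoint undefined)")
    elif qtheta == 0.0:
        eligible = False
        diagnostics.append("no net sensing: q'theta = 0")
    else:
        setpoint = -mu_eff / qtheta
        if mu_eff == 0.0:
            eligible = False
            diagnostics.append("zero setpoint: q'mu = 0")
        elif setpoint <= 0:
            eligible = False
            diagnostics.append(f"setpoint {setpoint:g} is not positive")
    report = validate_rules(network, mode="theorem1")
    if not report.theorem1_eligible:
        eligible = False
        diagnostics.extend(report.violations)
    return ChargeReport(
        q_plus=q_plus,
        q_minus=q_minus,
        q_zero=q_zero,
        q=q,
        mu_eff=mu_eff,
        theta_eff=theta_eff,
        setpoint=setpoint if eligible or not implicit else None,
        eligible=eligible,
        setpoint_implicit=implicit,
        diagnostics=tuple(diagnostics),
    )


def _sensing_values(network: ControllerNetwork, x: float) -> np.ndarray:
    out = np.zeros(network.M)
    for i, f in enumerate(network.sensing_fns or []):
        if f is not None:
            out[i] = f(x)
    return out


def implicit_setpoint(network: ControllerNetwork, x_hi: float = 1e6) -> float:
    """Numeric root of q'mu + q'f(x) = 0 for networks with nonlinear sensing."""
    from scipy.optimize import brentq

    if network.sensing_fns is None:
        raise ValueError("network has linear sensing; use rpa_verdict's closed-form setpoint")
    q_plus, q_minus, _, q = charge_vectors(network)
    mu_eff = float(q @ network.mu)

    def g(x):
        return mu_eff + float(q @ _sensing_values(network, x))

    return float(brentq(g, 0.0, x_hi))


def integrated_variable(network: ControllerNetwork):
    """Coefficients of the integrated variable z_I = qᵀz and its effective rates.

    Returns ``(q, mu_eff, theta_eff)`` with μ_eff = qᵀμ and θ_eff = -qᵀθ, so
    that ż_I = μ_eff - θ_eff·x_L along closed-loop trajectories with δ = 0.
    """
    *_, q = charge_vectors(network)
    mu_eff = float(q @ network.mu)
    theta_eff = float(-(q @ network.theta))
    return q, mu_eff, theta_eff


def nonlinear_sensing_hook(network: ControllerNetwork, fns: list, x_grid=None) -> ControllerNetwork:
    """Install monotone nonlinear sensing functions f_i(x_L) replacing θ_i·x_L.

    Each non-None entry must be a nonnegative, monotone (either direction)
    function of the output concentration; monotonicity and nonnegativity are
    checked on a grid.  Returns a copy of the network with the functions
    installed; the linear ``theta`` vector is retained only as metadata.
    """
    if len(fns) != network.M:
        raise ValueError("need one sensing entry (or None) per species")
    if x_grid is None:
        x_grid = np.linspace(0.0, 100.0, 201)
    for i, f in enumerate(fns):
        if f is None:
            continue
        vals = np.array([f(x) for x in x_grid], dtype=float)
        if np.any(vals < 0):
            raise ValueError(f"sensing function for species {i} takes negative values")
        d = np.diff(vals)
        if not (np.all(d >= -1e-12) or np.all(d <= 1e-12)):
            raise ValueError(f"sensing function for species {i} is not monotone")
    return network.with_params(sensing_fns=list(fns))
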