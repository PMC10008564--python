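"""Structural model reduction of intein controller networks.

A rule-compliant controller whose reversible binding/conversion reactions are
fast reduces to three effective species

    z+ = (q+)ᵀz,   z- = (q-)ᵀz,   z0 = (q0)ᵀz,

governed by three ODEs coupled to M-3 algebraic equations (the slow-manifold
equilibrium of the fast channels).  The structural conditions are

1. the binding stoichiometry matrix S_B is full-column rank,
2. the conversion columns S_C are linearly independent from those of S_B,
3. p + rank(S_C) = M - 3, with p the number of reversible binding reactions.

Ranks are computed exactly in rational arithmetic (stoichiometries are
integers).  The reduced dynamics are obtained by left-multiplying the full
mass-action right-hand side by Q = [q+ q- q0]ᵀ: the fast fluxes cancel
exactly because each charge vector is conserved by every binding/conversion
column, so no symbolic elimination is needed.  Networks carrying an extra
conservation law from *inactive* intein segments (competing-sequestration
designs, which violate the splicing-completeness rule) use the generalized
four-state path with the additional direction q* of inactive-segment counts.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction

import numpy as np
from scipy.integrate import solve_ivp
from scipy.optimize import nnls

from .crn_model import (
    ControllerNetwork,
    ODESystem,
    RegulatedNetwork,
    reaction_stoichiometry,
    validate_rules,
)
from .rpa_screen import charge_vectors

__all__ = [
    "StoichiometrySplit",
    "ReductionVerdict",
    "ReducedModel",
    "exact_rank",
    "split_stoichiometry",
    "check_reduction",
    "reduce",
    "reduce_generalized",
    "solve_slow_manifold",
    "effective_action",
]


def exact_rank(mat) -> int:
    """Rank of an integer matrix by Gaussian elimination over the rationals."""
    rows = [[Fraction(int(v)) for v in row] for row in np.atleast_2d(np.asarray(mat, dtype=int))]
    if not rows or not rows[0]:
        return 0
    n_rows, n_cols = len(rows), len(rows[0])
    rank = 0
    col = 0
    for col in range(n_cols):
        pivot = next((r for r in range(rank, n_rows) if rows[r][col] != 0), None)
        if pivot is None:
            continue
        rows[rank], rows[pivot] = rows[pivot], rows[rank]
        pv = rows[rank][col]
        rows[rank] = [v / pv for v in rows[rank]]
        for r in range(n_rows):
            if r != rank and rows[r][col] != 0:
                f = rows[r][col]
                rows[r] = [a - f * b for a, b in zip(rows[r], rows[rank])]
        rank += 1
        if rank == n_rows:
            break
    return rank


@dataclass
class StoichiometrySplit:
    """Stoichiometry and net propensities of the fast reversible channels."""

    S_B: np.ndarray  # M x p integer columns, one per reversible binding reaction
    S_C: np.ndarray  # M x c integer columns, one per reversible conversion
    binding_reactions: list
    conversion_reactions: list

    @property
    def p(self) -> int:
        return self.S_B.shape[1]

    @property
    def n_conversion(self) -> int:
        return self.S_C.shape[1]

    @property
    def S_fast(self) -> np.ndarray:
        return np.hstack([self.S_B, self.S_C])

    def lambda_B(self, network: ControllerNetwork, z: np.ndarray) -> np.ndarray:
        return _net_fluxes(network, self.binding_reactions, z)

    def lambda_C(self, network: ControllerNetwork, z: np.ndarray) -> np.ndarray:
        return _net_fluxes(network, self.conversion_reactions, z)

    def lambda_fast(self, network: ControllerNetwork, z: np.ndarray) -> np.ndarray:
        return np.concatenate(
            [self.lambda_B(network, z), self.lambda_C(network, z)]
        )


def _net_fluxes(network: ControllerNetwork, reactions, z: np.ndarray) -> np.ndarray:
    idx = network.species_index
    zc = np.maximum(z, 0.0)
    out = np.empty(len(reactions))
    for i, rxn in enumerate(reactions):
        fwd = rxn.rate_params.get("kf", 0.0)
        for nm, m in rxn.reactants.items():
            fwd *= zc[idx[nm]] ** m
        bwd = rxn.rate_params.get("kr", 0.0)
        for nm, m in rxn.products.items():
            bwd *= zc[idx[nm]] ** m
        out[i] = fwd - bwd
    return out


def split_stoichiometry(network: ControllerNetwork) -> StoichiometrySplit:
    """Collect the binding/conversion columns S_B, S_C and their net propensities.

    Raises if a binding or conversion reaction is irreversible (missing a
    forward or backward rate), which breaks the fast-equilibrium premise.
    """
    b_rxns, c_rxns = [], []
    for rxn in network.reactions:
        if rxn.rtype in ("binding", "conversion"):
            if rxn.rate_params.get("kf", 0.0) <= 0 or rxn.rate_params.get("kr", 0.0) <= 0:
                raise ValueError(
                    f"{rxn.rtype} reaction {rxn.reactants}->{rxn.products} must be "
                    "reversible (kf > 0 and kr > 0) for the fast-equilibrium reduction"
                )
            (b_rxns if rxn.rtype == "binding" else c_rxns).append(rxn)
    M = network.M
    S_B = (
        np.array([reaction_stoichiometry(network, r) for r in b_rxns], dtype=int).T
        if b_rxns
        else np.zeros((M, 0), dtype=int)
    )
    S_C = (
        np.array([reaction_stoichiometry(network, r) for r in c_rxns], dtype=int).T
        if c_rxns
        else np.zeros((M, 0), dtype=int)
    )
    return StoichiometrySplit(S_B=S_B, S_C=S_C, binding_reactions=b_rxns, conversion_reactions=c_rxns)


@dataclass
class ReductionVerdict:
    """Outcome of the three structural conditions plus rule compliance."""

    cond1: bool
    cond2: bool
    cond3: bool
    rules_ok: bool
    M: int
    p: int
    rank_S_B: int
    rank_S_C_extra: int
    failed_rules: list = field(default_factory=list)

    @property
    def reducible(self) -> bool:
        return self.cond1 and self.cond2 and self.cond3 and self.rules_ok


def check_reduction(network: ControllerNetwork) -> ReductionVerdict:
    """Evaluate the structural reduction conditions with exact integer ranks."""
    split = split_stoichiometry(network)
    M = network.M
    p = split.p
    rank_B = exact_rank(split.S_B.T) if p else 0
    cond1 = rank_B == p
    rank_BC = exact_rank(split.S_fast.T) if split.S_fast.shape[1] else 0
    rank_C_extra = rank_BC - rank_B
    cond2 = rank_C_extra == (exact_rank(split.S_C.T) if split.n_conversion else 0)
    cond3 = (p + rank_C_extra) == M - 3
    report = validate_rules(network, mode="theorem2")
    return ReductionVerdict(
        cond1=cond1,
        cond2=cond2,
        cond3=cond3,
        rules_ok=report.theorem2_eligible,
        M=M,
        p=p,
        rank_S_B=rank_B,
        rank_S_C_extra=rank_C_extra,
        failed_rules=report.failed_rules(),
    )


# ---------------------------------------------------------------------------
# Reduced model
# ---------------------------------------------------------------------------


class SlowManifoldError(RuntimeError):
    pass


@dataclass
class ReducedModel:
    """Differential states Qz plus the algebraic slow-manifold map.

    ``Q`` stacks the conserved directions (q+, q-, q0 and, on the
    generalized path, q*) as rows; the differential states are z_tot = Qz.
    ``solve_manifold`` recovers the full species vector z >= 0 on the slow
    manifold (fast net fluxes zero) from the totals; the reduced vector field
    is Q @ f_slow(z) with f_slow the production/splicing/dilution/degradation
    part of the full dynamics — the fast fluxes cancel exactly under Q.
    """

    network: ControllerNetwork
    Q: np.ndarray
    state_names: tuple
    split: StoichiometrySplit
    generalized: bool = False
    residual_tol: float = 1e-10
    _warm: np.ndarray | None = field(default=None, repr=False)
    _ods: ODESystem | None = field(default=None, repr=False)

    @property
    def n_states(self) -> int:
        return self.Q.shape[0]

    @property
    def n_algebraic(self) -> int:
        return self.network.M - 3 if not self.generalized else self.split.S_fast.shape[1]

    # -- slow manifold ------------------------------------------------------

    def _fast_residual(self, z: np.ndarray) -> np.ndarray:
        return self.split.lambda_fast(self.network, z)

    def _residual_scale(self, z: np.ndarray) -> float:
        idx = self.network.species_index
        zc = np.maximum(z, 0.0)
        scale = 1.0
        for rxn in self.split.binding_reactions + self.split.conversion_reactions:
            fwd = rxn.rate_params.get("kf", 0.0)
            for nm, m in rxn.reactants.items():
                fwd *= zc[idx[nm]] ** m
            bwd = rxn.rate_params.get("kr", 0.0)
            for nm, m in rxn.products.items():
                bwd *= zc[idx[nm]] ** m
            scale = max(scale, fwd, bwd)
        return scale

    def solve_manifold(self, z_tot: np.ndarray, guess: np.ndarray | None = None) -> np.ndarray:
        """Nonnegative full state z on the slow manifold with Qz = z_tot."""
        z_tot = np.asarray(z_tot, dtype=float)
        if np.any(z_tot < -1e-6 * max(1.0, float(np.max(np.abs(z_tot))))):
            raise SlowManifoldError(f"negative totals {z_tot}")
        z_tot = np.maximum(z_tot, 0.0)
        N = self.split.S_fast.astype(float)
        r = N.shape[1]
        if r == 0:
            # no fast channels: Q is square and invertible
            z = np.linalg.solve(self.Q.astype(float), z_tot)
            return np.maximum(z, 0.0)
        z_closed = self._try_closed_form(z_tot)
        if z_closed is not None:
            return z_closed
        z0 = self._particular(z_tot, guess)
        z = self._newton(z0, N)
        if z is None:
            z = self._relaxation(z_tot)
        scale = self._residual_scale(z)
        res = np.max(np.abs(self._fast_residual(z)))
        if res > self.residual_tol * scale * 10:
            raise SlowManifoldError(f"slow-manifold residual {res:g} exceeds tolerance")
        self._warm = z.copy()
        return z

    def _particular(self, z_tot: np.ndarray, guess: np.ndarray | None) -> np.ndarray:
        if guess is not None:
            g = np.asarray(guess, dtype=float)
            # project the guess onto the affine set Qz = z_tot
            corr = np.linalg.lstsq(self.Q.astype(float), z_tot - self.Q @ g, rcond=None)[0]
            return g + corr
        if self._warm is not None:
            return self._particular(z_tot, self._warm)
        z0, _ = nnls(self.Q.astype(float), z_tot)
        return z0

    def _newton(self, z0: np.ndarray, N: np.ndarray, max_iter: int = 80):
        r = N.shape[1]
        xi = np.zeros(r)
        z = z0

        def F(xi_):
            return self._fast_residual(z0 + N @ xi_)

        f = F(xi)
        scale = self._residual_scale(z0)
        for _ in range(max_iter):
            if np.max(np.abs(f)) <= self.residual_tol * scale:
                z = z0 + N @ xi
                if np.min(z) < -1e-8 * max(1.0, np.max(np.abs(z))):
                    return None
                return np.maximum(z, 0.0)
            J = np.empty((r, r))
            for j in range(r):
                h = 1e-7 * max(1.0, abs(xi[j]))
                e = np.zeros(r)
                e[j] = h
                J[:, j] = (F(xi + e) - f) / h
            try:
                step = np.linalg.solve(J, -f)
            except np.linalg.LinAlgError:
                step = np.linalg.lstsq(J, -f, rcond=None)[0]
            alpha = 1.0
            base = np.max(np.abs(f))
            improved = False
            for _ in range(30):
                f_new = F(xi + alpha * step)
                if np.max(np.abs(f_new)) < base * (1 - 1e-4 * alpha) or np.max(np.abs(f_new)) <= self.residual_tol * scale:
                    xi = xi + alpha * step
                    f = f_new
                    improved = True
                    break
                alpha *= 0.5
            if not improved:
                return None
            scale = self._residual_scale(z0 + N @ xi)
        return None

    def _relaxation(self, z_tot: np.ndarray) -> np.ndarray:
        """Fallback: integrate the fast subsystem alone to its equilibrium."""
        z0, resid = nnls(self.Q.astype(float), z_tot)
        if resid > 1e-8 * max(1.0, np.max(z_tot)):
            raise SlowManifoldError(f"no nonnegative state matches totals {z_tot}")
        N = self.split.S_fast.astype(float)

        def fun(t, z):
            return N @ self._fast_residual(z)

        z = z0
        t_span = 10.0
        for _ in range(12):
            sol = solve_ivp(fun, (0.0, t_span), z, method="BDF", rtol=1e-10, atol=1e-12)
            if not sol.success:
                break
            z = sol.y[:, -1]
            if np.max(np.abs(self._fast_residual(z))) <= self.residual_tol * self._residual_scale(z):
                return np.maximum(z, 0.0)
            t_span *= 10.0
        raise SlowManifoldError("fast-subsystem relaxation did not converge")

    def _try_closed_form(self, z_tot: np.ndarray):
        """Closed-form manifold for a single homodimerization 2A <-> B."""
        if self.split.S_fast.shape[1] != 1 or self.split.n_conversion:
            return None
        rxn = self.split.binding_reactions[0]
        if list(rxn.reactants.values()) != [2] or sum(rxn.products.values()) != 1:
            return None
        idx = self.network.species_index
        ia = idx[next(iter(rxn.reactants))]
        ib = idx[next(iter(rxn.products))]
        touching = [k for k in range(self.Q.shape[0]) if self.Q[k, ia] or self.Q[k, ib]]
        if len(touching) != 1:
            return None
        k = touching[0]
        cA, cB = float(self.Q[k, ia]), float(self.Q[k, ib])
        K = rxn.rate_params["kf"] / rxn.rate_params["kr"]
        # remaining rows must determine the remaining species uniquely
        rest = [i for i in range(self.network.M) if i not in (ia, ib)]
        sub = self.Q[np.ix_([r for r in range(self.Q.shape[0]) if r != k], rest)].astype(float)
        if sub.shape[0] != sub.shape[1] or abs(np.linalg.det(sub)) < 1e-12:
            return None
        T = z_tot[k]
        if cB * K <= 0:
            return None
        zA = (-cA + np.sqrt(cA * cA + 4.0 * cB * K * T)) / (2.0 * cB * K)
        zB = K * zA * zA
        rhs = np.delete(z_tot, k)
        z_rest = np.linalg.solve(sub, rhs)
        z = np.zeros(self.network.M)
        z[ia], z[ib] = zA, zB
        z[rest] = z_rest
        if np.min(z) < -1e-9 * max(1.0, np.max(np.abs(z))):
            raise SlowManifoldError(f"closed-form manifold is negative for totals {z_tot}")
        return np.maximum(z, 0.0)

    # -- reduced dynamics ---------------------------------------------------

    def _ode_system(self, regulated: RegulatedNetwork) -> ODESystem:
        if self._ods is None or self._ods.regulated is not regulated:
            self._ods = ODESystem(self.network, regulated)
        return self._ods

    def rhs(self, regulated: RegulatedNetwork):
        """Vector field over (z_tot, x) for direct-substitution DAE integration."""
        ods = self._ode_system(regulated)
        Q = self.Q.astype(float)
        k = self.n_states

        def fun(t, y):
            z_tot = y[:k]
            x = y[k:]
            z = self.solve_manifold(z_tot, guess=self._warm)
            u = self.network.actuation.u(ods.conc(z), x[-1], x[0])
            dz = ods.controller_rhs(z, x[-1])
            return np.concatenate([Q @ dz, regulated.rhs(x, u)])

        return fun

    def initial_state(self, regulated: RegulatedNetwork) -> np.ndarray:
        z0 = self.network.initial_state()
        return np.concatenate([self.Q.astype(float) @ z0, regulated.initial_state()])

    def control_action(self, z_tot: np.ndarray, x_L: float = 0.0, x1: float = 0.0) -> float:
        z = self.solve_manifold(np.asarray(z_tot, dtype=float))
        conc = {sp.name: z[i] for i, sp in enumerate(self.network.species)}
        return self.network.actuation.u(conc, x_L, x1)

    def extra_production(self, z_tot: np.ndarray) -> float:
        """The z0 gain term delta0 * [1(q+ + q-) o q0]ᵀ psi(z_tot).

        psi maps totals to the manifold concentrations of species that carry
        both an active segment and at least one inactive monomer; those
        species are represented in z0 but, being C/N-class, never degrade.
        """
        z = self.solve_manifold(np.asarray(z_tot, dtype=float))
        q_plus, q_minus, q_zero, _ = charge_vectors(self.network)
        mask = ((q_plus + q_minus) > 0).astype(float)
        return float(self.network.delta0 * (mask * q_zero) @ z)


def reduce(network: ControllerNetwork) -> ReducedModel:
    """Construct the three-state reduced model of a Theorem-2-eligible network."""
    verdict = check_reduction(network)
    if not verdict.reducible:
        raise ValueError(
            "network is not reducible to the three-species motif: "
            f"cond1={verdict.cond1}, cond2={verdict.cond2}, cond3={verdict.cond3}, "
            f"rule violations={verdict.failed_rules}"
        )
    q_plus, q_minus, q_zero, _ = charge_vectors(network)
    Q = np.vstack([q_plus, q_minus, q_zero])
    split = split_stoichiometry(network)
    if exact_rank(Q) != 3:
        raise ValueError("charge vectors q+, q-, q0 are not linearly independent")
    if split.S_fast.shape[1] and np.any(Q @ split.S_fast != 0):
        raise ValueError("charge vectors are not conserved by the fast channels")
    return ReducedModel(network=network, Q=Q, state_names=("z_plus", "z_minus", "z_zero"), split=split)


def reduce_generalized(network: ControllerNetwork) -> ReducedModel:
    """Four-state reduction for networks with an inactive-segment conservation law.

    Applies to competing-sequestration designs whose bound inactive Int^N
    segments block splicing (breaking the splicing-completeness rule) but
    add a fourth conserved direction q* (inactive-segment counts).  The
    reduced states are (z+, z-, z0, z*) and the algebraic system is solved
    numerically inside the right-hand side.
    """
    q_star = np.array([sp.q_inactive for sp in network.species], dtype=int)
    if not np.any(q_star):
        raise ValueError(
            "network has no inactive-segment conservation law; use reduce() instead"
        )
    q_plus, q_minus, q_zero, _ = charge_vectors(network)
    Q = np.vstack([q_plus, q_minus, q_zero, q_star])
    split = split_stoichiometry(network)
    r = split.S_fast.shape[1]
    if exact_rank(split.S_fast.T) != r:
        raise ValueError("fast stoichiometry columns are not independent")
    if network.M - r != 4:
        raise ValueError(
            f"fast channels leave {network.M - r} conserved directions; the "
            "generalized path requires exactly 4"
        )
    if exact_rank(Q) != 4:
        raise ValueError("q+, q-, q0, q* are not linearly independent")
    if r and np.any(Q @ split.S_fast != 0):
        raise ValueError("charge vectors are not conserved by the fast channels")
    return ReducedModel(
        network=network,
        Q=Q,
        state_names=("z_plus", "z_minus", "z_zero", "z_star"),
        split=split,
        generalized=True,
    )


def solve_slow_manifold(reduced: ReducedModel, z_tot, guess=None) -> np.ndarray:
    """Nonnegative root of the fast-equilibrium constraints at the given totals."""
    return reduced.solve_manifold(np.asarray(z_tot, dtype=float), guess=guess)


def effective_action(reduced: ReducedModel, z_plus: float, z_zero: float, z_star: float | None = None) -> float:
    """Evaluate the effective control action U(z+, z0) of a reduced model.

    The sensing species total z- is set to zero (the free Int^N does not
    participate in the fast binding channels of the supported circuits), the
    manifold is solved for the remaining species and the actuation h+ is
    evaluated there.
    """
    if z_plus < 0 or z_zero < 0:
        raise ValueError("effective-species concentrations must be nonnegative")
    if reduced.generalized:
        z_tot = np.array([z_plus, 0.0, z_zero, z_star if z_star is not None else z_zero])
    else:
        z_tot = np.array([z_plus, 0.0, z_zero])
    reduced._warm = None  # independent evaluations; no warm start across grid points
    return reduced.control_action(z_tot)
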