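"""Strictly convex maximum-entropy flux solver with dual recovery.

The program maximises the expression-weighted flux entropy

    H_g(v) = - v_f^T (log v_f - log g) - v_r^T (log v_r - log g)

over split unidirectional fluxes (v_f, v_r) of the internal reactions and
free exchange fluxes v_e, subject to steady-state mass balance
S (v_f - v_r) + S_e v_e = 0 and, in ``teraflux`` mode, net-flux
irreversibility v_f,i - v_r,i >= 0 for every reaction i in the
irreversible set. Exchange fluxes carry no objective term.

Three published modes are provided:

``teraflux``
    full split of every internal reaction + irreversibility inequalities;
``all_reversible``
    full split, inequalities dropped (the all-reversible control variant);
``pheflux``
    irreversible reactions keep a single non-negative flux variable, only
    reversible reactions are split (no cycle-freeness guarantee).

The optimum satisfies, reaction-wise, v_f = (g/e) exp(theta) and
v_r = (g/e) exp(-theta) with theta = (S^T lambda) + alpha, where lambda
are the mass-balance multipliers and alpha >= 0 the irreversibility
multipliers (nonzero only on irreversible reactions blocked at zero net
flux). Hence v_f * v_r = (g/e)^2 at any interior optimum, and the duals
encode chemical potentials: Delta_G = -2RT S^T lambda.

Numerically, a SciPy trust-region interior-point solve locates the
optimum; a Newton iteration on the reduced KKT system (unknowns: lambda,
interior exchange fluxes, active-constraint multipliers) then polishes
the solution to ~1e-12 residuals and yields the duals with a fixed sign
convention independent of the backend.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import Bounds, LinearConstraint, linprog, minimize

from .expression import ReactionWeights
from .network import ExchangeConstraints, MetabolicNetwork, apply_exchange_constraints

__all__ = [
    "SolverOptions",
    "FluxSolution",
    "SolverError",
    "solve",
    "closed_form_single_reaction",
    "kkt_report",
]

MODES = ("teraflux", "all_reversible", "pheflux")


class SolverError(RuntimeError):
    """Raised on infeasible constraint sets or non-convergent solves."""


@dataclass(frozen=True)
class SolverOptions:
    """Tunable solver settings.

    flux_floor : smallest allowed unidirectional flux (keeps logs finite);
        far below ``active_flux_threshold`` so it never masquerades as flux.
    tolerance : KKT / constraint residual tolerance.
    active_flux_threshold : |v| cutoff separating active from blocked
        reactions, mmol g^-1 h^-1.
    """

    mode: str = "teraflux"
    flux_floor: float = 1e-10
    tolerance: float = 1e-8
    max_iterations: int = 1000
    active_flux_threshold: float = 1e-6
    initialization: str = "feasible-split"  # or "symmetric": v_f = v_r = g

    def __post_init__(self):
        if self.mode not in MODES:
            raise ValueError(f"mode must be one of {MODES}, got {self.mode!r}")
        if self.flux_floor <= 0 or self.tolerance <= 0:
            raise ValueError("flux_floor and tolerance must be positive")
        if self.initialization not in ("feasible-split", "symmetric"):
            raise ValueError(f"unknown initialization policy {self.initialization!r}")


@dataclass
class FluxSolution:
    """Primal fluxes, duals and diagnostics of a converged solve."""

    internal_ids: list[str]
    exchange_ids: list[str]
    v_f: np.ndarray
    v_r: np.ndarray
    v_e: np.ndarray
    lambda_: np.ndarray | None
    alpha: np.ndarray
    objective_value: float
    status: str
    iterations: int
    mode: str
    options: SolverOptions
    diagnostics: dict = field(default_factory=dict)

    @property
    def v(self) -> np.ndarray:
        """Net internal fluxes v_f - v_r."""
        return self.v_f - self.v_r

    @property
    def active_mask(self) -> np.ndarray:
        return np.abs(self.v) > self.options.active_flux_threshold

    def to_frame(self, net: MetabolicNetwork):
        import pandas as pd

        irr = net.irreversible_mask
        return pd.DataFrame(
            {
                "reaction_id": self.internal_ids,
                "v_f": self.v_f,
                "v_r": self.v_r,
                "net_v": self.v,
                "alpha": self.alpha,
                "is_irreversible": irr,
                "active_flag": self.active_mask,
            }
        )

    def to_tsv(self, net: MetabolicNetwork, path) -> None:
        self.to_frame(net).to_csv(path, sep="\t", index=False, float_format="%.12g")


def closed_form_single_reaction(b: float, g: float) -> tuple[float, float]:
    """Analytic optimum of the split objective for one reaction with net flux b.

    Stationarity of the single-reaction program gives
    v_f = (b + sqrt(b^2 + 4 g^2 e^-2)) / 2 and v_r = v_f - b; the product
    v_f * v_r = (g/e)^2 for any b. Serves as the module's analytic oracle.
    """
    if g <= 0:
        raise ValueError("g must be positive")
    s = np.sqrt(b * b + 4.0 * (g / np.e) ** 2)
    v_f = 0.5 * (b + s)
    # v_f - b cancels catastrophically for b >> g; use the product identity
    return float(v_f), float((g / np.e) ** 2 / v_f)


# ------------------------------------------------------------------ solve

def _feasibility_check(net: MetabolicNetwork) -> np.ndarray:
    """Return an interior-leaning mass-balanced flux vector, or raise.

    Averages the solutions of a few deterministic-objective LPs over
    {S v + S_e v_e = 0, bounds}; deterministic by construction.
    """
    N, K = net.n_internal, net.n_exchange
    A = np.hstack([net.S, net.S_e])
    lb = np.concatenate([net.lb_int, net.lb_ex])
    ub = np.concatenate([net.ub_int, net.ub_ex])
    objectives = [np.zeros(N + K), np.ones(N + K), -np.ones(N + K)]
    pts = []
    for c in objectives:
        res = linprog(c, A_eq=A, b_eq=np.zeros(net.n_metabolites),
                      bounds=list(zip(lb, ub)), method="highs")
        if res.status == 2:
            raise SolverError("infeasible constraint set: no mass-balanced flux vector exists")
        if res.success:
            pts.append(res.x)
    if not pts:
        raise SolverError("feasibility LP failed")
    return np.mean(pts, axis=0)


def _primal_solve(net, g, opts, x_feas):
    """Interior-point solve of the (possibly partially) split program."""
    N, K, M = net.n_internal, net.n_exchange, net.n_metabolites
    irr = net.irreversible_mask
    if opts.mode == "pheflux":
        split = ~irr
    else:
        split = np.ones(N, dtype=bool)
    s_idx = np.flatnonzero(split)
    u_idx = np.flatnonzero(~split)
    ns, nu = len(s_idx), len(u_idx)
    gs, gu = g[s_idx], g[u_idx]
    n = 2 * ns + nu + K

    def unpack(x):
        return x[:ns], x[ns : 2 * ns], x[2 * ns : 2 * ns + nu], x[2 * ns + nu :]

    tiny = opts.flux_floor * 1e-3  # guard: trust-constr may probe outside bounds

    def fun(x):
        vf, vr, u, _ = (np.maximum(b, tiny) for b in unpack(x))
        val = np.sum(vf * (np.log(vf) - np.log(gs))) + np.sum(vr * (np.log(vr) - np.log(gs)))
        if nu:
            val += np.sum(u * (np.log(u) - np.log(gu)))
        return val

    def jac(x):
        vf, vr, u, _ = (np.maximum(b, tiny) for b in unpack(x))
        out = np.zeros(n)
        out[:ns] = np.log(vf) - np.log(gs) + 1.0
        out[ns : 2 * ns] = np.log(vr) - np.log(gs) + 1.0
        if nu:
            out[2 * ns : 2 * ns + nu] = np.log(u) - np.log(gu) + 1.0
        return out

    def hess(x):
        vf, vr, u, _ = (np.maximum(b, tiny) for b in unpack(x))
        d = np.zeros(n)
        d[:ns] = 1.0 / vf
        d[ns : 2 * ns] = 1.0 / vr
        if nu:
            d[2 * ns : 2 * ns + nu] = 1.0 / u
        return np.diag(d)

    # mass balance rows: S_s (vf - vr) + S_u u + S_e v_e = 0
    A_eq = np.zeros((M, n))
    A_eq[:, :ns] = net.S[:, s_idx]
    A_eq[:, ns : 2 * ns] = -net.S[:, s_idx]
    if nu:
        A_eq[:, 2 * ns : 2 * ns + nu] = net.S[:, u_idx]
    A_eq[:, 2 * ns + nu :] = net.S_e
    constraints = [LinearConstraint(A_eq, 0.0, 0.0)]

    if opts.mode == "teraflux":
        rows = np.flatnonzero(irr[s_idx])  # positions within split block
        if rows.size:
            A_in = np.zeros((rows.size, n))
            A_in[np.arange(rows.size), rows] = 1.0
            A_in[np.arange(rows.size), ns + rows] = -1.0
            constraints.append(LinearConstraint(A_in, 0.0, np.inf))

    floor = opts.flux_floor
    lb = np.full(n, floor)
    ub = np.full(n, np.inf)
    if nu:
        lb[2 * ns : 2 * ns + nu] = np.maximum(net.lb_int[u_idx], floor)
        ub[2 * ns : 2 * ns + nu] = net.ub_int[u_idx]
    lb[2 * ns + nu :] = net.lb_ex
    ub[2 * ns + nu :] = net.ub_ex

    # start mass-balance feasible: split the feasible net fluxes around the
    # symmetric g-sized core, so S(v_f - v_r) + S_e v_e = 0 at x0 exactly
    v0 = x_feas[:N]
    x0 = np.empty(n)
    core = np.maximum(gs, floor)
    if opts.initialization == "symmetric":
        x0[:ns] = x0[ns : 2 * ns] = core
    else:
        x0[:ns] = core + np.maximum(v0[s_idx], 0.0)
        x0[ns : 2 * ns] = core + np.maximum(-v0[s_idx], 0.0)
    if nu:
        x0[2 * ns : 2 * ns + nu] = np.clip(v0[u_idx], lb[2 * ns : 2 * ns + nu],
                                           ub[2 * ns : 2 * ns + nu])
        x0[2 * ns : 2 * ns + nu] = np.maximum(x0[2 * ns : 2 * ns + nu], floor)
    x0[2 * ns + nu :] = np.clip(x_feas[N:], lb[2 * ns + nu :], ub[2 * ns + nu :])

    import warnings

    with warnings.catch_warnings():
        # redundant mass-balance rows (conserved moieties) make the
        # constraint Jacobian rank-deficient; SciPy handles it via SVD
        warnings.filterwarnings("ignore", message="Singular Jacobian matrix")
        res = minimize(
            fun, x0, jac=jac, hess=hess, method="trust-constr",
            bounds=Bounds(lb, ub, keep_feasible=True), constraints=constraints,
            options={"gtol": 1e-9, "xtol": 1e-12, "maxiter": opts.max_iterations, "verbose": 0},
        )
    # status 1 (gtol) / 2 (xtol) are converged; status 0 (iteration budget)
    # is tolerated for the fully split modes, where the Newton polish must
    # subsequently drive the KKT residuals to tolerance or raise.
    converged = res.status in (1, 2)
    if not converged and opts.mode == "pheflux":
        raise SolverError(f"solver did not converge (status {res.status}: {res.message})")
    vf, vr, u, ve = unpack(res.x)
    vf = np.maximum(vf, opts.flux_floor)
    vr = np.maximum(vr, opts.flux_floor)
    v_f = np.empty(N)
    v_r = np.empty(N)
    v_f[s_idx], v_r[s_idx] = vf, vr
    if nu:
        v_f[u_idx] = u
        v_r[u_idx] = 0.0
    return v_f, v_r, ve, split, res


def _newton_polish(net, g, v_f0, v_r0, v_e0, opts, irr):
    """Polish a fully split optimum on the reduced KKT system; return duals.

    Unknowns: lambda (per metabolite), interior exchange fluxes, and the
    multipliers of the active irreversibility constraints. The primal is an
    explicit function of theta = S^T lambda + alpha, so the system is square
    and Newton converges quadratically near the trust-constr solution.
    """
    M, N, K = net.n_metabolites, net.n_internal, net.n_exchange
    S, S_e = net.S, net.S_e
    floor = opts.flux_floor
    thr = opts.active_flux_threshold
    ge = g / np.e

    # exchange classification
    span = net.ub_ex - net.lb_ex
    fixed_ex = span <= 1e-12
    v_e = v_e0.copy()
    at_lb = (~fixed_ex) & (v_e0 - net.lb_ex <= 1e-7 * (1.0 + np.abs(net.lb_ex)))
    at_ub = (~fixed_ex) & (net.ub_ex - v_e0 <= 1e-7 * (1.0 + np.abs(net.ub_ex)))
    v_e[fixed_ex] = net.lb_ex[fixed_ex]
    v_e[at_lb] = net.lb_ex[at_lb]
    v_e[at_ub] = net.ub_ex[at_ub]
    interior = ~(fixed_ex | at_lb | at_ub)
    ki = np.flatnonzero(interior)

    floored_f = v_f0 <= 10.0 * floor
    floored_r = v_r0 <= 10.0 * floor
    free_stat = ~(floored_f | floored_r)  # reactions with clean stationarity

    active = irr & free_stat & (np.abs(v_f0 - v_r0) <= max(thr, 1e3 * opts.tolerance))
    theta0 = np.zeros(N)
    theta0[free_stat] = 0.5 * (np.log(v_f0[free_stat]) - np.log(v_r0[free_stat]))

    def run(active):
        A = np.flatnonzero(active)
        # initial lambda: least squares over clean, non-active stationarity rows
        rows = np.flatnonzero(free_stat & ~active)
        Amat = np.vstack([S[:, rows].T, S_e[:, ki].T]) if ki.size else S[:, rows].T
        bvec = np.concatenate([theta0[rows], np.zeros(ki.size)]) if ki.size else theta0[rows]
        lam = np.linalg.lstsq(Amat, bvec, rcond=None)[0] if Amat.size else np.zeros(M)
        alpha = np.maximum(0.0, -(S[:, A].T @ lam))
        vei = v_e[ki].copy()

        nA, nI = A.size, ki.size
        for it in range(100):
            theta = S.T @ lam
            theta[A] += alpha
            theta_c = np.clip(theta, -60.0, 60.0)
            vf = np.where(floored_f, floor, ge * np.exp(theta_c))
            vr = np.where(floored_r, floor, ge * np.exp(-theta_c))
            ve_full = v_e.copy()
            ve_full[ki] = vei
            R1 = S @ (vf - vr) + S_e @ ve_full
            R2 = S_e[:, ki].T @ lam
            R3 = theta[A]
            R = np.concatenate([R1, R2, R3])
            scale = 1.0 + max(np.max(np.abs(vf)), np.max(np.abs(vr)))
            if np.max(np.abs(R)) < 1e-12 * scale:
                break
            w = np.where(floored_f, 0.0, vf) + np.where(floored_r, 0.0, vr)
            J = np.zeros((M + nI + nA, M + nI + nA))
            J[:M, :M] = S @ (w[:, None] * S.T)
            J[:M, M : M + nI] = S_e[:, ki]
            J[:M, M + nI :] = S[:, A] * w[A]
            J[M : M + nI, :M] = S_e[:, ki].T
            J[M + nI :, :M] = S[:, A].T
            J[M + nI :, M + nI :] = np.eye(nA)
            try:
                dz = np.linalg.lstsq(J, -R, rcond=None)[0]
            except np.linalg.LinAlgError:
                return None
            dtheta = S.T @ dz[:M]
            dtheta[A] += dz[M + nI :]
            mx = np.max(np.abs(dtheta)) if dtheta.size else 0.0
            step = min(1.0, 2.0 / mx) if mx > 2.0 else 1.0
            lam += step * dz[:M]
            vei += step * dz[M : M + nI]
            alpha += step * dz[M + nI :]
        else:
            return None
        theta = S.T @ lam
        theta[A] += alpha
        vf = np.where(floored_f, floor, ge * np.exp(np.clip(theta, -60, 60)))
        vr = np.where(floored_r, floor, ge * np.exp(-np.clip(theta, -60, 60)))
        ve_full = v_e.copy()
        ve_full[ki] = vei
        return lam, alpha, vf, vr, ve_full, it + 1

    total_it = 0
    for _pass in range(6):
        out = run(active)
        if out is None:
            return None
        lam, alpha_A, vf, vr, ve_full, its = out
        total_it += its
        A = np.flatnonzero(active)
        drop = A[alpha_A < -1e-9]
        viol = np.flatnonzero(irr & free_stat & ~active & (vf - vr < -1e-9))
        if drop.size == 0 and viol.size == 0:
            alpha = np.zeros(N)
            alpha[A] = np.maximum(alpha_A, 0.0)
            return lam, alpha, vf, vr, ve_full, total_it
        active = active.copy()
        active[drop] = False
        active[viol] = True
    return None


def _lstsq_duals(net, v_f, v_r, v_e, opts, split, irr=None):
    """Fallback dual estimate from primal stationarity (least squares)."""
    floor = opts.flux_floor
    clean = split & (v_f > 10 * floor) & (v_r > 10 * floor)
    if irr is None:
        irr = net.irreversible_mask
    blocked = clean & irr & (np.abs(v_f - v_r) <= opts.active_flux_threshold)
    rows = np.flatnonzero(clean & ~blocked)
    theta = 0.5 * (np.log(np.maximum(v_f, floor)) - np.log(np.maximum(v_r, floor)))
    span = net.ub_ex - net.lb_ex
    interior = (span > 1e-12) & (v_e - net.lb_ex > 1e-7) & (net.ub_ex - v_e > 1e-7)
    ki = np.flatnonzero(interior)
    Amat = np.vstack([net.S[:, rows].T, net.S_e[:, ki].T])
    bvec = np.concatenate([theta[rows], np.zeros(ki.size)])
    lam = np.linalg.lstsq(Amat, bvec, rcond=None)[0]
    alpha = np.zeros(net.n_internal)
    alpha[blocked] = np.maximum(0.0, -(net.S[:, np.flatnonzero(blocked)].T @ lam))
    return lam, alpha


def solve(
    net: MetabolicNetwork,
    weights: ReactionWeights,
    ec: ExchangeConstraints | None = None,
    opts: SolverOptions | None = None,
) -> FluxSolution:
    """Solve the weighted maximum-entropy flux program.

    Parameters
    ----------
    net : network (internal/exchange split, bounds, irreversible set).
    weights : positive per-reaction weights g over internal reactions.
    ec : optional measured exchange constraints, applied before solving.
    opts : solver mode and tolerances.

    Returns a :class:`FluxSolution` with unidirectional fluxes, exchange
    fluxes, mass-balance duals ``lambda_`` and irreversibility duals
    ``alpha`` (>= 0; nonzero only on irreversible reactions blocked at zero
    net flux). Raises :class:`SolverError` on infeasibility or
    non-convergence.
    """
    opts = opts or SolverOptions()
    if ec is not None:
        net = apply_exchange_constraints(net, ec)
    if list(weights.reaction_ids) != list(net.internal_ids):
        raise ValueError("weights are not aligned with the network's internal reactions")
    g = np.asarray(weights.g, dtype=float)
    x_feas = _feasibility_check(net)

    v_f, v_r, v_e, split, res = _primal_solve(net, g, opts, x_feas)
    diagnostics: dict = {"backend_status": int(res.status), "backend_iterations": int(res.niter)}

    lam: np.ndarray | None = None
    alpha = np.zeros(net.n_internal)
    if opts.mode in ("teraflux", "all_reversible"):
        irr = net.irreversible_mask if opts.mode == "teraflux" else np.zeros(net.n_internal, bool)
        polished = _newton_polish(net, g, v_f, v_r, v_e, opts, irr)
        if polished is not None:
            lam, alpha, v_f, v_r, v_e, its = polished
            diagnostics["polish"] = "newton"
            diagnostics["polish_iterations"] = int(its)
        else:
            if res.status not in (1, 2):
                raise SolverError(
                    f"solver did not converge (backend status {res.status}) "
                    "and KKT polish failed"
                )
            lam, alpha = _lstsq_duals(net, v_f, v_r, v_e, opts, split, irr)
            diagnostics["polish"] = "lstsq-fallback"
    else:
        lam, _ = _lstsq_duals(net, v_f, v_r, v_e, opts, split)
        diagnostics["polish"] = "pheflux-lstsq"
        diagnostics["note"] = "pheflux mode carries no thermodynamic dual guarantee"

    mass_res = float(np.max(np.abs(net.S @ (v_f - v_r) + net.S_e @ v_e)))
    diagnostics["mass_balance_residual"] = mass_res
    obj = -(
        np.sum(v_f[split] * (np.log(v_f[split]) - np.log(g[split])))
        + np.sum(v_r[split] * (np.log(np.maximum(v_r[split], opts.flux_floor))
                               - np.log(g[split])))
    )
    if not np.all(split):
        u = v_f[~split]
        obj -= np.sum(u * (np.log(np.maximum(u, opts.flux_floor)) - np.log(g[~split])))
    return FluxSolution(
        internal_ids=list(net.internal_ids),
        exchange_ids=list(net.exchange_ids),
        v_f=v_f,
        v_r=v_r,
        v_e=v_e,
        lambda_=lam,
        alpha=alpha,
        objective_value=float(obj),
        status="optimal",
        iterations=int(res.niter),
        mode=opts.mode,
        options=opts,
        diagnostics=diagnostics,
    )


def kkt_report(sol: FluxSolution, net: MetabolicNetwork, weights: ReactionWeights) -> dict:
    """Residuals of the first-order optimality conditions of a solution.

    Reports the maximum stationarity residual (over reactions with clean,
    non-floored splits), the mass-balance residual, the worst complementary
    slackness product, and the per-reaction discrepancy between the two
    Gibbs-energy routes ``-2RT S^T lambda`` and ``RT log(v_r/v_f) + 2RT
    alpha`` (in units of RT; multiply by RT for kJ/mol).
    """
    g = np.asarray(weights.g, dtype=float)
    floor = sol.options.flux_floor
    clean = (sol.v_f > 10 * floor) & (sol.v_r > 10 * floor)
    out: dict[str, float] = {}
    out["mass_balance"] = float(np.max(np.abs(net.S @ sol.v + net.S_e @ sol.v_e)))
    if sol.lambda_ is None:
        out["stationarity"] = np.nan
        return out
    theta = net.S.T @ sol.lambda_ + sol.alpha
    r_f = np.log(sol.v_f[clean]) - np.log(g[clean]) + 1.0 - theta[clean]
    r_r = np.log(sol.v_r[clean]) - np.log(g[clean]) + 1.0 + theta[clean]
    out["stationarity"] = float(max(np.max(np.abs(r_f)), np.max(np.abs(r_r)))) if clean.any() else 0.0
    out["complementary_slackness"] = float(np.max(np.abs(sol.alpha * sol.v))) if len(sol.alpha) else 0.0
    # dual-route discrepancy in RT units: (-2 S^T lambda) vs (log(vr/vf) + 2 alpha)
    route_dual = -2.0 * (net.S.T @ sol.lambda_)
    route_ratio = np.log(sol.v_r[clean]) - np.log(sol.v_f[clean]) + 2.0 * sol.alpha[clean]
    out["dual_route_discrepancy"] = float(
        np.max(np.abs(route_dual[clean] - route_ratio))
    ) if clean.any() else 0.0
    return out
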