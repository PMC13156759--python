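"""Chemical potentials, flux-force audits, cycle detection and TVA.

The mass-balance multipliers of the entropy program double as (scaled)
chemical potentials: mu = -2RT lambda*, hence Delta_G = S^T mu per internal
reaction. Equivalently, from the unidirectional fluxes,
Delta_G = RT ln(v_r/v_f) + 2RT alpha, where alpha >= 0 is the
irreversibility dual — zero on reversible and flux-carrying reactions, and
equal to the unexploited (reverse-direction) driving force / 2RT on
irreversible reactions blocked at zero net flux. Both routes agree at any
converged optimum; active net fluxes always oppose the sign of their
Delta_G (the flux-force relation), which is exactly what rules out
thermodynamically infeasible cycles.

Thermodynamic variability analysis (TVA) bounds each reaction's Delta_G by
linear programming over standard reaction energies (within a +/-2.58 sigma
confidence box around the component-contribution mean) and log metabolite
concentrations (physiological range, default 1 uM - 100 mM), subject to
second-law direction constraints sign(v_j) * Delta_G_j <= -epsilon on every
active reaction. All direction constraints share one variable set, so
infeasibility is a property of the condition, not of a single reaction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import linprog

from .network import MetabolicNetwork
from .solver import FluxSolution

__all__ = [
    "RT_DEFAULT",
    "ThermoState",
    "TVAProblem",
    "TVAResult",
    "potentials_from_duals",
    "flux_force_audit",
    "find_infeasible_cycle",
    "tva_bounds",
    "tva_consistency",
]

R_GAS = 8.314e-3  # kJ mol^-1 K^-1
RT_DEFAULT = R_GAS * 298.15  # ~2.4789 kJ mol^-1 at 25 C


@dataclass(frozen=True)
class ThermoState:
    """Chemical potentials and reaction Gibbs energies of a solution."""

    metabolite_ids: list[str]
    reaction_ids: list[str]
    mu: np.ndarray  # kJ mol^-1, per metabolite
    delta_g: np.ndarray  # kJ mol^-1, per internal reaction (S^T mu)
    delta_g_from_ratio: np.ndarray  # RT ln(v_r/v_f) + 2RT alpha
    RT: float
    active_mask: np.ndarray
    consistent: np.ndarray  # per active reaction: sign(v)*dG < 0

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "reaction_id": self.reaction_ids,
                "delta_g": self.delta_g,
                "delta_g_from_ratio": self.delta_g_from_ratio,
                "active": self.active_mask,
                "flux_force_consistent": self.consistent,
            }
        )


def potentials_from_duals(
    sol: FluxSolution, net: MetabolicNetwork, RT: float = RT_DEFAULT
) -> ThermoState:
    """Recover mu = -2RT lambda* and Delta_G = S^T mu from a converged solve.

    The sign of lambda is pinned at extraction so that active net fluxes
    run against their Delta_G (flux-force); the backend's Lagrangian
    convention never leaks into the API. The ratio route
    RT ln(v_r/v_f) + 2RT alpha is computed alongside and must agree at any
    true optimum (see ``delta_g_from_ratio``).
    """
    if sol.lambda_ is None:
        raise ValueError("solution carries no duals (non-dual mode or failed extraction)")
    lam = np.asarray(sol.lambda_, dtype=float)
    v = sol.v
    active = sol.active_mask

    def build(lam):
        mu = -2.0 * RT * lam
        return mu, net.S.T @ mu

    mu, dg = build(lam)
    if active.any():
        aligned = np.sum(np.sign(v[active]) * dg[active] < 0)
        if aligned < active.sum() - aligned:  # majority violated: flip convention
            lam = -lam
            mu, dg = build(lam)
    floor = sol.options.flux_floor
    clean = (sol.v_f > 10 * floor) & (sol.v_r > 10 * floor)
    ratio = np.full(net.n_internal, np.nan)
    ratio[clean] = RT * (np.log(sol.v_r[clean]) - np.log(sol.v_f[clean])) + 2.0 * RT * sol.alpha[clean]
    consistent = np.zeros(net.n_internal, dtype=bool)
    consistent[active] = np.sign(v[active]) * dg[active] < 0
    return ThermoState(
        metabolite_ids=list(net.metabolite_ids),
        reaction_ids=list(net.internal_ids),
        mu=mu,
        delta_g=dg,
        delta_g_from_ratio=ratio,
        RT=RT,
        active_mask=active,
        consistent=consistent,
    )


@dataclass(frozen=True)
class FluxForceReport:
    """Quadrant classification of active reactions against their Delta_G."""

    reaction_ids: list[str]
    quadrant: list[str]  # "consistent", "violation", "inactive", "blocked"
    n_active: int
    n_violations: int
    violations: list[str]
    blocked: dict[str, float]  # blocked irreversible reactions -> alpha


def flux_force_audit(
    sol: FluxSolution,
    thermo: ThermoState,
    threshold: float | None = None,
    net: MetabolicNetwork | None = None,
) -> FluxForceReport:
    """Classify each active reaction by the sign pair (v, Delta_G).

    (v>0, dG<0) and (v<0, dG>0) are consistent; the other two quadrants are
    second-law violations. Reactions with |v| <= threshold are not
    classified; blocked irreversible reactions are reported separately with
    their alpha duals.
    """
    thr = sol.options.active_flux_threshold if threshold is None else threshold
    v = sol.v
    dg = thermo.delta_g
    quadrant: list[str] = []
    violations: list[str] = []
    blocked: dict[str, float] = {}
    irr = net.irreversible_mask if net is not None else np.zeros(len(v), dtype=bool)
    for j, rid in enumerate(sol.internal_ids):
        if abs(v[j]) <= thr:
            if irr[j] and sol.alpha[j] > 0:
                quadrant.append("blocked")
                blocked[rid] = float(sol.alpha[j])
            else:
                quadrant.append("inactive")
            continue
        if np.sign(v[j]) * dg[j] < 0:
            quadrant.append("consistent")
        else:
            quadrant.append("violation")
            violations.append(rid)
    n_active = sum(q in ("consistent", "violation") for q in quadrant)
    return FluxForceReport(
        reaction_ids=list(sol.internal_ids),
        quadrant=quadrant,
        n_active=n_active,
        n_violations=len(violations),
        violations=violations,
        blocked=blocked,
    )


def find_infeasible_cycle(
    net: MetabolicNetwork, v: np.ndarray, threshold: float = 1e-6
) -> np.ndarray | None:
    """Search for a thermodynamically infeasible cycle in a net flux vector.

    A witness is a nonzero circulation y with S y = 0 (internal columns
    only; exchanges excluded), supported on active reactions
    (|v_j| > threshold), with sign(y_j) agreeing with sign(v_j) on its
    support, normalised to ||y||_1 = 1. Found by a small LP in the
    sign-aligned variables w_j = sign(v_j) y_j >= 0. Returns the witness
    (length = internal reactions) or None.
    """
    v = np.asarray(v, dtype=float)
    act = np.flatnonzero(np.abs(v) > threshold)
    if act.size == 0:
        return None
    signs = np.sign(v[act])
    A_eq = net.S[:, act] * signs  # columns scaled: S diag(sign) w = 0
    A_eq = np.vstack([A_eq, np.ones(act.size)])  # sum w = 1 (l1 normalisation)
    b_eq = np.zeros(net.n_metabolites + 1)
    b_eq[-1] = 1.0
    res = linprog(
        np.zeros(act.size), A_eq=A_eq, b_eq=b_eq,
        bounds=[(0.0, None)] * act.size, method="highs",
    )
    if not res.success:
        return None
    y = np.zeros(net.n_internal)
    y[act] = signs * res.x
    y[np.abs(y) < 1e-12] = 0.0
    return y


# ----------------------------------------------------------------- TVA

DEFAULT_EXCLUDED = ("h2o", "h2o_c", "h2o_e", "h", "h_c", "h_e", "h_p", "h2o_p")


@dataclass(frozen=True)
class TVAProblem:
    """Inputs of thermodynamic variability analysis for one condition.

    gamma/sigma: mean and SD of the standard biochemical reaction Gibbs
    energies (kJ/mol) per internal reaction id; directions: sign(v) on
    active reactions from a flux solution; conc_overrides pins individual
    metabolites to tighter ln-concentration intervals.
    """

    net: MetabolicNetwork
    gamma: dict[str, float]
    sigma: dict[str, float]
    directions: dict[str, int] = field(default_factory=dict)
    ci_multiplier: float = 2.58
    ln_conc_bounds: tuple[float, float] = (np.log(1e-6), np.log(1e-1))
    conc_overrides: dict[str, tuple[float, float]] = field(default_factory=dict)
    epsilon: float = 1e-3
    RT: float = RT_DEFAULT
    excluded_metabolites: tuple[str, ...] = DEFAULT_EXCLUDED

    def __post_init__(self):
        lo, hi = self.ln_conc_bounds
        if lo > hi:
            raise ValueError("ln concentration bounds out of order")
        if self.epsilon <= 0:
            raise ValueError("epsilon must be positive")
        for rid in self.net.internal_ids:
            if rid not in self.gamma or rid not in self.sigma:
                raise ValueError(f"missing gamma/sigma for reaction {rid}")
            if self.sigma[rid] < 0:
                raise ValueError(f"negative sigma for reaction {rid}")
        for rid in self.directions:
            self.net.internal_index(rid)

    @classmethod
    def from_solution(cls, net, sol: FluxSolution, gamma, sigma, **kw) -> "TVAProblem":
        directions = {
            rid: int(np.sign(vj))
            for rid, vj, act in zip(sol.internal_ids, sol.v, sol.active_mask)
            if act
        }
        return cls(net=net, gamma=gamma, sigma=sigma, directions=directions, **kw)


@dataclass(frozen=True)
class TVAResult:
    """Per-reaction feasible Gibbs-energy intervals."""

    reaction_ids: list[str]
    dg_min: np.ndarray
    dg_max: np.ndarray
    feasible: bool

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {"reaction_id": self.reaction_ids, "dG_min": self.dg_min, "dG_max": self.dg_max}
        )


def _tva_system(prob: TVAProblem):
    """Shared LP data: variables are [dG0 per reaction, ln c per metabolite]."""
    net = prob.net
    N = net.n_internal
    mets = [i for i, m in enumerate(net.metabolite_ids) if m not in prob.excluded_metabolites]
    n_c = len(mets)
    nvar = N + n_c
    # Delta_G_j = dG0_j + RT * sum_i S_ij ln c_i  (row per reaction)
    G = np.zeros((N, nvar))
    G[:, :N] = np.eye(N)
    G[:, N:] = prob.RT * net.S[mets, :].T
    lb = np.empty(nvar)
    ub = np.empty(nvar)
    for j, rid in enumerate(net.internal_ids):
        half = prob.ci_multiplier * prob.sigma[rid]
        lb[j] = prob.gamma[rid] - half
        ub[j] = prob.gamma[rid] + half
    lo, hi = prob.ln_conc_bounds
    lb[N:], ub[N:] = lo, hi
    for idx, i in enumerate(mets):
        mid = net.metabolite_ids[i]
        if mid in prob.conc_overrides:
            lb[N + idx], ub[N + idx] = prob.conc_overrides[mid]
    # direction constraints: sign_j * G_j x <= -epsilon
    rows, rhs = [], []
    for rid, s in prob.directions.items():
        if s == 0:
            continue
        j = net.internal_index(rid)
        rows.append(s * G[j])
        rhs.append(-prob.epsilon)
    A_ub = np.vstack(rows) if rows else None
    b_ub = np.array(rhs) if rows else None
    return G, A_ub, b_ub, list(zip(lb, ub))


def tva_bounds(prob: TVAProblem, reactions: list[str] | None = None) -> TVAResult:
    """Min/max Delta_G per reaction under the shared TVA constraint system.

    Solves two LPs per reaction. If the shared constraint set is infeasible
    the result carries ``feasible=False`` and NaN bounds for every reaction
    (infeasibility is global: no concentration/energy assignment supports
    the requested directions).
    """
    net = prob.net
    G, A_ub, b_ub, bounds = _tva_system(prob)
    rids = list(net.internal_ids) if reactions is None else list(reactions)
    # shared feasibility first
    feas = linprog(np.zeros(G.shape[1]), A_ub=A_ub, b_ub=b_ub, bounds=bounds, method="highs")
    if feas.status == 2:
        nan = np.full(len(rids), np.nan)
        return TVAResult(rids, nan, nan.copy(), feasible=False)
    if not feas.success:
        raise RuntimeError(f"TVA feasibility LP failed: {feas.message}")
    dg_min = np.empty(len(rids))
    dg_max = np.empty(len(rids))
    for out_i, rid in enumerate(rids):
        j = net.internal_index(rid)
        for sense, store in ((1.0, dg_min), (-1.0, dg_max)):
            res = linprog(sense * G[j], A_ub=A_ub, b_ub=b_ub, bounds=bounds, method="highs")
            if not res.success:
                raise RuntimeError(f"TVA LP failed for {rid}: {res.message}")
            store[out_i] = sense * res.fun
    return TVAResult(rids, dg_min, dg_max, feasible=True)


def tva_consistency(
    result: TVAResult,
    thermo: ThermoState,
    exclude: tuple[str, ...] = (),
    slack: float = 1e-6,
) -> float:
    """Fraction of active reactions whose inferred Delta_G lies in its TVA band.

    ``exclude`` lists reaction ids (e.g. extracellular transports) left out
    of the score. Raises on an infeasible TVA result.
    """
    if not result.feasible:
        raise ValueError("TVA system infeasible; consistency fraction undefined")
    idx = {rid: i for i, rid in enumerate(result.reaction_ids)}
    hits = total = 0
    for j, rid in enumerate(thermo.reaction_ids):
        if rid in exclude or not thermo.active_mask[j] or rid not in idx:
            continue
        total += 1
        i = idx[rid]
        if result.dg_min[i] - slack <= thermo.delta_g[j] <= result.dg_max[i] + slack:
            hits += 1
    if total == 0:
        raise ValueError("no active scored reactions")
    return hits / total
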