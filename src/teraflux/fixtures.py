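"""Synthetic networks, sampled fluxomes and simulated expression.

Everything needed to exercise the solver without downloads: the worked
two-metabolite loop network, a pair of antiparallel reactions forming a
textbook infeasible cycle (the fumarate-reductase / succinate-dehydrogenase
motif), a cofactor-coupled *feasible* cycle (glyoxylate-shunt motif, where
one leg consumes a cofactor regenerated across the boundary), and seeded
random networks guaranteed to contain a null-space circulation.

Fluxomes are drawn uniformly from the steady-state polytope with a simple
hit-and-run chain (null-space parameterisation, fixed burn-in and
thinning); simulated expression sets g = |v| per reaction, the convention
used to stress-test cycle elimination.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import null_space
from scipy.optimize import linprog

from .expression import ReactionWeights, weights_from_fluxes
from .network import MetabolicNetwork, build_fig1_network

__all__ = [
    "FixtureSpec",
    "make_network",
    "make_single_reaction_network",
    "sample_fluxomes",
    "expression_from_fluxes",
]

KINDS = ("fig1", "infeasible_pair", "feasible_coupled_loop", "random_loopy")


@dataclass(frozen=True)
class FixtureSpec:
    """Parameters of a synthetic network / sampling run.

    bounds: wide symmetric internal bounds (mmol g^-1 h^-1) mimicking the
    unconstrained-sampling regime in which infeasible cycles blow up;
    uptake_cap: limit on the substrate uptake exchange.
    """

    kind: str = "fig1"
    seed: int = 0
    n_chain: int = 4  # chain length of the random_loopy backbone
    n_extra: int = 2  # extra random reversible reactions
    bounds: float = 30000.0
    uptake_cap: float = 10.0
    burn_in: int = 1000
    thinning: int = 10

    def __post_init__(self):
        if self.kind not in KINDS:
            raise ValueError(f"kind must be one of {KINDS}, got {self.kind!r}")
        if self.bounds <= 0 or self.uptake_cap <= 0:
            raise ValueError("bounds and uptake_cap must be positive")


def _infeasible_pair(spec: FixtureSpec) -> MetabolicNetwork:
    # A <-> B twice over, with no cosubstrate: the internal null space
    # contains the circulation (1, 1) over the antiparallel pair.
    b = spec.bounds
    return MetabolicNetwork(
        metabolite_ids=["A", "B"],
        internal_ids=["fwd_AB", "rev_BA"],
        exchange_ids=["EX_A_in", "EX_B_out"],
        S=np.array([[-1.0, 1.0], [1.0, -1.0]]),
        S_e=np.array([[1.0, 0.0], [0.0, -1.0]]),
        lb_int=np.array([-b, -b]),
        ub_int=np.array([b, b]),
        lb_ex=np.array([0.0, 0.0]),
        ub_ex=np.array([spec.uptake_cap, b]),
        name="infeasible_pair",
    )


def _feasible_coupled_loop(spec: FixtureSpec) -> MetabolicNetwork:
    # A -> B consumes cofactor P (producing Q); B -> A returns. The
    # circulation over (use_P, return_BA) leaves P/Q unbalanced, so only
    # boundary turnover of the cofactor can sustain the cycle: it is
    # thermodynamically feasible, driven by the cofactor's potential drop.
    b = spec.bounds
    u = spec.uptake_cap
    return MetabolicNetwork(
        metabolite_ids=["A", "B", "P", "Q"],
        internal_ids=["use_P", "return_BA"],
        exchange_ids=["EX_A_in", "EX_B_out", "EX_P_in", "EX_Q_out"],
        # use_P: A + P -> B + Q ; return_BA: B -> A
        S=np.array([[-1.0, 1.0], [1.0, -1.0], [-1.0, 0.0], [1.0, 0.0]]),
        S_e=np.array(
            [[1.0, 0.0, 0.0, 0.0], [0.0, -1.0, 0.0, 0.0], [0.0, 0.0, 1.0, 0.0], [0.0, 0.0, 0.0, -1.0]]
        ),
        lb_int=np.array([0.0, 0.0]),
        ub_int=np.array([b, b]),
        # A uptake fixed at u/2, cofactor supply fixed above it: the excess
        # must return through the B -> A leg, keeping the coupled cycle hot.
        lb_ex=np.array([0.5 * u, 0.0, 1.5 * u, 0.0]),
        ub_ex=np.array([0.5 * u, b, 1.5 * u, b]),
        name="feasible_coupled_loop",
    )


def _random_loopy(spec: FixtureSpec) -> MetabolicNetwork:
    """Seeded random chain network with a planted three-reaction circulation.

    The planted cycle runs through two dedicated off-chain metabolites, so
    at steady state all three legs carry one common cycle flux; the
    internal null space therefore always contains the aligned circulation
    (1, 1, 1) on those columns.
    """
    rng = np.random.default_rng(spec.seed)
    m = max(3, spec.n_chain)
    mets = [f"M{i}" for i in range(m)] + ["CA", "CB"]
    idx = {x: i for i, x in enumerate(mets)}
    cols: list[np.ndarray] = []
    ids: list[str] = []
    lbs: list[float] = []

    def add(rid, stoich, lb):
        col = np.zeros(len(mets))
        for met, c in stoich.items():
            col[idx[met]] = c
        cols.append(col)
        ids.append(rid)
        lbs.append(lb)

    for i in range(m - 1):  # backbone chain, reversible
        add(f"chain_{i}", {f"M{i}": -1.0, f"M{i+1}": 1.0}, -spec.bounds)
    anchor = int(rng.integers(0, m))
    # planted cycle: Manchor -> CA -> CB -> Manchor, all reversible
    add("cyc_1", {f"M{anchor}": -1.0, "CA": 1.0}, -spec.bounds)
    add("cyc_2", {"CA": -1.0, "CB": 1.0}, -spec.bounds)
    add("cyc_3", {"CB": -1.0, f"M{anchor}": 1.0}, -spec.bounds)
    for e in range(spec.n_extra):  # random reversible shortcuts on the chain
        i, j = rng.choice(m, size=2, replace=False)
        add(f"extra_{e}", {f"M{i}": -1.0, f"M{j}": 1.0}, -spec.bounds)
    S = np.column_stack(cols)
    S_e = np.zeros((len(mets), 2))
    S_e[idx["M0"], 0] = 1.0
    S_e[idx[f"M{m-1}"], 1] = -1.0
    return MetabolicNetwork(
        metabolite_ids=mets,
        internal_ids=ids,
        exchange_ids=["EX_in", "EX_out"],
        S=S,
        S_e=S_e,
        lb_int=np.array(lbs),
        ub_int=np.full(len(ids), spec.bounds),
        lb_ex=np.array([0.0, 0.0]),
        ub_ex=np.array([spec.uptake_cap, spec.bounds]),
        name=f"random_loopy_seed{spec.seed}",
    )


def make_network(spec: FixtureSpec) -> MetabolicNetwork:
    """Build the fixture network named by ``spec.kind``."""
    if spec.kind == "fig1":
        return build_fig1_network()
    if spec.kind == "infeasible_pair":
        return _infeasible_pair(spec)
    if spec.kind == "feasible_coupled_loop":
        return _feasible_coupled_loop(spec)
    return _random_loopy(spec)


def make_single_reaction_network(b: float, big: float = 1e6) -> MetabolicNetwork:
    """One reversible reaction A <=> B with net flux forced to ``b`` by a
    fixed uptake; the analytic-oracle test bench."""
    return MetabolicNetwork(
        metabolite_ids=["A", "B"],
        internal_ids=["conv"],
        exchange_ids=["EX_A_in", "EX_B_out"],
        S=np.array([[-1.0], [1.0]]),
        S_e=np.array([[1.0, 0.0], [0.0, -1.0]]),
        lb_int=np.array([-big]),
        ub_int=np.array([big]),
        lb_ex=np.array([b, -big]),
        ub_ex=np.array([b, big]),
        name="single_reaction",
    )


# ------------------------------------------------------------- sampling

def _interior_point(A, lb, ub, rng):
    """A point well inside {A x = 0, lb <= x <= ub}: average of LP vertices
    found along random objectives."""
    n = A.shape[1]
    pts = []
    for _ in range(6):
        c = rng.standard_normal(n)
        res = linprog(c, A_eq=A, b_eq=np.zeros(A.shape[0]), bounds=list(zip(lb, ub)), method="highs")
        if res.status == 2:
            raise ValueError("empty steady-state polytope")
        if res.success:
            pts.append(res.x)
    if not pts:
        raise ValueError("could not locate a feasible point")
    return np.mean(pts, axis=0)


def sample_fluxomes(
    net: MetabolicNetwork,
    n: int,
    spec: FixtureSpec | None = None,
    seed: int | None = None,
) -> np.ndarray:
    """Uniform-ish hit-and-run samples of full flux vectors [v_int, v_e].

    The chain walks the null space of the combined stoichiometry, so every
    returned vector is mass-balanced to numerical precision; burn-in and
    thinning come from ``spec``. Deterministic for a fixed seed.
    Returns an array of shape (n, N + K).
    """
    spec = spec or FixtureSpec(kind="fig1")
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    A = np.hstack([net.S, net.S_e])
    lb = np.concatenate([net.lb_int, net.lb_ex])
    ub = np.concatenate([net.ub_int, net.ub_ex])
    # pinned coordinates (fixed exchanges) leave no room to move: treat
    # them as extra equality rows so the walk stays in the true interior
    pinned = ub - lb <= 1e-12
    rows = [A] + [np.eye(A.shape[1])[i][None, :] for i in np.flatnonzero(pinned)]
    basis = null_space(np.vstack(rows))
    x = _interior_point(A, lb, ub, rng)
    if basis.shape[1] == 0:  # polytope is a single point
        return np.tile(x, (n, 1))
    d_dim = basis.shape[1]
    out = np.empty((n, A.shape[1]))
    kept = 0
    total = spec.burn_in + n * spec.thinning
    for step in range(10 * total + 1000):
        if kept >= n:
            break
        t = basis @ rng.standard_normal(d_dim)
        nrm = np.linalg.norm(t)
        if nrm < 1e-14:
            continue
        t /= nrm
        # segment of x + s t inside the box
        with np.errstate(divide="ignore", invalid="ignore"):
            lo_s = np.where(t > 1e-12, (lb - x) / t, np.where(t < -1e-12, (ub - x) / t, -np.inf))
            hi_s = np.where(t > 1e-12, (ub - x) / t, np.where(t < -1e-12, (lb - x) / t, np.inf))
        s_min = np.max(lo_s)
        s_max = np.min(hi_s)
        if not np.isfinite(s_min) or not np.isfinite(s_max) or s_max <= s_min:
            continue
        x = x + rng.uniform(s_min, s_max) * t
        if step >= spec.burn_in and (step - spec.burn_in) % spec.thinning == 0:
            out[kept] = x
            kept += 1
    if kept < n:
        raise RuntimeError("hit-and-run failed to advance")
    return out


def expression_from_fluxes(
    net: MetabolicNetwork, v_full: np.ndarray, floor: float = 1e-6
) -> ReactionWeights:
    """Simulated expression g = max(|v|, floor) from a sampled flux vector.

    Accepts either a full vector [v_int, v_e] or just the internal part.
    """
    v_full = np.asarray(v_full, dtype=float)
    v_int = v_full[: net.n_internal] if v_full.size == net.n_internal + net.n_exchange else v_full
    return weights_from_fluxes(net, v_int, floor=floor)
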