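"""Metabolic network containers and SBML I/O.

A genome-scale model is held as an explicit split between *internal*
reactions (columns of ``S``) and *exchange* reactions crossing the system
boundary (columns of ``S_e``), so that the steady-state mass balance reads

    S (v_f - v_r) + S_e v_e = 0.

A reaction is classified as exchange when its stoichiometry sits on one
side only (pure source or pure sink), the standard boundary convention of
BiGG-style models; demand/sink reactions therefore count as exchange.
Internal reactions with a non-negative lower bound form the irreversible
set ``I``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "MetabolicNetwork",
    "ExchangeConstraints",
    "load_sbml",
    "write_sbml",
    "build_fig1_network",
    "apply_exchange_constraints",
]


@dataclass(frozen=True)
class MetabolicNetwork:
    """Stoichiometry, bounds and gene associations of a metabolic model.

    Attributes
    ----------
    metabolite_ids : list of str, length M
    internal_ids : list of str, length N — internal reaction identifiers.
    exchange_ids : list of str, length K — boundary reaction identifiers.
    S : ndarray (M, N) — internal stoichiometric matrix.
    S_e : ndarray (M, K) — exchange stoichiometric matrix.
    lb_int, ub_int : ndarray (N,) — internal flux bounds, mmol g^-1 h^-1.
    lb_ex, ub_ex : ndarray (K,) — exchange flux bounds.
    gpr_rules : list of str, length N — boolean gene rules ("" if none).
    name : str — free-form model name.
    """

    metabolite_ids: list[str]
    internal_ids: list[str]
    exchange_ids: list[str]
    S: np.ndarray
    S_e: np.ndarray
    lb_int: np.ndarray
    ub_int: np.ndarray
    lb_ex: np.ndarray
    ub_ex: np.ndarray
    gpr_rules: list[str] = field(default_factory=list)
    name: str = "model"

    def __post_init__(self):
        object.__setattr__(self, "S", np.asarray(self.S, dtype=float))
        object.__setattr__(self, "S_e", np.asarray(self.S_e, dtype=float))
        for attr in ("lb_int", "ub_int", "lb_ex", "ub_ex"):
            object.__setattr__(self, attr, np.asarray(getattr(self, attr), dtype=float))
        if not self.gpr_rules:
            object.__setattr__(self, "gpr_rules", [""] * self.n_internal)
        self.validate()

    # -- dimensions -------------------------------------------------
    @property
    def n_metabolites(self) -> int:
        return len(self.metabolite_ids)

    @property
    def n_internal(self) -> int:
        return len(self.internal_ids)

    @property
    def n_exchange(self) -> int:
        return len(self.exchange_ids)

    @property
    def irreversible_mask(self) -> np.ndarray:
        """Boolean mask over internal reactions: lower bound >= 0."""
        return self.lb_int >= 0.0

    @property
    def irreversible_set(self) -> list[str]:
        return [r for r, m in zip(self.internal_ids, self.irreversible_mask) if m]

    def validate(self) -> None:
        M, N, K = self.n_metabolites, self.n_internal, self.n_exchange
        if self.S.shape != (M, N):
            raise ValueError(f"S has shape {self.S.shape}, expected {(M, N)}")
        if self.S_e.shape != (M, K):
            raise ValueError(f"S_e has shape {self.S_e.shape}, expected {(M, K)}")
        if N == 0:
            raise ValueError("model has zero internal reactions")
        if np.any(self.lb_int > self.ub_int) or np.any(self.lb_ex > self.ub_ex):
            bad = [r for r, lo, hi in zip(self.internal_ids, self.lb_int, self.ub_int) if lo > hi]
            bad += [r for r, lo, hi in zip(self.exchange_ids, self.lb_ex, self.ub_ex) if lo > hi]
            raise ValueError(f"lower bound exceeds upper bound for: {bad}")
        if N and not np.all(np.any(self.S != 0.0, axis=0)):
            raise ValueError("internal reaction with all-zero stoichiometry")
        if K and not np.all(np.any(self.S_e != 0.0, axis=0)):
            raise ValueError("exchange reaction touching no metabolite")
        if len(self.gpr_rules) != N:
            raise ValueError("gpr_rules length must match internal reactions")

    # -- lookups ----------------------------------------------------
    def exchange_index(self, rid: str) -> int:
        try:
            return self.exchange_ids.index(rid)
        except ValueError:
            raise KeyError(f"unknown exchange reaction: {rid}") from None

    def internal_index(self, rid: str) -> int:
        try:
            return self.internal_ids.index(rid)
        except ValueError:
            raise KeyError(f"unknown internal reaction: {rid}") from None


@dataclass(frozen=True)
class ExchangeConstraints:
    """Measured boundary fluxes and bound overrides.

    ``fixed`` pins an exchange flux to a measured value (lb = ub = value),
    e.g. glucose uptake and growth rate. ``bounded`` overrides the interval
    of an exchange. ``uptake_caps`` accepts positive uptake *magnitudes* and
    resolves the BiGG sign convention internally: a cap of 10 becomes the
    interval (-10, 0).
    """

    fixed: dict[str, float] = field(default_factory=dict)
    bounded: dict[str, tuple[float, float]] = field(default_factory=dict)
    uptake_caps: dict[str, float] = field(default_factory=dict)

    @classmethod
    def from_dict(cls, d: dict) -> "ExchangeConstraints":
        return cls(
            fixed={k: float(v) for k, v in (d.get("fixed") or {}).items()},
            bounded={k: (float(v[0]), float(v[1])) for k, v in (d.get("bounded") or {}).items()},
            uptake_caps={k: float(v) for k, v in (d.get("uptake_caps") or {}).items()},
        )


def apply_exchange_constraints(net: MetabolicNetwork, ec: ExchangeConstraints) -> MetabolicNetwork:
    """Return a copy of *net* with exchange bounds resolved from *ec*.

    Fixed exchanges become equalities; capped uptakes become (-cap, 0);
    internal bounds are untouched. Raises ``KeyError`` for unknown ids and
    ``ValueError`` for fixed values outside the model bounds.
    """
    lb = net.lb_ex.copy()
    ub = net.ub_ex.copy()
    for rid, val in ec.fixed.items():
        k = net.exchange_index(rid)
        if not (net.lb_ex[k] - 1e-9 <= val <= net.ub_ex[k] + 1e-9):
            raise ValueError(
                f"fixed value {val} for {rid} outside model bounds "
                f"[{net.lb_ex[k]}, {net.ub_ex[k]}]"
            )
        lb[k] = ub[k] = val
    for rid, (lo, hi) in ec.bounded.items():
        k = net.exchange_index(rid)
        lb[k], ub[k] = lo, hi
    for rid, cap in ec.uptake_caps.items():
        k = net.exchange_index(rid)
        lb[k], ub[k] = -abs(cap), 0.0
    return replace(net, lb_ex=lb, ub_ex=ub)


def build_fig1_network() -> MetabolicNetwork:
    """The two-metabolite loop network used as the worked toy example.

    v1: uptake of X (exchange, positive = uptake into the system);
    v2: X <=> Y, reversible; v3: Y -> X, irreversible (the problematic
    return leg of the loop); v4: export of Y (exchange). Only v3 is in the
    irreversible set.
    """
    return MetabolicNetwork(
        metabolite_ids=["X", "Y"],
        internal_ids=["v2", "v3"],
        exchange_ids=["v1", "v4"],
        S=np.array([[-1.0, 1.0], [1.0, -1.0]]),
        S_e=np.array([[1.0, 0.0], [0.0, -1.0]]),
        lb_int=np.array([-1000.0, 0.0]),
        ub_int=np.array([1000.0, 1000.0]),
        lb_ex=np.array([0.0, 0.0]),
        ub_ex=np.array([1000.0, 1000.0]),
        gpr_rules=["", ""],
        name="fig1_loop",
    )


# ---------------------------------------------------------------- SBML I/O

def _to_cobra(net: MetabolicNetwork):
    import cobra

    model = cobra.Model(net.name)
    mets = {mid: cobra.Metabolite(mid, compartment="c") for mid in net.metabolite_ids}
    model.add_metabolites(list(mets.values()))
    rxns = []
    for j, rid in enumerate(net.internal_ids):
        r = cobra.Reaction(rid, lower_bound=float(net.lb_int[j]), upper_bound=float(net.ub_int[j]))
        r.add_metabolites(
            {mets[m]: net.S[i, j] for i, m in enumerate(net.metabolite_ids) if net.S[i, j] != 0}
        )
        if net.gpr_rules[j]:
            r.gene_reaction_rule = net.gpr_rules[j]
        rxns.append(r)
    for k, rid in enumerate(net.exchange_ids):
        r = cobra.Reaction(rid, lower_bound=float(net.lb_ex[k]), upper_bound=float(net.ub_ex[k]))
        r.add_metabolites(
            {mets[m]: net.S_e[i, k] for i, m in enumerate(net.metabolite_ids) if net.S_e[i, k] != 0}
        )
        rxns.append(r)
    model.add_reactions(rxns)
    return model


def _from_cobra(model, boundary_ids: tuple[str, ...] = ()) -> MetabolicNetwork:
    met_ids = [m.id for m in model.metabolites]
    met_index = {m: i for i, m in enumerate(met_ids)}
    internal, exchange = [], []
    for r in model.reactions:
        coeffs = list(r.metabolites.values())
        if not coeffs:
            raise ValueError(f"reaction {r.id} has empty stoichiometry")
        one_sided = all(c > 0 for c in coeffs) or all(c < 0 for c in coeffs)
        (exchange if one_sided or r.id in boundary_ids else internal).append(r)
    if not internal:
        raise ValueError("model has zero internal reactions")
    M = len(met_ids)
    S = np.zeros((M, len(internal)))
    S_e = np.zeros((M, len(exchange)))
    for j, r in enumerate(internal):
        for m, c in r.metabolites.items():
            S[met_index[m.id], j] = c
    for k, r in enumerate(exchange):
        for m, c in r.metabolites.items():
            S_e[met_index[m.id], k] = c
    return MetabolicNetwork(
        metabolite_ids=met_ids,
        internal_ids=[r.id for r in internal],
        exchange_ids=[r.id for r in exchange],
        S=S,
        S_e=S_e,
        lb_int=np.array([r.lower_bound for r in internal]),
        ub_int=np.array([r.upper_bound for r in internal]),
        lb_ex=np.array([r.lower_bound for r in exchange]),
        ub_ex=np.array([r.upper_bound for r in exchange]),
        gpr_rules=[r.gene_reaction_rule or "" for r in internal],
        name=model.id or "model",
    )


def load_sbml(path, boundary_ids: tuple[str, ...] = ()) -> MetabolicNetwork:
    """Load an SBML (Level 2/3 + fbc) model into a :class:`MetabolicNetwork`.

    ``boundary_ids`` forces listed reactions (e.g. a biomass pseudo-reaction
    fixed to a measured growth rate) into the exchange partition even if
    they carry two-sided stoichiometry.
    """
    from cobra.io import read_sbml_model

    model = read_sbml_model(str(path))
    return _from_cobra(model, boundary_ids=tuple(boundary_ids))


def write_sbml(net: MetabolicNetwork, path) -> None:
    """Write the network as SBML Level 3 + fbc (round-trips with load_sbml)."""
    from cobra.io import write_sbml_model

    write_sbml_model(_to_cobra(net), str(path))
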