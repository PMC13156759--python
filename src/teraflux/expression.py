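"""Gene expression to per-reaction weights via GPR rules.

The solver's reference distribution ``g`` assigns each internal reaction
the expression level of its catalysing enzyme complex: AND within a rule
takes the minimum operand (a complex is limited by its scarcest subunit),
OR takes the sum (isozymes add capacity). Reactions without a rule, or
rules over unmeasured genes, fall back to a small positive floor so that
log g stays finite without letting unmeasured reactions dominate.
"""

from __future__ import annotations

import ast
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .network import MetabolicNetwork

__all__ = [
    "ExpressionProfile",
    "ReactionWeights",
    "read_expression_table",
    "evaluate_gpr",
    "map_weights",
    "weights_from_fluxes",
]

DEFAULT_FLOOR_FRACTION = 1e-6  # of the median nonzero evaluated weight


@dataclass(frozen=True)
class ExpressionProfile:
    """Normalized expression values (TPM/FPKM/quantile units) per gene."""

    values: dict[str, float] = field(default_factory=dict)

    def __post_init__(self):
        for gene, v in self.values.items():
            if not np.isfinite(v) or v < 0:
                raise ValueError(f"expression for {gene} must be finite and >= 0, got {v}")

    def scaled(self, factor: float) -> "ExpressionProfile":
        return ExpressionProfile({g: v * factor for g, v in self.values.items()})


@dataclass(frozen=True)
class ReactionWeights:
    """Positive per-reaction weights g over internal reactions."""

    reaction_ids: list[str]
    g: np.ndarray
    floor_value: float
    normalized: bool = False

    def __post_init__(self):
        object.__setattr__(self, "g", np.asarray(self.g, dtype=float))
        if np.any(self.g <= 0) or not np.all(np.isfinite(self.g)):
            raise ValueError("all weights must be positive and finite (log g must exist)")
        if self.normalized and abs(self.g.sum() - 1.0) > 1e-8:
            raise ValueError("normalized weights must sum to 1")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"reaction_id": self.reaction_ids, "g": self.g})

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def read_expression_table(path) -> ExpressionProfile:
    """Read a two-column TSV (gene_id, value); header optional.

    Duplicate gene ids are aggregated by their mean. Negative values are
    rejected.
    """
    df = pd.read_csv(path, sep="\t", header=None, dtype=str, comment="#")
    if df.shape[1] < 2:
        raise ValueError(f"{path}: expected two tab-separated columns")
    df = df.iloc[:, :2]
    df.columns = ["gene_id", "value"]
    # tolerate a header row: first row whose value does not parse as float
    first = df.iloc[0]["value"]
    try:
        float(first)
    except (TypeError, ValueError):
        df = df.iloc[1:]
    if df.empty:
        raise ValueError(f"{path}: no data rows")
    try:
        vals = df["value"].astype(float)
    except ValueError as exc:
        raise ValueError(f"{path}: malformed numeric value ({exc})") from None
    if vals.isna().any() or df["gene_id"].isna().any():
        raise ValueError(f"{path}: malformed rows with missing fields")
    if (vals < 0).any():
        bad = df.loc[vals < 0, "gene_id"].tolist()
        raise ValueError(f"{path}: negative expression for {bad}")
    merged = vals.groupby(df["gene_id"]).mean()
    return ExpressionProfile(merged.to_dict())


def _eval_node(node: ast.AST, values: dict[str, float], floor: float) -> float:
    if isinstance(node, ast.BoolOp):
        parts = [_eval_node(v, values, floor) for v in node.values]
        return min(parts) if isinstance(node.op, ast.And) else sum(parts)
    if isinstance(node, ast.Name):
        return values.get(node.id, floor)
    raise ValueError(f"unsupported GPR element: {ast.dump(node)}")


def evaluate_gpr(rule: str, profile: ExpressionProfile, floor: float) -> float:
    """Evaluate a boolean GPR rule to a positive weight.

    AND maps to min, OR to sum; a missing gene contributes the floor and an
    empty rule evaluates to the floor.
    """
    if floor <= 0:
        raise ValueError("floor must be positive")
    rule = (rule or "").strip()
    if not rule:
        return floor
    from cobra.core.gene import GPR

    import warnings

    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # cobra warns instead of raising
            gpr = GPR.from_string(rule)
    except Exception as exc:
        raise ValueError(f"unparseable GPR rule {rule!r}: {exc}") from None
    if gpr.body is None:  # cobra signals a malformed rule with an empty tree
        raise ValueError(f"unparseable GPR rule {rule!r}")
    return max(_eval_node(gpr.body, profile.values, floor), floor)


def map_weights(
    net: MetabolicNetwork,
    profile: ExpressionProfile,
    floor: float | None = None,
    normalize: bool = True,
) -> ReactionWeights:
    """Map an expression profile onto per-reaction weights via GPR rules.

    When ``floor`` is None it defaults to ``1e-6 ×`` the median nonzero
    weight among reactions whose rule evaluated from measured genes (so
    unmeasured/spontaneous reactions stay negligible but log-finite).
    """
    if floor is None:
        probe = 1e-300  # sentinel floor to identify rule-backed weights
        raw = np.array([evaluate_gpr(r, profile, probe) for r in net.gpr_rules])
        backed = raw[raw > probe * len(net.gpr_rules)]
        if backed.size == 0:
            floor = 1e-6
        else:
            floor = DEFAULT_FLOOR_FRACTION * float(np.median(backed))
    g = np.array([evaluate_gpr(r, profile, floor) for r in net.gpr_rules])
    if normalize:
        g = g / g.sum()
    return ReactionWeights(list(net.internal_ids), g, floor_value=floor, normalized=normalize)


def weights_from_fluxes(
    net: MetabolicNetwork,
    v: np.ndarray,
    floor: float = 1e-6,
    normalize: bool = False,
) -> ReactionWeights:
    """Simulated-expression mode: g_j = max(|v_j|, floor), bypassing GPR."""
    v = np.asarray(v, dtype=float)
    if v.shape != (net.n_internal,):
        raise ValueError(f"flux vector length {v.shape} != internal reactions {net.n_internal}")
    g = np.maximum(np.abs(v), floor)
    if normalize:
        g = g / g.sum()
    return ReactionWeights(list(net.internal_ids), g, floor_value=floor, normalized=normalize)
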