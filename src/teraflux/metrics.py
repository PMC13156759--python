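"""Evaluation metrics: fluxome entropy, weighted entropy, MSE/Pearson.

Fluxome entropy treats the normalised net flux magnitudes
p_j = |v_j| / sum_k |v_k| over internal reactions as a distribution and
reports its Shannon entropy in bits; absolute bit values therefore depend
on this definition (net fluxes, exchanges excluded), which is stated
prominently because comparisons between methods hinge on it.

The weighted entropy H_g = -v_f^T log(v_f/g) - v_r^T log(v_r/g) is the
solver's objective; at an optimum it equals the reported objective value.

Prediction-vs-reference comparisons report MSE, Pearson r on raw fluxes
and Pearson r after an elementwise arcsinh transform (which compresses the
power-law dynamic range so a few dominant fluxes cannot mask the rest),
with seeded bootstrap confidence intervals over reaction pairs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = [
    "EvaluationReport",
    "fluxome_entropy",
    "weighted_entropy",
    "compare",
    "entropy_welch_test",
]


def fluxome_entropy(v: np.ndarray) -> float:
    """Shannon entropy (bits) of the normalised |net flux| distribution."""
    v = np.asarray(v, dtype=float)
    a = np.abs(v)
    tot = a.sum()
    if tot <= 0:
        raise ValueError("entropy undefined for an all-zero flux vector")
    p = a[a > 0] / tot
    return float(-np.sum(p * np.log2(p)))


def weighted_entropy(v_f: np.ndarray, v_r: np.ndarray, g: np.ndarray) -> float:
    """H_g = -v_f . log(v_f/g) - v_r . log(v_r/g) (natural log)."""
    v_f, v_r, g = (np.asarray(a, dtype=float) for a in (v_f, v_r, g))
    if np.any(v_f <= 0) or np.any(v_r <= 0) or np.any(g <= 0):
        raise ValueError("weighted entropy requires positive v_f, v_r and g")
    return float(-np.sum(v_f * np.log(v_f / g)) - np.sum(v_r * np.log(v_r / g)))


@dataclass(frozen=True)
class EvaluationReport:
    """Point metrics with bootstrap confidence intervals."""

    n_pairs: int
    mse: float
    pearson_r: float
    pearson_r_arcsinh: float
    ci: dict[str, tuple[float, float]]

    def to_dict(self) -> dict:
        return {
            "n_pairs": self.n_pairs,
            "mse": self.mse,
            "pearson_r": self.pearson_r,
            "pearson_r_arcsinh": self.pearson_r_arcsinh,
            **{f"{k}_ci_low": v[0] for k, v in self.ci.items()},
            **{f"{k}_ci_high": v[1] for k, v in self.ci.items()},
        }


def _metrics(pred: np.ndarray, ref: np.ndarray) -> tuple[float, float, float]:
    mse = float(np.mean((pred - ref) ** 2))
    if np.std(pred) == 0 or np.std(ref) == 0:
        raise ValueError("Pearson undefined for zero-variance input")
    r = float(stats.pearsonr(pred, ref).statistic)
    ra = float(stats.pearsonr(np.arcsinh(pred), np.arcsinh(ref)).statistic)
    return mse, r, ra


def compare(
    pred,
    ref,
    mapping: list[tuple[str, str, float]] | None = None,
    n_boot: int = 1000,
    seed: int = 0,
    ci_level: float = 0.95,
) -> EvaluationReport:
    """Compare predicted against reference fluxes over mapped reaction pairs.

    ``pred``/``ref`` are either aligned arrays, or dicts keyed by reaction
    id together with a ``mapping`` of (pred_id, ref_id, sign) rows — the
    explicit-table convention for sparse reference fluxomes. Bootstrap
    resamples reaction pairs with replacement (seeded).
    """
    if mapping is not None:
        p = np.array([float(pred[a]) * s for a, _, s in mapping])
        r = np.array([float(ref[b]) for _, b, _ in mapping])
    else:
        p = np.asarray(pred, dtype=float)
        r = np.asarray(ref, dtype=float)
        if p.shape != r.shape:
            raise ValueError("pred and ref must align")
    if p.size < 3:
        raise ValueError("need at least 3 mapped reaction pairs")
    mse, pr, pra = _metrics(p, r)
    rng = np.random.default_rng(seed)
    boots = {"mse": [], "pearson_r": [], "pearson_r_arcsinh": []}
    for _ in range(n_boot):
        idx = rng.integers(0, p.size, size=p.size)
        try:
            m, b_r, b_ra = _metrics(p[idx], r[idx])
        except ValueError:  # degenerate resample
            continue
        boots["mse"].append(m)
        boots["pearson_r"].append(b_r)
        boots["pearson_r_arcsinh"].append(b_ra)
    q = (1.0 - ci_level) / 2.0
    ci = {
        k: (float(np.quantile(v, q)), float(np.quantile(v, 1 - q))) if v else (np.nan, np.nan)
        for k, v in boots.items()
    }
    return EvaluationReport(
        n_pairs=int(p.size), mse=mse, pearson_r=pr, pearson_r_arcsinh=pra, ci=ci
    )


def entropy_welch_test(entropies_a, entropies_b):
    """Welch's t-test between two sets of fluxome entropies."""
    res = stats.ttest_ind(entropies_a, entropies_b, equal_var=False)
    return float(res.statistic), float(res.pvalue)
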