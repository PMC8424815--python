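"""Pearson co-expression filtering.

Candidate miRNA-target pairs must combine sequence evidence (>= 1 MRE) with
negative co-expression (r < -0.7, p < 0.01); lncRNA-mRNA pairs must be
positively co-expressed (r > 0.7, p < 0.01). Thresholds are strict
inequalities and correlations are computed across all samples pooled over
conditions. Note that at small n the p threshold dominates: with n = 6,
p < 0.01 already requires |r| above roughly 0.92.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import stats

from .io_formats import ExpressionMatrix

__all__ = [
    "CorrelationResult",
    "TargetInteraction",
    "pearson",
    "mirna_target_interactions",
    "lncrna_mrna_pairs",
    "trait_correlation",
    "R_NEG_MAX",
    "R_POS_MIN",
    "P_MAX",
]

R_NEG_MAX = -0.7
R_POS_MIN = 0.7
P_MAX = 0.01


@dataclass(frozen=True)
class CorrelationResult:
    id_a: str
    id_b: str
    r: float
    pvalue: float
    n: int


@dataclass(frozen=True)
class TargetInteraction:
    mirna_id: str
    target_id: str
    target_kind: str  # mRNA | lncRNA
    mre_count: int
    pcc: float
    pcc_pvalue: float


def _pearson_pvalue(r: float, n: int) -> float:
    """Two-sided p from the exact t transform: t = r sqrt((n-2)/(1-r^2))."""
    if abs(r) >= 1.0:
        return 0.0
    t = r * np.sqrt((n - 2) / (1.0 - r * r))
    return float(2.0 * stats.t.sf(abs(t), df=n - 2))


def pearson(x: Sequence[float], y: Sequence[float], id_a: str = "x", id_b: str = "y") -> CorrelationResult:
    """Sample Pearson correlation with its two-sided t-test p-value.

    Correlations within 1e-12 of +/-1 (numerically collinear data) are
    reported as exactly +/-1 with p = 0.
    """
    xa = np.asarray(x, dtype=float)
    ya = np.asarray(y, dtype=float)
    if xa.shape != ya.shape:
        raise ValueError(f"length mismatch: {xa.shape} vs {ya.shape}")
    n = xa.size
    if n < 3:
        raise ValueError("need at least 3 samples for a correlation p-value")
    if np.ptp(xa) == 0 or np.ptp(ya) == 0:
        raise ValueError("constant vector")
    r = float(stats.pearsonr(xa, ya).statistic)
    r = max(-1.0, min(1.0, r))
    if abs(r) > 1.0 - 1e-12:
        r = math.copysign(1.0, r)
    return CorrelationResult(id_a=id_a, id_b=id_b, r=r, pvalue=_pearson_pvalue(r, n), n=n)


def _corr_matrix(
    a: np.ndarray, b: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """All-pairs Pearson r and p between rows of a and rows of b.

    Rows with zero variance yield NaN r and p = 1 (they can never pass a
    strict threshold).
    """
    n = a.shape[1]
    az = a - a.mean(axis=1, keepdims=True)
    bz = b - b.mean(axis=1, keepdims=True)
    asd = az.std(axis=1, ddof=1)
    bsd = bz.std(axis=1, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        r = (az @ bz.T) / ((n - 1) * np.outer(asd, bsd))
        r = np.clip(r, -1.0, 1.0)
        t = r * np.sqrt((n - 2) / (1.0 - r * r))
    p = 2.0 * stats.t.sf(np.abs(t), df=n - 2)
    p[np.abs(r) >= 1.0] = 0.0
    p[np.isnan(r)] = 1.0
    return r, p


def mirna_target_interactions(
    mre_counts: Mapping[tuple[str, str], int],
    expr: ExpressionMatrix,
    target_kinds: Mapping[str, str],
    r_max: float = R_NEG_MAX,
    p_max: float = P_MAX,
) -> list[TargetInteraction]:
    """Intersect sequence evidence with negative co-expression.

    Retains (miRNA, target) pairs with >= 1 MRE, r < r_max and p < p_max.
    """
    values = expr.values
    out = []
    for (mid, tid), count in sorted(mre_counts.items()):
        for fid in (mid, tid):
            if fid not in values.index:
                raise ValueError(f"feature {fid!r} missing from expression matrix")
        res = pearson(values.loc[mid], values.loc[tid], mid, tid)
        if count >= 1 and res.r < r_max and res.pvalue < p_max:
            out.append(
                TargetInteraction(
                    mirna_id=mid,
                    target_id=tid,
                    target_kind=target_kinds.get(tid, "mRNA"),
                    mre_count=count,
                    pcc=res.r,
                    pcc_pvalue=res.pvalue,
                )
            )
    return out


def lncrna_mrna_pairs(
    expr: ExpressionMatrix,
    lnc_ids: Iterable[str],
    mrna_ids: Iterable[str],
    r_min: float = R_POS_MIN,
    p_max: float = P_MAX,
) -> list[CorrelationResult]:
    """All positively co-expressed lncRNA x mRNA pairs (r > r_min, p < p_max)."""
    lnc_ids = sorted(set(lnc_ids))
    mrna_ids = sorted(set(mrna_ids))
    values = expr.values
    for fid in (*lnc_ids, *mrna_ids):
        if fid not in values.index:
            raise ValueError(f"feature {fid!r} missing from expression matrix")
    if not lnc_ids or not mrna_ids:
        return []
    a = values.loc[lnc_ids].to_numpy()
    b = values.loc[mrna_ids].to_numpy()
    n = a.shape[1]
    r, p = _corr_matrix(a, b)
    out = []
    for i, lnc in enumerate(lnc_ids):
        for j, mrna in enumerate(mrna_ids):
            if not np.isnan(r[i, j]) and r[i, j] > r_min and p[i, j] < p_max:
                out.append(
                    CorrelationResult(
                        id_a=lnc, id_b=mrna, r=float(r[i, j]), pvalue=float(p[i, j]), n=n
                    )
                )
    return out


def trait_correlation(
    expr_feature: Sequence[float],
    trait: Sequence[float],
    feature_id: str = "feature",
    trait_id: str = "trait",
) -> CorrelationResult:
    """Pearson correlation between one expression profile and a phenotype."""
    return pearson(expr_feature, trait, feature_id, trait_id)
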