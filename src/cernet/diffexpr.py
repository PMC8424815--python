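"""Expression normalization (RPKM/TPM) and differential-expression calling.

Differential expression between the two conditions uses a Welch t-test on
log2(value + pseudo) with Benjamini-Hochberg adjustment; features are called
up when log2FC > 1 and adjusted p < 0.05, down when log2FC < -1 and adjusted
p < 0.05, else ns.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io_formats import ExpressionMatrix

__all__ = [
    "DERecord",
    "rpkm",
    "tpm",
    "differential_expression",
    "bh_adjust",
    "de_table",
    "LOG2FC_CUTOFF",
    "PADJ_CUTOFF",
]

LOG2FC_CUTOFF = 1.0
PADJ_CUTOFF = 0.05


@dataclass(frozen=True)
class DERecord:
    feature_id: str
    mean_control: float
    mean_treated: float
    log2fc: float
    pvalue: float
    padj: float
    status: str  # up | down | ns


def _lengths_vector(matrix: ExpressionMatrix, lengths: Mapping[str, int]) -> np.ndarray:
    missing = [f for f in matrix.feature_ids if f not in lengths]
    if missing:
        raise ValueError(f"features without a length: {missing[:5]}")
    vec = np.array([lengths[f] for f in matrix.feature_ids], dtype=float)
    if (vec <= 0).any():
        bad = [f for f, v in zip(matrix.feature_ids, vec) if v <= 0]
        raise ValueError(f"non-positive feature lengths: {bad[:5]}")
    return vec


def rpkm(counts: ExpressionMatrix, lengths: Mapping[str, int]) -> ExpressionMatrix:
    """Reads per kilobase per million mapped reads.

    value = count * 1e9 / (column_total * length).
    """
    if counts.unit != "count":
        raise ValueError(f"rpkm expects counts, got unit {counts.unit!r}")
    lens = _lengths_vector(counts, lengths)
    totals = counts.values.sum(axis=0)
    zero = totals[totals == 0]
    if len(zero):
        raise ValueError(f"zero column total for samples: {list(zero.index)}")
    values = counts.values * 1e9 / (totals.values[None, :] * lens[:, None])
    return counts.with_values(values, "RPKM")


def tpm(counts: ExpressionMatrix, lengths: Mapping[str, int]) -> ExpressionMatrix:
    """Transcripts per million; every column sums to 1e6."""
    if counts.unit != "count":
        raise ValueError(f"tpm expects counts, got unit {counts.unit!r}")
    lens = _lengths_vector(counts, lengths)
    rates = counts.values.div(lens, axis=0)
    totals = rates.sum(axis=0)
    zero = totals[totals == 0]
    if len(zero):
        raise ValueError(f"zero column total for samples: {list(zero.index)}")
    values = rates * 1e6 / totals
    return counts.with_values(values, "TPM")


def bh_adjust(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in input order."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def _welch_pvalues(log_ctrl: np.ndarray, log_trt: np.ndarray) -> np.ndarray:
    """Two-sided Welch t-test per feature (rows), with degenerate-variance
    handling: both groups constant -> p = 1 if means equal else 0."""
    with np.errstate(divide="ignore", invalid="ignore"):
        res = stats.ttest_ind(log_trt, log_ctrl, axis=1, equal_var=False)
        p = np.asarray(res.pvalue, dtype=float)
    var0 = (log_ctrl.var(axis=1) == 0) & (log_trt.var(axis=1) == 0)
    if var0.any():
        equal_means = np.isclose(log_ctrl.mean(axis=1), log_trt.mean(axis=1))
        p[var0 & equal_means] = 1.0
        p[var0 & ~equal_means] = 0.0
    p[np.isnan(p)] = 1.0
    return p


def differential_expression(
    expr: ExpressionMatrix,
    pseudo: float = 1.0,
    log2fc_cutoff: float = LOG2FC_CUTOFF,
    padj_cutoff: float = PADJ_CUTOFF,
) -> list[DERecord]:
    """Call differential expression, treated vs control.

    log2FC = log2((mean_treated + pseudo) / (mean_control + pseudo)); the
    p-value is a two-sided Welch t-test on log2(value + pseudo); BH
    adjustment across all tested features.
    """
    ctrl = expr.samples_of("control")
    trt = expr.samples_of("treated")
    if len(ctrl) < 2 or len(trt) < 2:
        raise ValueError("each condition needs >= 2 samples")
    values = expr.values
    mean_c = values[ctrl].mean(axis=1).to_numpy()
    mean_t = values[trt].mean(axis=1).to_numpy()
    log2fc = np.log2((mean_t + pseudo) / (mean_c + pseudo))
    log_ctrl = np.log2(values[ctrl].to_numpy() + pseudo)
    log_trt = np.log2(values[trt].to_numpy() + pseudo)
    pvalues = _welch_pvalues(log_ctrl, log_trt)
    padj = bh_adjust(pvalues)

    records = []
    for i, fid in enumerate(expr.feature_ids):
        if padj[i] < padj_cutoff and log2fc[i] > log2fc_cutoff:
            status = "up"
        elif padj[i] < padj_cutoff and log2fc[i] < -log2fc_cutoff:
            status = "down"
        else:
            status = "ns"
        records.append(
            DERecord(
                feature_id=fid,
                mean_control=float(mean_c[i]),
                mean_treated=float(mean_t[i]),
                log2fc=float(log2fc[i]),
                pvalue=float(pvalues[i]),
                padj=float(padj[i]),
                status=status,
            )
        )
    return records


def de_table(records: list[DERecord]) -> pd.DataFrame:
    return pd.DataFrame([r.__dict__ for r in records])
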