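"""Differential-expression gate.

The gate keeps circRNAs with |log2FC| > 1 and BH-adjusted p < 0.05 (strict
inequalities). When run from an expression matrix, group means are compared
with a Welch t-test and adjusted by Benjamini-Hochberg — a documented
stand-in for moderated-statistics pipelines; precomputed DE tables are
accepted directly so any upstream method can feed the funnel.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

from circscan.seq_io import AnnotationRow, DataError


@dataclass
class ExpressionMatrix:
    """log2 intensities, circRNAs as rows, samples as columns."""

    circ_ids: list
    sample_ids: list
    group_labels: list  # per-sample, "normal" or "tumor"
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.circ_ids), len(self.sample_ids)):
            raise DataError("expression matrix dimensions inconsistent")
        if len(self.group_labels) != len(self.sample_ids):
            raise DataError("group labels do not match samples")
        for label in ("normal", "tumor"):
            if sum(1 for g in self.group_labels if g == label) < 2:
                raise DataError(f"need >= 2 samples in group {label!r}")


@dataclass
class DEResult:
    circ_id: str
    log2fc: float  # tumor mean - normal mean, log2 scale
    p: float
    adj_p: float

    @property
    def direction(self) -> str:
        return "up" if self.log2fc > 0 else "down"


def welch_t_test(a: Sequence[float], b: Sequence[float]) -> float:
    """Two-sided Welch t-test p-value.

    Degenerate zero-variance cases: p = 1 when both groups are constant with
    equal means, p = 0 when constant with different means.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least 2 samples")
    if a.var(ddof=1) == 0.0 and b.var(ddof=1) == 0.0:
        return 1.0 if a.mean() == b.mean() else 0.0
    return float(stats.ttest_ind(a, b, equal_var=False).pvalue)


def bh_adjust(pvals: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, input order preserved."""
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def de_analyze(matrix: ExpressionMatrix) -> list[DEResult]:
    """Per-circRNA Welch t + BH across the two groups of the matrix."""
    labels = np.asarray(matrix.group_labels)
    tumor = matrix.values[:, labels == "tumor"]
    normal = matrix.values[:, labels == "normal"]
    lfcs = tumor.mean(axis=1) - normal.mean(axis=1)
    pvals = np.array(
        [welch_t_test(tumor[i], normal[i]) for i in range(len(matrix.circ_ids))]
    )
    adj = bh_adjust(pvals)
    return [
        DEResult(circ_id=cid, log2fc=float(lfcs[i]), p=float(pvals[i]), adj_p=float(adj[i]))
        for i, cid in enumerate(matrix.circ_ids)
    ]


def apply_de_gate(
    results: Sequence,
    lfc_cut: float = 1.0,
    q_cut: float = 0.05,
    pre_filtered: bool = False,
) -> list:
    """Keep rows passing |log2fc| > lfc_cut and adj_p < q_cut (both strict).

    ``pre_filtered`` declares the input already gated upstream (e.g. a
    published candidate table printing only fold changes): all rows are
    kept and only the direction partition applies downstream. Without that
    declaration a missing adj_p is an error.
    """
    if pre_filtered:
        return list(results)
    kept = []
    for r in results:
        adj_p = getattr(r, "adj_p", None)
        if adj_p is None:
            raise DataError(
                f"{r.circ_id}: adj_p missing; pass pre_filtered=True for gated tables"
            )
        if abs(r.log2fc) > lfc_cut and adj_p < q_cut:
            kept.append(r)
    return kept


def merge_de_tables(tables: Sequence[Sequence]) -> list:
    """Union several DE lists by circ_id, keeping the largest |log2fc| entry."""
    best: dict = {}
    for table in tables:
        for row in table:
            cur = best.get(row.circ_id)
            if cur is None or abs(row.log2fc) > abs(cur.log2fc):
                best[row.circ_id] = row
    return sorted(best.values(), key=lambda r: (-r.log2fc, r.circ_id))


def direction_partition(rows: Sequence) -> tuple[int, int]:
    """Count (up, down) by sign of log2fc; zero fold change counts as down
    only if negative, so exact zeros fall in neither bin."""
    up = sum(1 for r in rows if r.log2fc > 0)
    down = sum(1 for r in rows if r.log2fc < 0)
    return up, down
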