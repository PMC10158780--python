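"""Differential expression from TPM matrices.

All statistics operate on the log2(TPM + 1) scale.  Genes below a small
activity threshold in both groups are removed before testing; the remaining
genes get a per-gene two-sided Welch t-test and Benjamini-Hochberg q-values,
and are called differentially expressed at |log2FC| > 1, q < 0.05.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

ACTIVITY_THRESHOLD = 0.2

STATUS_UP_A = "up_in_a"
STATUS_UP_B = "up_in_b"
STATUS_NOT_DE = "not_de"
STATUS_FILTERED = "filtered_inactive"


@dataclass
class ExpressionMatrix:
    """TPM values (genes x replicates) plus a replicate -> group mapping."""

    tpm: pd.DataFrame
    groups: pd.Series  # index: replicate/sample id, value: group label

    def __post_init__(self) -> None:
        if (self.tpm.to_numpy() < 0).any():
            raise ValueError("TPM values must be non-negative")
        missing = set(self.tpm.columns) - set(self.groups.index)
        if missing:
            raise ValueError(f"replicates without group label: {sorted(missing)}")
        self.groups = self.groups.loc[list(self.tpm.columns)]

    @property
    def gene_ids(self) -> list[str]:
        return list(self.tpm.index)

    def replicates(self, group: str) -> list[str]:
        return list(self.groups.index[self.groups == group])


def log_transform(tpm) -> pd.DataFrame:
    """Elementwise log2(TPM + 1); zero maps to zero."""
    arr = np.asarray(tpm, dtype=float)
    if (arr < 0).any():
        raise ValueError("TPM values must be non-negative")
    if isinstance(tpm, (pd.DataFrame, pd.Series)):
        return np.log2(tpm + 1.0)
    return np.log2(arr + 1.0)


def classify_active(
    group_means: pd.DataFrame, threshold: float = ACTIVITY_THRESHOLD
) -> pd.DataFrame:
    """Activity call per gene and group: mean log2(TPM+1) strictly above the
    threshold.  A gene inactive in every group is dropped from DE testing."""
    return group_means > threshold


def expression_log2fc(group_a_values, group_b_values) -> float:
    """Difference of group means of log2(TPM + 1) (mean of logs, not log of
    mean TPM); positive favours group a."""
    a = np.asarray(group_a_values, dtype=float)
    b = np.asarray(group_b_values, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("empty group")
    return float(np.mean(np.log2(a + 1.0)) - np.mean(np.log2(b + 1.0)))


def _welch_pvalues(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Vectorised two-sided Welch t-test p-values per gene (rows).

    Degenerate rows (zero variance in both groups) get p = 1 when the means
    agree — no evidence — and p = 0 when they differ (decisive but flagged)."""
    va, vb = a.var(axis=1, ddof=1), b.var(axis=1, ddof=1)
    degenerate = (va == 0) & (vb == 0)
    p = np.ones(a.shape[0])
    ok = ~degenerate
    if ok.any():
        res = stats.ttest_ind(a[ok], b[ok], axis=1, equal_var=False)
        p[ok] = res.pvalue
    if degenerate.any():
        diff = a[degenerate].mean(axis=1) != b[degenerate].mean(axis=1)
        p[degenerate] = np.where(diff, 0.0, 1.0)
        if diff.any():
            logger.warning(
                "%d genes with zero variance but unequal means: p set to 0",
                int(diff.sum()),
            )
    return p


def differential_expression(
    expr: ExpressionMatrix,
    group_a: str,
    group_b: str,
    fc_threshold: float = 1.0,
    q_threshold: float = 0.05,
    activity_threshold: float = ACTIVITY_THRESHOLD,
) -> pd.DataFrame:
    """Per-gene differential expression between two replicate groups.

    Returns a frame with columns ``gene_id, log2fc, p_value, q_value,
    status``.  Genes inactive in both groups are ``filtered_inactive`` and
    carry no p/q; BH adjustment runs across the tested genes only.
    """
    reps_a, reps_b = expr.replicates(group_a), expr.replicates(group_b)
    if len(reps_a) < 2 or len(reps_b) < 2:
        raise ValueError("cannot estimate variance: need >= 2 replicates per group")
    log_a = log_transform(expr.tpm[reps_a]).to_numpy()
    log_b = log_transform(expr.tpm[reps_b]).to_numpy()
    means = pd.DataFrame(
        {group_a: log_a.mean(axis=1), group_b: log_b.mean(axis=1)},
        index=expr.tpm.index,
    )
    active = classify_active(means, activity_threshold)
    tested = active.any(axis=1).to_numpy()

    log2fc = means[group_a] - means[group_b]
    p = np.full(len(means), np.nan)
    q = np.full(len(means), np.nan)
    if tested.any():
        p[tested] = _welch_pvalues(log_a[tested], log_b[tested])
        q[tested] = multipletests(p[tested], method="fdr_bh")[1]

    status = np.full(len(means), STATUS_NOT_DE, dtype=object)
    status[~tested] = STATUS_FILTERED
    sig = tested & (q < q_threshold)
    status[sig & (log2fc.to_numpy() > fc_threshold)] = STATUS_UP_A
    status[sig & (log2fc.to_numpy() < -fc_threshold)] = STATUS_UP_B

    out = pd.DataFrame(
        {
            "gene_id": means.index,
            "log2fc": log2fc.to_numpy(),
            "p_value": p,
            "q_value": q,
            "status": status,
        }
    ).set_index("gene_id", drop=False)
    return out
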