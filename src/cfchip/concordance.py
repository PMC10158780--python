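"""Agreement statistics between enrichment profiles and expression.

Covers four questions about how well per-gene (cf)ChIP enrichment tracks
transcription:

* rank correlation between enrichment and expression (Spearman, with exact
  permutation p-values at small n);
* can enrichment separate active from inactive genes (ROC/AUC with a
  Mann-Whitney AUC, Hanley-McNeil standard error and z-test against 0.5);
* sensitivity at a fixed specificity cut-off on the step ROC curve;
* does the *direction* of differential enrichment agree with differential
  expression (per-direction sensitivity, 2x2 contingency table and a
  two-sided Fisher's exact test).
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .expression import STATUS_UP_A, STATUS_UP_B

logger = logging.getLogger(__name__)

EXACT_SPEARMAN_MAX_N = 9


@dataclass
class RocResult:
    """ROC of a score against binary activity labels.

    ``auc`` is the Mann-Whitney pairwise-exceedance probability (ties count
    one half); ``se`` the Hanley-McNeil standard error; ``z = (auc-0.5)/se``
    with a two-tailed normal p-value.  ``curve`` holds (specificity,
    sensitivity) points of the step curve from the all-negative to the
    all-positive threshold.
    """

    auc: float
    se: float
    z: float
    p_value: float
    curve: list[tuple[float, float]]
    n_active: int
    n_inactive: int


@dataclass
class AgreementResult:
    """Direction agreement between differential expression and enrichment."""

    sensitivity_a: float
    sensitivity_b: float
    contingency: np.ndarray  # rows: up_in_a/up_in_b; cols: enr sign agrees a / agrees b
    fisher_p: float
    genes: dict[str, list[str]] = field(default_factory=dict)


def spearman(x, y) -> tuple[float, float]:
    """Spearman rank correlation with a two-sided p-value.

    Ties get average ranks.  For n <= 9 the p-value is exact (all n!
    permutations of one rank vector); beyond that the classical
    t-approximation is used, which at those sample sizes agrees with the
    refined published algorithms to plotting precision.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length vectors")
    n = x.size
    if n < 3:
        raise ValueError("need at least 3 observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("undefined correlation: constant vector")
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    rho = float(np.corrcoef(rx, ry)[0, 1])
    if n <= EXACT_SPEARMAN_MAX_N:
        p = _exact_spearman_p(rx, ry, rho)
    else:
        t = rho * np.sqrt((n - 2) / (1.0 - rho**2)) if abs(rho) < 1 else np.inf
        p = float(2 * stats.t.sf(abs(t), df=n - 2))
    return rho, min(p, 1.0)


def _exact_spearman_p(rx: np.ndarray, ry: np.ndarray, rho_obs: float) -> float:
    """Two-sided permutation p: fraction of rank permutations with
    |rho| >= |observed| (within numerical slack)."""
    sy = np.std(ry) * np.std(rx)
    mx, my = rx.mean(), ry.mean()
    n = rx.size
    hits = 0
    total = 0
    thresh = abs(rho_obs) - 1e-12
    for perm in itertools.permutations(range(n)):
        rho = float(np.mean((rx[list(perm)] - mx) * (ry - my)) / sy)
        if abs(rho) >= thresh:
            hits += 1
        total += 1
    return hits / total


def roc_active_genes(scores, labels) -> RocResult:
    """ROC analysis of per-gene scores against active/inactive labels.

    AUC via the rank (Mann-Whitney) identity with ties counted 1/2; the step
    curve uses the distinct observed scores as thresholds (a gene is called
    active when its score >= threshold).
    """
    s = np.asarray(scores, dtype=float)
    lab = np.asarray(labels)
    if lab.dtype != bool:
        lab = np.asarray([_as_active(v) for v in lab])
    n1 = int(lab.sum())
    n0 = int((~lab).sum())
    if n1 == 0 or n0 == 0:
        raise ValueError("both classes must be non-empty")
    ranks = stats.rankdata(s)
    u = ranks[lab].sum() - n1 * (n1 + 1) / 2.0
    auc = float(u / (n1 * n0))
    se = _hanley_mcneil_se(auc, n1, n0)
    if se > 0:
        z = (auc - 0.5) / se
        p = float(2 * stats.norm.sf(abs(z)))
    else:
        z = np.inf if auc > 0.5 else (-np.inf if auc < 0.5 else 0.0)
        p = 0.0 if auc != 0.5 else 1.0
    curve = _roc_curve(s, lab, n1, n0)
    return RocResult(
        auc=auc, se=se, z=float(z), p_value=p, curve=curve, n_active=n1, n_inactive=n0
    )


def _as_active(v) -> bool:
    if isinstance(v, (bool, np.bool_)):
        return bool(v)
    if str(v).lower() in ("active", "1", "true"):
        return True
    if str(v).lower() in ("inactive", "0", "false"):
        return False
    raise ValueError(f"unrecognised activity label {v!r}")


def _hanley_mcneil_se(auc: float, n_pos: int, n_neg: int) -> float:
    q1 = auc / (2.0 - auc)
    q2 = 2.0 * auc**2 / (1.0 + auc)
    var = (
        auc * (1 - auc)
        + (n_pos - 1) * (q1 - auc**2)
        + (n_neg - 1) * (q2 - auc**2)
    ) / (n_pos * n_neg)
    return float(np.sqrt(max(var, 0.0)))


def _roc_curve(
    s: np.ndarray, lab: np.ndarray, n1: int, n0: int
) -> list[tuple[float, float]]:
    curve = [(1.0, 0.0)]
    for thr in np.sort(np.unique(s))[::-1]:
        called = s >= thr
        tp = int((called & lab).sum())
        fp = int((called & ~lab).sum())
        curve.append((1.0 - fp / n0, tp / n1))
    if curve[-1] != (0.0, 1.0):
        curve.append((0.0, 1.0))
    return curve


def sensitivity_at_specificity(roc: RocResult, specificity_cutoff: float = 0.75) -> float:
    """Maximum sensitivity over thresholds whose specificity meets the
    cut-off (step curve, no interpolation)."""
    eligible = [sens for spec, sens in roc.curve if spec >= specificity_cutoff]
    return max(eligible) if eligible else 0.0


def fisher_exact_2x2(table) -> float:
    """Two-sided Fisher's exact p for a 2x2 table by the probability-mass
    method: sum of hypergeometric probabilities (at the observed margins) of
    all tables no more probable than the observed one."""
    t = np.asarray(table, dtype=int)
    if t.shape != (2, 2) or (t < 0).any():
        raise ValueError("table must be 2x2 with non-negative entries")
    if t.sum() == 0:
        raise ValueError("all-zero table")
    r1 = t[0].sum()
    c1 = t[:, 0].sum()
    n = t.sum()
    support = np.arange(max(0, r1 + c1 - n), min(r1, c1) + 1)
    pmf = stats.hypergeom.pmf(support, n, r1, c1)
    p_obs = stats.hypergeom.pmf(t[0, 0], n, r1, c1)
    # relative slack guards against ties broken by floating-point noise
    p = float(pmf[pmf <= p_obs * (1 + 1e-7)].sum())
    return min(p, 1.0)


def agreement_analysis(
    de: pd.DataFrame, enrichment_log2fc: pd.Series
) -> AgreementResult:
    """Does differential enrichment point the same way as differential
    expression?

    A gene called up in group a agrees when its relative enrichment log2FC is
    strictly positive; up in group b agrees when strictly negative.  Zero
    enrichment fold-change counts as disagreement.  Sensitivity per direction
    is agreeing/total; the 2x2 table (DE direction x enrichment direction)
    gets a two-sided Fisher's exact test.
    """
    up_a = de.loc[de["status"] == STATUS_UP_A, "gene_id"].tolist()
    up_b = de.loc[de["status"] == STATUS_UP_B, "gene_id"].tolist()
    missing = [g for g in up_a + up_b if g not in enrichment_log2fc.index]
    if missing:
        raise ValueError(f"DE gene missing enrichment value: {missing[:5]}")
    fc_a = enrichment_log2fc.loc[up_a]
    fc_b = enrichment_log2fc.loc[up_b]
    n_zero = int((fc_a == 0).sum() + (fc_b == 0).sum())
    if n_zero:
        logger.warning(
            "%d DE genes with zero enrichment log2FC counted as disagreement", n_zero
        )
    agree_a = fc_a > 0
    agree_b = fc_b < 0
    table = np.array(
        [
            [int(agree_a.sum()), len(up_a) - int(agree_a.sum())],
            [len(up_b) - int(agree_b.sum()), int(agree_b.sum())],
        ]
    )
    sens_a = float(agree_a.mean()) if up_a else float("nan")
    sens_b = float(agree_b.mean()) if up_b else float("nan")
    fisher_p = fisher_exact_2x2(table) if table.sum() > 0 else float("nan")
    genes = {
        "up_in_a_agree": list(fc_a.index[agree_a]),
        "up_in_a_disagree": list(fc_a.index[~agree_a]),
        "up_in_b_agree": list(fc_b.index[agree_b]),
        "up_in_b_disagree": list(fc_b.index[~agree_b]),
    }
    return AgreementResult(
        sensitivity_a=sens_a,
        sensitivity_b=sens_b,
        contingency=table,
        fisher_p=fisher_p,
        genes=genes,
    )
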