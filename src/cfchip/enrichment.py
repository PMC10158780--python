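"""Per-gene (cf)ChIP enrichment quantification on a targeted capture panel.

Three quantities are computed, all restricted to panel-included genes:

* **ChIP enrichment** of sample *s*:
  ``E_i = N_i * 1e9 / (T * k_i)`` with ``T = sum_i N_i`` over included
  genes — a reads-per-billion rate normalised by library size and by the
  gene's captured footprint ``k_i``, comparable across genes and samples.

* **Background-subtracted cfChIP enrichment**: plasma cfDNA is dominated by
  the hematopoietic compartment, so the mean healthy-donor count profile
  ``Hbar_i`` is subtracted before normalising:
  ``E_i = (N_i - Hbar_i) * 1e9 / ((sum N - sum Hbar) * k_i)``.
  Values may be negative (depletion below the healthy background).

* **Relative enrichment** between two groups: the difference of log2 group
  means, ``log2FC_i = log2(mean E_i^a) - log2(mean E_i^b)``; positive values
  indicate higher enrichment in group a.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .panel import GenePanel

logger = logging.getLogger(__name__)

SCALE = 1e9

ASSAYS = ("chip", "cfchip", "input")


@dataclass
class CountMatrix:
    """Deduplicated per-gene read counts (genes x samples) with metadata.

    ``samples`` carries one row per column of ``counts`` with at least
    ``sample_id``, ``condition`` and ``assay`` columns; gene order must match
    the panel the counts will be analysed against.
    """

    counts: pd.DataFrame
    samples: pd.DataFrame

    def __post_init__(self) -> None:
        if not set(self.counts.columns) == set(self.samples["sample_id"]):
            raise ValueError("count columns and sample sheet disagree")
        vals = self.counts.to_numpy()
        if (vals < 0).any():
            raise ValueError("counts must be non-negative")
        if not np.allclose(vals, np.round(vals)):
            raise ValueError("counts must be integers")
        self.samples = self.samples.set_index("sample_id", drop=False).loc[
            list(self.counts.columns)
        ]

    @property
    def gene_ids(self) -> list[str]:
        return list(self.counts.index)

    def select(
        self, condition: str | list[str] | None = None, assay: str | None = None
    ) -> "CountMatrix":
        mask = pd.Series(True, index=self.samples.index)
        if condition is not None:
            conds = [condition] if isinstance(condition, str) else list(condition)
            mask &= self.samples["condition"].isin(conds)
        if assay is not None:
            mask &= self.samples["assay"] == assay
        ids = list(self.samples.index[mask])
        return CountMatrix(self.counts[ids], self.samples.loc[ids].reset_index(drop=True))

    def sample(self, sample_id: str) -> "CountMatrix":
        return CountMatrix(
            self.counts[[sample_id]],
            self.samples.loc[[sample_id]].reset_index(drop=True),
        )


@dataclass
class BackgroundProfile:
    """Mean healthy-donor cfChIP count per gene (the hematopoietic background)."""

    mean_counts: pd.Series
    n_donors: int
    total_mean: float = field(init=False)

    def __post_init__(self) -> None:
        self.total_mean = float(self.mean_counts.sum())

    @property
    def gene_ids(self) -> list[str]:
        return list(self.mean_counts.index)


@dataclass
class EnrichmentProfile:
    """Per-gene enrichment values (genes x samples/groups).

    Only panel-included genes carry values.  ``kind`` is ``"chip"``
    (non-negative rates) or ``"cfchip_relative"`` (background-subtracted,
    may be negative).
    """

    values: pd.DataFrame
    kind: str
    source_samples: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.kind not in ("chip", "cfchip_relative"):
            raise ValueError(f"unknown enrichment kind {self.kind!r}")
        if self.kind == "chip" and (self.values.to_numpy() < 0).any():
            raise ValueError("chip enrichment must be non-negative")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    def group_means(self, groups: pd.Series) -> pd.DataFrame:
        """Arithmetic mean enrichment per gene within each sample group."""
        return self.values.T.groupby(groups.loc[self.values.columns]).mean().T


def _included_counts(counts: CountMatrix, panel: GenePanel) -> tuple[pd.DataFrame, pd.Series]:
    ids = panel.included_ids
    missing = [g for g in ids if g not in counts.counts.index]
    if missing:
        raise ValueError(f"counts missing panel genes: {missing[:5]}")
    if not ids:
        raise ValueError("panel has no included genes")
    k = panel.coverage_factors(included_only=True)
    if (k <= 0).any():
        raise ValueError("included gene with coverage factor 0")
    return counts.counts.loc[ids], k


def chip_enrichment(counts: CountMatrix, panel: GenePanel) -> EnrichmentProfile:
    """ChIP enrichment ``E_i = N_i * 1e9 / (T * k_i)`` per sample.

    ``T`` is the included-gene library size of the sample, making the profile
    invariant to sequencing depth; dividing by ``k_i`` makes genes with
    different captured footprints comparable.
    """
    n, k = _included_counts(counts, panel)
    totals = n.sum(axis=0)
    if (totals == 0).any():
        empty = list(totals.index[totals == 0])
        raise ValueError(f"empty sample: {', '.join(empty)}")
    values = n.mul(SCALE).div(totals, axis=1).div(k, axis=0)
    return EnrichmentProfile(values=values, kind="chip", source_samples=list(n.columns))


def make_background(healthy_counts: CountMatrix, panel: GenePanel) -> BackgroundProfile:
    """Average per-gene counts across healthy cfChIP donors."""
    n, _ = _included_counts(healthy_counts, panel)
    if n.shape[1] == 0:
        raise ValueError("no healthy samples")
    return BackgroundProfile(mean_counts=n.mean(axis=1), n_donors=n.shape[1])


def cfchip_relative_enrichment(
    patient_counts: CountMatrix, background: BackgroundProfile, panel: GenePanel
) -> EnrichmentProfile:
    """Background-subtracted cfChIP enrichment (may be negative).

    ``E_i = (N_i - Hbar_i) * 1e9 / ((sum N - sum Hbar) * k_i)`` over included
    genes; the denominator is the background-subtracted library size.
    """
    n, k = _included_counts(patient_counts, panel)
    if list(background.gene_ids) != list(n.index):
        raise ValueError("background gene set does not match panel")
    denom = n.sum(axis=0) - background.total_mean
    if (denom == 0).any():
        bad = list(denom.index[denom == 0])
        raise ValueError(
            f"degenerate background-subtracted library size: {', '.join(bad)}"
        )
    values = (
        n.sub(background.mean_counts, axis=0).mul(SCALE).div(denom, axis=1).div(k, axis=0)
    )
    return EnrichmentProfile(
        values=values, kind="cfchip_relative", source_samples=list(n.columns)
    )


def _pseudo_enrichment(a: pd.Series, b: pd.Series) -> float:
    pos = np.concatenate([a[a > 0].to_numpy(), b[b > 0].to_numpy()])
    if pos.size == 0:
        return 1e-3
    return float(pos.min() / 2)


def relative_log2fc(
    group_a: pd.Series, group_b: pd.Series, pseudo: float | None = None
) -> pd.Series:
    """log2 fold-change between group-mean enrichment profiles.

    Negative means (possible after background subtraction) are clamped to
    zero and a pseudo-enrichment ``pseudo`` is added inside the logs.  When
    ``pseudo`` is None, half the smallest positive mean across both groups is
    used (fallback 1e-3 when none is positive).  Positive values indicate
    higher enrichment in group a; swapping groups negates the result exactly.
    """
    if list(group_a.index) != list(group_b.index):
        raise ValueError("mismatched gene sets")
    if pseudo is None:
        pseudo = _pseudo_enrichment(group_a, group_b)
    if pseudo <= 0:
        raise ValueError("pseudo-enrichment must be > 0")
    a = np.maximum(group_a.to_numpy(dtype=float), 0.0) + pseudo
    b = np.maximum(group_b.to_numpy(dtype=float), 0.0) + pseudo
    return pd.Series(np.log2(a) - np.log2(b), index=group_a.index, name="log2fc")
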