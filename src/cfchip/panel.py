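"""Targeted capture gene panel: capture geometry, coverage factors and the
TSS-proximal exclusion rule.

The hybridisation panel captures only parts of each gene body.  Because
H3K36me3 is deposited co-transcriptionally and accumulates toward the 3'
end of active genes, a gene whose captured bases all fall close to the
transcription start site carries almost no signal even when transcribed.
Such genes are flagged and excluded from enrichment analysis.

Coordinates are 0-based half-open (BED convention) throughout.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

Interval = tuple[int, int]

#: Default read-depth cutoff when estimating the coverage factor k from a
#: reference capture experiment (bases with depth strictly above this count).
DEFAULT_DEPTH_THRESHOLD = 100

#: Default fraction of the gene body, measured from the TSS in the direction
#: of transcription, inside which captured-only genes are excluded.
DEFAULT_TSS_FRACTION = 0.25


def _normalize_intervals(intervals: list[Interval]) -> list[Interval]:
    """Sort and merge overlapping/adjacent half-open intervals."""
    ivs = sorted((int(a), int(b)) for a, b in intervals)
    merged: list[Interval] = []
    for a, b in ivs:
        if b <= a:
            raise ValueError(f"empty or inverted interval ({a}, {b})")
        if merged and a <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], b))
        else:
            merged.append((a, b))
    return merged


@dataclass
class GeneRecord:
    """One panel gene: identity, capture geometry and coverage factor.

    ``coverage_factor_k`` is the number of effectively captured bases of the
    gene (bases exceeding a depth cutoff in a reference capture run); it is
    the per-gene length normaliser of the enrichment formulas.
    """

    gene_id: str
    chrom: str
    strand: str
    tss: int
    gene_length: int
    captured_intervals: list[Interval] = field(default_factory=list)
    coverage_factor_k: int = 0
    included: bool = True

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"{self.gene_id}: strand must be '+' or '-'")
        if self.gene_length <= 0:
            raise ValueError(f"{self.gene_id}: gene_length must be > 0")
        if self.coverage_factor_k < 0:
            raise ValueError(f"{self.gene_id}: coverage factor must be >= 0")
        self.captured_intervals = _normalize_intervals(self.captured_intervals)
        body_start, body_end = self.body
        for a, b in self.captured_intervals:
            if a < body_start or b > body_end:
                raise ValueError(
                    f"{self.gene_id}: capture outside gene "
                    f"(interval ({a}, {b}) not within [{body_start}, {body_end}))"
                )
        total = self.total_captured_bases
        if self.captured_intervals and self.coverage_factor_k > total:
            raise ValueError(
                f"{self.gene_id}: coverage factor {self.coverage_factor_k} exceeds "
                f"captured bases {total}"
            )
        if self.coverage_factor_k == 0:
            self.included = False

    @property
    def body(self) -> Interval:
        """Genomic span of the gene body as a half-open interval.

        For '+' genes the body runs [tss, tss + length); for '-' genes
        transcription proceeds toward smaller coordinates, so the body is
        [tss - length, tss).
        """
        if self.strand == "+":
            return (self.tss, self.tss + self.gene_length)
        return (self.tss - self.gene_length, self.tss)

    @property
    def total_captured_bases(self) -> int:
        return sum(b - a for a, b in self.captured_intervals)


def compute_coverage_factor(
    depth_profile, depth_threshold: int = DEFAULT_DEPTH_THRESHOLD
) -> int:
    """Count captured bases with read depth strictly greater than the cutoff.

    Parameters
    ----------
    depth_profile
        Per-base integer depths over a gene's captured bases.
    depth_threshold
        Depth cutoff; a base counts only if its depth exceeds it strictly.
    """
    depths = np.asarray(depth_profile)
    if depths.size == 0:
        raise ValueError("no captured bases")
    if depth_threshold < 0:
        raise ValueError("depth threshold must be >= 0")
    return int((depths > depth_threshold).sum())


def flag_tss_excluded(
    record: GeneRecord, fraction: float = DEFAULT_TSS_FRACTION
) -> bool:
    """True iff every captured base lies in the first ``fraction`` of the gene
    body walking from the TSS in the direction of transcription.

    The window length is ``floor(fraction * gene_length)`` bases.  A gene is
    excluded only when it is *solely* captured inside this TSS-proximal
    window, where H3K36me3 is depleted regardless of transcription.
    """
    if not 0 < fraction <= 1:
        raise ValueError("fraction must be in (0, 1]")
    if not record.captured_intervals:
        raise ValueError(f"{record.gene_id}: no captured intervals")
    w = math.floor(fraction * record.gene_length)
    if record.strand == "+":
        window = (record.tss, record.tss + w)
    else:
        window = (record.tss - w, record.tss)
    return all(a >= window[0] and b <= window[1] for a, b in record.captured_intervals)


@dataclass
class GenePanel:
    """Ordered collection of :class:`GeneRecord` with unique gene ids."""

    genes: list[GeneRecord]
    name: str = "panel"

    def __post_init__(self) -> None:
        ids = [g.gene_id for g in self.genes]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate gene_id: {', '.join(dupes)}")
        self._by_id = {g.gene_id: g for g in self.genes}

    def __len__(self) -> int:
        return len(self.genes)

    def __getitem__(self, gene_id: str) -> GeneRecord:
        return self._by_id[gene_id]

    def __contains__(self, gene_id: str) -> bool:
        return gene_id in self._by_id

    @property
    def gene_ids(self) -> list[str]:
        return [g.gene_id for g in self.genes]

    @property
    def included_ids(self) -> list[str]:
        return [g.gene_id for g in self.genes if g.included]

    def coverage_factors(self, included_only: bool = True) -> pd.Series:
        genes = [g for g in self.genes if g.included] if included_only else self.genes
        return pd.Series(
            {g.gene_id: g.coverage_factor_k for g in genes}, name="k", dtype=float
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "gene_id": [g.gene_id for g in self.genes],
                "chrom": [g.chrom for g in self.genes],
                "strand": [g.strand for g in self.genes],
                "tss": [g.tss for g in self.genes],
                "gene_length": [g.gene_length for g in self.genes],
                "k": [g.coverage_factor_k for g in self.genes],
                "included": [g.included for g in self.genes],
            }
        )


def build_panel(
    panel_table: pd.DataFrame,
    capture_intervals: dict[str, list[Interval]] | None = None,
    depth_profiles: dict[str, "np.ndarray"] | None = None,
    depth_threshold: int = DEFAULT_DEPTH_THRESHOLD,
    tss_fraction: float = DEFAULT_TSS_FRACTION,
    name: str = "panel",
) -> GenePanel:
    """Assemble a validated :class:`GenePanel` from tabular annotations.

    The coverage factor is taken from a ``k`` column when present, otherwise
    computed from ``depth_profiles``.  A gene is included iff its coverage
    factor is positive and, when capture geometry is available, it is not
    solely captured within the TSS-proximal exclusion window.
    """
    required = {"gene_id", "chrom", "strand", "tss", "gene_length"}
    missing = required - set(panel_table.columns)
    if missing:
        raise ValueError(f"panel table missing columns: {sorted(missing)}")
    if panel_table["gene_id"].duplicated().any():
        dupes = panel_table.loc[panel_table["gene_id"].duplicated(), "gene_id"]
        raise ValueError(f"duplicate gene_id: {', '.join(sorted(set(dupes)))}")
    capture_intervals = capture_intervals or {}
    has_k = "k" in panel_table.columns

    genes: list[GeneRecord] = []
    for row in panel_table.itertuples(index=False):
        gid = str(row.gene_id)
        if has_k and not pd.isna(row.k):
            k = int(row.k)
        elif depth_profiles is not None and gid in depth_profiles:
            k = compute_coverage_factor(depth_profiles[gid], depth_threshold)
        else:
            raise ValueError(f"{gid}: no coverage factor and no depth profile")
        rec = GeneRecord(
            gene_id=gid,
            chrom=str(row.chrom),
            strand=str(row.strand),
            tss=int(row.tss),
            gene_length=int(row.gene_length),
            captured_intervals=list(capture_intervals.get(gid, [])),
            coverage_factor_k=k,
        )
        excluded_tss = bool(rec.captured_intervals) and flag_tss_excluded(
            rec, tss_fraction
        )
        rec = replace(rec, included=(k > 0 and not excluded_tss))
        if k == 0:
            logger.warning("gene %s has coverage factor 0; excluded from sums", gid)
        genes.append(rec)
    panel = GenePanel(genes=genes, name=name)
    if not panel.included_ids:
        logger.warning("panel %s has no included genes", name)
    return panel
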