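"""Mutational allele fractions in paired input / cfChIP plasma samples.

If the mutant allele of a gene is transcribed more than the wild-type
allele, nucleosomes carrying the active-transcription mark are biased
toward the mutant haplotype, and the mutational allele fraction (MAF =
alt depth / total depth) rises in the immunoprecipitated sample relative to
the same patient's input plasma.  This module pairs variants observed in
both compartments and tests the per-pair MAF shift with a paired t-test.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

COMPARTMENTS = ("input", "cfchip")


@dataclass(frozen=True)
class VariantRecord:
    """One variant observation in one compartment of one patient."""

    patient_id: str
    gene_id: str
    variant_label: str
    compartment: str
    alt_depth: int
    total_depth: int

    def __post_init__(self) -> None:
        if self.compartment not in COMPARTMENTS:
            raise ValueError(f"unknown compartment {self.compartment!r}")
        if self.total_depth <= 0:
            raise ValueError("total_depth must be > 0")
        if not 0 <= self.alt_depth <= self.total_depth:
            raise ValueError("alt_depth must be in [0, total_depth]")

    @property
    def maf(self) -> float:
        return compute_maf(self.alt_depth, self.total_depth)


@dataclass
class PairedMafResult:
    """Summary of the paired input-vs-cfChIP MAF comparison.

    Differences are in percentage points (cfchip minus input); the CI is the
    t-based 95% interval around the mean difference.
    """

    n_pairs: int
    mean_difference: float
    ci95: tuple[float, float]
    p_value: float
    n_increased: int
    n_decreased: int
    pairs: pd.DataFrame


def compute_maf(alt_depth: int, total_depth: int) -> float:
    """Mutational allele fraction alt/total, as a fraction in [0, 1]."""
    if total_depth <= 0:
        raise ValueError("total_depth must be > 0")
    if not 0 <= alt_depth <= total_depth:
        raise ValueError("alt_depth must be in [0, total_depth]")
    return alt_depth / total_depth


def pair_variants(
    records: list[VariantRecord],
) -> list[tuple[VariantRecord, VariantRecord]]:
    """Match variants observed in BOTH compartments of the same patient.

    Returns one (input, cfchip) pair per (patient, variant); records present
    in only one compartment are dropped (count logged).  Each variant is its
    own pair — multiple variants in one gene are not collapsed.
    """
    by_key: dict[tuple[str, str, str], VariantRecord] = {}
    for rec in records:
        key = (rec.patient_id, rec.variant_label, rec.compartment)
        if key in by_key:
            raise ValueError(f"ambiguous pairing: duplicate record for {key}")
        by_key[key] = rec
    pairs = []
    seen = sorted({(p, v) for p, v, _ in by_key})
    for patient, variant in seen:
        inp = by_key.get((patient, variant, "input"))
        cf = by_key.get((patient, variant, "cfchip"))
        if inp is not None and cf is not None:
            pairs.append((inp, cf))
    dropped = len(records) - 2 * len(pairs)
    if dropped:
        logger.info("%d unpaired variant records dropped", dropped)
    return pairs


def paired_maf_test(
    pairs: list[tuple[VariantRecord, VariantRecord]],
    target_gene: str | None = None,
) -> PairedMafResult:
    """Paired t-test of the cfChIP-minus-input MAF difference.

    Differences are reported in percentage points.  With identical
    differences the CI degenerates to a point and the zero-variance rule
    applies: p = 1 for a zero mean difference, p = 0 otherwise (logged).
    """
    if target_gene is not None:
        pairs = [p for p in pairs if p[0].gene_id == target_gene]
    if len(pairs) < 2:
        raise ValueError("need at least 2 pairs for a paired test")
    rows = []
    for inp, cf in pairs:
        rows.append(
            {
                "patient_id": inp.patient_id,
                "gene_id": inp.gene_id,
                "variant_label": inp.variant_label,
                "maf_input": inp.maf,
                "maf_cfchip": cf.maf,
                "difference_pp": (cf.maf - inp.maf) * 100.0,
            }
        )
    table = pd.DataFrame(rows)
    d = table["difference_pp"].to_numpy()
    n = d.size
    mean = float(d.mean())
    sd = float(d.std(ddof=1))
    if sd == 0:
        p = 1.0 if mean == 0 else 0.0
        if mean != 0:
            logger.warning("all paired differences identical and nonzero: p set to 0")
        ci = (mean, mean)
    else:
        t = mean / (sd / np.sqrt(n))
        p = float(2 * stats.t.sf(abs(t), df=n - 1))
        half = float(stats.t.ppf(0.975, df=n - 1) * sd / np.sqrt(n))
        ci = (mean - half, mean + half)
    return PairedMafResult(
        n_pairs=n,
        mean_difference=mean,
        ci95=ci,
        p_value=p,
        n_increased=int((d > 0).sum()),
        n_decreased=int((d < 0).sum()),
        pairs=table,
    )
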