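"""End-to-end orchestration: panel -> enrichment -> differential expression
-> concordance -> allele fractions, with input validation and a derived run
report.

The pipeline is a pure function of its input files and configuration: two
runs on identical inputs write byte-identical outputs.  Every number in the
report is recomputable from the stage TSVs it writes.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io
from .concordance import (
    agreement_analysis,
    roc_active_genes,
    sensitivity_at_specificity,
    spearman,
)
from .enrichment import (
    SCALE,
    chip_enrichment,
    cfchip_relative_enrichment,
    make_background,
    relative_log2fc,
)
from .expression import ACTIVITY_THRESHOLD, differential_expression, log_transform
from .variants import pair_variants, paired_maf_test

logger = logging.getLogger(__name__)

__version__ = "0.1.0"


@dataclass
class PipelineConfig:
    """File locations, group definitions and analysis thresholds."""

    panel: str
    counts: str
    samples: str
    out_dir: str
    capture_bed: str | None = None
    tpm: str | None = None
    variants: str | None = None
    group_a: str = "NSCLC"
    group_b: str = "SCLC"
    healthy_condition: str = "healthy"
    fc_threshold: float = 1.0
    q_threshold: float = 0.05
    activity_threshold: float = ACTIVITY_THRESHOLD
    specificity_cutoff: float = 0.75
    tss_fraction: float = 0.25
    depth_threshold: int = 100
    pseudo: float | None = None
    target_gene: str | None = None

    def __post_init__(self) -> None:
        if self.group_a == self.group_b:
            raise ValueError("groups must be distinct")
        for name in ("fc_threshold", "q_threshold", "activity_threshold",
                     "specificity_cutoff", "tss_fraction"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            return cls(**yaml.safe_load(fh))


@dataclass
class Finding:
    level: str  # "warning" | "fatal"
    message: str


@dataclass
class RunReport:
    """Derived summary of one pipeline run (never authoritative: every value
    is recomputable from the stage output files)."""

    version: str = __version__
    config: dict = field(default_factory=dict)
    stages: dict = field(default_factory=dict)
    warnings: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "version": self.version,
            "config": self.config,
            "stages": self.stages,
            "warnings": self.warnings,
        }


def validate_inputs(config: PipelineConfig) -> list[Finding]:
    """Pre-flight checks; returns findings rather than raising, with
    ``fatal`` findings meaning the pipeline cannot run."""
    findings: list[Finding] = []
    for name in ("panel", "counts", "samples"):
        if not Path(getattr(config, name)).exists():
            findings.append(Finding("fatal", f"missing {name} file"))
    for name in ("tpm", "variants", "capture_bed"):
        path = getattr(config, name)
        if path is not None and not Path(path).exists():
            findings.append(Finding("fatal", f"missing {name} file"))
    if any(f.level == "fatal" for f in findings):
        return findings

    panel = io.read_panel(config.panel, config.capture_bed,
                          tss_fraction=config.tss_fraction)
    counts = io.read_counts(config.counts, config.samples)
    extra = set(counts.gene_ids) - set(panel.gene_ids)
    if extra:
        findings.append(
            Finding("fatal", f"counts contain genes absent from panel: {sorted(extra)[:5]}")
        )
    missing = set(panel.included_ids) - set(counts.gene_ids)
    if missing:
        findings.append(
            Finding("fatal", f"counts missing panel genes: {sorted(missing)[:5]}")
        )
    if not panel.included_ids:
        findings.append(Finding("fatal", "panel has no included genes"))
    if config.tpm is not None:
        expr = io.read_expression(config.tpm, config.samples)
        for group in (config.group_a, config.group_b):
            n = len(expr.replicates(group))
            if n == 0:
                findings.append(Finding("fatal", f"no replicates for group {group}"))
            elif n < 2:
                findings.append(
                    Finding("warning",
                            f"group {group} has one replicate: tests will be skipped")
                )
    return findings


def _conservation(values: pd.DataFrame, k: pd.Series) -> float:
    """Max relative deviation of sum(E_i * k_i) from 1e9 across samples."""
    sums = values.mul(k, axis=0).sum(axis=0)
    return float((sums / SCALE - 1.0).abs().max())


def run_pipeline(config: PipelineConfig) -> RunReport:
    """Execute all stages and write outputs under ``config.out_dir``."""
    findings = validate_inputs(config)
    fatal = [f for f in findings if f.level == "fatal"]
    if fatal:
        raise ValueError("validation failed: " + "; ".join(f.message for f in fatal))
    report = RunReport(config={k: v for k, v in vars(config).items()})
    report.warnings = [f.message for f in findings if f.level == "warning"]
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    # --- panel
    panel = io.read_panel(config.panel, config.capture_bed,
                          tss_fraction=config.tss_fraction)
    io.write_panel(panel, out / "panel_validated.tsv")
    report.stages["panel"] = {
        "genes": len(panel),
        "included": len(panel.included_ids),
        "excluded": len(panel) - len(panel.included_ids),
    }

    # --- enrichment
    counts = io.read_counts(config.counts, config.samples)
    k = panel.coverage_factors()
    groups = counts.samples["condition"]
    stage: dict = {}
    rel_fc = None
    chip = counts.select(assay="chip")
    if chip.counts.shape[1] > 0:
        prof = chip_enrichment(chip, panel)
        io.write_enrichment(prof, out / "enrichment_chip.tsv")
        stage["chip_samples"] = prof.values.shape[1]
        stage["chip_conservation_max_rel_err"] = _conservation(prof.values, k)

    cf = counts.select(assay="cfchip")
    healthy = cf.select(condition=config.healthy_condition)
    cf_patients = cf.select(condition=[config.group_a, config.group_b])
    if healthy.counts.shape[1] and cf_patients.counts.shape[1]:
        background = make_background(healthy, panel)
        rel = cfchip_relative_enrichment(cf_patients, background, panel)
        io.write_enrichment(rel, out / "enrichment_relative.tsv")
        stage["cfchip_patients"] = rel.values.shape[1]
        stage["background_donors"] = background.n_donors
        stage["relative_conservation_max_rel_err"] = _conservation(rel.values, k)
        means = rel.group_means(groups)
        if {config.group_a, config.group_b} <= set(means.columns):
            rel_fc = relative_log2fc(
                means[config.group_a], means[config.group_b], pseudo=config.pseudo
            )
    elif chip.counts.shape[1] > 0:
        report.warnings.append("no background subtraction: no healthy cfChIP samples")
        means = prof.group_means(groups)
        if {config.group_a, config.group_b} <= set(means.columns):
            rel_fc = relative_log2fc(
                means[config.group_a], means[config.group_b], pseudo=config.pseudo
            )
    if rel_fc is not None:
        rel_fc.rename_axis("gene_id").to_frame().to_csv(
            out / "relative_log2fc.tsv", sep="\t"
        )
    report.stages["enrichment"] = stage

    # --- differential expression + concordance
    if config.tpm is not None:
        expr = io.read_expression(config.tpm, config.samples)
        de = differential_expression(
            expr,
            config.group_a,
            config.group_b,
            fc_threshold=config.fc_threshold,
            q_threshold=config.q_threshold,
            activity_threshold=config.activity_threshold,
        )
        de.to_csv(out / "differential_expression.tsv", sep="\t", index=False)
        n_status = de["status"].value_counts().to_dict()
        report.stages["differential_expression"] = {
            "genes_in": len(de),
            "filtered_inactive": int(n_status.get("filtered_inactive", 0)),
            "tested": int(len(de) - n_status.get("filtered_inactive", 0)),
            "up_in_a": int(n_status.get("up_in_a", 0)),
            "up_in_b": int(n_status.get("up_in_b", 0)),
        }
        conc: dict = {}
        log_means = log_transform(expr.tpm).T.groupby(expr.groups).mean().T
        if config.group_a in log_means and chip.counts.shape[1] > 0:
            chip_a = chip.select(condition=config.group_a)
            if chip_a.counts.shape[1] > 0:
                score = chip_enrichment(chip_a, panel).values.mean(axis=1)
                common = score.index
                active = log_means.loc[common, config.group_a] > config.activity_threshold
                if active.any() and (~active).any():
                    roc = roc_active_genes(score.to_numpy(), active.to_numpy())
                    pd.DataFrame(roc.curve, columns=["specificity", "sensitivity"]).to_csv(
                        out / "roc_points.tsv", sep="\t", index=False
                    )
                    conc["roc"] = {
                        "auc": roc.auc, "se": roc.se, "z": roc.z,
                        "p_value": roc.p_value,
                        "sensitivity_at_specificity": sensitivity_at_specificity(
                            roc, config.specificity_cutoff
                        ),
                    }
                rho, p_rho = spearman(
                    score.to_numpy(), log_means.loc[common, config.group_a].to_numpy()
                )
                conc["spearman"] = {"rho": rho, "p_value": p_rho}
        if rel_fc is not None:
            de_genes = de.loc[de["status"].isin(["up_in_a", "up_in_b"]), "gene_id"]
            # DE genes not on the analysable panel (TSS-excluded or k=0)
            # cannot enter the agreement comparison
            n_off_panel = int((~de_genes.isin(rel_fc.index)).sum())
            de_on_panel = de[de["gene_id"].isin(rel_fc.index)]
            if len(de_genes) > n_off_panel:
                if n_off_panel:
                    report.warnings.append(
                        f"{n_off_panel} DE genes outside the included panel "
                        "dropped from the agreement analysis"
                    )
                agr = agreement_analysis(de_on_panel, rel_fc)
                rows = []
                for direction in ("a", "b"):
                    for verdict in ("agree", "disagree"):
                        for g in agr.genes[f"up_in_{direction}_{verdict}"]:
                            rows.append((g, f"up_in_{direction}", verdict))
                pd.DataFrame(rows, columns=["gene_id", "direction", "agreement"]).to_csv(
                    out / "agreement.tsv", sep="\t", index=False
                )
                conc["agreement"] = {
                    "sensitivity_a": agr.sensitivity_a,
                    "sensitivity_b": agr.sensitivity_b,
                    "contingency": agr.contingency.tolist(),
                    "fisher_p": agr.fisher_p,
                }
        report.stages["concordance"] = conc

    # --- allele fractions
    if config.variants is not None:
        records = io.read_variants(config.variants)
        pairs = pair_variants(records)
        maf_stage: dict = {
            "records": len(records),
            "pairs": len(pairs),
            "unpaired_dropped": len(records) - 2 * len(pairs),
        }
        if len(pairs) >= 2:
            res = paired_maf_test(pairs)
            res.pairs.to_csv(out / "maf_pairs.tsv", sep="\t", index=False)
            maf_stage["all"] = {
                "n_pairs": res.n_pairs,
                "mean_difference_pp": res.mean_difference,
                "ci95": list(res.ci95),
                "p_value": res.p_value,
                "n_increased": res.n_increased,
                "n_decreased": res.n_decreased,
            }
        if config.target_gene is not None:
            gene_pairs = [p for p in pairs if p[0].gene_id == config.target_gene]
            if len(gene_pairs) >= 2:
                res_g = paired_maf_test(pairs, target_gene=config.target_gene)
                maf_stage[config.target_gene] = {
                    "n_pairs": res_g.n_pairs,
                    "mean_difference_pp": res_g.mean_difference,
                    "ci95": list(res_g.ci95),
                    "p_value": res_g.p_value,
                }
        report.stages["maf"] = maf_stage

    _write_report(report, out)
    return report


def _write_report(report: RunReport, out: Path) -> None:
    with open(out / "report.json", "w") as fh:
        json.dump(report.to_dict(), fh, indent=2, sort_keys=True, default=str)
        fh.write("\n")
    lines = [f"cfchip pipeline report (v{report.version})", ""]
    for stage, values in report.stages.items():
        lines.append(f"[{stage}]")
        lines.extend(f"  {k}: {v}" for k, v in values.items())
        lines.append("")
    if report.warnings:
        lines.append("[warnings]")
        lines.extend(f"  - {w}" for w in report.warnings)
        lines.append("")
    (out / "report.txt").write_text("\n".join(lines))
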