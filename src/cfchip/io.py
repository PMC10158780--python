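"""Readers and writers for the plain-text interchange formats.

Everything is tab-separated text; genomic intervals use the BED convention
(0-based half-open).  One sample sheet (``sample_id``, ``condition``,
``assay``) is shared by count and TPM matrices.
"""

from __future__ import annotations

import os
from pathlib import Path

import pandas as pd

from .enrichment import CountMatrix, EnrichmentProfile
from .expression import ExpressionMatrix
from .panel import GenePanel, build_panel
from .synthetic import SyntheticDataset, config_to_dict
from .variants import VariantRecord

PANEL_COLUMNS = ["gene_id", "chrom", "strand", "tss", "gene_length", "k"]
VARIANT_COLUMNS = [
    "patient_id",
    "gene_id",
    "variant_label",
    "compartment",
    "alt_depth",
    "total_depth",
]


def read_bed_intervals(path: str | Path) -> dict[str, list[tuple[int, int]]]:
    """Capture geometry BED: chrom, start, end, gene_id."""
    bed = pd.read_csv(
        path, sep="\t", header=None, comment="#",
        names=["chrom", "start", "end", "gene_id"],
    )
    out: dict[str, list[tuple[int, int]]] = {}
    for row in bed.itertuples(index=False):
        out.setdefault(str(row.gene_id), []).append((int(row.start), int(row.end)))
    return out


def read_panel(
    panel_path: str | Path,
    capture_bed: str | Path | None = None,
    **kwargs,
) -> GenePanel:
    table = pd.read_csv(panel_path, sep="\t", comment="#")
    intervals = read_bed_intervals(capture_bed) if capture_bed else None
    name = kwargs.pop("name", Path(panel_path).stem)
    return build_panel(table, capture_intervals=intervals, name=name, **kwargs)


def write_panel(panel: GenePanel, path: str | Path) -> None:
    panel.to_frame().to_csv(path, sep="\t", index=False)


def write_capture_bed(panel: GenePanel, path: str | Path) -> None:
    rows = []
    for g in panel.genes:
        for a, b in g.captured_intervals:
            rows.append((g.chrom, a, b, g.gene_id))
    pd.DataFrame(rows, columns=["chrom", "start", "end", "gene_id"]).to_csv(
        path, sep="\t", index=False, header=False
    )


def read_sample_sheet(path: str | Path) -> pd.DataFrame:
    samples = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    required = {"sample_id", "condition", "assay"}
    missing = required - set(samples.columns)
    if missing:
        raise ValueError(f"sample sheet missing columns: {sorted(missing)}")
    return samples


def read_counts(counts_path: str | Path, samples_path: str | Path) -> CountMatrix:
    counts = pd.read_csv(counts_path, sep="\t", comment="#", index_col="gene_id")
    samples = read_sample_sheet(samples_path)
    keep = [s for s in samples["sample_id"] if s in counts.columns]
    return CountMatrix(
        counts=counts[keep], samples=samples[samples["sample_id"].isin(keep)]
    )


def write_counts(counts: CountMatrix, counts_path: str | Path) -> None:
    counts.counts.rename_axis("gene_id").to_csv(counts_path, sep="\t")


def write_sample_sheet(samples: pd.DataFrame, path: str | Path) -> None:
    samples[["sample_id", "condition", "assay"]].to_csv(path, sep="\t", index=False)


def read_expression(tpm_path: str | Path, samples_path: str | Path) -> ExpressionMatrix:
    tpm = pd.read_csv(tpm_path, sep="\t", comment="#", index_col="gene_id")
    samples = read_sample_sheet(samples_path).set_index("sample_id")
    groups = samples.loc[[c for c in tpm.columns if c in samples.index], "condition"]
    return ExpressionMatrix(tpm=tpm[list(groups.index)], groups=groups)


def write_expression(expr: ExpressionMatrix, tpm_path: str | Path) -> None:
    expr.tpm.rename_axis("gene_id").to_csv(tpm_path, sep="\t")


def write_enrichment(profile: EnrichmentProfile, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(f"# kind={profile.kind}\n")
        profile.values.rename_axis("gene_id").to_csv(fh, sep="\t")


def read_enrichment(path: str | Path) -> EnrichmentProfile:
    kind = "chip"
    with open(path) as fh:
        first = fh.readline()
        if first.startswith("# kind="):
            kind = first.strip().split("=", 1)[1]
    values = pd.read_csv(path, sep="\t", comment="#", index_col="gene_id")
    return EnrichmentProfile(values=values, kind=kind)


def read_variants(path: str | Path) -> list[VariantRecord]:
    table = pd.read_csv(path, sep="\t", comment="#")
    missing = set(VARIANT_COLUMNS) - set(table.columns)
    if missing:
        raise ValueError(f"variant table missing columns: {sorted(missing)}")
    return [
        VariantRecord(
            patient_id=str(r.patient_id),
            gene_id=str(r.gene_id),
            variant_label=str(r.variant_label),
            compartment=str(r.compartment),
            alt_depth=int(r.alt_depth),
            total_depth=int(r.total_depth),
        )
        for r in table.itertuples(index=False)
    ]


def write_variants(records: list[VariantRecord], path: str | Path) -> None:
    pd.DataFrame(
        [
            {
                "patient_id": r.patient_id,
                "gene_id": r.gene_id,
                "variant_label": r.variant_label,
                "compartment": r.compartment,
                "alt_depth": r.alt_depth,
                "total_depth": r.total_depth,
            }
            for r in records
        ],
        columns=VARIANT_COLUMNS,
    ).to_csv(path, sep="\t", index=False)


def write_dataset(dataset: SyntheticDataset, out_dir: str | Path) -> dict[str, Path]:
    """Write a simulated dataset as the pipeline's input files."""
    import yaml

    out = Path(out_dir)
    os.makedirs(out, exist_ok=True)
    paths = {
        "panel": out / "panel.tsv",
        "capture_bed": out / "capture.bed",
        "counts": out / "counts.tsv",
        "samples": out / "samples.tsv",
        "tpm": out / "tpm.tsv",
        "variants": out / "variants.tsv",
        "truth": out / "truth.tsv",
        "config": out / "sim_config.yaml",
    }
    write_panel(dataset.panel, paths["panel"])
    write_capture_bed(dataset.panel, paths["capture_bed"])
    write_counts(dataset.counts, paths["counts"])
    rna_samples = pd.DataFrame(
        {
            "sample_id": dataset.expression.tpm.columns,
            "condition": dataset.expression.groups.to_numpy(),
            "assay": "rna",
        }
    )
    write_sample_sheet(
        pd.concat(
            [dataset.counts.samples.reset_index(drop=True), rna_samples],
            ignore_index=True,
        ),
        paths["samples"],
    )
    write_expression(dataset.expression, paths["tpm"])
    write_variants(dataset.variants, paths["variants"])
    dataset.truth.drop(columns=["gene_id"]).rename_axis("gene_id").to_csv(
        paths["truth"], sep="\t"
    )
    with open(paths["config"], "w") as fh:
        yaml.safe_dump(config_to_dict(dataset.config), fh, sort_keys=True)
    return paths
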