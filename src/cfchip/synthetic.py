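"""Seedable generator of panel-scale synthetic datasets.

Emulates the statistical structure a targeted H3K36me3 (cf)ChIP study
produces, so every analysis stage can be exercised without sequencing data:

* a capture panel with realistic geometry, including a block of genes
  captured only near the TSS (excluded from analysis);
* TPM expression for two tumour groups: active genes with log-normal
  abundance, inactive genes with near-zero expression, a configurable set
  of differentially expressed genes, Gaussian replicate noise on the
  log2(TPM+1) scale;
* negative-binomial panel read counts whose expected rate per gene is
  proportional to (expression + nonspecific pulldown) x captured footprint,
  scaled to a log-uniform library size;
* plasma cfChIP samples as a tumour-fraction mixture of a sparse
  hematopoietic (PBMC-like) background expression profile and a tumour
  profile;
* allele-specific variant depths: binomial alt counts in the input
  compartment, with a logit-scale allele-fraction shift in the cfChIP
  compartment emulating preferential enrichment of the expressed allele.

All randomness flows from one seeded :class:`numpy.random.Generator`; the
same seed and config reproduce the dataset bit for bit.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .enrichment import CountMatrix
from .expression import ExpressionMatrix, ACTIVITY_THRESHOLD
from .panel import GenePanel, GeneRecord, build_panel
from .variants import VariantRecord


@dataclass
class VariantSpec:
    """One simulated somatic variant: gene, truth input MAF and the logit
    shift applied to the cfChIP-compartment allele fraction."""

    gene_index: int
    input_maf: float
    expression_bias: float


@dataclass
class SimulationConfig:
    """Generative parameters; defaults mirror the study shape (197-gene
    panel, 36 TSS-excluded genes, triplicate cell lines, 4 healthy donors,
    8 + 4 patients)."""

    n_genes: int = 197
    n_excluded_tss: int = 36
    seed: int = 0
    k_range: tuple[int, int] = (600, 6000)
    # expression model: active-gene TPM is log-normal (natural-log mu/sigma);
    # inactive-gene TPM is exponential with a small scale (near-zero mass)
    active_fraction: float = 0.76
    expression_mu: float = 1.5
    expression_sigma: float = 1.3
    inactive_tpm_scale: float = 0.03
    n_de_genes: int = 20
    de_effect_log2: float = 2.0
    replicate_sigma: float = 0.1
    replicates_per_line: int = 3
    # count model
    enrichment_slope: float = 1.0
    nonspecific_tpm: float = 1.5
    dispersion: float = 4.0
    poisson: bool = False
    library_size_range: tuple[float, float] = (5e5, 2e6)
    # healthy donors carry far less cfDNA than cancer patients, so their
    # cfChIP libraries are systematically smaller; this also keeps the
    # background-subtracted library size (sum N - sum Hbar) positive
    healthy_library_size_range: tuple[float, float] = (1e5, 4e5)
    # plasma model
    background_profile: np.ndarray | None = None
    tumor_fraction: float = 0.3
    n_healthy: int = 4
    n_patients_a: int = 8
    n_patients_b: int = 4
    group_a: str = "NSCLC"
    group_b: str = "SCLC"
    # variant model
    variant_spec: list[VariantSpec] | None = None
    variant_depth_mean: float = 1500.0

    def __post_init__(self) -> None:
        if not 0 < self.active_fraction <= 1:
            raise ValueError("active_fraction must be in (0, 1]")
        if not 0 <= self.tumor_fraction <= 1:
            raise ValueError("tumor_fraction must be in [0, 1]")
        if self.dispersion <= 0:
            raise ValueError("dispersion must be > 0")
        if self.n_excluded_tss >= self.n_genes:
            raise ValueError("n_excluded_tss must be < n_genes")
        if self.replicate_sigma < 0 or self.n_genes <= 0:
            raise ValueError("invalid config")


@dataclass
class SyntheticDataset:
    """A complete simulated study with per-gene ground truth."""

    panel: GenePanel
    expression: ExpressionMatrix
    counts: CountMatrix
    variants: list[VariantRecord]
    truth: pd.DataFrame
    config: SimulationConfig


# ---------------------------------------------------------------------------
# panel geometry


def simulate_panel(config: SimulationConfig, rng: np.random.Generator) -> GenePanel:
    """Panel with ``n_genes`` genes of which ``n_excluded_tss`` are captured
    solely within the first quarter of the gene body."""
    n = config.n_genes
    excluded = np.zeros(n, dtype=bool)
    excluded[rng.choice(n, size=config.n_excluded_tss, replace=False)] = True
    genes: list[GeneRecord] = []
    for i in range(n):
        gid = f"G{i + 1:04d}"
        chrom = f"chr{(i % 22) + 1}"
        strand = "+" if rng.random() < 0.5 else "-"
        length = int(rng.integers(20_000, 100_000))
        window = int(0.25 * length)
        if excluded[i]:
            k = int(rng.integers(config.k_range[0], min(config.k_range[1], window - 20)))
            offset = int(rng.integers(10, window - k - 5))
        else:
            k = int(rng.integers(*config.k_range))
            offset = int(rng.integers(length // 2, length - k - 5))
        tss = int(1_000_000 * (i + 1))
        if strand == "+":
            interval = (tss + offset, tss + offset + k)
        else:
            interval = (tss - offset - k, tss - offset)
        genes.append(
            GeneRecord(
                gene_id=gid,
                chrom=chrom,
                strand=strand,
                tss=tss,
                gene_length=length,
                captured_intervals=[interval],
                coverage_factor_k=k,
                included=not excluded[i],
            )
        )
    return GenePanel(genes=genes, name="synthetic-panel")


# ---------------------------------------------------------------------------
# expression


def simulate_expression(
    config: SimulationConfig, rng: np.random.Generator
) -> tuple[ExpressionMatrix, pd.DataFrame]:
    """Group-level TPM truth plus replicate matrices for two tumour groups.

    Active genes draw a log-normal TPM; a subset is made differentially
    expressed by a symmetric +-(effect/2) shift on the log2(TPM+1) scale.
    Replicates add Gaussian noise on that same scale.
    """
    n = config.n_genes
    ids = [f"G{i + 1:04d}" for i in range(n)]
    n_active = int(round(config.active_fraction * n))
    active = np.zeros(n, dtype=bool)
    active[rng.choice(n, size=n_active, replace=False)] = True

    base = np.empty(n)
    tpm_active = rng.lognormal(config.expression_mu, config.expression_sigma, size=n)
    base_active = np.log2(tpm_active + 1.0)
    base_active = np.maximum(base_active, ACTIVITY_THRESHOLD + 0.1)
    tpm_inactive = rng.exponential(config.inactive_tpm_scale, size=n)
    base_inactive = np.minimum(np.log2(tpm_inactive + 1.0), ACTIVITY_THRESHOLD - 0.01)
    base[active] = base_active[active]
    base[~active] = base_inactive[~active]

    de_direction = np.full(n, "none", dtype=object)
    active_idx = np.flatnonzero(active)
    n_de = min(config.n_de_genes, active_idx.size)
    de_idx = rng.choice(active_idx, size=n_de, replace=False)
    half = n_de // 2
    de_direction[de_idx[:half]] = "up_in_a"
    de_direction[de_idx[half:]] = "up_in_b"

    shift = np.zeros(n)
    shift[de_direction == "up_in_a"] = config.de_effect_log2 / 2.0
    shift[de_direction == "up_in_b"] = -config.de_effect_log2 / 2.0
    mean_a = np.maximum(base + shift, 0.0)
    mean_b = np.maximum(base - shift, 0.0)

    cols, data, groups = [], [], {}
    for group, mean in ((config.group_a, mean_a), (config.group_b, mean_b)):
        for r in range(config.replicates_per_line):
            rep = f"{group}_rep{r + 1}"
            noise = rng.normal(0.0, config.replicate_sigma, size=n)
            log_vals = np.maximum(mean + noise, 0.0)
            data.append(np.power(2.0, log_vals) - 1.0)
            cols.append(rep)
            groups[rep] = group
    tpm = pd.DataFrame(np.column_stack(data), index=ids, columns=cols)
    expr = ExpressionMatrix(tpm=tpm, groups=pd.Series(groups))
    truth = pd.DataFrame(
        {
            "gene_id": ids,
            "active": active,
            "active_a": mean_a > ACTIVITY_THRESHOLD,
            "active_b": mean_b > ACTIVITY_THRESHOLD,
            "de_direction": de_direction,
            "log_mean_a": mean_a,
            "log_mean_b": mean_b,
            "tpm_a": np.power(2.0, mean_a) - 1.0,
            "tpm_b": np.power(2.0, mean_b) - 1.0,
        }
    ).set_index("gene_id", drop=False)
    return expr, truth


# ---------------------------------------------------------------------------
# counts


def _expected_rates(
    tpm: np.ndarray, k: np.ndarray, config: SimulationConfig
) -> np.ndarray:
    """Un-normalised expected read rate per gene: specific signal
    proportional to expression plus nonspecific pulldown, both scaled by the
    captured footprint."""
    return (config.enrichment_slope * tpm + config.nonspecific_tpm) * k


def _draw_counts(
    rates: np.ndarray,
    library_size: float,
    config: SimulationConfig,
    rng: np.random.Generator,
) -> np.ndarray:
    total = rates.sum()
    if library_size <= 0 or total <= 0:
        raise ValueError("zero library size")
    mu = library_size * rates / total
    if config.poisson:
        return rng.poisson(mu)
    r = config.dispersion
    # NB with mean mu, variance mu + mu^2/r; genes with mu = 0 stay at 0
    out = np.zeros_like(mu, dtype=np.int64)
    pos = mu > 0
    out[pos] = rng.negative_binomial(r, r / (r + mu[pos]))
    return out


def _draw_library(
    config: SimulationConfig,
    rng: np.random.Generator,
    size_range: tuple[float, float] | None = None,
) -> float:
    lo, hi = size_range or config.library_size_range
    return float(np.exp(rng.uniform(np.log(lo), np.log(hi))))


def simulate_chip_counts(
    tpm_means: pd.Series,
    panel: GenePanel,
    config: SimulationConfig,
    rng: np.random.Generator,
    sample_ids: list[str],
    condition: str,
    assay: str = "chip",
    library_sizes: list[float] | None = None,
    library_size_range: tuple[float, float] | None = None,
) -> CountMatrix:
    """Negative-binomial panel counts for replicate samples sharing one
    expression profile (linear TPM per gene)."""
    k = np.array([panel[g].coverage_factor_k for g in panel.gene_ids], dtype=float)
    rates = _expected_rates(tpm_means.loc[panel.gene_ids].to_numpy(), k, config)
    cols = {}
    for j, sid in enumerate(sample_ids):
        lib = (
            library_sizes[j]
            if library_sizes
            else _draw_library(config, rng, library_size_range)
        )
        cols[sid] = _draw_counts(rates, lib, config, rng)
    counts = pd.DataFrame(cols, index=panel.gene_ids)
    samples = pd.DataFrame(
        {"sample_id": sample_ids, "condition": condition, "assay": assay}
    )
    return CountMatrix(counts=counts, samples=samples)


def simulate_plasma(
    background_tpm: pd.Series,
    tumor_tpm: pd.Series | None,
    tumor_fraction: float,
    panel: GenePanel,
    config: SimulationConfig,
    rng: np.random.Generator,
    sample_ids: list[str],
    condition: str,
) -> CountMatrix:
    """cfChIP counts for plasma samples: the expected expression profile is
    a (1 - f) background + f tumour mixture; healthy donors use f = 0."""
    if tumor_tpm is not None and list(tumor_tpm.index) != list(background_tpm.index):
        raise ValueError("mismatched background/tumor profiles")
    if tumor_tpm is None:
        if tumor_fraction != 0:
            raise ValueError("tumor_fraction > 0 requires a tumor profile")
        mix = background_tpm
    else:
        mix = (1.0 - tumor_fraction) * background_tpm + tumor_fraction * tumor_tpm
    size_range = (
        config.healthy_library_size_range if tumor_tpm is None else None
    )
    return simulate_chip_counts(
        mix, panel, config, rng, sample_ids, condition, assay="cfchip",
        library_size_range=size_range,
    )


def default_background_profile(
    config: SimulationConfig, rng: np.random.Generator
) -> pd.Series:
    """PBMC-like sparse expression: most panel genes near zero, a small
    subset highly expressed (the hematopoietic signature that dominates
    healthy plasma)."""
    n = config.n_genes
    tpm = rng.exponential(0.1, size=n)
    n_high = max(1, n // 12)
    high = rng.choice(n, size=n_high, replace=False)
    tpm[high] = rng.lognormal(2.5, 0.5, size=n_high)
    return pd.Series(tpm, index=[f"G{i + 1:04d}" for i in range(n)])


# ---------------------------------------------------------------------------
# variants


def _default_variant_spec(
    config: SimulationConfig, truth: pd.DataFrame, rng: np.random.Generator
) -> list[VariantSpec]:
    """Nine variants on distinct active genes; seven with a positive
    allele-expression bias, two negative."""
    active_idx = np.flatnonzero(truth["active"].to_numpy())
    chosen = rng.choice(active_idx, size=min(9, active_idx.size), replace=False)
    specs = []
    for j, gi in enumerate(chosen):
        maf = float(rng.uniform(0.08, 0.35))
        bias = 0.5 if j < 7 else -0.5
        specs.append(VariantSpec(gene_index=int(gi), input_maf=maf, expression_bias=bias))
    return specs


def _logit(p: float) -> float:
    return float(np.log(p / (1.0 - p)))


def _sigmoid(x: float) -> float:
    return float(1.0 / (1.0 + np.exp(-x)))


def simulate_variants(
    config: SimulationConfig,
    counts: CountMatrix,
    panel: GenePanel,
    rng: np.random.Generator,
    specs: list[VariantSpec],
    patient_ids: list[str] | None = None,
) -> list[VariantRecord]:
    """Paired input/cfChIP variant depths.

    Input alt depths are binomial at the configured allele fraction; the
    cfChIP compartment shifts the allele fraction by the variant's
    configured logit-scale bias, emulating
    preferential precipitation of the transcribed (mutant) haplotype.
    cfChIP total depth is tied to the gene's simulated read count.
    """
    cf_samples = list(counts.samples.index[counts.samples["assay"] == "cfchip"])
    if patient_ids is None:
        patient_ids = cf_samples
    records: list[VariantRecord] = []
    for j, spec in enumerate(specs):
        gid = f"G{spec.gene_index + 1:04d}"
        if gid not in panel:
            raise ValueError(f"variant on non-panel gene {gid}")
        patient = patient_ids[j % len(patient_ids)]
        depth_in = max(100, int(rng.poisson(config.variant_depth_mean)))
        alt_in = int(rng.binomial(depth_in, spec.input_maf))
        maf_cf = _sigmoid(_logit(spec.input_maf) + spec.expression_bias)
        depth_cf = max(100, int(counts.counts.loc[gid, patient]))
        alt_cf = int(rng.binomial(depth_cf, maf_cf))
        label = f"{gid}-var{j + 1}"
        records.append(
            VariantRecord(patient, gid, label, "input", alt_in, depth_in)
        )
        records.append(
            VariantRecord(patient, gid, label, "cfchip", alt_cf, depth_cf)
        )
    return records


# ---------------------------------------------------------------------------
# full dataset and analytic expectations


def simulate_dataset(config: SimulationConfig | None = None) -> SyntheticDataset:
    """Generate a full study: panel, expression, ChIP + plasma counts,
    variants and the per-gene truth table."""
    config = config or SimulationConfig()
    rng = np.random.default_rng(config.seed)
    panel = simulate_panel(config, rng)
    expr, truth = simulate_expression(config, rng)
    truth["k"] = [panel[g].coverage_factor_k for g in truth.index]
    truth["included"] = [panel[g].included for g in truth.index]

    blocks = []
    for group, col in ((config.group_a, "tpm_a"), (config.group_b, "tpm_b")):
        ids = [f"chip_{group}_{r + 1}" for r in range(config.replicates_per_line)]
        blocks.append(
            simulate_chip_counts(truth[col], panel, config, rng, ids, group, "chip")
        )
    if config.background_profile is not None:
        background = pd.Series(
            np.asarray(config.background_profile, dtype=float), index=truth.index
        )
    else:
        background = default_background_profile(config, rng)
    truth["background_tpm"] = background
    healthy_ids = [f"cf_healthy_{r + 1}" for r in range(config.n_healthy)]
    blocks.append(
        simulate_plasma(
            background, None, 0.0, panel, config, rng, healthy_ids, "healthy"
        )
    )
    for group, col, n_pat in (
        (config.group_a, "tpm_a", config.n_patients_a),
        (config.group_b, "tpm_b", config.n_patients_b),
    ):
        ids = [f"cf_{group}_{r + 1}" for r in range(n_pat)]
        blocks.append(
            simulate_plasma(
                background,
                truth[col],
                config.tumor_fraction,
                panel,
                config,
                rng,
                ids,
                group,
            )
        )
    counts = CountMatrix(
        counts=pd.concat([b.counts for b in blocks], axis=1),
        samples=pd.concat(
            [b.samples for b in blocks], ignore_index=True
        ),
    )
    specs = config.variant_spec or _default_variant_spec(config, truth, rng)
    patient_ids = [
        s for s in counts.samples.index
        if counts.samples.loc[s, "assay"] == "cfchip"
        and counts.samples.loc[s, "condition"] != "healthy"
    ]
    variants = simulate_variants(config, counts, panel, rng, specs, patient_ids)
    return SyntheticDataset(
        panel=panel,
        expression=expr,
        counts=counts,
        variants=variants,
        truth=truth,
        config=config,
    )


def expected_activity_auc(
    dataset: SyntheticDataset, library_size: float, group: str = "a"
) -> float:
    """Expected activity ROC AUC for one ChIP sample, conditional on the
    dataset's truth.

    For each (active, inactive) gene pair the exceedance probability
    ``P(N_i/k_i > N_j/k_j) + P(=)/2`` is computed from the two genes'
    negative-binomial count laws (mean = library x rate share, shape =
    dispersion), summing over the inactive gene's truncated support; the
    expectation of the Mann-Whitney AUC is the mean over all pairs.
    """
    from scipy.stats import nbinom, poisson

    config = dataset.config
    truth = dataset.truth
    col = f"tpm_{group}"
    act_col = f"active_{group}"
    included = truth["included"].to_numpy()
    k_all = truth["k"].to_numpy(dtype=float)
    rates = _expected_rates(truth[col].to_numpy(), k_all, config)
    mu = library_size * rates / rates.sum()

    act = np.flatnonzero(included & truth[act_col].to_numpy())
    inact = np.flatnonzero(included & ~truth[act_col].to_numpy())
    if act.size == 0 or inact.size == 0:
        raise ValueError("need both active and inactive included genes")

    def dist(m):
        if config.poisson:
            return poisson(m)
        r = config.dispersion
        return nbinom(r, r / (r + m))

    total = 0.0
    for j in inact:
        dj = dist(mu[j])
        x_max = int(dj.ppf(1 - 1e-6)) + 1
        x = np.arange(0, x_max + 1)
        pj = dj.pmf(x)
        for i in act:
            c = x * (k_all[i] / k_all[j])
            floor_c = np.floor(c + 1e-9)
            di = dist(mu[i])
            p_gt = di.sf(floor_c)
            is_int = np.abs(c - np.round(c)) < 1e-9
            tie = np.where(is_int, di.pmf(np.round(c)), 0.0)
            total += float(np.sum(pj * (p_gt + 0.5 * tie)))
    return total / (act.size * inact.size)


def config_to_dict(config: SimulationConfig) -> dict:
    """Plain-scalar dict representation (YAML-serialisable)."""
    d = asdict(config)
    for key in ("k_range", "library_size_range"):
        d[key] = list(d[key])
    if d.get("background_profile") is not None:
        d["background_profile"] = [float(v) for v in d["background_profile"]]
    return d


def config_from_dict(d: dict) -> SimulationConfig:
    d = dict(d)
    for key in ("k_range", "library_size_range"):
        if key in d:
            d[key] = tuple(d[key])
    if d.get("background_profile") is not None:
        d["background_profile"] = np.asarray(d["background_profile"], dtype=float)
    if d.get("variant_spec"):
        d["variant_spec"] = [
            VariantSpec(**v) if isinstance(v, dict) else v for v in d["variant_spec"]
        ]
    return SimulationConfig(**d)
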