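"""Generator contracts: reproducibility, calibration of the generative
model, and validity of every container it emits."""

import numpy as np
import pandas as pd
import pytest

from cfchip.enrichment import (
    cfchip_relative_enrichment,
    chip_enrichment,
    make_background,
)
from cfchip.synthetic import (
    SimulationConfig,
    VariantSpec,
    _expected_rates,
    simulate_chip_counts,
    simulate_dataset,
    simulate_expression,
    simulate_plasma,
    simulate_variants,
)
from cfchip.variants import pair_variants, paired_maf_test


def small_config(**kwargs):
    defaults = dict(
        seed=5, n_genes=40, n_excluded_tss=6, n_de_genes=6,
        n_patients_a=3, n_patients_b=2, n_healthy=2,
    )
    defaults.update(kwargs)
    return SimulationConfig(**defaults)


class TestReproducibility:
    def test_same_seed_is_bit_identical(self):
        a = simulate_dataset(small_config())
        b = simulate_dataset(small_config())
        pd.testing.assert_frame_equal(a.counts.counts, b.counts.counts)
        pd.testing.assert_frame_equal(a.expression.tpm, b.expression.tpm)
        pd.testing.assert_frame_equal(a.truth, b.truth)
        assert a.variants == b.variants

    def test_different_seeds_differ(self):
        a = simulate_dataset(small_config(seed=1))
        b = simulate_dataset(small_config(seed=2))
        assert not a.counts.counts.equals(b.counts.counts)


class TestExpressionModel:
    def test_all_active_when_fraction_is_one(self):
        cfg = SimulationConfig(n_genes=50, n_excluded_tss=5, active_fraction=1.0)
        _, truth = simulate_expression(cfg, np.random.default_rng(0))
        assert truth["active"].all()

    def test_zero_replicate_noise_gives_identical_replicates(self):
        cfg = small_config(replicate_sigma=0.0)
        expr, _ = simulate_expression(cfg, np.random.default_rng(0))
        a_reps = expr.tpm[expr.replicates(cfg.group_a)]
        assert (a_reps.nunique(axis=1) == 1).all()

    def test_realised_active_fraction_matches_configured(self):
        cfg = SimulationConfig(n_genes=2000, n_excluded_tss=36, active_fraction=0.76)
        expr, _ = simulate_expression(cfg, np.random.default_rng(1))
        log_means = np.log2(expr.tpm + 1).mean(axis=1)
        frac = (log_means > 0.2).mean()
        assert frac == pytest.approx(0.76, abs=0.03)


class TestCountModel:
    def test_poisson_mode_counts_proportional_to_k(self):
        # equal expression everywhere: expected counts reduce to L*k/sum(k)
        cfg = small_config(poisson=True, nonspecific_tpm=0.0)
        rng = np.random.default_rng(7)
        ds = simulate_dataset(cfg)
        panel = ds.panel
        tpm = pd.Series(2.0, index=panel.gene_ids)
        totals = np.zeros(len(panel.gene_ids))
        n_rep = 50
        for i in range(n_rep):
            cm = simulate_chip_counts(
                tpm, panel, cfg, rng, [f"s{i}"], "x", library_sizes=[1e6]
            )
            totals += cm.counts.iloc[:, 0].to_numpy()
        k = np.array([panel[g].coverage_factor_k for g in panel.gene_ids], float)
        expected = 1e6 * k / k.sum()
        np.testing.assert_allclose(totals / n_rep, expected, rtol=0.05)

    def test_zero_expression_zero_specific_signal(self):
        cfg = small_config(nonspecific_tpm=0.0)
        ds = simulate_dataset(cfg)
        tpm = pd.Series(1.0, index=ds.panel.gene_ids)
        tpm.iloc[3] = 0.0
        cm = simulate_chip_counts(
            tpm, ds.panel, cfg, np.random.default_rng(0), ["s"], "x",
            library_sizes=[1e6],
        )
        assert cm.counts.iloc[3, 0] == 0

    def test_library_size_doubles_expected_total(self):
        cfg = small_config(poisson=True)
        ds = simulate_dataset(cfg)
        tpm = pd.Series(2.0, index=ds.panel.gene_ids)
        rng = np.random.default_rng(3)
        tot1 = tot2 = 0.0
        for i in range(30):
            tot1 += simulate_chip_counts(
                tpm, ds.panel, cfg, rng, ["a"], "x", library_sizes=[5e5]
            ).counts.sum().sum()
            tot2 += simulate_chip_counts(
                tpm, ds.panel, cfg, rng, ["b"], "x", library_sizes=[1e6]
            ).counts.sum().sum()
        assert tot2 / tot1 == pytest.approx(2.0, rel=0.02)

    def test_zero_library_rejected(self):
        cfg = small_config()
        ds = simulate_dataset(cfg)
        tpm = pd.Series(1.0, index=ds.panel.gene_ids)
        with pytest.raises(ValueError, match="zero library"):
            simulate_chip_counts(
                tpm, ds.panel, cfg, np.random.default_rng(0), ["s"], "x",
                library_sizes=[0.0],
            )


class TestPlasmaModel:
    def test_mixture_endpoints(self):
        cfg = small_config()
        n = cfg.n_genes
        bg = pd.Series(np.arange(1.0, n + 1), index=[f"G{i + 1:04d}" for i in range(n)])
        tumor = pd.Series(2.0 * np.arange(1.0, n + 1), index=bg.index)
        k = np.ones(n)
        r0 = _expected_rates(((1 - 0.0) * bg + 0.0 * tumor).to_numpy(), k, cfg)
        r1 = _expected_rates(((1 - 1.0) * bg + 1.0 * tumor).to_numpy(), k, cfg)
        np.testing.assert_allclose(r0, _expected_rates(bg.to_numpy(), k, cfg))
        np.testing.assert_allclose(r1, _expected_rates(tumor.to_numpy(), k, cfg))

    def test_tumor_only_gene_gains_positive_relative_enrichment(self):
        cfg = small_config(tumor_fraction=0.3)
        ds = simulate_dataset(cfg)
        ids = ds.panel.gene_ids
        bg = pd.Series(1.0, index=ids)
        tumor = pd.Series(1.0, index=ids)
        target = ds.panel.included_ids[0]
        bg.loc[target] = 0.0
        tumor.loc[target] = 50.0
        signs = []
        for seed in range(20):
            rng = np.random.default_rng(100 + seed)
            healthy = simulate_plasma(
                bg, None, 0.0, ds.panel, cfg, rng,
                [f"h{i}" for i in range(4)], "healthy",
            )
            patient = simulate_plasma(
                bg, tumor, 0.3, ds.panel, cfg, rng, ["pat"], "case"
            )
            rel = cfchip_relative_enrichment(
                patient, make_background(healthy, ds.panel), ds.panel
            )
            signs.append(rel.values.loc[target].iloc[0])
        assert np.mean(np.array(signs) > 0) > 0.9

    def test_mismatched_profiles_rejected(self):
        cfg = small_config()
        ds = simulate_dataset(cfg)
        bg = pd.Series(1.0, index=ds.panel.gene_ids)
        tumor = bg.iloc[::-1]
        with pytest.raises(ValueError, match="mismatched"):
            simulate_plasma(
                bg, tumor, 0.5, ds.panel, cfg, np.random.default_rng(0), ["s"], "c"
            )


class TestVariantModel:
    def _counts(self, ds):
        return ds.counts

    def test_zero_bias_preserves_maf_in_expectation(self):
        cfg = small_config()
        ds = simulate_dataset(cfg)
        specs = [VariantSpec(gene_index=1, input_maf=0.2, expression_bias=0.0)]
        rng = np.random.default_rng(0)
        mafs_in, mafs_cf = [], []
        for _ in range(300):
            recs = simulate_variants(cfg, ds.counts, ds.panel, rng, specs)
            mafs_in.append(recs[0].maf)
            mafs_cf.append(recs[1].maf)
        assert np.mean(mafs_cf) == pytest.approx(np.mean(mafs_in), abs=0.01)

    def test_direction_table_in_low_noise_limit(self):
        cfg = small_config(variant_depth_mean=500_000)
        ds = simulate_dataset(cfg)
        counts = ds.counts
        counts.counts.iloc[:, :] = 500_000  # deep coverage everywhere
        specs = [
            VariantSpec(gene_index=i, input_maf=0.25,
                        expression_bias=0.5 if i < 7 else -0.5)
            for i in range(9)
        ]
        recs = simulate_variants(cfg, counts, ds.panel, np.random.default_rng(1), specs)
        res = paired_maf_test(pair_variants(recs))
        assert (res.n_increased, res.n_decreased) == (7, 2)

    def test_power_of_positive_bias(self):
        cfg = small_config(variant_depth_mean=2000)
        ds = simulate_dataset(cfg)
        counts = ds.counts
        counts.counts.iloc[:, :] = 2000
        specs = [
            VariantSpec(gene_index=i, input_maf=0.15 + 0.02 * i, expression_bias=0.3)
            for i in range(9)
        ]
        hits = 0
        for seed in range(100):
            rng = np.random.default_rng(1000 + seed)
            recs = simulate_variants(cfg, counts, ds.panel, rng, specs)
            if paired_maf_test(pair_variants(recs)).p_value < 0.05:
                hits += 1
        assert hits >= 80

    def test_non_panel_gene_rejected(self):
        cfg = small_config()
        ds = simulate_dataset(cfg)
        specs = [VariantSpec(gene_index=999, input_maf=0.2, expression_bias=0.0)]
        with pytest.raises(ValueError, match="non-panel gene"):
            simulate_variants(cfg, ds.counts, ds.panel, np.random.default_rng(0), specs)


class TestDatasetValidity:
    def test_generated_containers_satisfy_invariants(self):
        ds = simulate_dataset(small_config())
        # CountMatrix/ExpressionMatrix/VariantRecord constructors validate on
        # build; re-validate derived quantities here
        assert (ds.counts.counts.to_numpy() >= 0).all()
        assert (ds.expression.tpm.to_numpy() >= 0).all()
        for v in ds.variants:
            assert 0 <= v.alt_depth <= v.total_depth
        assert len(ds.panel.included_ids) == ds.truth["included"].sum()
        # truth labels consistent with generated expression means
        log_means_a = ds.truth["log_mean_a"]
        assert ((log_means_a > 0.2) == ds.truth["active_a"]).all()

    def test_chip_enrichment_runs_on_generated_counts(self):
        ds = simulate_dataset(small_config())
        chip = ds.counts.select(assay="chip")
        prof = chip_enrichment(chip, ds.panel)
        assert prof.values.shape[0] == len(ds.panel.included_ids)
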