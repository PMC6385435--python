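import numpy as np
import pytest

from beefgwas import formats_io as fio
from beefgwas.formats_io import TRAITS
from beefgwas.gwa import preprocess_trait, scan
from beefgwas.synthetic_data import (
    QtlEffect,
    SimConfig,
    simulate_annotation,
    simulate_dataset,
    simulate_genotypes,
    simulate_phenotypes,
)


class TestConfigValidation:
    def test_bad_h2_rejected(self):
        cfg = SimConfig(h2={**SimConfig().h2, "wbsf": 1.4})
        with pytest.raises(ValueError, match="h2"):
            cfg.validate()

    def test_non_psd_rg_rejected(self):
        rg = np.eye(len(TRAITS))
        rg[0, 1] = rg[1, 0] = 0.9
        rg[0, 2] = rg[2, 0] = 0.9
        rg[1, 2] = rg[2, 1] = -0.9
        with pytest.raises(ValueError, match="semi-definite"):
            SimConfig(rg=rg).validate()

    def test_qtl_fraction_exceeding_h2_rejected(self):
        cfg = SimConfig(qtl_spec=[QtlEffect("GENE010", "wbsf", 0.5, 2)])
        with pytest.raises(ValueError, match="heritability"):
            cfg.validate()

    def test_infeasible_gene_tiling_rejected(self):
        cfg = SimConfig(n_variants=100, n_genes=60, qtl_spec=[], seed=0)
        with pytest.raises(ValueError, match="infeasible"):
            simulate_genotypes(cfg)


class TestGenotypes:
    def test_same_seed_identical(self):
        cfg = SimConfig(n_samples=60, n_sensory=40, n_variants=200, n_genes=8,
                        seed=5, qtl_spec=[])
        g1, _ = simulate_genotypes(cfg)
        g2, _ = simulate_genotypes(cfg)
        np.testing.assert_array_equal(g1.dosages, g2.dosages)
        assert g1.variant_ids == g2.variant_ids

    def test_single_pool_pair_block_is_perfect_ld(self):
        # one population, founder pool of 2: within a block every SNP pair
        # has |r| = 1
        cfg = SimConfig(
            n_samples=150, n_sensory=100, n_variants=20, n_chromosomes=1,
            block_length_mean=10, block_length_jitter=False, within_block_r2=0.5,
            admixture=(1.0,) * 6, n_genes=1, qtl_spec=[], seed=3,
        )
        g, truth = simulate_genotypes(cfg)
        _, c0, c1 = truth.blocks[0]
        x = g.dosages[:, c0 : c1 + 1]
        corr = np.corrcoef(x, rowvar=False)
        assert np.all(np.abs(corr) > 0.999)

    def test_between_block_ld_far_below_within(self):
        cfg = SimConfig(
            n_samples=200, n_sensory=150, n_variants=200, n_chromosomes=1,
            n_genes=5, qtl_spec=[], seed=4,
        )
        g, truth = simulate_genotypes(cfg)
        x = g.imputed()
        within, between = [], []
        rng = np.random.default_rng(0)
        for (_, a0, a1), (_, b0, b1) in zip(truth.blocks[:-1], truth.blocks[1:]):
            i, j = int(rng.integers(a0, a1 + 1)), int(rng.integers(a0, a1 + 1))
            if i != j:
                within.append(np.corrcoef(x[:, i], x[:, j])[0, 1] ** 2)
            k = int(rng.integers(b0, b1 + 1))
            between.append(np.corrcoef(x[:, i], x[:, k])[0, 1] ** 2)
        assert np.mean(within) > 3 * np.mean(between)

    def test_breed_groups_cover_six_levels(self, small_dataset):
        assert sorted(small_dataset.phenotypes["breed_group"].unique()) == [
            1, 2, 3, 4, 5, 6,
        ]


class TestPhenotypes:
    def test_realized_heritability_matches_config(self):
        """var(breeding values) / var(transformed phenotype) tracks cfg.h2."""
        reps = 5
        ratios = {t: [] for t in ("marbling", "wbsf", "cooking_loss")}
        for s in range(reps):
            ds = simulate_dataset(SimConfig(seed=40 + s))
            bv = ds.truth.breeding_values
            for t in ratios:
                y = preprocess_trait(ds.phenotypes[t].to_numpy(), t)
                m = ~np.isnan(y)
                # phenotype = breeding value + independent noise on the latent
                # scale, so corr(bv, pheno)^2 = var(bv)/var(pheno), scale-free
                ratios[t].append(np.corrcoef(bv[t].to_numpy()[m], y[m])[0, 1] ** 2)
        for t in ratios:
            assert np.mean(ratios[t]) == pytest.approx(
                SimConfig().h2[t], abs=0.05
            ), t

    def test_breeding_value_correlation_matches_rg(self):
        vals = []
        for s in range(3):
            ds = simulate_dataset(SimConfig(seed=60 + s))
            bv = ds.truth.breeding_values
            vals.append(np.corrcoef(bv["wbsf"], bv["tenderness"])[0, 1])
        assert np.mean(vals) == pytest.approx(-0.97, abs=0.02)

    def test_zero_heritability_trait_has_no_genetic_signal(self):
        h2 = {**SimConfig().h2, "flavor": 0.0}
        cfg = SimConfig(seed=8, n_samples=300, n_sensory=300, n_variants=600,
                        n_genes=20, qtl_spec=[], h2=h2)
        g, truth = simulate_genotypes(cfg)
        pheno, truth = simulate_phenotypes(g, cfg, truth)
        bv = truth.breeding_values["flavor"].to_numpy()
        y = pheno["flavor"].to_numpy()
        assert np.var(bv) == pytest.approx(0.0, abs=1e-12)
        assert np.nanstd(y) > 0  # phenotype is pure environment, not constant

    def test_sensory_traits_are_panel_averages_on_subset(self, small_dataset):
        ph = small_dataset.phenotypes
        cfg = small_dataset.config
        for t in ("tenderness", "juiciness"):
            vals = ph[t].dropna()
            assert len(vals) == cfg.n_sensory
            # averages of panel_size integer scores land on a 1/panel_size grid
            frac = (vals * cfg.panel_size) % 1
            assert np.allclose(np.minimum(frac, 1 - frac), 0, atol=1e-9)
            assert vals.between(1, 8).all()

    def test_constant_panel_scores_average_exactly(self):
        scores = np.full((4, 9), 5.0)
        assert np.allclose(scores.mean(axis=1), 5.0)

    def test_wbsf_is_mean_of_six_core_loads(self, small_dataset):
        ds = small_dataset
        cores = ds.truth.core_loads
        assert cores.shape[1] == ds.config.n_cores
        np.testing.assert_allclose(
            ds.phenotypes["wbsf"].to_numpy(), cores.mean(axis=1), atol=5e-4
        )

    def test_qtl_effect_monotone_in_fraction(self):
        """Stronger planted QTLs give smaller causal-SNP p-values."""
        logp = {}
        for frac in (0.02, 0.12):
            spec = [QtlEffect("GENE005", "cooking_loss", frac, 2)]
            cfg = SimConfig(seed=9, n_samples=350, n_sensory=250, n_variants=800,
                            n_genes=12, qtl_spec=spec)
            ds = simulate_dataset(cfg)
            gq, _ = fio.qc_filter(ds.genotypes)
            res = scan(gq, ds.phenotypes, "cooking_loss")
            by_id = {r.variant.id: r.p for r in res}
            ps = [by_id[v] for v in ds.truth.causal_snps["cooking_loss"] if v in by_id]
            logp[frac] = np.mean(-np.log10(ps))
        assert logp[0.12] > logp[0.02]


class TestAnnotation:
    def test_genes_tile_without_overlap(self, small_dataset):
        genes = sorted(small_dataset.genes, key=lambda g: (g.chrom, g.start1))
        for a, b in zip(genes, genes[1:]):
            if a.chrom == b.chrom:
                assert a.end1 < b.start1

    def test_planted_term_covers_causal_genes(self, default_dataset):
        ds = default_dataset
        members = ds.go.genes_for_term(ds.config.planted_term)
        assert set(ds.truth.causal_genes) <= members

    def test_background_contains_causal_genes(self, default_dataset):
        assert set(default_dataset.truth.causal_genes) <= default_dataset.background

    def test_zero_density_planted_term_annotates_no_extra_genes(self):
        cfg = SimConfig(seed=10, n_samples=80, n_sensory=60, n_variants=400,
                        n_genes=12, qtl_spec=[], planted_extra_genes=0)
        g, truth = simulate_genotypes(cfg)
        _, truth = simulate_phenotypes(g, cfg, truth)
        _, go, _ = simulate_annotation(cfg, truth)
        assert go.genes_for_term(cfg.planted_term) == set()

    def test_emitted_files_readable_with_zero_qc_loss(self, tmp_path, small_dataset):
        from beefgwas.synthetic_data import write_dataset

        write_dataset(small_dataset, str(tmp_path))
        g = fio.read_dosage_tsv(str(tmp_path / "genotypes.tsv"))
        assert g.n_variants == small_dataset.genotypes.n_variants
        assert not np.isnan(g.dosages).any()  # no missingness simulated
        ph = fio.read_phenotypes(str(tmp_path / "phenotypes.tsv"))
        assert len(ph) == small_dataset.config.n_samples
        genes = fio.read_bed_genes(str(tmp_path / "genes.bed"))
        assert len(genes) == len(small_dataset.genes)
        bg = fio.read_background(str(tmp_path / "background.txt"))
        assert bg == small_dataset.background
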