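import math
from dataclasses import replace

import numpy as np
import pandas as pd
import pytest

from purplemap.assays import insilico_pcr
from purplemap.simdata import (
    BulkDesign,
    ChromosomeSpec,
    CrossConfig,
    ExprConfig,
    PhenotypeModel,
    assign_phenotypes,
    form_pools,
    haldane_recombination_fraction,
    make_promoter_fixture,
    select_extremes,
    simulate_bulk_depths,
    simulate_cross,
)
from purplemap.simdata.config import COLOR_CLASSES, ConfigurationError
from purplemap.simdata.expression import build_gene_models, expression_weights, simulate_expression


class TestCrossConfig:
    def test_causal_locus_must_be_on_declared_chromosome(self):
        with pytest.raises(ConfigurationError):
            CrossConfig(causal_chrom="chrX")

    def test_zero_length_chromosome_rejected(self):
        with pytest.raises(ConfigurationError):
            ChromosomeSpec("chr1", 0.0, 5)

    def test_causal_position_outside_chromosome_rejected(self):
        with pytest.raises(ConfigurationError):
            CrossConfig(causal_cm=500.0)

    def test_marker_positions_strictly_increasing(self):
        pos = ChromosomeSpec("chr1", 50.0, 100).marker_positions_cm()
        assert (np.diff(pos) > 0).all()


class TestSimulateCross:
    def test_population_size_127(self):
        pop = simulate_cross(CrossConfig(n_offspring=127))
        assert pop.n_offspring == 127

    def test_haldane_zero_distance_no_recombination(self):
        assert haldane_recombination_fraction(0.0) == 0.0
        # two loci 0 cM apart: never any recombinant gamete
        from purplemap.simdata.cross import _simulate_gametes

        gametes = _simulate_gametes(np.array([1.0, 1.0]), 5000, np.random.default_rng(3))
        assert (gametes[:, 0] == gametes[:, 1]).all()

    def test_haldane_50cm_recombinant_fraction(self):
        # closed form: r = (1 - e^-1)/2 ~= 0.316060
        expected = (1.0 - math.exp(-1.0)) / 2.0
        cfg = CrossConfig(
            n_offspring=10_000,
            chromosomes=(ChromosomeSpec("chr1", 100.0, 2),),  # markers at 25, 75 cM
            causal_chrom="chr1",
            causal_cm=50.0,
        )
        pop = simulate_cross(cfg, seed=11)
        observed = float((pop.purple_gamete[:, 0] != pop.purple_gamete[:, 1]).mean())
        sd = math.sqrt(expected * (1 - expected) / 10_000)
        assert abs(observed - expected) < 3 * sd

    def test_mendelian_conservation(self, small_config):
        pop = simulate_cross(small_config, seed=5)
        assert np.array_equal(pop.genotypes, pop.purple_gamete + pop.green_gamete)
        assert set(np.unique(pop.genotypes)) <= {0, 1}
        assert set(np.unique(pop.causal_dosage)) <= {0, 1}

    def test_seeded_determinism(self, small_config):
        a = simulate_cross(small_config, seed=9)
        b = simulate_cross(small_config, seed=9)
        assert np.array_equal(a.genotypes, b.genotypes)
        assert np.array_equal(a.causal_dosage, b.causal_dosage)


class TestPhenotypes:
    def test_noiseless_limit_is_deterministic(self, small_config):
        pop = simulate_cross(small_config, seed=1)
        model = PhenotypeModel(
            genotype_means=(0.0, 2.0), sigma=1e-12, thresholds=(0.5, 0.9, 1.2, 1.5)
        )
        pop = assign_phenotypes(pop, model, seed=2)
        classes = np.asarray(pop.color_class)
        assert (classes[pop.causal_dosage == 0] == 0).all()  # green
        assert (classes[pop.causal_dosage == 1] == 4).all()  # dark purple

    def test_all_aa_population_all_green(self, small_config):
        pop = simulate_cross(small_config, seed=1)
        pop.causal_dosage = np.zeros(pop.n_offspring, dtype=np.int8)
        model = PhenotypeModel(
            genotype_means=(0.0, 2.0), sigma=1e-12, thresholds=(0.5, 0.9, 1.2, 1.5)
        )
        pop = assign_phenotypes(pop, model, seed=2)
        assert pop.class_counts()["green"] == pop.n_offspring

    def test_default_model_expected_fractions_exact(self):
        model = PhenotypeModel.default()
        frac = model.expected_class_fractions()
        assert frac[0] == pytest.approx(18 / 127, abs=1e-9)
        assert frac[-1] == pytest.approx(32 / 127, abs=1e-9)
        assert frac.sum() == pytest.approx(1.0)

    def test_calibration_monte_carlo(self):
        # light version of the acceptance target: 300 populations of 127
        cfg = CrossConfig(
            n_offspring=127,
            chromosomes=(ChromosomeSpec("chr1", 10.0, 1),),
            causal_chrom="chr1",
            causal_cm=5.0,
        )
        greens, darks = [], []
        for s in range(300):
            pop = assign_phenotypes(simulate_cross(cfg, seed=s), seed=10_000 + s)
            counts = pop.class_counts()
            greens.append(counts["green"])
            darks.append(counts["dark_purple"])
        assert np.mean(greens) == pytest.approx(18.0, abs=1.0)
        assert np.mean(darks) == pytest.approx(32.0, abs=1.5)

    def test_non_increasing_thresholds_rejected(self):
        with pytest.raises(ConfigurationError):
            PhenotypeModel(thresholds=(1.0, 0.5, 2.0, 3.0))

    def test_refusing_to_overwrite(self, small_config):
        pop = assign_phenotypes(simulate_cross(small_config), seed=1)
        with pytest.raises(ValueError, match="overwrite"):
            assign_phenotypes(pop, seed=2)
        assign_phenotypes(pop, seed=2, overwrite=True)


class TestSelectExtremes:
    def test_k15_yields_30(self):
        pop = assign_phenotypes(simulate_cross(CrossConfig(n_offspring=127)), seed=0)
        green, purple = select_extremes(pop, k=15)
        assert len(green) == len(purple) == 15
        assert len(set(green) | set(purple)) == 30

    def test_k1_is_min_and_max(self, small_config):
        pop = assign_phenotypes(simulate_cross(small_config), seed=3)
        green, purple = select_extremes(pop, k=1)
        assert pop.liability[green[0]] == pop.liability.min()
        assert pop.liability[purple[0]] == pop.liability.max()

    def test_tie_break_by_lower_id(self, small_config):
        pop = assign_phenotypes(simulate_cross(small_config), seed=3)
        pop = replace(pop, liability=np.zeros(pop.n_offspring))  # total tie
        green, purple = select_extremes(pop, k=3)
        assert list(green) == [0, 1, 2]
        assert list(purple) == [0, 1, 2]

    def test_insufficient_individuals_error(self, small_config):
        pop = assign_phenotypes(simulate_cross(small_config), seed=3)
        with pytest.raises(ValueError, match="tail"):
            select_extremes(pop, k=pop.n_offspring)


class TestFormPools:
    def test_six_materials(self):
        pop = assign_phenotypes(simulate_cross(CrossConfig(n_offspring=127)), seed=0)
        green, purple = select_extremes(pop, k=15)
        pools = form_pools(green, 5) + form_pools(purple, 5)
        assert len(pools) == 6
        assert all(len(p) == 5 for p in pools)

    def test_single_pool(self):
        assert len(form_pools(np.arange(7), 7)) == 1

    def test_partition_property(self):
        group = np.array([4, 9, 2, 7, 5, 0])
        pools = form_pools(group, 2)
        flat = np.concatenate(pools)
        assert sorted(flat) == sorted(group)
        assert len(flat) == len(set(flat))

    def test_non_divisible_error(self):
        with pytest.raises(ValueError, match="divisible"):
            form_pools(np.arange(7), 3)


def _fixed_dosage_pop(small_config, dosage_value):
    pop = simulate_cross(small_config, seed=1)
    pop.genotypes = np.full_like(pop.genotypes, dosage_value)
    return pop


class TestBulkDepths:
    def test_fixed_dosage2_all_alt(self, small_config):
        pop = _fixed_dosage_pop(small_config, 2)
        table = simulate_bulk_depths(pop, np.arange(5), np.arange(5, 10), lam=30, error_rate=0.0, seed=4)
        assert (table["ref_GP"] == 0).all()
        assert (table["ref_PP"] == 0).all()
        assert (table["alt_GP"] > 0).any()

    def test_half_frequency_concentration(self, small_config):
        # f=0.5, e=0, lambda=10000: alt fraction within 3 binomial SD of 0.5
        pop = _fixed_dosage_pop(small_config, 1)
        table = simulate_bulk_depths(pop, np.arange(5), np.arange(5, 10), lam=10_000, error_rate=0.0, seed=4)
        frac = table["alt_GP"] / (table["alt_GP"] + table["ref_GP"])
        sd = math.sqrt(0.25 / 10_000)
        assert (np.abs(frac - 0.5) < 3.5 * sd).all()

    def test_zero_weight_marker_zero_rna_depth(self, small_config):
        pop = simulate_cross(small_config, seed=1)
        weights = np.ones(pop.n_markers)
        weights[7] = 0.0  # intergenic marker
        table = simulate_bulk_depths(pop, np.arange(5), np.arange(5, 10), lam=50, seed=4, weights=weights)
        row = table.iloc[7]
        assert row["ref_GP"] + row["alt_GP"] == 0
        assert row["ref_PP"] + row["alt_PP"] == 0

    def test_invalid_lambda(self, small_config):
        pop = simulate_cross(small_config, seed=1)
        with pytest.raises(ValueError, match="lambda"):
            simulate_bulk_depths(pop, np.arange(5), np.arange(5, 10), lam=0)


class TestExpression:
    @pytest.fixture()
    def pools(self, small_config):
        pop = assign_phenotypes(simulate_cross(small_config, seed=1), seed=1)
        green, purple = select_extremes(pop, k=10)
        pools = [(f"GP{i+1}", "green", p) for i, p in enumerate(form_pools(green, 5))]
        pools += [(f"PP{i+1}", "purple", p) for i, p in enumerate(form_pools(purple, 5))]
        return pop, pools

    def test_null_generator_equal_class_means(self, pools):
        pop, pls = pools
        genes, causal = build_gene_models(pop)
        expr = ExprConfig(deg_fraction=0.0, causal_log2fc=0.0, dispersion=1e-6)
        cm, truth = simulate_expression(pop, pls, genes, causal, expr, seed=5)
        g = cm.counts[[s for s, c, _ in pls if c == "green"]].mean(axis=1)
        p = cm.counts[[s for s, c, _ in pls if c == "purple"]].mean(axis=1)
        ratio = (p + 1) / (g + 1)
        assert ratio.between(0.8, 1.25).all()
        assert truth["planted_degs"] == {}

    def test_causal_fold_change_tracks_dosage(self, pools):
        # dispersion -> 0, causal log2FC=2: purple/green mean ratio -> 4
        pop, pls = pools
        genes, causal = build_gene_models(pop)
        expr = ExprConfig(deg_fraction=0.0, causal_log2fc=2.0, dispersion=1e-6)
        cm, _ = simulate_expression(pop, pls, genes, causal, expr, seed=5)
        g = cm.counts.loc[causal, [s for s, c, _ in pls if c == "green"]].mean()
        p = cm.counts.loc[causal, [s for s, c, _ in pls if c == "purple"]].mean()
        green_dos = np.mean([pop.causal_dosage[m].mean() for s, c, m in pls if c == "green"])
        purple_dos = np.mean([pop.causal_dosage[m].mean() for s, c, m in pls if c == "purple"])
        expected = 4.0 ** (purple_dos - green_dos)
        assert p / g == pytest.approx(expected, rel=0.2)

    def test_needs_replication(self, pools):
        pop, pls = pools
        genes, causal = build_gene_models(pop)
        with pytest.raises(ConfigurationError, match="pools"):
            simulate_expression(pop, pls[:1] + pls[2:], genes, causal, seed=5)

    def test_expression_weights_zero_for_intergenic(self, pools):
        pop, _ = pools
        genes, _ = build_gene_models(pop)
        w = expression_weights(pop.markers, genes, {g: 100.0 for g in genes["gene_id"]})
        genic = np.zeros(pop.n_markers, dtype=bool)
        genic[genes["marker_idx"].to_numpy()] = True
        assert (w[~genic] == 0).all()
        assert w[genic].mean() == pytest.approx(1.0)


class TestPromoterFixture:
    def test_default_length_difference_181(self):
        fx = make_promoter_fixture(seed=0)
        assert len(fx.long_allele) - len(fx.short_allele) == 181

    def test_zero_insertion_identical_alleles(self):
        fx = make_promoter_fixture(insertion_length=0, seed=0)
        assert fx.long_allele == fx.short_allele

    @pytest.mark.parametrize("seed", range(10))
    def test_amplicons_differ_by_insertion_length(self, seed):
        length = 50 + 17 * seed
        fx = make_promoter_fixture(insertion_length=min(length, 181), seed=seed)
        long_amps = insilico_pcr(fx.long_allele, fx.forward_primer, fx.reverse_primer)
        short_amps = insilico_pcr(fx.short_allele, fx.forward_primer, fx.reverse_primer)
        assert len(long_amps) == len(short_amps) == 1
        assert long_amps[0].length - short_amps[0].length == fx.insertion_length

    def test_primers_unique_per_allele(self):
        fx = make_promoter_fixture(seed=3)
        for allele in (fx.short_allele, fx.long_allele):
            assert allele.count(fx.forward_primer) == 1

    def test_oversized_insertion_rejected(self):
        with pytest.raises(ValueError, match="fit"):
            make_promoter_fixture(insertion_length=500, window=(-332, -152))


def test_color_classes_are_five_ordinals():
    assert len(COLOR_CLASSES) == 5
    assert COLOR_CLASSES[0] == "green" and COLOR_CLASSES[-1] == "dark_purple"


def test_bulk_design_invariants():
    with pytest.raises(ConfigurationError):
        BulkDesign(k=7, rna_pool_size=5)
    with pytest.raises(ConfigurationError):
        BulkDesign(error_rate=0.6)
    BulkDesign().validate_for(127)
    with pytest.raises(ConfigurationError):
        BulkDesign().validate_for(20)
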