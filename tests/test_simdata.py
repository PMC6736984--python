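"""Generator-level checks: the synthetic data must have the statistical
structure the downstream analysis assumes."""

import numpy as np
import pandas as pd
import pytest

from ailgxe import simdata
from ailgxe.simdata import (
    OtuSimModel,
    PhenoModel,
    QtlSpec,
    SimConfig,
    simulate_cross,
    simulate_founders,
    simulate_otu_table,
    simulate_phenotypes,
    simulate_variant_table,
    true_dosages,
)

SPEC = {"chr1": (30, 60.0), "chr2": (30, 60.0)}


class TestFounders:
    def test_fraction_private_one_gives_one_minority_founder_everywhere(self):
        panel = simulate_founders(4, SPEC, fraction_private=1.0, seed=0)
        # exactly one founder differs from the other three at every marker
        match_first = (panel.alleles == panel.alleles[0]).sum(axis=0)
        assert np.isin(match_first, [1, 3]).all()
        n_distinct = np.array([len(set(col)) for col in panel.alleles.T])
        assert (n_distinct == 2).all()

    def test_fraction_private_zero_gives_identical_founders(self):
        panel = simulate_founders(4, SPEC, fraction_private=0.0, seed=0)
        assert (panel.alleles == panel.alleles[0]).all()

    def test_private_marker_count_is_binomial(self):
        panel = simulate_founders(
            4, {"chr1": (1000, 1000.0)}, fraction_private=0.25, seed=3
        )
        # markers where not all founders agree
        n_private = int((~(panel.alleles == panel.alleles[0]).all(axis=0)).sum())
        sd = np.sqrt(1000 * 0.25 * 0.75)
        assert abs(n_private - 250) <= 3 * sd

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError, match="fraction_private"):
            simulate_founders(4, SPEC, fraction_private=1.5, seed=0)
        with pytest.raises(ValueError, match="marker_spec"):
            simulate_founders(4, {}, fraction_private=0.5, seed=0)

    def test_deterministic_given_seed(self):
        a = simulate_founders(4, SPEC, 0.5, seed=7)
        b = simulate_founders(4, SPEC, 0.5, seed=7)
        assert (a.alleles == b.alleles).all()
        pd.testing.assert_frame_equal(a.markers, b.markers)


class TestCross:
    def test_f1_of_two_founders_heterozygous_everywhere(self):
        panel = simulate_founders(2, SPEC, fraction_private=1.0, seed=1)
        cfg = SimConfig(generations=0, breeding_pairs=10, n_offspring=2,
                        genotyping_error=0.0, seed=2)
        _, diplo, gm = simulate_cross(panel, cfg)
        differs = panel.alleles[0] != panel.alleles[1]
        assert (gm.calls[:, differs] == 1).all()
        assert (np.sort(diplo, axis=2) == [0, 1]).all()

    def test_crossover_count_matches_poisson_mean(self):
        # 1-Morgan chromosome, dense map; count origin switches per gamete
        panel = simulate_founders(4, {"chr1": (200, 100.0)}, 1.0, seed=4)
        cfg = SimConfig(generations=1, breeding_pairs=50, n_offspring=100,
                        genotyping_error=0.0, seed=5)
        _, diplo, _ = simulate_cross(panel, cfg)
        # gametes of generation-1 meioses: haplotypes of the offspring
        switches = (np.diff(diplo, axis=1) != 0).sum(axis=1)  # (n, 2)
        n_gametes = switches.size
        mean = switches.mean()
        se = switches.std() / np.sqrt(n_gametes)
        assert abs(mean - 1.0) <= 3 * max(se, 1e-9) + 0.05

    def test_zero_error_genotypes_match_true_diplotypes(self):
        panel = simulate_founders(4, SPEC, 1.0, seed=6)
        cfg = SimConfig(generations=3, breeding_pairs=10, n_offspring=3,
                        genotyping_error=0.0, seed=7)
        _, diplo, gm = simulate_cross(panel, cfg)
        M = panel.n_markers
        expect = (
            panel.alleles[diplo[:, :, 0], np.arange(M)]
            + panel.alleles[diplo[:, :, 1], np.arange(M)]
        )
        assert (gm.calls == expect).all()

    def test_founder_origins_valid_and_reproducible(self):
        panel = simulate_founders(4, SPEC, 1.0, seed=8)
        cfg = SimConfig(generations=5, breeding_pairs=10, n_offspring=4, seed=9)
        _, d1, g1 = simulate_cross(panel, cfg)
        _, d2, g2 = simulate_cross(panel, cfg)
        assert (d1 == d2).all() and (g1.calls == g2.calls).all()
        assert d1.min() >= 0 and d1.max() < panel.n_founders

    def test_negative_generations_rejected(self):
        with pytest.raises(ValueError, match="generations"):
            SimConfig(generations=-1)


class TestPhenotypes:
    def test_pure_noise_trait_independent_of_genotype(self, small_posterior):
        model = PhenoModel()
        tab, realized = simulate_phenotypes(
            small_posterior.dosages, None, model, seed=10
        )
        assert realized["noise"] > 0.99
        d = small_posterior.dosages[:, 10, 0]
        r = np.corrcoef(tab["trait"], d)[0, 1]
        assert abs(r) < 0.2

    def test_qtl_r2_calibrated(self, small_posterior, small_kinship):
        r2s = []
        beta = np.array([1.0, 0.0, 0.0, -1.0])
        for seed in range(30):
            model = PhenoModel(qtl=[QtlSpec(locus=12, beta=beta)], h2_qtl=0.2)
            tab, _ = simulate_phenotypes(
                small_posterior.dosages, small_kinship, model, seed=seed
            )
            D = small_posterior.dosages[:, 12, :]
            X = np.column_stack([np.ones(len(tab)), D[:, :3]])
            y = tab["trait"].to_numpy()
            coef, *_ = np.linalg.lstsq(X, y, rcond=None)
            resid = y - X @ coef
            r2s.append(1 - resid.var() / y.var())
        assert abs(np.mean(r2s) - 0.2) < 0.05

    def test_pure_interaction_has_no_marginal_effect(self, small_posterior):
        n = small_posterior.n_individuals
        rng = np.random.default_rng(0)
        diet = np.arange(n) % 3  # balanced
        pattern = np.array([1.0, 0.0, 0.0, 0.0])
        diet_beta = np.outer([1.0, -1.0, 0.0], pattern)
        model = PhenoModel(
            qtl=[QtlSpec(locus=20, beta=np.zeros(4), diet_beta=diet_beta)],
            h2_qtl=0.3,
        )
        tab, _ = simulate_phenotypes(
            small_posterior.dosages, None, model, seed=1, diet=diet
        )
        y = tab["trait"].to_numpy()
        D = small_posterior.dosages[:, 20, :]
        X = np.column_stack([np.ones(n), D[:, :3]])
        coef, *_ = np.linalg.lstsq(X, y, rcond=None)
        r2_marginal = 1 - np.var(y - X @ coef) / np.var(y)
        assert r2_marginal < 0.05

    def test_bad_kinship_rejected(self, small_posterior):
        n = small_posterior.n_individuals
        K = np.eye(n)
        K[0, 1] = 0.5  # asymmetric
        model = PhenoModel(h2_polygenic=0.3)
        with pytest.raises(ValueError, match="symmetric"):
            simulate_phenotypes(small_posterior.dosages, K, model, seed=0)

    def test_variance_fractions_validated(self):
        with pytest.raises(ValueError, match="sum"):
            PhenoModel(h2_qtl=0.6, h2_polygenic=0.6)
        with pytest.raises(ValueError, match="non-negative"):
            PhenoModel(h2_qtl=-0.1)


@pytest.fixture(scope="module")
def genes(small_panel):
    return simdata.make_gene_annotation(small_panel, 10, 500_000, seed=2)


class TestVariantTable:
    def test_fraction_common_one_all_common(self, small_panel, genes):
        vt = simulate_variant_table(small_panel, genes, 50, fraction_common=1.0, seed=3)
        geno = vt[small_panel.strains].to_numpy()
        assert (geno == 1).all()

    def test_alt_carriers_proper_subset_when_not_common(self, small_panel, genes):
        vt = simulate_variant_table(small_panel, genes, 200, fraction_common=0.0, seed=4)
        geno = vt[small_panel.strains].to_numpy()
        carriers = geno.sum(axis=1)
        assert (carriers >= 1).all() and (carriers <= 3).all()

    def test_planted_causal_variant_present(self, small_panel, genes):
        gene = genes.iloc[3]["gene_id"]
        vt = simulate_variant_table(
            small_panel, genes, 50, 0.5, seed=5,
            causal={"gene": gene, "founders": {"NZM"}, "consequence": "missense"},
        )
        hit = vt[(vt["gene"] == gene) & (vt["consequence"] == "missense")]
        assert len(hit) >= 1
        row = hit.iloc[-1]
        assert row["NZM"] == 1 and row[["MRL", "BXD2", "CAST"]].sum() == 0


class TestOtuTable:
    def test_counts_close_to_depth_exactly(self):
        model = OtuSimModel(n_taxa=30, block_sizes=[10], depth=5000)
        counts, meta, labels = simulate_otu_table(model, 20, seed=6)
        assert (counts.sum(axis=0) == 5000).all()
        assert (counts.to_numpy() >= 0).all()
        assert (labels[:10] == 0).all() and (labels[10:] == -1).all()

    def test_depth_zero_rejected(self):
        with pytest.raises(ValueError, match="depth"):
            OtuSimModel(n_taxa=10, depth=0)

    def test_oversized_blocks_rejected(self):
        with pytest.raises(ValueError, match="block sizes"):
            OtuSimModel(n_taxa=10, block_sizes=[8, 8])

    def test_within_block_correlation_planted(self):
        model = OtuSimModel(n_taxa=40, block_sizes=[15], block_rho=0.8,
                            log_mean_sd=0.5)
        counts, _, labels = simulate_otu_table(model, 300, seed=7)
        logc = np.log(counts.to_numpy() + 0.5)
        cors = np.corrcoef(logc)
        block = np.flatnonzero(labels == 0)
        bg = np.flatnonzero(labels == -1)
        within = cors[np.ix_(block, block)][np.triu_indices(len(block), 1)].mean()
        between = cors[np.ix_(block, bg)].mean()
        assert within > 0.4
        assert within > between + 0.3


def test_writers_roundtrip(tmp_path, small_panel, small_cross):
    _, _, gm = small_cross
    simdata.write_plink(gm, tmp_path / "cohort")
    ped_lines = (tmp_path / "cohort.ped").read_text().strip().split("\n")
    map_lines = (tmp_path / "cohort.map").read_text().strip().split("\n")
    assert len(ped_lines) == gm.n_individuals
    assert len(map_lines) == gm.n_markers

    model = OtuSimModel(n_taxa=8, depth=100)
    counts, _, _ = simulate_otu_table(model, 5, seed=1)
    simdata.write_biom_json(counts, tmp_path / "otu.biom")
    import json

    obj = json.loads((tmp_path / "otu.biom").read_text())
    assert obj["shape"] == [8, 5]
    assert np.array(obj["data"]).sum() == counts.to_numpy().sum()
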