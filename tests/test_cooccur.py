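"""Compositional co-occurrence analysis: SparCC, adjacency/TOM, module
detection, eigenOTUs and module-trait statistics."""

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import adjusted_rand_score

from ailgxe import cooccur, simdata
from ailgxe.cooccur import (
    adjacency,
    detect_modules,
    eigenotus,
    module_trait_association,
    prevalence_filter,
    rarefy,
    sparcc,
    topological_overlap,
)


def counts_frame(arr, prefix="OTU"):
    arr = np.asarray(arr)
    return pd.DataFrame(
        arr,
        index=[f"{prefix}{i}" for i in range(arr.shape[0])],
        columns=[f"S{j}" for j in range(arr.shape[1])],
    )


class TestPrevalenceFilter:
    def test_boundary_inclusive(self):
        n_samples = 30
        row_pass = np.zeros(n_samples, dtype=int)
        row_pass[:25] = 10  # exactly 10 reads in exactly 25 samples
        row_fail = np.zeros(n_samples, dtype=int)
        row_fail[:24] = 100
        counts = counts_frame([row_pass, row_fail])
        out, _ = prevalence_filter(counts, min_reads=10, min_samples=25)
        assert list(out.index) == ["OTU0"]

    def test_singleton_removed_first(self):
        n_samples = 30
        single = np.zeros(n_samples, dtype=int)
        single[0] = 1
        counts = counts_frame([single, np.full(n_samples, 50)])
        out, report = prevalence_filter(counts)
        assert report["removed_singletons"] == 1
        assert "OTU0" not in out.index

    def test_hand_counted_fixture(self):
        rng = np.random.default_rng(0)
        n_samples = 40
        rows = []
        for _ in range(38):  # clear passes
            rows.append(rng.integers(20, 100, n_samples))
        for _ in range(6):  # too few reads everywhere
            rows.append(rng.integers(0, 5, n_samples))
        for _ in range(6):  # enough reads but in too few samples
            row = np.zeros(n_samples, dtype=int)
            row[:10] = 100
            rows.append(row)
        out, _ = prevalence_filter(counts_frame(rows), min_reads=10, min_samples=25)
        assert len(out) == 38


class TestSparcc:
    def test_diagonal_is_one(self):
        model = simdata.OtuSimModel(n_taxa=10, depth=2000)
        counts, _, _ = simdata.simulate_otu_table(model, 30, seed=1)
        rho, _ = sparcc(counts, n_bootstraps=0, seed=2)
        assert np.allclose(np.diag(rho.to_numpy()), 1.0)

    def test_null_mean_near_zero(self):
        model = simdata.OtuSimModel(n_taxa=50, depth=20_000, log_mean_sd=1.5)
        counts, _, _ = simdata.simulate_otu_table(model, 200, seed=3)
        rho, _ = sparcc(counts, n_bootstraps=0, seed=4)
        R = rho.to_numpy()
        off = R[np.triu_indices_from(R, 1)]
        assert abs(off.mean()) < 0.05

    def test_planted_pair_recovered(self):
        model = simdata.OtuSimModel(n_taxa=50, block_sizes=[2], block_rho=0.8,
                                    depth=20_000)
        counts, _, _ = simdata.simulate_otu_table(model, 200, seed=5)
        rho, _ = sparcc(counts, n_bootstraps=0, seed=6)
        assert 0.6 <= rho.iloc[0, 1] <= 0.95

    def test_too_few_taxa_or_samples_rejected(self):
        counts = counts_frame(np.ones((3, 30), dtype=int))
        with pytest.raises(ValueError, match="taxa"):
            sparcc(counts)
        counts = counts_frame(np.ones((10, 5), dtype=int))
        with pytest.raises(ValueError, match="samples"):
            sparcc(counts)

    def test_deterministic_given_seed(self):
        model = simdata.OtuSimModel(n_taxa=12, depth=1000)
        counts, _, _ = simdata.simulate_otu_table(model, 30, seed=7)
        r1, p1 = sparcc(counts, n_bootstraps=20, seed=8)
        r2, p2 = sparcc(counts, n_bootstraps=20, seed=8)
        pd.testing.assert_frame_equal(r1, r2)
        pd.testing.assert_frame_equal(p1, p2)


class TestAdjacency:
    def test_spot_values_forced_by_formula(self):
        rho = pd.DataFrame([[1.0, -1.0], [-1.0, 1.0]])
        a = adjacency(rho)
        assert a.iloc[0, 0] == 1.0
        assert a.iloc[0, 1] == 0.0
        rho0 = pd.DataFrame(np.eye(3))
        a0 = adjacency(rho0)
        assert a0.iloc[0, 1] == pytest.approx(0.0625)

    def test_monotone_in_rho(self):
        rhos = np.linspace(-1, 1, 21)
        vals = (0.5 + 0.5 * rhos) ** 4
        assert (np.diff(vals) > 0).all()

    def test_tom_symmetric_unit_range(self):
        rng = np.random.default_rng(9)
        X = rng.standard_normal((15, 60))
        rho = pd.DataFrame(np.corrcoef(X))
        T = topological_overlap(adjacency(rho)).to_numpy()
        assert np.allclose(T, T.T)
        assert T.min() >= 0 and T.max() <= 1


@pytest.fixture(scope="module")
def planted():
    model = simdata.OtuSimModel(
        n_taxa=35, block_sizes=[20, 15], block_rho=0.8, depth=20_000
    )
    counts, _, labels = simdata.simulate_otu_table(model, 200, seed=10)
    return counts, labels


class TestModules:
    def test_two_planted_blocks_recovered(self, planted):
        counts, truth = planted
        rho, _ = sparcc(counts, n_bootstraps=0, seed=11)
        labels = detect_modules(adjacency(rho), min_size=10)
        ari = adjusted_rand_score(truth, pd.factorize(labels)[0])
        assert ari >= 0.9

    def test_small_block_unassigned(self):
        model = simdata.OtuSimModel(
            n_taxa=30, block_sizes=[4], block_rho=0.9, depth=20_000
        )
        counts, _, labels_true = simdata.simulate_otu_table(model, 150, seed=12)
        rho, _ = sparcc(counts, n_bootstraps=0, seed=13)
        labels = detect_modules(adjacency(rho), min_size=10)
        block = labels.iloc[:4]
        assert (block == "unassigned").all()

    def test_identity_adjacency_all_unassigned(self):
        a = pd.DataFrame(np.eye(20))
        labels = detect_modules(a, min_size=5)
        assert (labels == "unassigned").all()

    def test_labels_invariant_to_taxon_order(self, planted):
        counts, _ = planted
        rho, _ = sparcc(counts, n_bootstraps=0, seed=14)
        a = adjacency(rho)
        labels = detect_modules(a, min_size=10)
        perm = np.random.default_rng(15).permutation(len(a))
        a_perm = a.iloc[perm, perm]
        labels_perm = detect_modules(a_perm, min_size=10)
        # same partition of taxa regardless of order
        for taxon in a.index:
            mates = set(labels.index[labels == labels[taxon]])
            mates_perm = set(labels_perm.index[labels_perm == labels_perm[taxon]])
            assert mates == mates_perm


class TestEigenotus:
    def test_rank_one_module_recovers_common_profile(self):
        rng = np.random.default_rng(16)
        profile = rng.standard_normal(40)
        counts = counts_frame(np.tile(profile, (5, 1)))
        labels = pd.Series(["FMC1"] * 5, index=counts.index)
        eig = eigenotus(counts, labels)
        c = np.corrcoef(eig.loc["FMC1"], profile)[0, 1]
        assert c == pytest.approx(1.0, abs=1e-9)
        assert eig.loc["FMC1"].var(ddof=1) == pytest.approx(1.0)

    def test_variance_explained_matches_svd(self):
        rng = np.random.default_rng(17)
        X = rng.standard_normal((8, 50)) + rng.standard_normal((1, 50))
        counts = counts_frame(X)
        labels = pd.Series(["FMC1"] * 8, index=counts.index)
        eig = eigenotus(counts, labels).loc["FMC1"].to_numpy()
        Z = (X - X.mean(axis=1, keepdims=True)) / X.std(axis=1, keepdims=True)
        s = np.linalg.svd(Z, compute_uv=False)
        share = s[0] ** 2 / (s**2).sum()
        # correlation-weighted reconstruction: mean squared correlation of
        # members with the eigenOTU equals the leading share
        r2 = np.mean([np.corrcoef(z, eig)[0, 1] ** 2 for z in Z])
        assert r2 == pytest.approx(share, abs=1e-8)

    def test_sign_flips_with_negated_profiles(self):
        rng = np.random.default_rng(18)
        X = np.tile(rng.standard_normal(30), (4, 1)) + 0.01 * rng.standard_normal((4, 30))
        labels = pd.Series(["FMC1"] * 4, index=[f"OTU{i}" for i in range(4)])
        e1 = eigenotus(counts_frame(X), labels).loc["FMC1"].to_numpy()
        e2 = eigenotus(counts_frame(-X), labels).loc["FMC1"].to_numpy()
        assert np.allclose(e1, -e2, atol=1e-8)


class TestAssociations:
    def test_identical_trait_gives_spearman_one(self):
        rng = np.random.default_rng(19)
        e = rng.standard_normal(50)
        eigen = pd.DataFrame([e], index=["FMC1"],
                             columns=[f"S{j}" for j in range(50)])
        meta = pd.DataFrame({"t": e}, index=eigen.columns)
        out = module_trait_association(eigen, meta)
        assert out.iloc[0]["spearman_rho"] == pytest.approx(1.0)

    def test_bh_adjustment_arithmetic(self):
        # independent check of the BH step on a known example
        from statsmodels.stats.multitest import multipletests

        padj = multipletests([0.01, 0.02, 0.03, 0.04], method="fdr_bh")[1]
        assert np.allclose(padj, 0.04)

    def test_coupled_module_found(self):
        model = simdata.OtuSimModel(
            n_taxa=40, block_sizes=[15, 10], block_rho=0.8, depth=20_000,
            trait_block=0, trait_coef=3.0,
        )
        hits = 0
        for seed in range(10):
            counts, meta, truth = simdata.simulate_otu_table(model, 120, seed=seed)
            rho, _ = sparcc(counts, n_bootstraps=0, seed=seed + 100)
            labels = detect_modules(adjacency(rho), min_size=8)
            if (labels != "unassigned").sum() == 0:
                continue
            eig = eigenotus(counts, labels)
            assoc = module_trait_association(eig, meta[["disease"]])
            best = assoc.sort_values("padj").iloc[0]["module"]
            members = set(labels.index[labels == best])
            block0 = {f"OTU_{i}" for i in range(15)}
            hits += len(members & block0) > len(members) / 2
        assert hits >= 8


class TestCrossDomain:
    def test_disjoint_samples_rejected(self):
        a = counts_frame(np.ones((5, 10), dtype=int), prefix="A")
        b = counts_frame(np.ones((5, 10), dtype=int), prefix="B")
        b.columns = [f"T{j}" for j in range(10)]
        with pytest.raises(ValueError, match="shared samples"):
            cooccur.cross_domain_correlation(a, b)

    def test_planted_cross_pair_strongest(self):
        rng = np.random.default_rng(20)
        hits = 0
        for seed in range(10):
            model = simdata.OtuSimModel(n_taxa=12, block_sizes=[2], block_rho=0.9,
                                        depth=10_000)
            counts, _, _ = simdata.simulate_otu_table(model, 120, seed=seed)
            a = counts.iloc[[0] + list(range(2, 7))]  # one block member + noise
            b = counts.iloc[[1] + list(range(7, 12))].copy()
            b.index = [f"B_{t}" for t in b.index]
            out = cooccur.cross_domain_correlation(a, b, seed=seed, n_bootstraps=0)
            top = out.sort_values("rho", ascending=False).iloc[0]
            hits += (top["taxon_a"] == "OTU_0") and (top["taxon_b"] == "B_OTU_1")
        assert hits >= 8


class TestRarefy:
    def test_low_depth_samples_dropped_never_upsampled(self):
        counts = counts_frame([[100, 3], [50, 2]])
        out = rarefy(counts, depth=100, seed=1)
        assert list(out.columns) == ["S0"]
        assert out["S0"].sum() == 100

    def test_deterministic(self):
        rng = np.random.default_rng(21)
        counts = counts_frame(rng.integers(0, 50, (10, 8)))
        o1 = rarefy(counts, depth=100, seed=5)
        o2 = rarefy(counts, depth=100, seed=5)
        pd.testing.assert_frame_equal(o1, o2)
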