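"""Calibration and recovery experiments on synthetic studies.

Each function builds its own inputs with the generator, runs the relevant
stage of the pipeline and measures an operating characteristic: family-wise
error of permutation thresholds, power and support-interval coverage for
planted QTL, sensitivity of the interaction scan to diet-masked effects,
variance-component recovery, SparCC and module recovery, and end-to-end
candidate-gene recovery.  These are the quantities the package's validation
rests on; everything is deterministic given the seed.
"""

from __future__ import annotations

import numpy as np

from . import cooccur, haplotypes, scan, simdata, traits
from .pipeline import StudyConfig, run_synthetic_study

__all__ = [
    "make_cohort",
    "hmm_oracle_error",
    "fwer_calibration",
    "additive_power_coverage",
    "hidden_association",
    "lod_identity_error",
    "h2_recovery",
    "sparcc_recovery",
    "adjacency_spot_value",
    "module_recovery",
    "worked_example_intersection",
    "funnel_success_rate",
    "ANA_QTL_CANDIDATES_11",
    "DIET_DE_OVERLAP_8",
]

# candidate-gene lists printed for the antinuclear-antibody QTL at the MHC
# locus: the 11 genes shared between the locus's variant-filtered candidates
# and trait differential expression, and the 8 of them that remain after
# intersection with the diet-stratified differential-expression set
ANA_QTL_CANDIDATES_11 = (
    "H2-Eb2", "Myo1f", "Tap1", "Cfb", "C2", "H2-K1",
    "Psmb9", "Psmb8", "Tnxb", "Rps28", "Col11a2",
)
DIET_DE_OVERLAP_8 = (
    "Myo1f", "Tap1", "Cfb", "C2", "H2-K1", "Psmb9", "Psmb8", "Tnxb",
)


def make_cohort(
    seed: int,
    n_chrom: int = 10,
    markers_per_chrom: int = 20,
    chrom_cm: float = 100.0,
    breeding_pairs: int = 50,
    n_offspring: int = 10,
    generations: int = 20,
) -> haplotypes.DiplotypePosterior:
    """Simulate an AIL cohort and return founder-dosage posteriors."""
    spec = {f"chr{c + 1}": (markers_per_chrom, chrom_cm) for c in range(n_chrom)}
    panel = simdata.simulate_founders(4, spec, fraction_private=1.0, seed=seed)
    cfg = simdata.SimConfig(
        generations=generations, breeding_pairs=breeding_pairs,
        n_offspring=n_offspring, genotyping_error=0.002, seed=seed + 1,
    )
    _, _, gm = simdata.simulate_cross(panel, cfg)
    gq, _ = haplotypes.qc_filter(gm)
    return haplotypes.reconstruct(gq, generations=generations, eps=0.002)


def _enumerate_posterior(calls_row, founder_alleles, cm, g_eff, eps):
    """Posterior by explicit summation over every diplotype state path."""
    F, M = founder_alleles.shape
    S = F * F
    em = haplotypes._emission_table(founder_alleles, eps)
    prior = np.full(S, 1.0 / S)
    Ts = [
        np.kron(
            haplotypes._transition(cm[k + 1] - cm[k], g_eff, F),
            haplotypes._transition(cm[k + 1] - cm[k], g_eff, F),
        )
        for k in range(M - 1)
    ]
    paths = np.indices((S,) * M).reshape(M, -1).T
    p = prior[paths[:, 0]].astype(float)
    for k in range(M):
        obs = calls_row[k]
        if obs != haplotypes.MISSING:
            p *= em[k, paths[:, k], obs]
        if k < M - 1:
            p *= Ts[k][paths[:, k], paths[:, k + 1]]
    p /= p.sum()
    post = np.zeros((M, S))
    for k in range(M):
        np.add.at(post[k], paths[:, k], p)
    # collapse ordered to unordered states
    pairs = [(i, j) for i in range(F) for j in range(i, F)]
    out = np.zeros((M, len(pairs)))
    for s, (i, j) in enumerate((i, j) for i in range(F) for j in range(F)):
        out[:, pairs.index((min(i, j), max(i, j)))] += post[:, s]
    return out


def hmm_oracle_error(seed: int, n_markers: int = 5, n_individuals: int = 3) -> float:
    """Max |forward-backward - exhaustive-enumeration| posterior difference."""
    import pandas as pd

    rng = np.random.default_rng(seed)
    founder = rng.integers(0, 2, size=(4, n_markers)).astype(np.int8)
    calls = rng.integers(0, 3, size=(n_individuals, n_markers)).astype(np.int8)
    calls[0, n_markers // 2] = -1
    cm = np.sort(rng.uniform(0, 15, n_markers))
    markers = pd.DataFrame(
        {"chrom": "chr1", "bp": (cm * 2e6).astype(int) + 1, "cM": cm}
    )
    gm = haplotypes.GenotypeMatrix(calls, markers, founder, list("abcd"))
    post = haplotypes.reconstruct(gm, generations=7, eps=0.01)
    err = 0.0
    for i in range(n_individuals):
        oracle = _enumerate_posterior(calls[i], founder, cm, 7.0, 0.01)
        err = max(err, float(np.abs(post.posteriors[i] - oracle).max()))
    return err


def fwer_calibration(
    seed: int, n_traits: int = 200, n_perm: int = 200,
    cohort: haplotypes.DiplotypePosterior | None = None,
) -> float:
    """Empirical family-wise error of the permutation genome-wide threshold.

    Null gaussian traits over a 10-chromosome cohort (n = 500): each trait
    gets its own permutation threshold; FWER is the fraction of traits whose
    genome-max LOD reaches it.
    """
    post = cohort if cohort is not None else make_cohort(seed)
    rng = np.random.default_rng(seed + 10)
    n = post.n_individuals
    hits = 0
    for t in range(n_traits):
        r = rng.standard_normal(n)
        r -= r.mean()
        a_gw, _ = scan.permutation_thresholds(
            r, post, model="additive", n_perm=n_perm, seed=seed + 100 + t
        )
        res = scan.scan_additive(r, post)
        hits += res.max_lod >= a_gw
    return hits / n_traits


def additive_power_coverage(
    seed: int, n_reps: int = 50, r2: float = 0.2, n_perm: int = 200,
    cohort: haplotypes.DiplotypePosterior | None = None,
) -> dict:
    """Detection power and 1.5-LOD support-interval coverage for planted QTL.

    Each replicate plants a QTL of dosage-R² ``r2`` at a random locus of the
    n = 500 cohort, scans, and calls QTL against that replicate's own
    permutation thresholds.
    """
    post = cohort if cohort is not None else make_cohort(seed)
    rng = np.random.default_rng(seed + 20)
    n = post.n_individuals
    detected = covered = 0
    for rep in range(n_reps):
        locus = int(rng.integers(0, post.n_loci))
        beta = np.zeros(4)
        beta[rng.integers(0, 4)] = 1.0
        g = post.dosages[:, locus, :] @ beta
        g = (g - g.mean()) / max(g.std(), 1e-9)
        r = np.sqrt(r2) * g + np.sqrt(1 - r2) * rng.standard_normal(n)
        r -= r.mean()
        a_gw, a_cw = scan.permutation_thresholds(
            r, post, model="additive", n_perm=n_perm, seed=seed + 200 + rep
        )
        res = scan.scan_additive(r, post)
        calls = scan.call_qtl(res, a_gw, a_cw, trait="sim")
        chrom = post.markers["chrom"].iloc[locus]
        bp = post.markers["bp"].iloc[locus]
        gw = [c for c in calls if c.tier == "genome-wide" and c.chrom == chrom]
        if gw:
            detected += 1
            lo, hi = gw[0].support_bp
            covered += lo <= bp <= hi
    return {
        "power": detected / n_reps,
        "coverage": covered / detected if detected else float("nan"),
    }


def hidden_association(
    seed: int, n_reps: int = 50, int_r2: float = 0.1, n_perm: int = 200,
    cohort: haplotypes.DiplotypePosterior | None = None,
) -> dict:
    """Power of the G x Diet scan vs the additive scan on diet-masked QTL.

    The planted effect is +a in the restricted diet, -a in the control diet
    and 0 in the western diet, with balanced diet groups, so the marginal
    genotype effect cancels; only the interaction scan should find it.
    """
    post = cohort if cohort is not None else make_cohort(
        seed, n_chrom=10, markers_per_chrom=20, n_offspring=12
    )
    rng = np.random.default_rng(seed + 30)
    n = post.n_individuals
    diet = np.array(simdata.DIET_LEVELS)[np.arange(n) % 3]
    coef = {"restricted": 1.0, "control": -1.0, "western": 0.0}
    hits_int = hits_add = 0
    for rep in range(n_reps):
        locus = int(rng.integers(0, post.n_loci))
        pattern = np.zeros(4)
        pattern[rng.integers(0, 4)] = 1.0
        g = post.dosages[:, locus, :] @ pattern
        g = g - g.mean()  # centering keeps the diet main effect out of g*c
        g_int = g * np.vectorize(coef.get)(diet)
        g_int = (g_int - g_int.mean()) / max(g_int.std(), 1e-9)
        r = np.sqrt(int_r2) * g_int + np.sqrt(1 - int_r2) * rng.standard_normal(n)
        r -= r.mean()

        a_int, _ = scan.permutation_thresholds(
            r, post, model="gxdiet", factor=diet, n_perm=n_perm,
            seed=seed + 300 + rep,
        )
        res_int = scan.scan_interaction(r, post, diet, model_name="gxdiet")
        hits_int += res_int.max_lod >= a_int

        a_add, _ = scan.permutation_thresholds(
            r, post, model="additive", n_perm=n_perm, seed=seed + 600 + rep
        )
        res_add = scan.scan_additive(r, post)
        hits_add += res_add.max_lod >= a_add
    return {"power_gxdiet": hits_int / n_reps, "power_additive": hits_add / n_reps}


def lod_identity_error(seed: int, cohort=None) -> float:
    """Max |LOD - (n/2) log10(1/(1-R²))| against an independent regression."""
    post = cohort if cohort is not None else make_cohort(
        seed, n_chrom=2, markers_per_chrom=15, n_offspring=4
    )
    rng = np.random.default_rng(seed + 40)
    n = post.n_individuals
    r = rng.standard_normal(n)
    r += post.dosages[:, 3, :] @ np.array([0.5, 0, -0.5, 0])
    r -= r.mean()
    res = scan.scan_additive(r, post)
    err = 0.0
    for locus in range(post.n_loci):
        X = np.column_stack([np.ones(n), post.dosages[:, locus, :3]])
        coef, *_ = np.linalg.lstsq(X, r, rcond=None)
        r2 = 1 - np.sum((r - X @ coef) ** 2) / np.sum(r**2)
        err = max(err, abs(res.table["lod"].iloc[locus] - scan.lod_from_r2(r2, n)))
    return float(err)


def h2_recovery(
    seed: int, n_seeds: int = 50, h2: float = 0.4,
    cohort: haplotypes.DiplotypePosterior | None = None,
) -> float:
    """Mean REML heritability estimate for simulated polygenic traits.

    Polygenic values are drawn with covariance K on an n = 800 cohort; the
    recovered sigma_g^2 / (sigma_g^2 + sigma_e^2) should track ``h2``.
    """
    post = cohort if cohort is not None else make_cohort(
        seed, n_chrom=5, markers_per_chrom=40, n_offspring=16
    )
    K = haplotypes.kinship(post)
    n = K.n
    w, U = np.linalg.eigh(K.values)
    w = np.clip(w, 0, None)
    import pandas as pd

    rng = np.random.default_rng(seed + 50)
    h2s = []
    for s in range(n_seeds):
        # exact-model draw: y ~ N(0, h2*K + (1-h2)*I); rescaling u per draw
        # would distort the eigen-structure REML estimates against
        u = U @ (np.sqrt(h2 * w) * rng.standard_normal(n))
        y = u + np.sqrt(1 - h2) * rng.standard_normal(n)
        t = pd.DataFrame(
            {
                "id": [f"i{k}" for k in range(n)],
                "sex": pd.Categorical(
                    np.array(simdata.SEX_LEVELS)[rng.integers(0, 2, n)],
                    categories=simdata.SEX_LEVELS,
                ),
                "diet": pd.Categorical(
                    np.array(simdata.DIET_LEVELS)[rng.integers(0, 3, n)],
                    categories=simdata.DIET_LEVELS,
                ),
                "y": y,
            }
        )
        rt = traits.residualize(t, "y", K, apply_boxcox=False)
        h2s.append(rt.h2)
    return float(np.mean(h2s))


def sparcc_recovery(seed: int, n_samples: int = 200) -> dict:
    """SparCC point estimate for a planted pair vs an all-null table.

    The planted pair sits at the median log-abundance (a correlation can
    only be recovered for taxa that receive reads) at a typical 16S survey's
    20,000-read subsampling depth.  The null table instead matches such a
    survey's reads-per-taxon ratio (20,000 reads over ~300 OTUs, i.e. depth
    3,400 for 50 taxa), the regime whose count noise governs
    false-correlation size.
    """
    planted = simdata.OtuSimModel(
        n_taxa=50, block_sizes=[2], block_rho=0.8, depth=20_000,
        block_log_mean=0.0,
    )
    counts, _, _ = simdata.simulate_otu_table(planted, n_samples, seed=seed)
    rho, _ = cooccur.sparcc(counts, n_bootstraps=0, seed=seed + 1)
    rho_pair = float(rho.iloc[0, 1])

    null = simdata.OtuSimModel(n_taxa=50, depth=3_400)
    counts0, _, _ = simdata.simulate_otu_table(null, n_samples, seed=seed + 2)
    rho0, _ = cooccur.sparcc(counts0, n_bootstraps=0, seed=seed + 3)
    R = rho0.to_numpy()
    null_mean_abs = float(np.abs(R[np.triu_indices_from(R, 1)]).mean())
    return {"rho_planted": rho_pair, "null_mean_abs_rho": null_mean_abs}


def adjacency_spot_value(rho: float = 0.0, beta: float = 4.0) -> float:
    """Network adjacency of a single correlation value."""
    import pandas as pd

    m = pd.DataFrame([[1.0, rho], [rho, 1.0]])
    return float(cooccur.adjacency(m, beta=beta).iloc[0, 1])


def module_recovery(seed: int, n_samples: int = 200) -> dict:
    """Adjusted Rand index for two planted blocks; small-block handling."""
    model = simdata.OtuSimModel(
        n_taxa=35, block_sizes=[20, 15], block_rho=0.8, depth=20_000
    )
    counts, _, truth = simdata.simulate_otu_table(model, n_samples, seed=seed)
    rho, _ = cooccur.sparcc(counts, n_bootstraps=0, seed=seed + 1)
    labels = cooccur.detect_modules(cooccur.adjacency(rho), min_size=10)
    codes = labels.astype("category").cat.codes.to_numpy()
    ari = _adjusted_rand(truth, codes)

    small = simdata.OtuSimModel(
        n_taxa=30, block_sizes=[4], block_rho=0.9, depth=20_000
    )
    counts2, _, _ = simdata.simulate_otu_table(small, 150, seed=seed + 2)
    rho2, _ = cooccur.sparcc(counts2, n_bootstraps=0, seed=seed + 3)
    labels2 = cooccur.detect_modules(cooccur.adjacency(rho2), min_size=10)
    frac_unassigned = float((labels2.iloc[:4] == "unassigned").mean())
    return {"ari": ari, "small_block_unassigned_frac": frac_unassigned}


def _adjusted_rand(a, b) -> float:
    """Adjusted Rand index from the pair-counting contingency table."""
    a = np.asarray(a)
    b = np.asarray(b)
    ua, ia = np.unique(a, return_inverse=True)
    ub, ib = np.unique(b, return_inverse=True)
    ct = np.zeros((len(ua), len(ub)), dtype=int)
    np.add.at(ct, (ia, ib), 1)

    def c2(x):
        return x * (x - 1) / 2.0

    sum_ij = c2(ct).sum()
    sum_a = c2(ct.sum(axis=1)).sum()
    sum_b = c2(ct.sum(axis=0)).sum()
    n = c2(len(a))
    expected = sum_a * sum_b / n
    max_idx = (sum_a + sum_b) / 2
    if max_idx == expected:
        return 1.0
    return float((sum_ij - expected) / (max_idx - expected))


def worked_example_intersection() -> list[str]:
    """Intersect the printed 11-gene locus list with the printed 8-gene
    diet-expression subset."""
    from . import integrate

    eleven = integrate.GeneSet.build(
        ANA_QTL_CANDIDATES_11, "ana-qtl-11", "published-list"
    )
    eight = integrate.GeneSet.build(DIET_DE_OVERLAP_8, "diet-de-8", "published-list")
    return sorted(integrate.intersect([eleven, eight]).ids)


def funnel_success_rate(seed: int, n_runs: int = 20, config: StudyConfig | None = None) -> float:
    """Fraction of end-to-end synthetic studies whose multi-omics funnel
    leaves exactly the planted causal gene."""
    hits = 0
    for k in range(n_runs):
        res = run_synthetic_study(seed + 1000 * k, config)
        hits += res.detected
    return hits / n_runs
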