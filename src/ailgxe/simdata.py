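"""Synthetic study generator for a four-founder advanced intercross line.

Emulates the data the analysis pipeline consumes: inbred founder genotypes,
an AIL pedigree bred for a configurable number of generations from a fixed
number of breeding pairs, observed genotypes with genotyping error, traits
with founder-specific QTL effects that may differ by diet (the
gene-environment structure the interaction scans are designed to detect),
polygenic covariance through a kinship matrix, founder variant tables for
fine-mapping, and block-correlated compositional OTU tables for community
detection.

Meiosis follows the Haldane model: the crossover count per chromosome is
Poisson with mean equal to the map length in Morgans and crossover positions
are uniform on the genetic map, with no interference.  This is the process
whose Markov structure the haplotype HMM assumes.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .haplotypes import GenotypeMatrix, KinshipMatrix

__all__ = [
    "FounderPanel",
    "SimConfig",
    "QtlSpec",
    "PhenoModel",
    "OtuSimModel",
    "simulate_founders",
    "simulate_cross",
    "true_dosages",
    "simulate_phenotypes",
    "simulate_variant_table",
    "simulate_otu_table",
    "simulate_de_genes",
    "make_gene_annotation",
    "write_vcf",
    "write_plink",
    "write_biom_json",
]

DIET_LEVELS = ["restricted", "control", "western"]
SEX_LEVELS = ["F", "M"]
DEFAULT_STRAINS = ["MRL", "NZM", "BXD2", "CAST"]
CONSEQUENCES = ["synonymous", "missense", "5_prime_UTR", "3_prime_UTR", "intergenic", "intronic"]

BP_PER_CM = 2_000_000  # simple linear physical:genetic map


@dataclass
class FounderPanel:
    """Inbred founder haplotypes over an ordered marker map."""

    markers: pd.DataFrame  # chrom, bp, cM
    alleles: np.ndarray  # (n_founders, n_markers) in {0,1}
    strains: list[str]

    def __post_init__(self) -> None:
        self.alleles = np.asarray(self.alleles, dtype=np.int8)
        if self.alleles.shape[0] < 2:
            raise ValueError("at least 2 founders required")
        if not np.isin(self.alleles, [0, 1]).all():
            raise ValueError("founder alleles must be binary")
        if len(self.markers) != self.alleles.shape[1]:
            raise ValueError("markers length must equal allele columns")
        for chrom, sub in self.markers.groupby("chrom", sort=False):
            if np.any(np.diff(sub["cM"].to_numpy()) < 0):
                raise ValueError(f"genetic positions decrease on chromosome {chrom!r}")

    @property
    def n_founders(self) -> int:
        return self.alleles.shape[0]

    @property
    def n_markers(self) -> int:
        return self.alleles.shape[1]

    def chromosomes(self) -> list:
        return list(dict.fromkeys(self.markers["chrom"]))


@dataclass
class SimConfig:
    """Breeding design of the advanced intercross.

    Defaults follow a large AIL design: 20 intercross generations with 50
    breeding pairs per generation, three diets and two sexes assigned at
    random to the final cohort.
    """

    generations: int = 20
    breeding_pairs: int = 50
    n_offspring: int = 10  # offspring per final breeding pair
    genotyping_error: float = 0.002
    missing_rate: float = 0.0
    avoid_sib_mating: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.generations < 0:
            raise ValueError("generations must be >= 0")
        if not (0 <= self.genotyping_error < 0.5):
            raise ValueError("genotyping_error must be in [0, 0.5)")
        if self.breeding_pairs < 1 or self.n_offspring < 1:
            raise ValueError("breeding_pairs and n_offspring must be >= 1")


@dataclass
class QtlSpec:
    """One simulated QTL: founder effect vector, optionally diet-specific."""

    locus: int
    beta: np.ndarray  # (n_founders,) additive founder effects
    diet_beta: np.ndarray | None = None  # (n_diets, n_founders) G x Diet effects

    def __post_init__(self) -> None:
        self.beta = np.asarray(self.beta, dtype=float)
        if self.diet_beta is not None:
            self.diet_beta = np.asarray(self.diet_beta, dtype=float)


@dataclass
class PhenoModel:
    """Variance-component description of a simulated trait."""

    qtl: list[QtlSpec] = field(default_factory=list)
    h2_qtl: float = 0.0
    h2_polygenic: float = 0.0
    v_diet: float = 0.0
    v_sex: float = 0.0
    family: str = "gaussian"  # or "binary"
    prevalence: float = 0.3  # binary traits: liability-threshold prevalence

    def __post_init__(self) -> None:
        fracs = (self.h2_qtl, self.h2_polygenic, self.v_diet, self.v_sex)
        if any(f < 0 for f in fracs):
            raise ValueError("variance fractions must be non-negative")
        if sum(fracs) > 1:
            raise ValueError("variance fractions must sum to <= 1")
        if self.family not in ("gaussian", "binary"):
            raise ValueError(f"unknown trait family {self.family!r}")

    @property
    def v_noise(self) -> float:
        return 1.0 - (self.h2_qtl + self.h2_polygenic + self.v_diet + self.v_sex)


@dataclass
class OtuSimModel:
    """Block-correlated compositional model for OTU count tables.

    Basis log-abundances are gaussian with an equicorrelated block structure
    (within-block correlation ``block_rho``); observed counts are multinomial
    draws at ``depth`` reads per sample, so samples are compositional by
    construction.  ``trait_block``/``trait_coef`` couple one block's shared
    factor to a binary trait through a logistic link.
    """

    n_taxa: int
    block_sizes: list[int] = field(default_factory=list)
    block_rho: float = 0.8
    log_mean_sd: float = 2.0
    log_sd: float = 1.0
    depth: int = 20_000
    block_log_mean: float | None = None  # pin block taxa at this log-mean
    trait_block: int | None = None
    trait_coef: float = 0.0

    def __post_init__(self) -> None:
        if sum(self.block_sizes) > self.n_taxa:
            raise ValueError("block sizes exceed n_taxa")
        if not (-1 <= self.block_rho <= 1):
            raise ValueError("block_rho must be in [-1, 1]")
        if self.depth <= 0:
            raise ValueError("depth must be > 0")


def simulate_founders(
    n_founders: int,
    marker_spec: dict,
    fraction_private: float,
    seed: int,
    strains: list[str] | None = None,
) -> FounderPanel:
    """Draw founder haplotypes with a stated fraction of strain-private markers.

    ``marker_spec`` maps chromosome id to ``(n_markers, map_length_cM)``.  At a
    private marker exactly one founder (chosen uniformly) carries the minority
    allele; at the remaining markers all founders are identical, so only the
    private fraction is informative for haplotype reconstruction.
    """
    if not marker_spec:
        raise ValueError("marker_spec is empty")
    if not (0 <= fraction_private <= 1):
        raise ValueError(f"fraction_private must be in [0, 1], got {fraction_private}")
    rng = np.random.default_rng(seed)
    if strains is None:
        strains = (DEFAULT_STRAINS + [f"F{i}" for i in range(4, n_founders)])[:n_founders]

    rows = []
    for chrom, (n_m, length_cm) in marker_spec.items():
        if n_m < 1 or length_cm < 0:
            raise ValueError(f"invalid marker_spec entry for chromosome {chrom!r}")
        cm = np.sort(rng.uniform(0, length_cm, size=n_m))
        for pos in cm:
            rows.append({"chrom": chrom, "bp": int(pos * BP_PER_CM) + 1, "cM": float(pos)})
    markers = pd.DataFrame(rows)

    M = len(markers)
    base = rng.integers(0, 2, size=M).astype(np.int8)
    alleles = np.tile(base, (n_founders, 1))
    private = rng.random(M) < fraction_private
    owner = rng.integers(0, n_founders, size=M)
    flip_idx = np.flatnonzero(private)
    alleles[owner[flip_idx], flip_idx] ^= 1
    return FounderPanel(markers=markers, alleles=alleles, strains=list(strains))


def _chrom_index(panel: FounderPanel) -> list[tuple[np.ndarray, np.ndarray]]:
    chrom = panel.markers["chrom"].to_numpy()
    cm = panel.markers["cM"].to_numpy(dtype=float)
    out = []
    for c in dict.fromkeys(chrom):
        idx = np.flatnonzero(chrom == c)
        out.append((idx, cm[idx]))
    return out


def _meiosis(hap_pair: np.ndarray, chrom_idx, rng: np.random.Generator) -> np.ndarray:
    """One gamete from a pair of whole-genome founder-origin haplotypes.

    Crossovers per chromosome are Poisson(map length in Morgans) with
    positions uniform in cM (Haldane, no interference).
    """
    gamete = np.empty(hap_pair.shape[1], dtype=np.int8)
    for idx, cm in chrom_idx:
        length = cm[-1] - cm[0] if len(cm) > 1 else 0.0
        n_xo = rng.poisson(length / 100.0)
        current = rng.integers(0, 2)
        if n_xo == 0:
            gamete[idx] = hap_pair[current, idx]
            continue
        xo = np.sort(rng.uniform(cm[0], cm[-1], size=n_xo))
        # chromatid at each marker: flips at every crossover passed
        n_passed = np.searchsorted(xo, cm, side="right")
        chromatid = (current + n_passed) % 2
        gamete[idx] = hap_pair[chromatid, idx[np.arange(len(idx))]]
    return gamete


def simulate_cross(
    panel: FounderPanel, config: SimConfig
) -> tuple[pd.DataFrame, np.ndarray, GenotypeMatrix]:
    """Breed an advanced intercross and genotype the final cohort.

    Generation 0 is the F1 of randomly paired distinct founders; each of
    ``config.generations`` subsequent generations is bred by random pairing
    among ``breeding_pairs`` couples.  Returns the pedigree, the true
    founder-origin diplotypes ``(n, n_markers, 2)`` of the final cohort, and
    the observed genotype matrix with per-read error ``genotyping_error``.
    """
    rng = np.random.default_rng(config.seed)
    chrom_idx = _chrom_index(panel)
    F, M = panel.n_founders, panel.n_markers

    ped_rows = []

    def f1_individual(i: int) -> tuple[str, np.ndarray]:
        a, b = rng.choice(F, size=2, replace=False)
        iid = f"G0_{i}"
        ped_rows.append(
            {"id": iid, "mother": panel.strains[a], "father": panel.strains[b], "generation": 0}
        )
        return iid, np.array([np.full(M, a), np.full(M, b)], dtype=np.int8)

    pop_size = 2 * config.breeding_pairs
    pop = [f1_individual(i) for i in range(pop_size)]

    def breed(parents, gen: int, n_out: int, per_pair: int):
        order = rng.permutation(len(parents))
        pairs = [(parents[order[2 * k]], parents[order[2 * k + 1]]) for k in range(len(parents) // 2)]
        if config.avoid_sib_mating:
            # re-draw full-sib pairs a few times; best effort only
            for _ in range(10):
                sibs = [
                    k
                    for k, ((ia, _), (ib, _)) in enumerate(pairs)
                    if _parents_of(ped_rows, ia) == _parents_of(ped_rows, ib)
                ]
                if not sibs:
                    break
                order = rng.permutation(len(parents))
                pairs = [
                    (parents[order[2 * k]], parents[order[2 * k + 1]])
                    for k in range(len(parents) // 2)
                ]
        out = []
        i = 0
        while len(out) < n_out:
            for (mid, mhap), (fid, fhap) in pairs:
                if len(out) >= n_out:
                    break
                for _ in range(per_pair):
                    if len(out) >= n_out:
                        break
                    child = np.array(
                        [_meiosis(mhap, chrom_idx, rng), _meiosis(fhap, chrom_idx, rng)],
                        dtype=np.int8,
                    )
                    iid = f"G{gen}_{i}"
                    i += 1
                    ped_rows.append(
                        {"id": iid, "mother": mid, "father": fid, "generation": gen}
                    )
                    out.append((iid, child))
        return out

    for gen in range(1, config.generations + 1):
        final = gen == config.generations
        n_out = config.breeding_pairs * config.n_offspring if final else pop_size
        per_pair = config.n_offspring if final else 2
        pop = breed(pop, gen, n_out, per_pair)

    ids = [iid for iid, _ in pop]
    diplo = np.stack([hap for _, hap in pop], axis=0).transpose(0, 2, 1)  # (n, M, 2)

    a1 = panel.alleles[diplo[:, :, 0], np.arange(M)[None, :]]
    a2 = panel.alleles[diplo[:, :, 1], np.arange(M)[None, :]]
    eps = config.genotyping_error
    if eps > 0:
        a1 = a1 ^ (rng.random(a1.shape) < eps)
        a2 = a2 ^ (rng.random(a2.shape) < eps)
    calls = (a1 + a2).astype(np.int8)
    if config.missing_rate > 0:
        calls[rng.random(calls.shape) < config.missing_rate] = -1

    gm = GenotypeMatrix(
        calls=calls,
        markers=panel.markers.copy(),
        founder_alleles=panel.alleles,
        strains=list(panel.strains),
    )
    ped = pd.DataFrame(ped_rows)
    ped.attrs["cohort_ids"] = ids
    ped.attrs["seed"] = config.seed
    return ped, diplo, gm


def _parents_of(ped_rows, iid):
    for row in reversed(ped_rows):
        if row["id"] == iid:
            return frozenset((row["mother"], row["father"]))
    return frozenset()


def true_dosages(diplo: np.ndarray, n_founders: int) -> np.ndarray:
    """Founder dosage tensor ``(n, M, F)`` from true diplotypes."""
    n, M, _ = diplo.shape
    dos = np.zeros((n, M, n_founders))
    for h in range(2):
        np.add.at(dos, (np.arange(n)[:, None], np.arange(M)[None, :], diplo[:, :, h]), 1.0)
    return dos


def _standardized(x: np.ndarray) -> np.ndarray:
    sd = x.std()
    if sd == 0:
        return np.zeros_like(x)
    return (x - x.mean()) / sd


def simulate_phenotypes(
    dosages: np.ndarray,
    kinship: KinshipMatrix | np.ndarray | None,
    model: PhenoModel,
    seed: int,
    trait_name: str = "trait",
    diet: np.ndarray | None = None,
    sex: np.ndarray | None = None,
) -> tuple[pd.DataFrame, dict]:
    """Simulate a trait over the cohort with stated variance fractions.

    Each component (QTL genetic value, polygenic draw with covariance K,
    diet and sex main effects, residual noise) is standardized empirically and
    scaled by the square root of its variance fraction, so realized fractions
    match the model up to sampling noise.  Binary traits threshold the latent
    gaussian at the model's prevalence.  Returns the trait table (id, sex,
    diet, trait) and a dict of realized variance fractions.
    """
    rng = np.random.default_rng(seed)
    n, L, F = dosages.shape
    K = kinship.values if isinstance(kinship, KinshipMatrix) else kinship
    if K is not None:
        K = np.asarray(K, dtype=float)
        if K.shape != (n, n):
            raise ValueError("kinship dimension does not match dosages")
        if not np.allclose(K, K.T, atol=1e-8):
            raise ValueError("kinship must be symmetric")
        w = np.linalg.eigvalsh((K + K.T) / 2)
        if w.min() < -1e-8:
            raise ValueError("kinship must be positive semi-definite")

    if diet is None:
        diet = rng.integers(0, len(DIET_LEVELS), size=n)
    if sex is None:
        sex = rng.integers(0, 2, size=n)

    g = np.zeros(n)
    for q in model.qtl:
        if len(q.beta) != F:
            raise ValueError("QTL effect vector length must equal n_founders")
        D = dosages[:, q.locus, :]
        g += D @ q.beta
        if q.diet_beta is not None:
            g += np.einsum("nf,nf->n", D, q.diet_beta[diet])

    comps = {}
    comps["qtl"] = _standardized(g) * np.sqrt(model.h2_qtl) if model.h2_qtl > 0 else 0.0
    if model.h2_polygenic > 0:
        if K is None:
            raise ValueError("kinship required when h2_polygenic > 0")
        wK, UK = np.linalg.eigh((K + K.T) / 2)
        u = UK @ (np.sqrt(np.clip(wK, 0, None)) * rng.standard_normal(n))
        comps["polygenic"] = _standardized(u) * np.sqrt(model.h2_polygenic)
    else:
        comps["polygenic"] = 0.0
    diet_eff = rng.standard_normal(len(DIET_LEVELS))
    sex_eff = rng.standard_normal(2)
    comps["diet"] = (
        _standardized(diet_eff[diet]) * np.sqrt(model.v_diet) if model.v_diet > 0 else 0.0
    )
    comps["sex"] = _standardized(sex_eff[sex]) * np.sqrt(model.v_sex) if model.v_sex > 0 else 0.0
    comps["noise"] = _standardized(rng.standard_normal(n)) * np.sqrt(model.v_noise)

    y = sum(v for v in comps.values() if not np.isscalar(v)) + 0.0
    realized = {
        k: float(np.var(v)) if not np.isscalar(v) else 0.0 for k, v in comps.items()
    }
    tot = np.var(y)
    realized = {k: v / tot for k, v in realized.items()}

    if model.family == "binary":
        thr = np.quantile(y, 1 - model.prevalence)
        y = (y > thr).astype(int)

    table = pd.DataFrame(
        {
            "id": [f"ind_{i}" for i in range(n)],
            "sex": pd.Categorical([SEX_LEVELS[s] for s in sex], categories=SEX_LEVELS),
            "diet": pd.Categorical([DIET_LEVELS[d] for d in diet], categories=DIET_LEVELS),
            trait_name: y,
        }
    )
    table.attrs["seed"] = seed
    return table, realized


def make_gene_annotation(
    panel: FounderPanel, genes_per_chrom: int, gene_length_bp: int, seed: int
) -> pd.DataFrame:
    """Evenly spaced non-overlapping gene intervals over the panel's map."""
    rng = np.random.default_rng(seed)
    rows = []
    gi = 0
    for chrom, sub in panel.markers.groupby("chrom", sort=False):
        lo, hi = int(sub["bp"].min()), int(sub["bp"].max())
        span = max(hi - lo, genes_per_chrom * (gene_length_bp + 1))
        starts = np.linspace(lo, lo + span - gene_length_bp, genes_per_chrom).astype(int)
        for s in starts:
            rows.append(
                {"chrom": chrom, "start": int(s), "end": int(s + gene_length_bp - 1),
                 "gene_id": f"Gene{gi:04d}"}
            )
            gi += 1
    return pd.DataFrame(rows)


def simulate_variant_table(
    panel: FounderPanel,
    genes: pd.DataFrame,
    n_variants: int,
    fraction_common: float,
    seed: int,
    consequence_probs: dict | None = None,
    causal: dict | None = None,
) -> pd.DataFrame:
    """Founder variant records with gene assignment and consequence labels.

    A ``fraction_common`` share of records carries the alternate allele in all
    founders (the class the fine-mapping filter removes).  ``causal`` plants
    one extra record, e.g. ``{"gene": "Gene0012", "founders": {"NZM"},
    "consequence": "missense"}`` — the ground truth for recovery experiments.
    """
    if not (0 <= fraction_common <= 1):
        raise ValueError(f"fraction_common must be in [0, 1], got {fraction_common}")
    bad = genes[genes["start"] > genes["end"]]
    if len(bad):
        raise ValueError("gene intervals with start > end")
    rng = np.random.default_rng(seed)
    if consequence_probs is None:
        consequence_probs = {
            "synonymous": 0.3, "missense": 0.1, "5_prime_UTR": 0.05,
            "3_prime_UTR": 0.05, "intronic": 0.3, "intergenic": 0.2,
        }
    cons = list(consequence_probs)
    p = np.array([consequence_probs[c] for c in cons], dtype=float)
    p /= p.sum()

    chroms = panel.chromosomes()
    spans = {}
    for c, sub in panel.markers.groupby("chrom", sort=False):
        gene_end = genes.loc[genes["chrom"] == c, "end"]
        hi = max(int(sub["bp"].max()), int(gene_end.max()) if len(gene_end) else 0)
        spans[c] = (int(sub["bp"].min()), hi)
    F = panel.n_founders
    rows = []
    for i in range(n_variants):
        chrom = chroms[rng.integers(len(chroms))]
        lo, hi = spans[chrom]
        pos = int(rng.integers(lo, hi + 1))
        common = rng.random() < fraction_common
        if common:
            geno = np.ones(F, dtype=int)
        else:
            k = int(rng.integers(1, F))  # proper subset of founders carries alt
            carriers = rng.choice(F, size=k, replace=False)
            geno = np.zeros(F, dtype=int)
            geno[carriers] = 1
        csq = cons[rng.choice(len(cons), p=p)]
        gene_hit = genes[
            (genes["chrom"] == chrom) & (genes["start"] <= pos) & (genes["end"] >= pos)
        ]
        gene_id = gene_hit.iloc[0]["gene_id"] if len(gene_hit) else ""
        if csq == "intergenic":
            gene_id = ""
        elif gene_id == "":
            csq = "intergenic"
        row = {"chrom": chrom, "pos": pos, "ref": "A", "alt": "G",
               "gene": gene_id, "consequence": csq}
        row.update({s: int(gv) for s, gv in zip(panel.strains, geno)})
        rows.append(row)

    if causal is not None:
        grow = genes[genes["gene_id"] == causal["gene"]].iloc[0]
        geno = {s: int(s in causal["founders"]) for s in panel.strains}
        row = {"chrom": grow["chrom"],
               "pos": int((grow["start"] + grow["end"]) // 2),
               "ref": "A", "alt": "G", "gene": causal["gene"],
               "consequence": causal.get("consequence", "missense")}
        row.update(geno)
        rows.append(row)

    vt = pd.DataFrame(rows).sort_values(["chrom", "pos"], kind="stable").reset_index(drop=True)
    vt.attrs["strains"] = list(panel.strains)
    vt.attrs["seed"] = seed
    return vt


def simulate_otu_table(
    model: OtuSimModel, n_samples: int, seed: int
) -> tuple[pd.DataFrame, pd.DataFrame, np.ndarray]:
    """Compositional OTU counts with planted co-occurrence blocks.

    Returns (counts taxa x samples, sample metadata, true module labels with
    ``-1`` for background taxa).  Counts in each sample sum exactly to
    ``model.depth`` (multinomial closure).
    """
    if n_samples < 2:
        raise ValueError("n_samples must be >= 2")
    rng = np.random.default_rng(seed)
    T = model.n_taxa
    labels = np.full(T, -1, dtype=int)
    pos = 0
    for b, size in enumerate(model.block_sizes):
        labels[pos : pos + size] = b
        pos += size

    z = rng.standard_normal((T, n_samples))
    factors = rng.standard_normal((len(model.block_sizes), n_samples))
    rho = model.block_rho
    for b in range(len(model.block_sizes)):
        members = labels == b
        z[members] = np.sqrt(abs(rho)) * np.sign(rho) * factors[b] + np.sqrt(1 - abs(rho)) * z[members]

    mu = rng.normal(0.0, model.log_mean_sd, size=T)
    if model.block_log_mean is not None:
        mu[labels >= 0] = model.block_log_mean
    log_ab = mu[:, None] + model.log_sd * z
    w = np.exp(log_ab)
    frac = w / w.sum(axis=0, keepdims=True)
    counts = np.empty((T, n_samples), dtype=int)
    for s in range(n_samples):
        counts[:, s] = rng.multinomial(model.depth, frac[:, s])

    meta = pd.DataFrame(
        {
            "sample": [f"S{s}" for s in range(n_samples)],
            "diet": pd.Categorical(
                [DIET_LEVELS[d] for d in rng.integers(0, 3, n_samples)], categories=DIET_LEVELS
            ),
            "sex": pd.Categorical(
                [SEX_LEVELS[s] for s in rng.integers(0, 2, n_samples)], categories=SEX_LEVELS
            ),
            "stage": pd.Categorical(
                [["naive", "transient", "final"][k] for k in rng.integers(0, 3, n_samples)],
                categories=["naive", "transient", "final"],
            ),
        }
    ).set_index("sample")
    if model.trait_block is not None:
        from scipy.special import expit

        pdis = expit(model.trait_coef * factors[model.trait_block])
        meta["disease"] = (rng.random(n_samples) < pdis).astype(int)
        meta["ana"] = meta["disease"]

    counts_df = pd.DataFrame(
        counts, index=[f"OTU_{t}" for t in range(T)], columns=meta.index
    )
    return counts_df, meta, labels


def simulate_de_genes(
    universe: list[str], must_include: list[str], n_extra: int, seed: int
) -> list[str]:
    """A differential-expression gene list: required hits plus random decoys."""
    rng = np.random.default_rng(seed)
    pool = [g for g in universe if g not in set(must_include)]
    extra = list(rng.choice(pool, size=min(n_extra, len(pool)), replace=False))
    return sorted(set(must_include) | set(extra))


# ---------------------------------------------------------------------------
# writers


def write_vcf(vt: pd.DataFrame, path, strains: list[str] | None = None) -> None:
    """Write a founder variant table as VCF 4.2 with one sample per founder."""
    strains = strains or vt.attrs.get("strains")
    if not strains:
        raise ValueError("founder strain names required")
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##INFO=<ID=CSQ,Number=1,Type=String,Description="Consequence|Gene">\n')
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for chrom in dict.fromkeys(vt["chrom"]):
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\t" + "\t".join(["FORMAT"] + strains) + "\n")
        for _, r in vt.iterrows():
            info = f"CSQ={r['consequence']}|{r['gene'] or '.'}"
            gts = ["1/1" if r[s] == 1 else ("./." if r[s] < 0 else "0/0") for s in strains]
            fh.write(
                f"{r['chrom']}\t{int(r['pos'])}\t.\t{r['ref']}\t{r['alt']}\t.\tPASS\t{info}\tGT\t"
                + "\t".join(gts) + "\n"
            )


def write_plink(gm: GenotypeMatrix, prefix, ids: list[str] | None = None) -> None:
    """Write genotypes as PLINK-text .ped/.map (alleles coded A/G)."""
    ids = ids or [f"ind_{i}" for i in range(gm.n_individuals)]
    with open(f"{prefix}.map", "w") as fh:
        for _, m in gm.markers.iterrows():
            fh.write(f"{m['chrom']}\tm{int(m['bp'])}\t{m['cM']:.4f}\t{int(m['bp'])}\n")
    code = {0: "A A", 1: "A G", 2: "G G", -1: "0 0"}
    with open(f"{prefix}.ped", "w") as fh:
        for i, iid in enumerate(ids):
            geno = "\t".join(code[int(c)] for c in gm.calls[i])
            fh.write(f"FAM\t{iid}\t0\t0\t0\t-9\t{geno}\n")


def write_biom_json(counts: pd.DataFrame, path) -> None:
    """Write a taxa x samples count table as minimal BIOM v1.0 JSON."""
    obj = {
        "id": None,
        "format": "Biological Observation Matrix 1.0.0",
        "format_url": "http://biom-format.org",
        "type": "OTU table",
        "generated_by": "ailgxe",
        "date": "",
        "matrix_type": "dense",
        "matrix_element_type": "int",
        "shape": [counts.shape[0], counts.shape[1]],
        "rows": [{"id": str(t), "metadata": None} for t in counts.index],
        "columns": [{"id": str(s), "metadata": None} for s in counts.columns],
        "data": counts.to_numpy().astype(int).tolist(),
    }
    with open(path, "w") as fh:
        json.dump(obj, fh)
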