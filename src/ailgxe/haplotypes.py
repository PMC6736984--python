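"""Founder-haplotype reconstruction for multiparental crosses.

Genotype QC, a hidden Markov model that converts biallelic marker calls into
posterior probabilities over founder diplotypes, collapse of those posteriors
to per-founder dosages, and a kinship matrix computed from the dosages.

The HMM runs one chain per chromosome with one hidden state per marker.  The
hidden state is the ordered pair of founder origins of the two haplotypes
(``n_founders**2`` states internally); posteriors are reported over the
unordered diplotypes (10 states for 4 founders).  Transitions model the
accumulated recombination of an advanced intercross: each haplotype switches
founder independently between adjacent markers with probability
``1 - exp(-G_eff * d / 100)`` for map distance ``d`` cM, landing uniformly on
any founder.  Emissions compare the observed allele count with the founder
alleles of the diplotype, allowing a per-read genotyping error ``eps``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "GenotypeMatrix",
    "DiplotypePosterior",
    "KinshipMatrix",
    "qc_filter",
    "reconstruct",
    "kinship",
]

MISSING = -1


@dataclass
class GenotypeMatrix:
    """Biallelic genotype calls for a mapping population.

    Parameters
    ----------
    calls
        ``(n_individuals, n_markers)`` integer array over ``{0, 1, 2}`` with
        ``-1`` flagging missing calls.  Values count copies of the "1" allele.
    markers
        Per-marker metadata with columns ``chrom``, ``bp``, ``cM``, sorted by
        chromosome then genetic position.
    founder_alleles
        ``(n_founders, n_markers)`` binary matrix of founder alleles.
    strains
        Founder strain names, in the row order of ``founder_alleles``.
    """

    calls: np.ndarray
    markers: pd.DataFrame
    founder_alleles: np.ndarray
    strains: list[str]

    def __post_init__(self) -> None:
        self.calls = np.asarray(self.calls)
        self.founder_alleles = np.asarray(self.founder_alleles)
        if self.calls.ndim != 2:
            raise ValueError("calls must be a 2-D individuals x markers array")
        if len(self.markers) != self.calls.shape[1]:
            raise ValueError(
                f"marker metadata ({len(self.markers)} rows) does not match "
                f"calls ({self.calls.shape[1]} columns)"
            )
        if self.founder_alleles.shape[1] != self.calls.shape[1]:
            raise ValueError("founder_alleles columns must match calls columns")
        for col in ("chrom", "bp", "cM"):
            if col not in self.markers.columns:
                raise ValueError(f"markers missing required column {col!r}")

    @property
    def n_individuals(self) -> int:
        return self.calls.shape[0]

    @property
    def n_markers(self) -> int:
        return self.calls.shape[1]

    @property
    def n_founders(self) -> int:
        return self.founder_alleles.shape[0]

    def chromosomes(self) -> list:
        """Chromosome identifiers in order of first appearance."""
        return list(dict.fromkeys(self.markers["chrom"]))


@dataclass
class DiplotypePosterior:
    """Posterior founder-diplotype probabilities and founder dosages.

    ``posteriors`` is ``(n, n_loci, n_states)`` over unordered founder pairs
    listed in ``state_pairs``; ``dosages`` is ``(n, n_loci, n_founders)`` with
    each row summing to 2 (expected haplotype copies per founder).
    """

    posteriors: np.ndarray
    dosages: np.ndarray
    state_pairs: list[tuple[int, int]]
    markers: pd.DataFrame
    strains: list[str]
    loglik: np.ndarray = field(default=None)  # per-individual log P(data)

    def __post_init__(self) -> None:
        p, d = self.posteriors, self.dosages
        if not np.allclose(p.sum(axis=2), 1.0, atol=1e-9):
            raise ValueError("state posteriors must sum to 1 per locus")
        if not np.allclose(d.sum(axis=2), 2.0, atol=1e-9):
            raise ValueError("founder dosages must sum to 2 per locus")
        if p.min() < -1e-12 or p.max() > 1 + 1e-12:
            raise ValueError("posteriors outside [0, 1]")

    @property
    def n_individuals(self) -> int:
        return self.posteriors.shape[0]

    @property
    def n_loci(self) -> int:
        return self.posteriors.shape[1]

    @property
    def n_founders(self) -> int:
        return self.dosages.shape[2]

    def argmax_states(self) -> np.ndarray:
        """Per-locus maximum a posteriori unordered diplotype index."""
        return self.posteriors.argmax(axis=2)


@dataclass
class KinshipMatrix:
    """Genetic similarity from founder dosages; mean diagonal scaled to 1."""

    values: np.ndarray
    scale: float

    def __post_init__(self) -> None:
        K = self.values
        if not np.allclose(K, K.T, atol=1e-10):
            raise ValueError("kinship must be symmetric")
        w = np.linalg.eigvalsh((K + K.T) / 2)
        if w.min() < -1e-8:
            raise ValueError(f"kinship not PSD (min eigenvalue {w.min():.3g})")

    @property
    def n(self) -> int:
        return self.values.shape[0]


def qc_filter(
    g: GenotypeMatrix,
    maf_min: float = 0.05,
    missing_max: float = 0.1,
    drop_common_homozygous: bool = True,
) -> tuple[GenotypeMatrix, dict]:
    """Filter markers on minor allele frequency, missingness and founder
    informativeness.

    Markers are kept when minor allele frequency > ``maf_min``, missing-call
    fraction < ``missing_max`` and (when ``drop_common_homozygous``) the
    founders are not all identical at the marker.  Returns the filtered matrix
    and a report dict with counts removed per rule (a marker failing several
    rules is attributed to the first in the order maf, missingness,
    founder-common).
    """
    calls = g.calls
    obs = calls != MISSING
    n_obs = obs.sum(axis=0)
    with np.errstate(invalid="ignore"):
        p = np.where(n_obs > 0, np.where(obs, calls, 0).sum(axis=0) / (2 * np.maximum(n_obs, 1)), 0.0)
    maf = np.minimum(p, 1 - p)
    miss_frac = 1 - n_obs / calls.shape[0]

    fail_maf = maf <= maf_min
    fail_miss = miss_frac >= missing_max
    if drop_common_homozygous:
        fail_common = (g.founder_alleles == g.founder_alleles[0]).all(axis=0)
    else:
        fail_common = np.zeros(g.n_markers, dtype=bool)

    removed_maf = fail_maf
    removed_miss = fail_miss & ~removed_maf
    removed_common = fail_common & ~removed_maf & ~removed_miss
    keep = ~(fail_maf | fail_miss | fail_common)

    report = {
        "n_in": g.n_markers,
        "removed_maf": int(removed_maf.sum()),
        "removed_missing": int(removed_miss.sum()),
        "removed_founder_common": int(removed_common.sum()),
        "n_out": int(keep.sum()),
    }
    if report["n_out"] == 0:
        dominant = max(
            ("maf", report["removed_maf"]),
            ("missingness", report["removed_missing"]),
            ("founder-common", report["removed_founder_common"]),
            key=lambda kv: kv[1],
        )[0]
        raise ValueError(
            f"all {g.n_markers} markers removed by QC; dominating filter: {dominant}"
        )
    out = GenotypeMatrix(
        calls=calls[:, keep],
        markers=g.markers.loc[keep],  # original index kept for traceability
        founder_alleles=g.founder_alleles[:, keep],
        strains=list(g.strains),
    )
    return out, report


def _unordered_states(n_founders: int) -> list[tuple[int, int]]:
    return [(i, j) for i in range(n_founders) for j in range(i, n_founders)]


def _emission_table(founder_alleles: np.ndarray, eps: float) -> np.ndarray:
    """P(observed call | ordered diplotype) per marker.

    Returns ``(n_markers, F*F, 3)``: probability of observing 0/1/2 copies of
    the "1" allele given the two haplotype founders, with each of the two
    allele reads flipped independently with probability ``eps``.
    """
    F, M = founder_alleles.shape
    a = founder_alleles.astype(float)
    # P(read = 1 | true allele)
    p1 = a * (1 - eps) + (1 - a) * eps  # (F, M)
    pa = p1[:, None, :]  # haplotype 1, (F,1,M)
    pb = p1[None, :, :]  # haplotype 2, (1,F,M)
    e0 = (1 - pa) * (1 - pb)
    e1 = pa * (1 - pb) + (1 - pa) * pb
    e2 = pa * pb
    em = np.stack([e0, e1, e2], axis=-1)  # (F, F, M, 3)
    return em.reshape(F * F, M, 3).transpose(1, 0, 2)


def _transition(d_cm: float, g_eff: float, n_founders: int) -> np.ndarray:
    """Per-haplotype founder transition matrix across a map distance."""
    if not np.isfinite(d_cm) or d_cm < 0:
        raise ValueError(f"non-finite or negative map distance {d_cm!r}")
    s = 1.0 - np.exp(-g_eff * d_cm / 100.0)
    F = n_founders
    T = np.full((F, F), s / F)
    np.fill_diagonal(T, 1 - s + s / F)
    return T


def reconstruct(
    g: GenotypeMatrix,
    generations: int,
    eps: float = 0.002,
    g_eff: float | None = None,
) -> DiplotypePosterior:
    """Forward-backward posteriors over founder diplotypes at every marker.

    Parameters
    ----------
    g
        QC-passed, map-sorted genotype matrix carrying the founder alleles.
    generations
        Number of intercross generations; sets the default effective
        recombination rate of the transition model.
    eps
        Per-read genotyping error used by the emission model.
    g_eff
        Effective generation count for the switch probability
        ``1 - exp(-g_eff * d/100)``; defaults to ``generations``.
    """
    if generations < 1:
        raise ValueError("generations must be >= 1")
    if g.n_markers == 0:
        raise ValueError("genotype matrix has zero markers")
    if not (0 <= eps < 0.5):
        raise ValueError("eps must be in [0, 0.5)")
    g_eff = float(generations if g_eff is None else g_eff)

    F = g.n_founders
    n = g.n_individuals
    n_states = F * F
    pairs = _unordered_states(F)

    em_all = _emission_table(g.founder_alleles, eps)  # (M, F*F, 3)
    # index emissions by observed call; missing -> likelihood 1
    calls = g.calls

    gamma_ord = np.empty((n, g.n_markers, n_states))
    loglik = np.zeros(n)

    chrom_col = g.markers["chrom"].to_numpy()
    cm = g.markers["cM"].to_numpy(dtype=float)
    prior = np.full(n_states, 1.0 / n_states)
    floor = 1e-300

    for chrom in dict.fromkeys(chrom_col):
        idx = np.flatnonzero(chrom_col == chrom)
        if np.any(np.diff(cm[idx]) < 0):
            raise ValueError(f"marker map not sorted on chromosome {chrom!r}")
        L = len(idx)
        # per-individual per-marker emission vectors (n, L, S)
        E = np.empty((n, L, n_states))
        for k, m in enumerate(idx):
            obs = calls[:, m]
            Em = np.ones((n, n_states))
            ok = obs != MISSING
            Em[ok] = em_all[m, :, obs[ok]]
            E[:, k] = np.maximum(Em, floor)

        # transition matrices between adjacent markers (ordered-pair chain)
        Ts = []
        for k in range(L - 1):
            Th = _transition(cm[idx[k + 1]] - cm[idx[k]], g_eff, F)
            Ts.append(np.kron(Th, Th))

        alpha = np.empty((n, L, n_states))
        scales = np.empty((n, L))
        a = prior * E[:, 0]
        s = a.sum(axis=1)
        s = np.maximum(s, floor)
        alpha[:, 0] = a / s[:, None]
        scales[:, 0] = s
        for k in range(1, L):
            a = (alpha[:, k - 1] @ Ts[k - 1]) * E[:, k]
            s = np.maximum(a.sum(axis=1), floor)
            alpha[:, k] = a / s[:, None]
            scales[:, k] = s

        beta = np.empty((n, L, n_states))
        beta[:, L - 1] = 1.0
        for k in range(L - 2, -1, -1):
            b = (beta[:, k + 1] * E[:, k + 1]) @ Ts[k].T
            beta[:, k] = b / np.maximum(b.max(axis=1), floor)[:, None]

        gam = alpha * beta
        gam /= np.maximum(gam.sum(axis=2, keepdims=True), floor)
        gamma_ord[:, idx] = gam
        loglik += np.log(scales).sum(axis=1)

    # collapse ordered (f1, f2) states to unordered pairs and to dosages
    post = np.zeros((n, g.n_markers, len(pairs)))
    dos = np.zeros((n, g.n_markers, F))
    for s_idx, (i, j) in enumerate(
        (i, j) for i in range(F) for j in range(F)
    ):
        u = pairs.index((min(i, j), max(i, j)))
        post[:, :, u] += gamma_ord[:, :, s_idx]
        dos[:, :, i] += gamma_ord[:, :, s_idx]
        dos[:, :, j] += gamma_ord[:, :, s_idx]

    post /= post.sum(axis=2, keepdims=True)
    dos *= 2.0 / dos.sum(axis=2, keepdims=True)

    return DiplotypePosterior(
        posteriors=post,
        dosages=dos,
        state_pairs=pairs,
        markers=g.markers.reset_index(drop=True),
        strains=list(g.strains),
        loglik=loglik,
    )


def kinship(d: DiplotypePosterior) -> KinshipMatrix:
    """Kinship from founder dosages.

    ``K_ij = (1/2L) sum_l sum_f dosage_il_f * dosage_jl_f`` scaled so the mean
    diagonal equals 1.  The result is symmetric and positive semi-definite by
    construction (a Gram matrix).
    """
    if d.n_loci == 0 or d.n_individuals == 0:
        raise ValueError("empty dosage tensor")
    X = d.dosages.reshape(d.n_individuals, -1)
    K = (X @ X.T) / (2.0 * d.n_loci)
    scale = float(np.mean(np.diag(K)))
    K = K / scale
    K = (K + K.T) / 2
    return KinshipMatrix(values=K, scale=scale)
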