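"""Genome scans on founder dosages with permutation significance.

At every locus the residualized trait r is regressed on the four founder
dosages (three estimable contrasts, since dosages sum to 2) and the evidence
is expressed as a LOD score

    LOD = (n/2) * log10(RSS_0 / RSS_1)

comparing nested gaussian models.  Three models are supported: additive
(r ~ dosages vs r ~ 1), G x Diet and G x Sex (r ~ dosages + factor +
 dosages:factor vs r ~ dosages + factor).  Significance thresholds are the
95th percentiles of permutation max-LOD distributions: genome-wide over the
whole scan and chromosome-wide per chromosome, from the same permutations.
Permutations shuffle the assignment of genotype rows against (r, factor)
pairs, so the r-factor relationship is preserved and only genotype and
genotype-by-factor terms are tested.

QTL are called one per chromosome at the LOD argmax (leftmost tie wins),
tiered genome-wide vs chromosome-wide (suggestive), with 1.5-LOD-drop
support intervals, founder allele effects under sum-to-zero contrasts, and
variance explained 1 - 10^(-2 LOD / n).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .haplotypes import DiplotypePosterior

__all__ = [
    "ScanResult",
    "QtlCall",
    "scan_additive",
    "scan_interaction",
    "permutation_thresholds",
    "call_qtl",
    "founder_effects",
    "lod_from_r2",
]

MODELS = ("additive", "gxdiet", "gxsex")


@dataclass
class ScanResult:
    """Per-locus LOD curve for one model, with optional thresholds."""

    table: pd.DataFrame  # chrom, bp, cM, lod
    model: str
    df_test: int
    n: int
    alpha_gw: float | None = None
    alpha_cw: dict = field(default_factory=dict)
    seed: int | None = None

    def __post_init__(self) -> None:
        if (self.table["lod"] < -1e-9).any():
            raise ValueError("negative LOD: models are nested, LOD must be >= 0")
        self.table["lod"] = self.table["lod"].clip(lower=0.0)

    @property
    def max_lod(self) -> float:
        return float(self.table["lod"].max())


@dataclass
class QtlCall:
    """One called QTL with its support interval and founder effects."""

    trait: str
    model: str
    chrom: object
    peak_bp: int
    peak_cm: float
    peak_lod: float
    tier: str  # "genome-wide" | "chromosome-wide"
    support_bp: tuple[int, int]
    support_cm: tuple[float, float]
    founder_coef: np.ndarray
    founder_se: np.ndarray
    high_group: tuple[int, ...]
    low_group: tuple[int, ...]
    gap: float
    variance_explained: float

    def __post_init__(self) -> None:
        lo, hi = self.support_bp
        if not (lo <= self.peak_bp <= hi):
            raise ValueError("support interval must contain the peak")


def lod_from_r2(r2: float, n: int) -> float:
    """LOD of a model explaining fraction ``r2`` of variance at sample size n."""
    return (n / 2.0) * np.log10(1.0 / (1.0 - r2))


def _contrast_dosages(d: DiplotypePosterior) -> np.ndarray:
    """(n, L, F-1) dosage contrasts; with an intercept they span the
    founder-dosage column space (dosages sum to 2)."""
    return d.dosages[:, :, :-1]


def _batched_rss(X: np.ndarray, r: np.ndarray) -> np.ndarray:
    """RSS of r on each design in a (L, n, p) stack, via gram matrices.

    Rank-deficient designs fall back to pseudo-inverse.
    """
    G = np.einsum("lnp,lnq->lpq", X, X, optimize=True)
    b = np.einsum("lnp,n->lp", X, r, optimize=True)
    rr = float(r @ r)
    L, _, p = X.shape
    G = G + 1e-12 * np.eye(p)[None]
    try:
        coef = np.linalg.solve(G, b[..., None])[..., 0]
        rss = rr - np.einsum("lp,lp->l", b, coef)
    except np.linalg.LinAlgError:
        rss = np.empty(L)
        for l in range(L):
            coef = np.linalg.pinv(G[l]) @ b[l]
            rss[l] = rr - b[l] @ coef
    return np.maximum(rss, 1e-12 * max(rr, 1.0))


def _factor_dummies(factor: np.ndarray) -> tuple[np.ndarray, list]:
    levels = list(pd.unique(factor))
    if len(levels) < 2:
        raise ValueError(f"factor must have >= 2 observed levels, got {levels!r}")
    dummies = np.column_stack([(factor == lev).astype(float) for lev in levels[1:]])
    return dummies, levels


def _additive_designs(C: np.ndarray) -> np.ndarray:
    n, L, p = C.shape
    ones = np.ones((L, n, 1))
    return np.concatenate([ones, C.transpose(1, 0, 2)], axis=2)  # (L, n, 1+p)


def _interaction_designs(C: np.ndarray, dummies: np.ndarray):
    n, L, p = C.shape
    k1 = dummies.shape[1]
    Ct = C.transpose(1, 0, 2)  # (L, n, p)
    ones = np.ones((L, n, 1))
    dum = np.broadcast_to(dummies, (L, n, k1))
    base = np.concatenate([ones, Ct, dum], axis=2)
    inter = (Ct[:, :, :, None] * dummies[None, :, None, :]).reshape(L, n, p * k1)
    full = np.concatenate([base, inter], axis=2)
    return base, full


def _lod_additive(r: np.ndarray, C: np.ndarray) -> np.ndarray:
    n = len(r)
    rss0 = float(np.sum((r - r.mean()) ** 2))
    if rss0 < 1e-12:  # constant trait: no variance to explain
        return np.zeros(C.shape[1])
    rss1 = _batched_rss(_additive_designs(C), r)
    return (n / 2.0) * np.log10(rss0 / np.minimum(rss1, rss0))


def _lod_interaction(r: np.ndarray, C: np.ndarray, dummies: np.ndarray) -> np.ndarray:
    n = len(r)
    if np.ptp(r) < 1e-12:
        return np.zeros(C.shape[1])
    base, full = _interaction_designs(C, dummies)
    rss_base = _batched_rss(base, r)
    rss_full = _batched_rss(full, r)
    return (n / 2.0) * np.log10(rss_base / np.minimum(rss_full, rss_base))


def _as_r_array(r) -> np.ndarray:
    arr = r.r if hasattr(r, "r") else np.asarray(r, dtype=float)
    return np.asarray(arr, dtype=float)


def _result_table(d: DiplotypePosterior, lod: np.ndarray) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "chrom": d.markers["chrom"].to_numpy(),
            "bp": d.markers["bp"].to_numpy(),
            "cM": d.markers["cM"].to_numpy(),
            "lod": lod,
        }
    )


def scan_additive(r, d: DiplotypePosterior) -> ScanResult:
    """Additive genome scan: r ~ founder dosages vs intercept-only."""
    rv = _as_r_array(r)
    if len(rv) != d.n_individuals:
        raise ValueError("residuals and dosages are not row-aligned")
    C = _contrast_dosages(d)
    lod = _lod_additive(rv, C)
    return ScanResult(table=_result_table(d, lod), model="additive",
                      df_test=d.n_founders - 1, n=len(rv))


def scan_interaction(
    r, d: DiplotypePosterior, factor: np.ndarray, min_level_size: int = 10,
    model_name: str | None = None,
) -> ScanResult:
    """Interaction scan: (dosages + factor + dosages:factor) vs
    (dosages + factor)."""
    rv = _as_r_array(r)
    factor = np.asarray(factor)
    if len(rv) != d.n_individuals or len(factor) != d.n_individuals:
        raise ValueError("residuals, factor and dosages are not row-aligned")
    dummies, levels = _factor_dummies(factor)
    counts = {lev: int((factor == lev).sum()) for lev in levels}
    small = [lev for lev, c in counts.items() if c < min_level_size]
    if small:
        raise ValueError(f"factor level(s) below size floor {min_level_size}: {small}")
    C = _contrast_dosages(d)
    lod = _lod_interaction(rv, C, dummies)
    k = len(levels)
    return ScanResult(table=_result_table(d, lod),
                      model=model_name or f"gx{k}-level-factor",
                      df_test=(d.n_founders - 1) * (k - 1), n=len(rv))


def permutation_thresholds(
    r,
    d: DiplotypePosterior,
    model: str = "additive",
    factor: np.ndarray | None = None,
    n_perm: int = 1000,
    level: float = 0.05,
    seed: int = 0,
) -> tuple[float, dict]:
    """Permutation 5% thresholds: genome-wide and per-chromosome maxima.

    Each permutation re-pairs genotype rows with (r, factor) rows — r stays
    paired with its factor — and rescans; thresholds are the (1 - level)
    quantiles (linear/type-7 interpolation) of the max-LOD distributions.
    """
    if n_perm < 100:
        raise ValueError("n_perm < 100 gives unstable thresholds; refuse")
    rv = _as_r_array(r)
    C = _contrast_dosages(d)
    rng = np.random.default_rng(seed)
    chrom = d.markers["chrom"].to_numpy()
    chroms = list(dict.fromkeys(chrom))
    chrom_idx = {c: np.flatnonzero(chrom == c) for c in chroms}

    if model == "additive":
        dummies = None
    else:
        if factor is None:
            raise ValueError(f"model {model!r} requires a factor")
        dummies, _ = _factor_dummies(np.asarray(factor))

    gmax = np.empty(n_perm)
    cmax = {c: np.empty(n_perm) for c in chroms}
    for b in range(n_perm):
        perm = rng.permutation(len(rv))
        rp = rv[perm]
        if dummies is None:
            lod = _lod_additive(rp, C)
        else:
            lod = _lod_interaction(rp, C, dummies[perm])
        gmax[b] = lod.max()
        for c in chroms:
            cmax[c][b] = lod[chrom_idx[c]].max()

    q = 1.0 - level
    alpha_gw = float(np.quantile(gmax, q, method="linear"))
    alpha_cw = {c: float(np.quantile(v, q, method="linear")) for c, v in cmax.items()}
    return alpha_gw, alpha_cw


def founder_effects(
    d: DiplotypePosterior, r, locus: int
) -> tuple[np.ndarray, np.ndarray, tuple, tuple, float]:
    """Founder allele effects at one locus under sum-to-zero contrasts.

    Returns (coefficients, SEs, high_group, low_group, gap); the bipartition
    is the exact 1-D 2-means split of the coefficients (all contiguous splits
    of the sorted values scored by within-group sum of squares) and ``gap``
    is the separation between the groups at the split boundary.
    """
    rv = _as_r_array(r)
    if not (0 <= locus < d.n_loci):
        raise ValueError(f"locus {locus} outside scanned range")
    D = d.dosages[:, locus, :]
    F = D.shape[1]
    # orthonormal basis of the sum-to-zero subspace
    Cmat = np.linalg.svd(np.eye(F) - np.ones((F, F)) / F)[0][:, : F - 1]
    X = np.column_stack([np.ones(len(rv)), D @ Cmat])
    coef, *_ = np.linalg.lstsq(X, rv, rcond=None)
    resid = rv - X @ coef
    dof = max(len(rv) - X.shape[1], 1)
    sigma2 = float(resid @ resid) / dof
    XtX_inv = np.linalg.pinv(X.T @ X)
    cov_theta = sigma2 * XtX_inv[1:, 1:]
    alpha = Cmat @ coef[1:]
    se = np.sqrt(np.clip(np.diag(Cmat @ cov_theta @ Cmat.T), 0, None))

    order = np.argsort(alpha)
    best = None
    for split in range(1, F):
        lo, hi = order[:split], order[split:]
        ss = np.sum((alpha[lo] - alpha[lo].mean()) ** 2) + np.sum(
            (alpha[hi] - alpha[hi].mean()) ** 2
        )
        if best is None or ss < best[0]:
            best = (ss, lo, hi)
    _, lo, hi = best
    gap = float(alpha[hi].min() - alpha[lo].max())
    return alpha, se, tuple(sorted(int(i) for i in hi)), tuple(sorted(int(i) for i in lo)), gap


def call_qtl(
    s: ScanResult,
    alpha_gw: float,
    alpha_cw: dict,
    d: DiplotypePosterior | None = None,
    r=None,
    trait: str = "trait",
    drop: float = 1.5,
) -> list[QtlCall]:
    """Call at most one QTL per chromosome with 1.5-LOD support intervals.

    A chromosome yields a genome-wide call when its peak reaches ``alpha_gw``,
    else a chromosome-wide (suggestive) call when it reaches its
    ``alpha_cw``; genome-wide calls are never duplicated in the suggestive
    tier.  The support interval is the maximal contiguous run of loci around
    the peak with LOD >= peak - drop, extended to the flanking locus
    boundaries.  Founder effects are computed at the peak when dosages and
    residuals are supplied.
    """
    if len(s.table) == 0:
        raise ValueError("empty scan result")
    calls: list[QtlCall] = []
    tbl = s.table
    for chrom, sub in tbl.groupby("chrom", sort=False):
        lod = sub["lod"].to_numpy()
        peak_i = int(np.argmax(lod))  # argmax -> leftmost tie
        peak_lod = float(lod[peak_i])
        if peak_lod >= alpha_gw:
            tier = "genome-wide"
        elif peak_lod >= alpha_cw.get(chrom, np.inf):
            tier = "chromosome-wide"
        else:
            continue
        thr = peak_lod - drop
        lo = peak_i
        while lo > 0 and lod[lo - 1] >= thr:
            lo -= 1
        hi = peak_i
        while hi < len(lod) - 1 and lod[hi + 1] >= thr:
            hi += 1
        # extend to flanking locus boundaries
        lo_b = max(lo - 1, 0)
        hi_b = min(hi + 1, len(lod) - 1)
        bp = sub["bp"].to_numpy()
        cm = sub["cM"].to_numpy()
        if d is not None and r is not None:
            locus = int(sub.index[peak_i])
            coef, se, high, low, gap = founder_effects(d, r, locus)
        else:
            F = 4
            coef = se = np.full(F, np.nan)
            high = low = ()
            gap = np.nan
        calls.append(
            QtlCall(
                trait=trait,
                model=s.model,
                chrom=chrom,
                peak_bp=int(bp[peak_i]),
                peak_cm=float(cm[peak_i]),
                peak_lod=peak_lod,
                tier=tier,
                support_bp=(int(bp[lo_b]), int(bp[hi_b])),
                support_cm=(float(cm[lo_b]), float(cm[hi_b])),
                founder_coef=coef,
                founder_se=se,
                high_group=high,
                low_group=low,
                gap=gap,
                variance_explained=float(1 - 10 ** (-2 * peak_lod / s.n)),
            )
        )
    return calls


def calls_to_bed(calls: list[QtlCall]) -> pd.DataFrame:
    """QTL calls as BED (0-based half-open support intervals)."""
    return pd.DataFrame(
        {
            "chrom": [c.chrom for c in calls],
            "start": [c.support_bp[0] - 1 for c in calls],
            "end": [c.support_bp[1] for c in calls],
            "name": [f"{c.trait}:{c.model}" for c in calls],
            "score": [round(c.peak_lod, 3) for c in calls],
        }
    )
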