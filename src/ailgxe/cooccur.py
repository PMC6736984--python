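"""Co-occurrence community detection for compositional OTU tables.

Implements the functional-community (FMC/FFC) pipeline: prevalence
filtering, SparCC basis correlations (compositionality-aware, via log-ratio
variances with iterative exclusion of strongly correlated pairs), the power
adjacency a_ij = (0.5 + 0.5 rho_ij)^beta with beta = 4, unsigned topological
overlap, module detection by average-linkage clustering of 1 - TOM with a
minimum module size, eigenOTU summaries (first principal component per
module), module-trait association (Spearman plus Wilcoxon/Kruskal-Wallis
with Benjamini-Hochberg adjustment across modules), and cross-domain
(bacteria-fungi) SparCC correlation between two modules' member taxa.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from statsmodels.stats.multitest import multipletests

__all__ = [
    "ModuleSet",
    "prevalence_filter",
    "rarefy",
    "sparcc",
    "adjacency",
    "topological_overlap",
    "detect_modules",
    "eigenotus",
    "module_trait_association",
    "cross_domain_correlation",
    "detect_communities",
]

UNASSIGNED = "unassigned"


@dataclass
class ModuleSet:
    """Full output of community detection on one OTU table."""

    rho: pd.DataFrame
    pvalues: pd.DataFrame
    adjacency: pd.DataFrame
    tom: pd.DataFrame
    labels: pd.Series  # taxon -> module name or "unassigned"
    eigenotus: pd.DataFrame  # modules x samples
    min_size: int
    associations: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        _check_corr(self.rho.to_numpy())
        a = self.adjacency.to_numpy()
        if a.min() < -1e-12 or a.max() > 1 + 1e-12:
            raise ValueError("adjacency entries must lie in [0, 1]")
        sizes = self.labels[self.labels != UNASSIGNED].value_counts()
        if (sizes < self.min_size).any():
            raise ValueError("assigned module below minimum size")
        if len(self.eigenotus):
            v = self.eigenotus.var(axis=1, ddof=1)
            if not np.allclose(v, 1.0, atol=1e-6):
                raise ValueError("eigenOTUs must have unit variance")

    def members(self, module: str) -> list[str]:
        return list(self.labels.index[self.labels == module])


def _check_corr(rho: np.ndarray) -> None:
    if not np.allclose(rho, rho.T, atol=1e-10):
        raise ValueError("correlation matrix must be symmetric")
    if not np.allclose(np.diag(rho), 1.0, atol=1e-9):
        raise ValueError("correlation matrix must have unit diagonal")
    if rho.min() < -1 - 1e-9 or rho.max() > 1 + 1e-9:
        raise ValueError("correlations outside [-1, 1]")


def prevalence_filter(
    counts: pd.DataFrame, min_reads: int = 10, min_samples: int = 25
) -> tuple[pd.DataFrame, dict]:
    """Keep taxa with >= min_reads in >= min_samples samples.

    Singletons (total count 1 across all samples) are removed first.  Both
    thresholds are inclusive.  Returns (filtered table, report).
    """
    n_in = len(counts)
    singleton = counts.sum(axis=1) == 1
    kept = counts.loc[~singleton]
    prevalent = (kept >= min_reads).sum(axis=1) >= min_samples
    out = kept.loc[prevalent]
    report = {
        "n_in": n_in,
        "removed_singletons": int(singleton.sum()),
        "removed_prevalence": int((~prevalent).sum()),
        "n_out": len(out),
    }
    return out, report


def rarefy(counts: pd.DataFrame, depth: int, seed: int) -> pd.DataFrame:
    """Subsample each sample to ``depth`` reads without replacement.

    Samples with fewer than ``depth`` reads are dropped, never up-sampled.
    Deterministic given the seed.
    """
    rng = np.random.default_rng(seed)
    keep = counts.columns[counts.sum(axis=0) >= depth]
    out = {}
    for s in keep:
        col = counts[s].to_numpy()
        picked = rng.choice(np.repeat(np.arange(len(col)), col), size=depth, replace=False)
        out[s] = np.bincount(picked, minlength=len(col))
    return pd.DataFrame(out, index=counts.index)


def _basis_corr_once(frac: np.ndarray, exclusion_threshold: float, exclusion_rounds: int):
    """One SparCC basis-correlation estimate from fractions (taxa x samples)."""
    D = frac.shape[0]
    logf = np.log(frac)
    cov = np.cov(logf)
    v = np.diag(cov)
    # variation matrix t_ij = var(log x_i - log x_j)
    Tm = v[:, None] + v[None, :] - 2 * cov
    incl = np.ones((D, D), dtype=bool)
    np.fill_diagonal(incl, False)

    def solve_basis():
        deg = incl.sum(axis=1).astype(float)
        A = incl.astype(float)
        A[np.arange(D), np.arange(D)] = deg
        t_sum = (Tm * incl).sum(axis=1)
        omega = np.linalg.solve(A, t_sum)
        omega = np.clip(omega, 1e-12, None)
        denom = 2 * np.sqrt(omega[:, None] * omega[None, :])
        rho = (omega[:, None] + omega[None, :] - Tm) / denom
        np.fill_diagonal(rho, 1.0)
        return np.clip(rho, -1.0, 1.0)

    rho = solve_basis()
    for _ in range(exclusion_rounds):
        masked = np.where(incl, np.abs(rho), 0.0)
        i, j = np.unravel_index(np.argmax(masked), masked.shape)
        if masked[i, j] <= exclusion_threshold:
            break
        incl[i, j] = incl[j, i] = False
        if incl.sum(axis=1).min() < 1:  # keep system solvable
            incl[i, j] = incl[j, i] = True
            break
        rho = solve_basis()
    return rho


def _sparcc_point(
    counts: np.ndarray,
    rng: np.random.Generator,
    n_iterations: int,
    exclusion_threshold: float,
    exclusion_rounds: int,
) -> np.ndarray:
    """Median basis correlation over Dirichlet-resampled fractions."""
    alpha = counts + 0.5  # pseudocount prior; covers zero counts
    estimates = []
    for _ in range(n_iterations):
        frac = rng.standard_gamma(alpha.T).T  # Dirichlet via gamma draws
        frac /= frac.sum(axis=0, keepdims=True)
        estimates.append(
            _basis_corr_once(frac, exclusion_threshold, exclusion_rounds)
        )
    rho = np.median(estimates, axis=0)
    rho = (rho + rho.T) / 2
    np.fill_diagonal(rho, 1.0)
    return np.clip(rho, -1.0, 1.0)


def sparcc(
    counts: pd.DataFrame,
    n_iterations: int = 20,
    exclusion_threshold: float = 0.1,
    exclusion_rounds: int = 10,
    n_bootstraps: int = 100,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """SparCC basis correlations with permutation p-values.

    Fractions are resampled from a Dirichlet posterior (counts + 0.5) per
    estimation iteration and the median basis correlation is reported.  The
    null distribution for p-values permutes each taxon's counts across
    samples independently, breaking all inter-taxon structure while keeping
    marginals; two-sided p-values are smoothed by +1 and BH-adjustment is
    left to the caller (module_trait_association adjusts its own tests).
    """
    if len(counts) < 4:
        raise ValueError("SparCC needs >= 4 taxa; aggregate or skip this table")
    if counts.shape[1] < 10:
        raise ValueError("SparCC needs >= 10 samples for stable estimates")
    rng = np.random.default_rng(seed)
    X = counts.to_numpy(dtype=float)
    rho = _sparcc_point(X, rng, n_iterations, exclusion_threshold, exclusion_rounds)
    idx = counts.index
    if n_bootstraps == 0:  # point estimate only
        return (
            pd.DataFrame(rho, index=idx, columns=idx),
            pd.DataFrame(np.ones_like(rho), index=idx, columns=idx),
        )

    exceed = np.zeros_like(rho)
    n_samp = X.shape[1]
    for _ in range(n_bootstraps):
        Xp = np.stack([row[rng.permutation(n_samp)] for row in X])
        rho_null = _sparcc_point(
            Xp, rng, max(n_iterations // 4, 1), exclusion_threshold, exclusion_rounds
        )
        exceed += np.abs(rho_null) >= np.abs(rho)
    pvals = (exceed + 1) / (n_bootstraps + 1)
    np.fill_diagonal(pvals, 0.0)

    return (
        pd.DataFrame(rho, index=idx, columns=idx),
        pd.DataFrame(pvals, index=idx, columns=idx),
    )


def adjacency(rho: pd.DataFrame, beta: float = 4.0) -> pd.DataFrame:
    """Weighted network adjacency a_ij = (0.5 + 0.5 rho_ij)^beta."""
    _check_corr(rho.to_numpy())
    return (0.5 + 0.5 * rho) ** beta


def topological_overlap(a: pd.DataFrame) -> pd.DataFrame:
    """Unsigned TOM: T_ij = (sum_u a_iu a_uj + a_ij) / (min(k_i,k_j)+1-a_ij)."""
    A = a.to_numpy(dtype=float).copy()
    np.fill_diagonal(A, 0.0)
    k = A.sum(axis=1)
    num = A @ A + A
    den = np.minimum(k[:, None], k[None, :]) + 1.0 - A
    T = num / den
    np.fill_diagonal(T, 1.0)
    T = np.clip((T + T.T) / 2, 0.0, 1.0)
    return pd.DataFrame(T, index=a.index, columns=a.columns)


def detect_modules(
    a: pd.DataFrame, min_size: int = 10, cut_fraction: float = 0.995,
    cohesion: float = 0.8, prefix: str = "FMC",
) -> pd.Series:
    """Module labels from average-linkage clustering of 1 - TOM.

    The top of the dendrogram (above ``cut_fraction`` of the maximum merge
    height) is discarded, and modules are the branches completing below
    ``cohesion`` times that cut: tight co-occurring groups merge low, while
    unconnected taxa chain together only near the top, so the two-level rule
    separates genuine branches from loose agglomerations.  Branches need
    ``min_size`` members and a mean within-branch distance below the branch
    height; everything else is "unassigned".  Modules are named FMC1,
    FMC2, ... (or FFC1, ... for fungal tables via ``prefix``) in decreasing
    size order.
    """
    T = topological_overlap(a)
    dist = 1.0 - T.to_numpy()
    np.fill_diagonal(dist, 0.0)
    dist = np.clip((dist + dist.T) / 2, 0.0, None)
    Z = linkage(squareform(dist, checks=False), method="average")
    cut = cohesion * cut_fraction * Z[:, 2].max() if len(Z) else 0.0
    raw = fcluster(Z, t=cut, criterion="distance")
    labels = pd.Series([UNASSIGNED] * len(a), index=a.index, dtype=object)
    sizes = pd.Series(raw).value_counts()
    kept = []
    for c in sizes.index:
        if sizes[c] < min_size:
            continue
        members = np.flatnonzero(raw == c)
        within = dist[np.ix_(members, members)]
        mean_d = within[np.triu_indices(len(members), 1)].mean()
        if mean_d <= cut:
            kept.append(c)
    kept.sort(key=lambda c: (-sizes[c], c))
    for rank, c in enumerate(kept, start=1):
        labels.iloc[np.flatnonzero(raw == c)] = f"{prefix}{rank}"
    return labels


def eigenotus(counts: pd.DataFrame, labels: pd.Series) -> pd.DataFrame:
    """First principal component per module of the standardized abundances.

    Rows of ``counts`` are taxa; abundances are standardized per taxon across
    samples.  Each eigenOTU is scaled to unit variance and sign-flipped so it
    correlates non-negatively with the module's mean abundance profile.
    """
    out = {}
    for module in sorted(set(labels) - {UNASSIGNED}):
        members = labels.index[labels == module]
        if len(members) < 2:
            raise ValueError(f"module {module} has fewer than 2 taxa")
        X = counts.loc[members].to_numpy(dtype=float)
        X = (X - X.mean(axis=1, keepdims=True)) / np.maximum(
            X.std(axis=1, keepdims=True), 1e-12
        )
        # samples x taxa SVD; leading right pattern over samples
        U, s, Vt = np.linalg.svd(X, full_matrices=False)
        e = Vt[0]
        mean_profile = X.mean(axis=0)
        if np.dot(e, mean_profile) < 0:
            e = -e
        e = (e - e.mean()) / e.std(ddof=1)
        out[module] = e
    return pd.DataFrame(out, index=counts.columns).T


def module_trait_association(
    eigen: pd.DataFrame, metadata: pd.DataFrame
) -> pd.DataFrame:
    """Module-trait statistics with BH adjustment across modules per trait.

    For every module x trait: Spearman correlation (traits encoded by their
    category codes when categorical), plus a Wilcoxon rank-sum p-value for
    2-level traits or Kruskal-Wallis for >= 3 levels; continuous traits use
    the Spearman test p-value.  Adjustment is Benjamini-Hochberg across
    modules within each trait.
    """
    if not eigen.columns.equals(metadata.index):
        metadata = metadata.loc[eigen.columns]
    rows = []
    for trait in metadata.columns:
        col = metadata[trait]
        if not pd.api.types.is_numeric_dtype(col):
            col = col.astype("category")
        is_cat = isinstance(col.dtype, pd.CategoricalDtype)
        codes = col.cat.codes.to_numpy() if is_cat else col.to_numpy(float)
        levels = pd.unique(codes[~pd.isna(codes)])
        for module in eigen.index:
            e = eigen.loc[module].to_numpy(dtype=float)
            rho, p_s = stats.spearmanr(e, codes)
            if len(levels) == 2:
                g0, g1 = (e[codes == lv] for lv in sorted(levels))
                p = stats.mannwhitneyu(g0, g1, alternative="two-sided").pvalue
                test = "wilcoxon"
            elif len(levels) > 2 and is_cat:
                groups = [e[codes == lv] for lv in sorted(levels)]
                p = stats.kruskal(*groups).pvalue
                test = "kruskal-wallis"
            else:
                p, test = p_s, "spearman"
            rows.append(
                {"module": module, "trait": trait, "spearman_rho": float(rho),
                 "pvalue": float(p), "test": test}
            )
    table = pd.DataFrame(rows)
    table["padj"] = np.nan
    for trait, sub in table.groupby("trait"):
        table.loc[sub.index, "padj"] = multipletests(sub["pvalue"], method="fdr_bh")[1]
    return table


def cross_domain_correlation(
    counts_a: pd.DataFrame,
    counts_b: pd.DataFrame,
    seed: int = 0,
    alpha: float = 0.05,
    **sparcc_kwargs,
) -> pd.DataFrame:
    """SparCC correlation between the member taxa of two domains' modules.

    The two tables (e.g. one FMC's bacterial OTUs and one FFC's fungal OTUs)
    are restricted to shared samples, concatenated and run through SparCC;
    the A x B sub-block is reported long-form with BH-adjusted p-values and a
    significance flag at ``alpha``.
    """
    shared = counts_a.columns.intersection(counts_b.columns)
    if len(shared) == 0:
        raise ValueError("no shared samples between the two tables")
    combined = pd.concat([counts_a[shared], counts_b[shared]])
    if combined.index.duplicated().any():
        raise ValueError("taxon ids overlap between the two tables")
    rho, pv = sparcc(combined, seed=seed, **sparcc_kwargs)
    block_r = rho.loc[counts_a.index, counts_b.index]
    block_p = pv.loc[counts_a.index, counts_b.index]
    long = block_r.stack().rename("rho").to_frame()
    long["pvalue"] = block_p.stack()
    long["padj"] = multipletests(long["pvalue"], method="fdr_bh")[1]
    long["significant"] = long["padj"] < alpha
    long.index.names = ["taxon_a", "taxon_b"]
    return long.reset_index()


def detect_communities(
    counts: pd.DataFrame,
    metadata: pd.DataFrame | None = None,
    min_reads: int = 10,
    min_samples: int = 25,
    min_size: int = 10,
    beta: float = 4.0,
    seed: int = 0,
    prefix: str = "FMC",
    **sparcc_kwargs,
) -> ModuleSet:
    """End-to-end community detection: filter, SparCC, adjacency, modules,
    eigenOTUs and (when metadata is given) module-trait association."""
    filtered, _ = prevalence_filter(counts, min_reads=min_reads, min_samples=min_samples)
    rho, pv = sparcc(filtered, seed=seed, **sparcc_kwargs)
    a = adjacency(rho, beta=beta)
    tom = topological_overlap(a)
    labels = detect_modules(a, min_size=min_size, prefix=prefix)
    modules = sorted(set(labels) - {UNASSIGNED})
    eigen = (
        eigenotus(filtered, labels)
        if modules
        else pd.DataFrame(index=pd.Index([]), columns=filtered.columns)
    )
    assoc = None
    if metadata is not None and len(eigen):
        assoc = module_trait_association(eigen, metadata)
    return ModuleSet(
        rho=rho, pvalues=pv, adjacency=a, tom=tom, labels=labels,
        eigenotus=eigen, min_size=min_size, associations=assoc,
    )
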