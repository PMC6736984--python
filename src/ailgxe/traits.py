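"""Trait normalization and mixed-model residualization.

Quantitative traits are Box-Cox transformed (profile-likelihood lambda on a
grid) and then residualized in a linear mixed model with sex and diet as
fixed effects and the kinship matrix as the covariance of a polygenic random
effect:

    y = X beta + u + e,   u ~ N(0, sigma_g^2 K),  e ~ N(0, sigma_e^2 I)

The residual r = y - X beta_hat - u_hat (conditional residual, BLUP
subtracted) is what the genome scans regress on founder dosages: because the
polygenic covariance has been absorbed, the scans need no further kinship
correction.  Binary traits use a penalized-quasi-likelihood approximation
(logistic link), returning working residuals on the linear-predictor scale.

Composite immunoglobulin traits (AGM, AG, AG/M, A/M, G/M, A/G) and IgG glycan
composites (Gal, term gal, sial, sial-by-gal, mono gal, bi gal) are derived
from measured isotype concentrations and HPLC glycan peak percentages.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import minimize_scalar
from scipy.special import expit

from .haplotypes import KinshipMatrix

__all__ = [
    "ResidualTrait",
    "boxcox",
    "derive_immunoglobulin_traits",
    "derive_glycan_traits",
    "residualize",
]


@dataclass
class ResidualTrait:
    """Residualized trait plus its transformation and variance records."""

    r: np.ndarray
    ids: list
    trait: str
    lam: float | None  # Box-Cox lambda (None if untransformed)
    shift: float
    sigma2_g: float
    sigma2_e: float
    beta: pd.Series
    variance_fractions: dict
    n_dropped: int
    family: str = "gaussian"
    converged: bool = True

    def __post_init__(self) -> None:
        if abs(float(np.mean(self.r))) > 1e-8:
            raise ValueError("residuals must have zero mean")

    @property
    def h2(self) -> float:
        tot = self.sigma2_g + self.sigma2_e
        return self.sigma2_g / tot if tot > 0 else 0.0


def boxcox(
    y: np.ndarray, lam_grid: np.ndarray | None = None
) -> tuple[np.ndarray, float, float]:
    """Box-Cox transform with grid profile-likelihood lambda.

    Non-positive inputs are shifted to be positive (shift recorded); lambda is
    the grid maximizer of the Box-Cox log-likelihood on [-2, 2] with step
    0.01; the transformed vector is standardized to mean 0, variance 1.

    Returns ``(z, lambda, shift)``.
    """
    y = np.asarray(y, dtype=float)
    if np.ptp(y) == 0:
        raise ValueError("constant trait: Box-Cox lambda undefined")
    shift = 0.0
    if y.min() <= 0:
        shift = -y.min() + 1e-3 * max(np.ptp(y), 1.0)
    ys = y + shift
    if lam_grid is None:
        lam_grid = np.arange(-2.0, 2.0 + 1e-9, 0.01)
    ll = np.array([stats.boxcox_llf(lam, ys) for lam in lam_grid])
    lam = float(lam_grid[np.argmax(ll)])
    z = np.log(ys) if lam == 0 else (ys**lam - 1) / lam
    z = (z - z.mean()) / z.std()
    return z, lam, shift


def derive_immunoglobulin_traits(
    ig: pd.DataFrame, standardize: bool = True
) -> pd.DataFrame:
    """Composite immunoglobulin traits from IgA/IgG/IgM concentrations.

    AGM = log IgA + log IgG + log IgM (total production capacity),
    AG = log IgA + log IgG (class switching), AG/M = AG - log IgM,
    A/M, G/M, A/G are pairwise log-ratios.  Composites are computed on the
    raw log concentrations and, when ``standardize`` is set, standardized to
    mean 0 / variance 1 afterwards.
    """
    for col in ("IgA", "IgG", "IgM"):
        if col not in ig.columns:
            raise ValueError(f"missing immunoglobulin column {col!r}")
        if (ig[col] <= 0).any():
            raise ValueError(f"non-positive {col} concentration")
    la, lg, lm = np.log(ig["IgA"]), np.log(ig["IgG"]), np.log(ig["IgM"])
    out = pd.DataFrame(
        {
            "AGM": la + lg + lm,
            "AG": la + lg,
            "AG/M": la + lg - lm,
            "A/M": la - lm,
            "G/M": lg - lm,
            "A/G": la - lg,
        },
        index=ig.index,
    )
    if standardize:
        out = (out - out.mean()) / out.std(ddof=0)
    return out


def derive_glycan_traits(glycans: pd.DataFrame) -> pd.DataFrame:
    """Composite IgG Fc glycan traits from HPLC peak percentages.

    Peaks: G0 (agalactosylated), G1/G2 (mono-/bi-galactosylated), G1S1, G2S1,
    G2S2 (sialylated).  Composites: Gal (all peaks except G0), term gal
    (G1+G2), sial (G1S1+G2S1+G2S2), sial-by-gal (sial/Gal), mono gal
    (G1+G1S1), bi gal (G2+G2S1+G2S2).
    """
    peaks = ["G0", "G1", "G2", "G1S1", "G2S1", "G2S2"]
    for p in peaks:
        if p not in glycans.columns:
            raise ValueError(f"missing glycan peak column {p!r}")
        if (glycans[p] < 0).any():
            raise ValueError(f"negative glycan peak percentage in {p!r}")
    g = glycans
    gal = g[["G1", "G2", "G1S1", "G2S1", "G2S2"]].sum(axis=1)
    sial = g[["G1S1", "G2S1", "G2S2"]].sum(axis=1)
    return pd.DataFrame(
        {
            "Gal": gal,
            "term_gal": g["G1"] + g["G2"],
            "sial": sial,
            "sial_by_gal": sial / gal,
            "mono_gal": g["G1"] + g["G1S1"],
            "bi_gal": g["G2"] + g["G2S1"] + g["G2S2"],
        },
        index=g.index,
    )


def _design(t: pd.DataFrame) -> tuple[np.ndarray, list[str]]:
    cols = [np.ones(len(t))]
    names = ["intercept"]
    for factor in ("sex", "diet"):
        levels = list(t[factor].cat.categories) if hasattr(t[factor], "cat") else sorted(
            t[factor].unique()
        )
        for lev in levels[1:]:
            cols.append((t[factor] == lev).to_numpy(float))
            names.append(f"{factor}[{lev}]")
    X = np.column_stack(cols)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("singular fixed-effect design (collinear sex/diet columns)")
    return X, names


def _reml_fit(y: np.ndarray, X: np.ndarray, S: np.ndarray, U: np.ndarray):
    """REML profile over h = sigma_g^2 / (sigma_g^2 + sigma_e^2).

    ``S, U`` are the eigenvalues/eigenvectors of K.  Returns
    (h, sigma2_g, sigma2_e, beta, u_hat, fitted_fixed).
    """
    n, p = X.shape
    ys, Xs = U.T @ y, U.T @ X

    def neg_reml(h: float) -> float:
        w = h * S + (1 - h)
        Xw = Xs / w[:, None]
        G = Xs.T @ Xw
        b = np.linalg.solve(G, Xw.T @ ys)
        e = ys - Xs @ b
        rss = float(e @ (e / w))
        sig2 = rss / (n - p)
        _, ld_g = np.linalg.slogdet(G)
        return 0.5 * ((n - p) * np.log(sig2) + np.log(w).sum() + ld_g)

    res = minimize_scalar(neg_reml, bounds=(1e-6, 1 - 1e-6), method="bounded",
                          options={"xatol": 1e-8})
    if not res.success:
        raise RuntimeError(f"REML optimization failed: {res}")
    h = float(res.x)
    # flat-profile tie-break toward the simpler model (no polygenic term);
    # K = I makes h unidentifiable and should not inflate sigma_g
    if neg_reml(1e-6) <= res.fun + 1e-8:
        h = 1e-6
    w = h * S + (1 - h)
    Xw = Xs / w[:, None]
    G = Xs.T @ Xw
    beta = np.linalg.solve(G, Xw.T @ ys)
    e_rot = ys - Xs @ beta
    sig2 = float(e_rot @ (e_rot / w)) / (n - p)
    sigma2_g, sigma2_e = h * sig2, (1 - h) * sig2
    # BLUP: u = sigma_g^2 K V^-1 (y - X beta) in the eigenbasis
    u_hat = U @ ((h * S / w) * e_rot)
    return h, sigma2_g, sigma2_e, beta, u_hat


def residualize(
    t: pd.DataFrame,
    trait: str,
    K: KinshipMatrix | np.ndarray,
    family: str | None = None,
    apply_boxcox: bool = True,
    max_pql_iter: int = 50,
) -> ResidualTrait:
    """Mixed-model residualization of one trait against sex, diet and kinship.

    Gaussian traits are (optionally) Box-Cox transformed, then fitted by REML
    using a single eigendecomposition of K; the residual subtracts both the
    fixed effects and the polygenic BLUP.  Binary traits use PQL with a logit
    link and return working residuals on the linear-predictor scale.  Rows
    with a missing trait value are dropped (complete-case) and counted.
    """
    Kv = K.values if isinstance(K, KinshipMatrix) else np.asarray(K, dtype=float)
    if Kv.shape[0] != len(t):
        raise ValueError("kinship dimension does not match trait table")
    mask = t[trait].notna().to_numpy()
    n_dropped = int((~mask).sum())
    sub = t.loc[mask]
    y = sub[trait].to_numpy(dtype=float)
    if np.ptp(y) == 0:
        raise ValueError(f"trait {trait!r} is constant")
    Kv = Kv[np.ix_(mask, mask)]

    uniq = np.unique(y)
    if family is None:
        family = "binary" if set(uniq) <= {0.0, 1.0} else "gaussian"

    X, names = _design(sub)
    S, U = np.linalg.eigh((Kv + Kv.T) / 2)
    S = np.clip(S, 0, None)

    lam = shift = None
    if family == "gaussian":
        if apply_boxcox:
            y, lam, shift = boxcox(y)
        h, s2g, s2e, beta, u_hat = _reml_fit(y, X, S, U)
        fitted = X @ beta + u_hat
        r = y - fitted
        converged = True
    else:
        # PQL: IRLS on the working response, variance components refit each
        # iteration on the working response with the gaussian machinery.
        pbar = np.clip(y.mean(), 0.05, 0.95)
        eta = np.full(len(y), np.log(pbar / (1 - pbar)))
        converged = False
        for _ in range(max_pql_iter):
            mu = expit(eta)
            wv = np.clip(mu * (1 - mu), 1e-6, None)
            z = eta + (y - mu) / wv
            h, s2g, s2e, beta, u_hat = _reml_fit(z, X, S, U)
            eta_new = X @ beta + u_hat
            if np.max(np.abs(eta_new - eta)) < 1e-6:
                eta = eta_new
                converged = True
                break
            eta = eta_new
        if not converged:
            raise RuntimeError(
                f"PQL did not converge in {max_pql_iter} iterations for trait {trait!r}"
            )
        mu = expit(eta)
        wv = np.clip(mu * (1 - mu), 1e-6, None)
        z = eta + (y - mu) / wv
        r = z - eta
        y = z  # for variance partition below
        fitted = eta

    r = r - r.mean()

    # variance partition: incremental R^2 of diet and sex on the full
    # (fixed + BLUP) predictions; kinship fraction = h scaled into the rest
    tss = float(np.sum((y - y.mean()) ** 2))
    fractions = {}
    for factor in ("diet", "sex"):
        keep = [j for j, nm in enumerate(names) if not nm.startswith(f"{factor}[")]
        Xr = X[:, keep]
        _, _, _, beta_r, u_r = _reml_fit(y, Xr, S, U)
        rss_r = float(np.sum((y - Xr @ beta_r - u_r) ** 2))
        rss_f = float(np.sum((y - fitted) ** 2))
        fractions[factor] = max((rss_r - rss_f) / tss, 0.0)
    remainder = max(1.0 - fractions["diet"] - fractions["sex"], 0.0)
    fractions["kinship"] = h * remainder
    fractions["residual"] = max(remainder - fractions["kinship"], 0.0)

    return ResidualTrait(
        r=r,
        ids=list(sub["id"]) if "id" in sub.columns else list(sub.index),
        trait=trait,
        lam=lam,
        shift=shift if shift is not None else 0.0,
        sigma2_g=s2g,
        sigma2_e=s2e,
        beta=pd.Series(beta, index=names),
        variance_fractions=fractions,
        n_dropped=n_dropped,
        family=family,
        converged=converged,
    )
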