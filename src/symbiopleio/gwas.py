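"""Kinship-corrected linear mixed-model association testing.

The model per variant is

    y = 1 a + x b + u + e,    u ~ N(0, sg^2 K),  e ~ N(0, se^2 I)

with K the centered genotype relatedness matrix. The variance ratio
lambda = sg^2/se^2 is estimated once per trait by REML on the null
(intercept-only) model after rotating into K's eigenbasis, which makes the
covariance diagonal; each site's effect is then a weighted (generalized)
least-squares fit with a Wald test on b. This mirrors the standard
eigendecomposition-based exact mixed-model pipeline used for bacterial and
plant GWAS, restricted to a single random effect and no covariates.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .datatypes import DataError, GenotypePanel

LAMBDA_GRID = np.logspace(-5, 5, 51)


@dataclass
class KinshipMatrix:
    """Strain relatedness K = Xc Xc^T / L with cached eigendecomposition."""

    matrix: np.ndarray
    eigenvalues: np.ndarray = field(init=False)
    eigenvectors: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        k = np.asarray(self.matrix, dtype=float)
        if not np.allclose(k, k.T, atol=1e-10):
            raise DataError("kinship matrix must be symmetric")
        self.matrix = 0.5 * (k + k.T)
        evals, evecs = np.linalg.eigh(self.matrix)
        if evals.min() < -1e-8:
            raise DataError("kinship matrix is not numerically PSD")
        self.eigenvalues = evals
        self.eigenvectors = evecs


def filter_variants(
    panel: GenotypePanel, maf_min: float = 0.05, miss_max: float = 0.2
) -> tuple[GenotypePanel, dict[str, int]]:
    """Keep sites with MAF >= ``maf_min`` and missing fraction <= ``miss_max``.

    Returns the filtered panel (raw genotypes untouched; imputation happens
    only inside association) and in/out counts.
    """
    if not (0.0 <= maf_min <= 0.5) or not (0.0 <= miss_max <= 1.0):
        raise DataError("thresholds out of range")
    keep = (panel.maf() >= maf_min) & (panel.missing_fraction() <= miss_max)
    keep &= ~np.isnan(panel.alt_frequency())
    if not keep.any():
        raise DataError("all sites removed by the MAF/missingness filter")
    counts = {"n_in": panel.n_sites, "n_kept": int(keep.sum()), "n_removed": int((~keep).sum())}
    return panel.subset_sites(np.where(keep)[0]), counts


def compute_kinship(panel: GenotypePanel) -> KinshipMatrix:
    """Centered-genotype kinship: K = Xc Xc^T / L over the panel's sites.

    Missing calls are mean-imputed per site before centering (the imputed
    value is then exactly the column mean, contributing zero).
    """
    if panel.n_strains < 2:
        raise DataError("kinship needs at least two strains")
    x = panel.imputed()
    xc = x - x.mean(axis=0)
    if not np.any(xc.std(axis=0) > 0):
        raise DataError("kinship needs at least one polymorphic site")
    return KinshipMatrix(xc @ xc.T / panel.n_sites)


@dataclass
class LMMWorkspace:
    """Eigen-rotated design shared across traits and permutations.

    Rotation (U^T applied to y, the intercept and every genotype column)
    depends only on the panel and K, so permutation replicates reuse it.
    """

    panel: GenotypePanel
    kinship: KinshipMatrix
    d: np.ndarray  # eigenvalues of K, ascending
    ones_r: np.ndarray  # rotated intercept, (S,)
    x_r: np.ndarray  # rotated allele-dosage matrix, (S, L)
    maf: np.ndarray

    @classmethod
    def build(cls, panel: GenotypePanel, kinship: KinshipMatrix) -> "LMMWorkspace":
        u = kinship.eigenvectors
        x = panel.imputed()
        return cls(
            panel=panel,
            kinship=kinship,
            d=kinship.eigenvalues,
            ones_r=u.T @ np.ones(panel.n_strains),
            x_r=u.T @ x,
            maf=panel.maf(),
        )


def _null_reml_nll(log_lambda: float, d: np.ndarray, yr: np.ndarray, ones_r: np.ndarray) -> float:
    """Negative REML log-likelihood of the intercept-only model at lambda."""
    lam = np.exp(log_lambda)
    w = 1.0 / (lam * d + 1.0)
    alpha = (w * ones_r * yr).sum() / (w * ones_r**2).sum()
    resid = yr - alpha * ones_r
    rss = (w * resid**2).sum()
    n = d.size
    # REML: profile out sigma_e^2; include the fixed-effect information term
    return 0.5 * (
        -np.log(w).sum()
        + np.log((w * ones_r**2).sum())
        + (n - 1) * np.log(rss)
    )


def _grid_reml_nll(d: np.ndarray, yr: np.ndarray, ones_r: np.ndarray) -> np.ndarray:
    """_null_reml_nll evaluated on LAMBDA_GRID at once (vectorized over lambda)."""
    w = 1.0 / (LAMBDA_GRID[:, None] * d[None, :] + 1.0)  # (G, n)
    sw1 = w @ ones_r**2
    alpha = (w @ (ones_r * yr)) / sw1
    rss = w @ yr**2 - 2.0 * alpha * (w @ (ones_r * yr)) + alpha**2 * sw1
    n = d.size
    return 0.5 * (-np.log(w).sum(axis=1) + np.log(sw1) + (n - 1) * np.log(rss))


def estimate_lambda(yr: np.ndarray, d: np.ndarray, ones_r: np.ndarray) -> tuple[float, bool]:
    """REML estimate of lambda by log-grid scan plus Brent refinement.

    Returns (lambda_hat, at_boundary).
    """
    grid = np.log(LAMBDA_GRID)
    vals = _grid_reml_nll(d, yr, ones_r)
    i = int(np.argmin(vals))
    at_boundary = i in (0, len(grid) - 1)
    lo = grid[max(i - 1, 0)]
    hi = grid[min(i + 1, len(grid) - 1)]
    if lo < hi:
        res = optimize.minimize_scalar(
            _null_reml_nll, bounds=(lo, hi), args=(d, yr, ones_r), method="bounded"
        )
        best = res.x if res.fun <= vals[i] else grid[i]
    else:
        best = grid[i]
    return float(np.exp(best)), at_boundary


def _site_gls(
    yr: np.ndarray, ws: "LMMWorkspace", lam: float
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized per-site weighted LS of rotated y on [intercept, dosage].

    Returns (beta, se, t) arrays over sites, in standardized-dosage units.
    """
    w = 1.0 / (lam * ws.d + 1.0)
    one = ws.ones_r
    x = ws.x_r
    sw = float((w * one**2).sum())
    swy = float((w * one * yr).sum())
    swx = (w[:, None] * x * one[:, None]).sum(axis=0)
    swxx = (w[:, None] * x**2).sum(axis=0)
    swxy = (x * (w * yr)[:, None]).sum(axis=0)
    swyy = float((w * yr**2).sum())

    denom = sw * swxx - swx**2
    denom = np.where(denom > 0, denom, np.nan)
    beta = (sw * swxy - swx * swy) / denom
    alpha = (swy - beta * swx) / sw
    rss = (
        swyy
        - 2.0 * alpha * swy
        - 2.0 * beta * swxy
        + alpha**2 * sw
        + 2.0 * alpha * beta * swx
        + beta**2 * swxx
    )
    n = yr.size
    df = n - 2
    sigma2 = np.clip(rss, 0.0, None) / df
    se = np.sqrt(sigma2 * sw / denom)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = beta / se
    return beta, se, t


def scan_statistics(
    y: np.ndarray,
    ws: LMMWorkspace,
    *,
    lambda_fixed: float | None = None,
    standardize: bool = True,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, float]:
    """Array-only association scan: (beta, se, p_wald, lambda_hat).

    Same numbers as :func:`lmm_association` without the table packaging;
    used in permutation loops where the scan runs thousands of times.
    """
    y = np.asarray(y, dtype=float)
    sd_y = y.std(ddof=1)
    ys = (y - y.mean()) / sd_y if standardize else y
    yr = ws.kinship.eigenvectors.T @ ys
    if lambda_fixed is None:
        lam, _ = estimate_lambda(yr, ws.d, ws.ones_r)
    else:
        lam = float(lambda_fixed)
    beta, se, t = _site_gls(yr, ws, lam)
    p = 2.0 * stats.t.sf(np.abs(t), df=y.size - 2)
    return beta, se, p, lam


def lmm_association(
    y: np.ndarray,
    panel: GenotypePanel,
    kinship: KinshipMatrix,
    *,
    trait: str = "",
    host: str = "",
    workspace: LMMWorkspace | None = None,
    lambda_fixed: float | None = None,
    standardize: bool = True,
) -> pd.DataFrame:
    """Association scan of one trait vector against every panel site.

    ``y`` must align with ``panel.strain_ids``. The trait is standardized to
    unit variance by default so betas are comparable across fitness proxies;
    raw-scale betas are reported alongside. Returns one row per site with
    beta, se, Wald p (t with n-2 df), MAF and the fitted lambda.
    """
    y = np.asarray(y, dtype=float)
    if y.shape != (panel.n_strains,):
        raise DataError("trait vector must align with panel strains")
    if not np.all(np.isfinite(y)):
        raise DataError("trait vector contains non-finite values")
    sd_y = y.std(ddof=1)
    if sd_y == 0:
        raise DataError("trait vector has zero variance")
    y_scale = sd_y if standardize else 1.0
    ys = (y - y.mean()) / y_scale if standardize else y

    ws = workspace or LMMWorkspace.build(panel, kinship)
    yr = ws.kinship.eigenvectors.T @ ys
    if lambda_fixed is None:
        lam, at_boundary = estimate_lambda(yr, ws.d, ws.ones_r)
    else:
        lam, at_boundary = float(lambda_fixed), False
    beta, se, t = _site_gls(yr, ws, lam)
    p = 2.0 * stats.t.sf(np.abs(t), df=panel.n_strains - 2)

    return pd.DataFrame(
        {
            "site_id": ws.panel.site_ids(),
            "replicon": ws.panel.replicon,
            "pos": ws.panel.pos,
            "trait": trait,
            "host": host,
            "maf": ws.maf,
            "beta": beta,
            "se": se,
            "beta_raw": beta * y_scale,
            "p_wald": p,
            "lambda_hat": lam,
            "lambda_boundary": at_boundary,
        }
    )
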