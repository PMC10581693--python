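"""Phylogenetic GLS association testing with bootstrap-replicate pooling.

Species are not independent observations: closely related species share
trait values through common descent.  The generalized least squares model
accounts for this by using the tree's Brownian-motion covariance matrix
as the error covariance.  Phenotypes arrive as bootstrap replicates (one
per resampling of each species' introns); each replicate is fitted
separately and the fits are combined with Rubin's rules, exactly as
multiple-imputation estimates are pooled, so that phenotype-estimation
uncertainty propagates into the final coefficient, CI and p value.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import linalg, stats
from statsmodels.stats.multitest import multipletests

from .phenotypes import PhenotypeVector
from .phylo import CovarianceMatrix, PhyloTree, tree_covariance

logger = logging.getLogger(__name__)

__all__ = [
    "GLSFit",
    "PooledResult",
    "gls_fit",
    "pool_replicates",
    "association_scan",
    "bh_adjust",
]


@dataclass
class GLSFit:
    """A single GLS fit: coefficients, their SEs and t-test p values."""

    params: np.ndarray
    bse: np.ndarray
    sigma2: float
    df_resid: int
    tvalues: np.ndarray
    pvalues: np.ndarray


def _whitening_factor(sigma: np.ndarray) -> np.ndarray:
    """Lower Cholesky factor, ridge-regularising a singular matrix."""
    try:
        return linalg.cholesky(sigma, lower=True)
    except linalg.LinAlgError:
        n = sigma.shape[0]
        ridge = 1e-8 * np.trace(sigma) / n
        warnings.warn(
            f"singular phylogenetic covariance; adding ridge {ridge:.3g} to the diagonal",
            stacklevel=3,
        )
        return linalg.cholesky(sigma + ridge * np.eye(n), lower=True)


def _check_rank(X: np.ndarray, names=None) -> None:
    r = np.linalg.matrix_rank(X)
    if r < X.shape[1]:
        # name the first column whose removal restores full column rank
        for j in range(X.shape[1]):
            keep = [k for k in range(X.shape[1]) if k != j]
            if np.linalg.matrix_rank(X[:, keep]) == r:
                name = names[j] if names is not None else f"column {j}"
                raise ValueError(f"design matrix is rank deficient: {name} is collinear")
        raise ValueError("design matrix is rank deficient")


def gls_fit(
    y: np.ndarray,
    X: np.ndarray,
    sigma: CovarianceMatrix | np.ndarray,
    column_names=None,
) -> GLSFit:
    """Fit y = X b + e with cov(e) = sigma2 * Sigma by generalized least squares.

    ``b_hat = (X' Sigma^-1 X)^-1 X' Sigma^-1 y`` computed by whitening with
    the Cholesky factor of Sigma; ``sigma2_hat = r' Sigma^-1 r / (n - p)``;
    two-sided p values from the t distribution with n - p df.  Scaling
    Sigma by a positive constant leaves the coefficients and p values
    unchanged (sigma2 absorbs the scale).
    """
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    if isinstance(sigma, CovarianceMatrix):
        sigma = sigma.values
    n, p = X.shape
    if y.shape != (n,):
        raise ValueError("y length does not match design matrix")
    _check_rank(X, column_names)
    L = _whitening_factor(np.asarray(sigma, dtype=float))
    Xw = linalg.solve_triangular(L, X, lower=True)
    yw = linalg.solve_triangular(L, y, lower=True)
    xtx_inv = np.linalg.inv(Xw.T @ Xw)
    params = xtx_inv @ (Xw.T @ yw)
    resid = yw - Xw @ params
    df = n - p
    sigma2 = float(resid @ resid) / df if df > 0 else float("nan")
    bse = np.sqrt(np.maximum(sigma2, 0.0) * np.diag(xtx_inv))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(bse > 0, params / bse, 0.0)
    pvals = np.where(
        bse > 0, 2 * stats.t.sf(np.abs(t), df) if df > 0 else np.nan, 1.0
    )
    return GLSFit(params, bse, sigma2, df, t, pvals)


def _gls_fit_multi(
    Y: np.ndarray, X: np.ndarray, sigma: np.ndarray, coef: int = 1
) -> tuple[np.ndarray, np.ndarray, int]:
    """Fit one design against many response vectors (columns of Y).

    Returns per-replicate estimates and SEs of coefficient ``coef`` plus
    the residual df.  Used by the association scan, where the B bootstrap
    replicates of the phenotype share a design and covariance.
    """
    n, p = X.shape
    _check_rank(X)
    L = _whitening_factor(sigma)
    Xw = linalg.solve_triangular(L, X, lower=True)
    Yw = linalg.solve_triangular(L, Y, lower=True)
    xtx_inv = np.linalg.inv(Xw.T @ Xw)
    params = xtx_inv @ (Xw.T @ Yw)  # (p, B)
    resid = Yw - Xw @ params
    df = n - p
    sigma2 = np.einsum("ij,ij->j", resid, resid) / df
    se = np.sqrt(np.maximum(sigma2, 0.0) * xtx_inv[coef, coef])
    return params[coef], se, df


@dataclass
class PooledResult:
    """Rubin's-rules combination of m replicate fits of one coefficient."""

    estimate: float
    within_variance: float
    between_variance: float
    total_variance: float
    df: float
    p: float
    ci_low: float
    ci_high: float
    m: int


def pool_replicates(
    estimates=None,
    standard_errors=None,
    df_complete: float = np.inf,
    fits: list[GLSFit] | None = None,
    coef: int = 1,
    ci_level: float = 0.95,
) -> PooledResult:
    """Pool replicate estimates of one coefficient by Rubin's rules.

    Qbar is the mean estimate, W the mean squared SE (within-replicate
    variance), B the sample variance of the estimates (between-replicate
    variance) and the total variance T = W + (1 + 1/m) B.  Degrees of
    freedom follow the Barnard-Rubin small-sample formula with the
    complete-data df of the underlying fits; p and the CI come from t(df).

    Pass either arrays of ``estimates``/``standard_errors`` (plus
    ``df_complete``) or a list of :class:`GLSFit` with a coefficient index.
    """
    if fits is not None:
        estimates = np.array([f.params[coef] for f in fits])
        standard_errors = np.array([f.bse[coef] for f in fits])
        df_complete = fits[0].df_resid
    estimates = np.asarray(estimates, dtype=float)
    standard_errors = np.asarray(standard_errors, dtype=float)
    m = len(estimates)
    if m < 2:
        raise ValueError("pooling requires at least two replicates")
    qbar = float(estimates.mean())
    W = float(np.mean(standard_errors**2))
    B = float(np.var(estimates, ddof=1))
    T = W + (1 + 1 / m) * B
    # Barnard-Rubin adjusted degrees of freedom
    dfc = float(df_complete)
    df_obs = (dfc + 1) / (dfc + 3) * dfc if np.isfinite(dfc) else np.inf
    if T > 0 and B > 0:
        lam = (1 + 1 / m) * B / T
        df_old = (m - 1) / lam**2
        df_obs = df_obs * (1 - lam) if np.isfinite(df_obs) else np.inf
        df = 1.0 / (1.0 / df_old + (1.0 / df_obs if np.isfinite(df_obs) else 0.0))
    else:
        df = df_obs if np.isfinite(df_obs) else float("inf")
    if T <= 1e-24 * max(1.0, qbar * qbar):
        # degenerate exact fit: spread is pure floating-point residue
        p, half = (1.0 if abs(qbar) < 1e-12 else 0.0), 0.0
    else:
        tstat = qbar / np.sqrt(T)
        dist = stats.t(df) if np.isfinite(df) else stats.norm()
        p = float(2 * dist.sf(abs(tstat)))
        half = float(dist.ppf(1 - (1 - ci_level) / 2) * np.sqrt(T))
    return PooledResult(
        estimate=qbar,
        within_variance=W,
        between_variance=B,
        total_variance=T,
        df=float(df),
        p=min(max(p, np.finfo(float).tiny), 1.0),
        ci_low=qbar - half,
        ci_high=qbar + half,
        m=m,
    )


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up q values (capped at 1, ties stable)."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    return multipletests(p, method="fdr_bh")[1]


def association_scan(
    phenotype: PhenotypeVector,
    genotypes,
    tree: PhyloTree,
    covariates: list[str] | None = None,
    min_variation: int = 2,
) -> pd.DataFrame:
    """Test every genotype column against a bootstrapped phenotype by PGLS.

    For each genotype column, each phenotype bootstrap replicate is fitted
    with design (intercept, genotype, covariates) and the tree covariance
    restricted to the species that have both phenotype and genotype; the
    replicate fits are pooled with Rubin's rules and q values are BH
    corrected across all tested columns.  Monomorphic columns are skipped.

    ``genotypes`` is a species x column DataFrame (NaN = missing) or any
    object with a ``genotype_frame()`` method returning one.
    """
    if hasattr(genotypes, "genotype_frame"):
        geno = genotypes.genotype_frame()
    else:
        geno = pd.DataFrame(genotypes)
    covariates = list(covariates or [])
    for cov in covariates:
        if cov not in geno.columns:
            raise KeyError(f"covariate {cov!r} is not a genotype column")
    common = [sp for sp in phenotype.species if sp in geno.index]
    if len(common) < 3:
        raise ValueError("fewer than 3 species shared by phenotype and genotypes")
    sigma_full = tree_covariance(tree, common)
    sp_pos = {sp: i for i, sp in enumerate(phenotype.species)}
    pheno_idx = np.array([sp_pos[sp] for sp in common])
    Y_all = phenotype.replicates[pheno_idx]
    rows = []
    test_cols = [c for c in geno.columns if c not in covariates]
    for col in test_cols:
        block = geno.loc[common, [col] + covariates]
        mask = block.notna().all(axis=1).to_numpy()
        used = [sp for sp, ok in zip(common, mask) if ok]
        g = block.loc[used, col].to_numpy(dtype=float)
        if len(np.unique(g)) < min_variation:
            logger.info("%s: monomorphic after intersection, skipped", col)
            continue
        X = np.column_stack(
            [np.ones(len(used)), g]
            + [block.loc[used, c].to_numpy(dtype=float) for c in covariates]
        )
        try:
            _check_rank(X, ["intercept", col] + covariates)
        except ValueError as exc:
            logger.info("%s: %s, skipped", col, exc)
            continue
        sig = sigma_full.values[np.ix_(np.flatnonzero(mask), np.flatnonzero(mask))]
        est, se, dfc = _gls_fit_multi(Y_all[mask], X, sig)
        pooled = pool_replicates(est, se, df_complete=dfc)
        rows.append(
            {
                "genotype_id": col,
                "coefficient": pooled.estimate,
                "ci_low": pooled.ci_low,
                "ci_high": pooled.ci_high,
                "p": pooled.p,
                "n_species": len(used),
                "n_present": int(np.sum(g != 0)),
                "within_variance": pooled.within_variance,
                "between_variance": pooled.between_variance,
                "df": pooled.df,
            }
        )
    result = pd.DataFrame(
        rows,
        columns=[
            "genotype_id",
            "coefficient",
            "ci_low",
            "ci_high",
            "p",
            "n_species",
            "n_present",
            "within_variance",
            "between_variance",
            "df",
        ],
    )
    if len(result):
        result["q"] = bh_adjust(result["p"].to_numpy())
    else:
        result["q"] = []
    return result
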