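"""Mixed-model GWAS: QC, pedigree relationship matrix, REML, per-SNP tests.

The animal model is y = X*beta + Z_k*g_k + u + e with u ~ MVN(0, A*sigma_u2)
(A the pedigree numerator relationship matrix) and e ~ MVN(0, I*sigma_e2).
Variance components are estimated once per trait under the null (no-SNP)
model by REML over a single eigendecomposition of A; each SNP is then
tested as a fixed covariate by generalized least squares with the
variance *ratio* held at the null estimate and the overall scale
re-profiled, giving a 1-df likelihood-ratio chi-square
LRT = n * ln(RSS0/RSS1) in whitened coordinates.  When sigma_u2 = 0 this
reduces exactly to the ordinary-least-squares likelihood-ratio test.
"""
from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .datatypes import GenotypeMatrix, GwasTable, Pedigree, TraitTable

log = logging.getLogger(__name__)

_LAMBDA_LO, _LAMBDA_HI = 1e-6, 1e6


# ---------------------------------------------------------------------------
# quality control


def qc_filter(
    genotypes: GenotypeMatrix,
    min_snp_call: float = 0.85,
    min_maf: float = 0.01,
    min_sample_call: float = 0.98,
) -> GenotypeMatrix:
    """Drop low-call-rate samples, then low-call-rate and rare SNPs.

    Samples are kept iff call rate > ``min_sample_call``; SNPs iff call
    rate > ``min_snp_call`` and MAF > ``min_maf`` (strict, matching the
    usual chip-QC convention).
    """
    for name, v in [
        ("min_snp_call", min_snp_call),
        ("min_maf", min_maf),
        ("min_sample_call", min_sample_call),
    ]:
        if not (0 < v <= 1):
            raise ValueError(f"{name} must lie in (0, 1], got {v}")
    vals = genotypes.values
    sample_keep = genotypes.call_rate_per_sample() > min_sample_call
    vals = vals.loc[sample_keep]
    interim = GenotypeMatrix(vals)
    snp_keep = (interim.call_rate_per_snp() > min_snp_call) & (interim.maf() > min_maf)
    out = vals.loc[:, snp_keep]
    log.info(
        "QC: kept %d/%d samples, %d/%d SNPs",
        sample_keep.sum(),
        len(sample_keep),
        int(snp_keep.sum()),
        len(snp_keep),
    )
    if out.shape[1] == 0:
        warnings.warn("QC removed every SNP", stacklevel=2)
    return GenotypeMatrix(out)


# ---------------------------------------------------------------------------
# numerator relationship matrix


def build_a_matrix(pedigree: Pedigree) -> pd.DataFrame:
    """Pedigree numerator relationship matrix by the tabular method.

    Animals are processed parents-before-offspring:
    A_ii = 1 + 0.5*A_(s,d) and A_ij = 0.5*(A_(j,s) + A_(j,d)), with an
    unknown parent contributing zero.
    """
    order = pedigree.topological_order()
    idx = {a: i for i, a in enumerate(order)}
    ped = pedigree.table.set_index("animal")
    n = len(order)
    A = np.zeros((n, n))
    for a in order:
        i = idx[a]
        sire, dam = ped.loc[a, "sire"], ped.loc[a, "dam"]
        si = idx.get(sire, -1)
        di = idx.get(dam, -1)
        if si >= 0 and di >= 0:
            A[i, i] = 1.0 + 0.5 * A[si, di]
        else:
            A[i, i] = 1.0
        row = np.zeros(n)
        if si >= 0:
            row += 0.5 * A[si]
        if di >= 0:
            row += 0.5 * A[di]
        row[i] = A[i, i]
        A[i, :] = row
        A[:, i] = row
    return pd.DataFrame(A, index=order, columns=order)


# ---------------------------------------------------------------------------
# variance components


@dataclass
class VarianceComponents:
    """Null-model REML fit for one trait."""

    sigma_u2: float
    sigma_e2: float
    beta_hat: pd.Series
    loglik: float  # ML log-likelihood at the REML variance estimates

    @property
    def lambda_(self) -> float:
        return self.sigma_u2 / self.sigma_e2 if self.sigma_e2 > 0 else np.inf

    @property
    def heritability(self) -> float:
        tot = self.sigma_u2 + self.sigma_e2
        return self.sigma_u2 / tot if tot > 0 else np.nan


def build_design(covariates: pd.DataFrame, columns: list[str] | None = None) -> pd.DataFrame:
    """Intercept + dummy-coded categorical covariates (first level dropped)."""
    cols = list(covariates.columns) if columns is None else list(columns)
    X = pd.DataFrame({"(intercept)": 1.0}, index=covariates.index)
    if cols:
        dummies = pd.get_dummies(
            covariates[cols].astype(str), drop_first=True, dtype=float
        )
        X = pd.concat([X, dummies], axis=1)
    _check_full_rank(X)
    return X

def _check_full_rank(X: pd.DataFrame) -> None:
    arr = X.to_numpy(float)
    rank = np.linalg.matrix_rank(arr)
    if rank < arr.shape[1]:
        full = rank
        collinear = [
            c
            for i, c in enumerate(X.columns)
            if np.linalg.matrix_rank(np.delete(arr, i, axis=1)) == full
        ]
        raise ValueError(f"singular fixed-effect design; collinear columns: {collinear}")


def eigendecompose_a(A: pd.DataFrame | np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    arr = A.to_numpy(float) if isinstance(A, pd.DataFrame) else np.asarray(A, float)
    d, U = np.linalg.eigh(arr)
    if d.min() < -1e-8:
        raise ValueError(f"relationship matrix not PSD (min eigenvalue {d.min():.3g})")
    return np.clip(d, 0.0, None), U


def _gls_rss(yr: np.ndarray, Xr: np.ndarray, w: np.ndarray):
    """GLS with diagonal variance w: returns (beta, rss, xtwx)."""
    sw = np.sqrt(w)
    yw = yr / sw
    Xw = Xr / sw[:, None]
    xtwx = Xw.T @ Xw
    beta = np.linalg.solve(xtwx, Xw.T @ yw)
    resid = yw - Xw @ beta
    return beta, float(resid @ resid), xtwx

def _reml_neg_loglik(lam: float, yr: np.ndarray, Xr: np.ndarray, d: np.ndarray) -> float:
    n, p = Xr.shape
    w = lam * d + 1.0
    _, rss, xtwx = _gls_rss(yr, Xr, w)
    sign, logdet_x = np.linalg.slogdet(xtwx)
    if sign <= 0 or rss <= 0:
        return np.inf
    return 0.5 * (
        (n - p) * np.log(rss / (n - p))
        + np.log(w).sum()
        + logdet_x
        + (n - p) * (1.0 + np.log(2.0 * np.pi))
    )


def mixed_model_loglik(
    y: np.ndarray,
    X: np.ndarray,
    beta: np.ndarray,
    sigma_u2: float,
    sigma_e2: float,
    eig: tuple[np.ndarray, np.ndarray],
) -> float:
    """Exact multivariate-normal log-likelihood via the rotated model."""
    d, U = eig
    r = U.T @ (np.asarray(y, float) - np.asarray(X, float) @ beta)
    v = sigma_u2 * d + sigma_e2
    return float(-0.5 * (np.log(2.0 * np.pi * v) + r * r / v).sum())


def fit_null_model(
    y: pd.Series | np.ndarray,
    X: pd.DataFrame | np.ndarray,
    A: pd.DataFrame | np.ndarray | None = None,
    eig: tuple[np.ndarray, np.ndarray] | None = None,
) -> VarianceComponents:
    """REML estimates of (sigma_u2, sigma_e2) for y = X*beta + u + e.

    One eigendecomposition of A reduces the problem to a 1-D profile
    over the variance ratio lambda = sigma_u2/sigma_e2.
    """
    if eig is None:
        if A is None:
            raise ValueError("either A or its eigendecomposition is required")
        eig = eigendecompose_a(A)
    d, U = eig
    names = list(X.columns) if isinstance(X, pd.DataFrame) else None
    Xarr = X.to_numpy(float) if isinstance(X, pd.DataFrame) else np.asarray(X, float)
    yarr = np.asarray(y, float)
    _check_full_rank(pd.DataFrame(Xarr, columns=names or range(Xarr.shape[1])))
    yr, Xr = U.T @ yarr, U.T @ Xarr
    n, p = Xr.shape

    grid = np.concatenate(([0.0], np.exp(np.linspace(np.log(_LAMBDA_LO), np.log(_LAMBDA_HI), 41))))
    vals = np.array([_reml_neg_loglik(l, yr, Xr, d) for l in grid])
    best = int(np.argmin(vals))
    lam = grid[best]
    if 0 < best < len(grid) - 1:
        res = optimize.minimize_scalar(
            lambda x: _reml_neg_loglik(np.exp(x), yr, Xr, d),
            bounds=(np.log(grid[best - 1] + 1e-12), np.log(grid[best + 1])),
            method="bounded",
            options={"xatol": 1e-8},
        )
        if res.fun <= vals[best]:
            lam = float(np.exp(res.x))

    w = lam * d + 1.0
    beta, rss, _ = _gls_rss(yr, Xr, w)
    sigma_e2 = rss / (n - p)
    sigma_u2 = lam * sigma_e2
    ll = mixed_model_loglik(yarr, Xarr, beta, sigma_u2, sigma_e2, eig)
    beta_s = pd.Series(beta, index=names if names is not None else range(p))
    return VarianceComponents(sigma_u2, sigma_e2, beta_s, ll)


# ---------------------------------------------------------------------------
# per-SNP association


def _whiten(eig, lam, y, X):
    d, U = eig
    sw = np.sqrt(lam * d + 1.0)
    return (U.T @ y) / sw, (U.T @ X) / sw[:, None], U, sw


def snp_association(
    y: pd.Series | np.ndarray,
    snp: pd.Series | np.ndarray,
    null: VarianceComponents,
    X: pd.DataFrame | np.ndarray,
    A: pd.DataFrame | np.ndarray | None = None,
    eig: tuple[np.ndarray, np.ndarray] | None = None,
) -> tuple[float, float, float]:
    """(effect, lrt, p) for one SNP with variance ratio held at the null.

    Missing genotypes are mean-imputed; a monomorphic SNP returns
    (nan, 0, 1) rather than raising.
    """
    if eig is None:
        eig = eigendecompose_a(A)
    yarr = np.asarray(y, float)
    Xarr = X.to_numpy(float) if isinstance(X, pd.DataFrame) else np.asarray(X, float)
    z = np.asarray(snp, float)
    if np.isnan(z).any():
        z = np.where(np.isnan(z), np.nanmean(z), z)
    if np.nanstd(z) == 0:
        return np.nan, 0.0, 1.0
    yw, Xw, U, sw = _whiten(eig, null.lambda_, yarr, Xarr)
    zw = (U.T @ z) / sw
    n = len(yw)
    beta0, _ = np.linalg.lstsq(Xw, yw, rcond=None)[:2]
    r0 = yw - Xw @ beta0
    rss0 = float(r0 @ r0)
    Xz = np.column_stack([Xw, zw])
    beta1 = np.linalg.lstsq(Xz, yw, rcond=None)[0]
    r1 = yw - Xz @ beta1
    rss1 = float(r1 @ r1)
    rss1 = min(rss1, rss0)
    lrt = n * np.log(rss0 / rss1) if rss1 > 0 else np.inf
    p = float(stats.chi2.sf(lrt, df=1))
    return float(beta1[-1]), float(lrt), max(p, np.finfo(float).tiny)


def run_gwas(
    genotypes: GenotypeMatrix,
    traits: TraitTable,
    pedigree: Pedigree,
    per_snp_reml: bool = False,
) -> GwasTable:
    """Full SNP x trait association grid under the animal model.

    Variance components are fitted once per trait under the null and
    reused across SNPs; ``per_snp_reml=True`` re-estimates the variance
    ratio for every SNP model (slow, near-identical at desk scale).
    """
    A = build_a_matrix(pedigree)
    eig_cache: dict[tuple[str, ...], tuple] = {}
    geno_animals = set(genotypes.animals)

    effects, pvalues, lrts, n_used = {}, {}, {}, {}
    for trait in traits.traits:
        y_all = traits.values[trait]
        cov_cols = traits.covariate_columns_for(trait)
        cov = traits.covariates[cov_cols] if cov_cols else traits.covariates.iloc[:, :0]
        mask = y_all.notna() & cov.notna().all(axis=1)
        animals = [a for a in y_all.index[mask] if a in geno_animals and a in A.index]
        y = y_all.loc[animals]
        if float(np.std(y)) == 0.0:
            warnings.warn(f"trait {trait} has zero variance; skipped", stacklevel=2)
            continue
        X = build_design(cov.loc[animals], cov_cols)
        key = tuple(animals)
        if key not in eig_cache:
            eig_cache[key] = eigendecompose_a(A.loc[animals, animals])
        eig = eig_cache[key]
        null = fit_null_model(y, X, eig=eig)

        Z = genotypes.values.loc[animals].to_numpy(float)
        col_mean = np.nanmean(Z, axis=0)
        nan_mask = np.isnan(Z)
        Z = np.where(nan_mask, col_mean[None, :], Z)

        yarr = y.to_numpy(float)
        Xarr = X.to_numpy(float)
        if per_snp_reml:
            eff = np.full(Z.shape[1], np.nan)
            lr = np.zeros(Z.shape[1])
            pv = np.ones(Z.shape[1])
            for j in range(Z.shape[1]):
                if np.std(Z[:, j]) == 0:
                    continue
                alt = fit_null_model(yarr, np.column_stack([Xarr, Z[:, j]]), eig=eig)
                e, l, p = snp_association(yarr, Z[:, j], alt, Xarr, eig=eig)
                eff[j], lr[j], pv[j] = e, l, p
        else:
            eff, lr, pv = _vectorized_association(yarr, Xarr, Z, null.lambda_, eig)
        snps = genotypes.snps
        effects[trait] = pd.Series(eff, index=snps)
        lrts[trait] = pd.Series(lr, index=snps)
        pvalues[trait] = pd.Series(pv, index=snps)
        n_used[trait] = pd.Series(len(animals), index=snps)

    if not effects:
        raise ValueError("no analyzable traits (all zero-variance or empty)")
    return GwasTable(
        effects=pd.DataFrame(effects),
        pvalues=pd.DataFrame(pvalues),
        lrt=pd.DataFrame(lrts),
        n_used=pd.DataFrame(n_used),
    )


def _vectorized_association(yarr, Xarr, Z, lam, eig):
    """All-SNP GLS via Frisch-Waugh residualization in whitened space."""
    yw, Xw, U, sw = _whiten(eig, lam, yarr, Xarr)
    Zw = (U.T @ Z) / sw[:, None]
    n = len(yw)
    Q, _ = np.linalg.qr(Xw)
    ry = yw - Q @ (Q.T @ yw)
    Rz = Zw - Q @ (Q.T @ Zw)
    rss0 = float(ry @ ry)
    zz = np.einsum("ij,ij->j", Rz, Rz)
    zy = Rz.T @ ry
    poly = (zz > 1e-12) & (np.std(Z, axis=0) > 0)
    eff = np.full(Z.shape[1], np.nan)
    lrt = np.zeros(Z.shape[1])
    pv = np.ones(Z.shape[1])
    slope = np.where(poly, zy / np.where(poly, zz, 1.0), 0.0)
    rss1 = np.clip(rss0 - slope * zy, np.finfo(float).tiny, None)
    eff[poly] = slope[poly]
    lrt[poly] = n * np.log(rss0 / rss1[poly])
    lrt = np.clip(lrt, 0.0, None)
    pv[poly] = stats.chi2.sf(lrt[poly], df=1)
    pv = np.maximum(pv, np.finfo(float).tiny)
    return eff, lrt, pv
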