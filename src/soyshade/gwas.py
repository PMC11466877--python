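"""Mixed-linear-model association engine.

The model for a per-accession phenotype vector ``y`` (trait mean or shade
tolerance coefficient) is::

    y = X b + u + e,   u ~ N(0, sg2 * K),   e ~ N(0, se2 * I)

with ``K`` the genomic relationship (kinship) matrix and ``X`` fixed
covariates (intercept, optional principal components).  Variance components
are estimated by REML through the eigendecomposition ``K = U L U'``: writing
``delta = se2/sg2`` and rotating everything by ``U'``, the covariance
becomes diagonal, ``diag(L + delta)``, and the REML log-likelihood is a 1-D
function of ``delta`` that is profiled and optimized numerically.

The scan tests each SNP by generalized least squares under
``V = sg2 K + se2 I``.  With P3D (population parameters previously
determined, the default) ``delta`` from the null model is reused for every
SNP and the residual scale is re-estimated per SNP, giving a t-test; the
exact mode refits REML per SNP.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .datatypes import MISSING, GenotypeMatrix

_CHI2_MEDIAN_1DF = stats.chi2.ppf(0.5, 1)  # 0.4549...


def _imputed_dosage(geno: GenotypeMatrix) -> np.ndarray:
    """Float dosage matrix with missing calls replaced by the SNP mean."""
    d = geno.dosage.astype(float)
    d[geno.dosage == MISSING] = np.nan
    means = np.nanmean(d, axis=0)
    idx = np.where(np.isnan(d))
    d[idx] = np.take(means, idx[1])
    return d


def kinship_vanraden(geno: GenotypeMatrix) -> np.ndarray:
    """VanRaden genomic relationship matrix.

    ``K = Z Z' / (2 * sum_k p_k (1 - p_k))`` with ``Z`` the dosage matrix
    centered at twice the alt-allele frequency.  Missing dosages are
    mean-imputed per SNP (for K only); monomorphic SNPs are excluded.
    """
    if geno.n_accessions < 2:
        raise ValueError("need at least 2 accessions")
    d = _imputed_dosage(geno)
    p = d.mean(axis=0) / 2.0
    poly = (p > 0) & (p < 1)
    if not poly.any():
        raise ValueError("all SNPs are monomorphic; kinship undefined")
    d, p = d[:, poly], p[poly]
    Z = d - 2.0 * p
    denom = 2.0 * np.sum(p * (1.0 - p))
    K = (Z @ Z.T) / denom
    return (K + K.T) / 2.0


def validate_kinship(K: np.ndarray, tol: float = 1e-8) -> None:
    """Check symmetry and positive semi-definiteness of a kinship matrix."""
    if not np.allclose(K, K.T, atol=1e-10):
        raise ValueError("kinship matrix is not symmetric")
    w = np.linalg.eigvalsh(K)
    if w.min() < -tol:
        raise ValueError(f"kinship matrix not PSD (min eigenvalue {w.min():.3g})")


@dataclass
class NullModelFit:
    """REML variance components and the spectral cache used by the scan."""

    sigma2_g: float
    sigma2_e: float
    delta: float
    reml_loglik: float
    eigenvalues: np.ndarray
    eigenvectors: np.ndarray
    at_bound: bool = False

    @property
    def heritability(self) -> float:
        """Pseudo-heritability sg2/(sg2+se2) of the null model."""
        return self.sigma2_g / (self.sigma2_g + self.sigma2_e)


def _reml_neg2ll(
    log_delta: float, lam: np.ndarray, yt: np.ndarray, Xt: np.ndarray, logdet_xtx: float
) -> float:
    delta = np.exp(log_delta)
    w = 1.0 / (lam + delta)
    Xw = Xt * w[:, None]
    XtHX = Xt.T @ Xw
    sign, logdet_xthx = np.linalg.slogdet(XtHX)
    if sign <= 0:
        return np.inf
    beta = np.linalg.solve(XtHX, Xw.T @ yt)
    resid = yt - Xt @ beta
    rss = float(resid @ (w * resid))
    n, q = len(yt), Xt.shape[1]
    if rss <= 0:
        return np.inf
    sigma2 = rss / (n - q)
    return (
        (n - q) * np.log(2 * np.pi * sigma2)
        + float(np.sum(np.log(lam + delta)))
        + logdet_xthx
        - logdet_xtx
        + (n - q)
    )


def fit_null_reml(
    y: np.ndarray,
    K: np.ndarray,
    covariates: np.ndarray | None = None,
    *,
    log_delta_bounds: tuple[float, float] = (-10.0, 10.0),
    n_grid: int = 64,
) -> NullModelFit:
    """REML fit of the null mixed model (no SNP term).

    A grid over ``log(delta)`` locates the basin and Brent refinement
    polishes the optimum.  Returns variance components plus the
    eigendecomposition of K for reuse by the scan.
    """
    y = np.asarray(y, dtype=float)
    n = len(y)
    if not np.isfinite(y).all():
        raise ValueError("phenotype vector contains non-finite values")
    X = _design(n, covariates)
    lam, U = np.linalg.eigh(K)
    lam = np.maximum(lam, 0.0)
    yt = U.T @ y
    Xt = U.T @ X
    sign, logdet_xtx = np.linalg.slogdet(X.T @ X)
    if sign <= 0:
        raise ValueError("covariate design is rank deficient")

    grid = np.linspace(*log_delta_bounds, n_grid)
    vals = np.array([_reml_neg2ll(g, lam, yt, Xt, logdet_xtx) for g in grid])
    if not np.isfinite(vals).any():
        raise ValueError("REML likelihood non-finite over the entire delta grid")
    i = int(np.nanargmin(vals))
    lo = grid[max(i - 1, 0)]
    hi = grid[min(i + 1, n_grid - 1)]
    res = optimize.minimize_scalar(
        _reml_neg2ll,
        bounds=(lo, hi),
        args=(lam, yt, Xt, logdet_xtx),
        method="bounded",
        options={"xatol": 1e-8},
    )
    log_delta = float(res.x)
    at_bound = i in (0, n_grid - 1)
    if at_bound:
        warnings.warn(
            f"REML delta estimate at search bound (log delta = {log_delta:.2f})",
            stacklevel=2,
        )
    delta = float(np.exp(log_delta))
    w = 1.0 / (lam + delta)
    Xw = Xt * w[:, None]
    beta = np.linalg.solve(Xt.T @ Xw, Xw.T @ yt)
    resid = yt - Xt @ beta
    sigma2_g = float(resid @ (w * resid)) / (n - X.shape[1])
    return NullModelFit(
        sigma2_g=sigma2_g,
        sigma2_e=delta * sigma2_g,
        delta=delta,
        reml_loglik=-0.5 * float(res.fun),
        eigenvalues=lam,
        eigenvectors=U,
        at_bound=at_bound,
    )


def _design(n: int, covariates: np.ndarray | None) -> np.ndarray:
    if covariates is None:
        return np.ones((n, 1))
    C = np.atleast_2d(np.asarray(covariates, dtype=float))
    if C.shape[0] != n:
        C = C.T
    return np.column_stack([np.ones(n), C])


@dataclass
class GWASResults:
    """Per-SNP association results plus scan metadata.

    ``table`` columns: snp_id, chrom, pos, maf, beta, se, p, neglog10p,
    r2_percent.  ``skipped`` lists SNPs excluded from testing with reasons.
    """

    table: pd.DataFrame
    skipped: pd.DataFrame
    null_fit: NullModelFit
    threshold: float
    trait: str | None = None
    year: str | None = None

    def significant(self, threshold: float | None = None) -> pd.DataFrame:
        return filter_significant(self.table, threshold or self.threshold)

    def lambda_gc(self) -> float:
        return genomic_inflation(self.table)

    def manhattan_data(self, chrom_lengths: dict[int, int] | None = None) -> pd.DataFrame:
        return manhattan_export(self.table, chrom_lengths, threshold=self.threshold)

    def summary(self) -> str:
        sig = self.significant()
        what = f"{self.trait or 'phenotype'}" + (f" / {self.year}" if self.year else "")
        lines = [
            f"Mixed-linear-model GWAS: {what}",
            "=" * 44,
            f"SNPs tested: {len(self.table)}  (skipped: {len(self.skipped)})",
            f"Variance components: sigma2_g={self.null_fit.sigma2_g:.4g}, "
            f"sigma2_e={self.null_fit.sigma2_e:.4g} (delta={self.null_fit.delta:.3g})",
            f"Genomic inflation lambda_GC: {self.lambda_gc():.3f}",
            f"Significant at -log10(p) >= {self.threshold}: {len(sig)}",
        ]
        if len(sig):
            top = sig.nlargest(min(5, len(sig)), "neglog10p")
            lines.append("Top signals:")
            for _, r in top.iterrows():
                lines.append(
                    f"  {r['snp_id']}: beta={r['beta']:+.3f}  "
                    f"-log10(p)={r['neglog10p']:.2f}  R2={r['r2_percent']:.2f}%"
                )
        return "\n".join(lines)


class MLMGWAS:
    """Mixed-linear-model genome scan for one phenotype vector.

    Parameters
    ----------
    y : pandas.Series or array
        Per-accession phenotype (trait mean or STC).  A Series is aligned to
        the genotype accessions by index; an array must already be aligned.
    genotypes : GenotypeMatrix
    kinship : ndarray, optional
        Defaults to :func:`kinship_vanraden` of the genotypes.
    covariates : ndarray, optional
        Extra fixed-effect columns (an intercept is always included).
    maf_threshold : float
        SNPs with minor allele frequency below this are skipped (default
        0.05).
    """

    def __init__(
        self,
        y,
        genotypes: GenotypeMatrix,
        kinship: np.ndarray | None = None,
        covariates: np.ndarray | None = None,
        maf_threshold: float = 0.05,
        trait: str | None = None,
        year: str | None = None,
    ) -> None:
        if isinstance(y, pd.Series):
            missing = [a for a in genotypes.accession_ids if a not in y.index]
            if missing:
                raise ValueError(f"phenotype missing for accessions {missing[:5]}...")
            y = y.loc[list(genotypes.accession_ids)].to_numpy(dtype=float)
        self.y = np.asarray(y, dtype=float)
        if len(self.y) != genotypes.n_accessions:
            raise ValueError("phenotype length does not match accession count")
        self.genotypes = genotypes
        self.K = kinship if kinship is not None else kinship_vanraden(genotypes)
        self.covariates = covariates
        self.maf_threshold = maf_threshold
        self.trait = trait
        self.year = year

    def fit_null(self) -> NullModelFit:
        return fit_null_reml(self.y, self.K, self.covariates)

    def fit(self, p3d: bool = True, threshold: float = 5.0) -> GWASResults:
        null = self.fit_null()
        table, skipped = mlm_scan(
            self.genotypes,
            self.y,
            self.K,
            covariates=self.covariates,
            p3d=p3d,
            null_fit=null,
            maf_threshold=self.maf_threshold,
        )
        return GWASResults(
            table=table,
            skipped=skipped,
            null_fit=null,
            threshold=threshold,
            trait=self.trait,
            year=self.year,
        )


def mlm_scan(
    genotypes: GenotypeMatrix,
    y: np.ndarray,
    K: np.ndarray,
    *,
    covariates: np.ndarray | None = None,
    p3d: bool = True,
    null_fit: NullModelFit | None = None,
    maf_threshold: float = 0.05,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-SNP GLS effect and Wald test under ``V = sg2 K + se2 I``.

    With ``p3d=True`` the null-model ``delta`` is fixed for every SNP and the
    residual scale re-estimated per SNP (t-test, df = n - q - 1); otherwise
    REML is refit per SNP with the SNP in the design.  ``r2_percent`` is the
    share of the total sum of squares (after covariates, on the whitened
    scale) explained by the SNP.  Missing dosages are mean-imputed; SNPs with
    MAF below threshold or constant after imputation are skipped.
    """
    y = np.asarray(y, dtype=float)
    n = genotypes.n_accessions
    if null_fit is None:
        null_fit = fit_null_reml(y, K, covariates)
    X = _design(n, covariates)
    q = X.shape[1]
    lam, U = null_fit.eigenvalues, null_fit.eigenvectors
    G = _imputed_dosage(genotypes)
    freq = G.mean(axis=0) / 2.0
    maf = np.minimum(freq, 1 - freq)
    var = G.var(axis=0)

    testable = np.ones(len(maf), dtype=bool)
    reasons = np.empty(len(maf), dtype=object)
    const = var == 0
    low = (~const) & (maf < maf_threshold)
    testable[const | low] = False
    reasons[const] = "constant after imputation"
    reasons[low] = f"MAF below {maf_threshold}"
    skipped = pd.DataFrame(
        {
            "snp_id": genotypes.snps.loc[~testable, "snp_id"].to_numpy(),
            "reason": reasons[~testable],
        }
    )

    idx = np.flatnonzero(testable)
    if p3d:
        w = 1.0 / np.sqrt(lam + null_fit.delta)
        yt = w * (U.T @ y)
        Xt = w[:, None] * (U.T @ X)
        Gt = w[:, None] * (U.T @ G[:, idx])
        # residualize against the whitened covariates
        Q, _ = np.linalg.qr(Xt)
        yr = yt - Q @ (Q.T @ yt)
        Gr = Gt - Q @ (Q.T @ Gt)
        gss = np.einsum("ij,ij->j", Gr, Gr)
        ok = gss > 1e-12
        gty = Gr.T @ yr
        tss = float(yr @ yr)
        beta = np.where(ok, gty / np.where(ok, gss, 1.0), np.nan)
        rss = tss - beta**2 * gss
        dof = n - q - 1
        sigma2 = rss / dof
        se = np.sqrt(sigma2 / np.where(ok, gss, np.nan))
        tstat = beta / se
        p = 2.0 * stats.t.sf(np.abs(tstat), dof)
        r2 = 100.0 * (beta**2 * gss) / tss
    else:
        beta = np.full(len(idx), np.nan)
        se = np.full(len(idx), np.nan)
        p = np.full(len(idx), np.nan)
        r2 = np.full(len(idx), np.nan)
        ok = np.ones(len(idx), dtype=bool)
        for j, col in enumerate(idx):
            Xs = np.column_stack([X, G[:, col]])
            try:
                fit_j = fit_null_reml(y, K, Xs[:, 1:])
            except ValueError:
                ok[j] = False
                continue
            w = 1.0 / np.sqrt(lam + fit_j.delta)
            yt = w * (U.T @ y)
            Xt = w[:, None] * (U.T @ Xs)
            coef, rss_arr, rank, _ = np.linalg.lstsq(Xt, yt, rcond=None)
            if rank < Xt.shape[1] or len(rss_arr) == 0:
                ok[j] = False
                continue
            dof = n - Xt.shape[1]
            sigma2 = float(rss_arr[0]) / dof
            XtX_inv = np.linalg.inv(Xt.T @ Xt)
            beta[j] = coef[-1]
            se[j] = np.sqrt(sigma2 * XtX_inv[-1, -1])
            p[j] = 2.0 * stats.t.sf(abs(beta[j] / se[j]), dof)
            Q, _ = np.linalg.qr(Xt[:, :-1])
            yr = yt - Q @ (Q.T @ yt)
            gr = Xt[:, -1] - Q @ (Q.T @ Xt[:, -1])
            r2[j] = 100.0 * (float(gr @ yr) ** 2 / float(gr @ gr)) / float(yr @ yr)

    table = genotypes.snps.loc[idx, ["snp_id", "chrom", "pos"]].reset_index(drop=True)
    table["maf"] = maf[idx]
    table["beta"] = beta
    table["se"] = se
    table["p"] = np.clip(p, np.finfo(float).tiny, 1.0)
    table["neglog10p"] = -np.log10(table["p"])
    table["r2_percent"] = r2
    bad = ~ok
    if bad.any():
        skipped = pd.concat(
            [
                skipped,
                pd.DataFrame(
                    {
                        "snp_id": table.loc[bad, "snp_id"],
                        "reason": "degenerate after whitening",
                    }
                ),
            ],
            ignore_index=True,
        )
        table = table.loc[~bad].reset_index(drop=True)
    return table, skipped


def filter_significant(table: pd.DataFrame, threshold: float = 5.0) -> pd.DataFrame:
    """SNPs with ``-log10(p) >= threshold`` (inclusive), strongest first."""
    sig = table[table["neglog10p"] >= threshold]
    return sig.sort_values("neglog10p", ascending=False).reset_index(drop=True)


def summarize_significant(
    tables: dict[tuple[str, str], pd.DataFrame], threshold: float = 5.0
) -> pd.DataFrame:
    """Per trait/year bookkeeping of the significant subset: count and the
    max/min of -log10(p) and R2 (the layout of a per-scan summary table)."""
    rows = []
    for (trait, year), table in tables.items():
        sig = filter_significant(table, threshold)
        rows.append(
            {
                "trait": trait,
                "year": year,
                "n_significant": len(sig),
                "neglog10p_max": sig["neglog10p"].max() if len(sig) else np.nan,
                "neglog10p_min": sig["neglog10p"].min() if len(sig) else np.nan,
                "r2_max": sig["r2_percent"].max() if len(sig) else np.nan,
                "r2_min": sig["r2_percent"].min() if len(sig) else np.nan,
            }
        )
    return pd.DataFrame(rows)


def genomic_inflation(table: pd.DataFrame) -> float:
    """Genomic-control lambda: median chi-square of the scan over the null
    1-df median (0.4549)."""
    p = table["p"].to_numpy(dtype=float)
    if len(p) < 100:
        warnings.warn("lambda_GC estimated from fewer than 100 SNPs", stacklevel=2)
    chi2 = stats.chi2.isf(p, 1)
    return float(np.median(chi2) / _CHI2_MEDIAN_1DF)


def manhattan_export(
    table: pd.DataFrame,
    chrom_lengths: dict[int, int] | None = None,
    threshold: float = 5.0,
) -> pd.DataFrame:
    """Plot-ready Manhattan table: cumulative bp, -log10(p), chromosome
    color index, with the threshold line value attached as an attribute.

    ``chrom_lengths`` defaults to the max observed position per chromosome.
    """
    out = table.sort_values(["chrom", "pos"]).reset_index(drop=True)
    if chrom_lengths is None:
        chrom_lengths = out.groupby("chrom")["pos"].max().to_dict()
    offsets, cum = {}, 0
    for chrom in sorted(chrom_lengths):
        offsets[chrom] = cum
        cum += int(chrom_lengths[chrom])
    out["cumulative_bp"] = [
        offsets[c] + p for c, p in zip(out["chrom"], out["pos"])
    ]
    chrom_order = {c: i for i, c in enumerate(sorted(chrom_lengths))}
    out["color_index"] = out["chrom"].map(lambda c: chrom_order[c] % 2)
    out = out[["snp_id", "chrom", "pos", "cumulative_bp", "neglog10p", "color_index"]]
    out.attrs["threshold"] = threshold
    return out
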