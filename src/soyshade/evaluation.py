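"""Shade-tolerance evaluation: STC, subordinate function values, PCA
contribution weights, D value, ASFV and five-class grading.

The evaluation chain for one year:

1. ``STC_ij = mean(shade replicates) / mean(CK replicates)`` per accession
   ``i`` and trait ``j`` (stored as a plain ratio);
2. ``F_ij = (STC_ij - min_i STC_ij) / (max_i STC_ij - min_i STC_ij)`` —
   the subordinate (fuzzy membership) function value, in [0, 1];
3. principal components of the standardized F matrix give contribution
   rates ``p_j`` and weights ``W_j = p_j / sum(p_j)``;
4. ``D = sum_j u(X_j) * W_j`` with ``u`` the min-max standardized indicator
   scores (principal-component scores by default, trait SFVs on request);
5. ``ASFV`` = unweighted mean of ``F_ij`` over traits; grading into five
   ordered classes HSS < SS < MST < ST < HST (higher ASFV = more tolerant).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .datatypes import PhenotypeTable

GRADE_ORDER = ("HSS", "SS", "MST", "ST", "HST")
GRADE_DTYPE = pd.CategoricalDtype(categories=list(GRADE_ORDER), ordered=True)


@dataclass
class STCTable:
    """Per-accession shade tolerance coefficients for one year.

    ``values``: DataFrame indexed by accession, one column per trait, NaN
    where a cell is undefined or missing.  ``counts``: replicate counts used
    per cell (``(accession, trait) -> (n_shade, n_ck)``).  ``flags``: reasons
    for undefined cells.
    """

    year: str
    values: pd.DataFrame
    counts: pd.DataFrame
    flags: dict[tuple[str, str], str] = field(default_factory=dict)


def compute_stc(pheno: PhenotypeTable, year: str) -> STCTable:
    """Shade tolerance coefficient per accession and trait for one year.

    STC is the ratio of the shade replicate mean to the CK replicate mean.
    A CK mean of zero flags the cell undefined; a missing condition flags it
    missing.  Both appear as NaN in ``values`` with a reason in ``flags``.
    """
    df = pheno.data[pheno.data["year"] == year]
    if df.empty:
        raise ValueError(f"no phenotype records for year {year!r}")
    agg = df.groupby(["accession", "trait", "condition"])["value"].agg(["mean", "size"])
    mean = agg["mean"].unstack("condition")
    size = agg["size"].unstack("condition").fillna(0).astype(int)
    for col in ("CK", "shade"):
        if col not in mean.columns:
            mean[col] = np.nan
            size[col] = 0
    flags: dict[tuple[str, str], str] = {}
    stc = mean["shade"] / mean["CK"]
    for key in mean.index:
        if np.isnan(mean.loc[key, "shade"]) or np.isnan(mean.loc[key, "CK"]):
            flags[key] = "missing condition"
            stc.loc[key] = np.nan
        elif mean.loc[key, "CK"] == 0:
            flags[key] = "CK mean is zero"
            stc.loc[key] = np.nan
    values = stc.unstack("trait")
    counts = pd.DataFrame(
        {
            "n_shade": size["shade"],
            "n_ck": size["CK"],
        }
    )
    return STCTable(year=year, values=values, counts=counts, flags=flags)


def compute_sfv(stc_values: pd.DataFrame) -> tuple[pd.DataFrame, list[str]]:
    """Min-max standardize STC within each trait to the subordinate
    function value F in [0, 1].

    Returns the SFV frame and the list of dropped traits (max == min: a
    constant indicator carries no ranking information).
    """
    dropped = []
    cols = {}
    for trait in stc_values.columns:
        col = stc_values[trait]
        lo, hi = col.min(skipna=True), col.max(skipna=True)
        if not np.isfinite(lo) or not np.isfinite(hi) or hi == lo:
            dropped.append(trait)
            continue
        cols[trait] = (col - lo) / (hi - lo)
    if dropped:
        warnings.warn(
            f"traits dropped from evaluation (constant or empty STC): {dropped}",
            stacklevel=2,
        )
    if not cols:
        raise ValueError("no traits left after dropping constant STC columns")
    return pd.DataFrame(cols, index=stc_values.index), dropped


def compute_weights(
    sfv: pd.DataFrame, n_components: int | None = None, mode: str = "pca"
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Contribution rates and weights from principal components of the SFV.

    Columns are standardized to zero mean / unit variance and the
    correlation-matrix eigendecomposition taken; ``p_j`` is the variance
    contribution rate of component j, ``W_j = p_j / sum(retained p_j)``.
    ``mode="equal"`` gives uniform weights over the trait columns instead.

    Returns ``(p, w, loadings)``; ``loadings`` has one column per retained
    component (eigenvectors scaled to unit length).
    """
    X = sfv.to_numpy(dtype=float)
    if X.shape[1] < 2:
        raise ValueError("need at least 2 retained traits to compute weights")
    if mode == "equal":
        k = X.shape[1]
        w = np.full(k, 1.0 / k)
        return w.copy(), w, np.eye(k)
    if mode != "pca":
        raise ValueError(f"unknown weight mode {mode!r}")
    Xc = X - np.nanmean(X, axis=0)
    sd = np.nanstd(Xc, axis=0, ddof=1)
    if np.any(sd == 0) or not np.all(np.isfinite(sd)):
        raise ValueError("degenerate SFV covariance: constant column")
    Z = Xc / sd
    Z = np.where(np.isfinite(Z), Z, 0.0)  # missing cells contribute the mean
    R = (Z.T @ Z) / (Z.shape[0] - 1)
    eigval, eigvec = np.linalg.eigh(R)
    order = np.argsort(eigval)[::-1]
    eigval, eigvec = np.maximum(eigval[order], 0.0), eigvec[:, order]
    if eigval.sum() <= 0:
        raise ValueError("degenerate SFV covariance (rank 0)")
    k = len(eigval) if n_components is None else int(n_components)
    p = eigval[:k] / eigval.sum()
    w = p / p.sum()
    return p, w, eigvec[:, :k]


def _minmax(col: np.ndarray) -> np.ndarray:
    lo, hi = np.nanmin(col), np.nanmax(col)
    if hi == lo:
        return np.zeros_like(col)
    return (col - lo) / (hi - lo)


def compute_d(
    indicators: pd.DataFrame | np.ndarray,
    weights: np.ndarray,
    *,
    standardize: bool = True,
) -> np.ndarray:
    """Comprehensive score ``D = sum_j u(X_j) * W_j`` per accession.

    ``u`` min-max standardizes each indicator column to [0, 1] (pass
    ``standardize=False`` when the indicators are already membership scores),
    so D lies in [0, 1] whenever the weights are normalized.
    """
    X = np.asarray(indicators, dtype=float)
    weights = np.asarray(weights, dtype=float)
    if X.shape[1] != len(weights):
        raise ValueError(
            f"{X.shape[1]} indicator columns but {len(weights)} weights"
        )
    if abs(weights.sum() - 1.0) > 1e-9:
        raise ValueError("weights must sum to 1")
    if standardize:
        X = np.column_stack([_minmax(X[:, j]) for j in range(X.shape[1])])
    return X @ weights


def compute_asfv(sfv: pd.DataFrame) -> pd.Series:
    """Average subordinate function value per accession (unweighted mean
    over retained traits; all-missing rows stay NaN)."""
    return sfv.mean(axis=1, skipna=True)


def grade(
    asfv: pd.Series,
    strategy: str = "quantile",
    *,
    proportions: tuple[float, ...] = (0.2, 0.2, 0.2, 0.2, 0.2),
    k_sd: float = 1.0,
) -> tuple[pd.Series, np.ndarray]:
    """Assign five ordered tolerance classes from ASFV.

    Higher ASFV means stronger shade tolerance.  Strategies:

    * ``quantile`` — cuts at the cumulative ``proportions`` quantiles
      (default equal fifths);
    * ``equal_width`` — cuts dividing [min, max] into five equal bins;
    * ``mean_sd`` — cuts at ``mean + k_sd * sd * (-1.5, -0.5, 0.5, 1.5)``.

    Returns the per-accession grades (ordered categorical HSS<SS<MST<ST<HST)
    and the four ascending cut points.
    """
    vals = asfv.dropna()
    if len(vals) < 5:
        raise ValueError("need at least 5 accessions to grade")
    if strategy == "quantile":
        if len(proportions) != 5 or abs(sum(proportions) - 1.0) > 1e-9:
            raise ValueError("proportions must be 5 values summing to 1")
        q = np.cumsum(proportions)[:4]
        cuts = np.quantile(vals, q)
    elif strategy == "equal_width":
        lo, hi = vals.min(), vals.max()
        cuts = lo + (hi - lo) * np.array([0.2, 0.4, 0.6, 0.8])
    elif strategy == "mean_sd":
        mu, sd = vals.mean(), vals.std(ddof=1)
        cuts = mu + k_sd * sd * np.array([-1.5, -0.5, 0.5, 1.5])
    else:
        raise ValueError(f"unknown grading strategy {strategy!r}")
    if not np.all(np.diff(cuts) > 0):
        warnings.warn("grade thresholds are not strictly increasing", stacklevel=2)
    idx = np.searchsorted(cuts, asfv.to_numpy(dtype=float), side="left")
    labels = pd.Series(
        pd.Categorical.from_codes(
            np.where(asfv.notna(), idx, -1), dtype=GRADE_DTYPE
        ),
        index=asfv.index,
        name="grade",
    )
    return labels, cuts


def select_tolerant(grades: pd.Series, asfv: pd.Series) -> tuple[pd.DataFrame, float]:
    """High-shade-tolerance accessions sorted by ASFV, and the percentage
    of the panel they represent (rounded to 2 decimals)."""
    hst = asfv[grades == "HST"].sort_values(ascending=False)
    out = pd.DataFrame({"accession": hst.index, "asfv": hst.to_numpy()})
    n = int(grades.notna().sum())
    percent = round(100.0 * len(hst) / n, 2) if n else 0.0
    return out, percent


@dataclass
class EvaluationResults:
    """Fitted shade-tolerance evaluation for one or more years.

    Attributes hold one entry per year: STC tables, SFV frames, contribution
    rates/weights, D values, ASFV, grades and the grading thresholds.
    """

    years: list[str]
    stc: dict[str, STCTable]
    sfv: dict[str, pd.DataFrame]
    dropped_traits: dict[str, list[str]]
    contribution: dict[str, np.ndarray]
    weights: dict[str, np.ndarray]
    d_value: dict[str, pd.Series]
    asfv: dict[str, pd.Series]
    grades: dict[str, pd.Series]
    thresholds: dict[str, np.ndarray]
    grading_strategy: str

    def per_accession(self, year: str) -> pd.DataFrame:
        """One row per accession: STCs, SFVs, D, ASFV, grade for a year."""
        stc = self.stc[year].values.add_prefix("stc_")
        sfv = self.sfv[year].add_prefix("sfv_")
        out = stc.join(sfv, how="outer")
        out["d_value"] = self.d_value[year]
        out["asfv"] = self.asfv[year]
        out["grade"] = self.grades[year].astype(str)
        out.index.name = "accession"
        return out.reset_index()

    def tolerant(self, year: str) -> tuple[pd.DataFrame, float]:
        return select_tolerant(self.grades[year], self.asfv[year])

    def tolerant_union(self) -> pd.DataFrame:
        """Cross-year union of HST accessions with per-year and mean ASFV;
        accessions selected in both years appear once."""
        rows: dict[str, dict] = {}
        for year in self.years:
            hst, _ = self.tolerant(year)
            for _, r in hst.iterrows():
                rec = rows.setdefault(r["accession"], {"accession": r["accession"]})
                rec[f"asfv_{year}"] = r["asfv"]
                rec.setdefault("years", []).append(year)
        out = pd.DataFrame(rows.values())
        if out.empty:
            return pd.DataFrame(columns=["accession", "years", "mean_asfv"])
        asfv_cols = [c for c in out.columns if c.startswith("asfv_")]
        out["mean_asfv"] = out[asfv_cols].mean(axis=1)
        out["years"] = out["years"].map(",".join)
        return out.sort_values("mean_asfv", ascending=False).reset_index(drop=True)

    def summary(self) -> str:
        lines = ["Shade-tolerance evaluation", "=" * 40]
        for year in self.years:
            counts = self.grades[year].value_counts().reindex(list(GRADE_ORDER))
            hst, pct = self.tolerant(year)
            lines.append(f"Year {year} (grading: {self.grading_strategy})")
            lines.append(
                "  thresholds: "
                + " / ".join(f"{t:.3f}" for t in self.thresholds[year])
            )
            lines.append(
                "  grades: "
                + ", ".join(f"{g}={int(c)}" for g, c in counts.items())
            )
            lines.append(f"  HST: {len(hst)} accessions ({pct:.2f}% of panel)")
            for _, r in hst.head(5).iterrows():
                lines.append(f"    {r['accession']}  ASFV={r['asfv']:.2f}")
            if len(hst) > 5:
                lines.append(f"    ... and {len(hst) - 5} more")
        return "\n".join(lines)


class ShadeToleranceEvaluation:
    """Model object: evaluate shade tolerance of a panel from phenotypes.

    Parameters
    ----------
    pheno : PhenotypeTable
        Plant-level observations under both conditions.
    years : list of str, optional
        Years to evaluate (default: all years present).
    grading : {"quantile", "equal_width", "mean_sd"}
        Threshold strategy for the five tolerance classes.
    weight_mode : {"pca", "equal"}
        Contribution-rate weights from principal components (default) or
        uniform.
    indicator : {"pc_scores", "sfv"}
        Indicators entering the D value: standardized principal-component
        scores (default) or the trait SFVs directly.
    """

    def __init__(
        self,
        pheno: PhenotypeTable,
        years: list[str] | None = None,
        grading: str = "quantile",
        weight_mode: str = "pca",
        indicator: str = "pc_scores",
        n_components: int | None = None,
    ) -> None:
        self.pheno = pheno
        self.years = years or pheno.years
        self.grading = grading
        self.weight_mode = weight_mode
        if indicator not in ("pc_scores", "sfv"):
            raise ValueError(f"unknown indicator mode {indicator!r}")
        self.indicator = indicator
        self.n_components = n_components

    @classmethod
    def from_csv(cls, path, **kwargs) -> "ShadeToleranceEvaluation":
        from .io import read_phenotypes

        return cls(read_phenotypes(path), **kwargs)

    def fit(self) -> EvaluationResults:
        stc_t, sfv_t, dropped_t = {}, {}, {}
        contrib, weights_t, d_t, asfv_t, grades_t, thr_t = {}, {}, {}, {}, {}, {}
        for year in self.years:
            stc = compute_stc(self.pheno, year)
            sfv, dropped = compute_sfv(stc.values)
            p, w, loadings = compute_weights(
                sfv, n_components=self.n_components, mode=self.weight_mode
            )
            if self.indicator == "pc_scores" and self.weight_mode == "pca":
                X = sfv.to_numpy(dtype=float)
                Z = (X - np.nanmean(X, axis=0)) / np.nanstd(X, axis=0, ddof=1)
                Z = np.where(np.isfinite(Z), Z, 0.0)
                indicators = Z @ loadings
            else:
                indicators = sfv.to_numpy(dtype=float)
                if len(w) != indicators.shape[1]:
                    w = np.full(indicators.shape[1], 1.0 / indicators.shape[1])
                    p = w.copy()
            d = pd.Series(compute_d(indicators, w), index=sfv.index, name="d_value")
            asfv = compute_asfv(sfv)
            grades, cuts = grade(asfv, self.grading)
            stc_t[year], sfv_t[year], dropped_t[year] = stc, sfv, dropped
            contrib[year], weights_t[year] = p, w
            d_t[year], asfv_t[year] = d, asfv
            grades_t[year], thr_t[year] = grades, cuts
        return EvaluationResults(
            years=list(self.years),
            stc=stc_t,
            sfv=sfv_t,
            dropped_traits=dropped_t,
            contribution=contrib,
            weights=weights_t,
            d_value=d_t,
            asfv=asfv_t,
            grades=grades_t,
            thresholds=thr_t,
            grading_strategy=self.grading,
        )
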