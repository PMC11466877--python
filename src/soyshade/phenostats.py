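"""Descriptive statistics, genotype x environment ANOVA, broad-sense
heritability and trait correlations for the accession panel.

Skewness and kurtosis use the small-sample bias-corrected (adjusted
Fisher-Pearson / excess) estimators — the convention of mainstream
spreadsheet and statistics packages — via ``scipy.stats`` with
``bias=False``; a ``bias_correction=False`` switch gives the raw moment
ratios.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.formula.api import ols
from statsmodels.stats.anova import anova_lm

from .datatypes import PhenotypeTable


@dataclass
class DescriptiveStats:
    n: int
    max: float
    min: float
    mean: float
    sd: float
    cv_percent: float
    skewness: float
    kurtosis: float


def describe(values, *, bias_correction: bool = True) -> DescriptiveStats:
    """Descriptive statistics of a vector: max, min, mean, sample SD,
    CV (%), skewness and excess kurtosis.

    Sample SD uses n-1; CV = 100*sd/mean (NaN when mean == 0).  Skewness
    needs n >= 3 and kurtosis n >= 4; both are NaN (undefined) below that or
    for constant input.
    """
    x = np.asarray(values, dtype=float)
    x = x[np.isfinite(x)]
    n = x.size
    if n < 2:
        raise ValueError("need at least 2 finite values")
    mean = float(x.mean())
    sd = float(x.std(ddof=1))
    cv = 100.0 * sd / mean if mean != 0 else float("nan")
    if sd == 0:
        skew = kurt = float("nan")
    else:
        skew = float(stats.skew(x, bias=not bias_correction)) if n >= 3 else float("nan")
        kurt = (
            float(stats.kurtosis(x, fisher=True, bias=not bias_correction))
            if n >= 4
            else float("nan")
        )
    return DescriptiveStats(
        n=n,
        max=float(x.max()),
        min=float(x.min()),
        mean=mean,
        sd=sd,
        cv_percent=cv,
        skewness=skew,
        kurtosis=kurt,
    )


def describe_stc(stc_values_by_year: dict[str, pd.DataFrame]) -> pd.DataFrame:
    """Descriptive table (one row per trait x year) of STC values."""
    rows = []
    for year, values in stc_values_by_year.items():
        for trait in values.columns:
            col = values[trait].dropna()
            if len(col) < 2:
                continue
            d = describe(col)
            rows.append(
                {
                    "trait": trait,
                    "year": year,
                    "n": d.n,
                    "max": d.max,
                    "min": d.min,
                    "mean": d.mean,
                    "sd": d.sd,
                    "cv_percent": d.cv_percent,
                    "skewness": d.skewness,
                    "kurtosis": d.kurtosis,
                }
            )
    return pd.DataFrame(rows)


def _is_balanced(df: pd.DataFrame) -> bool:
    counts = df.groupby(["accession", "env"], observed=True).size()
    return counts.nunique() == 1


def anova_gxe(
    pheno: PhenotypeTable,
    trait: str,
    *,
    env: str = "year",
    condition: str | None = "CK",
    typ: int = 1,
) -> pd.DataFrame:
    """Two-factor fixed-effects ANOVA with interaction for one trait.

    Genotype (accession) and environment (``env``: the ``year`` column by
    default, or ``condition``) as crossed factors; plant replicates supply
    the error term.  ``condition`` restricts the data to one light regime
    ("CK"/"shade") when the environment factor is year; ``None`` pools both.

    Balanced data are required for the default type-I decomposition (the
    factors are then orthogonal); pass ``typ=2`` for unbalanced layouts.

    Returns a table with rows G, E, GxE, error and columns ss, df, ms, F, p.
    """
    if env not in ("year", "condition"):
        raise ValueError("env must be 'year' or 'condition'")
    df = pheno.data[pheno.data["trait"] == trait].copy()
    if condition is not None and env == "year":
        df = df[df["condition"] == condition]
    if df.empty:
        raise ValueError(f"no records for trait {trait!r}")
    df["env"] = df[env].astype(str)
    if df["accession"].nunique() < 2 or df["env"].nunique() < 2:
        raise ValueError("need >=2 genotypes and >=2 environments")
    if typ == 1 and not _is_balanced(df):
        raise ValueError(
            "unbalanced replication: pass typ=2 for a type-II decomposition"
        )
    model = ols("value ~ C(accession) * C(env)", data=df).fit()
    table = anova_lm(model, typ=typ)
    rename = {
        "C(accession)": "G",
        "C(env)": "E",
        "C(accession):C(env)": "GxE",
        "Residual": "error",
    }
    out = table.rename(index=rename)
    out = out.loc[["G", "E", "GxE", "error"]]
    result = pd.DataFrame(
        {
            "source": out.index,
            "ss": out["sum_sq"].to_numpy(),
            "df": out["df"].to_numpy(),
        }
    )
    result["ms"] = result["ss"] / result["df"]
    result["F"] = [out.loc[s, "F"] if s != "error" else np.nan for s in result["source"]]
    result["p"] = [
        out.loc[s, "PR(>F)"] if s != "error" else np.nan for s in result["source"]
    ]
    return result.reset_index(drop=True)


@dataclass
class HeritabilityResult:
    h2_percent: float
    var_g: float
    var_gxe: float
    var_error: float
    flag: str | None = None


def heritability(anova: pd.DataFrame, n_env: int, n_rep: int) -> HeritabilityResult:
    """Broad-sense heritability on an entry-mean basis from the G x E ANOVA.

    Variance components from expected mean squares (e environments, r
    replicates): ``s2_e = MS_error``, ``s2_gxe = (MS_GxE - MS_error)/r``,
    ``s2_g = (MS_G - MS_GxE)/(e*r)``, negative estimates truncated at zero;
    then ``H2 = s2_g / (s2_g + s2_gxe/e + s2_e/(e*r)) * 100``.
    """
    ms = anova.set_index("source")["ms"]
    ms_err, ms_gxe, ms_g = ms["error"], ms["GxE"], ms["G"]
    if ms_err == 0 and ms_gxe == 0 and ms_g == 0:
        return HeritabilityResult(0.0, 0.0, 0.0, 0.0, flag="all mean squares zero")
    var_e = float(ms_err)
    var_gxe = max(0.0, (ms_gxe - ms_err) / n_rep)
    var_g = max(0.0, (ms_g - ms_gxe) / (n_env * n_rep))
    denom = var_g + var_gxe / n_env + var_e / (n_env * n_rep)
    if denom == 0:
        # no variance anywhere below G; conventionally fully heritable
        return HeritabilityResult(100.0, var_g, var_gxe, var_e, flag="zero error MS")
    return HeritabilityResult(100.0 * var_g / denom, var_g, var_gxe, var_e)


def heritability_from_phenotypes(
    pheno: PhenotypeTable, trait: str, *, condition: str | None = "CK"
) -> HeritabilityResult:
    """Convenience: ANOVA across years then entry-mean H² for one trait."""
    df = pheno.data
    n_env = df["year"].nunique()
    sub = df[(df["trait"] == trait)]
    if condition is not None:
        sub = sub[sub["condition"] == condition]
    n_rep = int(sub.groupby(["accession", "year"]).size().iloc[0])
    table = anova_gxe(pheno, trait, env="year", condition=condition)
    return heritability(table, n_env=n_env, n_rep=n_rep)


def correlate(
    stc_values_by_year: dict[str, pd.DataFrame], alpha: float = 0.05
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Pearson correlations among trait STCs across years.

    Builds one column per (trait, year) — 12 columns for six traits over two
    years — and computes pairwise-complete Pearson r with p-values.  Returns
    (r, p, stars); stars mark p < ``alpha``, empty where undefined (<3
    complete pairs).
    """
    wide = pd.concat(
        {year: vals for year, vals in stc_values_by_year.items()}, axis=1
    )
    wide.columns = [f"{trait}_{year}" for year, trait in wide.columns]
    cols = list(wide.columns)
    k = len(cols)
    r = np.full((k, k), np.nan)
    p = np.full((k, k), np.nan)
    for i in range(k):
        for j in range(i, k):
            pair = wide[[cols[i], cols[j]]].dropna()
            if len(pair) < 3:
                continue
            if i == j:
                r[i, j] = 1.0
                p[i, j] = 0.0
                continue
            xi, xj = pair.iloc[:, 0], pair.iloc[:, 1]
            if xi.std() == 0 or xj.std() == 0:
                continue
            res = stats.pearsonr(xi, xj)
            r[i, j] = r[j, i] = res.statistic
            p[i, j] = p[j, i] = res.pvalue
    r_df = pd.DataFrame(r, index=cols, columns=cols)
    p_df = pd.DataFrame(p, index=cols, columns=cols)
    stars = p_df.map(lambda v: "*" if (not math.isnan(v)) and v < alpha else "")
    return r_df, p_df, stars
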