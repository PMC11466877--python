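"""Post-association analysis: SNP-id arithmetic, candidate-gene window
queries, allele-effect (haplotype) comparison and favorable-allele counting.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .datatypes import MISSING, GeneAnnotationSet, GenotypeMatrix

_SNP_ID_RE = re.compile(r"^S(\d+)_(\d+)$")


def parse_snp_id(snp_id: str) -> tuple[int, int]:
    """Parse ``S{chrom}_{pos}`` into (chromosome, 1-based position).

    Zero-padded chromosome numbers (``S04_...``) are accepted.
    """
    m = _SNP_ID_RE.match(snp_id)
    if not m:
        raise ValueError(f"malformed SNP id {snp_id!r}; expected S{{chrom}}_{{pos}}")
    return int(m.group(1)), int(m.group(2))


def snp_distance(id_a: str, id_b: str) -> tuple[int, int]:
    """Distance between two SNPs on the same chromosome.

    Returns (bp, kb) with kb rounded half-up to the nearest integer, the
    convention that matches distances quoted in kb in locus reports.
    """
    chrom_a, pos_a = parse_snp_id(id_a)
    chrom_b, pos_b = parse_snp_id(id_b)
    if chrom_a != chrom_b:
        raise ValueError(
            f"{id_a} and {id_b} are on different chromosomes ({chrom_a} vs {chrom_b})"
        )
    bp = abs(pos_a - pos_b)
    return bp, (bp + 500) // 1000


def candidate_genes(
    snp_id: str, annotation: GeneAnnotationSet, window: int = 120_000
) -> pd.DataFrame:
    """Genes whose [start, end] intersects [pos - window, pos + window].

    Both interval ends are inclusive (a gene starting exactly at
    ``pos + window`` is included).  The returned frame carries a ``distance``
    column (0 for genes overlapping the SNP) and is sorted by distance, then
    start.  An annotation without the SNP's chromosome yields an empty frame
    with a warning.
    """
    chrom, pos = parse_snp_id(snp_id)
    genes = annotation.on_chromosome(chrom)
    if genes.empty:
        warnings.warn(f"no genes annotated on chromosome {chrom}", stacklevel=2)
        return genes.assign(distance=pd.Series(dtype=int))
    lo, hi = pos - window, pos + window
    hit = genes[(genes["start"] <= hi) & (genes["end"] >= lo)].copy()
    dist = np.where(
        (hit["start"] <= pos) & (hit["end"] >= pos),
        0,
        np.minimum(np.abs(hit["start"] - pos), np.abs(hit["end"] - pos)),
    )
    hit["distance"] = dist.astype(int)
    return hit.sort_values(["distance", "start"]).reset_index(drop=True)


def _stars(p: float) -> str:
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return "ns"


@dataclass
class AlleleEffect:
    """Two-group allele comparison at one SNP for one trait-year STC."""

    snp_id: str
    alleles: tuple[str, str]  # (ref, alt)
    group_n: dict[str, int]
    group_mean: dict[str, float]
    group_sd: dict[str, float]
    welch_t: float
    p: float
    stars: str
    favorable_allele: str
    favorable_tied: bool
    allele_ratio_percent: dict[str, float]
    r2_percent: float


def allele_effect(
    snp_id: str,
    genotypes: GenotypeMatrix,
    stc: pd.Series,
    *,
    include_heterozygotes: bool = False,
    higher_is_favorable: bool = True,
) -> AlleleEffect:
    """Compare STC between the two homozygote classes at a SNP.

    Accessions are grouped by allele (dosage 0 -> ref homozygotes, dosage 2
    -> alt homozygotes; heterozygotes excluded unless
    ``include_heterozygotes``, which pools each het once into both groups is
    *not* done — instead het dosage 1 joins the alt group).  A Welch
    two-sample t-test compares the groups; the favorable allele is the one
    with the higher mean STC (configurable direction), ties broken to the
    alt allele with a flag.  ``r2_percent`` is the between-group share of the
    total sum of squares; ratios are group percentages among analyzed
    accessions.
    """
    row = genotypes.snps[genotypes.snps["snp_id"] == snp_id]
    if row.empty:
        raise KeyError(f"SNP {snp_id!r} not in genotype matrix")
    ref, alt = row["ref"].iloc[0], row["alt"].iloc[0]
    dose = genotypes.dosage_for(snp_id)
    values = stc.reindex(genotypes.accession_ids).to_numpy(dtype=float)
    usable = (dose != MISSING) & np.isfinite(values)
    if include_heterozygotes:
        in_ref = usable & (dose == 0)
        in_alt = usable & (dose >= 1)
    else:
        in_ref = usable & (dose == 0)
        in_alt = usable & (dose == 2)
    groups = {ref: values[in_ref], alt: values[in_alt]}
    for allele, vals in groups.items():
        if len(vals) < 2:
            raise ValueError(
                f"allele class {allele!r} at {snp_id} has n={len(vals)} < 2"
            )
    a, b = groups[ref], groups[alt]
    t, p = stats.ttest_ind(a, b, equal_var=False)
    mean = {ref: float(a.mean()), alt: float(b.mean())}
    if mean[ref] == mean[alt]:
        favorable, tied = alt, True
    else:
        better = max(mean, key=mean.get) if higher_is_favorable else min(mean, key=mean.get)
        favorable, tied = better, False
    pooled = np.concatenate([a, b])
    grand = pooled.mean()
    ss_between = len(a) * (a.mean() - grand) ** 2 + len(b) * (b.mean() - grand) ** 2
    ss_total = float(((pooled - grand) ** 2).sum())
    r2 = 100.0 * ss_between / ss_total if ss_total > 0 else 0.0
    n_total = len(a) + len(b)
    return AlleleEffect(
        snp_id=snp_id,
        alleles=(ref, alt),
        group_n={ref: len(a), alt: len(b)},
        group_mean=mean,
        group_sd={ref: float(a.std(ddof=1)), alt: float(b.std(ddof=1))},
        welch_t=float(t),
        p=float(p),
        stars=_stars(float(p)),
        favorable_allele=favorable,
        favorable_tied=tied,
        allele_ratio_percent={
            ref: 100.0 * len(a) / n_total,
            alt: 100.0 * len(b) / n_total,
        },
        r2_percent=float(r2),
    )


def count_favorable(
    calls: dict[str, str], favorable: dict[str, str]
) -> tuple[int, list[str]]:
    """Count marker SNPs where an accession carries the favorable allele.

    ``calls`` maps snp_id -> the accession's (homozygous) allele call;
    ``favorable`` maps snp_id -> favorable allele.  Missing or empty calls
    are skipped and reported.  Every favorable-set SNP must appear in the
    calls.
    """
    absent = [s for s in favorable if s not in calls]
    if absent:
        raise KeyError(f"calls missing marker SNPs {absent}")
    skipped = [s for s in favorable if not calls[s] or calls[s] in (".", "N")]
    count = sum(
        1 for s, allele in favorable.items() if s not in skipped and calls[s] == allele
    )
    return count, skipped


def count_favorable_table(
    calls: pd.DataFrame, favorable: dict[str, str]
) -> pd.DataFrame:
    """Vector version: ``calls`` is accessions x marker-SNP allele calls;
    returns per-accession favorable counts and the number of skipped calls."""
    rows = []
    for accession, row in calls.iterrows():
        count, skipped = count_favorable(row.to_dict(), favorable)
        rows.append(
            {"accession": accession, "favorable_count": count, "n_skipped": len(skipped)}
        )
    return pd.DataFrame(rows)
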