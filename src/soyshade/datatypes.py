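"""Core in-memory containers shared across the pipeline.

Conventions used throughout the package:

* genomic coordinates are 1-based and inclusive at both ends (VCF/GFF3 native);
* genotype dosage counts ALT alleles (0 = homozygous reference, 1 =
  heterozygous, 2 = homozygous alternate), with ``MISSING`` (-1) for
  uncalled genotypes — missing values are never imputed at I/O time;
* SNP identifiers follow the ``S{chrom}_{pos}`` convention, e.g.
  ``S11_19943066``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

MISSING = -1

#: The six agronomic traits, in canonical order.  The shade tolerance
#: coefficients STC1..STC6 refer to the traits in this order.
TRAITS = (
    "first_pod_height",
    "plant_height",
    "stem_node_number",
    "pod_number",
    "grain_weight",
    "branch_number",
)

CONDITIONS = ("CK", "shade")


def snp_name(chrom: int, pos: int) -> str:
    """Canonical SNP identifier, ``S{chrom}_{pos}`` with no zero padding."""
    return f"S{int(chrom)}_{int(pos)}"


@dataclass
class GenotypeMatrix:
    """Accessions x biallelic SNPs alt-allele dosage matrix.

    Parameters
    ----------
    accession_ids : list of str
        Unique accession identifiers (rows of ``dosage``).
    snps : pandas.DataFrame
        One row per SNP with columns ``snp_id, chrom, pos, ref, alt``;
        positions strictly increasing within each chromosome.
    dosage : ndarray of int8, shape (n_accessions, n_snps)
        Alt-allele counts in {0, 1, 2}, ``MISSING`` (-1) when uncalled.
    """

    accession_ids: list[str]
    snps: pd.DataFrame
    dosage: np.ndarray

    def __post_init__(self) -> None:
        self.dosage = np.asarray(self.dosage, dtype=np.int8)
        if self.dosage.shape != (len(self.accession_ids), len(self.snps)):
            raise ValueError(
                f"dosage shape {self.dosage.shape} does not match "
                f"{len(self.accession_ids)} accessions x {len(self.snps)} SNPs"
            )
        self.validate()

    @property
    def n_accessions(self) -> int:
        return len(self.accession_ids)

    @property
    def n_snps(self) -> int:
        return len(self.snps)

    @property
    def snp_ids(self) -> pd.Index:
        return pd.Index(self.snps["snp_id"])

    def validate(self) -> None:
        if len(set(self.accession_ids)) != len(self.accession_ids):
            raise ValueError("accession ids are not unique")
        snps = self.snps
        expected = [snp_name(c, p) for c, p in zip(snps["chrom"], snps["pos"])]
        bad = snps.loc[[a != b for a, b in zip(snps["snp_id"], expected)], "snp_id"]
        if len(bad):
            raise ValueError(f"snp_id does not match S{{chrom}}_{{pos}}: {bad.iloc[0]!r}")
        if snps["snp_id"].duplicated().any():
            dup = snps.loc[snps["snp_id"].duplicated(), "snp_id"].iloc[0]
            raise ValueError(f"duplicate SNP id {dup!r}")
        for chrom, grp in snps.groupby("chrom", sort=False):
            if not grp["pos"].is_monotonic_increasing or grp["pos"].duplicated().any():
                raise ValueError(
                    f"positions not strictly increasing on chromosome {chrom}"
                )
        valid = (self.dosage == MISSING) | (
            (self.dosage >= 0) & (self.dosage <= 2)
        )
        if not valid.all():
            raise ValueError("dosage values must be in {0,1,2} or MISSING (-1)")

    def allele_frequency(self) -> np.ndarray:
        """Per-SNP alt-allele frequency over non-missing calls."""
        d = np.ma.masked_equal(self.dosage, MISSING)
        return np.asarray(d.mean(axis=0) / 2.0)

    def maf(self) -> np.ndarray:
        p = self.allele_frequency()
        return np.minimum(p, 1.0 - p)

    def dosage_for(self, snp_id: str) -> np.ndarray:
        """Dosage column for one SNP (int8, MISSING where uncalled)."""
        idx = self.snps.index[self.snps["snp_id"] == snp_id]
        if len(idx) == 0:
            raise KeyError(f"SNP {snp_id!r} not in genotype matrix")
        return self.dosage[:, self.snps.index.get_loc(idx[0])]

    def subset_accessions(self, ids: list[str]) -> "GenotypeMatrix":
        lookup = {a: i for i, a in enumerate(self.accession_ids)}
        rows = [lookup[a] for a in ids]
        return GenotypeMatrix(list(ids), self.snps.copy(), self.dosage[rows])


PHENO_COLUMNS = ("accession", "year", "condition", "replicate", "trait", "value")


@dataclass
class PhenotypeTable:
    """Long-format plant-level trait observations.

    Wraps a DataFrame with columns ``accession, year, condition, replicate,
    trait, value``; one row per measured plant.  The key
    (accession, year, condition, replicate, trait) is unique and values are
    finite and non-negative.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.data
        missing = [c for c in PHENO_COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"phenotype table missing columns {missing}")
        self.data = df = df.loc[:, list(PHENO_COLUMNS)].reset_index(drop=True)
        unknown = set(df["trait"]) - set(TRAITS)
        if unknown:
            raise ValueError(f"unknown trait names {sorted(unknown)}")
        bad_cond = set(df["condition"]) - set(CONDITIONS)
        if bad_cond:
            raise ValueError(f"unknown conditions {sorted(bad_cond)}; expected CK/shade")
        vals = df["value"].to_numpy(dtype=float)
        if not np.isfinite(vals).all():
            raise ValueError("phenotype values must be finite")
        if (vals < 0).any():
            i = int(np.flatnonzero(vals < 0)[0])
            raise ValueError(f"negative phenotype value at row {i}: {vals[i]}")
        key = ["accession", "year", "condition", "replicate", "trait"]
        dup = df.duplicated(subset=key)
        if dup.any():
            k = df.loc[dup, key].iloc[0].tolist()
            raise ValueError(f"duplicate phenotype key {tuple(k)}")

    @property
    def accessions(self) -> list[str]:
        return sorted(self.data["accession"].unique())

    @property
    def years(self) -> list[str]:
        return sorted(self.data["year"].unique())

    def condition_means(self) -> pd.DataFrame:
        """Replicate means per (accession, year, condition, trait)."""
        return (
            self.data.groupby(["accession", "year", "condition", "trait"], sort=True)[
                "value"
            ]
            .mean()
            .reset_index()
        )


@dataclass
class GeneAnnotationSet:
    """Gene records from a GFF3: 1-based inclusive [start, end] intervals."""

    genes: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(
            columns=["gene_id", "chrom", "start", "end", "strand", "annotation"]
        )
    )

    def __post_init__(self) -> None:
        df = self.genes
        if len(df):
            if (df["start"] > df["end"]).any():
                bad = df.loc[df["start"] > df["end"]].iloc[0]
                raise ValueError(
                    f"gene {bad['gene_id']!r} has start {bad['start']} > end {bad['end']}"
                )
            if df["gene_id"].duplicated().any():
                dup = df.loc[df["gene_id"].duplicated(), "gene_id"].iloc[0]
                raise ValueError(f"duplicate gene id {dup!r}")

    def __len__(self) -> int:
        return len(self.genes)

    def on_chromosome(self, chrom: int) -> pd.DataFrame:
        return self.genes[self.genes["chrom"] == chrom]
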