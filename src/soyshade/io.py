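"""Readers and writers for the standard formats the pipeline touches.

VCF (GT subset), GFF3 gene rows, the long-format phenotype CSV schema and
TSV result tables.  Dosage counts ALT alleles; ``./.`` becomes the missing
sentinel and is never imputed here.
"""

from __future__ import annotations

import re
from pathlib import Path

import numpy as np
import pandas as pd
from cyvcf2 import VCF

from .datatypes import (
    CONDITIONS,
    MISSING,
    PHENO_COLUMNS,
    TRAITS,
    GeneAnnotationSet,
    GenotypeMatrix,
    PhenotypeTable,
    snp_name,
)


class ParseError(ValueError):
    """Raised when an input file violates its format contract."""


_CHROM_RE = re.compile(r"^(?:chr)?0*(\d+)$", re.IGNORECASE)


def _chrom_to_int(chrom: str, record: int) -> int:
    m = _CHROM_RE.match(chrom)
    if not m:
        raise ParseError(f"record {record}: non-numeric chromosome {chrom!r}")
    return int(m.group(1))


def read_vcf(path: str | Path, *, skip_non_biallelic_snp: bool = True) -> GenotypeMatrix:
    """Read a VCF with GT fields into a :class:`GenotypeMatrix`.

    Parameters
    ----------
    path : str or Path
        Uncompressed or bgzipped VCF.
    skip_non_biallelic_snp : bool
        If True (default) multiallelic or non-SNP records are skipped;
        if False they raise :class:`ParseError`.

    Dosage is the per-genotype count of ALT alleles; ``./.`` maps to the
    missing sentinel.  SNP ids are synthesized as ``S{chrom}_{pos}``.
    """
    path = Path(path)
    try:
        vcf = VCF(str(path))
    except Exception as exc:  # cyvcf2 raises bare Exception on bad headers
        raise ParseError(f"{path}: cannot parse VCF header: {exc}") from exc
    samples = list(vcf.samples)
    if not samples:
        raise ParseError(f"{path}: VCF has no sample columns")
    rows, dosage_cols = [], []
    seen: dict[int, int] = {}
    for i, rec in enumerate(vcf, start=1):
        is_snp = (
            len(rec.ALT) == 1
            and len(rec.REF) == 1
            and len(rec.ALT[0]) == 1
            and set(rec.REF + rec.ALT[0]) <= set("ACGT")
        )
        if not is_snp:
            if skip_non_biallelic_snp:
                continue
            raise ParseError(
                f"record {i} ({rec.CHROM}:{rec.POS}): not a biallelic SNP"
            )
        chrom = _chrom_to_int(rec.CHROM, i)
        if seen.get(chrom) == rec.POS:
            raise ParseError(
                f"record {i}: duplicate position {rec.POS} on chromosome {chrom}"
            )
        seen[chrom] = rec.POS
        # gt_types: 0=hom-ref, 1=het, 2=hom-alt (with gts012), 3=missing
        gts = np.asarray(rec.genotype.array())[:, :2]
        dose = np.where((gts < 0).any(axis=1), MISSING, (gts > 0).sum(axis=1))
        rows.append((snp_name(chrom, rec.POS), chrom, rec.POS, rec.REF, rec.ALT[0]))
        dosage_cols.append(dose.astype(np.int8))
    snps = pd.DataFrame(rows, columns=["snp_id", "chrom", "pos", "ref", "alt"])
    dosage = (
        np.column_stack(dosage_cols)
        if dosage_cols
        else np.empty((len(samples), 0), dtype=np.int8)
    )
    return GenotypeMatrix(samples, snps, dosage)


def write_vcf(geno: GenotypeMatrix, path: str | Path) -> Path:
    """Write a minimal VCF 4.2 (CHROM/POS/REF/ALT/GT) for the matrix."""
    path = Path(path)
    gt_strings = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for chrom, grp in geno.snps.groupby("chrom", sort=True):
            fh.write(f"##contig=<ID={chrom},length={int(grp['pos'].max()) + 1}>\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(geno.accession_ids)
            + "\n"
        )
        for j, snp in geno.snps.iterrows():
            col = geno.dosage[:, geno.snps.index.get_loc(j)]
            gts = "\t".join(gt_strings[int(d)] for d in col)
            fh.write(
                f"{snp['chrom']}\t{snp['pos']}\t{snp['snp_id']}\t{snp['ref']}\t"
                f"{snp['alt']}\t.\tPASS\t.\tGT\t{gts}\n"
            )
    return path


def read_phenotypes(path: str | Path) -> PhenotypeTable:
    """Read the long-format phenotype CSV (accession, year, condition,
    replicate, trait, value).  Condition is case-folded to CK/shade."""
    path = Path(path)
    df = pd.read_csv(path, dtype={"accession": str, "year": str})
    missing = [c for c in PHENO_COLUMNS if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing columns {missing}")
    folded = df["condition"].astype(str).str.strip().str.lower()
    df["condition"] = folded.map({"ck": "CK", "shade": "shade"}).fillna(df["condition"])
    bad = set(df["condition"]) - set(CONDITIONS)
    if bad:
        raise ParseError(f"{path}: unknown condition labels {sorted(bad)}")
    unknown = set(df["trait"].astype(str)) - set(TRAITS)
    if unknown:
        raise ParseError(
            f"{path}: unknown trait names {sorted(unknown)}; expected {TRAITS}"
        )
    try:
        return PhenotypeTable(df)
    except ValueError as exc:
        raise ParseError(f"{path}: {exc}") from exc


def write_phenotypes(pheno: PhenotypeTable, path: str | Path) -> Path:
    path = Path(path)
    pheno.data.to_csv(path, index=False)
    return path


def read_gff3(path: str | Path) -> GeneAnnotationSet:
    """Ingest rows of type ``gene`` from a GFF3 into a GeneAnnotationSet.

    Coordinates stay 1-based inclusive as in GFF3.  Other feature types
    (mRNA, exon, ...) are ignored.
    """
    path = Path(path)
    rows = []
    with open(path) as fh:
        for ln, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) != 9:
                raise ParseError(f"{path}:{ln}: expected 9 GFF3 columns, got {len(parts)}")
            seqid, _source, ftype, start, end, _score, strand, _phase, attrs = parts
            if ftype != "gene":
                continue
            start_i, end_i = int(start), int(end)
            if start_i > end_i:
                raise ParseError(f"{path}:{ln}: start {start_i} > end {end_i}")
            attr_map = dict(
                kv.split("=", 1) for kv in attrs.split(";") if "=" in kv
            )
            gene_id = attr_map.get("ID") or attr_map.get("gene_id") or f"gene_{ln}"
            rows.append(
                (
                    gene_id,
                    _chrom_to_int(seqid, ln),
                    start_i,
                    end_i,
                    strand if strand in "+-" else "+",
                    attr_map.get("Note", attr_map.get("description", "")),
                )
            )
    genes = pd.DataFrame(
        rows, columns=["gene_id", "chrom", "start", "end", "strand", "annotation"]
    )
    return GeneAnnotationSet(genes)


def write_gff3(annot: GeneAnnotationSet, path: str | Path) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for _, g in annot.genes.iterrows():
            note = f";Note={g['annotation']}" if g["annotation"] else ""
            fh.write(
                f"{g['chrom']}\tsoyshade\tgene\t{g['start']}\t{g['end']}\t.\t"
                f"{g['strand']}\t.\tID={g['gene_id']}{note}\n"
            )
    return path


def read_flanks_fasta(path: str | Path) -> dict[str, tuple[str, str]]:
    """Read SNP flanking sequences from FASTA records named
    ``{snp_id}|left`` / ``{snp_id}|right``."""
    from Bio.SeqIO.FastaIO import SimpleFastaParser

    sides: dict[str, dict[str, str]] = {}
    with open(path) as fh:
        for title, seq in SimpleFastaParser(fh):
            name = title.split()[0]
            if "|" not in name:
                raise ParseError(f"{path}: record {name!r} not named snp_id|left/right")
            snp_id, side = name.rsplit("|", 1)
            if side not in ("left", "right"):
                raise ParseError(f"{path}: record {name!r} has side {side!r}")
            sides.setdefault(snp_id, {})[side] = seq.upper()
    out = {}
    for snp_id, d in sides.items():
        if set(d) != {"left", "right"}:
            raise ParseError(f"{path}: {snp_id} missing a flank side")
        out[snp_id] = (d["left"], d["right"])
    return out


def write_flanks_fasta(flanks: dict[str, tuple[str, str]], path: str | Path) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        for snp_id, (left, right) in flanks.items():
            fh.write(f">{snp_id}|left\n{left}\n>{snp_id}|right\n{right}\n")
    return path


#: columns rendered in scientific notation when writing result tables
_SCI_COLUMNS = {"p", "p_value", "welch_p"}


def write_results(
    table: pd.DataFrame,
    path: str | Path,
    *,
    float_precision: int = 6,
    allow_empty: bool = True,
) -> Path:
    """Write a result table as TSV with a stable column order.

    Floats are written at fixed precision; p-value columns in scientific
    notation.  An empty table produces a header-only file unless
    ``allow_empty`` is False.
    """
    path = Path(path)
    if not allow_empty and table.empty:
        raise ValueError(f"refusing to write empty table to {path}")
    out = table.copy()
    for col in out.columns:
        if pd.api.types.is_float_dtype(out[col]):
            fmt = "{:.3e}" if col in _SCI_COLUMNS else f"{{:.{float_precision}f}}"
            out[col] = out[col].map(lambda v: "" if pd.isna(v) else fmt.format(v))
    out.to_csv(path, sep="\t", index=False)
    return path
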