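"""End-to-end orchestration: simulate (optional) -> phenotype stats ->
shade-tolerance evaluation -> GWAS per phenotype set -> post-GWAS ->
KASP assembly for top SNPs, with a manifest recording the seed and
per-stage row counts."""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .datatypes import GeneAnnotationSet, GenotypeMatrix, PhenotypeTable
from .evaluation import ShadeToleranceEvaluation
from .gwas import MLMGWAS, kinship_vanraden, summarize_significant
from .io import (
    read_flanks_fasta,
    read_gff3,
    read_phenotypes,
    read_vcf,
    write_flanks_fasta,
    write_gff3,
    write_phenotypes,
    write_results,
    write_vcf,
)
from .kasp import assay_from_flank, validate_assay
from .phenostats import correlate, describe_stc, heritability_from_phenotypes
from .postgwas import candidate_genes
from .simulate import (
    QTLSpec,
    SimulationConfig,
    simulate_annotation,
    simulate_flanks,
    simulate_genotypes,
    simulate_phenotypes,
)

log = logging.getLogger("soyshade")


@dataclass
class PipelineConfig:
    """Declarative run configuration; flags on the CLI override fields."""

    outdir: str = "soyshade_run"
    vcf: str | None = None
    pheno: str | None = None
    gff: str | None = None
    flanks: str | None = None
    simulate: bool = True
    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    grading: str = "quantile"
    weight_mode: str = "pca"
    threshold: float = 5.0
    maf: float = 0.05
    p3d: bool = True
    pcs: int = 0
    window: int = 120_000
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        sim = raw.pop("simulation", {})
        cfg = cls(**raw)
        if sim:
            qtls = [QTLSpec(**q) for q in sim.pop("qtls", [])]
            if "maf_range" in sim:
                sim["maf_range"] = tuple(sim["maf_range"])
            if "traits" in sim:
                sim["traits"] = tuple(sim["traits"])
            cfg.simulation = SimulationConfig(qtls=qtls, **sim)
        cfg.simulation.seed = cfg.seed
        return cfg


def _pc_covariates(K: np.ndarray, k: int) -> np.ndarray | None:
    if k <= 0:
        return None
    w, U = np.linalg.eigh(K)
    return U[:, np.argsort(w)[::-1][:k]]


def run_pipeline(config: PipelineConfig) -> Path:
    """Run every stage in order and return the output directory.

    Re-running with the same config is bit-identical: all randomness flows
    from ``config.seed``.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"version": __version__, "seed": config.seed, "stages": {}}

    if config.simulate:
        sim = config.simulation
        geno = simulate_genotypes(sim)
        pheno = simulate_phenotypes(geno, sim)
        annot = simulate_annotation(sim)
        flanks = simulate_flanks(geno, seed=sim.seed)
        write_vcf(geno, outdir / "genotypes.vcf")
        write_phenotypes(pheno, outdir / "phenotypes.csv")
        write_gff3(annot, outdir / "genes.gff3")
        write_flanks_fasta(flanks, outdir / "flanks.fa")
        manifest["stages"]["simulate"] = {
            "n_accessions": geno.n_accessions,
            "n_snps": geno.n_snps,
            "n_pheno_rows": len(pheno.data),
            "n_genes": len(annot),
        }
    else:
        for name, path in [("pheno", config.pheno), ("vcf", config.vcf)]:
            if path is None or not Path(path).exists():
                raise FileNotFoundError(f"pipeline input {name!r} missing: {path}")
        geno = read_vcf(config.vcf)
        pheno = read_phenotypes(config.pheno)
        annot = read_gff3(config.gff) if config.gff else GeneAnnotationSet()
        flanks = read_flanks_fasta(config.flanks) if config.flanks else {}
    log.info("inputs ready: %d accessions, %d SNPs", geno.n_accessions, geno.n_snps)

    # --- evaluation -----------------------------------------------------
    results = ShadeToleranceEvaluation(
        pheno, grading=config.grading, weight_mode=config.weight_mode
    ).fit()
    for year in results.years:
        write_results(results.per_accession(year), outdir / f"evaluation_{year}.tsv")
    thresholds = {y: results.thresholds[y].tolist() for y in results.years}
    (outdir / "grade_thresholds.json").write_text(json.dumps(thresholds, indent=2))
    manifest["stages"]["evaluate"] = {
        "years": results.years,
        "hst_per_year": {y: int((results.grades[y] == "HST").sum()) for y in results.years},
    }

    # --- phenotype statistics -------------------------------------------
    stc_by_year = {y: results.stc[y].values for y in results.years}
    write_results(describe_stc(stc_by_year), outdir / "stc_descriptives.tsv")
    r_df, p_df, _ = correlate(stc_by_year)
    r_df.to_csv(outdir / "stc_correlations.tsv", sep="\t")
    herit = {}
    for trait in stc_by_year[results.years[0]].columns:
        try:
            herit[trait] = heritability_from_phenotypes(pheno, trait).h2_percent
        except ValueError:
            herit[trait] = float("nan")
    (outdir / "heritability.json").write_text(json.dumps(herit, indent=2))
    manifest["stages"]["stats"] = {"n_traits": len(herit)}

    # --- GWAS per phenotype set ------------------------------------------
    K = kinship_vanraden(geno)
    covars = _pc_covariates(K, config.pcs)
    means = pheno.condition_means()
    gwas_tables: dict[tuple[str, str], pd.DataFrame] = {}
    n_runs = 0
    for year in results.years:
        sets: dict[str, pd.Series] = {}
        for cond in ("CK", "shade"):
            sub = means[(means["year"] == year) & (means["condition"] == cond)]
            for trait, grp in sub.groupby("trait"):
                sets[f"{trait}_{cond}"] = grp.set_index("accession")["value"]
        for trait in results.stc[year].values.columns:
            sets[f"{trait}_STC"] = results.stc[year].values[trait]
        for name, y in sets.items():
            y = y.reindex(geno.accession_ids)
            if y.isna().any():
                log.warning("skipping %s/%s: incomplete phenotype", name, year)
                continue
            model = MLMGWAS(
                y, geno, kinship=K, covariates=covars,
                maf_threshold=config.maf, trait=name, year=year,
            )
            res = model.fit(p3d=config.p3d, threshold=config.threshold)
            gwas_tables[(name, year)] = res.table
            write_results(res.table, outdir / f"gwas_{name}_{year}.tsv")
            n_runs += 1
    summary = summarize_significant(gwas_tables, config.threshold)
    write_results(summary, outdir / "gwas_summary.tsv")
    manifest["stages"]["gwas"] = {
        "n_runs": n_runs,
        "n_significant_total": int(summary["n_significant"].sum()),
    }

    # --- post-GWAS: candidate genes for top STC SNPs ----------------------
    top_snps: list[str] = []
    for (name, year), table in gwas_tables.items():
        if not name.endswith("_STC"):
            continue
        sig = table[table["neglog10p"] >= config.threshold]
        if len(sig):
            top_snps.append(sig.loc[sig["neglog10p"].idxmax(), "snp_id"])
    top_snps = sorted(set(top_snps))
    gene_rows = []
    for snp_id in top_snps:
        hits = candidate_genes(snp_id, annot, window=config.window)
        for _, g in hits.iterrows():
            gene_rows.append({"snp_id": snp_id, **g.to_dict()})
    genes_df = pd.DataFrame(gene_rows)
    write_results(
        genes_df if len(genes_df) else pd.DataFrame(columns=["snp_id", "gene_id"]),
        outdir / "candidate_genes.tsv",
    )
    manifest["stages"]["postgwas"] = {
        "top_snps": top_snps,
        "n_candidate_genes": len(genes_df),
    }

    # --- KASP assembly for the top SNPs ----------------------------------
    kasp_rows = []
    rng = np.random.default_rng(config.seed + 9)
    for snp_id in top_snps:
        if snp_id not in flanks:
            continue
        row = geno.snps[geno.snps["snp_id"] == snp_id].iloc[0]
        left, right = flanks[snp_id]
        # common reverse primer: reverse complement downstream of the SNP
        comp = str.maketrans("ACGT", "TGCA")
        start = int(rng.integers(2, max(3, len(right) - 22)))
        reverse = right[start : start + 22].translate(comp)[::-1]
        assay = assay_from_flank(snp_id, left, row["ref"], row["alt"], reverse)
        report = validate_assay(assay)
        for sid, which, seq in assay.to_rows():
            kasp_rows.append(
                {"snp_id": sid, "primer": which, "sequence": seq,
                 "all_pass": report.all_pass}
            )
    write_results(
        pd.DataFrame(kasp_rows)
        if kasp_rows
        else pd.DataFrame(columns=["snp_id", "primer", "sequence"]),
        outdir / "kasp_primers.tsv",
    )
    manifest["stages"]["kasp"] = {"n_assays": len(kasp_rows) // 3}

    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    log.info("pipeline complete: %s", outdir)
    return outdir


def manifest_of(outdir: str | Path) -> dict:
    return json.loads((Path(outdir) / "manifest.json").read_text())


def _listify(obj):
    if isinstance(obj, dict):
        return {k: _listify(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_listify(v) for v in obj]
    return obj


def config_to_yaml(config: PipelineConfig, path: str | Path) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        yaml.safe_dump(_listify(asdict(config)), fh, sort_keys=False)
    return path
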