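"""Synthetic accession panels with the statistical structure the analysis
pipeline assumes.

The generator emulates a shade-tolerance field trial: a panel of accessions
grown under full light (CK) and under a shading net, over several years,
with ~10 measured plants per accession x condition x year.  Trait values are
log-normal around an accession mean; QTLs act *multiplicatively on the
shade/CK ratio*, so a planted QTL shows up in the shade tolerance
coefficient (STC = shade mean / CK mean) and not in the control trait.

Generative model for one trait ``j`` (all effects on the log scale)::

    log CK(i,j,y,r)    = log(baseline_j) + g_ij + u_ijy + e
    log shade(i,j,y,r) = log CK mean     + log(S_j) + sum_q d_iq*log(rho_q)
                         + eta_ijy + e

with ``g ~ N(0, var_g)`` the genotypic value, ``u ~ N(0, var_gxe)`` the
accession x year effect, ``eta ~ N(0, var_shade_response)`` the accession x
year noise on the shade response, ``e ~ N(0, var_residual)`` the plant-level
residual, ``S_j`` the base shade multiplier of the trait (>1 for the two
height traits, <1 for the rest) and ``rho_q`` the ratio effect of QTL ``q``
per alt allele.

``var_g`` is derived from a target entry-mean broad-sense heritability
``H² = var_g / (var_g + var_gxe/e + var_residual/(e*r))`` so that the
heritability the phenotype-statistics module estimates from the simulated
trial recovers the configured value.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .datatypes import TRAITS, GeneAnnotationSet, GenotypeMatrix, PhenotypeTable, snp_name

#: Base shade/CK multiplier per trait: shade elongates the two height traits
#: and depresses node, pod, grain-weight and branch counts.
DEFAULT_SHADE_MULTIPLIERS = {
    "first_pod_height": 1.75,
    "plant_height": 1.90,
    "stem_node_number": 0.95,
    "pod_number": 0.90,
    "grain_weight": 0.93,
    "branch_number": 0.90,
}

#: Plausible CK trait means (cm, counts, g) for the baseline.
DEFAULT_BASELINES = {
    "first_pod_height": 12.0,
    "plant_height": 80.0,
    "stem_node_number": 15.0,
    "pod_number": 45.0,
    "grain_weight": 18.0,
    "branch_number": 3.5,
}


@dataclass(frozen=True)
class QTLSpec:
    """A planted QTL: multiplicative effect on the shade/CK ratio.

    ``ratio_effect`` multiplies the shade/CK ratio once per alt allele, so a
    dosage-2 accession has its ratio scaled by ``ratio_effect ** 2``.
    """

    snp_index: int
    trait: str
    ratio_effect: float

    def __post_init__(self) -> None:
        if self.trait not in TRAITS:
            raise ValueError(f"unknown QTL trait {self.trait!r}")
        if self.ratio_effect <= 0:
            raise ValueError("ratio_effect must be positive")


@dataclass
class SimulationConfig:
    """Panel dimensions, variance structure and planted QTLs."""

    n_accessions: int = 264
    n_chrom: int = 20
    chrom_length_bp: int = 50_000_000
    n_snps: int = 2_000
    maf_range: tuple[float, float] = (0.05, 0.5)
    missing_rate: float = 0.0
    qtls: list[QTLSpec] = field(default_factory=list)
    heritability: float = 0.40
    var_gxe: float = 0.12
    var_residual: float = 0.20
    var_shade_response: float = 0.12
    n_replicates: int = 10
    n_years: int = 2
    traits: tuple[str, ...] = TRAITS
    shade_multipliers: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_SHADE_MULTIPLIERS)
    )
    baselines: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_BASELINES))
    branch_zero_fraction: float = 0.0
    gene_spacing_bp: int = 50_000
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.maf_range
        if not (0 < lo <= hi <= 0.5):
            raise ValueError(f"maf_range must be within (0, 0.5], got {self.maf_range}")
        for name, v in [
            ("var_gxe", self.var_gxe),
            ("var_residual", self.var_residual),
            ("var_shade_response", self.var_shade_response),
        ]:
            if v < 0:
                raise ValueError(f"{name} must be >= 0")
        if not 0 <= self.heritability < 1:
            raise ValueError("heritability must be in [0, 1)")
        if not 0 <= self.branch_zero_fraction <= 1:
            raise ValueError("branch_zero_fraction must be in [0, 1]")
        for q in self.qtls:
            if not 0 <= q.snp_index < self.n_snps:
                raise ValueError(f"QTL snp_index {q.snp_index} out of range")
            if q.trait not in self.traits:
                raise ValueError(f"QTL trait {q.trait!r} not among simulated traits")
        unknown = set(self.traits) - set(TRAITS)
        if unknown:
            raise ValueError(f"unknown traits {sorted(unknown)}")

    @property
    def years(self) -> list[str]:
        return [f"E{k + 1}" for k in range(self.n_years)]

    @property
    def var_genotype(self) -> float:
        """Genotypic log-variance implied by the target entry-mean H²."""
        h2 = self.heritability
        noise = self.var_gxe / self.n_years + self.var_residual / (
            self.n_years * self.n_replicates
        )
        return h2 / (1.0 - h2) * noise

    def stc_noise_variance(self) -> float:
        """Approximate non-QTL variance of log STC for one trait-year.

        The accession x year shade-response term enters once; plant-level
        residuals enter through both replicate means (2 * var / r on the log
        scale, to first order).
        """
        return self.var_shade_response + 2.0 * self.var_residual / self.n_replicates


def ratio_effect_for_variance_fraction(
    target_fraction: float, dosage_variance: float, config: SimulationConfig
) -> float:
    """Ratio effect making a QTL explain ``target_fraction`` of log-STC variance.

    Solves ``beta^2 * var(dosage) / (beta^2 * var(dosage) + noise) = f`` for
    the per-allele log effect ``beta`` and returns ``exp(beta)``.
    """
    if not 0 < target_fraction < 1:
        raise ValueError("target_fraction must be in (0, 1)")
    if dosage_variance <= 0:
        raise ValueError("dosage_variance must be positive")
    noise = config.stc_noise_variance()
    beta = math.sqrt(target_fraction / (1.0 - target_fraction) * noise / dosage_variance)
    return math.exp(beta)


def simulate_genotypes(config: SimulationConfig) -> GenotypeMatrix:
    """Unlinked biallelic SNPs: per-SNP alt frequency uniform in
    ``maf_range``, dosages binomial(2, p) per accession."""
    if config.n_snps < 1:
        raise ValueError("n_snps must be >= 1")
    rng = np.random.default_rng(config.seed)
    per_chrom = np.full(config.n_chrom, config.n_snps // config.n_chrom)
    per_chrom[: config.n_snps % config.n_chrom] += 1
    if per_chrom.max() > config.chrom_length_bp:
        raise ValueError("n_snps exceeds available positions")
    rows = []
    bases = np.array(list("ACGT"))
    for chrom0, k in enumerate(per_chrom):
        pos = np.sort(
            rng.choice(config.chrom_length_bp, size=int(k), replace=False) + 1
        )
        for p in pos:
            ref, alt = rng.choice(4, size=2, replace=False)
            rows.append(
                (snp_name(chrom0 + 1, p), chrom0 + 1, int(p), bases[ref], bases[alt])
            )
    snps = pd.DataFrame(rows, columns=["snp_id", "chrom", "pos", "ref", "alt"])
    freqs = rng.uniform(config.maf_range[0], config.maf_range[1], size=config.n_snps)
    dosage = rng.binomial(2, freqs, size=(config.n_accessions, config.n_snps)).astype(
        np.int8
    )
    if config.missing_rate > 0:
        mask = rng.random(dosage.shape) < config.missing_rate
        dosage[mask] = -1
    accession_ids = [f"NPS{i + 1:03d}" for i in range(config.n_accessions)]
    return GenotypeMatrix(accession_ids, snps, dosage)


def simulate_phenotypes(
    genotypes: GenotypeMatrix, config: SimulationConfig
) -> PhenotypeTable:
    """Plant-level trait observations under CK and shade for every year.

    Deterministic given ``config.seed``; all values strictly positive except
    for the optional zero-inflated shade branch counts.
    """
    rng = np.random.default_rng(config.seed + 1)
    n = config.n_accessions
    if genotypes.n_accessions != n:
        raise ValueError("genotype matrix size does not match config.n_accessions")
    sd_g = math.sqrt(config.var_genotype)
    sd_gxe = math.sqrt(config.var_gxe)
    sd_eta = math.sqrt(config.var_shade_response)
    sd_e = math.sqrt(config.var_residual)
    reps = np.arange(1, config.n_replicates + 1)
    qtl_by_trait: dict[str, list[QTLSpec]] = {}
    for q in config.qtls:
        qtl_by_trait.setdefault(q.trait, []).append(q)

    frames = []
    for trait in config.traits:
        base = math.log(config.baselines[trait])
        log_s = math.log(config.shade_multipliers[trait])
        g = rng.normal(0.0, sd_g, size=n)
        qtl_shift = np.zeros(n)
        for q in qtl_by_trait.get(trait, ()):
            dose = genotypes.dosage[:, q.snp_index].astype(float)
            dose[dose < 0] = np.nan
            dose = np.where(np.isnan(dose), np.nanmean(dose), dose)
            qtl_shift += dose * math.log(q.ratio_effect)
        for year in config.years:
            u = rng.normal(0.0, sd_gxe, size=n)
            eta = rng.normal(0.0, sd_eta, size=n)
            log_ck_mean = base + g + u
            log_shade_mean = log_ck_mean + log_s + qtl_shift + eta
            for cond, log_mean in (("CK", log_ck_mean), ("shade", log_shade_mean)):
                noise = rng.normal(0.0, sd_e, size=(n, config.n_replicates))
                vals = np.exp(log_mean[:, None] + noise)
                if (
                    cond == "shade"
                    and trait == "branch_number"
                    and config.branch_zero_fraction > 0
                ):
                    zero = rng.random(vals.shape) < config.branch_zero_fraction
                    vals = np.where(zero, 0.0, vals)
                frames.append(
                    pd.DataFrame(
                        {
                            "accession": np.repeat(
                                genotypes.accession_ids, config.n_replicates
                            ),
                            "year": year,
                            "condition": cond,
                            "replicate": np.tile(reps, n),
                            "trait": trait,
                            "value": vals.ravel(),
                        }
                    )
                )
    return PhenotypeTable(pd.concat(frames, ignore_index=True))


def simulate_annotation(config: SimulationConfig) -> GeneAnnotationSet:
    """Non-overlapping genes tiled every ``gene_spacing_bp`` along each
    chromosome, so any ±120 kb window at default spacing contains genes."""
    if config.gene_spacing_bp < 2_000:
        raise ValueError("gene_spacing_bp too small for non-overlapping genes")
    rng = np.random.default_rng(config.seed + 2)
    rows = []
    for chrom in range(1, config.n_chrom + 1):
        n_genes = config.chrom_length_bp // config.gene_spacing_bp
        if n_genes == 0:
            raise ValueError(
                f"chromosome length {config.chrom_length_bp} incompatible with "
                f"gene spacing {config.gene_spacing_bp}"
            )
        for k in range(n_genes):
            slot = k * config.gene_spacing_bp
            length = int(rng.integers(1_500, min(8_000, config.gene_spacing_bp - 1)))
            start = slot + int(
                rng.integers(1, max(2, config.gene_spacing_bp - length))
            )
            strand = "+" if rng.random() < 0.5 else "-"
            rows.append(
                (
                    f"Gene.{chrom:02d}G{k + 1:05d}",
                    chrom,
                    start,
                    start + length - 1,
                    strand,
                    "simulated gene model",
                )
            )
    genes = pd.DataFrame(
        rows, columns=["gene_id", "chrom", "start", "end", "strand", "annotation"]
    )
    return GeneAnnotationSet(genes)


def simulate_flanks(
    genotypes: GenotypeMatrix, flank_len: int = 50, seed: int = 0
) -> dict[str, tuple[str, str]]:
    """Random ACGT flanking sequences of ``flank_len`` per side of each SNP."""
    if flank_len < 20:
        raise ValueError("flank_len must be >= 20 (KASP core extraction needs 20 nt)")
    rng = np.random.default_rng(seed + 3)
    bases = np.array(list("ACGT"))
    out = {}
    for snp_id in genotypes.snps["snp_id"]:
        seqs = bases[rng.integers(0, 4, size=2 * flank_len)]
        out[snp_id] = (
            "".join(seqs[:flank_len]),
            "".join(seqs[flank_len:]),
        )
    return out


def with_planted_qtl(
    config: SimulationConfig,
    genotypes: GenotypeMatrix,
    trait: str,
    target_fraction: float,
    snp_index: int | None = None,
) -> SimulationConfig:
    """Return a config with one QTL planted to explain ``target_fraction`` of
    the trait's log-STC variance, sized from the realized dosage variance.

    If ``snp_index`` is None the most informative SNP (highest dosage
    variance) is used.
    """
    dos = genotypes.dosage.astype(float)
    dos[dos < 0] = np.nan
    var = np.nanvar(dos, axis=0)
    idx = int(np.nanargmax(var)) if snp_index is None else int(snp_index)
    rho = ratio_effect_for_variance_fraction(target_fraction, float(var[idx]), config)
    return replace(config, qtls=list(config.qtls) + [QTLSpec(idx, trait, rho)])
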