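"""KASP (competitive allele-specific PCR) assay assembly and validation.

A KASP assay genotypes one SNP with two tailed forward primers and one
common reverse primer.  Each forward primer is the fluorophore tail, a
shared core ending one base 5' of the SNP, and the allele base at the 3'
end; the FAM- and HEX-tailed forwards differ only in tail and final base::

    F1 = FAM_TAIL + core + fam_allele
    F2 = HEX_TAIL + core + hex_allele

The FAM/HEX-to-allele assignment is the caller's choice (no fixed ref/alt
rule exists in practice), and the common reverse primer is accepted as an
input.  Design is on the strand of the provided flank; for a minus-strand
design pass the reverse-complemented flank.
"""

from __future__ import annotations

from dataclasses import dataclass, field

FAM_TAIL = "GAAGGTGACCAAGTTCATGCT"
HEX_TAIL = "GAAGGTCGGAGTCAACGGATT"

_BASES = set("ACGT")


def extract_core(left_flank: str, core_len: int = 20) -> str:
    """The ``core_len`` bases immediately 5' of the SNP, uppercased.

    ``left_flank`` must end at the base adjacent to the SNP position.
    """
    seq = left_flank.upper()
    if len(seq) < core_len:
        raise ValueError(
            f"flank length {len(seq)} shorter than core length {core_len}"
        )
    core = seq[-core_len:]
    if not set(core) <= _BASES:
        raise ValueError(f"non-ACGT characters in flank: {set(core) - _BASES}")
    return core


def wallace_tm(seq: str) -> float:
    """Wallace-rule melting temperature, 2(A+T) + 4(G+C); a reported
    metric only, never a filter."""
    seq = seq.upper()
    at = sum(seq.count(b) for b in "AT")
    gc = sum(seq.count(b) for b in "GC")
    return 2.0 * at + 4.0 * gc


@dataclass
class KASPAssay:
    """Assembled primer triplet for one SNP."""

    snp_id: str
    core: str
    fam_allele: str
    hex_allele: str
    reverse: str
    f1: str = field(init=False)
    f2: str = field(init=False)

    def __post_init__(self) -> None:
        self.core = self.core.upper()
        self.fam_allele = self.fam_allele.upper()
        self.hex_allele = self.hex_allele.upper()
        self.reverse = self.reverse.upper()
        if not self.core or not set(self.core) <= _BASES:
            raise ValueError(f"invalid core sequence {self.core!r}")
        for name, a in (("fam_allele", self.fam_allele), ("hex_allele", self.hex_allele)):
            if a not in _BASES:
                raise ValueError(f"{name} must be one of A/C/G/T, got {a!r}")
        if self.fam_allele == self.hex_allele:
            raise ValueError("FAM and HEX alleles must differ")
        if not set(self.reverse) <= _BASES:
            raise ValueError("reverse primer contains non-ACGT characters")
        self.f1 = FAM_TAIL + self.core + self.fam_allele
        self.f2 = HEX_TAIL + self.core + self.hex_allele

    def to_rows(self) -> list[tuple[str, str, str]]:
        """Three-row (F1/F2/R) layout for a primer table."""
        return [
            (self.snp_id, "F1", self.f1),
            (self.snp_id, "F2", self.f2),
            (self.snp_id, "R", self.reverse),
        ]


def assemble_assay(
    snp_id: str, core: str, fam_allele: str, hex_allele: str, reverse: str
) -> KASPAssay:
    """Build the F1/F2/R primer triplet from the core, the two allele bases
    and the common reverse primer."""
    return KASPAssay(
        snp_id=snp_id,
        core=core,
        fam_allele=fam_allele,
        hex_allele=hex_allele,
        reverse=reverse,
    )


def assay_from_flank(
    snp_id: str,
    left_flank: str,
    fam_allele: str,
    hex_allele: str,
    reverse: str,
    core_len: int = 20,
) -> KASPAssay:
    """Extract the core from a left flank and assemble the assay."""
    return assemble_assay(
        snp_id, extract_core(left_flank, core_len), fam_allele, hex_allele, reverse
    )


def _kmers(seq: str, k: int) -> set[str]:
    return {seq[i : i + k] for i in range(len(seq) - k + 1)}


@dataclass
class ValidationReport:
    checks: dict[str, bool]
    all_pass: bool
    tm: dict[str, float]


def validate_assay(assay: KASPAssay, dimer_k: int = 12) -> ValidationReport:
    """Rule checks on an assembled assay.

    Verifies the tail constants, identical cores between the two forwards,
    the 3' base against the declared allele, and a primer-dimer heuristic:
    the reverse primer must share no ``dimer_k``-mer with either forward.
    Failures are reported, never raised.
    """
    checks = {
        "f1_tail": assay.f1.startswith(FAM_TAIL),
        "f2_tail": assay.f2.startswith(HEX_TAIL),
        "cores_identical": assay.f1[len(FAM_TAIL) : -1] == assay.f2[len(HEX_TAIL) : -1],
        "f1_3prime_allele": assay.f1.endswith(assay.fam_allele),
        "f2_3prime_allele": assay.f2.endswith(assay.hex_allele),
        "alleles_distinct": assay.fam_allele != assay.hex_allele,
        "no_reverse_dimer": (
            not (_kmers(assay.reverse, dimer_k) & _kmers(assay.f1, dimer_k))
            and not (_kmers(assay.reverse, dimer_k) & _kmers(assay.f2, dimer_k))
        ),
    }
    tm = {
        "f1": wallace_tm(assay.f1),
        "f2": wallace_tm(assay.f2),
        "reverse": wallace_tm(assay.reverse),
        "core": wallace_tm(assay.core),
    }
    return ValidationReport(checks=checks, all_pass=all(checks.values()), tm=tm)
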