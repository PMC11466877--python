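"""Reference marker panel: the four published KASP markers for soybean
shade-tolerance coefficients, with their assay components, favorable
alleles, and the genotype calls of the five high-shade-tolerance (HST)
germplasms at those markers.

These small published tables serve as worked examples for the post-GWAS and
KASP modules and as fixture inputs for the test suite.
"""

from __future__ import annotations

#: KASP assay components per marker SNP: the 20-nt core immediately 5' of
#: the SNP, the FAM- and HEX-reported allele bases, and the common reverse
#: primer.  The trait tagged by each marker is the STC of:
#: S18_1766721 -> first pod height, S09_48870909 -> plant height,
#: S19_49517336 -> pod number per plant, S18_3429732 -> branch number.
KASP_COMPONENTS: dict[str, dict[str, str]] = {
    "S18_1766721": {
        "core": "TAAAAAAAAATGACAATTAG",
        "fam_allele": "A",
        "hex_allele": "G",
        "reverse": "TGGCATCCACTCATGAAATCG",
        "trait": "first_pod_height",
    },
    "S09_48870909": {
        "core": "TCATTGATGATAGTATGGTT",
        "fam_allele": "G",
        "hex_allele": "T",
        "reverse": "GTGTTTCACAACTGCTGGGC",
        "trait": "plant_height",
    },
    "S19_49517336": {
        "core": "ATCTAATTTTAATTTACAGT",
        "fam_allele": "A",
        "hex_allele": "T",
        "reverse": "ACGAATTGTGTTGGCTGTAACC",
        "trait": "pod_number",
    },
    "S18_3429732": {
        "core": "TGTAGAAAACGCGCTTTGTA",
        "fam_allele": "A",
        "hex_allele": "G",
        "reverse": "TGACAACGACATATGCAAACACAA",
        "trait": "branch_number",
    },
}

#: Favorable allele per marker (the allele whose carriers show the higher
#: mean shade tolerance coefficient in the association panel).
FAVORABLE_ALLELES: dict[str, str] = {
    "S18_1766721": "G",
    "S09_48870909": "T",
    "S19_49517336": "G",
    "S18_3429732": "G",
}

#: Population frequency (%) of the favorable allele at each marker.
FAVORABLE_ALLELE_RATIO_PERCENT: dict[str, float] = {
    "S18_1766721": 37.9,
    "S09_48870909": 34.5,
    "S19_49517336": 87.5,
    "S18_3429732": 13.6,
}

#: Allele calls of the five HST germplasms at the four marker SNPs.
HST_CALLS: dict[str, dict[str, str]] = {
    "NPS044": {
        "S18_1766721": "A",
        "S09_48870909": "T",
        "S19_49517336": "G",
        "S18_3429732": "G",
    },
    "NPS060": {
        "S18_1766721": "G",
        "S09_48870909": "T",
        "S19_49517336": "G",
        "S18_3429732": "A",
    },
    "NPS151": {
        "S18_1766721": "A",
        "S09_48870909": "G",
        "S19_49517336": "G",
        "S18_3429732": "G",
    },
    "NPS187": {
        "S18_1766721": "G",
        "S09_48870909": "T",
        "S19_49517336": "G",
        "S18_3429732": "G",
    },
    "NPS254": {
        "S18_1766721": "A",
        "S09_48870909": "G",
        "S19_49517336": "G",
        "S18_3429732": "A",
    },
}

#: Reported SNP pairs flanking the same locus under different conditions /
#: phenotype sets, with their published distances in kb.
REPORTED_SNP_PAIRS: list[tuple[str, str, int]] = [
    ("S11_19943066", "S11_19738980", 204),
    ("S15_50935714", "S15_51517560", 582),
    ("S19_45102497", "S19_45149787", 47),
    ("S15_36102679", "S15_36134614", 32),
    ("S10_43122500", "S10_43121286", 1),
    ("S18_55349193", "S18_55354172", 5),
]
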