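import numpy as np
import pandas as pd

from soyshade.datatypes import GenotypeMatrix


def make_genotypes(dosage) -> GenotypeMatrix:
    """GenotypeMatrix around a raw dosage array, single chromosome."""
    dosage = np.asarray(dosage, dtype=np.int8)
    n_acc, n_snp = dosage.shape
    pos = list(range(10, 10 * (n_snp + 1), 10))
    snps = pd.DataFrame(
        {
            "snp_id": [f"S1_{p}" for p in pos],
            "chrom": [1] * n_snp,
            "pos": pos,
            "ref": ["A"] * n_snp,
            "alt": ["G"] * n_snp,
        }
    )
    return GenotypeMatrix([f"a{i}" for i in range(n_acc)], snps, dosage)
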