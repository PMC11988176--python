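import numpy as np
import pandas as pd
import pytest

from gpcomp import GenotypeMatrix, desk_scale_config, simulate_dataset


def make_geno(dosage, chrom=None, variant_class=None, ids=None):
    """Small GenotypeMatrix from a plain dosage array."""
    dosage = np.asarray(dosage, dtype=float)
    n, m = dosage.shape
    markers = pd.DataFrame(
        {
            "chromosome": chrom if chrom is not None else ["1"] * m,
            "position": np.arange(1, m + 1) * 1000,
            "variant_class": variant_class if variant_class is not None else ["SNP"] * m,
            "allele_a": "A",
            "allele_b": "B",
        }
    )
    return GenotypeMatrix(
        dosage, ids if ids is not None else np.arange(1, n + 1), markers
    )


@pytest.fixture(scope="session")
def small_population():
    """~300 individuals, 400 markers, h2=0.5, no fixed effects."""
    cfg = desk_scale_config(
        seed=42,
        n_founders=80,
        n_generations=2,
        offspring_per_mating=3,
        n_markers=400,
        target_h2=0.5,
        fixed_effect_spec=(),
    )
    ped, geno, truth, pheno = simulate_dataset(cfg)
    return cfg, ped, geno, truth, pheno
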