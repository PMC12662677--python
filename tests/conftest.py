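import numpy as np
import pytest

from chp.io_formats import GenotypeMatrix, VariantMeta
from chp import synthetic_data as sd


@pytest.fixture
def tiny_gm() -> GenotypeMatrix:
    """Four samples x three variants, one missing genotype."""
    variants = [
        VariantMeta(id="rs1", chrom="1", pos=100, ref="A", alt="G"),
        VariantMeta(id="rs2", chrom="1", pos=200, ref="C", alt="T"),
        VariantMeta(id="rs3", chrom="2", pos=150, ref="G", alt="A"),
    ]
    dosages = np.array(
        [
            [0.0, 1.0, 2.0],
            [1.0, 0.0, 1.0],
            [2.0, np.nan, 0.0],
            [1.0, 1.0, 1.0],
        ]
    )
    return GenotypeMatrix(samples=["s1", "s2", "s3", "s4"], variants=variants, dosages=dosages)


@pytest.fixture(scope="session")
def cohort_gm() -> GenotypeMatrix:
    """Study-scale unstructured cohort: 90 samples, 120 variants, block LD."""
    return sd.simulate_genotypes(90, 120, seed=11)
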