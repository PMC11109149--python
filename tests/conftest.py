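import numpy as np
import pytest

from metabomr.harmonize import from_arrays
from metabomr.sumstats_io import StudyTable, VariantAssociation

#: single fixed seed for every simulation-based test
SEED = 1234


def make_variant(
    variant_id="rs1",
    chrom="1",
    pos=1_000_000,
    effect_allele="A",
    other_allele="G",
    eaf=0.3,
    beta=0.1,
    se=0.01,
    pval=1e-8,
    n=7824,
):
    return VariantAssociation(
        variant_id, chrom, pos, effect_allele, other_allele, eaf, beta, se, pval, n
    )


def make_table(records, trait_id="exposure", **kwargs):
    table = StudyTable(trait_id=trait_id, records=list(records), **kwargs)
    table.validate()
    return table


def random_harmonized_set(rng, j=12):
    """Arbitrary but well-posed harmonized effects for oracle comparisons."""
    gamma = rng.normal(0.2, 0.05, j) * rng.choice([-1.0, 1.0], j)
    se_gamma = rng.uniform(0.005, 0.02, j)
    big_gamma = rng.normal(0.0, 0.05, j)
    se_big_gamma = rng.uniform(0.005, 0.05, j)
    return from_arrays(gamma, se_gamma, big_gamma, se_big_gamma)


@pytest.fixture
def rng():
    return np.random.default_rng(SEED)
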