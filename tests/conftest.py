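import numpy as np
import pytest

from gbgc_codon import SyntheticConfig, simulate

SMALL_CONFIG = SyntheticConfig(
    n_genes=300,
    n_chromosomes=2,
    chrom_length=8_000_000,
    n_gene_sets=80,
    set_size_range=(40, 120),
    seed=1,
)


@pytest.fixture(scope="session")
def small_dataset():
    """One fully synthesized small world shared across tests."""
    return simulate(SMALL_CONFIG)


@pytest.fixture(scope="session")
def small_dataset_dir(small_dataset, tmp_path_factory):
    out = tmp_path_factory.mktemp("dataset")
    small_dataset.write(out)
    return out


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def random_codon_table(rng, max_count=30):
    """Random codon usage table over the 61 sense codons."""
    from gbgc_codon._genetic_code import SENSE_CODONS
    from gbgc_codon.sequence_features import CodonUsageTable

    counts = {
        c: int(k)
        for c, k in zip(SENSE_CODONS, rng.integers(0, max_count, len(SENSE_CODONS)))
        if k > 0
    }
    return CodonUsageTable(counts=counts, n_codons_total=sum(counts.values()))
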