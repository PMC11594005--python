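import numpy as np
import pytest

from cnvpop.simdata import SimConfig, simulate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """A small but complete cohort: 2 breeds x 4, 3 Mb genome, 25 loci."""
    cfg = SimConfig(
        seed=42,
        n_loci=25,
        chrom_lengths={"chr1": 1_500_000, "chr2": 1_500_000},
        pop_sizes=(4, 4),
        mean_depth_per_bin=10.0,
        min_locus_len=5_000,
        max_locus_len=40_000,
        n_genes=30,
    )
    return simulate_cohort(cfg)


def truth_dosages(truth) -> np.ndarray:
    """Variant-allele dosages straight from the planted truth."""
    loss = (truth.locus_table["allele_type"] == "loss").to_numpy()
    g = truth.genotypes
    return np.where(loss[None, :], 2 - g, g - 2)
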