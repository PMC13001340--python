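import numpy as np
import pandas as pd
import pytest

from hlbquant import simulate, workflows


@pytest.fixture(scope="session")
def tiny_spec():
    """One 10-kb chromosome plus two plain 8-kb chromosomes; 3x500-bp array."""
    return simulate.SimGenomeSpec(
        chrom_lengths={"chrA": 10_000, "chrB": 8_000, "chrC": 8_000},
        array_chrom="chrA",
        array_start=2_001,
        array_end=3_500,
        unit_length=500,
        copy_number=3,
    )


@pytest.fixture(scope="session")
def tiny_genome(tiny_spec):
    return simulate.simulate_genome(tiny_spec, seed=11, strict=True)


@pytest.fixture(scope="session")
def toy_genome():
    """The 3 x 1-Mb study genome with a 100-copy 5,080-bp array."""
    return simulate.simulate_genome(workflows.toy_genome_spec(), seed=1, strict=True)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


@pytest.fixture()
def cell_table():
    """Small per-cell label table over two genotypes x two embryos."""
    rows = []
    rng = np.random.default_rng(7)
    for genotype, p_edu, p_fish_given_not_edu in [("control", 0.4, 0.1), ("mutant", 0.4, 0.8)]:
        for embryo in range(1, 3):
            for _ in range(50):
                edu = rng.random() < p_edu
                fish = True if edu else rng.random() < p_fish_given_not_edu
                rows.append(
                    {
                        "embryo": f"{genotype}_{embryo}",
                        "genotype": genotype,
                        "edu": edu,
                        "fish": fish,
                        "nascent": fish and rng.random() < 0.5,
                        "ph3": rng.random() < 0.1,
                    }
                )
    return pd.DataFrame(rows)
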