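import numpy as np
import pytest

from mitotrace.reference import Feature, FeatureAnnotation, MitoGenome
from mitotrace.simulate import SimConfig, simulate_hybrid_genomes


@pytest.fixture(scope="session")
def small_cfg():
    """A desk-sized study configuration: short genome, modest depth."""
    return SimConfig(seed=7, genome_length=4000, n_snps=40, mean_depth=60,
                     n_embryos_per_group=4, read_length=80)


@pytest.fixture(scope="session")
def hybrid(small_cfg):
    """(maternal, paternal, truth SnpTable, FeatureAnnotation) tuple."""
    return simulate_hybrid_genomes(small_cfg)


@pytest.fixture()
def toy_annotation():
    return FeatureAnnotation(
        features=[
            Feature("tRNA-X", 10, 20, "+", "mt-tRNA"),
            Feature("rRNA-1", 15, 60, "+", "mt-rRNA"),
            Feature("mRNA-1", 50, 120, "+", "mt-mRNA"),
            Feature("dloop", 150, 200, "+", "control_region"),
        ],
        genome_name="chrM",
        genome_length=220,
    )


@pytest.fixture()
def toy_genome():
    rng = np.random.default_rng(11)
    return MitoGenome("chrM", "".join(rng.choice(list("ACGT"), 220)))
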