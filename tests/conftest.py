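import numpy as np
import pytest

from lupinqg import pipeline


@pytest.fixture(scope="session")
def sim():
    """Desk-scale factorial-cross population: 16 families x 9 F5 lines,
    25 chromosomes x 80 markers, two environments x 4 blocks."""
    cfg, geno, truth, plots = pipeline.simulate(3, markers_per_chromosome=80)
    return {"cfg": cfg, "geno": geno, "truth": truth, "plots": plots}


@pytest.fixture(scope="session")
def small_sim():
    """Cheaper population (40 markers/chromosome) for repeated-fit tests."""
    cfg, geno, truth, plots = pipeline.simulate(11, markers_per_chromosome=40)
    return {"cfg": cfg, "geno": geno, "truth": truth, "plots": plots}


@pytest.fixture(scope="session")
def complete(sim):
    """QC'd and knn-imputed genotype matrix from the session population."""
    return pipeline.qc_impute(sim["geno"], impute="knn", seed=5)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(2024)
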