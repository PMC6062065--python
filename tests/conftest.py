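import numpy as np
import pytest

from ggiforest.expression import ExpressionDataset, zscore_normalise
from ggiforest.simulate import SimulationConfig, simulate_dataset


@pytest.fixture
def toy_ds():
    """3 genes x 4 samples, labels [0,0,1,1]."""
    return ExpressionDataset(
        gene_ids=("G1", "G2", "G3"),
        sample_ids=("s1", "s2", "s3", "s4"),
        values=np.array([[1.0, 2.0, 3.0, 4.0],
                         [4.0, 3.0, 2.0, 1.0],
                         [0.5, 1.5, 0.5, 1.5]]),
        labels=np.array([0, 0, 1, 1]),
    )


@pytest.fixture
def toy_matrix_files(tmp_path):
    matrix = tmp_path / "expr.tsv"
    labels = tmp_path / "labels.tsv"
    matrix.write_text(
        "gene_id\ts1\ts2\ts3\ts4\n"
        "G1\t1\t2\t3\t4\n"
        "G2\t4\t3\t2\t1\n"
        "G3\t0.5\t1.5\t0.5\t1.5\n"
    )
    labels.write_text("s1\t0\ns2\t0\ns3\t1\ns4\t1\n")
    return matrix, labels


SMALL_CFG = SimulationConfig(
    n_genes=120, n_samples_class0=20, n_samples_class1=20,
    n_disease_pairs=20, rng_seed=11)


@pytest.fixture(scope="session")
def small_sim():
    """A small planted benchmark shared across tests (read-only)."""
    return simulate_dataset(SMALL_CFG)


@pytest.fixture(scope="session")
def small_sim_norm(small_sim):
    return zscore_normalise(small_sim.dataset)


def random_pair(rng, n0=None, n1=None):
    """A random GenePair with class sizes drawn in [5, 50]."""
    from ggiforest.features import GenePair

    n0 = n0 or int(rng.integers(5, 51))
    n1 = n1 or int(rng.integers(5, 51))
    return GenePair.make(
        "GA", "GB",
        rng.normal(size=n0), rng.normal(size=n1),
        rng.normal(size=n0), rng.normal(size=n1),
    )
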