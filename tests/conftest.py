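import numpy as np
import pytest
import scipy.sparse as sp

from autoqc import CountsMatrix, generate_sample, run_scautoqc


def make_counts(array, gene_ids=None, cell_ids=None) -> CountsMatrix:
    """Build a CountsMatrix from a dense cells x genes array."""
    arr = np.asarray(array)
    gene_ids = gene_ids or [f"G{j}" for j in range(arr.shape[1])]
    cell_ids = cell_ids or [f"C{i}" for i in range(arr.shape[0])]
    return CountsMatrix(cell_ids, gene_ids, sp.csr_matrix(arr))


@pytest.fixture(scope="session")
def standard_sample():
    """The standard five-population synthetic sample (1500 good, 300 debris,
    200 high-mito, 100 soup-heavy, 100 doublets), seed 7."""
    return generate_sample(seed=7)


@pytest.fixture(scope="session")
def standard_result(standard_sample):
    return run_scautoqc(standard_sample.counts, standard_sample.aux, seed=7)


@pytest.fixture(scope="session")
def blob_latents():
    """Two well-separated Gaussian blobs in a 10-D latent space, with labels."""
    rng = np.random.default_rng(11)
    ref = np.vstack(
        [rng.normal(0, 1, (300, 10)), rng.normal(8, 1, (300, 10))]
    )
    ref_labels = np.array(["B cell"] * 300 + ["T cell"] * 300)
    query = np.vstack(
        [rng.normal(0, 1, (200, 10)), rng.normal(8, 1, (200, 10))]
    )
    query_labels = np.array(["B cell"] * 200 + ["T cell"] * 200)
    return ref, ref_labels, query, query_labels
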