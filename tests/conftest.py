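import numpy as np
import pytest

from dynheter.data_io import make_splits
from dynheter.similarity import drug_similarity_matrix, protein_similarity_matrix
from dynheter.synthetic import SyntheticSpec, generate_dataset


@pytest.fixture(scope="session")
def tiny_dataset():
    """Small synthetic dataset shared by pipeline-level tests."""
    drugs, proteins, table = generate_dataset(
        SyntheticSpec(n_drugs=6, n_proteins=8, seq_len_range=(20, 30), seed=1))
    return drugs, proteins, table


@pytest.fixture(scope="session")
def tiny_sims(tiny_dataset):
    drugs, proteins, _ = tiny_dataset
    return drug_similarity_matrix(drugs), protein_similarity_matrix(proteins)


@pytest.fixture(scope="session")
def conformance_fixture():
    """The fixed seed-42, 20-drug x 30-protein dataset with its similarity
    matrices and split plan; reused by the end-to-end acceptance tests."""
    drugs, proteins, table = generate_dataset(SyntheticSpec())
    Sd = drug_similarity_matrix(drugs)
    Sp = protein_similarity_matrix(proteins)
    splits = make_splits(table, 42)
    return drugs, proteins, table, Sd, Sp, splits


def random_graph(rng, n, p=0.4):
    """Random undirected edge list on n nodes."""
    edges = [(i, j) for i in range(n) for j in range(i + 1, n) if rng.random() < p]
    return edges


def dense_adjacency(n, edges):
    A = np.zeros((n, n))
    for i, j in edges:
        A[i, j] = A[j, i] = 1.0
    return A
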