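import numpy as np
import pytest

from cisnet import (
    ExpressionMatrix,
    KmerCountTable,
    PromoterRecord,
    count_kmers,
)


@pytest.fixture
def rng():
    return np.random.default_rng(20260926)


@pytest.fixture
def toy_promoters():
    return [
        PromoterRecord("g1", "ACGTACGTAC"),
        PromoterRecord("g2", "AAAAAAAAAA"),
        PromoterRecord("g3", "ACGNACGTAC"),
        PromoterRecord("g4", "TTTTACGTTT"),
    ]


@pytest.fixture
def toy_table(toy_promoters):
    return count_kmers(toy_promoters, k=3)


@pytest.fixture
def fasta_file(tmp_path):
    def make(content: str, name: str = "promoters.fasta"):
        path = tmp_path / name
        path.write_text(content)
        return path

    return make


@pytest.fixture
def block_expression():
    """Two independent 4-gene blocks of near-identical profiles + noise."""
    rng = np.random.default_rng(7)
    n_arrays = 40
    latent_a = rng.standard_normal(n_arrays)
    latent_b = rng.standard_normal(n_arrays)
    rows, ids = [], []
    for i in range(4):
        rows.append(latent_a + 0.15 * rng.standard_normal(n_arrays))
        ids.append(f"a{i}")
    for i in range(4):
        rows.append(latent_b + 0.15 * rng.standard_normal(n_arrays))
        ids.append(f"b{i}")
    arrays = [f"c{j}" for j in range(n_arrays)]
    return ExpressionMatrix(ids, arrays, np.array(rows))


def brute_force_kmer_counts(sequence: str, k: int) -> dict:
    """Independent oracle: slide a window, increment a dictionary."""
    counts: dict[str, int] = {}
    seq = sequence.upper()
    for i in range(len(seq) - k + 1):
        word = seq[i : i + k]
        if all(b in "ACGT" for b in word):
            counts[word] = counts.get(word, 0) + 1
    return counts
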