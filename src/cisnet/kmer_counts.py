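"""Promoter k-mer occurrence tables.

Builds the background occurrence table ``C`` (one row per promoter, one
column per enumerated k-mer) and row subsets ``D`` aligned to a
co-expression network's gene order.  Counting is exact-match over
overlapping windows on the forward strand; windows containing any
non-ACGT symbol (N or IUPAC ambiguity codes) are skipped so counts stay
integral and conservative.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from Bio import SeqIO

logger = logging.getLogger(__name__)

BASES = "ACGT"

_BASE_CODE = np.full(256, -1, dtype=np.int64)
for _i, _b in enumerate(BASES):
    _BASE_CODE[ord(_b)] = _i


def enumerate_kmers(k: int) -> list[str]:
    """All 4**k DNA words of length k in lexicographic order (A<C<G<T)."""
    if k < 1:
        raise ValueError(f"k must be >= 1, got {k}")
    return ["".join(p) for p in itertools.product(BASES, repeat=k)]


def reverse_complement(kmer: str) -> str:
    return kmer.translate(str.maketrans("ACGT", "TGCA"))[::-1]


@dataclass
class PromoterRecord:
    """One promoter sequence; ``gene_id`` is the first header token."""

    gene_id: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.gene_id:
            raise ValueError("gene_id must be non-empty")
        if len(self.sequence) < 1:
            raise ValueError(f"empty sequence for gene {self.gene_id!r}")
        self.sequence = self.sequence.upper()


@dataclass
class KmerCountTable:
    """Occurrence matrix of k-mers per promoter (rows=genes, cols=motifs).

    Column order is the full lexicographic enumeration of 4**k words and
    is stable across runs.  Entries are non-negative integers; for a
    promoter free of ambiguity codes the row sum is max(0, L - k + 1).
    """

    gene_ids: list[str]
    k: int
    motifs: list[str] = field(repr=False)
    counts: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.shape != (len(self.gene_ids), len(self.motifs)):
            raise ValueError(
                f"counts shape {self.counts.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.motifs)} motifs"
            )
        if (self.counts < 0).any():
            raise ValueError("counts must be non-negative")

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.gene_ids, columns=self.motifs)

    def to_tsv(self, path) -> None:
        df = self.to_frame()
        df.index.name = "gene"
        df.to_csv(path, sep="\t")

    @classmethod
    def from_tsv(cls, path) -> "KmerCountTable":
        df = pd.read_csv(path, sep="\t", index_col=0)
        motifs = [str(m) for m in df.columns]
        k = len(motifs[0])
        return cls(
            gene_ids=[str(g) for g in df.index],
            k=k,
            motifs=motifs,
            counts=df.to_numpy(dtype=np.int64),
        )


def read_fasta(path) -> list[PromoterRecord]:
    """Read promoters from FASTA; gene id = first whitespace token of header.

    Sequences are uppercased and input order preserved.  Duplicate gene
    ids raise with the full duplicate list.
    """
    records: list[PromoterRecord] = []
    try:
        for rec in SeqIO.parse(str(path), "fasta"):
            records.append(PromoterRecord(gene_id=rec.id, sequence=str(rec.seq)))
    except ValueError as exc:  # Biopython flags the offending content
        raise ValueError(f"malformed FASTA in {path}: {exc}") from exc
    if not records:
        logger.warning("no FASTA records found in %s", path)
    seen: dict[str, int] = {}
    for rec in records:
        seen[rec.gene_id] = seen.get(rec.gene_id, 0) + 1
    dups = sorted(g for g, c in seen.items() if c > 1)
    if dups:
        raise ValueError(f"duplicate gene ids in {path}: {', '.join(dups)}")
    return records


def _encode(sequence: str) -> np.ndarray:
    return _BASE_CODE[np.frombuffer(sequence.encode("ascii"), dtype=np.uint8)]


def count_kmers(
    promoters: list[PromoterRecord],
    k: int = 6,
    collapse_revcomp: bool = False,
) -> KmerCountTable:
    """Count overlapping exact k-mer occurrences per promoter.

    Each of the max(0, L-k+1) windows of a promoter increments the column
    of the word it spells; windows containing a non-ACGT symbol increment
    nothing.  With ``collapse_revcomp`` each word is pooled with its
    reverse complement (column labelled by the lexicographically smaller
    of the pair); off by default, giving the full 4**k columns.
    """
    if k < 1:
        raise ValueError(f"k must be >= 1, got {k}")
    if not promoters:
        raise ValueError("promoters must be non-empty")
    l = 4 ** k
    counts = np.zeros((len(promoters), l), dtype=np.int64)
    powers = 4 ** np.arange(k - 1, -1, -1, dtype=np.int64)
    any_window = False
    for i, rec in enumerate(promoters):
        codes = _encode(rec.sequence)
        if codes.size < k:
            continue
        any_window = True
        windows = np.lib.stride_tricks.sliding_window_view(codes, k)
        valid = (windows >= 0).all(axis=1)
        if valid.any():
            idx = windows[valid] @ powers
            counts[i] = np.bincount(idx, minlength=l)
    if not any_window:
        logger.warning("k=%d exceeds every sequence length; all counts zero", k)
    motifs = enumerate_kmers(k)
    table = KmerCountTable([r.gene_id for r in promoters], k, motifs, counts)
    if collapse_revcomp:
        table = _collapse_revcomp(table)
    return table


def _collapse_revcomp(table: KmerCountTable) -> KmerCountTable:
    canon: dict[str, list[int]] = {}
    for j, m in enumerate(table.motifs):
        canon.setdefault(min(m, reverse_complement(m)), []).append(j)
    motifs = sorted(canon)
    counts = np.zeros((table.n_genes, len(motifs)), dtype=np.int64)
    for out_j, m in enumerate(motifs):
        cols = canon[m]
        counts[:, out_j] = table.counts[:, cols].sum(axis=1)
    return KmerCountTable(table.gene_ids, table.k, motifs, counts)


def subset_counts(table: KmerCountTable, gene_ids: list[str]) -> KmerCountTable:
    """Row-subset ``C`` -> ``D`` in the exact order requested."""
    pos = {g: i for i, g in enumerate(table.gene_ids)}
    missing = [g for g in gene_ids if g not in pos]
    if missing:
        raise KeyError(f"gene ids absent from count table: {', '.join(missing)}")
    rows = [pos[g] for g in gene_ids]
    return KmerCountTable(list(gene_ids), table.k, list(table.motifs), table.counts[rows])


def presence_counts(table: KmerCountTable) -> np.ndarray:
    """Per-motif number of promoters with at least one occurrence (K_j)."""
    return (table.counts > 0).sum(axis=0)
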