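"""Rank-based gene co-expression networks.

The network connects genes i and j when each ranks the other within the
top ``rank_threshold`` of its Pearson-correlation ranking (mutual-rank
criterion).  The adjacency is symmetric with a unit diagonal, so every
gene belongs to its own neighborhood.  Typical thresholds from published
yeast/Arabidopsis analyses are 120 and 100; the threshold here is always
an explicit parameter.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)


@dataclass
class ExpressionMatrix:
    """Genes x arrays matrix of log-ratio expression values."""

    gene_ids: list[str]
    array_ids: list[str]
    values: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.gene_ids), len(self.array_ids)):
            raise ValueError("values shape does not match gene/array labels")
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise ValueError("gene_ids must be unique")

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.gene_ids, columns=self.array_ids)

    def to_tsv(self, path) -> None:
        df = self.to_frame()
        df.index.name = "gene"
        df.to_csv(path, sep="\t")

    @classmethod
    def from_tsv(cls, path) -> "ExpressionMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        n_missing = int(df.isna().any(axis=1).sum())
        if n_missing:
            logger.warning("dropping %d genes with missing values", n_missing)
            df = df.dropna(axis=0)
        return cls(
            gene_ids=[str(g) for g in df.index],
            array_ids=[str(a) for a in df.columns],
            values=df.to_numpy(dtype=float),
        )


@dataclass
class CoexpressionNetwork:
    """Symmetric binary adjacency over n genes with unit diagonal."""

    gene_ids: list[str]
    adjacency: np.ndarray = field(repr=False)
    rank_threshold: int | None = None

    def __post_init__(self) -> None:
        self.adjacency = np.asarray(self.adjacency, dtype=np.int8)
        n = len(self.gene_ids)
        if self.adjacency.shape != (n, n):
            raise ValueError("adjacency must be n x n")
        if not (self.adjacency == self.adjacency.T).all():
            raise ValueError("adjacency must be symmetric")
        np.fill_diagonal(self.adjacency, 1)

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    def neighborhood_sizes(self) -> np.ndarray:
        return self.adjacency.sum(axis=1)

    def edge_set(self) -> set[tuple[str, str]]:
        """Undirected off-diagonal edges as sorted id pairs."""
        ii, jj = np.nonzero(np.triu(self.adjacency, k=1))
        return {
            tuple(sorted((self.gene_ids[i], self.gene_ids[j])))
            for i, j in zip(ii.tolist(), jj.tolist())
        }


def neighborhood(net: CoexpressionNetwork, gene: str) -> set[str]:
    """pi_g = {i : a_gi = 1}; always contains g itself."""
    try:
        g = net.gene_ids.index(gene)
    except ValueError:
        raise KeyError(f"gene {gene!r} not in network") from None
    return {net.gene_ids[i] for i in np.nonzero(net.adjacency[g])[0]}


def select_top_variance_genes(expr: ExpressionMatrix, n: int) -> ExpressionMatrix:
    """Keep the n genes with the largest sample variance across arrays.

    Ties are broken by gene id lexicographic order; rows come out sorted
    by decreasing variance, arrays untouched.
    """
    if not 1 <= n <= expr.n_genes:
        raise ValueError(f"n must be in [1, {expr.n_genes}], got {n}")
    var = expr.values.var(axis=1, ddof=1)
    order = sorted(range(expr.n_genes), key=lambda i: (-var[i], expr.gene_ids[i]))
    keep = order[:n]
    return ExpressionMatrix(
        [expr.gene_ids[i] for i in keep], list(expr.array_ids), expr.values[keep]
    )


def quantile_normalize(expr: ExpressionMatrix) -> ExpressionMatrix:
    """Force every array (column) onto the mean order-statistic distribution.

    Ties within a column receive the mean of the quantile values they
    span (average-rank convention).
    """
    if len(expr.array_ids) == 1:
        logger.warning("single-array matrix: quantile normalization is a no-op")
        return ExpressionMatrix(list(expr.gene_ids), list(expr.array_ids), expr.values.copy())
    values = expr.values
    mean_order_stat = np.sort(values, axis=0).mean(axis=1)
    out = np.empty_like(values, dtype=float)
    for j in range(values.shape[1]):
        col = values[:, j]
        order = np.argsort(col, kind="mergesort")
        assigned = np.empty(len(col))
        assigned[order] = mean_order_stat
        # tied values share the mean of the quantile slots they occupy
        out[:, j] = pd.Series(assigned).groupby(col).transform("mean").to_numpy()
    return ExpressionMatrix(list(expr.gene_ids), list(expr.array_ids), out)


def build_rank_network(
    expr: ExpressionMatrix, rank_threshold: int
) -> CoexpressionNetwork:
    """Mutual-rank network: edge iff each gene ranks the other <= threshold.

    Rank 1 is the most-correlated other gene; correlation ties are broken
    by gene id lexicographic order.  Zero-variance genes have undefined
    correlations and are dropped with a warning before ranking.
    """
    if rank_threshold < 1:
        raise ValueError("rank_threshold must be >= 1")
    if expr.n_genes < 3 or len(expr.array_ids) < 3:
        raise ValueError("need >= 3 genes and >= 3 arrays")
    var = expr.values.var(axis=1)
    if (var == 0).any():
        dropped = [g for g, v in zip(expr.gene_ids, var) if v == 0]
        logger.warning("dropping %d zero-variance genes: %s", len(dropped), dropped[:10])
        keep = np.nonzero(var > 0)[0]
        expr = ExpressionMatrix(
            [expr.gene_ids[i] for i in keep], list(expr.array_ids), expr.values[keep]
        )
    n = expr.n_genes
    corr = np.corrcoef(expr.values)
    # lexicographic tiebreak: order candidates by (-corr, gene id)
    id_order = np.argsort(np.argsort(expr.gene_ids))  # lexicographic rank of each id
    rank = np.empty((n, n), dtype=np.int64)
    for i in range(n):
        c = corr[i].copy()
        c[i] = np.inf  # self excluded from ranking; sentinel keeps slot
        order = np.lexsort((id_order, -c))  # primary: corr desc, secondary: id asc
        r = np.empty(n, dtype=np.int64)
        r[order] = np.arange(n)  # self lands at rank 0
        rank[i] = r
    mutual = (rank <= rank_threshold) & (rank.T <= rank_threshold)
    adjacency = mutual.astype(np.int8)
    np.fill_diagonal(adjacency, 1)
    return CoexpressionNetwork(list(expr.gene_ids), adjacency, rank_threshold)


def preprocess_and_build(
    expr: ExpressionMatrix,
    top_n: int | None,
    rank_threshold: int,
    normalize: bool = True,
) -> CoexpressionNetwork:
    """Standard pipeline preset: top-variance selection, quantile
    normalization, then mutual-rank network construction."""
    if top_n is not None:
        expr = select_top_variance_genes(expr, top_n)
    if normalize:
        expr = quantile_normalize(expr)
    return build_rank_network(expr, rank_threshold)


def read_network_edgelist(path) -> CoexpressionNetwork:
    """Load a symmetric network from a two-column (optionally weighted) TSV.

    Nodes are collected from the edges; self-loops are added on load.
    """
    genes: list[str] = []
    seen: set[str] = set()
    edges: list[tuple[str, str]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise ValueError(f"{path}:{lineno}: expected >= 2 tab-separated fields")
            a, b = parts[0], parts[1]
            for g in (a, b):
                if g not in seen:
                    seen.add(g)
                    genes.append(g)
            edges.append((a, b))
    pos = {g: i for i, g in enumerate(genes)}
    n = len(genes)
    adjacency = np.zeros((n, n), dtype=np.int8)
    for a, b in edges:
        adjacency[pos[a], pos[b]] = 1
        adjacency[pos[b], pos[a]] = 1
    np.fill_diagonal(adjacency, 1)
    return CoexpressionNetwork(genes, adjacency)


def write_network_edgelist(net: CoexpressionNetwork, path) -> None:
    """Write off-diagonal undirected edges, one sorted pair per line."""
    with open(path, "w") as fh:
        for a, b in sorted(net.edge_set()):
            fh.write(f"{a}\t{b}\n")


def write_network_graphml(net: CoexpressionNetwork, path) -> None:
    import networkx as nx

    g = nx.Graph()
    g.add_nodes_from(net.gene_ids)
    g.add_edges_from(net.edge_set())
    nx.write_graphml(g, path)
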