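"""Neighborhood motif over-representation and the bipartite gene-motif network.

For every target gene g the co-expression neighborhood pi_g (g plus its
direct network neighbors) is tested, motif by motif, for an excess of
promoters containing the motif relative to the m background promoters.
The default test is the cumulative hypergeometric tail

    p_gj = sum_{r=x}^{min(K,q)} C(K,r) C(m-K, q-r) / C(m,q)

with x = motif-containing genes in pi_g, K = motif-containing background
promoters, q = |pi_g|.  A Welch two-sample t-test on raw occurrence
counts (neighborhood vs the other target genes) is available as an
alternative.  p-values map to significance scores s = min(cap, -log10 p)
with cap 40; the cis-regulatory network keeps gene-motif pairs with
s strictly above a cutoff (2 <-> p = 0.01 for evaluation; 17 or 30 for
sparse, visualization-grade networks).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .coexpression import CoexpressionNetwork
from .kmer_counts import KmerCountTable, presence_counts

logger = logging.getLogger(__name__)

DEFAULT_CAP = 40.0
P_FLOOR = 1e-300


def hypergeom_pvalue(x: int, K: int, q: int, m: int) -> float:
    """P(X >= x) for X hypergeometric(m population, K marked, q draws).

    Never returns exactly 0: floored at 1e-300.
    """
    if not (0 <= K <= m and 0 <= q <= m):
        raise ValueError(f"require 0 <= K,q <= m; got K={K}, q={q}, m={m}")
    if not (0 <= x <= min(K, q)):
        raise ValueError(f"require 0 <= x <= min(K,q); got x={x}, K={K}, q={q}")
    p = float(stats.hypergeom.sf(x - 1, m, K, q))
    return min(1.0, max(p, P_FLOOR))


def ttest_pvalue(
    neigh_counts: np.ndarray,
    background_counts: np.ndarray,
    alternative: str = "greater",
) -> float:
    """Welch two-sample t-test p-value for neighborhood over-representation.

    One-sided (neighborhood mean greater) by default.  Degenerate inputs
    (a group smaller than 2, or both groups constant and equal) give p=1.
    """
    a = np.asarray(neigh_counts, dtype=float)
    b = np.asarray(background_counts, dtype=float)
    if a.size < 2 or b.size < 2:
        logger.warning("degenerate group sizes (%d, %d): p = 1", a.size, b.size)
        return 1.0
    if a.var(ddof=1) == 0 and b.var(ddof=1) == 0:
        if a.mean() == b.mean():
            return 1.0
        if alternative == "two-sided" or a.mean() > b.mean():
            return P_FLOOR
        return 1.0
    res = stats.ttest_ind(a, b, equal_var=False, alternative=alternative)
    return min(1.0, max(float(res.pvalue), P_FLOOR))


def score_from_pvalue(p, cap: float = DEFAULT_CAP):
    """s = min(cap, -log10 p); p <= 0 is floored at 1e-300, p > 1 is an error."""
    arr = np.asarray(p, dtype=float)
    if (arr > 1).any():
        raise ValueError("p-values must be <= 1")
    arr = np.clip(arr, P_FLOOR, 1.0)
    s = np.minimum(cap, -np.log10(arr))
    return float(s) if np.isscalar(p) else s


@dataclass
class EnrichmentResult:
    """p-value and capped score matrices over n target genes x l motifs."""

    gene_ids: list[str]
    motifs: list[str]
    pvalues: np.ndarray = field(repr=False)
    scores: np.ndarray = field(repr=False)
    cap: float = DEFAULT_CAP
    method: str = "hypergeometric"

    def __post_init__(self) -> None:
        shape = (len(self.gene_ids), len(self.motifs))
        if self.pvalues.shape != shape or self.scores.shape != shape:
            raise ValueError("matrix shapes do not match labels")

    def scores_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.scores, index=self.gene_ids, columns=self.motifs)

    def pvalues_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.pvalues, index=self.gene_ids, columns=self.motifs)

    def qvalues(self) -> np.ndarray:
        """Benjamini-Hochberg adjusted p-values over the whole matrix."""
        flat = self.pvalues.ravel()
        q = stats.false_discovery_control(flat, method="bh")
        return q.reshape(self.pvalues.shape)

    def to_tsv(self, path, what: str = "scores") -> None:
        df = self.scores_frame() if what == "scores" else self.pvalues_frame()
        df.index.name = "gene"
        df.to_csv(path, sep="\t", float_format="%.6g")

    @classmethod
    def scores_from_tsv(cls, path, cap: float = DEFAULT_CAP) -> "EnrichmentResult":
        df = pd.read_csv(path, sep="\t", index_col=0)
        scores = df.to_numpy(dtype=float)
        return cls(
            gene_ids=[str(g) for g in df.index],
            motifs=[str(m) for m in df.columns],
            pvalues=np.power(10.0, -scores),
            scores=scores,
            cap=cap,
        )


def compute_enrichment(
    D: KmerCountTable,
    background: KmerCountTable,
    net: CoexpressionNetwork,
    method: str = "hypergeometric",
    cap: float = DEFAULT_CAP,
    include_self: bool = True,
    ttest_alternative: str = "greater",
) -> EnrichmentResult:
    """Score every (target gene, motif) pair for neighborhood enrichment.

    ``D`` must carry the network's genes in the network's order (use
    ``subset_counts``); ``background`` is the full m-promoter table.
    ``include_self`` drops gene g from its own neighborhood before
    testing when False (sensitivity analysis; the adjacency convention
    a_gg = 1 makes True the standard behaviour).
    """
    if D.gene_ids != net.gene_ids:
        missing = [g for g in net.gene_ids if g not in set(D.gene_ids)]
        if missing:
            raise KeyError(f"network genes absent from D: {', '.join(missing[:10])}")
        raise ValueError("D gene order must equal the network gene order")
    if D.motifs != background.motifs:
        raise ValueError("D and background must share the same motif columns")
    adjacency = net.adjacency.astype(np.int64)
    if not include_self:
        adjacency = adjacency.copy()
        np.fill_diagonal(adjacency, 0)
    q = adjacency.sum(axis=1)
    n_single = int((q <= 1).sum())
    if n_single:
        logger.info("%d genes have neighborhoods of size <= 1", n_single)

    if method == "hypergeometric":
        m = background.n_genes
        K = presence_counts(background).astype(np.int64)
        present = (D.counts > 0).astype(np.int64)
        x = adjacency @ present  # n x l: motif-containing genes in pi_g
        pvalues = _hypergeom_matrix(x, K, q, m)
    elif method == "ttest":
        pvalues = _ttest_matrix(D.counts, adjacency, ttest_alternative)
    else:
        raise ValueError(f"unknown method {method!r}")

    pvalues = np.clip(pvalues, P_FLOOR, 1.0)
    scores = np.minimum(cap, -np.log10(pvalues))
    return EnrichmentResult(
        gene_ids=list(net.gene_ids),
        motifs=list(D.motifs),
        pvalues=pvalues,
        scores=scores,
        cap=cap,
        method=method,
    )


def _hypergeom_matrix(x: np.ndarray, K: np.ndarray, q: np.ndarray, m: int) -> np.ndarray:
    """Vectorized upper-tail p-values; duplicates (x,K,q) computed once."""
    n, l = x.shape
    Kb = np.broadcast_to(K, (n, l))
    qb = np.broadcast_to(q[:, None], (n, l))
    triples = np.stack([x.ravel(), Kb.ravel(), qb.ravel()], axis=1)
    uniq, inverse = np.unique(triples, axis=0, return_inverse=True)
    pu = stats.hypergeom.sf(uniq[:, 0] - 1, m, uniq[:, 1], uniq[:, 2])
    return pu[inverse].reshape(n, l)


def _ttest_matrix(counts: np.ndarray, adjacency: np.ndarray, alternative: str) -> np.ndarray:
    """Welch t-test of in-neighborhood vs out-of-neighborhood mean counts,
    computed for all genes x motifs from group sums (no per-pair loop)."""
    counts = counts.astype(float)
    n = counts.shape[0]
    n1 = adjacency.sum(axis=1).astype(float)[:, None]
    n2 = n - n1
    s1 = adjacency @ counts
    sq1 = adjacency @ (counts ** 2)
    tot = counts.sum(axis=0)[None, :]
    tot_sq = (counts ** 2).sum(axis=0)[None, :]
    with np.errstate(divide="ignore", invalid="ignore"):
        mean1 = s1 / n1
        mean2 = (tot - s1) / n2
        var1 = (sq1 - n1 * mean1 ** 2) / (n1 - 1)
        var2 = ((tot_sq - sq1) - n2 * mean2 ** 2) / (n2 - 1)
        var1 = np.maximum(var1, 0.0)
        var2 = np.maximum(var2, 0.0)
        se2 = var1 / n1 + var2 / n2
        t = (mean1 - mean2) / np.sqrt(se2)
        df = se2 ** 2 / ((var1 / n1) ** 2 / (n1 - 1) + (var2 / n2) ** 2 / (n2 - 1))
        if alternative == "greater":
            p = stats.t.sf(t, df)
        elif alternative == "two-sided":
            p = 2 * stats.t.sf(np.abs(t), df)
        else:
            raise ValueError(f"unknown alternative {alternative!r}")
    # degenerate cells: zero pooled variance, or a group of size < 2
    degenerate = ~np.isfinite(p)
    equal_means = np.isclose(mean1, mean2)
    p = np.where(degenerate & equal_means, 1.0, p)
    higher = mean1 > mean2
    if alternative == "greater":
        p = np.where(degenerate & ~equal_means, np.where(higher, P_FLOOR, 1.0), p)
    else:
        p = np.where(degenerate & ~equal_means, P_FLOOR, p)
    p = np.where((n1 < 2) | (n2 < 2), 1.0, p)
    return p


@dataclass
class CisRegulatoryNetwork:
    """Bipartite gene-motif graph keeping scores strictly above a cutoff."""

    genes: list[str]
    motifs: list[str]
    edges: dict[tuple[str, str], float]
    cutoff: float

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def to_graph(self):
        import networkx as nx

        g = nx.Graph()
        g.add_nodes_from(self.genes, bipartite="gene")
        g.add_nodes_from(self.motifs, bipartite="motif")
        for (u, v), w in self.edges.items():
            g.add_edge(u, v, score=w)
        return g


def build_crn(result: EnrichmentResult, cutoff: float) -> CisRegulatoryNetwork:
    """Threshold the score matrix: edge iff s_uv > cutoff (strict).

    Genes and motifs with no retained edge are omitted.
    """
    if cutoff < 0:
        raise ValueError("cutoff must be >= 0")
    ii, jj = np.nonzero(result.scores > cutoff)
    edges = {
        (result.gene_ids[i], result.motifs[j]): float(result.scores[i, j])
        for i, j in zip(ii.tolist(), jj.tolist())
    }
    genes = sorted({u for u, _ in edges})
    motifs = sorted({v for _, v in edges})
    return CisRegulatoryNetwork(genes, motifs, edges, cutoff)


def export_crn(crn: CisRegulatoryNetwork, path, format: str = "tsv") -> None:
    """Write the bipartite network; TSV rows sorted by (gene, motif)."""
    if format == "tsv":
        with open(path, "w") as fh:
            fh.write("gene\tmotif\tscore\n")
            for (u, v) in sorted(crn.edges):
                fh.write(f"{u}\t{v}\t{crn.edges[(u, v)]:.6g}\n")
    elif format == "graphml":
        import networkx as nx

        nx.write_graphml(crn.to_graph(), path)
    else:
        raise ValueError(f"unknown format {format!r}")


def read_crn_tsv(path, cutoff: float = 0.0) -> CisRegulatoryNetwork:
    df = pd.read_csv(path, sep="\t")
    edges = {
        (str(r.gene), str(r.motif)): float(r.score) for r in df.itertuples(index=False)
    }
    genes = sorted({u for u, _ in edges})
    motifs = sorted({v for _, v in edges})
    return CisRegulatoryNetwork(genes, motifs, edges, cutoff)
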