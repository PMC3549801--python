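"""Indirect evaluation of a predicted cis-regulatory network.

Two complementary strategies:

1. *Co-regulatory network comparison.*  Genes sharing many regulatory
   elements should be functionally related, so the Pearson similarity of
   their motif-score rows, thresholded into a gene-gene graph, is
   compared edge-by-edge against a reference network (annotated regulons,
   ChIP co-binding, or a synthetic module clique graph) via the usual
   confusion-matrix metrics over all unordered gene pairs.

2. *Per-array expression modeling.*  If the network is right, a gene's
   motif scores should predict its expression: for each array, expression
   is regressed on the top-``n_features`` motif columns (by absolute
   correlation with that array) and in-sample RMSE and PCC are reported.
   The same machinery accepts raw k-mer counts (the naive baseline) or
   any other gene x feature matrix.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .coexpression import CoexpressionNetwork, ExpressionMatrix
from .enrichment import EnrichmentResult

logger = logging.getLogger(__name__)

Edge = tuple[str, str]


def _norm_edge(a: str, b: str) -> Edge:
    return (a, b) if a <= b else (b, a)


@dataclass
class CoRegulatoryNetwork:
    gene_ids: list[str]
    edges: set[Edge]
    similarity_threshold: float | None = None

    def __post_init__(self) -> None:
        nodes = set(self.gene_ids)
        for a, b in self.edges:
            if a == b or a not in nodes or b not in nodes:
                raise ValueError(f"invalid edge ({a}, {b})")


@dataclass
class ComparisonMetrics:
    TP: int
    FP: int
    TN: int
    FN: int
    n_common_genes: int

    @property
    def PPV(self) -> float:
        return self.TP / (self.TP + self.FP) if self.TP + self.FP else 0.0

    @property
    def TPR(self) -> float:
        return self.TP / (self.TP + self.FN) if self.TP + self.FN else 0.0


@dataclass
class RegressionFit:
    array_id: str
    selected_motifs: list[str]
    coefficients: np.ndarray
    intercept: float
    rmse: float
    pcc: float
    fitted: np.ndarray | None = None


def gene_similarity(scores: EnrichmentResult | np.ndarray) -> np.ndarray:
    """Pairwise Pearson correlation of gene score rows; diagonal 1.

    Rows with zero variance have undefined correlations: their
    off-diagonal entries are NaN ("no edge possible" markers).
    """
    mat = scores.scores if isinstance(scores, EnrichmentResult) else np.asarray(scores, float)
    if mat.shape[0] < 2:
        raise ValueError("need >= 2 genes")
    sd = mat.std(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        sim = np.corrcoef(mat)
    sim[sd == 0, :] = np.nan
    sim[:, sd == 0] = np.nan
    np.fill_diagonal(sim, 1.0)
    return sim


def build_coreg_network(
    similarity: np.ndarray,
    threshold: float,
    gene_ids: list[str],
) -> CoRegulatoryNetwork:
    """Edge iff similarity > threshold (strict); NaN entries never edges."""
    n = len(gene_ids)
    if similarity.shape != (n, n):
        raise ValueError("similarity must be n x n for the given gene_ids")
    ii, jj = np.nonzero(np.triu(similarity > threshold, k=1))
    edges = {_norm_edge(gene_ids[i], gene_ids[j]) for i, j in zip(ii.tolist(), jj.tolist())}
    return CoRegulatoryNetwork(list(gene_ids), edges, threshold)


def network_from_edgelist(path) -> CoRegulatoryNetwork:
    """Reference network from a two-column TSV edge list."""
    genes: list[str] = []
    seen: set[str] = set()
    edges: set[Edge] = set()
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
            if a != b:
                edges.add(_norm_edge(a, b))
    return CoRegulatoryNetwork(genes, edges)


def intersect_networks(
    n1: CoRegulatoryNetwork, n2: CoRegulatoryNetwork
) -> tuple[CoRegulatoryNetwork, CoRegulatoryNetwork]:
    """Restrict both networks to their common gene set."""
    common = set(n1.gene_ids) & set(n2.gene_ids)
    if not common:
        raise ValueError("networks share no genes")

    def restrict(net: CoRegulatoryNetwork) -> CoRegulatoryNetwork:
        genes = [g for g in net.gene_ids if g in common]
        edges = {e for e in net.edges if e[0] in common and e[1] in common}
        return CoRegulatoryNetwork(genes, edges, net.similarity_threshold)

    return restrict(n1), restrict(n2)


def compare_networks(
    predicted: CoRegulatoryNetwork, reference: CoRegulatoryNetwork
) -> ComparisonMetrics:
    """Confusion matrix over all C(n,2) unordered pairs of the common genes."""
    if set(predicted.gene_ids) != set(reference.gene_ids):
        raise ValueError("node sets differ; call intersect_networks first")
    n = len(predicted.gene_ids)
    total = n * (n - 1) // 2
    tp = len(predicted.edges & reference.edges)
    fp = len(predicted.edges - reference.edges)
    fn = len(reference.edges - predicted.edges)
    tn = total - tp - fp - fn
    return ComparisonMetrics(TP=tp, FP=fp, TN=tn, FN=fn, n_common_genes=n)


def pr_curve(
    similarity: np.ndarray,
    gene_ids: list[str],
    reference: CoRegulatoryNetwork,
    thresholds="auto",
) -> pd.DataFrame:
    """Precision/recall sweep of the similarity threshold.

    ``"auto"`` sweeps the sorted unique finite similarity values.  Rows
    are ordered by decreasing threshold, along which recall (TPR) is
    non-decreasing.
    """
    if set(reference.gene_ids) - set(gene_ids):
        raise ValueError("reference contains genes absent from the similarity matrix")
    if isinstance(thresholds, str) and thresholds == "auto":
        upper = similarity[np.triu_indices_from(similarity, k=1)]
        vals = np.unique(upper[np.isfinite(upper)])
        # a threshold just below each value, so edges at that value are kept
        thresholds = np.nextafter(vals, -np.inf)
    rows = []
    for t in sorted(np.atleast_1d(np.asarray(thresholds, float)), reverse=True):
        pred = build_coreg_network(similarity, t, gene_ids)
        p, r = intersect_networks(pred, reference)
        m = compare_networks(p, r)
        rows.append(
            {"threshold": t, "TP": m.TP, "FP": m.FP, "TN": m.TN, "FN": m.FN,
             "PPV": m.PPV, "TPR": m.TPR}
        )
    return pd.DataFrame(rows)


def plot_pr_curve(table: pd.DataFrame, path) -> None:
    """Convenience precision-recall figure from a pr_curve table."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 4))
    ax.plot(table["TPR"], table["PPV"], marker=".", lw=1)
    ax.set_xlabel("Recall (TPR)")
    ax.set_ylabel("Precision (PPV)")
    ax.set_ylim(0, 1.02)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def _safe_corr_columns(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Pearson correlation of each column of X with y; NaN where undefined."""
    Xc = X - X.mean(axis=0)
    yc = y - y.mean()
    sx = np.sqrt((Xc ** 2).sum(axis=0))
    sy = np.sqrt((yc ** 2).sum())
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = (Xc.T @ yc) / (sx * sy)
    corr[sx == 0] = np.nan
    if sy == 0:
        corr[:] = np.nan
    return corr


def select_top_motifs(
    scores: EnrichmentResult,
    expr_vector: np.ndarray,
    n_features: int,
    absolute: bool = True,
) -> list[str]:
    """Motifs whose score columns correlate most with the expression vector.

    Absolute correlation by default (repressive motifs selectable);
    zero-variance columns are excluded; ties break lexicographically.
    """
    if n_features < 1:
        raise ValueError("n_features must be >= 1")
    y = np.asarray(expr_vector, float)
    if y.shape[0] != len(scores.gene_ids):
        raise ValueError("expr_vector must align with scores' gene order")
    corr = _safe_corr_columns(scores.scores, y)
    strength = np.abs(corr) if absolute else corr
    valid = np.isfinite(strength)
    if not valid.any():
        logger.warning("no valid motif columns (all zero variance)")
        return []
    idx = np.nonzero(valid)[0]
    order = sorted(idx.tolist(), key=lambda j: (-strength[j], scores.motifs[j]))
    if len(order) < n_features:
        logger.warning("only %d valid motif columns < n_features=%d", len(order), n_features)
    return [scores.motifs[j] for j in order[:n_features]]


def fit_expression_model(
    scores: EnrichmentResult,
    expr_vector: np.ndarray,
    n_features: int,
    array_id: str = "",
    absolute: bool = True,
) -> RegressionFit:
    """OLS of expression on the selected motif score columns plus intercept.

    Rank-deficient designs get the minimum-norm least-squares solution.
    Reports in-sample RMSE and the PCC between fitted and observed values.
    """
    y = np.asarray(expr_vector, float)
    if n_features == 0:
        selected: list[str] = []
    else:
        selected = select_top_motifs(scores, y, n_features, absolute=absolute)
    cols = [scores.motifs.index(m) for m in selected]
    X = scores.scores[:, cols]
    design = np.column_stack([X, np.ones(len(y))])
    beta, *_ = np.linalg.lstsq(design, y, rcond=None)
    fitted = design @ beta
    resid = y - fitted
    rmse = float(np.sqrt(np.mean(resid ** 2)))
    if fitted.std() == 0 or y.std() == 0:
        pcc = 0.0
    else:
        pcc = float(np.corrcoef(fitted, y)[0, 1])
    return RegressionFit(
        array_id=array_id,
        selected_motifs=selected,
        coefficients=beta[:-1],
        intercept=float(beta[-1]),
        rmse=rmse,
        pcc=pcc,
        fitted=fitted,
    )


def evaluate_model_per_array(
    scores_or_counts,
    expr: ExpressionMatrix,
    n_features: int,
    absolute: bool = True,
) -> pd.DataFrame:
    """One regression per array; returns a tidy per-array report.

    Accepts an EnrichmentResult (main model on scores), a KmerCountTable
    (naive count baseline), a CoexpressionNetwork (adjacency rows as
    features), or any aligned gene x feature DataFrame.  Genes are
    intersected with the expression matrix; the final row 'mean' carries
    the across-array mean RMSE and PCC.
    """
    feats = _as_feature_result(scores_or_counts)
    common = [g for g in feats.gene_ids if g in set(expr.gene_ids)]
    if not common:
        raise ValueError("no genes shared between features and expression")
    if len(common) < len(feats.gene_ids) or len(common) < expr.n_genes:
        logger.info("restricting to %d shared genes", len(common))
    fpos = {g: i for i, g in enumerate(feats.gene_ids)}
    feats = EnrichmentResult(
        gene_ids=common,
        motifs=feats.motifs,
        pvalues=feats.pvalues[[fpos[g] for g in common]],
        scores=feats.scores[[fpos[g] for g in common]],
        cap=feats.cap,
        method=feats.method,
    )
    epos = {g: i for i, g in enumerate(expr.gene_ids)}
    evalues = expr.values[[epos[g] for g in common]]
    rows = []
    for a, array_id in enumerate(expr.array_ids):
        fit = fit_expression_model(
            feats, evalues[:, a], n_features, array_id=array_id, absolute=absolute
        )
        rows.append(
            {"array_id": array_id, "rmse": fit.rmse, "pcc": fit.pcc,
             "n_features": len(fit.selected_motifs)}
        )
    report = pd.DataFrame(rows)
    summary = pd.DataFrame(
        [{"array_id": "mean", "rmse": report["rmse"].mean(),
          "pcc": report["pcc"].mean(), "n_features": n_features}]
    )
    return pd.concat([report, summary], ignore_index=True)


def _as_feature_result(obj) -> EnrichmentResult:
    from .kmer_counts import KmerCountTable

    if isinstance(obj, EnrichmentResult):
        return obj
    if isinstance(obj, KmerCountTable):
        mat = obj.counts.astype(float)
        return EnrichmentResult(
            gene_ids=list(obj.gene_ids), motifs=list(obj.motifs),
            pvalues=np.ones_like(mat), scores=mat, method="counts",
        )
    if isinstance(obj, CoexpressionNetwork):
        mat = obj.adjacency.astype(float)
        return EnrichmentResult(
            gene_ids=list(obj.gene_ids), motifs=list(obj.gene_ids),
            pvalues=np.ones_like(mat), scores=mat, method="adjacency",
        )
    if isinstance(obj, pd.DataFrame):
        return EnrichmentResult(
            gene_ids=[str(g) for g in obj.index],
            motifs=[str(c) for c in obj.columns],
            pvalues=np.ones(obj.shape), scores=obj.to_numpy(float), method="features",
        )
    raise TypeError(f"unsupported feature container {type(obj)!r}")
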