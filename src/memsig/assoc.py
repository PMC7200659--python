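"""Downstream discrimination and association statistics.

Hierarchical clustering of binned divergence vectors (Ward linkage),
PCA followed by linear discriminant classification with leave-one-out
accuracy, the methylation-divergence vs expression association
(Spearman per expression stratum plus a linear-by-linear trend test on
rank-binned grids), and interval joins between feature sets.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import fcluster, leaves_list, linkage

from memsig.bsio import GenomicAnnotation

__all__ = [
    "ClusterResult",
    "AssociationResult",
    "hierarchical_cluster",
    "pca_lda",
    "md_per_gene",
    "md_expression_assoc",
    "interval_join",
    "set_overlap",
]


@dataclass
class ClusterResult:
    linkage_matrix: np.ndarray
    sample_ids: list[str]
    leaf_order: list[str]

    def cut(self, n_clades: int) -> pd.Series:
        labels = fcluster(self.linkage_matrix, t=n_clades, criterion="maxclust")
        return pd.Series(labels, index=self.sample_ids)

    def to_newick(self) -> str:
        from skbio.tree import TreeNode

        tree = TreeNode.from_linkage_matrix(self.linkage_matrix, self.sample_ids)
        return str(tree).strip()


@dataclass
class AssociationResult:
    spearman_rho_up: float
    spearman_rho_down: float
    lbl_stat: float  # linear-by-linear M^2
    lbl_p: float
    n_genes: int


def hierarchical_cluster(matrix: pd.DataFrame, method: str = "ward") -> ClusterResult:
    """Ward-linkage clustering of sample vectors (rows) on Euclidean
    distances. scipy's "ward" update on unsquared Euclidean input is the
    Ward.D2 variant; merge heights are monotone non-decreasing."""
    if matrix.shape[0] < 3:
        raise ValueError("clustering needs >= 3 samples")
    if not np.any(matrix.to_numpy()):
        import warnings

        warnings.warn("all-zero matrix: every merge is at height 0", stacklevel=2)
    Z = linkage(matrix.to_numpy(float), method=method, metric="euclidean")
    order = [matrix.index[i] for i in leaves_list(Z)]
    return ClusterResult(Z, list(matrix.index), order)


def pca_lda(
    matrix: pd.DataFrame,
    labels: pd.Series,
    var_explained: float = 0.9,
) -> tuple[pd.DataFrame, float]:
    """PCA projection (fewest centered/scaled components reaching
    ``var_explained``) followed by linear discriminant analysis.

    Returns the discriminant projections of all samples and the
    leave-one-out classification accuracy (PCA and LDA refit in every
    fold). Classes with a single sample are skipped in LOO with a
    warning."""
    from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
    from sklearn.decomposition import PCA
    from sklearn.preprocessing import StandardScaler

    X = matrix.to_numpy(float)
    y = np.asarray(labels.loc[matrix.index])
    if len(np.unique(y)) < 2:
        raise ValueError("need >= 2 classes")

    def fit_chain(X_tr, y_tr):
        scaler = StandardScaler().fit(X_tr)
        Xs = scaler.transform(X_tr)
        pca = PCA(n_components=min(Xs.shape) - 1 or 1).fit(Xs)
        cum = np.cumsum(pca.explained_variance_ratio_)
        k = int(np.searchsorted(cum, var_explained) + 1)
        k = min(k, pca.n_components_)
        lda = LinearDiscriminantAnalysis().fit(pca.transform(Xs)[:, :k], y_tr)
        return scaler, pca, k, lda

    scaler, pca, k, lda = fit_chain(X, y)
    proj = lda.transform(pca.transform(scaler.transform(X))[:, :k])
    proj_df = pd.DataFrame(
        proj, index=matrix.index, columns=[f"LD{i + 1}" for i in range(proj.shape[1])]
    )

    counts = pd.Series(y).value_counts()
    singletons = set(counts.index[counts < 2])
    if singletons:
        import warnings

        warnings.warn(f"LOO skips single-sample classes: {sorted(map(str, singletons))}",
                      stacklevel=2)
    correct = 0
    total = 0
    for i in range(len(y)):
        if y[i] in singletons:
            continue
        mask = np.ones(len(y), dtype=bool)
        mask[i] = False
        sc, pc, kk, ld = fit_chain(X[mask], y[mask])
        pred = ld.predict(pc.transform(sc.transform(X[i:i + 1]))[:, :kk])[0]
        correct += int(pred == y[i])
        total += 1
    loo_accuracy = correct / total if total else float("nan")
    return proj_df, loo_accuracy


def md_per_gene(
    div_tables: list[pd.DataFrame],
    annotation: GenomicAnnotation,
    stat: str = "sum",
) -> pd.Series:
    """Methylation divergence per gene: the sum (default; mean by flag) of
    HD over the extended gene region, averaged across the supplied sample
    divergence tables."""
    from intervaltree import IntervalTree

    genes = annotation.genes()
    trees: dict[str, IntervalTree] = {}
    for chrom, s, e, gid in zip(genes["chrom"], genes["extended_start"],
                                genes["extended_end"], genes["feature_id"]):
        trees.setdefault(chrom, IntervalTree()).addi(int(s), int(e) + 1, gid)
    acc = pd.DataFrame(0.0, index=list(genes["feature_id"]),
                       columns=range(len(div_tables)))
    cnt = acc.copy()
    for j, dt in enumerate(div_tables):
        for row in dt.itertuples():
            tree = trees.get(row.chrom)
            if tree is None:
                continue
            for iv in tree.at(int(row.pos)):
                acc.loc[iv.data, j] += row.hd
                cnt.loc[iv.data, j] += 1
    if stat == "sum":
        per_sample = acc
    elif stat == "mean":
        with np.errstate(invalid="ignore"):
            per_sample = acc / cnt.replace(0, np.nan)
        per_sample = per_sample.fillna(0.0)
    else:
        raise ValueError(f"unknown stat {stat!r}")
    return per_sample.mean(axis=1)


def linear_by_linear(x, y, n_bins: int = 10) -> tuple[float, float]:
    """Linear-by-linear association on equal-frequency rank-binned grids.

    Both variables are cut into (up to) ``n_bins`` equal-frequency ordinal
    classes scored by bin index; M^2 = (N - 1) r^2 with r the Pearson
    correlation of the scores, referred to chi-squared with 1 df.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    bx = pd.qcut(pd.Series(x).rank(method="first"), q=n_bins, labels=False, duplicates="drop")
    by = pd.qcut(pd.Series(y).rank(method="first"), q=n_bins, labels=False, duplicates="drop")
    r = np.corrcoef(bx, by)[0, 1]
    if not np.isfinite(r):
        return 0.0, 1.0
    m2 = (len(x) - 1) * r**2
    return float(m2), float(stats.chi2.sf(m2, df=1))


def md_expression_assoc(
    md: pd.Series, expression: pd.DataFrame, n_bins: int = 10
) -> AssociationResult:
    """Association of per-gene methylation divergence with expression
    divergence.

    Only genes with MD > 0 enter. Expression is split into up
    (log2fc > 0) and down (log2fc < 0) strata; within each, Spearman's
    rho of MD against |log2fc| is reported, and the pooled
    linear-by-linear trend statistic tests for a monotone association.
    Strata with fewer than 10 genes get a warning.
    """
    expr = expression.set_index("gene_id")
    genes = md.index.intersection(expr.index)
    md = md.loc[genes]
    md = md[md > 0]
    expr = expr.loc[md.index]

    rhos = {}
    for name, mask in (("up", expr["log2fc"] > 0), ("down", expr["log2fc"] < 0)):
        sub = expr[mask]
        if len(sub) < 10:
            import warnings

            warnings.warn(f"{name}-stratum has only {len(sub)} genes", stacklevel=2)
        if len(sub) >= 2:
            rhos[name] = float(stats.spearmanr(md.loc[sub.index], sub["log2fc"].abs())[0])
        else:
            rhos[name] = float("nan")
    m2, p = linear_by_linear(md.to_numpy(), expr["log2fc"].abs().to_numpy(), n_bins)
    return AssociationResult(
        spearman_rho_up=rhos["up"], spearman_rho_down=rhos["down"],
        lbl_stat=m2, lbl_p=p, n_genes=len(md),
    )


def interval_join(
    clusters: pd.DataFrame, annotation: GenomicAnnotation, dist: int = 1000
) -> set[str]:
    """Genes whose body lies within ``dist`` of any interval in
    ``clusters`` (columns chrom, start, end; overlap counts)."""
    from intervaltree import IntervalTree

    trees: dict[str, IntervalTree] = {}
    for row in clusters.itertuples():
        trees.setdefault(row.chrom, IntervalTree()).addi(int(row.start), int(row.end) + 1)
    joined: set[str] = set()
    for row in annotation.genes().itertuples():
        tree = trees.get(row.chrom)
        if tree is not None and tree.overlap(int(row.start) - dist, int(row.end) + dist + 1):
            joined.add(row.feature_id)
    return joined


def set_overlap(a: set[str], b: set[str]) -> tuple[int, float, float]:
    """Intersection size and the fraction of each set it covers."""
    a, b = set(a), set(b)
    n = len(a & b)
    return n, n / len(a) if a else 0.0, n / len(b) if b else 0.0
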