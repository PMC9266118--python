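"""Per-condition unsupervised clustering, cluster profiles and marker genes.

The clustering stage reduces the normalized matrix to its top variable genes,
embeds cells in a 10-dimensional PCA space and partitions them either by
Leiden community detection on a kNN graph (``method="leiden"``) or by k-means
with model selection over k by mean silhouette (``method="kmeans"``, the
default: on centroid-level analyses the number of clusters must be emergent
and reproducible across platforms, and silhouette-selected k-means is both).

Cluster profiles store mean expression per gene on the linear
(counts-per-10k) scale — the unit in which average marker expression values
and the differentiation-score ranges are conventionally printed.

Characteristic markers are one-vs-rest Wilcoxon rank-sum tests with
Benjamini–Hochberg correction across genes within each cluster, ranked by
log fold change.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.stats import mannwhitneyu
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA
from sklearn.metrics import silhouette_score
from sklearn.neighbors import NearestNeighbors
from statsmodels.stats.multitest import multipletests

from .preprocess import NormalizedMatrix


class ClusteringError(ValueError):
    pass


@dataclass
class ClusterLabeling:
    """Cell → cluster assignment for one condition."""

    cell_ids: list[str]
    labels: list[str]                 # cluster id per cell, e.g. "EC1"
    condition: str
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.cell_ids) != len(self.labels):
            raise ClusteringError("labels do not cover the cells")

    @property
    def n_clusters(self) -> int:
        return len(set(self.labels))

    def cluster_ids(self) -> list[str]:
        """Cluster ids ordered by decreasing size (ties: lexicographic)."""
        counts = pd.Series(self.labels).value_counts()
        return sorted(counts.index, key=lambda c: (-counts[c], c))

    def sizes(self) -> dict[str, int]:
        return dict(pd.Series(self.labels).value_counts())

    def mapping(self) -> dict[str, str]:
        return dict(zip(self.cell_ids, self.labels))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"cell_id": self.cell_ids, "cluster_id": self.labels})


@dataclass
class ClusterProfile:
    """Per-cluster summary: size and mean linear expression per gene."""

    cluster_id: str
    condition: str
    n_cells: int
    mean_expr: pd.Series              # gene -> mean counts-per-10k
    epithelial: bool | None = None    # set by the classification stage

    @property
    def label(self) -> str:
        return f"{self.cluster_id}|{self.condition}"


def variable_genes(nm: NormalizedMatrix, n_top: int = 500) -> list[str]:
    """Top genes by standardized dispersion (variance / mean of log expr)."""
    x = nm.expr
    mean = np.asarray(x.mean(axis=0)).ravel()
    sq = np.asarray(x.multiply(x).mean(axis=0)).ravel()
    var = np.maximum(sq - mean**2, 0.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        disp = np.where(mean > 0, var / mean, 0.0)
    order = np.argsort(-disp, kind="stable")[:n_top]
    return [nm.gene_symbols[i] for i in sorted(order)]


def _pca_embedding(
    nm: NormalizedMatrix, n_pcs: int, n_var_genes: int, seed: int
) -> np.ndarray:
    if nm.n_cells < 2:
        raise ClusteringError("need at least 2 cells")
    if n_pcs > min(nm.n_cells, nm.n_genes) - 1:
        raise ClusteringError(
            f"n_pcs={n_pcs} too large for a {nm.n_cells}x{nm.n_genes} matrix"
        )
    genes = variable_genes(nm, n_var_genes)
    idx = [nm.gene_index()[g] for g in genes]
    x = np.asarray(nm.expr[:, idx].todense())
    sd = x.std(axis=0)
    if not (sd > 0).any():
        raise ClusteringError("degenerate constant matrix")
    keep = sd > 0
    x = (x[:, keep] - x[:, keep].mean(axis=0)) / sd[keep]
    n_pcs = min(n_pcs, x.shape[1] - 1) if x.shape[1] > 1 else 1
    pca = PCA(n_components=n_pcs, svd_solver="full", random_state=seed)
    return pca.fit_transform(x)


def _leiden_labels(emb: np.ndarray, k: int, resolution: float, seed: int) -> np.ndarray:
    import igraph
    import leidenalg

    n = emb.shape[0]
    nn = NearestNeighbors(n_neighbors=min(k + 1, n)).fit(emb)
    _, ind = nn.kneighbors(emb)
    edges = {tuple(sorted((i, j))) for i, row in enumerate(ind) for j in row[1:]}
    g = igraph.Graph(n=n, edges=sorted(edges))
    part = leidenalg.find_partition(
        g,
        leidenalg.RBConfigurationVertexPartition,
        resolution_parameter=resolution,
        seed=seed,
        n_iterations=-1,
    )
    return np.asarray(part.membership)


def _kmeans_labels(
    emb: np.ndarray, k_range: tuple[int, int], seed: int
) -> np.ndarray:
    n = emb.shape[0]
    lo, hi = k_range
    hi = min(hi, n - 1)
    best, best_score = None, -np.inf
    for k in range(max(2, lo), hi + 1):
        km = KMeans(n_clusters=k, n_init=10, random_state=seed)
        lab = km.fit_predict(emb)
        if len(set(lab)) < 2:
            continue
        sample = 2000 if n > 2000 else None
        score = silhouette_score(emb, lab, sample_size=sample, random_state=seed)
        if score > best_score + 1e-12:
            best, best_score = lab, score
    if best is None:
        raise ClusteringError("model selection found no valid partition")
    return best


def cluster_cells(
    nm: NormalizedMatrix,
    n_pcs: int = 10,
    method: str = "kmeans",
    seed: int = 0,
    resolution: float = 1.0,
    knn: int = 20,
    k_range: tuple[int, int] = (2, 20),
    n_var_genes: int = 500,
    prefix: str = "EC",
) -> ClusterLabeling:
    """Partition cells into clusters; the number of clusters is emergent.

    Deterministic for a fixed seed.  Clusters are renamed by decreasing size
    as ``<prefix>1``, ``<prefix>2``, ... — the names are presentation-level
    only and no downstream logic depends on them.
    """
    emb = _pca_embedding(nm, n_pcs, n_var_genes, seed)
    if method == "leiden":
        raw = _leiden_labels(emb, knn, resolution, seed)
    elif method == "kmeans":
        raw = _kmeans_labels(emb, k_range, seed)
    else:
        raise ClusteringError(f"unknown clustering method {method!r}")
    # stable renaming by decreasing cluster size (ties: first appearance)
    sizes = pd.Series(raw).value_counts()
    first_seen = {lab: i for i, lab in reversed(list(enumerate(raw)))}
    order = sorted(sizes.index, key=lambda l: (-sizes[l], first_seen[l]))
    rename = {lab: f"{prefix}{i + 1}" for i, lab in enumerate(order)}
    return ClusterLabeling(
        cell_ids=list(nm.cell_ids),
        labels=[rename[l] for l in raw],
        condition=nm.condition,
        params={
            "n_pcs": n_pcs,
            "method": method,
            "seed": seed,
            "resolution": resolution,
            "knn": knn,
            "k_range": list(k_range),
            "n_var_genes": n_var_genes,
        },
    )


def profile_clusters(
    nm: NormalizedMatrix, labels: ClusterLabeling, scale: str = "linear"
) -> list[ClusterProfile]:
    """Summarize clusters as mean expression vectors.

    ``scale="linear"`` averages counts-per-10k values (expm1 of the log
    matrix), matching how average marker expression is printed;
    ``scale="log"`` averages the log-normalized matrix directly.
    """
    if labels.cell_ids != nm.cell_ids:
        raise ClusteringError("labeling does not match the matrix cells")
    mat = nm.linear() if scale == "linear" else nm.expr
    lab = np.asarray(labels.labels)
    profiles = []
    for cid in labels.cluster_ids():
        mask = lab == cid
        mean = np.asarray(mat[mask].mean(axis=0)).ravel()
        profiles.append(
            ClusterProfile(
                cluster_id=cid,
                condition=labels.condition,
                n_cells=int(mask.sum()),
                mean_expr=pd.Series(mean, index=nm.gene_symbols),
            )
        )
    return profiles


def profiles_to_frame(profiles: list[ClusterProfile]) -> pd.DataFrame:
    """Long-format cluster x gene mean table."""
    rows = []
    for p in profiles:
        df = pd.DataFrame(
            {"gene": p.mean_expr.index, "mean_expr": p.mean_expr.to_numpy()}
        )
        df.insert(0, "cluster_id", p.cluster_id)
        df.insert(1, "condition", p.condition)
        df.insert(2, "n_cells", p.n_cells)
        rows.append(df)
    return pd.concat(rows, ignore_index=True)


def find_markers(
    nm: NormalizedMatrix,
    labels: ClusterLabeling,
    min_lfc: float = 0.25,
    alpha: float = 0.05,
    pseudocount: float = 0.01,
) -> pd.DataFrame:
    """One-vs-rest Wilcoxon rank-sum marker table.

    Per cluster, reports genes with BH-adjusted p <= alpha and natural-log
    fold change (linear-scale means, pseudocount added) >= min_lfc, ranked by
    LFC descending; ties broken by adjusted p, then gene symbol.
    Columns: cluster_id, gene, log_fold_change, statistic, p_value,
    adj_p_value, rank.
    """
    if labels.n_clusters < 2:
        raise ClusteringError("markers undefined for fewer than 2 clusters")
    if labels.cell_ids != nm.cell_ids:
        raise ClusteringError("labeling does not match the matrix cells")
    lab = np.asarray(labels.labels)
    logx = np.asarray(nm.expr.todense())
    linx = np.expm1(logx)
    out = []
    for cid in labels.cluster_ids():
        mask = lab == cid
        a, b = logx[mask], logx[~mask]
        stat, p = mannwhitneyu(a, b, axis=0, alternative="two-sided")
        p = np.asarray(p)
        adj = multipletests(p, method="fdr_bh")[1]
        lfc = np.log(
            (linx[mask].mean(axis=0) + pseudocount)
            / (linx[~mask].mean(axis=0) + pseudocount)
        )
        df = pd.DataFrame(
            {
                "cluster_id": cid,
                "gene": nm.gene_symbols,
                "log_fold_change": lfc,
                "statistic": np.asarray(stat),
                "p_value": p,
                "adj_p_value": adj,
            }
        )
        hits = df[(df.adj_p_value <= alpha) & (df.log_fold_change >= min_lfc)]
        hits = hits.sort_values(
            ["log_fold_change", "adj_p_value", "gene"],
            ascending=[False, True, True],
            kind="stable",
        ).reset_index(drop=True)
        hits["rank"] = np.arange(1, len(hits) + 1)
        out.append(hits)
    return pd.concat(out, ignore_index=True)


def marker_pvalues(
    nm: NormalizedMatrix, labels: ClusterLabeling
) -> pd.DataFrame:
    """Raw one-vs-rest rank-sum p-values for every (cluster, gene) pair."""
    if labels.n_clusters < 2:
        raise ClusteringError("markers undefined for fewer than 2 clusters")
    lab = np.asarray(labels.labels)
    logx = np.asarray(nm.expr.todense())
    rows = []
    for cid in labels.cluster_ids():
        mask = lab == cid
        _, p = mannwhitneyu(logx[mask], logx[~mask], axis=0, alternative="two-sided")
        rows.append(pd.DataFrame({"cluster_id": cid, "gene": nm.gene_symbols,
                                  "p_value": np.asarray(p)}))
    return pd.concat(rows, ignore_index=True)
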