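"""Two-cluster transcriptomic subtyping.

The workflow: log-space expression over the top variable genes is
decomposed by PCA (samples as observations), samples are split into two
clusters by seeded k-means on the leading principal coordinates (or by
hierarchical clustering of a gene panel with correlation distance), and the
cluster with the higher mean EMT index is labelled the mesenchymal subtype,
its counterpart the HRR-activated subtype.  Genes strongly correlated with
PC1 (|r| above a threshold) recover the subtype-defining expression
programs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import pdist
from sklearn.decomposition import PCA

from .emt import EMTIndexResult
from .expression import ExpressionMatrix, GenePanel, Unit

__all__ = [
    "PCAResult",
    "ClusterAssignment",
    "SUBTYPE_HRR",
    "SUBTYPE_MES",
    "pca",
    "kmeans_two",
    "hierarchical_two",
    "pc1_gene_correlation",
    "assign_subtype",
]

SUBTYPE_HRR = "HRR-activated"
SUBTYPE_MES = "mesenchymal"

DEFAULT_KMEANS_SEED = 17
DEFAULT_KMEANS_RESTARTS = 50


@dataclass(frozen=True)
class PCAResult:
    """Principal components of a gene-centered expression matrix."""

    coordinates: pd.DataFrame  # samples x components ("PC1", "PC2", ...)
    loadings: pd.DataFrame  # genes x components
    variance_explained: np.ndarray  # fraction per component, non-increasing

    @property
    def samples(self) -> list[str]:
        return list(self.coordinates.index)

    def pc(self, k: int) -> pd.Series:
        """1-based accessor for the k-th component's sample coordinates."""
        return self.coordinates[f"PC{k}"]


@dataclass(frozen=True)
class ClusterAssignment:
    """Two-cluster sample partition with optional subtype labels."""

    clusters: pd.Series  # sample ID -> "A" / "B"
    method: str  # "kmeans" / "hierarchical"
    subtypes: pd.Series | None = None  # sample ID -> SUBTYPE_* once assigned
    tie_flag: bool = False

    @property
    def samples(self) -> list[str]:
        return list(self.clusters.index)

    def members(self, label: str) -> list[str]:
        return list(self.clusters.index[self.clusters == label])


def pca(
    m: ExpressionMatrix,
    panel: GenePanel | None = None,
    n_components: int = 2,
) -> PCAResult:
    """PCA with samples as observations and genes as (centered) features.

    ``panel`` restricts the gene set (e.g. the top-5000 variable genes);
    omitted, all genes are used.  Deterministic up to component sign.
    """
    sub = m if panel is None else m.subset_genes(list(panel), strict=True)
    X = sub.values.to_numpy().T  # samples x genes
    n_samples, n_genes = X.shape
    if n_samples < 2:
        raise ValueError("PCA requires at least 2 samples")
    max_comp = min(n_samples - 1, n_genes)
    if not 1 <= n_components <= max_comp:
        raise ValueError(f"n_components must be in [1, {max_comp}], got {n_components}")
    dec = PCA(n_components=n_components, svd_solver="full")
    coords = dec.fit_transform(X)
    names = [f"PC{i + 1}" for i in range(n_components)]
    return PCAResult(
        coordinates=pd.DataFrame(coords, index=sub.samples, columns=names),
        loadings=pd.DataFrame(dec.components_.T, index=sub.genes, columns=names),
        variance_explained=dec.explained_variance_ratio_.copy(),
    )


def kmeans_two(
    coords: pd.DataFrame,
    seed: int = DEFAULT_KMEANS_SEED,
    restarts: int = DEFAULT_KMEANS_RESTARTS,
    emt: EMTIndexResult | None = None,
) -> ClusterAssignment:
    """Seeded k-means with k=2 on sample coordinates.

    Best of ``restarts`` initialisations by within-cluster sum of squares.
    Cluster "A" is the one with the lower mean EMT index when ``emt`` is
    supplied; otherwise the cluster containing the first sample.
    """
    from sklearn.cluster import KMeans

    X = coords.to_numpy(dtype=float)
    if X.shape[0] < 2:
        raise ValueError("k-means requires at least 2 samples")
    if np.unique(X, axis=0).shape[0] < 2:
        raise ValueError("k-means requires at least 2 distinct points")
    km = KMeans(n_clusters=2, n_init=restarts, random_state=seed)
    raw = km.fit_predict(X)
    return _orient_two_clusters(pd.Series(raw, index=coords.index), "kmeans", emt)


def hierarchical_two(
    m: ExpressionMatrix,
    panel: GenePanel,
    emt: EMTIndexResult | None = None,
) -> ClusterAssignment:
    """Average-linkage hierarchical clustering of samples on a gene panel.

    Genes are z-scored, the sample-sample distance is 1 - Pearson
    correlation, and the tree is cut into two clusters — the common
    expression-heatmap defaults.
    """
    if m.unit != Unit.LOG2:
        raise ValueError("hierarchical clustering expects a LOG2 matrix")
    sub = m.subset_genes(list(panel), strict=False)
    vals = sub.values
    sds = vals.std(axis=1, ddof=0)
    flat = sds[sds == 0].index
    if len(flat):
        if len(flat) == vals.shape[0]:
            raise ValueError("all panel genes have zero variance after subsetting")
        warnings.warn(f"dropping zero-variance gene(s): {list(flat)}")
        vals = vals.drop(index=flat)
        sds = sds.drop(index=flat)
    z = vals.sub(vals.mean(axis=1), axis=0).div(sds, axis=0)
    X = z.to_numpy().T  # samples x genes
    if X.shape[0] < 2:
        raise ValueError("hierarchical clustering requires at least 2 samples")
    dist = pdist(X, metric="correlation")
    tree = linkage(dist, method="average")
    raw = fcluster(tree, t=2, criterion="maxclust") - 1
    return _orient_two_clusters(pd.Series(raw, index=sub.samples), "hierarchical", emt)


def _orient_two_clusters(
    raw: pd.Series, method: str, emt: EMTIndexResult | None
) -> ClusterAssignment:
    labels = sorted(raw.unique())
    if len(labels) != 2:
        raise ValueError(f"expected exactly 2 clusters, got {len(labels)}")
    if emt is not None:
        idx = emt.index.reindex(raw.index)
        if idx.isna().any():
            raise ValueError("EMT index missing for some clustered samples")
        means = {lab: idx[raw == lab].mean() for lab in labels}
        # cluster A = lower mean EMT index (HRR-activated side)
        a_label = min(labels, key=lambda lab: (means[lab], lab))
    else:
        first_member = {lab: min(raw.index[raw == lab]) for lab in labels}
        a_label = min(labels, key=lambda lab: first_member[lab])
    named = raw.map(lambda v: "A" if v == a_label else "B").rename("cluster")
    return ClusterAssignment(named, method)


def pc1_gene_correlation(
    m: ExpressionMatrix,
    p: PCAResult,
    threshold: float = 0.9,
    emt: EMTIndexResult | None = None,
) -> tuple[GenePanel, GenePanel, list[str]]:
    """Split genes by Pearson correlation with PC1.

    Returns ``(negative_panel, positive_panel, skipped)`` where the panels
    hold genes with r < -threshold and r > +threshold and ``skipped`` lists
    constant genes (correlation undefined).  When ``emt`` is given, PC1 is
    sign-oriented so the EMT index correlates positively with it, making
    "positive set" mean mesenchymal-side genes.
    """
    if not 0 < threshold < 1:
        raise ValueError("threshold must lie in (0, 1)")
    if len(p.samples) < 3:
        raise ValueError("correlation requires >= 3 samples")
    pc1 = p.pc(1).reindex(m.samples)
    if pc1.isna().any():
        raise ValueError("PCA samples do not match the expression matrix")
    pc1 = pc1.to_numpy()
    if emt is not None:
        idx = emt.index.reindex(m.samples).to_numpy()
        r_orient = np.corrcoef(pc1, idx)[0, 1]
        if r_orient < 0:
            pc1 = -pc1
    X = m.values.to_numpy()
    centered = X - X.mean(axis=1, keepdims=True)
    gene_sd = centered.std(axis=1)
    skipped = [g for g, sd in zip(m.genes, gene_sd) if sd == 0]
    pc = pc1 - pc1.mean()
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (centered @ pc) / (
            np.sqrt((centered**2).sum(axis=1)) * np.sqrt((pc**2).sum())
        )
    genes = np.array(m.genes)
    ok = gene_sd > 0
    neg = tuple(genes[ok & (r < -threshold)])
    pos = tuple(genes[ok & (r > threshold)])
    neg_panel = GenePanel("pc1_negative", neg) if neg else None
    pos_panel = GenePanel("pc1_positive", pos) if pos else None
    # empty panels are represented as None (GenePanel forbids emptiness)
    return neg_panel, pos_panel, skipped


def assign_subtype(c: ClusterAssignment, r: EMTIndexResult) -> ClusterAssignment:
    """Label the cluster with the higher mean EMT index mesenchymal.

    The other cluster becomes HRR-activated.  On an exact tie of means the
    smaller cluster is called mesenchymal and the assignment is flagged.
    """
    idx = r.index.reindex(c.clusters.index)
    if idx.isna().any() or len(r.index) != len(c.clusters):
        raise ValueError("cluster assignment and EMT index cover different samples")
    means = {lab: idx[c.clusters == lab].mean() for lab in ("A", "B")}
    sizes = {lab: int((c.clusters == lab).sum()) for lab in ("A", "B")}
    tie = means["A"] == means["B"]
    if tie:
        mes = min(("A", "B"), key=lambda lab: (sizes[lab], lab))
        warnings.warn("cluster EMT-index means tie; labelling the smaller cluster mesenchymal")
    else:
        mes = max(("A", "B"), key=lambda lab: means[lab])
    subtype = c.clusters.map(lambda lab: SUBTYPE_MES if lab == mes else SUBTYPE_HRR)
    return replace(c, subtypes=subtype.rename("subtype"), tie_flag=tie)
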