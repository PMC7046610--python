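"""Two-way hierarchical clustering of a cohort on the EMT signature and
Epi/Mes label assignment.

Samples are clustered with distance 1 − centered (Pearson) correlation over
the signature genes and complete linkage, then the dendrogram is cut into
two clusters; the cluster with the higher mesenchymal-minus-epithelial
z-score contrast is labelled Mes. A gene dendrogram is computed the same
way on the transposed restricted matrix. The correlation/complete default
matches the clustering description used to derive the subgroups; distance
and linkage are configurable so the Euclidean/Ward variant is one flag away.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import pdist

from .io import DataQualityWarning, ExpressionMatrix
from .signature import EMTSignature

__all__ = [
    "ClusterResult",
    "SubgroupAssignment",
    "hierarchical_cluster_two_way",
    "assign_subgroup_labels",
]


@dataclass
class ClusterResult:
    sample_clusters: pd.Series  # sample id -> cluster id (1..k)
    gene_clusters: pd.Series  # gene -> cluster id (1..k)
    sample_linkage: np.ndarray
    gene_linkage: np.ndarray
    signature_genes_used: list[str]
    metric: str
    method: str


@dataclass
class SubgroupAssignment:
    """Epi/Mes label per sample; BCCP assignments additionally carry P(Mes)."""

    labels: pd.Series  # sample id -> {"Epi", "Mes"}
    method: str  # "clustering" | "bccp" | "truth"
    posterior: pd.Series | None = field(default=None)  # P(Mes | sample)

    def __post_init__(self) -> None:
        bad = set(self.labels.unique()) - {"Epi", "Mes"}
        if bad:
            raise ValueError(f"labels must be Epi/Mes, got {bad}")
        if self.posterior is not None:
            p = self.posterior
            if ((p < 0) | (p > 1)).any():
                raise ValueError("posteriors must lie in [0, 1]")

    @property
    def samples(self) -> pd.Index:
        return self.labels.index

    def to_frame(self) -> pd.DataFrame:
        frame = pd.DataFrame({"label": self.labels, "method": self.method})
        if self.posterior is not None:
            frame["p_mes"] = self.posterior
        frame.index.name = "sample"
        return frame


def _restrict_to_signature(expr: ExpressionMatrix, signature: EMTSignature) -> pd.DataFrame:
    present = [g for g in signature.genes if g in expr.genes]
    absent = [g for g in signature.genes if g not in expr.genes]
    if absent:
        warnings.warn(
            f"{len(absent)} signature gene(s) absent from cohort {expr.name!r}: "
            f"{', '.join(absent[:10])}{'...' if len(absent) > 10 else ''}",
            DataQualityWarning,
            stacklevel=3,
        )
    if len(present) < 2:
        raise ValueError(
            f"only {len(present)} signature gene(s) found in cohort {expr.name!r}; need >= 2"
        )
    return expr.values.loc[present]


def hierarchical_cluster_two_way(
    expr: ExpressionMatrix,
    signature: EMTSignature,
    k: int = 2,
    metric: str = "correlation",
    method: str = "complete",
) -> ClusterResult:
    """Cluster samples (and genes) on the signature genes.

    ``metric='correlation'`` is scipy's 1 − centered Pearson distance;
    ``metric='euclidean'`` with ``method='ward'`` gives the alternative
    reading. The sample dendrogram is cut into exactly ``k`` clusters.
    """
    sub = _restrict_to_signature(expr, signature)
    n = sub.shape[1]
    if k > n:
        raise ValueError(f"k={k} exceeds number of samples ({n})")
    if n < 2 * k:
        raise ValueError(f"need >= {2 * k} samples for k={k}, got {n}")

    sample_d = pdist(sub.to_numpy().T, metric=metric)
    sample_z = linkage(np.clip(sample_d, 0.0, None), method=method)
    sample_ids = fcluster(sample_z, t=k, criterion="maxclust")

    gene_d = pdist(sub.to_numpy(), metric=metric)
    gene_z = linkage(np.clip(gene_d, 0.0, None), method=method)
    gene_ids = fcluster(gene_z, t=k, criterion="maxclust")

    return ClusterResult(
        sample_clusters=pd.Series(sample_ids, index=sub.columns, name="cluster"),
        gene_clusters=pd.Series(gene_ids, index=sub.index, name="cluster"),
        sample_linkage=sample_z,
        gene_linkage=gene_z,
        signature_genes_used=list(sub.index),
        metric=metric,
        method=method,
    )


def assign_subgroup_labels(
    clusters: ClusterResult | pd.Series,
    expr: ExpressionMatrix,
    signature: EMTSignature,
) -> SubgroupAssignment:
    """Label the two clusters Epi/Mes by their mesenchymal-epithelial contrast.

    For each cluster, average the gene-wise z-scores of mesenchymal-oriented
    genes and subtract the average over epithelial-oriented genes; the
    cluster with the larger contrast is Mes. Invariant under swapping
    cluster ids. An exact tie is a degenerate input and raises.
    """
    member = clusters.sample_clusters if isinstance(clusters, ClusterResult) else clusters
    ids = sorted(pd.unique(member))
    if len(ids) != 2:
        raise ValueError(f"expected exactly 2 clusters, got {len(ids)}")

    sub = _restrict_to_signature(expr, signature)
    sub = sub[member.index]
    sd = sub.std(axis=1, ddof=1)
    keep = sd > 0
    z = sub.loc[keep].sub(sub.loc[keep].mean(axis=1), axis=0).div(sd[keep], axis=0)

    mes_genes = [g for g in signature.mesenchymal_genes if g in z.index]
    epi_genes = [g for g in signature.epithelial_genes if g in z.index]

    contrast = {}
    for cid in ids:
        cols = member.index[member == cid]
        mes_part = z.loc[mes_genes, cols].to_numpy().mean() if mes_genes else 0.0
        epi_part = z.loc[epi_genes, cols].to_numpy().mean() if epi_genes else 0.0
        contrast[cid] = mes_part - epi_part
    if contrast[ids[0]] == contrast[ids[1]]:
        raise ValueError(
            "cluster contrasts are exactly equal; Epi/Mes labels cannot be "
            "assigned automatically for this degenerate input"
        )
    mes_cluster = max(ids, key=lambda cid: contrast[cid])
    labels = member.map(lambda cid: "Mes" if cid == mes_cluster else "Epi")
    labels.name = "label"
    return SubgroupAssignment(labels=labels, method="clustering")
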