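"""Correlation-anchored EMT signature discovery.

Every non-marker gene is correlated (Pearson) with the four canonical EMT
anchor markers — CDH1 (epithelial) and VIM, CDH2, FN1 (mesenchymal) — and
a gene enters the signature when it is sufficiently strongly and
significantly correlated with at least one anchor. Each selected gene is
then oriented: a gene that rises with the mesenchymal anchors (or falls
with CDH1) is mesenchymal, otherwise epithelial.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io import ExpressionMatrix, GeneSetCollection

__all__ = [
    "ANCHOR_MARKERS",
    "MarkerCorrelationTable",
    "EMTSignature",
    "compute_marker_correlations",
    "select_signature_genes",
]

#: anchor markers in tie-break priority order (epithelial first)
ANCHOR_MARKERS = ("CDH1", "VIM", "CDH2", "FN1")
_MES_ANCHORS = frozenset({"VIM", "CDH2", "FN1"})


@dataclass
class MarkerCorrelationTable:
    """One row per (gene, marker) pair: Pearson r, two-sided p, BH q.

    ``zero_variance`` flags genes whose correlation is undefined; they are
    recorded as r = 0, p = 1 so nothing downstream sees a NaN.
    """

    table: pd.DataFrame  # columns: gene, marker, r, p, q, zero_variance
    n_samples: int

    @property
    def genes(self) -> pd.Index:
        return pd.Index(self.table["gene"].unique())


def compute_marker_correlations(
    expr: ExpressionMatrix, markers: tuple[str, ...] = ANCHOR_MARKERS
) -> MarkerCorrelationTable:
    """Pearson r of every non-marker gene against each anchor marker.

    p-values are exact two-sided under the bivariate-normal null
    (t distribution with n - 2 degrees of freedom); BH adjustment is pooled
    across all gene-marker pairs jointly, since selection is a single event
    per gene over its four correlations.
    """
    missing = [m for m in markers if m not in expr.genes]
    if missing:
        raise ValueError(f"anchor marker(s) absent from matrix: {', '.join(missing)}")
    n = expr.shape[1]
    if n < 3:
        raise ValueError(f"need >= 3 samples to correlate, got {n}")

    other = [g for g in expr.genes if g not in set(markers)]
    X = expr.values.loc[other].to_numpy()
    M = expr.values.loc[list(markers)].to_numpy()

    Xc = X - X.mean(axis=1, keepdims=True)
    Mc = M - M.mean(axis=1, keepdims=True)
    x_norm = np.sqrt((Xc**2).sum(axis=1))
    m_norm = np.sqrt((Mc**2).sum(axis=1))
    zero_var = x_norm == 0
    marker_zero = m_norm == 0

    denom = np.outer(np.where(zero_var, 1.0, x_norm), np.where(marker_zero, 1.0, m_norm))
    r = (Xc @ Mc.T) / denom
    r[zero_var, :] = 0.0
    r[:, marker_zero] = 0.0
    r = np.clip(r, -1.0, 1.0)

    with np.errstate(divide="ignore"):
        t = r * np.sqrt((n - 2) / np.maximum(1.0 - r**2, 0.0))
    p = 2.0 * stats.t.sf(np.abs(t), df=n - 2)
    p[np.abs(r) == 1.0] = 0.0
    p[zero_var, :] = 1.0
    p[:, marker_zero] = 1.0

    flat = pd.DataFrame(
        {
            "gene": np.repeat(other, len(markers)),
            "marker": np.tile(markers, len(other)),
            "r": r.ravel(),
            "p": p.ravel(),
            "zero_variance": np.repeat(zero_var, len(markers)) | np.tile(marker_zero, len(other)),
        }
    )
    flat["q"] = multipletests(flat["p"].to_numpy(), method="fdr_bh")[1]
    return MarkerCorrelationTable(table=flat, n_samples=n)


@dataclass
class EMTSignature:
    """Selected signature genes with orientation and best-anchor evidence."""

    entries: pd.DataFrame  # columns: gene, orientation, anchor, r, q
    r_min: float
    q_max: float

    def __post_init__(self) -> None:
        if self.entries["gene"].duplicated().any():
            raise ValueError("signature contains duplicate genes")
        bad = set(self.entries["gene"]) & set(ANCHOR_MARKERS)
        if bad:
            raise ValueError(f"anchor markers may not be signature entries: {bad}")

    @property
    def genes(self) -> list[str]:
        return self.entries["gene"].tolist()

    @property
    def epithelial_genes(self) -> list[str]:
        return self.entries.loc[self.entries["orientation"] == "epithelial", "gene"].tolist()

    @property
    def mesenchymal_genes(self) -> list[str]:
        return self.entries.loc[self.entries["orientation"] == "mesenchymal", "gene"].tolist()

    def __len__(self) -> int:
        return len(self.entries)

    def to_tsv(self, path: str | Path) -> None:
        self.entries.to_csv(path, sep="\t", index=False)

    def to_gene_sets(self) -> GeneSetCollection:
        """Two-set collection (EPI, MES) consumable by the clustering stage."""
        sets = {}
        if self.epithelial_genes:
            sets["EPI"] = self.epithelial_genes
        if self.mesenchymal_genes:
            sets["MES"] = self.mesenchymal_genes
        return GeneSetCollection(
            sets=sets,
            descriptions={k: f"EMT signature ({k.lower()} oriented)" for k in sets},
        )


def select_signature_genes(
    table: MarkerCorrelationTable, r_min: float = 0.6, q_max: float = 0.05
) -> EMTSignature:
    """Select genes with |r| >= r_min and q <= q_max against >= 1 anchor.

    Orientation comes from the (marker, r) pair with the largest |r|;
    mesenchymal iff that pair rises with a mesenchymal anchor or falls with
    CDH1. |r| ties break by anchor priority CDH1 > VIM > CDH2 > FN1 for
    determinism.
    """
    if not 0.0 < r_min <= 1.0:
        raise ValueError("r_min must lie in (0, 1]")
    if not 0.0 < q_max <= 1.0:
        raise ValueError("q_max must lie in (0, 1]")

    t = table.table.copy()
    t["abs_r"] = t["r"].abs()
    t["priority"] = t["marker"].map({m: i for i, m in enumerate(ANCHOR_MARKERS)})
    qualifies = (t["abs_r"] >= r_min) & (t["q"] <= q_max) & ~t["zero_variance"]
    selected_genes = t.loc[qualifies, "gene"].unique()

    rows = []
    best = (
        t[t["gene"].isin(selected_genes)]
        .sort_values(["gene", "abs_r", "priority"], ascending=[True, False, True])
        .groupby("gene", sort=True)
        .head(1)
    )
    for _, row in best.iterrows():
        mes = (row["marker"] in _MES_ANCHORS and row["r"] > 0) or (
            row["marker"] == "CDH1" and row["r"] < 0
        )
        rows.append(
            {
                "gene": row["gene"],
                "orientation": "mesenchymal" if mes else "epithelial",
                "anchor": row["marker"],
                "r": row["r"],
                "q": row["q"],
            }
        )
    entries = pd.DataFrame(rows, columns=["gene", "orientation", "anchor", "r", "q"])
    return EMTSignature(entries=entries, r_min=r_min, q_max=q_max)
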