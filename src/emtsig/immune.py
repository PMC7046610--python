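"""Immunotherapy-related per-sample scores: INFG, CYT, TIS, IIS and IS.

All scores except CYT operate on cohort-wise z-scored expression, so they
are invariant under any per-gene positive-slope affine transform. CYT is
defined on the log expression level itself (the arithmetic mean of the two
cytolytic effector genes, i.e. the log geometric mean of their linear
values) and therefore shifts equivariantly — a deliberate asymmetry.

* INFG — mean z-score of the six interferon-gamma programme genes
  (CXCL9, CXCL10, IDO1, IFNG, HLA-DRA, STAT1).
* CYT — mean log expression of GZMA and PRF1.
* TIS — mean of standardized per-cell-type scores over the T-cell subsets,
  excluding T gamma delta and T follicular helper cells.
* IIS — the same over the full immune-cell roster (macrophages, dendritic
  cell subsets, B cells, cytotoxic cells, eosinophils, mast cells,
  neutrophils, NK subsets, plus all TIS T-cell subsets).
* IS — mean z-score over a user-supplied immune signature gene list
  (externally defined; commonly 105 genes).

Cell-subset gene memberships are inputs (GMT), not package constants.
Scores computed from zero available genes are reported as absent and
flagged, never silently zero.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .io import DataQualityWarning, ExpressionMatrix, GeneSetCollection

__all__ = [
    "TIS_SUBSET_NAMES",
    "EXCLUDED_SUBSET_NAMES",
    "IIS_EXTRA_SUBSET_NAMES",
    "INFG_GENES",
    "CYT_GENES",
    "CHECKPOINT_GENES",
    "ImmuneScorePanel",
    "zscore_genes",
    "infg_score",
    "cyt_score",
    "gene_set_sample_score",
    "tis_score",
    "iis_score",
    "is_score",
    "compute_immune_panel",
]

INFG_GENES = ("CXCL9", "CXCL10", "IDO1", "IFNG", "HLA-DRA", "STAT1")
CYT_GENES = ("GZMA", "PRF1")
CHECKPOINT_GENES = ("PDCD1", "CD274", "CTLA4")

#: T-cell subsets entering the T-cell infiltration score
TIS_SUBSET_NAMES = (
    "CD8 T cells", "T helper cells", "T cells",
    "T central memory", "T effector memory",
    "Th1 cells", "Th2 cells", "Th17 cells", "Treg cells",
)
#: subsets deliberately excluded from both TIS and IIS
EXCLUDED_SUBSET_NAMES = ("T gamma delta", "T follicular helper")
#: additional populations entering the overall immune infiltration score
IIS_EXTRA_SUBSET_NAMES = (
    "Macrophages", "DC", "pDC", "iDC", "aDC",
    "B cells", "Cytotoxic cells", "Eosinophils", "Mast cells",
    "Neutrophils", "NK cells", "NK CD56bright", "NK CD56dim",
)


def zscore_genes(expr: ExpressionMatrix, genes: Sequence[str]) -> pd.DataFrame:
    """Gene-wise z-scored sub-matrix over the listed genes.

    Absent genes are logged; zero-variance genes are dropped with a warning.
    Raises if no listed gene is present.
    """
    if expr.shape[1] < 2:
        raise ValueError("z-scoring needs >= 2 samples")
    present = [g for g in genes if g in expr.genes]
    absent = [g for g in genes if g not in expr.genes]
    if not present:
        raise ValueError(f"none of the listed genes present: {', '.join(genes)}")
    if absent:
        warnings.warn(
            f"{len(absent)} listed gene(s) absent from cohort {expr.name!r}: "
            f"{', '.join(absent[:10])}{'...' if len(absent) > 10 else ''}",
            DataQualityWarning,
            stacklevel=2,
        )
    sub = expr.values.loc[present]
    sd = sub.std(axis=1, ddof=1)
    constant = list(sd.index[sd == 0])
    if constant:
        warnings.warn(
            f"zero-variance gene(s) dropped: {', '.join(constant)}",
            DataQualityWarning,
            stacklevel=2,
        )
    keep = sd > 0
    if not keep.any():
        raise ValueError("all listed genes have zero variance")
    return sub.loc[keep].sub(sub.loc[keep].mean(axis=1), axis=0).div(sd[keep], axis=0)


def infg_score(expr: ExpressionMatrix) -> pd.Series:
    """Interferon-gamma score: mean z-score of the six INFG programme genes."""
    z = zscore_genes(expr, INFG_GENES)
    score = z.mean(axis=0)
    score.name = "INFG"
    return score


def cyt_score(expr: ExpressionMatrix) -> pd.Series:
    """Cytolytic activity: per-sample mean log expression of GZMA and PRF1."""
    missing = [g for g in CYT_GENES if g not in expr.genes]
    if missing:
        raise ValueError(f"CYT gene(s) absent: {', '.join(missing)}")
    score = expr.values.loc[list(CYT_GENES)].mean(axis=0)
    score.name = "CYT"
    return score


def gene_set_sample_score(expr: ExpressionMatrix, genes: Sequence[str]) -> pd.Series:
    """Per-cell-type score: mean z-score over the set, then standardized.

    The per-sample mean of z-scored member genes is itself scaled to
    mean 0 / sd 1 across samples so every cell type contributes on the same
    scale when aggregated into TIS/IIS.
    """
    z = zscore_genes(expr, genes)
    raw = z.mean(axis=0)
    sd = raw.std(ddof=1)
    if sd == 0:
        raise ValueError("gene-set score is constant across samples")
    return (raw - raw.mean()) / sd


def _roster_score(
    expr: ExpressionMatrix,
    cell_sets: GeneSetCollection,
    roster: Sequence[str],
    excluded: Sequence[str],
    name: str,
) -> tuple[pd.Series, dict]:
    resolvable, skipped = [], []
    for subset in roster:
        if subset in EXCLUDED_SUBSET_NAMES or subset in excluded:
            continue
        if subset not in cell_sets:
            skipped.append(subset)
            continue
        resolvable.append(subset)
    if not resolvable:
        raise ValueError(f"{name}: no resolvable cell subsets in the collection")
    if skipped:
        warnings.warn(
            f"{name}: subset(s) missing from collection: {', '.join(skipped)}",
            DataQualityWarning,
            stacklevel=3,
        )
    parts, used, failed = [], [], []
    for subset in resolvable:
        try:
            parts.append(gene_set_sample_score(expr, cell_sets[subset]))
            used.append(subset)
        except ValueError:
            failed.append(subset)
    if not parts:
        raise ValueError(f"{name}: no subset had scorable genes in this cohort")
    if failed:
        warnings.warn(
            f"{name}: subset(s) without scorable genes: {', '.join(failed)}",
            DataQualityWarning,
            stacklevel=3,
        )
    score = pd.concat(parts, axis=1).mean(axis=1)
    score.name = name
    return score, {"subsets_used": used, "subsets_missing": skipped + failed}


def tis_score(
    expr: ExpressionMatrix,
    cell_sets: GeneSetCollection,
    subsets: Sequence[str] = TIS_SUBSET_NAMES,
    excluded: Sequence[str] = EXCLUDED_SUBSET_NAMES,
) -> pd.Series:
    """T-cell infiltration score over the nine eligible T-cell subsets."""
    score, _ = _roster_score(expr, cell_sets, subsets, excluded, "TIS")
    return score


def iis_score(
    expr: ExpressionMatrix,
    cell_sets: GeneSetCollection,
    subsets: Sequence[str] | None = None,
    excluded: Sequence[str] = EXCLUDED_SUBSET_NAMES,
) -> pd.Series:
    """Overall immune infiltration score over the full immune-cell roster."""
    if subsets is None:
        subsets = tuple(TIS_SUBSET_NAMES) + tuple(IIS_EXTRA_SUBSET_NAMES)
    score, _ = _roster_score(expr, cell_sets, subsets, excluded, "IIS")
    return score


def is_score(expr: ExpressionMatrix, is_genes: Sequence[str]) -> pd.Series:
    """Immune signature score: mean z-score over the supplied gene list."""
    if not list(is_genes):
        raise ValueError("immune signature gene list is empty")
    z = zscore_genes(expr, is_genes)
    score = z.mean(axis=0)
    score.name = "IS"
    return score


@dataclass
class ImmuneScorePanel:
    """All available per-sample scores plus checkpoint-gene expression."""

    scores: pd.DataFrame  # samples x available scores
    checkpoints: pd.DataFrame  # samples x present checkpoint genes
    provenance: dict = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        frame = self.scores.join(self.checkpoints)
        frame.index.name = "sample"
        return frame


def compute_immune_panel(
    expr: ExpressionMatrix,
    cell_sets: GeneSetCollection | None = None,
    is_genes: Sequence[str] | None = None,
) -> ImmuneScorePanel:
    """Compute every score whose inputs are available; log the rest.

    TIS/IIS require ``cell_sets``; IS requires ``is_genes``. A score whose
    gene inputs are entirely absent is recorded in ``provenance['missing']``
    and omitted from the table rather than reported as zero.
    """
    columns: dict[str, pd.Series] = {}
    provenance: dict = {"missing": {}, "gene_sets": {}}

    def attempt(name, fn):
        try:
            columns[name] = fn()
        except ValueError as exc:
            provenance["missing"][name] = str(exc)

    attempt("INFG", lambda: infg_score(expr))
    attempt("CYT", lambda: cyt_score(expr))
    if cell_sets is not None:
        attempt("TIS", lambda: tis_score(expr, cell_sets))
        attempt("IIS", lambda: iis_score(expr, cell_sets))
        provenance["gene_sets"]["cell_sets"] = cell_sets.names
    if is_genes is not None:
        attempt("IS", lambda: is_score(expr, is_genes))
        provenance["gene_sets"]["is_genes"] = list(is_genes)

    scores = pd.DataFrame(columns, index=expr.samples)
    present_cp = [g for g in CHECKPOINT_GENES if g in expr.genes]
    absent_cp = [g for g in CHECKPOINT_GENES if g not in expr.genes]
    if absent_cp:
        provenance["missing"]["checkpoints"] = absent_cp
    checkpoints = expr.values.loc[present_cp].T if present_cp else pd.DataFrame(index=expr.samples)
    return ImmuneScorePanel(scores=scores, checkpoints=checkpoints, provenance=provenance)
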