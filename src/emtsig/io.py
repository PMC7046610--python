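"""Reading, writing and harmonizing expression cohorts, clinical tables and gene sets.

Expression matrices are log-scale gene-by-sample tables (genes in rows,
header row of sample ids). Clinical tables carry right-censored survival
(time in months, event in {0, 1}) plus arbitrary covariate columns. Gene
sets use the standard GMT layout: ``name TAB description TAB gene ...``.

Gene identity is by exact symbol string; no alias resolution is attempted.
Missing expression values are a hard error — every downstream formula
assumes a complete matrix.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "DataQualityWarning",
    "ExpressionMatrix",
    "ClinicalTable",
    "GeneSetCollection",
    "read_expression_matrix",
    "write_expression_matrix",
    "read_clinical_table",
    "read_gmt",
    "write_gmt",
    "harmonize_cohorts",
]


class DataQualityWarning(UserWarning):
    """Non-fatal data issue (dropped gene, deduplicated entry, absent symbol)."""


class ExpressionMatrix:
    """Log-scale expression values, genes in rows and samples in columns.

    Parameters
    ----------
    values : pandas.DataFrame
        Numeric frame indexed by unique gene symbols with unique sample-id
        columns. All values must be finite.
    name : str, optional
        Cohort label used in logs and reports.
    """

    def __init__(self, values: pd.DataFrame, name: str = "cohort"):
        if values.shape[0] == 0 or values.shape[1] == 0:
            raise ValueError("expression matrix is empty")
        dup_genes = values.index[values.index.duplicated()].unique()
        if len(dup_genes) > 0:
            raise ValueError(f"duplicate gene symbol(s): {', '.join(map(str, dup_genes))}")
        dup_samples = values.columns[values.columns.duplicated()].unique()
        if len(dup_samples) > 0:
            raise ValueError(f"duplicate sample id(s): {', '.join(map(str, dup_samples))}")
        try:
            numeric = values.astype(float)
        except (TypeError, ValueError) as exc:
            raise ValueError(f"non-numeric expression value: {exc}") from exc
        if not np.isfinite(numeric.to_numpy()).all():
            bad = np.argwhere(~np.isfinite(numeric.to_numpy()))[0]
            raise ValueError(
                "non-finite expression value at gene "
                f"{numeric.index[bad[0]]!r}, sample {numeric.columns[bad[1]]!r}"
            )
        self.values = numeric
        self.name = name

    @property
    def genes(self) -> pd.Index:
        return self.values.index

    @property
    def samples(self) -> pd.Index:
        return self.values.columns

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def restrict(self, genes: Sequence[str]) -> "ExpressionMatrix":
        """Subset to ``genes`` (order preserved); absent symbols raise KeyError."""
        missing = [g for g in genes if g not in self.values.index]
        if missing:
            raise KeyError(f"genes absent from matrix: {', '.join(missing)}")
        return ExpressionMatrix(self.values.loc[list(genes)], name=self.name)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"ExpressionMatrix({self.name!r}, {self.shape[0]} genes x {self.shape[1]} samples)"


@dataclass
class ClinicalTable:
    """Per-sample survival endpoint plus covariates.

    ``data`` is indexed by sample id with float column ``time`` (months),
    integer column ``event`` (1 = death/recurrence) and any number of
    covariate columns, preserved as given.
    """

    data: pd.DataFrame
    endpoint: str = "OS"

    def __post_init__(self) -> None:
        if self.data.index.duplicated().any():
            dup = self.data.index[self.data.index.duplicated()].unique()
            raise ValueError(f"duplicate sample id(s): {', '.join(map(str, dup))}")
        for col in ("time", "event"):
            if col not in self.data.columns:
                raise ValueError(f"clinical table missing required column {col!r}")
        time = pd.to_numeric(self.data["time"])
        if (time < 0).any():
            raise ValueError("negative survival time")
        event = pd.to_numeric(self.data["event"])
        if not event.isin([0, 1]).all():
            raise ValueError("event indicator outside {0, 1}")
        self.data = self.data.assign(time=time.astype(float), event=event.astype(int))

    @property
    def samples(self) -> pd.Index:
        return self.data.index

    @property
    def time(self) -> pd.Series:
        return self.data["time"]

    @property
    def event(self) -> pd.Series:
        return self.data["event"]

    def covariate(self, name: str) -> pd.Series:
        if name not in self.data.columns:
            raise KeyError(f"covariate {name!r} not present")
        return self.data[name]


@dataclass
class GeneSetCollection:
    """Named gene sets with optional per-set descriptions."""

    sets: dict[str, list[str]] = field(default_factory=dict)
    descriptions: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, genes in self.sets.items():
            if len(genes) == 0:
                raise ValueError(f"gene set {name!r} is empty")

    def __contains__(self, name: str) -> bool:
        return name in self.sets

    def __getitem__(self, name: str) -> list[str]:
        return self.sets[name]

    def __len__(self) -> int:
        return len(self.sets)

    @property
    def names(self) -> list[str]:
        return list(self.sets)

    def all_genes(self) -> list[str]:
        seen: dict[str, None] = {}
        for genes in self.sets.values():
            for g in genes:
                seen.setdefault(g, None)
        return list(seen)

    def subset(self, names: Iterable[str]) -> "GeneSetCollection":
        names = [n for n in names if n in self.sets]
        return GeneSetCollection(
            sets={n: list(self.sets[n]) for n in names},
            descriptions={n: self.descriptions.get(n, "") for n in names},
        )


# ---------------------------------------------------------------------------
# readers / writers


def read_expression_matrix(path: str | Path, sep: str = "\t", name: str | None = None) -> ExpressionMatrix:
    """Read a genes-x-samples table (first column gene symbols, header of sample ids)."""
    path = Path(path)
    raw = pd.read_csv(path, sep=sep, index_col=0, dtype=str, keep_default_na=False)
    if raw.shape[0] == 0 or raw.shape[1] == 0:
        raise ValueError(f"{path}: empty expression matrix")
    values = pd.DataFrame(index=raw.index, columns=raw.columns, dtype=float)
    arr = raw.to_numpy()
    parsed = np.empty(arr.shape, dtype=float)
    for i in range(arr.shape[0]):
        for j in range(arr.shape[1]):
            try:
                parsed[i, j] = float(arr[i, j])
            except ValueError as exc:
                raise ValueError(
                    f"{path}: non-numeric cell {arr[i, j]!r} at gene "
                    f"{raw.index[i]!r} (row {i + 2}), sample {raw.columns[j]!r} (column {j + 2})"
                ) from exc
    values.loc[:, :] = parsed
    return ExpressionMatrix(values, name=name or path.stem)


def write_expression_matrix(expr: ExpressionMatrix, path: str | Path, sep: str = "\t") -> None:
    """Write with full float precision so a read round-trips bit-exactly."""
    frame = expr.values.copy()
    frame.index.name = "gene"
    frame.to_csv(path, sep=sep, float_format=None)


def read_clinical_table(
    path: str | Path,
    schema: Mapping[str, str] | None = None,
    sep: str = "\t",
    endpoint: str = "OS",
) -> ClinicalTable:
    """Read a clinical table, renaming columns via ``schema`` (file name -> canonical).

    The canonical columns ``id``, ``time`` and ``event`` must be resolvable;
    every other column is kept verbatim as a covariate.
    """
    raw = pd.read_csv(path, sep=sep)
    if schema:
        raw = raw.rename(columns=dict(schema))
    for col in ("id", "time", "event"):
        if col not in raw.columns:
            raise ValueError(f"{path}: required column {col!r} missing after schema mapping")
    raw = raw.set_index("id")
    return ClinicalTable(raw, endpoint=endpoint)


def read_gmt(path: str | Path) -> GeneSetCollection:
    """Parse a GMT file (one set per line: name, description, genes...)."""
    sets: dict[str, list[str]] = {}
    descriptions: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}:{lineno}: GMT line has {len(fields)} fields, need >= 3")
            set_name, desc, *genes = fields
            genes = [g for g in genes if g]
            if set_name in sets:
                raise ValueError(f"{path}:{lineno}: duplicate gene-set name {set_name!r}")
            deduped = list(dict.fromkeys(genes))
            if len(deduped) < len(genes):
                warnings.warn(
                    f"{path}:{lineno}: set {set_name!r} had duplicate genes; deduplicated",
                    DataQualityWarning,
                    stacklevel=2,
                )
            if not deduped:
                raise ValueError(f"{path}:{lineno}: gene set {set_name!r} is empty")
            sets[set_name] = deduped
            descriptions[set_name] = desc
    return GeneSetCollection(sets=sets, descriptions=descriptions)


def write_gmt(collection: GeneSetCollection, path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, genes in collection.sets.items():
            desc = collection.descriptions.get(name, "")
            fh.write("\t".join([name, desc, *genes]) + "\n")


# ---------------------------------------------------------------------------
# harmonization


def harmonize_cohorts(cohorts: Sequence[ExpressionMatrix]) -> list[ExpressionMatrix]:
    """Project cohorts onto their common gene set and z-score each gene per cohort.

    Cross-platform intensities are not commensurable; gene-wise
    standardization within each cohort is the minimal platform-shift
    correction compatible with the compound-covariate classifier's input
    contract. Genes with zero variance in ANY cohort are dropped from all
    cohorts (a constant gene carries no within-cohort information and would
    produce an undefined z-score).

    The operation is idempotent: a second application leaves values
    unchanged up to floating-point error.
    """
    if len(cohorts) < 2:
        raise ValueError("harmonize_cohorts needs at least two cohorts")
    common = cohorts[0].genes
    for cohort in cohorts[1:]:
        common = common.intersection(cohort.genes)
    if len(common) == 0:
        raise ValueError("cohorts share no gene symbols")
    # keep the first cohort's ordering for determinism
    common = [g for g in cohorts[0].genes if g in set(common)]

    keep = list(common)
    for cohort in cohorts:
        sub = cohort.values.loc[common]
        sd = sub.std(axis=1, ddof=1)
        constant = sd.index[(sd == 0) | sd.isna()]
        if len(constant) > 0:
            warnings.warn(
                f"cohort {cohort.name!r}: zero-variance gene(s) dropped from all cohorts: "
                f"{', '.join(map(str, constant))}",
                DataQualityWarning,
                stacklevel=2,
            )
            constant_set = set(constant)
            keep = [g for g in keep if g not in constant_set]
    if not keep:
        raise ValueError("no genes with nonzero variance in all cohorts")

    out = []
    for cohort in cohorts:
        sub = cohort.values.loc[keep]
        centred = sub.sub(sub.mean(axis=1), axis=0)
        scaled = centred.div(sub.std(axis=1, ddof=1), axis=0)
        out.append(ExpressionMatrix(scaled, name=cohort.name))
    return out
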