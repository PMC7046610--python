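"""Survival estimation and association statistics for subtype analyses.

Kaplan-Meier curves, the two-group log-rank test and Cox proportional
hazards regression (Efron tie handling) are delegated to ``lifelines``;
Wilcoxon rank-sum comparisons, Fisher's exact test and chi-square
contingency tests to ``scipy.stats``; Benjamini-Hochberg adjustment to
``statsmodels``. This module owns the subtype-analysis contracts around
them: group handling, complete-case covariate dropping, score-comparison
direction reporting and local gene-set enrichment (a Fisher 2x2 per
annotation set over an explicit gene universe, replacing a web service).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.statistics import multivariate_logrank_test
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io import ClinicalTable, DataQualityWarning, GeneSetCollection
from .subgroup import SubgroupAssignment

__all__ = [
    "KMCurve",
    "LogrankResult",
    "CoxResult",
    "ContingencyResult",
    "km_estimate",
    "plot_km",
    "logrank_test",
    "cox_fit",
    "compare_scores_between_groups",
    "fisher_exact",
    "contingency_association",
    "enrichment_test",
]


def _group_series(groups: SubgroupAssignment | pd.Series) -> pd.Series:
    return groups.labels if isinstance(groups, SubgroupAssignment) else groups


def _aligned(clinical: ClinicalTable, groups: SubgroupAssignment | pd.Series) -> pd.DataFrame:
    labels = _group_series(groups)
    common = labels.index.intersection(clinical.samples)
    if len(common) == 0:
        raise ValueError("no overlap between grouped samples and clinical table")
    frame = clinical.data.loc[common, ["time", "event"]].copy()
    frame["group"] = labels.loc[common]
    return frame


# ---------------------------------------------------------------------------
# Kaplan-Meier / log-rank


@dataclass
class KMCurve:
    """Product-limit survival curve for one group."""

    group: str
    times: np.ndarray
    survival: np.ndarray
    at_risk: np.ndarray
    n: int

    def __post_init__(self) -> None:
        s = np.asarray(self.survival)
        if s.size and (np.any(np.diff(s) > 1e-12) or s.min() < -1e-12 or s.max() > 1 + 1e-12):
            raise ValueError("survival probabilities must be non-increasing within [0, 1]")

    def survival_at(self, t: float) -> float:
        """S(t): step-function value at time t (1 before the first event)."""
        idx = np.searchsorted(self.times, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival[idx])


def km_estimate(
    clinical: ClinicalTable, groups: SubgroupAssignment | pd.Series
) -> dict[str, KMCurve]:
    """Kaplan-Meier curve per group (ties reduce the risk set simultaneously)."""
    frame = _aligned(clinical, groups)
    curves: dict[str, KMCurve] = {}
    for label, part in frame.groupby("group", sort=True):
        if len(part) == 0:
            raise ValueError(f"group {label!r} is empty")
        kmf = KaplanMeierFitter()
        kmf.fit(part["time"], part["event"], label=str(label))
        table = kmf.event_table
        curves[str(label)] = KMCurve(
            group=str(label),
            times=kmf.survival_function_.index.to_numpy(dtype=float),
            survival=kmf.survival_function_.iloc[:, 0].to_numpy(dtype=float),
            at_risk=table["at_risk"].to_numpy(dtype=float),
            n=len(part),
        )
    return curves


@dataclass
class LogrankResult:
    statistic: float
    p: float
    df: int = 1


def logrank_test(
    clinical: ClinicalTable, groups: SubgroupAssignment | pd.Series
) -> LogrankResult:
    """Two-group log-rank test (chi-square, 1 df, two-sided)."""
    frame = _aligned(clinical, groups)
    levels = frame["group"].unique()
    if len(levels) != 2:
        raise ValueError(f"log-rank test needs exactly 2 groups, got {len(levels)}")
    events = frame.groupby("group")["event"].sum()
    if (events == 0).all():
        raise ValueError("no events in either group; log-rank undefined")
    res = multivariate_logrank_test(frame["time"], frame["group"], frame["event"])
    return LogrankResult(statistic=float(res.test_statistic), p=float(res.p_value), df=1)


def plot_km(curves: Mapping[str, KMCurve], path: str | Path, title: str = "") -> None:
    """Write Kaplan-Meier step curves for each group to an image file."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 4))
    for label, curve in curves.items():
        times = np.concatenate([[0.0], curve.times])
        surv = np.concatenate([[1.0], curve.survival])
        ax.step(times, surv, where="post", label=f"{label} (n={curve.n})")
    ax.set_xlabel("time (months)")
    ax.set_ylabel("survival probability")
    ax.set_ylim(0, 1.05)
    if title:
        ax.set_title(title)
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


# ---------------------------------------------------------------------------
# Cox proportional hazards


@dataclass
class CoxResult:
    """Per-covariate hazard ratios with Wald 95% CIs, statsmodels-table style."""

    table: pd.DataFrame  # index covariate; columns hr, ci_low, ci_high, p
    model: str  # "univariate" | "multivariate"
    n_used: int
    n_dropped: int

    def summary(self) -> str:
        lines = [f"Cox proportional hazards ({self.model}), n = {self.n_used}"]
        if self.n_dropped:
            lines.append(f"dropped for missing covariates: {self.n_dropped}")
        lines.append(f"{'covariate':<28}{'HR':>8}{'95% CI':>18}{'p':>12}")
        for cov, row in self.table.iterrows():
            ci = f"({row.ci_low:.2f}-{row.ci_high:.2f})"
            lines.append(f"{cov:<28}{row.hr:>8.2f}{ci:>18}{row.p:>12.2g}")
        return "\n".join(lines)


def _design_matrix(
    data: pd.DataFrame,
    covariates: Sequence[str],
    reference_levels: Mapping[str, str] | None,
) -> pd.DataFrame:
    pieces = []
    for cov in covariates:
        col = data[cov]
        if pd.api.types.is_numeric_dtype(col):
            pieces.append(col.astype(float).rename(cov))
            continue
        levels = sorted(col.dropna().astype(str).unique())
        if len(levels) < 2:
            raise ValueError(f"covariate {cov!r} has a single level; no information")
        ref = (reference_levels or {}).get(cov, levels[0])
        if ref not in levels:
            raise ValueError(f"reference level {ref!r} not observed for {cov!r}")
        for lvl in levels:
            if lvl == ref:
                continue
            pieces.append((col.astype(str) == lvl).astype(float).rename(f"{cov} ({lvl})"))
    return pd.concat(pieces, axis=1)


def cox_fit(
    clinical: ClinicalTable,
    covariates: Sequence[str] | str,
    reference_levels: Mapping[str, str] | None = None,
    groups: SubgroupAssignment | pd.Series | None = None,
) -> CoxResult:
    """Proportional-hazards fit (Efron ties) with complete-case handling.

    ``covariates`` may reference clinical columns or, when ``groups`` is
    given, the pseudo-covariate ``"subgroup"`` (Epi vs reference Mes).
    One covariate yields a univariate model; several, a joint multivariate
    model. Samples missing any covariate are dropped with a logged count.
    """
    if isinstance(covariates, str):
        covariates = [covariates]
    if not covariates:
        raise ValueError("no covariates given")
    data = clinical.data.copy()
    if groups is not None:
        labels = _group_series(groups)
        data = data.loc[data.index.intersection(labels.index)]
        data["subgroup"] = labels.loc[data.index]
    for cov in covariates:
        if cov not in data.columns:
            raise ValueError(f"covariate {cov!r} absent from clinical table")

    complete = data.dropna(subset=["time", "event", *covariates])
    n_dropped = len(data) - len(complete)
    if n_dropped:
        warnings.warn(
            f"{n_dropped} sample(s) dropped for missing covariates",
            DataQualityWarning,
            stacklevel=2,
        )
    constant = [c for c in covariates if complete[c].nunique() < 2]
    if constant:
        raise ValueError(f"covariate(s) constant across samples: {', '.join(constant)}")

    refs = dict(reference_levels or {})
    refs.setdefault("subgroup", "Mes")  # HR reported for Epithelial vs Mes
    design = _design_matrix(complete, covariates, refs)
    frame = pd.concat([complete[["time", "event"]], design], axis=1)

    cph = CoxPHFitter()
    try:
        cph.fit(frame, duration_col="time", event_col="event")
    except Exception as exc:  # lifelines raises ConvergenceError subclasses
        raise ValueError(f"Cox model failed to converge: {exc}") from exc

    summary = cph.summary
    table = pd.DataFrame(
        {
            "hr": np.exp(summary["coef"]),
            "ci_low": np.exp(summary["coef lower 95%"]),
            "ci_high": np.exp(summary["coef upper 95%"]),
            "p": summary["p"],
        }
    )
    return CoxResult(
        table=table,
        model="univariate" if len(covariates) == 1 else "multivariate",
        n_used=len(frame),
        n_dropped=n_dropped,
    )


# ---------------------------------------------------------------------------
# group comparisons


def compare_scores_between_groups(
    scores: pd.DataFrame | pd.Series,
    groups: SubgroupAssignment | pd.Series,
    method: str = "ranksum",
) -> pd.DataFrame:
    """Two-sided per-score comparison between the two subgroups.

    Default is the Wilcoxon rank-sum (Mann-Whitney) test; ``method='welch'``
    switches to Welch's t-test. Direction reports which group has the
    higher median (``"none"`` on an exact tie).
    """
    if isinstance(scores, pd.Series):
        scores = scores.to_frame(scores.name or "score")
    labels = _group_series(groups)
    common = scores.index.intersection(labels.index)
    levels = sorted(labels.loc[common].unique())
    if len(levels) != 2:
        raise ValueError(f"need exactly 2 groups, got {levels}")
    a_idx = common[labels.loc[common] == levels[0]]
    b_idx = common[labels.loc[common] == levels[1]]
    if len(a_idx) < 2 or len(b_idx) < 2:
        raise ValueError("each group needs >= 2 samples")

    rows = []
    for col in scores.columns:
        a, b = scores.loc[a_idx, col].to_numpy(), scores.loc[b_idx, col].to_numpy()
        if method == "ranksum":
            stat, p = stats.mannwhitneyu(a, b, alternative="two-sided")
        elif method == "welch":
            stat, p = stats.ttest_ind(a, b, equal_var=False)
        else:
            raise ValueError(f"unknown method {method!r}")
        med_a, med_b = float(np.median(a)), float(np.median(b))
        if med_a > med_b:
            direction = f"{levels[0]}>{levels[1]}"
        elif med_b > med_a:
            direction = f"{levels[1]}>{levels[0]}"
        else:
            direction = "none"
        rows.append(
            {
                "score": col,
                "statistic": float(stat),
                "p": float(p),
                "direction": direction,
                f"median_{levels[0]}": med_a,
                f"median_{levels[1]}": med_b,
            }
        )
    return pd.DataFrame(rows).set_index("score")


# ---------------------------------------------------------------------------
# contingency tests and enrichment


@dataclass
class ContingencyResult:
    counts: pd.DataFrame
    p: float
    odds_ratio: float | None = None  # 2x2 only
    method: str = "fisher"

    def __post_init__(self) -> None:
        if not 0.0 <= self.p <= 1.0 + 1e-12:
            raise ValueError("p outside [0, 1]")


def fisher_exact(table: Sequence[Sequence[int]] | np.ndarray | pd.DataFrame) -> ContingencyResult:
    """Two-sided Fisher's exact test on a 2x2 table.

    The two-sided p sums hypergeometric probabilities of all tables with
    the observed margins whose probability does not exceed the observed
    table's (the conventional definition).
    """
    counts = pd.DataFrame(table)
    if counts.shape != (2, 2):
        raise ValueError(f"fisher_exact needs a 2x2 table, got {counts.shape}")
    arr = counts.to_numpy()
    if not np.issubdtype(arr.dtype, np.number) or np.any(arr < 0) or np.any(arr != np.floor(arr)):
        raise ValueError("counts must be non-negative integers")
    odds, p = stats.fisher_exact(arr.astype(int), alternative="two-sided")
    return ContingencyResult(counts=counts, p=float(p), odds_ratio=float(odds), method="fisher")


def contingency_association(
    clinical: ClinicalTable,
    groups: SubgroupAssignment | pd.Series,
    variable: str,
) -> ContingencyResult:
    """Association between subgroup membership and a categorical covariate.

    2x2 tables use Fisher's exact test; larger tables fall back to the
    chi-square test of independence (method recorded in the result).
    """
    labels = _group_series(groups)
    if variable not in clinical.data.columns:
        raise ValueError(f"covariate {variable!r} absent from clinical table")
    common = labels.index.intersection(clinical.samples)
    var = clinical.data.loc[common, variable].dropna()
    if var.nunique() < 2:
        raise ValueError(f"covariate {variable!r} has fewer than 2 observed levels")
    crosstab = pd.crosstab(labels.loc[var.index], var)
    if crosstab.shape == (2, 2):
        res = fisher_exact(crosstab)
        return ContingencyResult(
            counts=crosstab, p=res.p, odds_ratio=res.odds_ratio, method="fisher"
        )
    chi2, p, _, _ = stats.chi2_contingency(crosstab.to_numpy())
    return ContingencyResult(counts=crosstab, p=float(p), odds_ratio=None, method="chi2")


def enrichment_test(
    query: Sequence[str],
    annotation_sets: GeneSetCollection,
    universe: Sequence[str],
) -> pd.DataFrame:
    """Local gene-set over-representation: one Fisher 2x2 per annotation set.

    For each set the 2x2 classifies every universe gene by (in query) x
    (in set); p-values are BH-adjusted across sets. Query genes outside the
    universe are dropped with a warning; sets disjoint from the universe are
    skipped with a warning.
    """
    uni = list(dict.fromkeys(universe))
    uni_set = set(uni)
    q = [g for g in dict.fromkeys(query) if g in uni_set]
    outside = [g for g in dict.fromkeys(query) if g not in uni_set]
    if outside:
        warnings.warn(
            f"{len(outside)} query gene(s) outside the universe dropped",
            DataQualityWarning,
            stacklevel=2,
        )
    if not q:
        raise ValueError("query is empty after restricting to the universe")
    q_set = set(q)

    rows = []
    for name in annotation_sets.names:
        members = [g for g in annotation_sets[name] if g in uni_set]
        if not members:
            warnings.warn(
                f"annotation set {name!r} disjoint from universe; skipped",
                DataQualityWarning,
                stacklevel=2,
            )
            continue
        m_set = set(members)
        a = len(q_set & m_set)
        b = len(q_set) - a
        c = len(m_set) - a
        d = len(uni) - a - b - c
        res = fisher_exact([[a, b], [c, d]])
        rows.append(
            {
                "set": name,
                "overlap": a,
                "set_size": len(members),
                "query_size": len(q),
                "universe_size": len(uni),
                "odds_ratio": res.odds_ratio,
                "p": res.p,
            }
        )
    if not rows:
        raise ValueError("no annotation set overlaps the universe")
    out = pd.DataFrame(rows).set_index("set")
    out["q"] = multipletests(out["p"].to_numpy(), method="fdr_bh")[1]
    return out.sort_values("p")
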