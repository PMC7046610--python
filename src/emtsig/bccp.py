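"""Bayesian compound covariate predictor (BCCP) for Epi/Mes classification.

The compound covariate of sample j is the t-statistic-weighted sum

    c_j = sum_i t_i * x~_ij

over signature genes, where x~ are gene-standardized expression values and
t_i is the two-sample t statistic (Mes minus Epi, pooled variance) of gene
i in the training cohort. The classifier models c as a one-dimensional
Gaussian per class with a pooled within-class standard deviation and
applies Bayes' rule:

    P(Mes | c) = pi_M phi(c; mu_M, sigma)
                 / [pi_M phi(c; mu_M, sigma) + pi_E phi(c; mu_E, sigma)]

with equal class priors by default and a posterior threshold of 0.5
(posterior exactly 0.5 classifies as Mes, a documented deterministic
tie-break). Robustness on the training set is measured by leave-one-out
cross-validation, refitting weights and standardization without the
held-out sample in every fold.

For prediction on an independent cohort the gene standardization comes
from the test cohort itself (the harmonization contract): cross-platform
intensities are not commensurable, so training means/sds do not transfer.
Training-parameter transfer remains available via ``standardize="training"``.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.special import expit

from .io import DataQualityWarning, ExpressionMatrix
from .signature import EMTSignature
from .subgroup import SubgroupAssignment

__all__ = [
    "BCCP",
    "BCCPResults",
    "fit_bccp",
    "bccp_posterior",
    "predict_bccp",
    "loocv_misclassification",
]


def _standardize_rows(values: pd.DataFrame) -> tuple[pd.DataFrame, pd.Series, pd.Series]:
    means = values.mean(axis=1)
    sds = values.std(axis=1, ddof=1)
    keep = sds > 0
    z = values.loc[keep].sub(means[keep], axis=0).div(sds[keep], axis=0)
    return z, means[keep], sds[keep]


class BCCP:
    """Compound covariate classifier specification, ``statsmodels``-style.

    Construct from a training cohort, its Epi/Mes labels and an EMT
    signature; :meth:`fit` returns a :class:`BCCPResults` carrying the
    fitted weights, the class-conditional Gaussians and prediction methods.
    """

    def __init__(
        self,
        expr: ExpressionMatrix,
        labels: SubgroupAssignment | pd.Series,
        signature: EMTSignature,
        priors: tuple[float, float] = (0.5, 0.5),
    ):
        label_series = labels.labels if isinstance(labels, SubgroupAssignment) else labels
        missing = label_series.index.difference(expr.samples)
        if len(missing) > 0:
            raise ValueError(f"labelled samples absent from matrix: {list(missing)[:5]}")
        if not np.isclose(sum(priors), 1.0):
            raise ValueError("class priors must sum to 1")
        if min(priors) < 0:
            raise ValueError("class priors must be non-negative")
        present = [g for g in signature.genes if g in expr.genes]
        if len(present) == 0:
            raise ValueError("no signature genes present in training matrix")
        self.expr = expr
        self.labels = label_series
        self.signature = signature
        self.genes = present
        self.priors = (float(priors[0]), float(priors[1]))  # (pi_Mes, pi_Epi)

    def fit(self) -> "BCCPResults":
        labels = self.labels
        mes = labels.index[labels == "Mes"]
        epi = labels.index[labels == "Epi"]
        if len(mes) < 2 or len(epi) < 2:
            raise ValueError(
                f"each class needs >= 2 samples (Mes={len(mes)}, Epi={len(epi)})"
            )
        values = self.expr.values.loc[self.genes, labels.index]
        z, means, sds = _standardize_rows(values)
        dropped = [g for g in self.genes if g not in z.index]

        zm, ze = z[mes].to_numpy(), z[epi].to_numpy()
        n_m, n_e = zm.shape[1], ze.shape[1]
        mean_diff = zm.mean(axis=1) - ze.mean(axis=1)
        sp2 = ((n_m - 1) * zm.var(axis=1, ddof=1) + (n_e - 1) * ze.var(axis=1, ddof=1)) / (
            n_m + n_e - 2
        )
        pooled_ok = sp2 > 0
        if dropped or (~pooled_ok).any():
            bad = dropped + list(z.index[~pooled_ok])
            warnings.warn(
                f"{len(bad)} gene(s) excluded for zero variance: "
                f"{', '.join(bad[:10])}{'...' if len(bad) > 10 else ''}",
                DataQualityWarning,
                stacklevel=2,
            )
        if not pooled_ok.any():
            raise ValueError("all signature genes excluded; cannot fit BCCP")
        t = mean_diff[pooled_ok] / np.sqrt(sp2[pooled_ok] * (1.0 / n_m + 1.0 / n_e))
        weights = pd.Series(t, index=z.index[pooled_ok], name="t_weight")

        c = weights @ z.loc[weights.index]
        c_m, c_e = c[mes], c[epi]
        mu_m, mu_e = float(c_m.mean()), float(c_e.mean())
        sigma2 = ((n_m - 1) * c_m.var(ddof=1) + (n_e - 1) * c_e.var(ddof=1)) / (n_m + n_e - 2)
        sigma = float(np.sqrt(sigma2))
        if sigma <= 0 or not np.isfinite(sigma):
            raise ValueError("degenerate compound covariate: pooled within-class sigma is 0")

        return BCCPResults(
            weights=weights,
            gene_means=means[weights.index],
            gene_sds=sds[weights.index],
            mu_mes=mu_m,
            mu_epi=mu_e,
            sigma=sigma,
            priors=self.priors,
            train_covariate=c,
            train_labels=labels.copy(),
        )


@dataclass
class BCCPResults:
    """Fitted BCCP: gene t-weights, standardization parameters and the
    one-dimensional Gaussian class-conditionals of the compound covariate."""

    weights: pd.Series
    gene_means: pd.Series
    gene_sds: pd.Series
    mu_mes: float
    mu_epi: float
    sigma: float
    priors: tuple[float, float]
    train_covariate: pd.Series = field(repr=False)
    train_labels: pd.Series = field(repr=False)

    @property
    def genes(self) -> list[str]:
        return list(self.weights.index)

    # -- inference ---------------------------------------------------------

    def posterior(self, c: float | np.ndarray) -> float | np.ndarray:
        """P(Mes | c) via Bayes' rule on the class-conditional Gaussians.

        Computed in log space: the log density ratio collapses to
        ((c - mu_E)^2 - (c - mu_M)^2) / (2 sigma^2), fed through a logistic.
        """
        c = np.asarray(c, dtype=float)
        pi_m, pi_e = self.priors
        if pi_m == 0:
            out = np.zeros_like(c)
            return float(out) if out.ndim == 0 else out
        if pi_e == 0:
            out = np.ones_like(c)
            return float(out) if out.ndim == 0 else out
        log_odds = np.log(pi_m / pi_e) + ((c - self.mu_epi) ** 2 - (c - self.mu_mes) ** 2) / (
            2.0 * self.sigma**2
        )
        p = expit(log_odds)
        return float(p) if p.ndim == 0 else p

    def compound_covariate(
        self, expr: ExpressionMatrix, standardize: str = "cohort"
    ) -> pd.Series:
        """Weighted sum of standardized expression for each sample of ``expr``.

        ``standardize='cohort'`` z-scores each gene within ``expr`` (a no-op
        on harmonized input); ``'training'`` applies the training means/sds;
        ``'none'`` assumes the matrix is already standardized.
        """
        present = [g for g in self.genes if g in expr.genes]
        if len(present) < 0.5 * len(self.genes):
            raise ValueError(
                f"only {len(present)}/{len(self.genes)} model genes present in "
                f"cohort {expr.name!r}; need >= 50%"
            )
        if len(present) < len(self.genes):
            absent = sorted(set(self.genes) - set(present))
            warnings.warn(
                f"{len(absent)} model gene(s) absent from cohort {expr.name!r}; "
                "dropped from the weight sum",
                DataQualityWarning,
                stacklevel=2,
            )
        sub = expr.values.loc[present]
        if standardize == "cohort":
            z, _, _ = _standardize_rows(sub)
        elif standardize == "training":
            z = sub.sub(self.gene_means[present], axis=0).div(self.gene_sds[present], axis=0)
        elif standardize == "none":
            z = sub
        else:
            raise ValueError(f"unknown standardize mode {standardize!r}")
        w = self.weights[z.index]
        c = w @ z
        c.name = "compound_covariate"
        return c

    def predict(
        self, expr: ExpressionMatrix, standardize: str = "cohort", threshold: float = 0.5
    ) -> SubgroupAssignment:
        """Classify every sample of ``expr``; posterior >= threshold is Mes."""
        c = self.compound_covariate(expr, standardize=standardize)
        post = pd.Series(self.posterior(c.to_numpy()), index=c.index, name="p_mes")
        labels = pd.Series(
            np.where(post >= threshold, "Mes", "Epi"), index=c.index, name="label"
        )
        return SubgroupAssignment(labels=labels, method="bccp", posterior=post)

    # -- reporting ---------------------------------------------------------

    def summary(self) -> str:
        lines = [
            "Bayesian compound covariate predictor",
            "=" * 46,
            f"genes in model:          {len(self.genes)}",
            f"training samples:        {len(self.train_labels)} "
            f"(Mes={int((self.train_labels == 'Mes').sum())}, "
            f"Epi={int((self.train_labels == 'Epi').sum())})",
            f"priors (Mes, Epi):       ({self.priors[0]:.3f}, {self.priors[1]:.3f})",
            f"covariate mu_Mes:        {self.mu_mes:.4f}",
            f"covariate mu_Epi:        {self.mu_epi:.4f}",
            f"pooled sigma:            {self.sigma:.4f}",
            "",
            "top |t| weighted genes:",
        ]
        top = self.weights.reindex(self.weights.abs().sort_values(ascending=False).index)[:10]
        for gene, w in top.items():
            lines.append(f"  {gene:<15} t = {w:+.3f}")
        return "\n".join(lines)

    def to_dict(self) -> dict:
        return {
            "format_version": 1,
            "model": "bccp",
            "genes": self.genes,
            "weights": [float(v) for v in self.weights],
            "gene_means": [float(v) for v in self.gene_means],
            "gene_sds": [float(v) for v in self.gene_sds],
            "mu_mes": self.mu_mes,
            "mu_epi": self.mu_epi,
            "sigma": self.sigma,
            "priors": list(self.priors),
        }

    def save(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2, sort_keys=True)
            fh.write("\n")

    @classmethod
    def from_dict(cls, payload: dict) -> "BCCPResults":
        genes = payload["genes"]
        return cls(
            weights=pd.Series(payload["weights"], index=genes, name="t_weight"),
            gene_means=pd.Series(payload["gene_means"], index=genes),
            gene_sds=pd.Series(payload["gene_sds"], index=genes),
            mu_mes=float(payload["mu_mes"]),
            mu_epi=float(payload["mu_epi"]),
            sigma=float(payload["sigma"]),
            priors=(float(payload["priors"][0]), float(payload["priors"][1])),
            train_covariate=pd.Series(dtype=float),
            train_labels=pd.Series(dtype=object),
        )

    @classmethod
    def load(cls, path: str | Path) -> "BCCPResults":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


# ---------------------------------------------------------------------------
# functional surface


def fit_bccp(
    expr: ExpressionMatrix,
    labels: SubgroupAssignment | pd.Series,
    signature: EMTSignature,
    priors: tuple[float, float] = (0.5, 0.5),
) -> BCCPResults:
    """Fit the compound covariate classifier on a labelled training cohort."""
    return BCCP(expr, labels, signature, priors=priors).fit()


def bccp_posterior(model: BCCPResults, c: float | np.ndarray) -> float | np.ndarray:
    """P(Mes | compound covariate value)."""
    return model.posterior(c)


def predict_bccp(
    model: BCCPResults, expr: ExpressionMatrix, standardize: str = "cohort"
) -> SubgroupAssignment:
    """Classify an (harmonized) independent cohort with a fitted model."""
    return model.predict(expr, standardize=standardize)


def loocv_misclassification(
    expr: ExpressionMatrix,
    labels: SubgroupAssignment | pd.Series,
    signature: EMTSignature,
    priors: tuple[float, float] = (0.5, 0.5),
) -> float:
    """Leave-one-out misclassification rate of the training cohort.

    Every fold re-derives gene standardization, t-weights and the Gaussian
    class-conditionals without the held-out sample; the held-out sample is
    standardized with the fold's training parameters.
    """
    label_series = labels.labels if isinstance(labels, SubgroupAssignment) else labels
    n = len(label_series)
    if n < 4:
        raise ValueError("LOOCV needs >= 4 samples")
    errors = 0
    for sample in label_series.index:
        fold_labels = label_series.drop(sample)
        counts = fold_labels.value_counts()
        if counts.get("Mes", 0) < 2 or counts.get("Epi", 0) < 2:
            raise ValueError(
                f"leaving out {sample!r} leaves a class with < 2 samples"
            )
        fold = BCCP(expr, fold_labels, signature, priors=priors).fit()
        x = expr.values.loc[fold.genes, [sample]]
        z = x.sub(fold.gene_means, axis=0).div(fold.gene_sds, axis=0)
        c = float(fold.weights @ z[sample])
        predicted = "Mes" if fold.posterior(c) >= 0.5 else "Epi"
        errors += predicted != label_series[sample]
    return errors / n
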