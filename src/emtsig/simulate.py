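"""Synthetic multi-cohort expression + survival data with planted EMT structure.

The generator emulates the statistical skeleton the analysis relies on:

* a latent epithelial/mesenchymal state per sample (Bernoulli draw);
* anchor markers — CDH1 elevated in the epithelial state, VIM/CDH2/FN1 in
  the mesenchymal state — with unit Gaussian noise around a common
  log-scale baseline;
* planted signature genes that co-shift with their anchor (epithelial
  genes with CDH1, mesenchymal genes with VIM), which induces a positive
  population correlation with the anchor through the shared latent state;
* immune genes (checkpoints, interferon-gamma programme, cytolytic
  effectors, plus any supplied immune-cell gene sets) elevated in the
  mesenchymal state by ``immune_effect``;
* i.i.d. Gaussian noise genes;
* exponential survival with hazard multiplied by ``hazard_ratio_epi`` for
  epithelial samples (proportional hazards holds exactly) and independent
  uniform censoring calibrated to a target censoring fraction.

For two genes sharing the latent state with shift ``d`` and unit noise the
population Pearson correlation has the closed form

    rho = d^2 p (1 - p) / (d^2 p (1 - p) + 1),      p = mes_fraction,

exposed as :func:`planted_anchor_correlation` so tests can check sample
correlations against it.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .io import ClinicalTable, ExpressionMatrix, GeneSetCollection

__all__ = [
    "SyntheticCohortSpec",
    "SyntheticCohort",
    "generate_cohort",
    "generate_multi_cohort",
    "planted_anchor_correlation",
    "default_cell_sets",
    "default_is_genes",
    "EPITHELIAL_MARKER",
    "MESENCHYMAL_MARKERS",
    "IMMUNE_CORE_GENES",
]

EPITHELIAL_MARKER = "CDH1"
MESENCHYMAL_MARKERS = ("VIM", "CDH2", "FN1")
MARKERS = (EPITHELIAL_MARKER, *MESENCHYMAL_MARKERS)

#: checkpoint + interferon-gamma + cytolytic genes always planted as immune
IMMUNE_CORE_GENES = (
    "PDCD1", "CD274", "CTLA4",
    "CXCL9", "CXCL10", "IDO1", "IFNG", "HLA-DRA", "STAT1",
    "GZMA", "PRF1",
)

#: baseline log2-scale expression level around which genes fluctuate
_BASELINE = 8.0
#: baseline exponential hazard for the mesenchymal state (median ~30 months)
_BASE_HAZARD = math.log(2.0) / 30.0


@dataclass(frozen=True)
class SyntheticCohortSpec:
    """Study conditions for one synthetic cohort.

    Defaults mirror a mid-sized HNSCC expression cohort: roughly balanced
    epithelial/mesenchymal composition, a two-standard-deviation marker
    separation (strong but realistic for a transition programme on the log
    scale), a 1.5-sd immune elevation in the mesenchymal state, an
    epithelial-vs-mesenchymal hazard ratio of 0.65 and ~30% censoring.
    """

    n_samples: int = 300
    n_noise_genes: int = 1000
    n_epi_genes: int = 20
    n_mes_genes: int = 20
    marker_effect: float = 2.0
    immune_effect: float = 1.5
    mes_fraction: float = 0.5
    hazard_ratio_epi: float = 0.65
    censoring_rate: float = 0.3
    platform_shift: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_samples", "n_noise_genes", "n_epi_genes", "n_mes_genes"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if not 0.0 < self.mes_fraction < 1.0:
            raise ValueError("mes_fraction must lie in (0, 1)")
        if self.marker_effect < 0:
            raise ValueError("marker_effect must be >= 0")
        if not 0.0 <= self.censoring_rate < 1.0:
            raise ValueError("censoring_rate must lie in [0, 1)")
        if self.hazard_ratio_epi <= 0:
            raise ValueError("hazard_ratio_epi must be > 0")


@dataclass
class SyntheticCohort:
    expression: ExpressionMatrix
    clinical: ClinicalTable
    true_labels: pd.Series  # sample id -> {"Epi", "Mes"}
    spec: SyntheticCohortSpec
    planted_epi_genes: list[str] = field(default_factory=list)
    planted_mes_genes: list[str] = field(default_factory=list)
    immune_genes: list[str] = field(default_factory=list)

    @property
    def planted_signature_genes(self) -> list[str]:
        return self.planted_epi_genes + self.planted_mes_genes


def planted_anchor_correlation(marker_effect: float, mes_fraction: float) -> float:
    """Population Pearson r between two unit-noise genes sharing the latent shift."""
    v = marker_effect**2 * mes_fraction * (1.0 - mes_fraction)
    return v / (v + 1.0)


def _censoring_horizon(rates: np.ndarray, weights: np.ndarray, target: float) -> float:
    """Upper bound u of Uniform(0, u) censoring giving the target censored fraction.

    With T ~ Exp(rate) and C ~ Uniform(0, u) independent,
    P(censored) = P(C < T) = (1 - exp(-rate*u)) / (rate*u); the overall
    fraction is the mixture over latent states. Monotone decreasing in u,
    from 1 (u -> 0) to 0 (u -> inf), so a root always exists for
    target in (0, 1).
    """

    def frac(u: float) -> float:
        ru = rates * u
        return float(np.sum(weights * (1.0 - np.exp(-ru)) / ru)) - target

    lo, hi = 1e-9, 1e9
    return brentq(frac, lo, hi, xtol=1e-10)


def _simulate_survival(
    rng: np.random.Generator, is_mes: np.ndarray, spec: SyntheticCohortSpec
) -> tuple[np.ndarray, np.ndarray]:
    rate = np.where(is_mes, _BASE_HAZARD, _BASE_HAZARD * spec.hazard_ratio_epi)
    t = rng.exponential(1.0 / rate)
    if spec.censoring_rate == 0:
        return t, np.ones_like(t, dtype=int)
    p = spec.mes_fraction
    u = _censoring_horizon(
        np.array([_BASE_HAZARD, _BASE_HAZARD * spec.hazard_ratio_epi]),
        np.array([p, 1.0 - p]),
        spec.censoring_rate,
    )
    c = rng.uniform(0.0, u, size=t.shape)
    time = np.minimum(t, c)
    event = (t <= c).astype(int)
    return time, event


def _clinical_covariates(rng: np.random.Generator, n: int) -> pd.DataFrame:
    """Categorical covariates drawn independently of the latent EMT state."""
    sites = np.array(["Oral cavity", "Oropharynx", "Larynx", "Hypopharynx"])
    stages = np.array(["I", "II", "III", "IV"])
    return pd.DataFrame(
        {
            "age": np.round(rng.normal(61.0, 12.0, n), 1),
            "gender": rng.choice(["male", "female"], n, p=[0.75, 0.25]),
            "hpv": rng.choice(["positive", "negative"], n, p=[0.2, 0.8]),
            "site": rng.choice(sites, n, p=[0.55, 0.2, 0.18, 0.07]),
            "t_stage": rng.choice(["T1-2", "T3-4"], n, p=[0.4, 0.6]),
            "n_stage": rng.choice(["N0", "N+"], n, p=[0.45, 0.55]),
            "stage": rng.choice(stages, n, p=[0.05, 0.18, 0.2, 0.57]),
            "smoking": rng.choice(["never", "yes"], n, p=[0.22, 0.78]),
            "alcohol": rng.choice(["never", "yes"], n, p=[0.3, 0.7]),
        }
    )


def generate_cohort(
    spec: SyntheticCohortSpec,
    cell_sets: GeneSetCollection | None = None,
    extra_immune_genes: Sequence[str] | None = None,
    name: str = "training",
) -> SyntheticCohort:
    """Draw one cohort: expression matrix, clinical table and true labels.

    Genes from ``cell_sets`` and ``extra_immune_genes`` are planted as
    immune genes (shifted by ``immune_effect`` in the mesenchymal state)
    alongside the built-in checkpoint/interferon/cytolytic panel.
    Fully reproducible from ``spec.seed``.
    """
    rng = np.random.default_rng(np.random.SeedSequence(spec.seed))
    n = spec.n_samples
    is_mes = rng.binomial(1, spec.mes_fraction, n).astype(bool)

    immune_genes: dict[str, None] = dict.fromkeys(IMMUNE_CORE_GENES)
    if cell_sets is not None:
        for g in cell_sets.all_genes():
            immune_genes.setdefault(g, None)
    if extra_immune_genes is not None:
        for g in extra_immune_genes:
            immune_genes.setdefault(g, None)
    immune = [g for g in immune_genes if g not in MARKERS]

    epi_genes = [f"EPI{i:03d}" for i in range(1, spec.n_epi_genes + 1)]
    mes_genes = [f"MES{i:03d}" for i in range(1, spec.n_mes_genes + 1)]
    noise_genes = [f"NOISE{i:04d}" for i in range(1, spec.n_noise_genes + 1)]

    order = list(MARKERS) + epi_genes + mes_genes + immune + noise_genes
    mes_ind = is_mes.astype(float)
    epi_ind = 1.0 - mes_ind

    shifts = np.zeros((len(order), n))
    for i, gene in enumerate(order):
        if gene == EPITHELIAL_MARKER or gene in epi_genes:
            shifts[i] = spec.marker_effect * epi_ind
        elif gene in MESENCHYMAL_MARKERS or gene in mes_genes:
            shifts[i] = spec.marker_effect * mes_ind
        elif gene in immune_genes:
            shifts[i] = spec.immune_effect * mes_ind
    values = _BASELINE + shifts + rng.standard_normal((len(order), n))

    samples = [f"{name}-S{j:04d}" for j in range(1, n + 1)]
    expr = ExpressionMatrix(pd.DataFrame(values, index=order, columns=samples), name=name)

    time, event = _simulate_survival(rng, is_mes, spec)
    clinical_df = pd.DataFrame({"time": time, "event": event}, index=pd.Index(samples, name="id"))
    clinical_df = pd.concat([clinical_df, _clinical_covariates(rng, n).set_index(clinical_df.index)], axis=1)
    clinical = ClinicalTable(clinical_df, endpoint="OS")

    labels = pd.Series(np.where(is_mes, "Mes", "Epi"), index=samples, name="true_label")
    return SyntheticCohort(
        expression=expr,
        clinical=clinical,
        true_labels=labels,
        spec=spec,
        planted_epi_genes=epi_genes,
        planted_mes_genes=mes_genes,
        immune_genes=immune,
    )


def _distort_platform(
    expr: ExpressionMatrix, rng: np.random.Generator, magnitude: float
) -> ExpressionMatrix:
    """Per-gene affine distortion (scale, offset) plus independent noise."""
    if magnitude == 0:
        return expr
    g = expr.shape[0]
    scale = np.exp(rng.normal(0.0, 0.15 * magnitude, size=g))
    offset = rng.normal(0.0, magnitude, size=g)
    noise = rng.normal(0.0, 0.2 * magnitude, size=expr.shape)
    distorted = expr.values.mul(scale, axis=0).add(offset, axis=0) + noise
    return ExpressionMatrix(distorted, name=expr.name)


def generate_multi_cohort(
    spec: SyntheticCohortSpec,
    n_test_cohorts: int = 3,
    cell_sets: GeneSetCollection | None = None,
    extra_immune_genes: Sequence[str] | None = None,
) -> list[SyntheticCohort]:
    """One training cohort plus platform-shifted test cohorts.

    Test cohorts share the latent generative model but are drawn with
    deterministically derived per-cohort seeds and then pushed through a
    per-gene affine distortion of magnitude ``platform_shift``, emulating
    array/sequencing platform differences.
    """
    if n_test_cohorts < 1:
        raise ValueError("n_test_cohorts must be >= 1")
    derived = np.random.SeedSequence(spec.seed).generate_state(2 * n_test_cohorts + 1)
    cohorts = [generate_cohort(spec, cell_sets, extra_immune_genes, name="training")]
    for k in range(n_test_cohorts):
        sub_seed = int(derived[2 * k + 1] % (2**31 - 1))
        sub = replace(spec, seed=sub_seed)
        cohort = generate_cohort(sub, cell_sets, extra_immune_genes, name=f"test{k + 1}")
        distort_rng = np.random.default_rng(int(derived[2 * k + 2] % (2**31 - 1)))
        cohort.expression = _distort_platform(cohort.expression, distort_rng, spec.platform_shift)
        cohorts.append(cohort)
    return cohorts


# ---------------------------------------------------------------------------
# synthetic immune-cell resources (stand-ins for externally curated lists)


def default_cell_sets(genes_per_set: int = 6) -> GeneSetCollection:
    """Synthetic immune-cell gene sets (marker lists are inputs, not constants).

    Builds one disjoint set of fabricated symbols per cell subset, including
    the excluded subsets so exclusion logic is exercised. Deterministic.
    """
    from .immune import (
        EXCLUDED_SUBSET_NAMES,
        IIS_EXTRA_SUBSET_NAMES,
        TIS_SUBSET_NAMES,
    )

    sets: dict[str, list[str]] = {}
    all_names = TIS_SUBSET_NAMES + EXCLUDED_SUBSET_NAMES + IIS_EXTRA_SUBSET_NAMES
    for idx, subset in enumerate(all_names):
        tag = "".join(ch for ch in subset.upper() if ch.isalnum())[:8]
        sets[subset] = [f"{tag}.G{idx:02d}{j:02d}" for j in range(1, genes_per_set + 1)]
    return GeneSetCollection(sets=sets, descriptions={n: "synthetic marker set" for n in sets})


def default_is_genes(n_genes: int = 105) -> list[str]:
    """Synthetic stand-in for the externally defined 105-gene immune signature."""
    return [f"ISG{i:03d}" for i in range(1, n_genes + 1)]
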