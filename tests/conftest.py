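import numpy as np
import pandas as pd
import pytest

from emtsig import (
    ExpressionMatrix,
    SyntheticCohortSpec,
    compute_marker_correlations,
    default_cell_sets,
    default_is_genes,
    generate_cohort,
    select_signature_genes,
)


def make_expr(values, genes, samples, name="toy"):
    return ExpressionMatrix(
        pd.DataFrame(np.asarray(values, dtype=float), index=genes, columns=samples),
        name=name,
    )


@pytest.fixture(scope="session")
def cell_sets():
    return default_cell_sets()


@pytest.fixture(scope="session")
def is_genes():
    return default_is_genes()


@pytest.fixture(scope="session")
def small_cohort(cell_sets, is_genes):
    """Mid-sized synthetic cohort with planted structure, shared across tests."""
    spec = SyntheticCohortSpec(seed=11, n_samples=150, n_noise_genes=80)
    return generate_cohort(spec, cell_sets=cell_sets, extra_immune_genes=is_genes)


@pytest.fixture(scope="session")
def small_signature(small_cohort):
    table = compute_marker_correlations(small_cohort.expression)
    return select_signature_genes(table, r_min=0.5, q_max=0.05)
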