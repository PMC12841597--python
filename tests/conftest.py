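import numpy as np
import pandas as pd
import pytest

from panepiclock.gene_matrix import GeneMatrix
from panepiclock.harmonize import StratumMinMaxScaler
from panepiclock.simulate import SimConfig, simulate_gene_matrix


def make_assoc_table(rho, gene_ids=None, n=50):
    """Build an association table directly from a rho vector (unit-test
    shortcut for statistics that only consume rho rankings)."""
    rho = np.asarray(rho, dtype=float)
    if gene_ids is None:
        gene_ids = [f"G{i:05d}" for i in range(len(rho))]
    from panepiclock.age_stats import spearman_t_pvalue
    p = spearman_t_pvalue(rho, n)
    return pd.DataFrame({"rho": rho, "n": n, "p": p, "q": p, "constant": False},
                        index=pd.Index(gene_ids, name="gene_id"))


def make_matrix(values, samples):
    return GeneMatrix(pd.DataFrame(values), pd.DataFrame(samples))


@pytest.fixture(scope="session")
def small_cohort():
    """A modest two-species cohort with planted signal, shared by the
    slower model-level tests."""
    config = SimConfig(n_genes=300, n_informative=100, n_donors_per_species=60, seed=11)
    matrix, truth = simulate_gene_matrix(config)
    return config, matrix, truth


@pytest.fixture(scope="session")
def small_cohort_scaled(small_cohort):
    config, matrix, truth = small_cohort
    scaled = StratumMinMaxScaler().fit(matrix).transform(matrix)
    return config, scaled, truth
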