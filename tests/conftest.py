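import numpy as np
import pandas as pd
import pytest

import precisenet as pn


def flat_prior(proteins: list[str], w: float = 0.5) -> pn.PriorInclusionMatrix:
    """Uniform prior inclusion matrix over all ordered protein pairs."""
    p = len(proteins)
    mat = np.full((p, p), w)
    np.fill_diagonal(mat, 0.0)
    return pn.PriorInclusionMatrix(proteins=list(proteins), w=mat)


@pytest.fixture(scope="session")
def small_cohort() -> pn.SimulatedCohort:
    """Six proteins, one pathway, moderate signal; reused across tests."""
    spec = pn.SimulationSpec(
        n_samples=150,
        pathway_sizes=(6,),
        edge_density=0.3,
        noise_sd=0.3,
        seed=11,
    )
    return pn.simulate_cohort(spec)


@pytest.fixture(scope="session")
def small_fit(small_cohort):
    """Fitted pathway (flat prior, upstream platforms included)."""
    cfg = pn.AnalysisConfig(seed=11)
    prior = flat_prior(small_cohort.matrices["protein"].feature_ids)
    return pn.fit_pathway_network(
        small_cohort.matrices["protein"],
        small_cohort.pathways[0],
        prior,
        cfg,
        mrna=small_cohort.matrices["mrna"],
        methylation=small_cohort.matrices["methylation"],
        mirna=small_cohort.matrices.get("mirna"),
        mirna_map=small_cohort.mirna_map,
    )


@pytest.fixture(scope="session")
def small_tensor(small_fit):
    return pn.patient_probability_tensor(small_fit, delta=0.5)


def make_expression(values, samples=None, features=None, platform="protein"):
    values = np.asarray(values, dtype=float)
    n, m = values.shape
    samples = samples or [f"s{i}" for i in range(n)]
    features = features or [f"f{j}" for j in range(m)]
    return pn.ExpressionMatrix(
        platform=platform, data=pd.DataFrame(values, index=samples, columns=features)
    )
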