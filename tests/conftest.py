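import numpy as np
import pytest

from multipen import CohortSpec, ExpressionMatrix, generate_cohort


@pytest.fixture
def tiny_expression() -> ExpressionMatrix:
    return ExpressionMatrix(
        gene_ids=["G1", "G2", "G3"],
        sample_ids=["S1", "S2"],
        values=np.array([[1.5, 2.25], [0.0, 7.0], [3.0, 0.125]]),
    )


@pytest.fixture(scope="session")
def small_cohort():
    """A small planted-signal cohort for fast end-to-end tests."""
    spec = CohortSpec(
        n_samples=40,
        p_mrna=30,
        p_mirna=12,
        n_prognostic_mrna=6,
        n_prognostic_mirna=3,
        effect_size=3.0,
        coupling=0.7,
        zero_inflation=0.02,
        noise_sd=0.5,
        seed=9,
    )
    return generate_cohort(spec)


@pytest.fixture(scope="session")
def strong_cohort():
    return generate_cohort(CohortSpec.strong_signal(seed=1))
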