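import numpy as np
import pytest

from methbp.simulate import CohortConfig, generate_cohort


@pytest.fixture(scope="session")
def null_cohort():
    """A medium null cohort (all methylation effects zero)."""
    return generate_cohort(CohortConfig(n_samples=1500, seed=11))


@pytest.fixture(scope="session")
def small_cohort():
    """A small cohort with SBP effects on several CpGs."""
    cfg = CohortConfig(
        n_samples=400,
        seed=7,
        beta_sbp_per5=np.array([-1.0, 0.0, -0.5, 0.0, 0.0, -0.5, 0.0, -0.5, 0.0]),
    )
    return generate_cohort(cfg)
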