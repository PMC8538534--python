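import numpy as np
import pytest

from mitralmorph import cohort_frame, default_config, generate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """A deterministic 60-dog synthetic cohort with its ground truth."""
    cfg = default_config(n=60, seed=42)
    records, truth = generate_cohort(cfg)
    return records, truth


@pytest.fixture(scope="session")
def medium_cohort():
    """A deterministic 2000-dog cohort for distributional checks."""
    cfg = default_config(n=2000, seed=1)
    records, truth = generate_cohort(cfg)
    return records, truth


@pytest.fixture(scope="session")
def medium_frame(medium_cohort):
    records, _ = medium_cohort
    return cohort_frame(records)
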