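import numpy as np
import pytest

from mirsig import CohortDesign, ExpressionMatrix, SampleAnnotation, generate_cohort


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def tiny_matrix():
    """3 features x 4 samples with one masked cell."""
    values = np.array(
        [
            [1.0, 2.0, 3.0, 4.0],
            [0.5, np.nan, -0.5, 1.5],
            [-2.0, -1.0, 0.0, 1.0],
        ]
    )
    mask = np.zeros_like(values, dtype=bool)
    mask[1, 1] = True
    return ExpressionMatrix(
        ["miR-a", "miR-b", "miR-c"], ["s1", "s2", "s3", "s4"], values, mask
    )


@pytest.fixture
def small_cohort():
    """A small, fast cohort with strong planted signal (seeded)."""
    design = CohortDesign(
        n_features=120,
        group_sizes={"MLL": 14, "t_8_21": 12, "NPM1": 10, "other": 24},
        signature_sizes={"MLL": 10, "t_8_21": 8, "NPM1": 5},
        effect_log2=3.0,
        noise_sd=1.0,
        missing_rate=0.0,
        rng_seed=7,
    )
    return generate_cohort(design)


@pytest.fixture
def annotation4():
    return SampleAnnotation(
        ["s1", "s2", "s3", "s4"],
        np.array(["MLL", "MLL", "other", "other"], dtype=object),
    )
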