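import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))

from trioforge.synthetic_cohort import SimulationConfig, generate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """A seeded 16-quad cohort with 600 shared sites, annotated."""
    cfg = SimulationConfig(seed=11, variants_per_exome=600)
    cohort, truth = generate_cohort(cfg)
    return cohort, truth, cfg


@pytest.fixture(scope="session")
def trio_cohort():
    """A seeded 4-trio cohort, small enough for exhaustive checks."""
    cfg = SimulationConfig(
        n_families=4, n_quads=0, n_male_probands=3, variants_per_exome=120, seed=3,
    )
    cohort, truth = generate_cohort(cfg)
    return cohort, truth, cfg
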