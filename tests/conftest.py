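import numpy as np
import pytest

from autozyg import GenomeSpec, detect_roh, make_study_design

#: Canonical fixed seed for every stochastic fixture in the suite.
SEED = 1


@pytest.fixture(scope="session")
def study_design():
    """Two-line x 8-generation breeding design with F1 cross.

    30 individuals per generation on the 5 x 50 Mb desk-scale genome at
    100 markers/Mb — the standard conditions for parameter-recovery
    checks.
    """
    return make_study_design(
        g_line=8, n_per_gen=30, cross=True, seed=SEED,
        spec=GenomeSpec.desk_scale(),
    )


@pytest.fixture(scope="session")
def study_segments(study_design):
    """Detected ROH per genotyped population of the study design."""
    return {
        name: detect_roh(g, study_design.marker_map)
        for name, g in study_design.populations.items()
    }


@pytest.fixture()
def rng():
    return np.random.default_rng(SEED)
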