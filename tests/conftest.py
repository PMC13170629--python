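import numpy as np
import pandas as pd
import pytest

from axonet import (CohortConfig, generate_cohort, generate_connectomes,
                    PhantomSpec, StraightTube, generate_phantom, track_fact)

PLANTED = [(0, 1), (1, 2), (1, 3), (3, 4), (4, 5)]


@pytest.fixture(scope="session")
def cohort77():
    """Default-condition cohort: 77 AN + 77 HC, fixed seed."""
    return generate_cohort(CohortConfig(seed=11))


@pytest.fixture(scope="session")
def small_cohort():
    return generate_cohort(CohortConfig(n_per_group=20, seed=5))


@pytest.fixture(scope="session")
def planted_connectomes(cohort77):
    """30-node connectomes with a planted 5-edge NF-L component
    (per-edge expected t about 6 at n = 77)."""
    return generate_connectomes(cohort77, n_nodes=30,
                                planted_components=[PLANTED],
                                edge_effect=0.0205, seed=13)


@pytest.fixture(scope="session")
def an_frame(cohort77):
    return cohort77[cohort77["group"] == "AN"].set_index("id")


@pytest.fixture(scope="session")
def tube_tracked():
    spec = PhantomSpec(shape=(12, 5, 5),
                       bundles=[StraightTube(start=(1, 2, 2), length=10,
                                             fa=0.6)])
    vol, parc = generate_phantom(spec)
    return vol, parc, track_fact(vol)
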