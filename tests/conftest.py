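"""Shared fixtures: a small symmetric template and a simulated cohort.

Session-scoped because template construction and cohort simulation are
the expensive parts of the suite; tests must not mutate them.
"""

import numpy as np
import pytest

from facesym.simulate import FaceSimConfig, make_template, simulate_faces


@pytest.fixture(scope="session")
def template():
    """Small symmetric face template (600 vertices)."""
    return make_template(600)


@pytest.fixture(scope="session")
def template_1k():
    """Default-resolution template (1000 vertices)."""
    return make_template(1000)


@pytest.fixture(scope="session")
def sim_cohort(template_1k):
    """Small simulated cohort with planted symmetric + asymmetric modes.

    3 symmetric and 2 asymmetric modes, 0.1 mm capture noise, 30 controls
    and 12 FS cases with a 1 mm planted asymmetry amplitude.
    """
    cfg = FaceSimConfig(
        mesh_resolution=1000,
        n_per_group={"CTRL": 30, "FS": 12, "FC": 0, "IGE": 0},
        sym_mode_sds=(2.0, 1.5, 1.0),
        asym_mode_sds=(0.5, 0.3),
        group_asym_amplitude={"CTRL": 0.0, "FC": 0.0, "FS": 1.0, "IGE": 0.0},
        noise_sd=0.1,
        seed=7,
    )
    return simulate_faces(cfg, template=template_1k)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
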