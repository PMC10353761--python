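"""Shared fixtures: a small seeded cohort with an injected band effect.

Cohort sizes here are desk-scale (10 patients per outcome, 10 epochs per
recording, synthesis directly at 500 Hz) so the whole suite stays fast;
the statistical structure is the same as the full-size generator default.
"""

import numpy as np
import pytest

from comaspectra.clusterstat import build_adjacency
from comaspectra.montage import get_montage
from comaspectra.pipeline import compute_spectra
from comaspectra.spectral import SpectrumGrid
from comaspectra.synthetic import CohortConfig, generate_cohort


@pytest.fixture(scope="session")
def grid():
    return SpectrumGrid()


@pytest.fixture(scope="session")
def montage19():
    return get_montage(19)


@pytest.fixture(scope="session")
def adjacency19(montage19):
    labels, positions = montage19
    return build_adjacency(positions, labels)


@pytest.fixture(scope="session")
def effect_config():
    return CohortConfig(
        n_fo=10, n_uo=10, n_epochs_per_recording=10, fs_raw=500.0, seed=42
    )


@pytest.fixture(scope="session")
def effect_cohort(effect_config):
    return generate_cohort(effect_config)


@pytest.fixture(scope="session")
def effect_labels(effect_cohort):
    return {r.patient_id: r.outcome for r in effect_cohort}


@pytest.fixture(scope="session")
def effect_spectra_day1(effect_cohort, grid):
    return compute_spectra(effect_cohort, 1, "per_electrode", grid)


@pytest.fixture(scope="session")
def effect_spectra_day2(effect_cohort, grid):
    return compute_spectra(effect_cohort, 2, "per_electrode", grid)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
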