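"""Shared fixtures.

The expensive Monte-Carlo studies (null calibration of the rotation test,
spin-test calibration) are session-scoped so that the property tests and the
acceptance-level checks share one computation.
"""

from __future__ import annotations

import numpy as np
import pytest

import gliocircuit as g
from gliocircuit.calibration import null_rotation_pvalues


@pytest.fixture(scope="session")
def null_rotation_results():
    """Rotation-test results for 200 synthetic null electrodes, 2000 rotations."""
    return null_rotation_pvalues(n_electrodes=200, n_rotations=2000, base_seed=0)


@pytest.fixture(scope="session")
def desk_config():
    return g.AnalysisConfig(fs_target=2000.0, n_rotations=500, n_spins=500)


@pytest.fixture(scope="session")
def small_recording():
    """One 4-electrode strip with planted condition effects, 2 kHz."""
    spec = g.EcogSimSpec(
        n_strips=1,
        fs=2000.0,
        trial_plan=[("rest", 12.0, 1), ("easy", 8.0, 2), ("hard", 8.0, 2)],
        easy_vs_rest=1.5,
        hard_vs_easy=2.0,
        noise_amplitude=1.0,
        rng_seed=11,
    )
    return g.simulate_ecog(spec)


@pytest.fixture(scope="session")
def sphere_and_parcels():
    mesh = g.make_icosphere(3)
    labels = g.make_parcellation(mesh, 7, rng_seed=4)
    return mesh, labels


@pytest.fixture(scope="session")
def bold_world():
    """Default synthetic BOLD session (tumour coupled to network 1 at w=0.6)."""
    bold, masks, affine, truth = g.simulate_bold(g.BoldSimSpec(rng_seed=21))
    return {"bold": bold, "masks": masks, "affine": affine, "truth": truth}


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
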