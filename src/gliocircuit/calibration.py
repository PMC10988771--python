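"""Monte-Carlo calibration studies for the pipeline's permutation tests.

These helpers run the full preprocessing + inference chain over synthetic
data in batches, and back both the test suite and the acceptance script.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .config import AnalysisConfig
from .contrast import HARD_GT_EASY, rotation_permutation_test
from .preprocess import preprocess
from .simulate import EcogSimSpec, simulate_ecog

#: trial layout of the null/power studies: four 10-s trials per condition.
STUDY_TRIAL_PLAN = [("easy", 10.0, 4), ("hard", 10.0, 4)]


def null_rotation_pvalues(
    n_electrodes: int = 200,
    n_rotations: int = 2000,
    base_seed: int = 0,
    hard_vs_easy: float = 1.0,
    batch_strips: int = 20,
    fs: float = 2000.0,
) -> pd.DataFrame:
    """Rotation-test results for independent synthetic electrodes.

    Each electrode is the bipolar derivation of a 2-contact strip carrying
    1/f background noise (no line components, no planted high-gamma carrier),
    with four 10-s trials per condition; under ``hard_vs_easy = 1`` the two
    conditions have identical power and the returned p-values are null draws.
    The full fixed-order preprocessing chain runs before the test.
    """
    cfg = AnalysisConfig(fs_target=fs, n_rotations=n_rotations)
    frames = []
    n_batches = int(np.ceil(n_electrodes / batch_strips))
    for b in range(n_batches):
        strips = min(batch_strips, n_electrodes - b * batch_strips)
        spec = EcogSimSpec(
            n_strips=strips,
            electrodes_per_strip=2,
            fs=fs,
            trial_plan=STUDY_TRIAL_PLAN,
            hard_vs_easy=hard_vs_easy,
            carrier_amplitude=0.0 if hard_vs_easy == 1.0 else 10.0,
            noise_amplitude=20.0,
            line_amplitudes={},
            rng_seed=(base_seed * 1009 + b) % (2**31 - 1),
        )
        rec, _ = simulate_ecog(spec)
        seg = preprocess(rec, cfg)
        res = rotation_permutation_test(
            seg,
            HARD_GT_EASY,
            n_rotations=n_rotations,
            rng_seed=(base_seed * 2027 + b) % (2**31 - 1),
            alpha=cfg.alpha_level,
        )
        res["batch"] = b
        frames.append(res)
    return pd.concat(frames, ignore_index=True).iloc[:n_electrodes].reset_index(drop=True)


def rejection_rate(results: pd.DataFrame, alpha: float = 0.05) -> float:
    """Fraction of electrodes declared significant at ``alpha`` (two-tailed)."""
    return float((results["p"] < alpha).mean())


def spin_null_pvalues(
    n_replicates: int = 200,
    n_spins: int = 500,
    subdivisions: int = 3,
    n_parcels: int = 7,
    base_seed: int = 0,
) -> pd.DataFrame:
    """Spin-test p-values for smooth random maps uncorrelated with parcels.

    Each replicate draws a first-order spherical pattern (a random linear
    form of the vertex coordinates, the smoothest non-trivial map on the
    sphere) and runs the spin test against a fixed random parcellation.
    Under this rotation-symmetric null the p-values should be calibrated.
    """
    from .simulate import make_icosphere, make_parcellation
    from .spin import spin_test
    from .surface import SurfaceMap

    mesh = make_icosphere(subdivisions)
    labels = make_parcellation(mesh, n_parcels, rng_seed=base_seed)
    rng = np.random.default_rng(base_seed + 1)
    frames = []
    for rep in range(n_replicates):
        smap = SurfaceMap(mesh.vertices @ rng.standard_normal(3))
        res = spin_test(smap, labels, mesh, n_surrogates=n_spins,
                        rng_seed=(base_seed * 131 + 17 + rep) % (2**31 - 1))
        res["replicate"] = rep
        frames.append(res)
    return pd.concat(frames, ignore_index=True)
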