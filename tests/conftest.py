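"""Shared fixtures: small synthetic cohorts and simulated detector matrices.

Everything is generated at test time from fixed seeds; nothing is read
from disk.
"""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import settings

import afibvote as av
from afibvote.synthetic import DetectorProfile, simulate_detector_matrix

settings.register_profile("repro", derandomize=True, deadline=None)
settings.load_profile("repro")

#: Balanced-ish mix used by the small training fixtures.
SMALL_MIX = {"AFib": 0.25, "non-AFib": 0.65, "noise": 0.10}


@pytest.fixture(scope="session")
def easy_profile() -> av.DifficultyProfile:
    """A low-noise cohort profile with no hard subtypes (well-separated)."""
    return av.DifficultyProfile("easy", noise_level=0.02,
                                hard_subtype_share=0.0, ectopic_share=0.0)


@pytest.fixture(scope="session")
def easy_train(easy_profile) -> av.LabeledDataset:
    return av.generate_dataset(160, SMALL_MIX, easy_profile, seed=11,
                               name="easy-train")


@pytest.fixture(scope="session")
def easy_test(easy_profile) -> av.LabeledDataset:
    return av.generate_dataset(120, SMALL_MIX, easy_profile, seed=12,
                               name="easy-test")


@pytest.fixture(scope="session")
def calibration(easy_train) -> av.DetectorCalibration:
    return av.calibrate_detectors(easy_train, seed=0)


@pytest.fixture(scope="session")
def easy_test_matrix(easy_test, calibration) -> av.DetectorMatrix:
    return av.build_detector_matrix(easy_test, calibration)


@pytest.fixture(scope="session")
def sim_labels_2000() -> np.ndarray:
    rng = np.random.default_rng(42)
    return rng.choice(["AFib", "non-AFib", "noise"], size=2000,
                      p=[0.25, 0.65, 0.10])


@pytest.fixture(scope="session")
def informative_matrix(sim_labels_2000) -> av.DetectorMatrix:
    """Label-copy column, three partially informative columns, pure noise."""
    profiles = [
        DetectorProfile("label_copy", 1.0, 1.0),
        DetectorProfile("strong", 0.95, 0.97),
        DetectorProfile("medium", 0.90, 0.93),
        DetectorProfile("weak", 0.85, 0.90),
        DetectorProfile("pure_noise", 0.5, 0.5),
    ]
    return simulate_detector_matrix(sim_labels_2000, profiles, seed=7,
                                    correlation=0.0)
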