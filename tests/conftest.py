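import numpy as np
import pytest

from fetalkick import synthetic_cine, tracking
from fetalkick.scenarios import KickScenario, default_cohort


@pytest.fixture(scope="session")
def cohort():
    return default_cohort()


@pytest.fixture(scope="session")
def fetus_a(cohort):
    return cohort[0]


@pytest.fixture(scope="session")
def fetus_a_noiseless(fetus_a):
    from dataclasses import replace
    return replace(fetus_a, noise_sd=0.0)


@pytest.fixture(scope="session")
def fetus_a_truth(fetus_a):
    return synthetic_cine.generate_kick_kinematics(fetus_a)


@pytest.fixture(scope="session")
def fetus_a_sequence(fetus_a, fetus_a_truth):
    return synthetic_cine.render_frames(fetus_a_truth, fetus_a)


@pytest.fixture(scope="session")
def fetus_a_tracked(fetus_a, fetus_a_truth, fetus_a_sequence):
    seeds = tracking.seeds_from_truth(fetus_a_truth, fetus_a_sequence)
    return tracking.track_sequence(fetus_a_sequence, seeds)


def truth_as_trajectories(truth, sequence):
    """Wrap ground-truth joint positions as tracker-style trajectories."""
    out = []
    for name, arr in (("hip", truth.hip), ("knee", truth.knee),
                      ("ankle", truth.ankle)):
        px = (arr - sequence.origin_mm) / sequence.pixel_size_mm
        out.append(tracking.JointTrajectory(
            name=name, px=px, pixel_size_mm=sequence.pixel_size_mm,
            origin_mm=np.asarray(sequence.origin_mm, float),
            score=np.ones(len(px)), valid=np.ones(len(px), bool),
        ))
    return tuple(out)
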