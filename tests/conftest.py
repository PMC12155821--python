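"""Shared fixtures: synthetic trials and a fully rendered capture bundle."""

from __future__ import annotations

import numpy as np
import pytest

import tapmocap as tm


@pytest.fixture(scope="session")
def e2e_profile() -> tm.TapProfile:
    """Profile of the end-to-end fixture trial: a moderate tap at 2.5 Hz
    with mild cycle-to-cycle variability, 10 s long."""
    return tm.TapProfile(
        base_amplitude=6.0,
        base_frequency=2.5,
        amp_cv=0.15,
        freq_cv=0.08,
        trial_duration=10.0,
        seed=7,
    )


@pytest.fixture(scope="session")
def e2e_truth(e2e_profile):
    """Ground-truth trajectory + per-cycle table of the fixture trial."""
    return tm.simulate_tapping_trajectory(e2e_profile)


@pytest.fixture(scope="session")
def rendered_bundle(tmp_path_factory, e2e_profile, e2e_truth):
    """A noise-free capture bundle rendered from the fixture trial."""
    traj, truth = e2e_truth
    out = tmp_path_factory.mktemp("bundle")
    rig = tm.VirtualRigSpec(seed=7)
    tm.render_virtual_capture(traj, rig, out, truth=truth)
    return out


@pytest.fixture(scope="session")
def reconstructed(rendered_bundle):
    """The fixture bundle reconstructed with the oracle detector."""
    det = tm.OracleDetector.from_csv(rendered_bundle / "oracle_landmarks.csv")
    return tm.reconstruct_bundle(rendered_bundle, det)


def random_rigid(rng: np.random.Generator, scale: float = 1.0) -> np.ndarray:
    """A uniformly random proper rigid transform (helper for tests)."""
    A = rng.standard_normal((3, 3))
    Q, R = np.linalg.qr(A)
    Q = Q @ np.diag(np.sign(np.diag(R)))
    if np.linalg.det(Q) < 0:
        Q[:, 0] = -Q[:, 0]
    T = np.eye(4)
    T[:3, :3] = Q
    T[:3, 3] = rng.standard_normal(3) * scale
    return T
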