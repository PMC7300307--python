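import numpy as np
import pytest

from topofold import (TopologicalFeaturizer, TrajectorySpec,
                      generate_fig1_cloud, generate_two_state_trajectory)
from topofold.alpha import build_alpha_filtration
from topofold.persistence import compute_persistence
from topofold.cloud import PointCloud


@pytest.fixture(scope="session")
def two_state_run():
    """The reference synthetic study: 2000 frames of the 10-bead chain
    switching between native (contact 1-8), misfolded (contact 1-7) and
    unfolded states, 0.2 A coordinate noise, seed 7; featurized with
    death-mode TFVs.  Computed once per session."""
    spec = TrajectorySpec(seed=7, n_frames=2000, noise_sigma=0.2)
    traj = generate_two_state_trajectory(spec)
    X = TopologicalFeaturizer(mode="death").transform(traj.coords)
    return {"spec": spec, "traj": traj, "X": X,
            "labels": np.array(traj.labels)}


@pytest.fixture(scope="session")
def fig1_filtration():
    """The six-point worked-example cloud with its filtration and
    persistence pairs."""
    cloud = generate_fig1_cloud()
    fc = build_alpha_filtration(cloud)
    return cloud, fc, compute_persistence(fc)


@pytest.fixture()
def equilateral_triangle():
    """Side-2 equilateral triangle: one loop, birth 1, death 2/sqrt(3)."""
    pts = np.array([[0.0, 0, 0], [2, 0, 0], [1, np.sqrt(3), 0]])
    return PointCloud(pts)
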