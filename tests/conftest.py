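import numpy as np
import pandas as pd
import pytest

from cnmigrate import SimConfig, build_profile, compute_cn_pairs, simulate_tracks


def tracks_from_steps(cell_steps, nuc_steps, dt_min=1.0, movie="m0", cell="c0"):
    """Build a one-cell track table from per-interval displacement vectors."""
    cell_pos = np.vstack([[0.0, 0.0], np.cumsum(np.atleast_2d(cell_steps), axis=0)])
    nuc_pos = np.vstack([[0.0, 0.0], np.cumsum(np.atleast_2d(nuc_steps), axis=0)])
    n = len(cell_pos)
    return pd.DataFrame(
        {
            "movie_id": movie,
            "cell_id": cell,
            "frame": np.arange(n),
            "time_min": np.arange(n) * dt_min,
            "cell_x": cell_pos[:, 0],
            "cell_y": cell_pos[:, 1],
            "nuc_x": nuc_pos[:, 0],
            "nuc_y": nuc_pos[:, 1],
        }
    )


@pytest.fixture(scope="session")
def sim_cfg():
    return SimConfig(seed=11)


@pytest.fixture(scope="session")
def sim_tracks(sim_cfg):
    return simulate_tracks(sim_cfg)


@pytest.fixture(scope="session")
def sim_profile(sim_tracks):
    tracks, _ = sim_tracks
    return build_profile(compute_cn_pairs(tracks), "simulated")
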