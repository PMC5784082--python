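"""Synthetic coupled cell/nucleus trajectories with per-interval ground truth.

Movies are composed of labeled subcellular-activity *episodes*.  Each
activity draws a polar angle theta ~ Normal(theta_mean, theta_sd) and a pole
distance r ~ LogNormal(radius_log_mean, radius_log_sd); the generated pair is

    CCD = r sin(theta),   NCD_par = r cos(theta)

so the extraction stage can recover the generated values exactly.  Episode
durations are geometric with the configured mean; on exit the next activity
is drawn with probability proportional to weight / duration, which makes the
configured ``transition_weights`` the stationary per-interval occupancy.

Tracks are laid out in the plane with a persistent heading: the cell steps by
CCD along the heading, the nucleus by NCD_par along the heading plus
independent perpendicular noise (the perpendicular nuclear component is not
modeled, so the parallel projection stays exactly recoverable).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "ActivitySpec",
    "SimConfig",
    "default_activity_library",
    "simulate_pairs",
    "simulate_tracks",
    "simulate_prw_tracks",
]


@dataclass(frozen=True)
class ActivitySpec:
    """Distributional parameters of one subcellular migratory activity."""

    name: str
    theta_mean: float  # degrees
    theta_sd: float  # degrees
    radius_log_mean: float  # log-µm
    radius_log_sd: float  # log-µm
    mean_duration: float = 3.0  # minutes

    def __post_init__(self):
        if not 0 < self.theta_mean < 180:
            raise ValueError("theta_mean must lie in (0, 180)")
        if self.theta_sd <= 0:
            raise ValueError("theta_sd must be positive")
        if self.mean_duration < 1:
            raise ValueError("mean_duration must be >= 1 minute")


def default_activity_library() -> tuple:
    """The five canonical activities, centered on their polar-angle zones.

    Angle means sit at the centers of the activity zones (detachment
    [20, 70], leading-edge protrusion [60, 90], sampling [60, 120], side
    protrusion [90, 130], contraction [130, 170]).  Median step radii
    decrease from detachment (farthest from the pole) through the
    protrusions to sampling and contraction (closest to the pole).
    """
    return (
        ActivitySpec("detachment", 45.0, 10.0, math.log(1.0), 0.45, 4.0),
        ActivitySpec("leading-edge protrusion", 75.0, 9.0, math.log(0.55), 0.40, 3.0),
        ActivitySpec("sampling", 90.0, 10.0, math.log(0.25), 0.40, 3.0),
        ActivitySpec("side protrusion", 110.0, 9.0, math.log(0.45), 0.40, 3.0),
        ActivitySpec("contraction", 150.0, 9.0, math.log(0.22), 0.40, 2.0),
    )


@dataclass
class SimConfig:
    """Simulator configuration; ``seed`` is mandatory for reproducibility."""

    seed: int
    activities: tuple = field(default_factory=default_activity_library)
    transition_weights: tuple = (0.25, 0.25, 0.20, 0.15, 0.15)
    heading_persistence: float = 4.0  # von-Mises concentration of turn angles
    n_movies: int = 25
    frames_per_movie: int = 61
    dt_min: float = 1.0
    nuc_perp_sd: float = 0.15  # µm

    def __post_init__(self):
        w = np.asarray(self.transition_weights, dtype=float)
        if len(w) != len(self.activities):
            raise ValueError("one transition weight per activity required")
        if (w < 0).any() or not np.isclose(w.sum(), 1.0, atol=1e-9):
            raise ValueError("transition_weights must be non-negative and sum to 1")
        if self.frames_per_movie < 2:
            raise ValueError("frames_per_movie must be >= 2")
        if self.seed is None:
            raise ValueError("seed is mandatory")

    def to_yaml(self, path) -> None:
        payload = asdict(self)
        payload["activities"] = [asdict(a) for a in self.activities]
        payload["transition_weights"] = list(self.transition_weights)
        Path(path).write_text(yaml.safe_dump(payload))

    @classmethod
    def from_yaml(cls, path) -> "SimConfig":
        payload = yaml.safe_load(Path(path).read_text())
        payload["activities"] = tuple(ActivitySpec(**a) for a in payload["activities"])
        payload["transition_weights"] = tuple(payload["transition_weights"])
        return cls(**payload)


def _sample_labels(cfg: SimConfig, n: int, rng: np.random.Generator) -> np.ndarray:
    """Episode-structured activity labels with stationary occupancy =
    ``transition_weights`` (entry probabilities are weight/duration)."""
    w = np.asarray(cfg.transition_weights, dtype=float)
    durations = np.array([a.mean_duration for a in cfg.activities])
    entry = w / durations
    positive = entry.sum()
    if positive <= 0:
        raise ValueError("all transition weights are zero")
    entry = entry / positive
    exit_p = 1.0 / durations
    labels = np.empty(n, dtype=int)
    current = rng.choice(len(w), p=w)  # start from the stationary law
    for i in range(n):
        labels[i] = current
        if rng.random() < exit_p[current]:
            current = rng.choice(len(w), p=entry)
    return labels


def _draw_pairs(cfg: SimConfig, labels: np.ndarray, rng: np.random.Generator):
    th_mean = np.array([a.theta_mean for a in cfg.activities])[labels]
    th_sd = np.array([a.theta_sd for a in cfg.activities])[labels]
    r_lm = np.array([a.radius_log_mean for a in cfg.activities])[labels]
    r_ls = np.array([a.radius_log_sd for a in cfg.activities])[labels]
    theta = np.clip(rng.normal(th_mean, th_sd), 1e-3, 180.0 - 1e-3)
    radius = rng.lognormal(r_lm, r_ls)
    rad = np.radians(theta)
    ccd = radius * np.sin(rad)
    ncd_par = radius * np.cos(rad)
    return theta, radius, ccd, ncd_par


def _truth_frame(cfg, labels, theta, radius, ccd, ncd_par, movie_id, cell_id, start_frames):
    names = np.array([a.name for a in cfg.activities])
    return pd.DataFrame(
        {
            "movie_id": movie_id,
            "cell_id": cell_id,
            "interval_index": start_frames,
            "activity": names[labels],
            "ccd": ccd,
            "ncd_par": ncd_par,
            "theta_deg": theta,
            "radius": radius,
        }
    )


def simulate_pairs(cfg: SimConfig, n: int):
    """Draw ``n`` CN pairs directly (no spatial layout).

    Returns ``(pairs, truth)``: a pair table with the extraction schema and
    the matching ground-truth table carrying the activity labels.
    """
    rng = np.random.default_rng(cfg.seed)
    labels = _sample_labels(cfg, n, rng)
    theta, radius, ccd, ncd_par = _draw_pairs(cfg, labels, rng)
    idx = np.arange(n)
    pairs = pd.DataFrame(
        {
            "movie_id": "sim",
            "cell_id": "pairs",
            "interval_index": idx,
            "ccd": ccd,
            "ncd_par": ncd_par,
            "theta_deg": theta,
            "radius": radius,
        }
    )
    truth = _truth_frame(cfg, labels, theta, radius, ccd, ncd_par, "sim", "pairs", idx)
    return pairs, truth


def simulate_tracks(cfg: SimConfig):
    """Lay out coupled cell/nucleus trajectories for ``n_movies`` movies.

    Returns ``(tracks, truth)`` where ``tracks`` is a canonical track table
    (one cell per movie) and ``truth`` holds the per-interval activity and
    generated (CCD, NCD_par, theta, radius).  Pair extraction on ``tracks``
    reproduces ``truth`` interval-for-interval.
    """
    rng = np.random.default_rng(cfg.seed)
    n_int = cfg.frames_per_movie - 1
    track_rows, truth_frames = [], []
    for m in range(cfg.n_movies):
        movie_id = f"m{m:03d}"
        labels = _sample_labels(cfg, n_int, rng)
        theta, radius, ccd, ncd_par = _draw_pairs(cfg, labels, rng)
        if cfg.heading_persistence > 0:
            turns = rng.vonmises(0.0, cfg.heading_persistence, size=n_int)
        else:
            turns = rng.uniform(-np.pi, np.pi, size=n_int)
        heading = rng.uniform(0, 2 * np.pi) + np.cumsum(turns)
        ux, uy = np.cos(heading), np.sin(heading)
        perp = rng.normal(0.0, cfg.nuc_perp_sd, size=n_int)
        cell = np.zeros((cfg.frames_per_movie, 2))
        nuc = np.zeros((cfg.frames_per_movie, 2))
        cell[1:, 0] = np.cumsum(ccd * ux)
        cell[1:, 1] = np.cumsum(ccd * uy)
        nuc[1:, 0] = np.cumsum(ncd_par * ux - perp * uy)
        nuc[1:, 1] = np.cumsum(ncd_par * uy + perp * ux)
        frames = np.arange(cfg.frames_per_movie)
        track_rows.append(
            pd.DataFrame(
                {
                    "movie_id": movie_id,
                    "cell_id": "c1",
                    "frame": frames,
                    "time_min": frames * cfg.dt_min,
                    "cell_x": cell[:, 0],
                    "cell_y": cell[:, 1],
                    "nuc_x": nuc[:, 0],
                    "nuc_y": nuc[:, 1],
                }
            )
        )
        truth_frames.append(
            _truth_frame(cfg, labels, theta, radius, ccd, ncd_par, movie_id, "c1", frames[:-1])
        )
    tracks = pd.concat(track_rows, ignore_index=True)
    truth = pd.concat(truth_frames, ignore_index=True)
    return tracks, truth


def simulate_prw_tracks(
    n_cells: int = 25,
    n_frames: int = 61,
    *,
    dt_min: float = 1.0,
    speed: float = 0.8,
    persistence: float = 4.0,
    seed: int = 0,
    n_substeps: int = 10,
) -> pd.DataFrame:
    """Persistent-random-walk reference tracks (Ornstein-Uhlenbeck velocity).

    Each velocity component follows an OU process with relaxation time
    ``persistence`` and stationary variance ``speed**2 / 2``, integrated on a
    substep grid and sampled every ``dt_min``; the resulting MSD follows the
    Fuerth curve with D = speed**2 * persistence / 2.  The nucleus is tied to
    the cell centroid (these tracks exist to exercise MSD/PRW fitting).
    """
    rng = np.random.default_rng(seed)
    dt_s = dt_min / n_substeps
    a = np.exp(-dt_s / persistence)
    sigma = speed / np.sqrt(2.0)
    rows = []
    for c in range(n_cells):
        v = rng.normal(0.0, sigma, size=2)
        pos = np.zeros(2)
        path = [pos.copy()]
        for _ in range((n_frames - 1) * n_substeps):
            pos = pos + v * dt_s
            v = a * v + rng.normal(0.0, sigma * np.sqrt(1 - a * a), size=2)
            path.append(pos.copy())
        path = np.asarray(path)[::n_substeps]
        frames = np.arange(n_frames)
        rows.append(
            pd.DataFrame(
                {
                    "movie_id": f"prw{c:03d}",
                    "cell_id": "c1",
                    "frame": frames,
                    "time_min": frames * dt_min,
                    "cell_x": path[:, 0],
                    "cell_y": path[:, 1],
                    "nuc_x": path[:, 0],
                    "nuc_y": path[:, 1],
                }
            )
        )
    return pd.concat(rows, ignore_index=True)
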