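"""CN-correlation pairs, profiles, and 5-degree polar-angle diagrams.

For each one-interval step of a tracked cell, the *CN correlation* couples the
cell centroid displacement magnitude (CCD, µm) with the signed scalar
projection of the nuclear centroid displacement onto the cell displacement
direction (NCD_par, µm).  Read in polar coordinates in the plane
(x = NCD_par, y = CCD), the angle

    theta = atan2(CCD, NCD_par)  in [0, 180] degrees

separates subcellular migratory activities: trailing-edge detachment steps
(nucleus advancing faster than the cell body) sit below 45 degrees, pure
protrusion with a stationary nucleus sits at 90 degrees, and contraction
steps with rearward nuclear motion sit above 90 degrees.

A *profile* pools the pairs of one cell type/condition; its *occurrence
diagram* is the histogram of angles in 5-degree bins and its *CCD diagram*
the per-bin mean CCD.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

BIN_WIDTH_DEG = 5.0
N_BINS = 36
BIN_EDGES = np.arange(0.0, 180.0 + BIN_WIDTH_DEG, BIN_WIDTH_DEG)

#: Cell steps shorter than this (µm) have no usable direction for the
#: projection; they are excluded from pair extraction and tallied.
ZERO_CCD_THRESHOLD = 1e-6

PAIR_COLUMNS = (
    "movie_id",
    "cell_id",
    "interval_index",
    "ccd",
    "ncd_par",
    "theta_deg",
    "radius",
)


def polar_transform(ccd, ncd_par):
    """Map (CCD, NCD_par) to (theta in degrees, radius in µm).

    theta = atan2(CCD, NCD_par) measured from the +NCD_par axis; since
    CCD >= 0 the angle lies in [0, 180].  Raises for the undefined origin.
    """
    ccd_arr = np.asarray(ccd, dtype=float)
    ncd_arr = np.asarray(ncd_par, dtype=float)
    if np.any(ccd_arr < 0):
        raise ValueError("ccd must be non-negative")
    if np.any((ccd_arr == 0) & (ncd_arr == 0)):
        raise ValueError("polar angle undefined at (ccd, ncd_par) = (0, 0)")
    theta = np.degrees(np.arctan2(ccd_arr, ncd_arr))
    radius = np.hypot(ccd_arr, ncd_arr)
    if np.isscalar(ccd) and np.isscalar(ncd_par):
        return float(theta), float(radius)
    return theta, radius


def compute_cn_pairs(
    tracks: pd.DataFrame,
    *,
    zero_threshold: float = ZERO_CCD_THRESHOLD,
    report=None,
) -> pd.DataFrame:
    """Extract one CN pair per consecutive-frame interval of every cell.

    CCD = ||c_{t+1} - c_t|| and NCD_par = (n_{t+1} - n_t) . (c_{t+1} - c_t)
    / CCD.  Intervals with CCD < ``zero_threshold`` are excluded; their count
    is stored in ``result.attrs['n_zero_ccd']`` and, when a
    :class:`~cnmigrate.io_trajectories.ValidationReport` is passed, appended
    to its warnings.

    Returns a DataFrame with columns :data:`PAIR_COLUMNS`;
    ``interval_index`` is the frame number at the start of the interval.
    """
    t = tracks.sort_values(["movie_id", "cell_id", "frame"], kind="mergesort")
    g = t.groupby(["movie_id", "cell_id"], sort=False)
    d = g[["cell_x", "cell_y", "nuc_x", "nuc_y"]].diff()
    start_frame = g["frame"].shift(1)
    valid = d["cell_x"].notna()

    dcx = d.loc[valid, "cell_x"].to_numpy()
    dcy = d.loc[valid, "cell_y"].to_numpy()
    dnx = d.loc[valid, "nuc_x"].to_numpy()
    dny = d.loc[valid, "nuc_y"].to_numpy()
    ccd = np.hypot(dcx, dcy)

    moving = ccd >= zero_threshold
    n_zero = int((~moving).sum())
    with np.errstate(invalid="ignore", divide="ignore"):
        ncd_par = np.where(moving, (dnx * dcx + dny * dcy) / np.where(moving, ccd, 1.0), 0.0)

    sub = t.loc[valid]
    pairs = pd.DataFrame(
        {
            "movie_id": sub["movie_id"].to_numpy()[moving],
            "cell_id": sub["cell_id"].to_numpy()[moving],
            "interval_index": start_frame.loc[valid].to_numpy()[moving].astype(np.int64),
            "ccd": ccd[moving],
            "ncd_par": ncd_par[moving],
        }
    )
    theta, radius = polar_transform(pairs["ccd"].to_numpy(), pairs["ncd_par"].to_numpy())
    pairs["theta_deg"] = theta
    pairs["radius"] = radius
    pairs.attrs["n_zero_ccd"] = n_zero
    if report is not None and n_zero:
        report.add(
            "zero_ccd",
            f"{n_zero} interval(s) with CCD < {zero_threshold:g} µm excluded from pairs",
            "",
        )
    return pairs


@dataclass
class CNProfile:
    """A pooled set of CN pairs for one cell type or condition."""

    label: str
    pairs: pd.DataFrame
    source: tuple = field(default_factory=tuple)

    def __post_init__(self):
        if not self.label:
            raise ValueError("profile label must be non-empty")

    @property
    def n(self) -> int:
        return len(self.pairs)


def build_profile(
    pairs: pd.DataFrame,
    label: str,
    *,
    n_movies: int | None = None,
    seed: int | None = None,
) -> CNProfile:
    """Pool pairs into a profile, optionally sampling movies first.

    When ``n_movies`` is given, that many distinct movies are drawn without
    replacement (seeded) and only their pairs are pooled — mirroring profile
    construction from a random selection of one-hour movies.  The selected
    movie ids are recorded in ``source``.
    """
    if len(pairs) == 0:
        raise ValueError("cannot build a profile from an empty pair set")
    movies = sorted(pairs["movie_id"].unique())
    if n_movies is None:
        return CNProfile(label=label, pairs=pairs.reset_index(drop=True), source=tuple(movies))
    if n_movies > len(movies):
        raise ValueError(f"requested {n_movies} movies but only {len(movies)} available")
    rng = np.random.default_rng(seed)
    chosen = sorted(rng.choice(np.asarray(movies, dtype=object), size=n_movies, replace=False))
    sub = pairs[pairs["movie_id"].isin(chosen)].reset_index(drop=True)
    return CNProfile(label=label, pairs=sub, source=tuple(chosen))


def bin_index(theta_deg) -> np.ndarray:
    """Map angles to 5-degree bin indices 0..35.

    Bins are right-open [0,5), ..., [175,180]; a value at a bin edge goes to
    the upper bin except 180, which belongs to the last bin.
    """
    theta = np.asarray(theta_deg, dtype=float)
    idx = np.floor(theta / BIN_WIDTH_DEG).astype(int)
    return np.clip(idx, 0, N_BINS - 1)


@dataclass
class BinnedDiagram:
    """Occurrence/CCD/NCD_par summaries of a profile over 5-degree bins.

    Empty bins have ``nan`` means (never 0).  The raw per-bin value lists are
    retained so distributional tests can run on the unbinned data.
    """

    bin_edges: np.ndarray
    counts: np.ndarray
    proportions: np.ndarray
    mean_ccd: np.ndarray
    mean_ncd_par: np.ndarray
    ccd_values: list
    ncd_par_values: list
    label: str = ""

    @property
    def n(self) -> int:
        return int(self.counts.sum())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "bin_lo": self.bin_edges[:-1],
                "bin_hi": self.bin_edges[1:],
                "count": self.counts,
                "proportion": self.proportions,
                "mean_ccd": self.mean_ccd,
                "mean_ncd_par": self.mean_ncd_par,
            }
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def make_diagrams(profile: CNProfile) -> BinnedDiagram:
    """Bin a profile's pairs into the 36 polar-angle bins."""
    if profile.n == 0:
        raise ValueError("cannot bin an empty profile")
    theta = profile.pairs["theta_deg"].to_numpy()
    ccd = profile.pairs["ccd"].to_numpy()
    ncd = profile.pairs["ncd_par"].to_numpy()
    idx = bin_index(theta)
    counts = np.bincount(idx, minlength=N_BINS)
    proportions = counts / counts.sum()
    mean_ccd = np.full(N_BINS, np.nan)
    mean_ncd = np.full(N_BINS, np.nan)
    ccd_values, ncd_values = [], []
    for i in range(N_BINS):
        sel = idx == i
        ccd_values.append(ccd[sel])
        ncd_values.append(ncd[sel])
        if counts[i]:
            mean_ccd[i] = ccd[sel].mean()
            mean_ncd[i] = ncd[sel].mean()
    return BinnedDiagram(
        bin_edges=BIN_EDGES.copy(),
        counts=counts,
        proportions=proportions,
        mean_ccd=mean_ccd,
        mean_ncd_par=mean_ncd,
        ccd_values=ccd_values,
        ncd_par_values=ncd_values,
        label=profile.label,
    )
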