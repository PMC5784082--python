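"""Motility metrics: CMPI, MSD, persistent-random-walk fit, D/T, velocity.

The cell migration potential index (CMPI) accumulates the forward nuclear
displacement (NCD_par) over the CN pairs falling in the detachment
("active migration") polar-angle zone, normalized per observed interval by
default so profiles of different sizes are comparable.

Mean-squared displacements use overlapping windows, weight each cell
equally, and feed a 2-D persistent-random-walk (Fuerth) fit

    MSD(tau) = 4 D [tau - P (1 - exp(-tau / P))],   D = S**2 P / 2

with speed S (µm/min), persistence time P (min) and diffusion coefficient D
(µm**2/min).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import optimize, stats

__all__ = [
    "MSDCurve",
    "PRWFit",
    "MotilitySummary",
    "cmpi",
    "msd",
    "prw_msd",
    "fit_prw",
    "directionality",
    "velocity",
    "cmpi_vs_diffusion",
    "summarize",
]


@dataclass
class MSDCurve:
    """Ensemble mean-squared displacement vs. time lag."""

    lags: np.ndarray  # minutes, starting at 0
    msd: np.ndarray  # µm^2
    n_obs: np.ndarray  # windows averaged per lag
    subject: str = "cell"

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"lag_min": self.lags, "msd_um2": self.msd, "n_obs": self.n_obs})

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


@dataclass
class PRWFit:
    """Persistent-random-walk parameters fitted to an MSD curve."""

    S: float  # µm/min
    P: float  # min
    D: float  # µm^2/min
    r2: float
    converged: bool = True

    def to_dict(self) -> dict:
        return {"S": self.S, "P": self.P, "D": self.D, "r2": self.r2, "converged": self.converged}


@dataclass
class MotilitySummary:
    cmpi: float
    directionality: float
    velocity: float
    prw: PRWFit
    n_cells: int

    def to_dict(self) -> dict:
        return {
            "cmpi": self.cmpi,
            "directionality": self.directionality,
            "velocity": self.velocity,
            "prw": self.prw.to_dict(),
            "n_cells": self.n_cells,
        }

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))


def cmpi(profile, zone, *, normalization: str = "per_interval") -> float:
    """Cell migration potential index.

    Sum of NCD_par over pairs whose polar angle lies in ``zone``;
    ``normalization`` is ``'per_interval'`` (divide by the total pair count
    of the profile — the default, a per-observed-minute rate),
    ``'sum'`` (raw accumulated µm), or ``'per_cell_hour'`` (per 60 observed
    intervals, i.e. µm per cell-hour of observation).
    """
    if profile.n == 0:
        raise ValueError("cannot compute CMPI of an empty profile")
    theta = profile.pairs["theta_deg"].to_numpy()
    sel = (theta >= zone.lo) & (theta <= zone.hi)
    total = float(profile.pairs["ncd_par"].to_numpy()[sel].sum())
    if normalization == "sum":
        return total
    if normalization == "per_interval":
        return total / profile.n
    if normalization == "per_cell_hour":
        return total / (profile.n / 60.0)
    raise ValueError(f"unknown normalization {normalization!r}")


def _positions_per_cell(tracks: pd.DataFrame, subject: str):
    cols = ("cell_x", "cell_y") if subject == "cell" else ("nuc_x", "nuc_y")
    out = []
    for _, g in tracks.groupby(["movie_id", "cell_id"], sort=False):
        g = g.sort_values("frame")
        out.append((g[list(cols)].to_numpy(), g["time_min"].to_numpy()))
    return out


def _infer_dt(tracks: pd.DataFrame) -> float:
    dt = tracks.groupby(["movie_id", "cell_id"], sort=False)["time_min"].diff().dropna()
    if dt.empty:
        raise ValueError("tracks contain no intervals")
    return float(dt.median())


def msd(
    tracks: pd.DataFrame,
    subject: str = "cell",
    *,
    max_lag_fraction: float = 1 / 3,
    dt_min: float | None = None,
) -> MSDCurve:
    """Overlapping-window ensemble MSD.

    Per lag tau, the per-cell mean of ||x_{t+tau} - x_t||**2 over all start
    frames, then the unweighted mean over cells (so long tracks do not
    dominate).  Lags run up to ``max_lag_fraction`` of the shortest track.
    """
    cells = _positions_per_cell(tracks, subject)
    if any(len(p) < 2 for p, _ in cells):
        raise ValueError("every cell needs at least 2 frames")
    dt = _infer_dt(tracks) if dt_min is None else dt_min
    shortest = min(len(p) for p, _ in cells)
    max_lag = max(1, int(np.floor((shortest - 1) * max_lag_fraction)))
    msd_vals = np.zeros(max_lag + 1)
    n_obs = np.zeros(max_lag + 1, dtype=int)
    n_obs[0] = len(cells)
    for tau in range(1, max_lag + 1):
        per_cell = []
        for pos, _ in cells:
            if len(pos) <= tau:
                continue
            d = pos[tau:] - pos[:-tau]
            per_cell.append(np.mean(np.sum(d * d, axis=1)))
            n_obs[tau] += len(pos) - tau
        msd_vals[tau] = float(np.mean(per_cell))
    lags = np.arange(max_lag + 1) * dt
    return MSDCurve(lags=lags, msd=msd_vals, n_obs=n_obs, subject=subject)


def prw_msd(tau, D: float, P: float):
    """Fuerth 2-D persistent-random-walk MSD model."""
    tau = np.asarray(tau, dtype=float)
    return 4.0 * D * (tau - P * (1.0 - np.exp(-tau / P)))


def fit_prw(curve: MSDCurve) -> PRWFit:
    """Least-squares PRW fit with log-parameterized D, P > 0.

    Residuals are relative (scaled by the observed MSD) because the sampling
    error of an overlapping-window MSD grows roughly in proportion to its
    value; absolute residuals would let the noisiest long lags dominate and
    leave the persistence time poorly constrained.
    """
    mask = curve.lags > 0
    lags = curve.lags[mask]
    y = curve.msd[mask]
    if lags.size < 4:
        raise ValueError("need at least 4 positive lags to fit the PRW model")
    d0 = max(y[-1] / (4.0 * lags[-1]), 1e-12)
    p0 = max(lags[-1] / 4.0, lags[0] / 2.0)
    scale = y if np.all(y > 0) else np.ones_like(y)

    def residuals(logparams):
        D, P = np.exp(logparams)
        return (prw_msd(lags, D, P) - y) / scale

    sol = optimize.least_squares(residuals, x0=np.log([d0, p0]), xtol=1e-14, ftol=1e-14)
    D, P = np.exp(sol.x)
    ss_res = float(np.sum((prw_msd(lags, D, P) - y) ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else float("nan")
    return PRWFit(
        S=float(np.sqrt(2.0 * D / P)),
        P=float(P),
        D=float(D),
        r2=r2,
        converged=bool(sol.success),
    )


def _windowed(tracks, subject, window_min, dt_min):
    """Yield (net displacement, path length) per overlapping window per cell."""
    cells = _positions_per_cell(tracks, subject)
    dt = _infer_dt(tracks) if dt_min is None else dt_min
    w = int(round(window_min / dt))
    if w < 1:
        raise ValueError("window shorter than the frame interval")
    per_cell = []
    for pos, _ in cells:
        if len(pos) < w + 1:
            continue
        steps = np.linalg.norm(np.diff(pos, axis=0), axis=1)
        cum = np.concatenate([[0.0], np.cumsum(steps)])
        vals = []
        for i in range(len(pos) - w):
            path = cum[i + w] - cum[i]
            net = float(np.linalg.norm(pos[i + w] - pos[i]))
            vals.append((net, path))
        per_cell.append(vals)
    if not per_cell:
        raise ValueError(f"no track long enough for a {window_min:g}-min window")
    return per_cell


def directionality(
    tracks: pd.DataFrame,
    window_min: float = 10.0,
    *,
    subject: str = "cell",
    dt_min: float | None = None,
) -> float:
    """Mean D/T ratio: net displacement over path length per overlapping
    10-min window (1-frame stride), averaged per cell then across cells.
    Zero-path windows are skipped."""
    per_cell = _windowed(tracks, subject, window_min, dt_min)
    cell_means = []
    for vals in per_cell:
        ratios = [net / path for net, path in vals if path > 0]
        if ratios:
            cell_means.append(np.mean(ratios))
    if not cell_means:
        raise ValueError("no window with positive path length")
    return float(np.mean(cell_means))


def velocity(
    tracks: pd.DataFrame,
    window_min: float = 60.0,
    *,
    subject: str = "cell",
    dt_min: float | None = None,
) -> float:
    """Mean speed: path length / window duration per overlapping one-hour
    window, averaged per cell then across cells (µm/min)."""
    per_cell = _windowed(tracks, subject, window_min, dt_min)
    cell_means = [np.mean([path for _, path in vals]) / window_min for vals in per_cell]
    return float(np.mean(cell_means))


def cmpi_vs_diffusion(points):
    """OLS regression of diffusion coefficient on CMPI across cell types.

    ``points`` is a sequence of (cmpi, D) tuples; returns
    (slope, intercept, r2).
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2 or pts.shape[0] < 3:
        raise ValueError("need at least 3 (cmpi, D) points")
    res = stats.linregress(pts[:, 0], pts[:, 1])
    return float(res.slope), float(res.intercept), float(res.rvalue**2)


def summarize(tracks: pd.DataFrame, profile, zone, **cmpi_kwargs) -> MotilitySummary:
    """One-stop motility summary for a cell type/condition."""
    curve = msd(tracks, subject="cell")
    fit = fit_prw(curve)
    n_cells = tracks.groupby(["movie_id", "cell_id"]).ngroups
    return MotilitySummary(
        cmpi=cmpi(profile, zone, **cmpi_kwargs),
        directionality=directionality(tracks),
        velocity=velocity(tracks),
        prw=fit,
        n_cells=n_cells,
    )
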