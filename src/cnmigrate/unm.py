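"""Univariate normal mixtures (UNM): EM fitting, AIC selection, signatures.

A migration profile's polar-angle sample is deconvolved into k Gaussian
components by expectation-maximization; the component count is chosen by the
Akaike information criterion with p = 3k - 1 free parameters (k means,
k standard deviations, k - 1 weights):

    AIC = 2 (3k - 1) - 2 loglik.

The fitted component means are the *signature angles* of the cell type; each
is labeled with the subcellular activity whose polar-angle zone contains it.
Angles are treated as linear on [0, 180]: CCD >= 0 confines the data to a
half-plane, so no wrap-around occurs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.special import logsumexp

__all__ = [
    "MixtureModel",
    "ActivityZone",
    "SignatureSet",
    "ACTIVITY_ZONES",
    "fit_em",
    "select_by_aic",
    "label_angle",
    "signature_from_profile",
    "detachment_zone",
    "decompose_ccd_zone",
    "cumulative_weight",
]

#: Absolute lower bound on component standard deviations (degrees) — prevents
#: variance collapse onto a single observation.
SD_FLOOR_DEG = 0.5
#: Absolute floor for µm-scale (CCD) mixture fits.
SD_FLOOR_UM = 0.01
#: Resolution limit: no component SD may drop below this fraction of the
#: sample SD.  Structure narrower than ~10% of the data spread is below the
#: resolution the deconvolution targets; clamping it removes most of the
#: likelihood advantage of spurious narrow components (the mixture
#: likelihood is unbounded without such a constraint).
SD_FLOOR_REL = 0.1
#: Degeneracy screen (Hathaway-style): a fitted mixture is treated as a
#: spurious likelihood spike, not a genuine local maximum, when a component
#: SD sits at the absolute floor, the within-model SD ratio
#: min(sd)/max(sd) falls below this bound, or a component claims fewer
#: than MIN_COMPONENT_COUNT observations.
MIN_SD_RATIO = 0.15
MIN_COMPONENT_COUNT = 3


@dataclass
class MixtureModel:
    """An AIC-scored univariate Gaussian mixture, components sorted by mean."""

    k: int
    means: np.ndarray
    sds: np.ndarray
    weights: np.ndarray
    loglik: float
    aic: float
    n: int
    converged: bool
    seed: int | None = None
    degenerate: bool = False
    aic_table: list = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "k": self.k,
            "means": self.means.tolist(),
            "sds": self.sds.tolist(),
            "weights": self.weights.tolist(),
            "loglik": self.loglik,
            "aic": self.aic,
            "n": self.n,
            "converged": self.converged,
            "aic_table": [list(row) for row in self.aic_table],
        }


@dataclass(frozen=True)
class ActivityZone:
    """A polar-angle interval associated with one subcellular activity."""

    name: str
    lo: float
    hi: float

    def __post_init__(self):
        if not (0 <= self.lo < self.hi <= 180):
            raise ValueError("require 0 <= lo < hi <= 180")

    @property
    def center(self) -> float:
        return 0.5 * (self.lo + self.hi)

    def contains(self, theta: float) -> bool:
        return self.lo <= theta <= self.hi


#: Non-overlapping labeling partition of [0, 180].  Boundaries follow the
#: zone structure of the activity map: the detachment zone tops out at 60
#: degrees and contraction starts at 130; angles below 30 degrees mark the
#: initial, nucleus-led phase of detachment.  Pure protrusion is centered at
#: 90 degrees, so the protrusion band must extend past 90; its upper edge
#: sits at the midpoint (105) between the canonical protrusion (~80) and
#: side-protrusion (~128) signature angles.
ACTIVITY_ZONES = (
    ActivityZone("initial detachment", 0.0, 30.0),
    ActivityZone("detachment", 30.0, 60.0),
    ActivityZone("protrusion", 60.0, 105.0),
    ActivityZone("large-angle protrusion", 105.0, 130.0),
    ActivityZone("contraction", 130.0, 180.0),
)


def label_angle(theta: float, zones=ACTIVITY_ZONES) -> str:
    """Name of the activity zone containing ``theta``; ties and out-of-range
    values resolve to the nearest zone center."""
    hits = [z for z in zones if z.lo <= theta < z.hi or (theta == 180 and z.hi == 180)]
    if len(hits) == 1:
        return hits[0].name
    return min(zones, key=lambda z: abs(theta - z.center)).name


@dataclass
class SignatureSet:
    """Ordered signature angles with weights, SDs and activity labels."""

    signature_angles: np.ndarray
    weights: np.ndarray
    sds: np.ndarray
    activity_labels: list
    model: MixtureModel

    @property
    def k(self) -> int:
        return len(self.signature_angles)

    def to_dict(self) -> dict:
        return {
            "signature_angles": self.signature_angles.tolist(),
            "weights": self.weights.tolist(),
            "sds": self.sds.tolist(),
            "activity_labels": list(self.activity_labels),
            "model": self.model.to_dict(),
        }

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "component": np.arange(1, self.k + 1),
                "mean": self.signature_angles,
                "sd": self.sds,
                "weight": self.weights,
                "label": self.activity_labels,
            }
        )


_LOG_SQRT_2PI = 0.5 * np.log(2 * np.pi)


def _loglik(values, means, sds, weights):
    lp = (
        np.log(weights)
        - _LOG_SQRT_2PI
        - np.log(sds)
        - 0.5 * ((values[:, None] - means) / sds) ** 2
    )
    return float(logsumexp(lp, axis=1).sum())


def _em_run(values, means, sds, weights, *, tol, max_iter, sd_floor):
    n = values.size
    x = values[:, None]
    ll_prev = -np.inf
    clamped_prev = False
    converged = False
    for _ in range(max_iter):
        z = (x - means) / sds
        lp = np.log(weights / sds) - _LOG_SQRT_2PI - 0.5 * z * z
        mx = lp.max(axis=1, keepdims=True)
        np.subtract(lp, mx, out=lp)
        np.exp(lp, out=lp)  # lp is now the unnormalized responsibility
        rowsum = lp.sum(axis=1, keepdims=True)
        ll = float(np.log(rowsum).sum() + mx.sum())
        # EM guarantees a non-decreasing likelihood except on iterations that
        # follow an SD-floor clamp (a constrained move).
        if not clamped_prev and ll < ll_prev - 1e-6 * (abs(ll_prev) + 1.0):
            raise RuntimeError("EM log-likelihood decreased; numerical failure")
        if abs(ll - ll_prev) < tol * (abs(ll_prev) + 1.0):
            ll_prev = ll
            converged = True
            break
        ll_prev = ll
        np.divide(lp, rowsum, out=lp)
        nk = np.clip(lp.sum(axis=0), 1e-12, None)
        weights = nk / n
        means = values @ lp / nk
        var = np.clip((values * values) @ lp / nk - means**2, 0.0, None)
        new_sds = np.sqrt(var)
        clamped_prev = bool(np.any(new_sds < sd_floor))
        sds = np.maximum(new_sds, sd_floor)
    return means, sds, weights, ll_prev, converged


def fit_em(
    values,
    k: int,
    seed: int | None = None,
    *,
    n_restarts: int = 10,
    tol: float = 1e-8,
    max_iter: int = 2000,
    explore_iter: int = 300,
    sd_floor: float = SD_FLOOR_DEG,
    sd_floor_rel: float = SD_FLOOR_REL,
    min_sd_ratio: float = MIN_SD_RATIO,
) -> MixtureModel:
    """Fit a k-component univariate Gaussian mixture by EM.

    Runs ``n_restarts`` seeded initializations (component means drawn from
    sample quantiles, the first restart at evenly spaced quantiles); each
    restart is an exploratory EM capped at ``explore_iter`` iterations, and
    the highest-likelihood candidate is then refined to the full ``tol`` /
    ``max_iter`` budget.  ``k = 1`` uses the closed-form mean and population
    SD.  Non-convergence within ``max_iter`` is flagged, the best iterate
    returned.
    """
    values = np.asarray(values, dtype=float).ravel()
    n = values.size
    if k < 1:
        raise ValueError("k must be >= 1")
    if n < 3 * k:
        raise ValueError(f"need at least 3k = {3 * k} observations, got {n}")
    sd_floor_abs = sd_floor
    sd_floor = max(sd_floor_abs, sd_floor_rel * values.std())

    if k == 1:
        mean = values.mean()
        sd = max(values.std(), sd_floor, sd_floor_rel * values.std())
        ll = _loglik(values, np.array([mean]), np.array([sd]), np.array([1.0]))
        return MixtureModel(
            k=1,
            means=np.array([mean]),
            sds=np.array([sd]),
            weights=np.array([1.0]),
            loglik=ll,
            aic=2 * (3 * 1 - 1) - 2 * ll,
            n=n,
            converged=True,
            seed=seed,
        )

    rng = np.random.default_rng(seed)
    spread = max(values.std(), sd_floor)
    best = None
    for r in range(n_restarts):
        if r == 0:
            qs = (np.arange(k) + 0.5) / k
        else:
            qs = np.sort(rng.uniform(0, 1, size=k))
        means0 = np.quantile(values, qs)
        means0 = means0 + rng.normal(0, 1e-3 * spread, size=k) if r else means0
        sds0 = np.full(k, max(spread / k, sd_floor))
        w0 = np.full(k, 1.0 / k)
        out = _em_run(
            values, means0, sds0, w0,
            tol=max(tol, 1e-6), max_iter=explore_iter, sd_floor=sd_floor,
        )
        if best is None or out[3] > best[3]:
            best = out
    means, sds, weights, ll, converged = _em_run(
        values, best[0], best[1], best[2], tol=tol, max_iter=max_iter, sd_floor=sd_floor
    )
    order = np.argsort(means)
    model = MixtureModel(
        k=k,
        means=means[order],
        sds=sds[order],
        weights=weights[order] / weights.sum(),
        loglik=ll,
        aic=2 * (3 * k - 1) - 2 * ll,
        n=n,
        converged=converged,
        seed=seed,
        degenerate=bool(
            np.any(sds <= sd_floor_abs * 1.05)
            or sds.min() / sds.max() < min_sd_ratio
            or n * weights.min() < MIN_COMPONENT_COUNT
        ),
    )
    if not converged:
        warnings.warn(f"EM did not converge for k={k} within {max_iter} iterations")
    return model


def select_by_aic(
    values,
    k_range=range(1, 9),
    seed: int | None = None,
    **em_controls,
) -> MixtureModel:
    """Fit each candidate k and return the AIC-minimizing mixture.

    Candidates containing a component whose SD sits at the floor are
    degenerate likelihood spikes, not genuine modes; they are excluded from
    the selection whenever at least one clean candidate exists.  The full
    AIC table is retained on the returned model as
    ``aic_table = [(k, aic, converged, degenerate), ...]``.  Ties break to
    the smaller k.
    """
    values = np.asarray(values, dtype=float).ravel()
    ks = sorted(k_range)
    if not ks:
        raise ValueError("k_range is empty")
    if values.size < 3 * max(ks):
        raise ValueError(
            f"need at least {3 * max(ks)} observations for k up to {max(ks)}, got {values.size}"
        )
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(len(ks))
    models = []
    table = []
    for k, child in zip(ks, children):
        model = fit_em(values, k, seed=int(child.generate_state(1)[0] % (2**31)), **em_controls)
        table.append((k, model.aic, model.converged, model.degenerate))
        models.append(model)
    clean = [m for m in models if not m.degenerate]
    pool = clean if clean else models
    best = min(pool, key=lambda m: (m.aic, m.k))
    best.aic_table = table
    return best


def signature_from_profile(
    profile,
    seed: int | None = None,
    *,
    k_range=range(1, 9),
    zones=ACTIVITY_ZONES,
    **em_controls,
) -> SignatureSet:
    """AIC-selected mixture over a profile's raw polar angles -> signatures.

    Fits on the raw angle sample (the occurrence diagram is its
    visualization), sorts components by mean, and labels each with the
    activity zone containing it.
    """
    theta = profile.pairs["theta_deg"].to_numpy()
    if theta.size < 100:
        warnings.warn(
            f"profile has only {theta.size} pairs; signature angles may be unstable"
        )
    model = select_by_aic(theta, k_range=k_range, seed=seed, **em_controls)
    labels = [label_angle(m, zones) for m in model.means]
    return SignatureSet(
        signature_angles=model.means.copy(),
        weights=model.weights.copy(),
        sds=model.sds.copy(),
        activity_labels=labels,
        model=model,
    )


def detachment_zone(s: SignatureSet) -> ActivityZone:
    """Active-migration zone: angles below the detachment signature + 2 SD.

    Uses the detachment-labeled component (the largest-weight one if several)
    and returns [0, mean + 2 sd].
    """
    idx = [i for i, lab in enumerate(s.activity_labels) if lab == "detachment"]
    if not idx:
        raise ValueError(
            "no component labeled 'detachment'; supply a manual ActivityZone instead"
        )
    i = max(idx, key=lambda j: s.weights[j])
    hi = float(s.signature_angles[i] + 2.0 * s.sds[i])
    return ActivityZone("detachment zone", 0.0, min(hi, 180.0))


def decompose_ccd_zone(
    profile,
    zone: ActivityZone,
    seed: int | None = None,
    *,
    k_range=range(1, 9),
    sd_floor: float = SD_FLOOR_UM,
    **em_controls,
) -> MixtureModel:
    """AIC-selected mixture of the CCD values whose angle falls in ``zone``.

    The component count and modes summarize step-size regimes within the
    zone (e.g. immobile vs. abrupt detachment); interpretation is left to
    the caller.
    """
    theta = profile.pairs["theta_deg"].to_numpy()
    sel = (theta >= zone.lo) & (theta <= zone.hi)
    ccd = profile.pairs["ccd"].to_numpy()[sel]
    if ccd.size < 30:
        raise ValueError(
            f"only {ccd.size} pairs inside zone [{zone.lo}, {zone.hi}]; need >= 30"
        )
    ks = [k for k in k_range if ccd.size >= 3 * k]
    return select_by_aic(ccd, k_range=ks, seed=seed, sd_floor=sd_floor, **em_controls)


def cumulative_weight(s: SignatureSet, m: int) -> float:
    """Total weight of the first ``m`` components in ascending-angle order."""
    if not 1 <= m <= s.k:
        raise ValueError(f"m must be in [1, {s.k}], got {m}")
    return float(np.sum(s.weights[:m]))
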