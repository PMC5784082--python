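"""Per-bin nonparametric comparison of two CN-correlation profiles.

Occurrence diagrams are compared bin-by-bin with an exact sign
(binomial-split) test; CCD diagrams with the Lepage location-scale test,
which combines the standardized Wilcoxon rank-sum and Ansari-Bradley
statistics as L = z_W**2 + z_A**2 with a chi-square(2) null.

Ties are handled with mid-ranks throughout.  Null means and variances of the
rank statistics come from the finite-population sampling formulas on the
observed (possibly tied) score vector — for a score vector ``a`` over the
pooled sample of size N, the sum of the scores of a random size-n1 subset has

    E0 = n1 * mean(a),   Var0 = n1 * n2 * popvar(a) / (N - 1)

which reduces to the classical tie-corrected closed forms when ties are
absent and stays exact under arbitrary ties.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
from scipy import stats

__all__ = [
    "sign_test_bin",
    "wilcoxon_component",
    "ansari_component",
    "lepage_test",
    "compare_profiles",
    "ComparisonResult",
]


def sign_test_bin(k1: int, n1: int, k2: int, n2: int) -> float:
    """Exact two-sided sign test for one occurrence-diagram bin.

    The k1 + k2 events pooled in the bin each carry a sign by source profile;
    under H0 the split is Binomial(k1 + k2, n1 / (n1 + n2)).  Two-sided p by
    tail doubling, capped at 1.  Returns ``nan`` when the bin is empty in
    both profiles (no information).
    """
    if not (0 <= k1 <= n1 and 0 <= k2 <= n2):
        raise ValueError("require 0 <= k <= n for both groups")
    m = k1 + k2
    if m == 0:
        return float("nan")
    p0 = n1 / (n1 + n2)
    lower = stats.binom.cdf(k1, m, p0)
    upper = stats.binom.sf(k1 - 1, m, p0)
    return float(min(1.0, 2.0 * min(lower, upper)))


def _subset_moments(scores: np.ndarray, n1: int):
    """Mean/variance of the score-sum of a random n1-subset (without replacement)."""
    N = scores.size
    mean = scores.mean()
    popvar = scores.var()
    e0 = n1 * mean
    var0 = n1 * (N - n1) * popvar / (N - 1) if N > 1 else 0.0
    return float(e0), float(var0)


class RankComponent(NamedTuple):
    stat: float
    e0: float
    var0: float
    z: float


def _component(scores: np.ndarray, n1: int) -> RankComponent:
    stat = float(scores[:n1].sum())
    e0, var0 = _subset_moments(scores, n1)
    z = 0.0 if var0 <= 0 else (stat - e0) / np.sqrt(var0)
    return RankComponent(stat, e0, var0, float(z))


def _wilcoxon_scores(pooled: np.ndarray) -> np.ndarray:
    return stats.rankdata(pooled)


def _ansari_scores(pooled: np.ndarray) -> np.ndarray:
    r = stats.rankdata(pooled)
    return np.minimum(r, pooled.size + 1 - r)


def wilcoxon_component(x, y) -> RankComponent:
    """Wilcoxon rank-sum of ``x`` in the pooled mid-ranked sample.

    Returns ``(W, E0, Var0, z)``; ``z = 0`` with ``Var0 = 0`` when all pooled
    values are identical (degenerate, flagged by the caller).
    """
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if x.size < 1 or y.size < 1:
        raise ValueError("both samples must be non-empty")
    return _component(_wilcoxon_scores(np.concatenate([x, y])), x.size)


def ansari_component(x, y) -> RankComponent:
    """Ansari-Bradley scale statistic min(rank, N+1-rank) for ``x``."""
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if x.size < 1 or y.size < 1:
        raise ValueError("both samples must be non-empty")
    return _component(_ansari_scores(np.concatenate([x, y])), x.size)


class LepageResult(NamedTuple):
    L: float
    p: float
    method: str
    z_w: float
    z_a: float


def _permutation_pvalue(w_scores, a_scores, n1, L_obs, n_perm, rng):
    """Monte-Carlo permutation p for L via vectorized label shuffles."""
    N = w_scores.size
    _, var_w = _subset_moments(w_scores, n1)
    _, var_a = _subset_moments(a_scores, n1)
    e_w = n1 * w_scores.mean()
    e_a = n1 * a_scores.mean()
    count = 0
    chunk = max(1, min(n_perm, int(2e7 // max(N, 1))))
    done = 0
    while done < n_perm:
        b = min(chunk, n_perm - done)
        order = np.argsort(rng.random((b, N)), axis=1)[:, :n1]
        ws = w_scores[order].sum(axis=1)
        as_ = a_scores[order].sum(axis=1)
        zw = (ws - e_w) / np.sqrt(var_w) if var_w > 0 else np.zeros(b)
        za = (as_ - e_a) / np.sqrt(var_a) if var_a > 0 else np.zeros(b)
        count += int(np.sum(zw**2 + za**2 >= L_obs - 1e-12))
        done += b
    return (1 + count) / (n_perm + 1)


def lepage_test(
    x,
    y,
    *,
    method: str = "auto",
    n_perm: int = 10_000,
    seed: int | None = None,
) -> LepageResult:
    """Lepage location-scale test: L = z_W**2 + z_A**2.

    ``method='asymptotic'`` uses the chi-square(2) null; ``'permutation'``
    estimates p from ``n_perm`` seeded label shuffles; ``'auto'`` picks
    permutation when min(|x|, |y|) < 10.  When both component variances are
    degenerate (all pooled values tied) the result is flagged with p = 1.
    """
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if x.size < 2 or y.size < 2:
        raise ValueError("lepage_test requires at least 2 observations per sample")
    wil = wilcoxon_component(x, y)
    ans = ansari_component(x, y)
    if wil.var0 <= 0 and ans.var0 <= 0:
        return LepageResult(0.0, 1.0, "degenerate", 0.0, 0.0)
    L = wil.z**2 + ans.z**2
    if method == "auto":
        method = "permutation" if min(x.size, y.size) < 10 else "asymptotic"
    if method == "asymptotic":
        p = float(stats.chi2.sf(L, df=2))
    elif method == "permutation":
        rng = np.random.default_rng(seed)
        pooled = np.concatenate([x, y])
        p = _permutation_pvalue(
            _wilcoxon_scores(pooled), _ansari_scores(pooled), x.size, L, n_perm, rng
        )
    else:
        raise ValueError(f"unknown method {method!r}")
    return LepageResult(float(L), float(p), method, wil.z, ans.z)


@dataclass
class ComparisonResult:
    """Per-bin test results for a pair of binned diagrams."""

    bin_edges: np.ndarray
    sign_p: np.ndarray
    lepage_stat: np.ndarray
    lepage_p: np.ndarray
    method_flags: list
    alpha: float = 0.05

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "bin_lo": self.bin_edges[:-1],
                "bin_hi": self.bin_edges[1:],
                "sign_p": self.sign_p,
                "lepage_stat": self.lepage_stat,
                "lepage_p": self.lepage_p,
                "method_flag": self.method_flags,
            }
        )

    def to_csv(self, path):
        self.to_frame().to_csv(path, index=False)

    def n_significant(self, which: str = "sign") -> int:
        p = self.sign_p if which == "sign" else self.lepage_p
        return int(np.nansum(p < self.alpha))


def compare_profiles(
    d1,
    d2,
    alpha: float = 0.05,
    *,
    method: str = "auto",
    n_perm: int = 10_000,
    seed: int = 0,
    adjust: str | None = None,
) -> ComparisonResult:
    """Compare two binned diagrams bin-by-bin.

    Sign test on the occurrence counts, Lepage test on the raw per-bin CCD
    values.  Bins with < 2 CCD values in either group are flagged
    ``insufficient`` (p = nan), never silently dropped.  No multiple-testing
    correction by default; ``adjust='bh'`` applies Benjamini-Hochberg to the
    defined p-values of each family.
    """
    if not np.array_equal(d1.bin_edges, d2.bin_edges):
        raise ValueError("diagrams have mismatched bin edges")
    n_bins = len(d1.counts)
    n1, n2 = d1.n, d2.n
    sign_p = np.full(n_bins, np.nan)
    lep_stat = np.full(n_bins, np.nan)
    lep_p = np.full(n_bins, np.nan)
    flags = []
    for i in range(n_bins):
        k1, k2 = int(d1.counts[i]), int(d2.counts[i])
        flag = []
        if k1 + k2 == 0:
            flag.append("empty")
        else:
            sign_p[i] = sign_test_bin(k1, n1, k2, n2)
        x, y = d1.ccd_values[i], d2.ccd_values[i]
        if min(len(x), len(y)) < 2:
            flag.append("insufficient")
        else:
            res = lepage_test(x, y, method=method, n_perm=n_perm, seed=seed + i)
            lep_stat[i], lep_p[i] = res.L, res.p
            flag.append(res.method)
        flags.append("+".join(flag))
    if adjust == "bh":
        for arr in (sign_p, lep_p):
            ok = np.isfinite(arr)
            if ok.any():
                arr[ok] = stats.false_discovery_control(arr[ok], method="bh")
    elif adjust is not None:
        raise ValueError(f"unknown adjustment {adjust!r}")
    return ComparisonResult(
        bin_edges=np.asarray(d1.bin_edges, dtype=float),
        sign_p=sign_p,
        lepage_stat=lep_stat,
        lepage_p=lep_p,
        method_flags=flags,
        alpha=alpha,
    )
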