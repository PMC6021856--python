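"""Sensor profiles: per-time-of-day activation estimates and period comparison.

A *sensor profile* summarises one sensor's typical day: for each time bin
(default 30 min, 48 bins/day) it estimates either the expected fraction of
time the sensor is active (state sensors) or the probability of seeing at
least one activation (impulsive sensors).  The sampling unit is the day:
point estimates are means over days, confidence intervals come from a
percentile bootstrap over days (which respects the [0, 1] range even when
estimates sit near the boundaries).

Two periods are compared bin-by-bin with a two-sample test on the
day-level statistics — a permutation test of the difference in means by
default, with Welch-t / two-proportion parametric alternatives — and the
per-bin p-values are Holm-Bonferroni adjusted across the day's bins, so
the family-wise error rate of one sensor comparison is controlled.
"""

from __future__ import annotations

from dataclasses import dataclass
from datetime import timedelta

import numpy as np
import pandas as pd
from scipy import stats

from .events import SignatureMatrix, SensorSpec

__all__ = [
    "SensorProfile",
    "ProfileComparison",
    "daily_bin_stats",
    "compute_profile",
    "compare_periods",
    "adjust_holm_bonferroni",
]


@dataclass(frozen=True)
class SensorProfile:
    sensor_id: str
    bin_width: timedelta
    estimate: np.ndarray  # per-bin mean in [0, 1]
    ci_low: np.ndarray
    ci_high: np.ndarray
    n_days: int
    level: float = 0.95

    def __post_init__(self) -> None:
        eps = 1e-12
        if not (
            (self.ci_low <= self.estimate + eps).all()
            and (self.estimate <= self.ci_high + eps).all()
            and (self.ci_low >= -eps).all()
            and (self.ci_high <= 1 + eps).all()
        ):
            raise ValueError("profile CI must satisfy 0 <= low <= estimate <= high <= 1")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"estimate": self.estimate, "ci_low": self.ci_low, "ci_high": self.ci_high},
            index=pd.RangeIndex(len(self.estimate), name="bin"),
        )


@dataclass(frozen=True)
class ProfileComparison:
    sensor_id: str
    bin_width: timedelta
    p_raw: np.ndarray
    p_adj: np.ndarray
    significant: np.ndarray  # bool, p_adj <= alpha
    direction: np.ndarray  # sign of (period2 - period1) per bin
    periods: tuple[int, int]
    alpha: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "p_raw": self.p_raw,
                "p_adj": self.p_adj,
                "significant": self.significant,
                "direction": self.direction,
            },
            index=pd.RangeIndex(len(self.p_raw), name="bin"),
        )


def _n_bins(bin_width: timedelta) -> int:
    day = timedelta(hours=24)
    n, rem = divmod(day, bin_width)
    if rem != timedelta(0):
        raise ValueError("bin_width must divide 24 h")
    return int(n)


def daily_bin_stats(
    sig: SignatureMatrix,
    spec: SensorSpec,
    bin_width: timedelta = timedelta(minutes=30),
) -> pd.DataFrame:
    """Day x bin matrix of day-level statistics for one sensor.

    State sensors: fraction of active fine bins within each coarse bin.
    Impulsive sensors: indicator of >= 1 activation within the bin.
    Only full days (complete bin coverage) are kept.
    """
    n_bins = _n_bins(bin_width)
    per_coarse = int(bin_width / sig.bin_width)
    if per_coarse * sig.bin_width != bin_width:
        raise ValueError("bin_width must be a multiple of the signature resolution")
    col = sig.data[spec.sensor_id]
    dates = col.index.date
    minutes = (col.index - col.index.normalize()) / sig.bin_width
    coarse = (minutes / per_coarse).astype(int)
    df = pd.DataFrame({"v": col.to_numpy(), "date": dates, "bin": coarse})
    fine_per_day = int(timedelta(hours=24) / sig.bin_width)
    full = df.groupby("date")["v"].count() == fine_per_day
    df = df[df["date"].map(full)]
    if spec.kind == "impulsive":
        stat = df.groupby(["date", "bin"])["v"].apply(lambda s: float((s >= 1).any()))
    else:
        stat = df.groupby(["date", "bin"])["v"].apply(lambda s: float((s > 0).mean()))
    mat = stat.unstack("bin")
    mat = mat.reindex(columns=range(n_bins), fill_value=0.0)
    return mat


def compute_profile(
    day_stats: pd.DataFrame | np.ndarray,
    sensor_id: str = "",
    bin_width: timedelta = timedelta(minutes=30),
    level: float = 0.95,
    n_boot: int = 1000,
    seed: int = 0,
) -> SensorProfile:
    """Estimate a sensor profile with percentile-bootstrap CIs.

    ``day_stats`` is the day x bin matrix from :func:`daily_bin_stats`
    (rows are days — the resampling unit).  Requires >= 5 days.
    """
    x = np.asarray(day_stats, dtype=float)
    if x.ndim != 2 or x.shape[0] < 5:
        raise ValueError("need a day x bin matrix with at least 5 days")
    n_days = x.shape[0]
    rng = np.random.default_rng(seed)
    est = x.mean(axis=0)
    idx = rng.integers(0, n_days, size=(n_boot, n_days))
    boots = x[idx].mean(axis=1)  # (n_boot, n_bins)
    a = (1.0 - level) / 2.0
    lo = np.quantile(boots, a, axis=0)
    hi = np.quantile(boots, 1.0 - a, axis=0)
    # guard against quantile-interpolation wobble around the point estimate
    lo = np.minimum(lo, est)
    hi = np.maximum(hi, est)
    return SensorProfile(
        sensor_id=sensor_id,
        bin_width=bin_width,
        estimate=est,
        ci_low=np.clip(lo, 0.0, 1.0),
        ci_high=np.clip(hi, 0.0, 1.0),
        n_days=n_days,
        level=level,
    )


def adjust_holm_bonferroni(
    p: np.ndarray, alpha: float = 0.05
) -> tuple[np.ndarray, np.ndarray]:
    """Holm-Bonferroni step-down adjustment.

    Sort p ascending, multiply the i-th smallest by ``m - i`` (0-based),
    enforce a running maximum so adjusted values are monotone in the
    step-down order, cap at 1; reject where the adjusted value is <= alpha.
    Controls the family-wise error rate at ``alpha`` for any dependence.
    """
    p = np.asarray(p, dtype=float)
    if p.ndim != 1:
        raise ValueError("p must be a 1-D vector")
    if ((p < 0) | (p > 1)).any() or np.isnan(p).any():
        raise ValueError("p-values must lie in [0, 1]")
    m = len(p)
    order = np.argsort(p, kind="stable")
    adj_sorted = p[order] * (m - np.arange(m))
    adj_sorted = np.minimum(np.maximum.accumulate(adj_sorted), 1.0)
    p_adj = np.empty(m)
    p_adj[order] = adj_sorted
    return p_adj, p_adj <= alpha


def _permutation_pvalues(
    x1: np.ndarray, x2: np.ndarray, n_perm: int, rng: np.random.Generator
) -> np.ndarray:
    """Two-sided permutation p-values of the mean difference, per column."""
    n1, n2 = x1.shape[0], x2.shape[0]
    n = n1 + n2
    pooled = np.vstack([x1, x2])  # (n, bins)
    obs = x2.mean(axis=0) - x1.mean(axis=0)
    count = np.zeros(pooled.shape[1])
    base = np.concatenate([np.full(n1, -1.0 / n1), np.full(n2, 1.0 / n2)])
    # days are the exchangeable unit: one shared day permutation is applied
    # across all bins per replicate; evaluated as a signed-weight matmul
    chunk = 1000
    done = 0
    while done < n_perm:
        b = min(chunk, n_perm - done)
        weights = rng.permuted(np.tile(base, (b, 1)), axis=1)
        diffs = weights @ pooled  # (b, bins)
        count += (np.abs(diffs) >= np.abs(obs) - 1e-12).sum(axis=0)
        done += b
    return (1.0 + count) / (n_perm + 1.0)


def _parametric_pvalues(x1: np.ndarray, x2: np.ndarray, impulsive: bool) -> np.ndarray:
    n_bins = x1.shape[1]
    p = np.ones(n_bins)
    for b in range(n_bins):
        a, c = x1[:, b], x2[:, b]
        if np.all(a == a[0]) and np.all(c == c[0]) and a[0] == c[0]:
            p[b] = 1.0
            continue
        if impulsive:
            # two-proportion z-test on the per-day activation indicators
            k1, k2 = a.sum(), c.sum()
            n1, n2 = len(a), len(c)
            pool = (k1 + k2) / (n1 + n2)
            se = np.sqrt(pool * (1 - pool) * (1 / n1 + 1 / n2))
            if se == 0:
                p[b] = 1.0
            else:
                z = (k2 / n2 - k1 / n1) / se
                p[b] = 2 * stats.norm.sf(abs(z))
        else:
            res = stats.ttest_ind(a, c, equal_var=False)
            p[b] = 1.0 if np.isnan(res.pvalue) else float(res.pvalue)
    return p


def compare_periods(
    period1: pd.DataFrame | np.ndarray,
    period2: pd.DataFrame | np.ndarray,
    sensor_id: str = "",
    bin_width: timedelta = timedelta(minutes=30),
    alpha: float = 0.05,
    method: str = "permutation",
    n_perm: int = 5000,
    seed: int = 0,
    impulsive: bool = False,
) -> ProfileComparison:
    """Bin-by-bin two-sample comparison of two periods of day-level stats.

    Each period is a day x bin matrix (:func:`daily_bin_stats` output).
    The multiplicity family is the set of bins of this one comparison.
    """
    x1 = np.asarray(period1, dtype=float)
    x2 = np.asarray(period2, dtype=float)
    if x1.ndim != 2 or x2.ndim != 2 or x1.shape[1] != x2.shape[1]:
        raise ValueError("periods must be day x bin matrices with equal bin counts")
    if x1.shape[0] < 5 or x2.shape[0] < 5:
        raise ValueError("each period needs at least 5 days")
    if method == "permutation":
        rng = np.random.default_rng(seed)
        p_raw = _permutation_pvalues(x1, x2, n_perm, rng)
    elif method == "parametric":
        p_raw = _parametric_pvalues(x1, x2, impulsive)
    else:
        raise ValueError(f"unknown method {method!r}")
    p_adj, reject = adjust_holm_bonferroni(p_raw, alpha)
    direction = np.sign(x2.mean(axis=0) - x1.mean(axis=0))
    return ProfileComparison(
        sensor_id=sensor_id,
        bin_width=bin_width,
        p_raw=p_raw,
        p_adj=p_adj,
        significant=reject,
        direction=direction,
        periods=(x1.shape[0], x2.shape[0]),
        alpha=alpha,
    )
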