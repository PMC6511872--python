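"""Group aggregation and per-zone significance testing.

The unit of analysis is the nucleus: per-zone values from all nuclei of a
treatment group are summarized as mean ± SEM, and two groups are compared
zone by zone with the unpaired pooled-variance (Student) two-sample t-test
— the "consistent standard deviation" assumption — at alpha = 0.05,
without multiple-testing correction across zones (an optional Holm switch
exists but is off by default, matching the convention of reporting
per-zone significance plus the run length of consecutively significant
peripheral zones).  Star labels follow the usual bins: * for p <= 0.05,
** for p <= 0.01, *** for p <= 0.001, **** for p <= 0.0001.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .zonation import RadialProfile


@dataclass
class GroupProfile:
    label: str
    n: int
    zone_mean: np.ndarray
    zone_sem: np.ndarray


@dataclass
class ZoneComparison:
    t: np.ndarray
    p: np.ndarray
    significant: np.ndarray
    stars: list[str]
    significant_peripheral_run: int
    group1: GroupProfile | None = None
    group2: GroupProfile | None = None
    alpha: float = 0.05

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({
            "zone": np.arange(1, len(self.t) + 1),
            "t": self.t,
            "p": self.p,
            "significant": self.significant,
            "stars": self.stars,
        })
        if self.group1 is not None and self.group2 is not None:
            df["mean_1"] = self.group1.zone_mean
            df["sem_1"] = self.group1.zone_sem
            df["mean_2"] = self.group2.zone_mean
            df["sem_2"] = self.group2.zone_sem
        return df


@dataclass
class ScalarComparison:
    t: float
    p: float
    stars: str
    mean1: float
    mean2: float
    sem1: float
    sem2: float
    n1: int
    n2: int


@dataclass
class TimeSeriesResult:
    time_points: np.ndarray          # minutes, strictly increasing
    group_means: dict[str, np.ndarray]
    group_sems: dict[str, np.ndarray]
    final_comparison: ScalarComparison
    zone: int = 1


def _profile_matrix(profiles: Sequence[RadialProfile]) -> np.ndarray:
    if len(profiles) < 2:
        raise ValueError("need at least 2 profiles per group")
    n_zones = {p.n_zones for p in profiles}
    if len(n_zones) != 1:
        raise ValueError(f"mixed n_zones in group: {sorted(n_zones)}")
    return np.vstack([p.zone_means for p in profiles])


def summarize_group(profiles: Sequence[RadialProfile],
                    label: str = "") -> GroupProfile:
    """Per-zone mean and SEM (sd/sqrt(n)) across the nuclei of one group."""
    mat = _profile_matrix(profiles)
    n = np.sum(~np.isnan(mat), axis=0)
    mean = np.nanmean(mat, axis=0)
    sem = np.full(mat.shape[1], np.nan)
    ok = n >= 2
    if ok.any():
        sem[ok] = np.nanstd(mat[:, ok], axis=0, ddof=1) / np.sqrt(n[ok])
    return GroupProfile(label=label, n=mat.shape[0], zone_mean=mean,
                        zone_sem=sem)


def pooled_t_test(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Unpaired two-sample Student t-test with pooled variance.

    Returns (t, two-sided p) with df = n1 + n2 - 2.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise ValueError("each sample needs n >= 2")
    res = stats.ttest_ind(x, y, equal_var=True)
    return float(res.statistic), float(res.pvalue)


def significance_stars(p: float, alpha: float = 0.05) -> str:
    """Map a p-value to the conventional star label (``ns`` above alpha)."""
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"p-value {p} outside [0, 1]")
    if p > alpha:
        return "ns"
    if p > 0.01:
        return "*"
    if p > 0.001:
        return "**"
    if p > 0.0001:
        return "***"
    return "****"


def _holm(p: np.ndarray, alpha: float) -> np.ndarray:
    """Holm step-down rejection decisions for a vector of p-values."""
    finite = np.isfinite(p)
    m = int(finite.sum())
    reject = np.zeros(len(p), dtype=bool)
    order = np.argsort(np.where(finite, p, np.inf))
    for rank, idx in enumerate(order[:m]):
        if p[idx] <= alpha / (m - rank):
            reject[idx] = True
        else:
            break
    return reject


def compare_zones(g1: Sequence[RadialProfile], g2: Sequence[RadialProfile],
                  alpha: float = 0.05, holm: bool = False,
                  labels: tuple[str, str] = ("group1", "group2")
                  ) -> ZoneComparison:
    """Per-zone pooled t-test between two groups of radial profiles.

    Zones where either group has fewer than two non-missing values get
    NaN statistics and are never significant.  The peripheral run counts
    consecutive significant zones starting at zone 1.
    """
    m1 = _profile_matrix(g1)
    m2 = _profile_matrix(g2)
    if m1.shape[1] != m2.shape[1]:
        raise ValueError("groups have different n_zones")
    n_zones = m1.shape[1]
    t = np.full(n_zones, np.nan)
    p = np.full(n_zones, np.nan)
    for k in range(n_zones):
        a = m1[:, k][~np.isnan(m1[:, k])]
        b = m2[:, k][~np.isnan(m2[:, k])]
        if len(a) < 2 or len(b) < 2:
            continue
        pooled_sd = np.sqrt((((len(a) - 1) * a.var(ddof=1)
                              + (len(b) - 1) * b.var(ddof=1))
                             / (len(a) + len(b) - 2)))
        if pooled_sd == 0:
            if a.mean() == b.mean():
                t[k], p[k] = 0.0, 1.0
                continue
            raise ValueError(f"zone {k + 1}: zero pooled variance with unequal means")
        t[k], p[k] = pooled_t_test(a, b)
    if holm:
        significant = _holm(p, alpha)
    else:
        significant = np.where(np.isfinite(p), p <= alpha, False)
    stars = [significance_stars(v, alpha) if np.isfinite(v) else "na" for v in p]
    run = 0
    for k in range(n_zones):
        if significant[k]:
            run += 1
        else:
            break
    return ZoneComparison(t=t, p=p, significant=significant, stars=stars,
                          significant_peripheral_run=run,
                          group1=summarize_group(g1, labels[0]),
                          group2=summarize_group(g2, labels[1]),
                          alpha=alpha)


def compare_scalar(x: Sequence[float], y: Sequence[float],
                   alpha: float = 0.05) -> ScalarComparison:
    """Pooled t-test on per-nucleus scalars (e.g. the P/I relative ratio)."""
    x = np.asarray(list(x), dtype=float)
    y = np.asarray(list(y), dtype=float)
    if x.std(ddof=1) == 0 and y.std(ddof=1) == 0 and x.mean() == y.mean():
        t, p = 0.0, 1.0
    else:
        t, p = pooled_t_test(x, y)
    return ScalarComparison(
        t=t, p=p, stars=significance_stars(p, alpha),
        mean1=float(x.mean()), mean2=float(y.mean()),
        sem1=float(x.std(ddof=1) / np.sqrt(len(x))),
        sem2=float(y.std(ddof=1) / np.sqrt(len(y))),
        n1=len(x), n2=len(y))


#: alias matching the P/I terminology
compare_relative_ratio = compare_scalar


def timelapse_zone_trajectory(
        groups_by_time: Mapping[float, Mapping[str, Sequence[RadialProfile]]],
        zone: int = 1, alpha: float = 0.05) -> TimeSeriesResult:
    """Zone trajectory over a time-lapse, e.g. zone 1 every 15 min.

    *groups_by_time* maps time (minutes) to {group label: profiles}.  All
    time points must carry the same groups; the final time point gets a
    two-group comparison of the zone values.
    """
    times = np.array(sorted(groups_by_time), dtype=float)
    if len(times) < 2:
        raise ValueError("need at least 2 time points")
    keys = list(groups_by_time)
    if any(a > b for a, b in zip(keys, keys[1:])):
        raise ValueError("time points must be given in increasing order")
    group_names = sorted(groups_by_time[times[0]])
    if len(group_names) != 2:
        raise ValueError("time-lapse comparison requires exactly 2 groups")
    means: dict[str, list[float]] = {g: [] for g in group_names}
    sems: dict[str, list[float]] = {g: [] for g in group_names}
    for tpt in times:
        groups = groups_by_time[tpt]
        if sorted(groups) != group_names:
            raise ValueError(f"missing group at time {tpt}")
        for g in group_names:
            vals = np.array([p.zone_means[zone - 1] for p in groups[g]])
            means[g].append(float(np.nanmean(vals)))
            sems[g].append(float(np.nanstd(vals, ddof=1) / np.sqrt(len(vals))))
    final = groups_by_time[times[-1]]
    x = [p.zone_means[zone - 1] for p in final[group_names[0]]]
    y = [p.zone_means[zone - 1] for p in final[group_names[1]]]
    comparison = compare_scalar(x, y, alpha)
    return TimeSeriesResult(
        time_points=times,
        group_means={g: np.array(v) for g, v in means.items()},
        group_sems={g: np.array(v) for g, v in sems.items()},
        final_comparison=comparison, zone=zone)
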