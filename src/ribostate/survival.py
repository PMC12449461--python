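"""Kaplan–Meier estimation, log-rank testing and cutoff stratification.

The two-group stratification scheme splits subjects by a score threshold
chosen to minimize the log-rank p-value over the score's 10th–90th
percentile window (an "optimal cutoff"; note that minimum-p selection
inflates type-I error, a property the test suite measures rather than
hides).  The three-group scheme first splits by a marker's mean (e.g.
CD8A or CD68 expression), then applies the optimal score cutoff within
the marker-high subgroup only.

The log-rank statistic is the k-group Mantel–Haenszel sum of observed
minus expected events over event times with hypergeometric covariance;
Kaplan–Meier curves come from lifelines' product-limit estimator.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from scipy.stats import chi2 as chi2_dist

_log = logging.getLogger("ribostate.survival")


@dataclass
class SurvivalTable:
    """Per-subject follow-up: time, event indicator, score, optional marker."""

    df: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.df
        for col in ("subject_id", "time", "event"):
            if col not in df.columns:
                raise ValueError(f"survival table lacks column {col!r}")
        if df["subject_id"].duplicated().any():
            raise ValueError("duplicate subject_id")
        if df[["time", "event"]].isna().any().any():
            raise ValueError("missing time/event values")
        if (df["time"] < 0).any():
            raise ValueError("negative follow-up time")
        if not df["event"].isin((0, 1)).all():
            raise ValueError("event indicator must be 0 or 1")
        self.df = df.reset_index(drop=True)

    @classmethod
    def from_csv(cls, path) -> "SurvivalTable":
        return cls(pd.read_csv(path))

    @property
    def time(self) -> np.ndarray:
        return self.df["time"].to_numpy(dtype=float)

    @property
    def event(self) -> np.ndarray:
        return self.df["event"].to_numpy(dtype=int)

    @property
    def score(self) -> np.ndarray:
        if "score" not in self.df.columns:
            raise ValueError("survival table lacks a 'score' column")
        return self.df["score"].to_numpy(dtype=float)

    @property
    def marker(self) -> np.ndarray:
        if "marker" not in self.df.columns:
            raise ValueError("survival table lacks a 'marker' column")
        return self.df["marker"].to_numpy(dtype=float)

    def subset(self, mask: np.ndarray) -> "SurvivalTable":
        return SurvivalTable(self.df.loc[np.asarray(mask)].reset_index(drop=True))


@dataclass
class CutoffScanResult:
    best_cutoff: float
    best_p: float
    scanned: pd.DataFrame  # columns: cutoff, p, n_low, n_high
    percentile_window: tuple

    def __post_init__(self) -> None:
        if len(self.scanned) and self.best_p > np.nanmin(self.scanned["p"]) + 1e-15:
            raise ValueError("best_p must be the minimum of the scan trace")


# ---------------------------------------------------------------------------
# log-rank machinery
# ---------------------------------------------------------------------------

def logrank_statistic(
    time: np.ndarray, event: np.ndarray, labels: np.ndarray
) -> tuple[float, float]:
    """K-group Mantel–Haenszel log-rank test.

    At each event time, observed minus expected events per group are
    accumulated with the hypergeometric variance-covariance; the statistic
    is the quadratic form over the first k−1 groups, chi-square with k−1
    degrees of freedom under the null.
    """
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    labels = np.asarray(labels)
    groups = np.unique(labels)
    k = len(groups)
    if k < 2:
        raise ValueError("log-rank needs >= 2 groups")
    if event.sum() == 0:
        raise ValueError("no events; log-rank p undefined")
    member = np.stack([labels == g for g in groups], axis=1)  # n × k
    z = np.zeros(k)
    V = np.zeros((k, k))
    for t in np.unique(time[event == 1]):
        at_risk = time >= t
        n = at_risk.sum()
        n_g = member[at_risk].sum(axis=0).astype(float)
        dying = at_risk & (time == t) & (event == 1)
        d = dying.sum()
        d_g = member[dying].sum(axis=0).astype(float)
        z += d_g - d * n_g / n
        if n > 1:
            p_g = n_g / n
            V += d * (n - d) / (n - 1) * (np.diag(p_g) - np.outer(p_g, p_g))
    Vr = V[:-1, :-1]
    zr = z[:-1]
    if not Vr.any():
        return 0.0, 1.0
    stat = float(zr @ np.linalg.pinv(Vr) @ zr)
    stat = max(stat, 0.0)
    return stat, float(chi2_dist.sf(stat, k - 1))


def _two_group_logrank_sorted(
    t: np.ndarray, e: np.ndarray, g: np.ndarray, starts: np.ndarray, n_at_risk: np.ndarray
) -> tuple[float, float]:
    """Vectorized two-group log-rank on time-sorted arrays (scan fast path)."""
    n1_from = np.cumsum(g[::-1])[::-1]
    n1 = n1_from[starts].astype(float)
    d = np.add.reduceat(e, starts).astype(float)
    d1 = np.add.reduceat(e * g, starts).astype(float)
    n = n_at_risk.astype(float)
    use = (d > 0) & (n > 1)
    if not use.any():
        return 0.0, 1.0
    p1 = n1[use] / n[use]
    du, nu = d[use], n[use]
    z = float(np.sum(d1[use] - du * p1))
    var = float(np.sum(du * (nu - du) / (nu - 1) * p1 * (1 - p1)))
    if var == 0:
        return 0.0, 1.0
    stat = z * z / var
    return stat, float(chi2_dist.sf(stat, 1))


def km_curves(table: SurvivalTable, groups: Sequence) -> dict:
    """Product-limit survival curves per group (lifelines)."""
    groups = np.asarray(groups)
    curves: dict = {}
    for g in np.unique(groups):
        sel = groups == g
        kmf = KaplanMeierFitter()
        kmf.fit(table.time[sel], table.event[sel], label=str(g))
        sf = kmf.survival_function_
        curves[g] = pd.DataFrame(
            {"time": sf.index.to_numpy(), "survival": sf.iloc[:, 0].to_numpy()}
        )
    return curves


def km_logrank(table: SurvivalTable, groups: Sequence) -> tuple[dict, float, float]:
    """Kaplan–Meier curves plus the log-rank test across the given groups."""
    groups = np.asarray(groups)
    if len(groups) != len(table.df):
        raise ValueError("group labels must cover every subject")
    uniq, counts = np.unique(groups, return_counts=True)
    if len(uniq) < 2:
        raise ValueError("need >= 2 non-empty groups")
    stat, p = logrank_statistic(table.time, table.event, groups)
    return km_curves(table, groups), stat, p


# ---------------------------------------------------------------------------
# cutoff stratification
# ---------------------------------------------------------------------------

def optimal_cutoff_scan(
    table: SurvivalTable, lo_pct: float = 0.10, hi_pct: float = 0.90
) -> CutoffScanResult:
    """Minimum-p two-group log-rank scan over score cutoffs.

    Candidates are every distinct observed score within the inclusive
    [lo_pct, hi_pct] percentile window; each splits subjects into
    score > cutoff vs the rest.  Ties on p break to the more balanced
    split, then the lower cutoff.
    """
    score = table.score
    if np.unique(score).size == 1:
        raise ValueError("constant score; no cutoff exists")
    lo, hi = np.percentile(score, [100 * lo_pct, 100 * hi_pct])
    candidates = np.unique(score)
    candidates = candidates[(candidates >= lo) & (candidates <= hi)]
    if candidates.size < 3:
        raise ValueError(
            f"fewer than 3 distinct score values in the percentile window [{lo}, {hi}]"
        )
    order = np.argsort(table.time, kind="stable")
    t = table.time[order]
    e = table.event[order]
    s = score[order]
    starts = np.flatnonzero(np.r_[True, np.diff(t) > 0])
    n_at_risk = len(t) - starts
    rows = []
    for c in candidates:
        g = (s > c).astype(int)
        n_high = int(g.sum())
        n_low = len(g) - n_high
        if n_high == 0 or n_low == 0:
            continue
        _, p = _two_group_logrank_sorted(t, e, g, starts, n_at_risk)
        rows.append((float(c), float(p), n_low, n_high))
    if not rows:
        raise ValueError("no cutoff produced two non-empty groups")
    scanned = pd.DataFrame(rows, columns=["cutoff", "p", "n_low", "n_high"])
    ranked = sorted(
        rows, key=lambda r: (r[1], abs(r[3] - r[2]), r[0])
    )
    best_cutoff, best_p = ranked[0][0], ranked[0][1]
    if not lo <= best_cutoff <= hi:
        raise AssertionError("best cutoff escaped the percentile window")
    return CutoffScanResult(
        best_cutoff=best_cutoff,
        best_p=best_p,
        scanned=scanned,
        percentile_window=(lo_pct, hi_pct),
    )


def three_group_stratify(
    table: SurvivalTable, min_high: int = 10
) -> tuple[pd.Series, CutoffScanResult, tuple]:
    """Marker-mean split, then optimal score cutoff within marker-high.

    Subjects with marker strictly above the marker mean form the high
    group (ties at the mean go low); the optimal score cutoff computed on
    that subgroup alone splits it further.  Returns the three labels, the
    scan result, and (curves, statistic, p) of the three-group log-rank.
    """
    marker = table.marker
    high = marker > marker.mean()
    if high.sum() < min_high:
        raise ValueError(
            f"marker-high subgroup has {high.sum()} subjects; "
            f"needs >= {min_high} to scan"
        )
    scan = optimal_cutoff_scan(table.subset(high))
    score = table.score
    labels = np.where(
        ~high,
        "Marker_low",
        np.where(score > scan.best_cutoff, "Marker_high/Score_high", "Marker_high/Score_low"),
    )
    labels = pd.Series(labels, index=table.df["subject_id"], name="group")
    curves, stat, p = km_logrank(table, labels.to_numpy())
    _log.info("three-group log-rank: chi2=%.3f p=%.3g", stat, p)
    return labels, scan, (curves, stat, p)
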