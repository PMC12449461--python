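"""Selecting ribosome-related programs from an NMF catalog.

Each program's per-cell activity is correlated (Pearson, within its own
sample) against K reference ribosome gene-set scores; the mean of the K
correlations (R_mean) summarizes how ribosome-like the program is.  Per
sample, at most one *mean-maxed* program is selected under two criteria:
its rank's decomposition must contain at least two programs each covering
more than 10% of the sample's cells, and its R_mean must exceed 0.1.
Hierarchical clustering of the K-dimensional correlation profiles then
separates a ribosome-related cluster (highest mean R_mean) from an
anti-program cluster (lowest mean R_mean).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.stats import rankdata

from .nmf import ProgramCatalog
from .scoring import ScoreMatrix

_log = logging.getLogger("ribostate.selection")


@dataclass
class CorrelationProfile:
    program_ref: tuple  # (sample_id, rank, index_in_rank)
    correlations: np.ndarray  # length K, one Pearson r per reference signature
    reference_names: Sequence[str]

    def __post_init__(self) -> None:
        self.correlations = np.asarray(self.correlations, dtype=float)
        if np.any(np.abs(self.correlations) > 1 + 1e-9):
            raise ValueError("correlations must lie in [-1, 1]")

    @property
    def mean_correlation(self) -> float:
        """R_mean: the arithmetic mean of the K reference correlations."""
        return float(self.correlations.mean())


@dataclass
class SelectionConfig:
    min_cell_fraction: float = 0.10
    min_programs_above_fraction: int = 2
    min_mean_correlation: float = 0.1

    def __post_init__(self) -> None:
        if not 0.0 < self.min_cell_fraction < 1.0:
            raise ValueError("min_cell_fraction must lie in (0, 1)")


@dataclass
class ProgramClusterResult:
    labels: dict  # program_ref -> cluster id (1-based)
    linkage_record: np.ndarray
    ribosome_cluster_id: int | None = None
    anti_cluster_id: int | None = None

    def members(self, cluster_id: int) -> list:
        return [ref for ref, c in self.labels.items() if c == cluster_id]

    def to_json(self) -> str:
        return json.dumps(
            {
                "labels": {"|".join(map(str, k)): int(v) for k, v in self.labels.items()},
                "linkage": self.linkage_record.tolist(),
                "ribosome_cluster_id": self.ribosome_cluster_id,
                "anti_cluster_id": self.anti_cluster_id,
            },
            indent=1,
        )


def _pearson_columns(x: np.ndarray, Y: np.ndarray) -> np.ndarray:
    """Pearson r between vector x and each column of Y; 0 where degenerate."""
    x = x - x.mean()
    Y = Y - Y.mean(axis=0)
    sx = np.sqrt((x ** 2).sum())
    sy = np.sqrt((Y ** 2).sum(axis=0))
    r = np.zeros(Y.shape[1])
    ok = (sx > 0) & (sy > 0)
    if sx > 0:
        r[sy > 0] = (x @ Y[:, sy > 0]) / (sx * sy[sy > 0])
    if not ok.all():
        _log.warning("zero-variance vector(s) in correlation; r set to 0")
    return np.clip(r, -1.0, 1.0)


def correlate_programs(
    catalog: ProgramCatalog, ref_scores: ScoreMatrix, method: str = "pearson"
) -> list:
    """Correlate each program's cell scores with the reference signature scores.

    Correlations are computed within the program's own sample (its cells
    only).  Zero-variance program scores yield r = 0 with a warning, so
    degenerate programs can never win selection.
    """
    if method not in ("pearson", "spearman"):
        raise ValueError("method must be 'pearson' or 'spearman'")
    row_index = {c: i for i, c in enumerate(ref_scores.row_ids)}
    profiles: list[CorrelationProfile] = []
    cache: dict[int, np.ndarray] = {}
    for p in catalog.programs:
        key = id(p.cell_ids)
        if key not in cache:
            try:
                cache[key] = np.array([row_index[c] for c in p.cell_ids])
            except KeyError as err:
                raise ValueError(
                    f"reference scores lack cell {err} of sample {p.sample_id}"
                ) from None
        Y = ref_scores.values[cache[key], :]
        x = p.cell_scores
        if method == "spearman":
            x = rankdata(x)
            Y = rankdata(Y, axis=0)
        profiles.append(
            CorrelationProfile(p.ref, _pearson_columns(x, Y), ref_scores.signature_names)
        )
    return profiles


def select_mean_maxed(
    profiles: Sequence[CorrelationProfile],
    catalog: ProgramCatalog,
    cfg: SelectionConfig | None = None,
) -> dict:
    """Pick at most one mean-maxed program per sample.

    A program is a candidate if its own rank's decomposition contains at
    least ``min_programs_above_fraction`` programs with cell fraction above
    ``min_cell_fraction`` (the candidate itself need not be one of them).
    Among candidates with R_mean above ``min_mean_correlation``, the
    max-R_mean program wins; ties break to lower rank then lower index.
    Returns sample_id → CorrelationProfile of the winner.
    """
    cfg = cfg or SelectionConfig()
    if not catalog.programs:
        raise ValueError("empty program catalog")
    by_ref = catalog.by_ref()
    # how many programs in each (sample, rank) decomposition exceed the fraction
    n_above: dict[tuple, int] = {}
    for p in catalog.programs:
        key = (p.sample_id, p.rank)
        n_above[key] = n_above.get(key, 0) + (p.cell_fraction > cfg.min_cell_fraction)
    selected: dict[str, CorrelationProfile] = {}
    for prof in sorted(profiles, key=lambda q: (q.program_ref[1], q.program_ref[2])):
        sample_id, rank, _ = prof.program_ref
        if prof.program_ref not in by_ref:
            raise ValueError(f"profile {prof.program_ref} not in catalog")
        if n_above.get((sample_id, rank), 0) < cfg.min_programs_above_fraction:
            continue
        if prof.mean_correlation <= cfg.min_mean_correlation:
            continue
        cur = selected.get(sample_id)
        if cur is None or prof.mean_correlation > cur.mean_correlation:
            selected[sample_id] = prof
    for sid, prof in selected.items():
        _log.info(
            "sample %s: mean-maxed program rank=%d index=%d R_mean=%.3f",
            sid, prof.program_ref[1], prof.program_ref[2], prof.mean_correlation,
        )
    return selected


def cluster_program_profiles(
    profiles: Sequence[CorrelationProfile], n_clusters: int = 3
) -> ProgramClusterResult:
    """Ward-linkage hierarchical clustering of correlation profiles.

    Programs are points in the K-dimensional space of reference
    correlations; Euclidean/Ward agglomeration is deterministic given the
    inputs.  Requesting more clusters than distinguishable profiles is an
    error.
    """
    if len(profiles) < 2:
        raise ValueError("clustering needs at least 2 profiles")
    if n_clusters > len(profiles):
        raise ValueError(f"n_clusters={n_clusters} exceeds {len(profiles)} profiles")
    X = np.vstack([p.correlations for p in profiles])
    Z = linkage(X, method="ward")
    if n_clusters == 1:
        flat = np.ones(len(profiles), dtype=int)
    else:
        flat = fcluster(Z, t=n_clusters, criterion="maxclust")
        if len(np.unique(flat)) < n_clusters:
            raise ValueError(
                f"profiles support only {len(np.unique(flat))} distinct clusters, "
                f"{n_clusters} requested"
            )
    labels = {p.program_ref: int(c) for p, c in zip(profiles, flat)}
    return ProgramClusterResult(labels=labels, linkage_record=Z)


def pick_ribosome_and_anti_clusters(
    result: ProgramClusterResult,
    profiles: Sequence[CorrelationProfile],
    mean_maxed: dict,
) -> tuple[list, list]:
    """Name the ribosome-related and anti-program clusters.

    The ribosome cluster is the one with the highest mean R_mean across its
    member programs; the anti cluster has the lowest.  The fraction of
    mean-maxed programs falling in the ribosome cluster is logged as a
    coherence check.  Sets the cluster ids on ``result`` and returns the
    two member lists (program refs).
    """
    if not mean_maxed:
        raise ValueError("no mean-maxed programs; nothing to anchor the clusters")
    by_ref = {p.program_ref: p for p in profiles}
    cluster_means: dict[int, float] = {}
    for cid in sorted(set(result.labels.values())):
        members = result.members(cid)
        cluster_means[cid] = float(
            np.mean([by_ref[r].mean_correlation for r in members])
        )
    ribo = max(cluster_means, key=lambda c: (cluster_means[c], -c))
    anti = min(cluster_means, key=lambda c: (cluster_means[c], c))
    if ribo == anti:
        raise ValueError("ribosome and anti clusters coincide; increase n_clusters")
    result.ribosome_cluster_id = ribo
    result.anti_cluster_id = anti
    ribo_members = result.members(ribo)
    mm_refs = {p.program_ref for p in mean_maxed.values()}
    frac = len(mm_refs & set(ribo_members)) / len(mm_refs)
    _log.info(
        "ribosome cluster %d (mean R_mean=%.3f, %d programs, %.0f%% of mean-maxed); "
        "anti cluster %d (mean R_mean=%.3f, %d programs)",
        ribo, cluster_means[ribo], len(ribo_members), 100 * frac,
        anti, cluster_means[anti], len(result.members(anti)),
    )
    return ribo_members, result.members(anti)


def profiles_to_frame(profiles: Sequence[CorrelationProfile]) -> pd.DataFrame:
    """Tabulate profiles: one row per program with per-reference r and R_mean."""
    rows = []
    for p in profiles:
        row = {
            "sample_id": p.program_ref[0],
            "rank": p.program_ref[1],
            "index_in_rank": p.program_ref[2],
            "R_mean": p.mean_correlation,
        }
        row.update({f"r_{n}": v for n, v in zip(p.reference_names, p.correlations)})
        rows.append(row)
    return pd.DataFrame(rows)
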