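"""Gene-signature scoring.

Two scorers are provided:

* :func:`ucell_scores` — a per-cell rank-based score derived from the
  Mann–Whitney U statistic of the signature genes' expression ranks within
  each cell.  Scores are bounded in [0, 1] and depend only on the relative
  expression within a cell, so they are invariant to any strictly monotone
  transform of that cell's expression vector and robust to dataset
  composition.
* :func:`ssgsea_scores` — a single-sample enrichment score for bulk
  (sample × gene) data: the sum over the ranked gene list of the weighted
  in-set ECDF minus the out-of-set ECDF.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .datamodel import ExpressionMatrix, GeneSet

_log = logging.getLogger("ribostate.scoring")


@dataclass
class ScoreMatrix:
    """Scores for cells-or-samples (rows) × signatures (columns)."""

    values: np.ndarray
    row_ids: Sequence[str]
    signature_names: Sequence[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.row_ids = list(map(str, self.row_ids))
        self.signature_names = list(map(str, self.signature_names))
        if self.values.shape != (len(self.row_ids), len(self.signature_names)):
            raise ValueError("score matrix shape does not match id lists")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.row_ids, columns=self.signature_names)

    def column(self, name: str) -> np.ndarray:
        return self.values[:, self.signature_names.index(name)]


@dataclass
class UCellConfig:
    """Parameters of the rank-based per-cell scorer.

    ``max_rank`` caps the rank a signature gene can contribute: genes ranked
    below it (weakly expressed or undetected) all count as ``max_rank + 1``,
    which makes the score robust to the long tail of zeros in sparse
    single-cell data.  1500 is the scorer family's published default.
    """

    max_rank: int = 1500
    tie_method: str = "average"

    def __post_init__(self) -> None:
        if self.max_rank < 1:
            raise ValueError("max_rank must be >= 1")
        if self.tie_method not in ("average", "min"):
            raise ValueError("tie_method must be 'average' or 'min'")


def _effective_indices(sets: Sequence[GeneSet], gene_ids: Sequence[str]) -> dict[str, np.ndarray]:
    lookup = {g: i for i, g in enumerate(gene_ids)}
    out: dict[str, np.ndarray] = {}
    for s in sets:
        present = sorted(g for g in s.genes if g in lookup)
        missing = len(s.genes) - len(present)
        if missing:
            _log.warning(
                "signature %r: %d/%d genes absent from the matrix and dropped",
                s.name, missing, len(s.genes),
            )
        if not present:
            raise ValueError(f"signature {s.name!r} has no genes in the matrix")
        out[s.name] = np.array([lookup[g] for g in present], dtype=int)
    return out


def ucell_scores(
    m: ExpressionMatrix, sets: Sequence[GeneSet], cfg: UCellConfig | None = None
) -> ScoreMatrix:
    """Mann–Whitney-U-based per-cell signature scores in [0, 1].

    Per cell, genes are ranked by decreasing expression; ranks beyond
    ``cfg.max_rank`` are clipped to ``max_rank + 1``.  For a signature of
    effective size n with clipped rank-sum R, U = R − n(n+1)/2 and
    score = max(0, 1 − U / (n · max_rank)).
    """
    cfg = cfg or UCellConfig()
    if cfg.max_rank >= m.n_genes:
        _log.warning(
            "max_rank=%d is not below the gene count %d; scores will saturate",
            cfg.max_rank, m.n_genes,
        )
    idx = _effective_indices(sets, m.gene_ids)
    X = m.dense()
    if not np.isfinite(X).all():
        raise ValueError("non-finite expression values")
    ranks = rankdata(-X, axis=1, method=cfg.tie_method).astype(float)
    ranks[ranks > cfg.max_rank] = cfg.max_rank + 1
    cols = []
    for s in sets:
        gi = idx[s.name]
        n = len(gi)
        R = ranks[:, gi].sum(axis=1)
        U = R - n * (n + 1) / 2.0
        cols.append(np.maximum(0.0, 1.0 - U / (n * cfg.max_rank)))
    return ScoreMatrix(np.column_stack(cols), m.cell_ids, [s.name for s in sets])


def ssgsea_scores(
    bulk: ExpressionMatrix,
    sets: Sequence[GeneSet],
    alpha: float = 0.25,
    normalize: bool = False,
) -> ScoreMatrix:
    """Single-sample enrichment scores for a samples × genes matrix.

    Per sample, genes get ascending ranks (top-expressed gene has rank G)
    and are walked in decreasing order; the score is the sum over positions
    of the in-set ECDF weighted by |rank|^alpha minus the uniform
    out-of-set ECDF.  ``normalize=True`` min-max scales each signature's
    scores across samples.
    """
    idx = _effective_indices(sets, bulk.gene_ids)
    G = bulk.n_genes
    for s in sets:
        if len(idx[s.name]) == G:
            raise ValueError(
                f"signature {s.name!r} covers every gene; out-of-set ECDF undefined"
            )
    X = bulk.dense()
    scores = np.zeros((bulk.n_cells, len(sets)))
    for i in range(bulk.n_cells):
        r = rankdata(X[i], method="average")  # ascending: top gene has rank G
        order = np.argsort(-r, kind="stable")
        for j, s in enumerate(sets):
            in_set = np.zeros(G, dtype=bool)
            in_set[idx[s.name]] = True
            in_ordered = in_set[order]
            w = np.where(in_ordered, np.abs(r[order]) ** alpha, 0.0)
            cdf_in = np.cumsum(w) / w.sum()
            cdf_out = np.cumsum(~in_ordered) / (G - in_ordered.sum())
            scores[i, j] = float(np.sum(cdf_in - cdf_out))
    if normalize:
        lo, hi = scores.min(axis=0), scores.max(axis=0)
        span = np.where(hi > lo, hi - lo, 1.0)
        scores = (scores - lo) / span
    return ScoreMatrix(scores, bulk.cell_ids, [s.name for s in sets])


def scale_scores(s: ScoreMatrix) -> ScoreMatrix:
    """Z-scale each signature column to mean 0, sd 1 (sample sd, ddof=1)."""
    if s.values.shape[0] < 2:
        raise ValueError("scaling needs at least 2 rows")
    sd = s.values.std(axis=0, ddof=1)
    if (sd == 0).any():
        bad = [n for n, v in zip(s.signature_names, sd) if v == 0]
        raise ValueError(f"constant score column(s): {bad}")
    vals = (s.values - s.values.mean(axis=0)) / sd
    return ScoreMatrix(vals, s.row_ids, s.signature_names)
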