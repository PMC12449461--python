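"""Tissue prevalence (Ro/e) and rule-based subtype labeling.

Ro/e compares the observed cell-type × condition contingency table with
the counts expected under independence (chi-square expected frequencies):
values above 1 mean a cell type is enriched in a condition, below 1
depleted.  The iCMS-style classifier assigns epithelial subtype labels
from sign rules on z-scaled up/down signature scores.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats.contingency import expected_freq

from .scoring import ScoreMatrix

_log = logging.getLogger("ribostate.prevalence")


@dataclass
class RoeTable:
    observed: pd.DataFrame
    expected: pd.DataFrame
    roe: pd.DataFrame
    undefined: pd.DataFrame  # True where expected == 0 (Ro/e undefined)


@dataclass(frozen=True)
class SubtypeRuleSet:
    """Score-column names and output labels for two-way subtype calling.

    ``score_names`` order: (up_A, down_A, up_B, down_B) — e.g. the iCMS2
    up / iCMS2 down / iCMS3 up / iCMS3 down signature scores.
    """

    score_names: tuple
    labels: tuple = ("A", "B", "unassigned")

    def __post_init__(self) -> None:
        if len(self.score_names) != 4 or len(set(self.score_names)) != 4:
            raise ValueError("score_names must be four distinct names")
        if len(self.labels) != 3:
            raise ValueError("labels must be (A, B, unassigned)")


def roe_table(meta: pd.DataFrame, type_field: str, condition_field: str) -> RoeTable:
    """Observed/expected enrichment of each cell type per condition.

    Expected counts come from the chi-square independence model:
    expected(i, j) = row_total_i × col_total_j / grand_total.  Cells with
    expected 0 (an empty row or column level) are flagged undefined
    rather than producing infinities.
    """
    if meta.empty:
        raise ValueError("empty cell metadata")
    for f in (type_field, condition_field):
        if f not in meta.columns:
            raise ValueError(f"metadata lacks field {f!r}")
        if meta[f].isna().any():
            raise ValueError(f"unlabeled cells in field {f!r}")
        if meta[f].nunique() < 2:
            raise ValueError(f"field {f!r} has fewer than 2 levels")
    observed = pd.crosstab(meta[type_field], meta[condition_field])
    expected = pd.DataFrame(
        expected_freq(observed.to_numpy()),
        index=observed.index,
        columns=observed.columns,
    )
    undefined = expected == 0
    with np.errstate(divide="ignore", invalid="ignore"):
        roe = observed / expected
    roe = roe.where(~undefined)
    return RoeTable(observed=observed, expected=expected, roe=roe, undefined=undefined)


def classify_icms(
    scores: ScoreMatrix, rules: SubtypeRuleSet, mean_tolerance: float = 1e-6
) -> pd.Series:
    """Per-cell subtype labels from sign rules on z-scaled scores.

    A cell is labeled A when its up_A and down_B scores are above zero and
    its up_B and down_A scores below zero; B symmetrically; anything else
    (including exact zeros) is unassigned.  Input must be z-scaled — a
    column mean beyond ``mean_tolerance`` raises, directing the caller to
    :func:`ribostate.scoring.scale_scores`.
    """
    missing = [n for n in rules.score_names if n not in scores.signature_names]
    if missing:
        raise ValueError(f"score matrix lacks columns {missing}")
    col_means = scores.values.mean(axis=0)
    if np.any(np.abs(col_means) > mean_tolerance):
        raise ValueError(
            "scores do not look z-scaled (column mean beyond tolerance); "
            "apply ribostate.scoring.scale_scores first"
        )
    up_a, down_a, up_b, down_b = (scores.column(n) for n in rules.score_names)
    a_label, b_label, unassigned = rules.labels
    is_a = (up_a > 0) & (down_b > 0) & (up_b < 0) & (down_a < 0)
    is_b = (up_b > 0) & (down_a > 0) & (up_a < 0) & (down_b < 0)
    labels = np.where(is_a, a_label, np.where(is_b, b_label, unassigned))
    _log.info(
        "subtype calls: %d %s, %d %s, %d %s",
        is_a.sum(), a_label, is_b.sum(), b_label,
        len(labels) - is_a.sum() - is_b.sum(), unassigned,
    )
    return pd.Series(labels, index=scores.row_ids, name="subtype")
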