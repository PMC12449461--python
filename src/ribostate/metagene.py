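"""Frequency-based metagene signature assembly.

The ribosome-related programs' top-gene lists are pooled; a gene's
frequency is the number of programs whose list contains it (membership,
not multiplicity).  The metagene signature keeps genes present in at
least ``min_frequency`` programs (default 10).  The anti-signature is the
analogous set from anti-program lists (default: more than two programs,
i.e. frequency >= 3) with any metagene overlap removed, giving a
negative-control gene set disjoint by construction.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import pandas as pd

from .datamodel import GeneSet

_log = logging.getLogger("ribostate.metagene")


@dataclass
class MetageneSignature:
    genes: list
    frequency: dict
    source_program_count: int
    min_frequency: int

    def __post_init__(self) -> None:
        low = [g for g in self.genes if self.frequency.get(g, 0) < self.min_frequency]
        if low:
            raise ValueError(f"genes below min_frequency in signature: {low[:5]}")

    def as_gene_set(self, name: str = "ribosomal_state") -> GeneSet:
        return GeneSet(name, frozenset(self.genes))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"gene": self.genes, "frequency": [self.frequency[g] for g in self.genes]}
        )


@dataclass
class AntiSignature:
    genes: list
    frequency: dict
    excluded_overlap: list

    def as_gene_set(self, name: str = "anti_program") -> GeneSet:
        return GeneSet(name, frozenset(self.genes))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"gene": self.genes, "frequency": [self.frequency[g] for g in self.genes]}
        )


def gene_frequency_table(top_gene_lists: Sequence[Iterable]) -> dict:
    """Count, per gene, how many program lists contain it (membership)."""
    if not top_gene_lists:
        raise ValueError("no program gene lists supplied")
    counts: Counter = Counter()
    for genes in top_gene_lists:
        counts.update(set(genes))
    return dict(counts)


def _sorted_genes(freq: dict, keep: Iterable) -> list:
    return sorted(keep, key=lambda g: (-freq[g], g))


def assemble_metagene_signature(
    freq: dict, min_frequency: int = 10, source_program_count: int | None = None
) -> MetageneSignature:
    """Keep genes present in at least ``min_frequency`` programs (inclusive)."""
    if not freq:
        raise ValueError("empty frequency table")
    keep = [g for g, c in freq.items() if c >= min_frequency]
    if not keep:
        raise ValueError(
            f"no gene reaches frequency {min_frequency} "
            f"(max observed {max(freq.values())}); review the threshold"
        )
    genes = _sorted_genes(freq, keep)
    _log.info("metagene signature: %d genes at frequency >= %d", len(genes), min_frequency)
    return MetageneSignature(
        genes=genes,
        frequency={g: freq[g] for g in genes},
        source_program_count=source_program_count or max(freq.values()),
        min_frequency=min_frequency,
    )


def assemble_anti_signature(
    anti_freq: dict, metagenes: MetageneSignature, min_frequency: int = 3
) -> AntiSignature:
    """Anti-program genes at frequency >= ``min_frequency`` minus metagenes.

    The default of 3 encodes the "more than two programs" rule.  Genes
    dropped for overlapping the metagene signature are recorded in
    ``excluded_overlap``; the remaining set is disjoint from the metagene
    signature by construction.
    """
    if not anti_freq:
        raise ValueError("empty anti-program frequency table")
    passing = {g for g, c in anti_freq.items() if c >= min_frequency}
    overlap = passing & set(metagenes.genes)
    keep = passing - overlap
    genes = _sorted_genes(anti_freq, keep)
    assert not set(genes) & set(metagenes.genes), "anti-signature overlaps metagenes"
    _log.info(
        "anti-signature: %d genes (%d excluded for metagene overlap)",
        len(genes), len(overlap),
    )
    return AntiSignature(
        genes=genes,
        frequency={g: anti_freq[g] for g in genes},
        excluded_overlap=_sorted_genes(anti_freq, overlap),
    )
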