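"""Per-sample NMF program discovery over a rank sweep.

Each tumour sample's log-normalized cell × gene matrix is factorized at
every rank in a sweep (default 2..10) as X ≈ W H with W, H ≥ 0.  Each
column of W / row of H is one *program*: a gene-coefficient vector plus
per-cell activity scores.  Cells are assigned to their argmax program
within a rank's decomposition, giving per-program cell fractions; a
rank-2..10 sweep emits Σ_{r=2..10} r = 54 programs per sample.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .datamodel import ExpressionMatrix

_log = logging.getLogger("ribostate.nmf")

_EPS = 1e-12


@dataclass
class NMFConfig:
    ranks: tuple = tuple(range(2, 11))
    n_top_genes: int = 200
    max_iter: int = 200
    tol: float = 1e-4
    seed: int = 0
    min_epithelial_cells: int = 200
    objective_every: int = 10  # iterations between objective evaluations

    def __post_init__(self) -> None:
        self.ranks = tuple(int(r) for r in self.ranks)
        if any(r < 2 for r in self.ranks):
            raise ValueError("all ranks must be >= 2")
        if self.n_top_genes <= 0:
            raise ValueError("n_top_genes must be positive")


@dataclass
class Program:
    """One NMF component: gene coefficients plus per-cell activity scores."""

    sample_id: str
    rank: int
    index_in_rank: int
    gene_coefficients: np.ndarray
    cell_scores: np.ndarray
    cell_fraction: float
    top_genes: list
    gene_ids: Sequence[str]
    cell_ids: Sequence[str]

    @property
    def ref(self) -> tuple:
        """(sample_id, rank, index_in_rank) identity of this program."""
        return (self.sample_id, self.rank, self.index_in_rank)


@dataclass
class ProgramCatalog:
    programs: list
    provenance: NMFConfig

    def by_sample(self) -> dict:
        out: dict[str, list] = {}
        for p in self.programs:
            out.setdefault(p.sample_id, []).append(p)
        return out

    def by_ref(self) -> dict:
        return {p.ref: p for p in self.programs}

    def save(self, out_dir) -> None:
        """Persist per-sample W/H matrices as CSV plus a JSON manifest."""
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        manifest: dict = {
            "config": {
                "ranks": list(self.provenance.ranks),
                "n_top_genes": self.provenance.n_top_genes,
                "max_iter": self.provenance.max_iter,
                "tol": self.provenance.tol,
                "seed": self.provenance.seed,
                "min_epithelial_cells": self.provenance.min_epithelial_cells,
            },
            "programs": [],
        }
        for p in self.programs:
            stem = f"{p.sample_id}_r{p.rank}_p{p.index_in_rank}"
            pd.Series(p.gene_coefficients, index=list(p.gene_ids)).to_csv(
                out_dir / f"{stem}_H.csv", header=["coefficient"]
            )
            pd.Series(p.cell_scores, index=list(p.cell_ids)).to_csv(
                out_dir / f"{stem}_W.csv", header=["score"]
            )
            manifest["programs"].append(
                {
                    "sample_id": p.sample_id,
                    "rank": p.rank,
                    "index_in_rank": p.index_in_rank,
                    "cell_fraction": p.cell_fraction,
                    "top_genes": list(p.top_genes),
                }
            )
        (out_dir / "catalog.json").write_text(json.dumps(manifest, indent=1))


def nmf_decompose(
    m: ExpressionMatrix, rank: int, cfg: NMFConfig | None = None
) -> tuple[np.ndarray, np.ndarray, list]:
    """Seeded multiplicative-update NMF under the Frobenius objective.

    Returns (W cells × rank, H rank × genes, objective trace).  The trace
    records ||X − WH||_F at ``cfg.objective_every``-iteration intervals;
    multiplicative updates make it non-increasing, which callers may
    assert.  Convergence: relative objective change < ``cfg.tol`` between
    consecutive evaluations, or ``cfg.max_iter`` iterations.
    """
    cfg = cfg or NMFConfig()
    X = m.dense()
    if np.min(X) < 0:
        X = np.clip(X, 0.0, None)  # scaled layers may carry negatives
    if rank >= min(X.shape):
        raise ValueError(f"rank {rank} must be < min(cells, genes) = {min(X.shape)}")
    if not X.any():
        raise ValueError("all-zero matrix cannot be factorized")
    rng = np.random.default_rng(np.random.SeedSequence([int(cfg.seed), int(rank)]))
    scale = np.sqrt(X.mean() / rank)
    W = rng.uniform(_EPS, 2 * scale, size=(X.shape[0], rank))
    H = rng.uniform(_EPS, 2 * scale, size=(rank, X.shape[1]))
    trace: list[float] = []
    prev = None
    for it in range(1, cfg.max_iter + 1):
        H *= (W.T @ X) / (W.T @ (W @ H) + _EPS)
        W *= (X @ H.T) / (W @ (H @ H.T) + _EPS)
        if it % cfg.objective_every == 0 or it == cfg.max_iter:
            obj = float(np.linalg.norm(X - W @ H))
            trace.append(obj)
            if prev is not None and (prev - obj) / max(prev, _EPS) < cfg.tol:
                break
            prev = obj
    return W, H, trace


def program_cell_fractions(W: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Assign each cell to its argmax program and return (fractions, labels).

    Ties break to the lowest program index.  An all-zero cell row is
    assigned to program 0 with a warning.
    """
    W = np.asarray(W, dtype=float)
    if np.min(W) < 0:
        raise ValueError("cell-score matrix must be non-negative")
    zero_rows = ~W.any(axis=1)
    if zero_rows.any():
        _log.warning("%d all-zero cell rows assigned to program 0", zero_rows.sum())
    labels = W.argmax(axis=1)
    fractions = np.bincount(labels, minlength=W.shape[1]) / W.shape[0]
    return fractions, labels


def top_program_genes(
    coefficients: np.ndarray, gene_ids: Sequence[str], n: int
) -> list:
    """Top-n genes by decreasing coefficient; ties by lexicographic gene id."""
    if n <= 0:
        raise ValueError("n must be positive")
    if n > len(gene_ids):
        raise ValueError(f"n={n} exceeds gene count {len(gene_ids)}")
    order = sorted(range(len(gene_ids)), key=lambda i: (-coefficients[i], gene_ids[i]))
    return [gene_ids[i] for i in order[:n]]


def rank_sweep(
    m: ExpressionMatrix, cfg: NMFConfig | None = None, sample_id: str = "sample"
) -> list:
    """Run NMF at every configured rank for one sample's matrix.

    Samples with fewer than ``cfg.min_epithelial_cells`` cells are skipped
    (empty result, logged) — small samples yield unstable programs.
    """
    cfg = cfg or NMFConfig()
    if m.n_cells < cfg.min_epithelial_cells:
        _log.info(
            "skipped sample %s: %d cells < %d required",
            sample_id, m.n_cells, cfg.min_epithelial_cells,
        )
        return []
    programs: list[Program] = []
    for rank in cfg.ranks:
        try:
            W, H, trace = nmf_decompose(m, rank, cfg)
        except ValueError as err:
            raise ValueError(f"sample {sample_id}, rank {rank}: {err}") from err
        if any(b > a + 1e-8 * max(a, 1.0) for a, b in zip(trace, trace[1:])):
            raise AssertionError(
                f"sample {sample_id}, rank {rank}: objective increased"
            )
        fractions, _ = program_cell_fractions(W)
        n_top = min(cfg.n_top_genes, m.n_genes)
        for k in range(rank):
            programs.append(
                Program(
                    sample_id=sample_id,
                    rank=rank,
                    index_in_rank=k,
                    gene_coefficients=H[k].copy(),
                    cell_scores=W[:, k].copy(),
                    cell_fraction=float(fractions[k]),
                    top_genes=top_program_genes(H[k], m.gene_ids, n_top),
                    gene_ids=m.gene_ids,
                    cell_ids=m.cell_ids,
                )
            )
    return programs


def sweep_catalog(
    samples: dict, cfg: NMFConfig | None = None
) -> ProgramCatalog:
    """Rank-sweep every sample matrix in ``samples`` (sample_id → matrix)."""
    cfg = cfg or NMFConfig()
    programs: list[Program] = []
    for sample_id, m in samples.items():
        programs.extend(rank_sweep(m, cfg, sample_id=sample_id))
    return ProgramCatalog(programs, cfg)
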