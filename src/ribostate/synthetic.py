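"""Synthetic multi-sample scRNA-seq data with planted gene programs.

The generator emulates the statistical structure the discovery pipeline
assumes: each cell draws a lognormal activity for every planted program;
a gene's relative expression is a baseline plus the activity-weighted
program loadings; counts are negative-binomial (gamma-Poisson) draws at a
lognormal per-cell library size.  One planted program (the "ribo"
program) is paired with K reference gene sets that each overlap its gene
list by a configurable fraction, mirroring the premise that a real
ribosome-biogenesis program correlates with published ribosome signatures
without being identical to any of them.  Ground truth (per-cell
activities, program gene lists, reference sets) is returned alongside the
counts so recovery can be scored without re-simulation.

All generators are pure functions of their config; the seed fully
determines the output.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .datamodel import ExpressionMatrix, GeneSet

_log = logging.getLogger("ribostate.synthetic")


@dataclass(frozen=True)
class ProgramSpec:
    """One planted program: member genes, activity law, loading strength."""

    gene_indices: tuple
    activity_mean: float = -0.5  # log-scale mean of the lognormal activity
    activity_sd: float = 0.8
    loading_strength: float = 3.0

    def __post_init__(self) -> None:
        if len(self.gene_indices) < 20:
            raise ValueError("each planted program needs >= 20 genes")
        if self.loading_strength < 0:
            raise ValueError("loading_strength must be >= 0")


@dataclass
class SimConfig:
    n_samples: int = 5
    cells_per_sample: int = 1000
    n_genes: int = 2000
    planted_programs: tuple | None = None  # None -> 3 disjoint 100-gene blocks
    ribo_program_index: int = 0
    baseline_dispersion: float = 0.3
    sample_gene_sd: float = 0.6  # lognormal sigma of per-sample gene-scale variation
    library_size_mean: float = 2500.0
    library_size_sd: float = 0.35  # lognormal sigma of per-cell library sizes
    n_reference_sets: int = 5
    reference_set_size: int = 100
    ribo_overlap_fraction: float = 0.5
    low_quality_fraction: float = 0.0
    low_quality_library: float = 100.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.planted_programs is None:
            block = 200
            if 3 * block > self.n_genes:
                block = max(20, self.n_genes // 4)
            self.planted_programs = tuple(
                ProgramSpec(gene_indices=tuple(range(p * block, (p + 1) * block)))
                for p in range(3)
            )
        self.planted_programs = tuple(self.planted_programs)
        for spec in self.planted_programs:
            if max(spec.gene_indices) >= self.n_genes:
                raise ValueError("program gene index out of range")
        if not 0 <= self.ribo_program_index < len(self.planted_programs):
            raise ValueError("exactly one valid ribo_program_index required")
        if not 0.0 <= self.ribo_overlap_fraction <= 1.0:
            raise ValueError("ribo_overlap_fraction must lie in [0, 1]")


def null_config(**overrides) -> SimConfig:
    """Default config with all program loadings zeroed (no planted signal)."""
    cfg = SimConfig(**overrides)
    cfg.planted_programs = tuple(
        replace(p, loading_strength=0.0) for p in cfg.planted_programs
    )
    return cfg


@dataclass
class GroundTruth:
    """Everything needed to score recovery without re-simulating."""

    activities: pd.DataFrame  # cells × programs, index = cell_id
    program_genes: dict  # program name -> list of gene ids
    reference_sets: list  # list of GeneSet
    ribo_program: str
    low_quality_cells: list

    def to_json(self, path) -> None:
        payload = {
            "activities": {
                c: self.activities[c].round(6).tolist() for c in self.activities.columns
            },
            "cell_ids": self.activities.index.tolist(),
            "program_genes": self.program_genes,
            "reference_sets": {s.name: sorted(s.genes) for s in self.reference_sets},
            "ribo_program": self.ribo_program,
            "low_quality_cells": self.low_quality_cells,
        }
        Path(path).write_text(json.dumps(payload))


def _gene_ids(n: int) -> list:
    return [f"G{i:04d}" for i in range(n)]


def simulate_multitumor_scrna(
    cfg: SimConfig | None = None,
) -> tuple[ExpressionMatrix, pd.DataFrame, GroundTruth]:
    """Generate a multi-sample counts matrix with planted programs.

    Returns (counts matrix, cell metadata, ground truth).  Metadata has
    cell_id, sample_id and a planted_low_quality flag.
    """
    cfg = cfg or SimConfig()
    root = np.random.SeedSequence([int(cfg.seed), 0x51B0])
    seeds = root.spawn(cfg.n_samples + 1)
    g_rng = np.random.default_rng(seeds[0])
    gene_ids = _gene_ids(cfg.n_genes)
    P = len(cfg.planted_programs)

    baseline = g_rng.gamma(0.8, 1.0, size=cfg.n_genes) + 1e-3
    loadings = np.zeros((P, cfg.n_genes))
    program_genes: dict[str, list] = {}
    in_any_program = np.zeros(cfg.n_genes, dtype=bool)
    for p, spec in enumerate(cfg.planted_programs):
        idx = np.array(spec.gene_indices, dtype=int)
        loadings[p, idx] = spec.loading_strength * g_rng.uniform(0.5, 1.0, size=len(idx))
        program_genes[f"program_{p}"] = [gene_ids[i] for i in idx]
        in_any_program[idx] = True

    # reference gene sets overlapping the ribo program by the configured fraction
    ribo_idx = np.array(cfg.planted_programs[cfg.ribo_program_index].gene_indices)
    background = np.flatnonzero(~in_any_program)
    reference_sets = []
    for k in range(cfg.n_reference_sets):
        n_in = min(int(round(cfg.reference_set_size * cfg.ribo_overlap_fraction)), len(ribo_idx))
        n_out = min(cfg.reference_set_size - n_in, len(background))
        members = np.concatenate([
            g_rng.choice(ribo_idx, size=n_in, replace=False),
            g_rng.choice(background, size=n_out, replace=False),
        ])
        reference_sets.append(GeneSet(f"RIBO_REF_{k}", frozenset(gene_ids[i] for i in members)))

    blocks, meta_rows, act_rows, act_index, low_quality = [], [], [], [], []
    for s in range(cfg.n_samples):
        rng = np.random.default_rng(seeds[s + 1])
        sample_id = f"S{s}"
        n = cfg.cells_per_sample
        cell_ids = [f"{sample_id}_c{j:04d}" for j in range(n)]
        acts = np.column_stack([
            rng.lognormal(spec.activity_mean, spec.activity_sd, size=n)
            for spec in cfg.planted_programs
        ])
        # inter-tumour heterogeneity: each sample rescales every gene's baseline
        sample_baseline = baseline * rng.lognormal(0.0, cfg.sample_gene_sd, size=cfg.n_genes)
        w = sample_baseline[None, :] + acts @ loadings
        probs = w / w.sum(axis=1, keepdims=True)
        mu_lib = np.log(cfg.library_size_mean) - cfg.library_size_sd ** 2 / 2.0
        libs = rng.lognormal(mu_lib, cfg.library_size_sd, size=n)
        lowq = np.zeros(n, dtype=bool)
        if cfg.low_quality_fraction > 0:
            n_low = int(round(cfg.low_quality_fraction * n))
            lowq[rng.choice(n, size=n_low, replace=False)] = True
            libs[lowq] = cfg.low_quality_library
        mu = libs[:, None] * probs
        if cfg.baseline_dispersion > 0:
            lam = rng.gamma(1.0 / cfg.baseline_dispersion, mu * cfg.baseline_dispersion)
        else:
            lam = mu
        counts = rng.poisson(lam)
        blocks.append(sp.csr_matrix(counts))
        meta_rows.append(pd.DataFrame({
            "cell_id": cell_ids,
            "sample_id": sample_id,
            "planted_low_quality": lowq,
        }))
        act_rows.append(acts)
        act_index.extend(cell_ids)
        low_quality.extend(np.array(cell_ids)[lowq].tolist())

    matrix = ExpressionMatrix(
        sp.vstack(blocks), act_index, gene_ids, layer_tag="counts"
    )
    meta = pd.concat(meta_rows, ignore_index=True)
    truth = GroundTruth(
        activities=pd.DataFrame(
            np.vstack(act_rows), index=act_index,
            columns=[f"program_{p}" for p in range(P)],
        ),
        program_genes=program_genes,
        reference_sets=reference_sets,
        ribo_program=f"program_{cfg.ribo_program_index}",
        low_quality_cells=low_quality,
    )
    _log.info(
        "simulated %d samples × %d cells × %d genes (%d planted programs)",
        cfg.n_samples, cfg.cells_per_sample, cfg.n_genes, P,
    )
    return matrix, meta, truth


# ---------------------------------------------------------------------------
# survival cohorts
# ---------------------------------------------------------------------------

@dataclass
class SurvivalSimConfig:
    n_subjects: int = 300
    score_distribution: tuple = ("normal", 0.0, 1.0)
    true_cutoff: float = 0.0
    hazard_ratio_above_cutoff: float = 2.0
    censoring_rate: float = 0.2
    baseline_hazard: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.hazard_ratio_above_cutoff <= 0:
            raise ValueError("hazard_ratio_above_cutoff must be > 0")
        if not 0.0 <= self.censoring_rate < 1.0:
            raise ValueError("censoring_rate must lie in [0, 1)")


def simulate_survival_cohort(cfg: SurvivalSimConfig | None = None):
    """Exponential event times with a hazard step at the score cutoff.

    Subjects whose score exceeds ``true_cutoff`` have their hazard
    multiplied by ``hazard_ratio_above_cutoff``; censoring is an
    independent exponential calibrated to the requested overall rate.
    """
    from .survival import SurvivalTable

    cfg = cfg or SurvivalSimConfig()
    rng = np.random.default_rng(np.random.SeedSequence([int(cfg.seed), 0x5CAF]))
    kind, *params = cfg.score_distribution
    if kind == "normal":
        score = rng.normal(params[0], params[1], size=cfg.n_subjects)
    elif kind == "lognormal":
        score = rng.lognormal(params[0], params[1], size=cfg.n_subjects)
    elif kind == "uniform":
        score = rng.uniform(params[0], params[1], size=cfg.n_subjects)
    else:
        raise ValueError(f"unknown score distribution {kind!r}")
    if np.unique(score).size == 1:
        raise ValueError("degenerate score distribution: all scores equal")
    hazard = cfg.baseline_hazard * np.where(
        score > cfg.true_cutoff, cfg.hazard_ratio_above_cutoff, 1.0
    )
    t_event = rng.exponential(1.0 / hazard)
    if cfg.censoring_rate > 0:
        rate_c = cfg.baseline_hazard * cfg.censoring_rate / (1.0 - cfg.censoring_rate)
        t_cens = rng.exponential(1.0 / rate_c, size=cfg.n_subjects)
    else:
        t_cens = np.full(cfg.n_subjects, np.inf)
    event = (t_event <= t_cens).astype(int)
    time = np.minimum(t_event, t_cens)
    return SurvivalTable(pd.DataFrame({
        "subject_id": [f"P{i:04d}" for i in range(cfg.n_subjects)],
        "time": time,
        "event": event,
        "score": score,
    }))


# ---------------------------------------------------------------------------
# labeled cell-type × tissue tables
# ---------------------------------------------------------------------------

def simulate_tissue_table(spec: pd.DataFrame, n_cells: int, seed: int = 0) -> pd.DataFrame:
    """Multinomial draws of (cell_type, tissue) pairs matching ``spec``.

    ``spec`` is a cell-type × tissue matrix of non-negative weights
    (normalized internally to joint probabilities).
    """
    if spec.shape[0] < 2 or spec.shape[1] < 2:
        raise ValueError("spec needs >= 2 cell types and >= 2 tissues")
    w = spec.to_numpy(dtype=float)
    if (w < 0).any():
        raise ValueError("negative probabilities in spec")
    total = w.sum()
    if total <= 0:
        raise ValueError("spec probabilities are not normalizable")
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0x7155]))
    draws = rng.multinomial(n_cells, (w / total).ravel()).reshape(w.shape)
    rows = []
    i = 0
    for r, ct in enumerate(spec.index):
        for c, tis in enumerate(spec.columns):
            for _ in range(draws[r, c]):
                rows.append((f"c{i:06d}", "sim", str(ct), str(tis)))
                i += 1
    return pd.DataFrame(rows, columns=["cell_id", "sample_id", "cell_type", "tissue"])
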