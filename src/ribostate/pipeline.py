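"""End-to-end orchestration: discovery and application pipelines.

``run_discovery_pipeline`` derives the ribosomal-state metagene signature
from raw counts: QC → normalize/HVG → reference signature scoring →
per-sample NMF rank sweep → program–reference correlation → mean-maxed
selection → profile clustering → metagene / anti-signature assembly.
``run_scoring_pipeline`` applies a derived signature to new data: per-cell
scores, optional tissue prevalence (Ro/e) and survival stratification.

A single global seed fans out to per-stage seeds via stable hashing of
the stage name, so any stage can be re-run in isolation reproducibly.
Every artifact directory receives the exact config used (audit trail).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .datamodel import (
    ExpressionMatrix,
    QCConfig,
    normalize_and_select_hvgs,
    qc_filter_cells,
    scale_genes,
    validate_cell_meta,
    write_gene_sets,
)
from .metagene import (
    AntiSignature,
    MetageneSignature,
    assemble_anti_signature,
    assemble_metagene_signature,
    gene_frequency_table,
)
from .nmf import NMFConfig, ProgramCatalog, rank_sweep
from .prevalence import RoeTable, roe_table
from .scoring import ScoreMatrix, UCellConfig, ucell_scores
from .selection import (
    SelectionConfig,
    cluster_program_profiles,
    correlate_programs,
    pick_ribosome_and_anti_clusters,
    profiles_to_frame,
    select_mean_maxed,
)
from .survival import CutoffScanResult, SurvivalTable, optimal_cutoff_scan

_log = logging.getLogger("ribostate.pipeline")


def stage_seed(global_seed: int, stage: str) -> int:
    """Derive a deterministic per-stage seed (< 2**31) from the global one."""
    digest = hashlib.blake2s(f"{global_seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "little") % (2 ** 31)


@dataclass
class PipelineConfig:
    """Tunable knobs of the discovery pipeline, serialized with every run."""

    qc: QCConfig = field(default_factory=QCConfig)
    scale_factor: float = 1e4
    n_hvgs: int = 2000
    nmf: NMFConfig = field(default_factory=NMFConfig)
    selection: SelectionConfig = field(default_factory=SelectionConfig)
    ucell: UCellConfig = field(default_factory=UCellConfig)
    n_clusters: int = 3
    metagene_min_frequency: int = 10
    anti_min_frequency: int = 3
    seed: int = 0

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclass
class DiscoveryResult:
    signature: MetageneSignature | None
    anti_signature: AntiSignature | None
    catalog: ProgramCatalog
    profiles: list
    mean_maxed: dict
    cluster_result: object
    ribosome_programs: list
    anti_programs: list
    stage_log: dict


def _persist_discovery(out_dir: Path, cfg: PipelineConfig, res: DiscoveryResult) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    (out_dir / "config.json").write_text(json.dumps(cfg.to_dict(), indent=1, sort_keys=True))
    if res.signature is not None:
        write_gene_sets(
            [res.signature.as_gene_set(), res.anti_signature.as_gene_set()],
            out_dir / "signatures.gmt",
        )
        res.signature.to_frame().to_csv(out_dir / "metagene_signature.csv", index=False)
        res.anti_signature.to_frame().to_csv(out_dir / "anti_signature.csv", index=False)
    profiles_to_frame(res.profiles).to_csv(out_dir / "correlation_profiles.csv", index=False)
    pd.DataFrame(
        [
            {
                "sample_id": sid,
                "rank": p.program_ref[1],
                "index_in_rank": p.program_ref[2],
                "R_mean": p.mean_correlation,
            }
            for sid, p in sorted(res.mean_maxed.items())
        ]
    ).to_csv(out_dir / "mean_maxed_programs.csv", index=False)
    (out_dir / "clusters.json").write_text(res.cluster_result.to_json())
    (out_dir / "stage_log.json").write_text(json.dumps(res.stage_log, indent=1, sort_keys=True))


def run_discovery_pipeline(
    counts: ExpressionMatrix,
    meta: pd.DataFrame,
    reference_sets: Sequence,
    cfg: PipelineConfig | None = None,
    out_dir=None,
) -> DiscoveryResult:
    """Derive the metagene and anti signatures from raw counts.

    ``meta`` must map every cell to a sample_id.  ``reference_sets`` are
    the K reference ribosome gene sets the programs are correlated with.
    """
    cfg = cfg or PipelineConfig()
    validate_cell_meta(meta, counts)
    log: dict = {"n_cells_input": counts.n_cells, "n_genes": counts.n_genes}

    stage = "qc"
    try:
        filtered, qc_report = qc_filter_cells(counts, cfg.qc)
        log["qc"] = qc_report
        meta_f = meta[meta["cell_id"].isin(set(filtered.cell_ids))]

        stage = "normalize_hvg"
        lognorm_hvg, hvgs = normalize_and_select_hvgs(
            filtered, cfg.scale_factor, min(cfg.n_hvgs, filtered.n_genes)
        )
        log["n_hvgs"] = len(hvgs)

        # rank-based scores are invariant to the (monotone) log-normalization,
        # so reference scoring runs on the filtered counts over all genes
        stage = "reference_scoring"
        ref_scores = ucell_scores(filtered, list(reference_sets), cfg.ucell)
        log["n_reference_sets"] = len(reference_sets)

        stage = "rank_sweep"
        sample_of = dict(zip(meta_f["cell_id"], meta_f["sample_id"]))
        cell_samples = np.array([sample_of[c] for c in lognorm_hvg.cell_ids])
        programs = []
        samples_run = []
        for sid in sorted(set(cell_samples)):
            # per-sample gene scaling (clipped at 0) so components capture
            # above-average co-expression, not absolute abundance
            sub = scale_genes(
                lognorm_hvg.subset_cells(cell_samples == sid), clip_negative=True
            )
            nmf_cfg = replace(cfg.nmf, seed=stage_seed(cfg.seed, f"nmf:{sid}"))
            prog = rank_sweep(sub, nmf_cfg, sample_id=str(sid))
            if prog:
                samples_run.append(str(sid))
            programs.extend(prog)
        catalog = ProgramCatalog(programs, cfg.nmf)
        log["samples_run"] = samples_run
        log["n_programs"] = len(programs)
        if not programs:
            raise ValueError("no sample passed the minimum-cell filter")

        stage = "correlation_selection"
        profiles = correlate_programs(catalog, ref_scores)
        mean_maxed = select_mean_maxed(profiles, catalog, cfg.selection)
        log["n_mean_maxed"] = len(mean_maxed)
        log["mean_maxed"] = {
            sid: {"rank": p.program_ref[1], "index": p.program_ref[2],
                  "R_mean": round(p.mean_correlation, 4)}
            for sid, p in sorted(mean_maxed.items())
        }

        stage = "clustering"
        cluster_result = cluster_program_profiles(profiles, cfg.n_clusters)
        log["cluster_sizes"] = {
            str(c): sum(1 for v in cluster_result.labels.values() if v == c)
            for c in sorted(set(cluster_result.labels.values()))
        }

        stage = "assembly"
        signature = anti_signature = None
        ribo_refs: list = []
        anti_refs: list = []
        if not mean_maxed:
            # a null dataset legitimately selects nothing; the run completes
            # with the counts on record instead of aborting
            log["degenerate"] = "no mean-maxed programs selected"
            _log.warning("no mean-maxed programs; signatures not assembled")
        else:
            ribo_refs, anti_refs = pick_ribosome_and_anti_clusters(
                cluster_result, profiles, mean_maxed
            )
            by_ref = catalog.by_ref()
            ribo_lists = [by_ref[r].top_genes for r in ribo_refs]
            anti_lists = [by_ref[r].top_genes for r in anti_refs]
            freq = gene_frequency_table(ribo_lists)
            if max(freq.values()) < cfg.metagene_min_frequency:
                log["degenerate"] = (
                    f"no gene reaches frequency {cfg.metagene_min_frequency} "
                    f"(max {max(freq.values())})"
                )
                _log.warning("%s; signatures not assembled", log["degenerate"])
            else:
                signature = assemble_metagene_signature(
                    freq, cfg.metagene_min_frequency, source_program_count=len(ribo_lists)
                )
                anti_freq = gene_frequency_table(anti_lists)
                anti_signature = assemble_anti_signature(
                    anti_freq, signature, cfg.anti_min_frequency
                )
                log["n_metagenes"] = len(signature.genes)
                log["n_anti_genes"] = len(anti_signature.genes)
    except Exception as err:
        raise RuntimeError(f"discovery pipeline failed at stage {stage!r}: {err}") from err

    result = DiscoveryResult(
        signature=signature,
        anti_signature=anti_signature,
        catalog=catalog,
        profiles=profiles,
        mean_maxed=mean_maxed,
        cluster_result=cluster_result,
        ribosome_programs=ribo_refs,
        anti_programs=anti_refs,
        stage_log=log,
    )
    if out_dir is not None:
        _persist_discovery(Path(out_dir), cfg, result)
    return result


@dataclass
class ScoringResult:
    scores: ScoreMatrix
    roe: RoeTable | None
    scan: CutoffScanResult | None


def run_scoring_pipeline(
    signature: MetageneSignature,
    matrix: ExpressionMatrix,
    meta: pd.DataFrame | None = None,
    type_field: str | None = None,
    condition_field: str | None = None,
    survival: SurvivalTable | None = None,
    ucell_cfg: UCellConfig | None = None,
    out_dir=None,
) -> ScoringResult:
    """Score cells with a derived signature; optional Ro/e and survival scan."""
    scores = ucell_scores(matrix, [signature.as_gene_set()], ucell_cfg)
    roe = None
    if type_field or condition_field:
        if meta is None or not (type_field and condition_field):
            raise ValueError(
                "Ro/e needs metadata plus both type_field and condition_field"
            )
        roe = roe_table(meta, type_field, condition_field)
    scan = optimal_cutoff_scan(survival) if survival is not None else None
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        scores.to_frame().to_csv(out / "cell_scores.csv")
        if roe is not None:
            roe.observed.to_csv(out / "roe_observed.csv")
            roe.expected.to_csv(out / "roe_expected.csv")
            roe.roe.to_csv(out / "roe.csv")
        if scan is not None:
            scan.scanned.to_csv(out / "cutoff_scan.csv", index=False)
    return ScoringResult(scores=scores, roe=roe, scan=scan)
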