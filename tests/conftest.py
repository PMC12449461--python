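"""Shared fixtures: the expensive end-to-end discovery runs are session-scoped
so recovery, selection and null-calibration tests reuse a single pipeline
execution."""

import pytest

import ribostate as rs

SESSION_SEED = 11


def jaccard(a, b) -> float:
    a, b = set(a), set(b)
    return len(a & b) / len(a | b)


def match_program_to_truth(catalog, truth_genes):
    """Per sample, the program whose top-gene list best overlaps a planted set."""
    best = {}
    for p in catalog.programs:
        ov = len(set(p.top_genes) & set(truth_genes))
        if p.sample_id not in best or ov > best[p.sample_id][1]:
            best[p.sample_id] = (p, ov)
    return {s: p for s, (p, _) in best.items()}


@pytest.fixture(scope="session")
def default_sim():
    """Default synthetic preset: 5 samples × 1,000 cells × 2,000 genes."""
    cfg = rs.SimConfig(seed=SESSION_SEED)
    matrix, meta, truth = rs.simulate_multitumor_scrna(cfg)
    return cfg, matrix, meta, truth


@pytest.fixture(scope="session")
def default_discovery(default_sim):
    """Full discovery pipeline on the default preset (the heavy fixture)."""
    _, matrix, meta, truth = default_sim
    result = rs.run_discovery_pipeline(
        matrix, meta, truth.reference_sets, rs.PipelineConfig(seed=SESSION_SEED)
    )
    return matrix, meta, truth, result


@pytest.fixture(scope="session")
def null_discovery():
    """Discovery pipeline on data with no planted correlation (reduced size)."""
    cfg = rs.null_config(
        seed=SESSION_SEED, n_samples=3, cells_per_sample=1000, n_genes=1000
    )
    matrix, meta, truth = rs.simulate_multitumor_scrna(cfg)
    pcfg = rs.PipelineConfig(
        seed=SESSION_SEED, nmf=rs.NMFConfig(ranks=range(2, 7)), n_hvgs=1000
    )
    result = rs.run_discovery_pipeline(matrix, meta, truth.reference_sets, pcfg)
    return matrix, meta, truth, result
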