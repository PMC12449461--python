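"""Correlation profiles, mean-maxed selection and program clustering."""

import numpy as np
import pytest

import ribostate as rs
from ribostate.nmf import Program
from conftest import match_program_to_truth


def make_program(sample, rank, index, cell_scores, fraction, cell_ids):
    n_genes = 5
    return Program(
        sample_id=sample,
        rank=rank,
        index_in_rank=index,
        gene_coefficients=np.ones(n_genes),
        cell_scores=np.asarray(cell_scores, dtype=float),
        cell_fraction=fraction,
        top_genes=[f"g{j}" for j in range(n_genes)],
        gene_ids=[f"g{j}" for j in range(n_genes)],
        cell_ids=cell_ids,
    )


def make_profile(ref, correlations):
    return rs.CorrelationProfile(ref, np.asarray(correlations, dtype=float),
                                 [f"R{k}" for k in range(len(correlations))])


class TestCorrelate:
    def test_exact_match_gives_r_one(self):
        rng = np.random.default_rng(0)
        cells = [f"c{i}" for i in range(50)]
        ref_col = rng.uniform(0, 1, size=50)
        scores = rs.ScoreMatrix(ref_col[:, None], cells, ["R0"])
        prog = make_program("S", 2, 0, ref_col, 0.5, cells)
        catalog = rs.ProgramCatalog([prog], rs.NMFConfig())
        profiles = rs.correlate_programs(catalog, scores)
        assert profiles[0].correlations[0] == pytest.approx(1.0, abs=1e-12)
        assert profiles[0].mean_correlation == pytest.approx(1.0, abs=1e-12)

    def test_zero_variance_program_gets_zero_with_warning(self, caplog):
        cells = [f"c{i}" for i in range(10)]
        scores = rs.ScoreMatrix(np.random.default_rng(1).uniform(size=(10, 2)),
                                cells, ["R0", "R1"])
        prog = make_program("S", 2, 0, np.ones(10), 0.5, cells)
        catalog = rs.ProgramCatalog([prog], rs.NMFConfig())
        with caplog.at_level("WARNING"):
            profiles = rs.correlate_programs(catalog, scores)
        assert np.array_equal(profiles[0].correlations, [0.0, 0.0])
        assert any("zero-variance" in r.message for r in caplog.records)

    def test_null_programs_rarely_exceed_rmean_threshold(self):
        """Independent program scores vs 5 references at 1,000 cells:
        |R_mean| < 0.1 in at least 95 of 100 replicates."""
        rng = np.random.default_rng(2)
        cells = [f"c{i}" for i in range(1000)]
        ref = rs.ScoreMatrix(rng.uniform(size=(1000, 5)), cells,
                             [f"R{k}" for k in range(5)])
        programs = [
            make_program("S", 100, k, rng.lognormal(0, 1, size=1000), 0.5, cells)
            for k in range(100)
        ]
        catalog = rs.ProgramCatalog(programs, rs.NMFConfig())
        profiles = rs.correlate_programs(catalog, ref)
        ok = sum(abs(p.mean_correlation) < 0.1 for p in profiles)
        assert ok >= 95

    def test_planted_ribo_program_has_top_rmean(self, default_discovery):
        _, _, truth, result = default_discovery
        prof_by_ref = {p.program_ref: p for p in result.profiles}
        ribo_matched = match_program_to_truth(
            result.catalog, truth.program_genes[truth.ribo_program]
        )
        for name, genes in truth.program_genes.items():
            if name == truth.ribo_program:
                continue
            other = match_program_to_truth(result.catalog, genes)
            for sid in ribo_matched:
                assert (
                    prof_by_ref[ribo_matched[sid].ref].mean_correlation
                    > prof_by_ref[other[sid].ref].mean_correlation
                )


class TestSelect:
    def _fixture_catalog(self):
        cells = [f"c{i}" for i in range(4)]
        fractions = [0.5, 0.4, 0.1]
        programs = [
            make_program("T", 3, k, np.arange(4) + k, fractions[k], cells)
            for k in range(3)
        ]
        return rs.ProgramCatalog(programs, rs.NMFConfig())

    def test_both_criteria_hand_fixture(self):
        """Rank 3 with fractions [0.5, 0.4, 0.1]: two programs exceed 10%, so
        all three are candidates; R_means [0.05, 0.30, 0.60] -> index 2 wins."""
        catalog = self._fixture_catalog()
        profiles = [
            make_profile(("T", 3, 0), [0.05] * 5),
            make_profile(("T", 3, 1), [0.30] * 5),
            make_profile(("T", 3, 2), [0.60] * 5),
        ]
        selected = rs.select_mean_maxed(profiles, catalog)
        assert selected["T"].program_ref == ("T", 3, 2)
        assert selected["T"].mean_correlation == pytest.approx(0.60)

    def test_no_selection_when_all_rmeans_below_threshold(self):
        catalog = self._fixture_catalog()
        profiles = [make_profile(("T", 3, k), [0.1] * 5) for k in range(3)]
        assert rs.select_mean_maxed(profiles, catalog) == {}

    def test_dominant_rank_contributes_no_candidates(self):
        cells = [f"c{i}" for i in range(4)]
        fractions = [0.95, 0.03, 0.02]
        programs = [
            make_program("T", 3, k, np.arange(4) + k, fractions[k], cells)
            for k in range(3)
        ]
        catalog = rs.ProgramCatalog(programs, rs.NMFConfig())
        profiles = [make_profile(("T", 3, k), [0.9] * 5) for k in range(3)]
        assert rs.select_mean_maxed(profiles, catalog) == {}

    def test_selected_programs_satisfy_both_criteria(self, default_discovery):
        _, _, _, result = default_discovery
        cfg = rs.SelectionConfig()
        frac_by_key = {}
        for p in result.catalog.programs:
            key = (p.sample_id, p.rank)
            frac_by_key.setdefault(key, []).append(p.cell_fraction)
        assert len(result.mean_maxed) <= 5
        for sid, prof in result.mean_maxed.items():
            assert prof.mean_correlation > cfg.min_mean_correlation
            fracs = frac_by_key[(sid, prof.program_ref[1])]
            assert sum(f > cfg.min_cell_fraction for f in fracs) >= 2

    def test_empty_catalog_is_error(self):
        with pytest.raises(ValueError, match="empty"):
            rs.select_mean_maxed([], rs.ProgramCatalog([], rs.NMFConfig()))


class TestClustering:
    def _two_group_profiles(self, rng):
        profs = []
        for i in range(10):
            base = 0.8 if i < 5 else -0.8
            profs.append(make_profile(("S", 2 + i, 0),
                                      base + rng.uniform(-0.01, 0.01, size=5)))
        return profs

    def test_recovers_construction_groups(self):
        profs = self._two_group_profiles(np.random.default_rng(3))
        result = rs.cluster_program_profiles(profs, n_clusters=2)
        labels = [result.labels[p.program_ref] for p in profs]
        assert len(set(labels[:5])) == 1 and len(set(labels[5:])) == 1
        assert labels[0] != labels[5]

    def test_identical_vectors_cannot_split(self):
        profs = [make_profile(("S", 2 + i, 0), [0.5] * 5) for i in range(4)]
        with pytest.raises(ValueError, match="distinct clusters"):
            rs.cluster_program_profiles(profs, n_clusters=2)
        one = rs.cluster_program_profiles(profs, n_clusters=1)
        assert set(one.labels.values()) == {1}

    def test_permutation_invariance(self):
        rng = np.random.default_rng(4)
        profs = self._two_group_profiles(rng)
        r1 = rs.cluster_program_profiles(profs, 2)
        perm = [profs[i] for i in rng.permutation(len(profs))]
        r2 = rs.cluster_program_profiles(perm, 2)
        part1 = {frozenset(r1.members(c)) for c in set(r1.labels.values())}
        part2 = {frozenset(r2.members(c)) for c in set(r2.labels.values())}
        assert part1 == part2

    def test_too_many_clusters_is_error(self):
        profs = [make_profile(("S", 2, 0), [0.1] * 5)]
        with pytest.raises(ValueError):
            rs.cluster_program_profiles(profs, 2)


class TestPickClusters:
    def test_extreme_means_define_ribo_and_anti(self):
        rng = np.random.default_rng(5)
        profs, mm = [], {}
        for i, base in enumerate([0.5, 0.0, -0.4]):
            for j in range(3):
                p = make_profile(("S", 2 + i, j), base + rng.uniform(-0.01, 0.01, 5))
                profs.append(p)
        mm["S"] = profs[0]
        result = rs.cluster_program_profiles(profs, 3)
        ribo, anti = rs.pick_ribosome_and_anti_clusters(result, profs, mm)
        by_ref = {p.program_ref: p for p in profs}
        assert all(by_ref[r].mean_correlation > 0.4 for r in ribo)
        assert all(by_ref[r].mean_correlation < -0.3 for r in anti)

    def test_single_cluster_cannot_supply_both(self):
        profs = [make_profile(("S", 2, j), [0.2 + 0.001 * j] * 5) for j in range(3)]
        result = rs.cluster_program_profiles(profs, 1)
        with pytest.raises(ValueError, match="coincide"):
            rs.pick_ribosome_and_anti_clusters(result, profs, {"S": profs[0]})

    def test_planted_program_lands_in_ribosome_cluster(self, default_discovery):
        _, _, truth, result = default_discovery
        matched = match_program_to_truth(
            result.catalog, truth.program_genes[truth.ribo_program]
        )
        ribo = set(result.ribosome_programs)
        for sid, prog in matched.items():
            assert prog.ref in ribo

    def test_membership_stable_without_small_cell_programs(self, default_discovery):
        """Mean-maxed programs stay in the top cluster when programs covering
        <=10% of cells are excluded and the clustering repeated."""
        _, _, _, result = default_discovery
        frac = {p.ref: p.cell_fraction for p in result.catalog.programs}
        kept = [p for p in result.profiles if frac[p.program_ref] > 0.10]
        reclustered = rs.cluster_program_profiles(kept, 3)
        mm = {sid: p for sid, p in result.mean_maxed.items()
              if frac[p.program_ref] > 0.10}
        if not mm:
            pytest.skip("all mean-maxed programs cover <=10% of cells")
        ribo, _ = rs.pick_ribosome_and_anti_clusters(reclustered, kept, mm)
        assert {p.program_ref for p in mm.values()} <= set(ribo)
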