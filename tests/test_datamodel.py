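"""Loading, validation, QC filtering and normalization of expression data."""

import numpy as np
import pytest
import scipy.sparse as sp

import ribostate as rs
from ribostate.datamodel import scale_genes


def toy_matrix(values, layer="counts", prefix=""):
    values = np.asarray(values)
    cells = [f"{prefix}c{i}" for i in range(values.shape[0])]
    genes = [f"{prefix}g{j}" for j in range(values.shape[1])]
    return rs.ExpressionMatrix(values, cells, genes, layer_tag=layer)


class TestExpressionMatrix:
    def test_duplicate_ids_rejected(self):
        with pytest.raises(ValueError, match="duplicate gene"):
            rs.ExpressionMatrix(np.zeros((2, 2)), ["a", "b"], ["g", "g"])
        with pytest.raises(ValueError, match="duplicate cell"):
            rs.ExpressionMatrix(np.zeros((2, 2)), ["a", "a"], ["g", "h"])

    def test_counts_must_be_nonneg_integers(self):
        with pytest.raises(ValueError, match="integer"):
            toy_matrix([[0.5, 1.0]])
        with pytest.raises(ValueError, match="negative"):
            toy_matrix([[-1, 1]])

    def test_shape_mismatch(self):
        with pytest.raises(ValueError, match="shape"):
            rs.ExpressionMatrix(np.zeros((2, 3)), ["a", "b"], ["g1", "g2"])


class TestLoaders:
    def test_mtx_roundtrip(self, tmp_path):
        m = toy_matrix([[1, 0, 2, 0], [0, 3, 0, 0], [4, 0, 0, 5]])
        rs.save_counts(m, tmp_path / "mtx", format="mtx_dir")
        back = rs.load_counts(tmp_path / "mtx", format="mtx_dir")
        assert back.values.shape == (3, 4)
        assert back.values.sum() == m.values.sum() == 15
        assert np.array_equal(back.dense(), m.dense())
        assert back.cell_ids == m.cell_ids and back.gene_ids == m.gene_ids

    def test_csv_roundtrip_both_orientations(self, tmp_path):
        m = toy_matrix([[1, 2], [3, 4], [5, 6]])
        rs.save_counts(m, tmp_path / "m.csv", format="csv")
        rows = rs.load_counts(tmp_path / "m.csv", format="csv", cells_as="rows")
        assert np.array_equal(rows.dense(), m.dense())
        cols = rs.load_counts(tmp_path / "m.csv", format="csv", cells_as="cols")
        assert np.array_equal(cols.dense(), m.dense().T)

    def test_csv_duplicate_gene_named_in_error(self, tmp_path):
        (tmp_path / "dup.csv").write_text("id,GENEX,GENEX\nc1,1,2\n")
        with pytest.raises(ValueError, match="GENEX"):
            rs.load_counts(tmp_path / "dup.csv", format="csv")

    def test_missing_sidecar(self, tmp_path):
        (tmp_path / "partial").mkdir()
        (tmp_path / "partial" / "matrix.mtx").write_text("")
        with pytest.raises(FileNotFoundError, match="barcodes"):
            rs.load_counts(tmp_path / "partial", format="mtx_dir")

    def test_sim_written_matrix_reloads_identically(self, tmp_path):
        cfg = rs.SimConfig(n_samples=1, cells_per_sample=30, n_genes=120,
                           planted_programs=(rs.ProgramSpec(tuple(range(20))),),
                           seed=3)
        m, _, _ = rs.simulate_multitumor_scrna(cfg)
        rs.save_counts(m, tmp_path / "sim", format="mtx_dir")
        back = rs.load_counts(tmp_path / "sim", format="mtx_dir")
        assert np.array_equal(back.dense(), m.dense())


class TestGeneSets:
    def test_gmt_parsing(self, tmp_path):
        lines = ["RIBO\tdesc\tA\tB\tC"] + [f"S{i}\td\tG{i}" for i in range(4)]
        (tmp_path / "sets.gmt").write_text("\n".join(lines) + "\n")
        sets = rs.read_gene_sets(tmp_path / "sets.gmt")
        assert len(sets) == 5
        assert sets[0].name == "RIBO" and sets[0].genes == {"A", "B", "C"}

    def test_gmt_duplicate_gene_deduplicated(self, tmp_path, caplog):
        (tmp_path / "d.gmt").write_text("S\tdesc\tA\tA\n")
        with caplog.at_level("WARNING"):
            sets = rs.read_gene_sets(tmp_path / "d.gmt")
        assert sets[0].genes == {"A"}
        assert any("duplicate" in r.message for r in caplog.records)

    @pytest.mark.parametrize("line", ["NAME\tdesc", "NAME\tdesc\t\t"])
    def test_gmt_malformed_lines(self, tmp_path, line):
        (tmp_path / "bad.gmt").write_text(line + "\n")
        with pytest.raises(ValueError):
            rs.read_gene_sets(tmp_path / "bad.gmt")

    def test_gmt_write_read_roundtrip(self, tmp_path):
        sets = [rs.GeneSet("X", frozenset("ABC")), rs.GeneSet("Y", frozenset("DE"))]
        rs.write_gene_sets(sets, tmp_path / "rt.gmt")
        back = rs.read_gene_sets(tmp_path / "rt.gmt")
        assert {(s.name, s.genes) for s in back} == {(s.name, s.genes) for s in sets}


class TestQC:
    def _matrix_with_detected(self, detected_counts, n_genes=250):
        rows = []
        for d in detected_counts:
            row = np.zeros(n_genes, dtype=int)
            row[:d] = 1
            rows.append(row)
        return toy_matrix(rows)

    def test_200_gene_rule_is_strict(self):
        m = self._matrix_with_detected([199, 200, 201])
        out, report = rs.qc_filter_cells(m, rs.QCConfig(min_genes_per_cell=200))
        assert out.cell_ids == ["c1", "c2"]  # 199 removed, boundary 200 kept
        assert report["removed_min_genes_per_cell"] == 1
        assert out.gene_ids == m.gene_ids

    def test_idempotent(self):
        m = self._matrix_with_detected([150, 220, 260])
        once, _ = rs.qc_filter_cells(m)
        twice, rep = rs.qc_filter_cells(once)
        assert rep["n_cells_removed"] == 0
        assert twice.cell_ids == once.cell_ids

    def test_mito_fraction_filter(self):
        vals = np.array([[100, 100], [10, 190]])
        m = rs.ExpressionMatrix(vals, ["a", "b"], ["MT-CO1", "ACTB"])
        out, rep = rs.qc_filter_cells(
            m, rs.QCConfig(min_genes_per_cell=0, max_mito_fraction=0.2)
        )
        assert out.cell_ids == ["b"]
        assert rep["removed_max_mito_fraction"] == 1

    def test_all_cells_removed_is_error(self):
        m = self._matrix_with_detected([10, 20])
        with pytest.raises(ValueError, match="every cell"):
            rs.qc_filter_cells(m, rs.QCConfig(min_genes_per_cell=200))

    def test_planted_low_quality_cells_are_the_removed_ones(self):
        cfg = rs.SimConfig(
            n_samples=1, cells_per_sample=500, n_genes=2000,
            low_quality_fraction=0.1, seed=5,
        )
        m, meta, truth = rs.simulate_multitumor_scrna(cfg)
        out, report = rs.qc_filter_cells(m, rs.QCConfig(min_genes_per_cell=200,
                                                        max_mito_fraction=1.0))
        removed = set(m.cell_ids) - set(out.cell_ids)
        assert removed == set(truth.low_quality_cells)
        assert report["n_cells_removed"] == 50


class TestNormalization:
    def test_identity_when_sum_equals_scale_factor(self):
        m = toy_matrix([[2, 2, 6]])
        out = rs.normalize_log1p(m, scale_factor=10)
        assert np.allclose(out.dense(), np.log1p([2, 2, 6]))
        assert out.layer_tag == "lognorm"

    def test_identical_cells_normalize_identically(self):
        m = toy_matrix([[1, 4, 5], [1, 4, 5]])
        out = rs.normalize_log1p(m)
        assert np.array_equal(out.dense()[0], out.dense()[1])

    def test_prelog_sums_equal_scale_factor(self):
        rng = np.random.default_rng(0)
        m = toy_matrix(rng.poisson(2.0, size=(40, 30)) + 1)
        out = rs.normalize_log1p(m, scale_factor=1e4)
        sums = np.expm1(out.dense()).sum(axis=1)
        assert np.allclose(sums, 1e4, rtol=1e-9)

    def test_zero_count_cell_rejected(self):
        m = toy_matrix([[0, 0], [1, 2]])
        with pytest.raises(ValueError, match="zero total"):
            rs.normalize_log1p(m)

    def test_high_variance_gene_ranked_first(self):
        rng = np.random.default_rng(1)
        base = rng.poisson(5.0, size=(50, 10)) + 1
        base[:, 3] = np.where(np.arange(50) % 2 == 0, 1, 300)  # 100x variance
        m = toy_matrix(base)
        lognorm = rs.normalize_log1p(m)
        hvgs = rs.select_hvgs(lognorm, n_hvgs=3)
        assert hvgs[0] == "g3"

    def test_hvg_bounds(self):
        m = toy_matrix([[1, 2], [3, 4]])
        with pytest.raises(ValueError):
            rs.select_hvgs(rs.normalize_log1p(m), n_hvgs=5)
        with pytest.raises(ValueError):
            rs.select_hvgs(rs.normalize_log1p(m), n_hvgs=0)

    def test_scale_genes_centers_and_clips(self):
        m = toy_matrix([[1, 10], [2, 20], [3, 30]], layer="lognorm")
        z = scale_genes(m)
        assert np.allclose(z.dense().mean(axis=0), 0.0)
        assert np.allclose(z.dense().std(axis=0), 1.0)
        clipped = scale_genes(m, clip_negative=True)
        assert clipped.dense().min() >= 0.0
        assert clipped.layer_tag == "scaled"
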