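import numpy as np
import pandas as pd
import pytest

import cascadefit as cf
from cascadefit.dataio import read_count_matrix, read_pseudotime


def _write_mtx(tmp_path, entries, shape, genes, cells):
    lines = ["%%MatrixMarket matrix coordinate integer general",
             f"{shape[0]} {shape[1]} {len(entries)}"]
    lines += [f"{r} {c} {v}" for r, c, v in entries]
    (tmp_path / "m.mtx").write_text("\n".join(lines) + "\n")
    (tmp_path / "genes.txt").write_text("\n".join(genes) + "\n")
    (tmp_path / "cells.txt").write_text("\n".join(cells) + "\n")
    return tmp_path / "m.mtx", tmp_path / "genes.txt", tmp_path / "cells.txt"


class TestReadCountMatrix:
    def test_zero_tsv(self, tmp_path):
        df = pd.DataFrame(np.zeros((3, 4), dtype=int),
                          index=["g1", "g2", "g3"],
                          columns=["c1", "c2", "c3", "c4"])
        path = tmp_path / "m.tsv"
        df.to_csv(path, sep="\t")
        cm = read_count_matrix(path)
        assert cm.shape == (3, 4)
        assert np.all(cm.counts == 0)
        assert cm.gene_ids == ["g1", "g2", "g3"]

    def test_mtx_coordinate_expansion(self, tmp_path):
        paths = _write_mtx(tmp_path, [(1, 1, 5), (2, 3, 2)], (2, 3),
                           ["gA", "gB"], ["c1", "c2", "c3"])
        cm = read_count_matrix(*paths)
        assert np.array_equal(cm.counts, [[5, 0, 0], [0, 0, 2]])

    def test_mtx_duplicate_entries_summed(self, tmp_path):
        # naive-sum oracle over the coordinate list: 2 + 3 = 5 at (1,1)
        paths = _write_mtx(tmp_path, [(1, 1, 2), (1, 1, 3)], (2, 3),
                           ["gA", "gB"], ["c1", "c2", "c3"])
        cm = read_count_matrix(*paths)
        assert cm.counts[0, 0] == 5

    def test_orientation_autodetect_transposed(self, tmp_path):
        # matrix stored cells x genes; gene sidecar matches the column count
        paths = _write_mtx(tmp_path, [(1, 2, 7)], (3, 2),
                           ["gA", "gB"], ["c1", "c2", "c3"])
        cm = read_count_matrix(*paths)
        assert cm.shape == (2, 3)
        assert cm.counts[1, 0] == 7

    def test_sidecar_mismatch_raises(self, tmp_path):
        paths = _write_mtx(tmp_path, [(1, 1, 1)], (2, 3),
                           ["gA"], ["c1", "c2"])
        with pytest.raises(ValueError, match="sidecar"):
            read_count_matrix(*paths)

    def test_negative_entry_rejected(self, tmp_path):
        df = pd.DataFrame([[1, -2]], index=["g"], columns=["c1", "c2"])
        path = tmp_path / "m.tsv"
        df.to_csv(path, sep="\t")
        with pytest.raises(ValueError, match="negative"):
            read_count_matrix(path)


class TestBuildTrajectory:
    def _cm(self, counts, cells):
        genes = [f"g{i}" for i in range(counts.shape[0])]
        return cf.CountMatrix(genes, cells, counts)

    def test_sorts_by_pseudotime(self):
        counts = np.arange(1, 31).reshape(3, 10)
        cells = [f"c{i}" for i in range(10)]
        cm = self._cm(counts, cells)
        ptv = np.array([0.9, 0.1, 0.5, 0.2, 0.3, 0.4, 0.6, 0.7, 0.8, 0.05])
        td = cf.build_trajectory(cm, cf.PseudotimeOrdering(cells, ptv))
        assert td.cell_ids[:3] == ["c9", "c1", "c3"]
        assert td.cell_ids[-1] == "c0"

    def test_median_size_factor(self):
        # column totals 100, 200, 300 plus padding cells -> median checks
        counts = np.array([[100, 200, 300, 1000, 150, 250, 120, 180, 220, 140]])
        cells = [f"c{i}" for i in range(10)]
        td = cf.build_trajectory(
            self._cm(counts, cells),
            cf.PseudotimeOrdering(cells, np.arange(10) / 10))
        assert td.size_factor == np.median(counts)
        assert np.array_equal(td.umi_totals, counts[0])

    def test_even_length_median_is_midpoint(self):
        counts = np.tile([[10, 20, 30, 100]], (1, 3))[:, :12]
        cells = [f"c{i}" for i in range(12)]
        td = cf.build_trajectory(
            self._cm(counts, cells),
            cf.PseudotimeOrdering(cells, np.arange(12) / 12))
        assert td.size_factor == np.median(counts[0])

    def test_ties_broken_by_cell_id(self):
        counts = np.ones((1, 10), dtype=int)
        cells = ["b", "a", "d", "c", "f", "e", "h", "g", "j", "i"]
        td = cf.build_trajectory(
            self._cm(counts, cells),
            cf.PseudotimeOrdering(cells, np.zeros(10)))
        assert td.cell_ids == sorted(cells)

    def test_unknown_cell_raises(self):
        counts = np.ones((1, 10), dtype=int)
        cells = [f"c{i}" for i in range(10)]
        pt = cf.PseudotimeOrdering(cells[:-1] + ["nope"], np.arange(10) / 10)
        with pytest.raises(ValueError, match="nope"):
            cf.build_trajectory(self._cm(counts, cells), pt)

    def test_too_few_cells_raises(self):
        counts = np.ones((1, 5), dtype=int)
        cells = [f"c{i}" for i in range(5)]
        with pytest.raises(ValueError, match="too few"):
            cf.build_trajectory(self._cm(counts, cells),
                                cf.PseudotimeOrdering(cells, np.arange(5.0)))

    def test_ingest_order_invariance(self):
        rng = np.random.default_rng(3)
        counts = rng.integers(1, 50, size=(4, 20))
        cells = [f"c{i:02d}" for i in range(20)]
        ptv = rng.random(20)
        td1 = cf.build_trajectory(
            cf.CountMatrix([f"g{i}" for i in range(4)], cells, counts),
            cf.PseudotimeOrdering(cells, ptv))
        perm = rng.permutation(20)
        td2 = cf.build_trajectory(
            cf.CountMatrix([f"g{i}" for i in range(4)],
                           [cells[i] for i in perm], counts[:, perm]),
            cf.PseudotimeOrdering(cells, ptv))
        assert td1.cell_ids == td2.cell_ids
        assert np.array_equal(td1.counts, td2.counts)
        assert td1.size_factor == td2.size_factor


class TestFilterGenes:
    def _td(self, counts):
        genes = [f"g{i}" for i in range(counts.shape[0])]
        cells = [f"c{i}" for i in range(counts.shape[1])]
        cm = cf.CountMatrix(genes, cells, counts)
        return cf.build_trajectory(
            cm, cf.PseudotimeOrdering(cells, np.arange(counts.shape[1]) / 10))

    def test_boundary_inclusive_at_one_percent(self):
        counts = np.ones((1, 100), dtype=int)
        sparse = np.zeros((1, 100), dtype=int)
        sparse[0, 0] = 1
        td = self._td(np.vstack([counts, sparse]))
        out = cf.filter_genes(td, 0.01)
        assert "g1" in out.gene_ids  # expressed in exactly 1% of cells

    def test_all_zero_gene_removed(self):
        counts = np.vstack([np.ones((1, 50), dtype=int),
                            np.zeros((1, 50), dtype=int)])
        td = self._td(counts)
        out = cf.filter_genes(td, 0.01)
        assert out.gene_ids == ["g0"]

    def test_threshold_zero_keeps_all(self):
        counts = np.vstack([np.ones((1, 50), dtype=int),
                            np.zeros((1, 50), dtype=int)])
        td = self._td(counts)
        assert cf.filter_genes(td, 0.0).gene_ids == ["g0", "g1"]

    def test_idempotent(self):
        rng = np.random.default_rng(0)
        counts = (rng.random((20, 60)) < 0.1).astype(int)
        counts[0, :] += 1  # avoid zero-total cells
        td = self._td(counts)
        once = cf.filter_genes(td, 0.05)
        twice = cf.filter_genes(once, 0.05)
        assert once.gene_ids == twice.gene_ids
        assert np.array_equal(once.counts, twice.counts)


class TestResultSerialization:
    def test_empty_results_header_only(self, tmp_path):
        summary = cf.write_fit_results([], tmp_path)
        assert len(summary) == 0
        text = (tmp_path / "summary.tsv").read_text()
        assert text.startswith("gene\t")

    def test_roundtrip_preserves_draws(self, tmp_path):
        from _utils import fake_fit_result, point_cloud

        res = fake_fit_result("gX", "sigmoidal",
                              point_cloud(100.0, n=50, seed=1)[:, None], [[1.0]])
        cf.write_fit_results([res], tmp_path, metadata={"seed": 1})
        back = cf.read_fit_results(tmp_path)
        assert len(back) == 1
        np.testing.assert_allclose(back[0].inflections.times,
                                   res.inflections.times, rtol=1e-12)
        assert back[0].family.name == "sigmoidal"

    def test_cardinality(self, tmp_path):
        from _utils import fake_fit_result

        res = [fake_fit_result(f"g{i}", "sigmoidal",
                               np.full((10, 1), 50.0 + i), [[1.0]])
               for i in range(2)]
        cf.write_fit_results(res, tmp_path)
        summary = pd.read_csv(tmp_path / "summary.tsv", sep="\t")
        assert len(summary) == 2
        assert (tmp_path / "g0_samples.tsv").exists()
        assert (tmp_path / "g1_samples.tsv").exists()


def test_read_pseudotime(tmp_path):
    pd.DataFrame({"cell_id": ["a", "b"], "pseudotime": [0.2, 0.1]}).to_csv(
        tmp_path / "pt.tsv", sep="\t", index=False)
    pt = read_pseudotime(tmp_path / "pt.tsv")
    assert pt.cell_ids == ["a", "b"]
    assert np.allclose(pt.pseudotime, [0.2, 0.1])
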