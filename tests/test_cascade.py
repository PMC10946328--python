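import numpy as np
import pytest
from hypothesis import given, strategies as st

import cascadefit as cf

from _utils import fake_fit_result, point_cloud


class TestInflectionOverlap:
    def test_identical_samples_overlap_one(self):
        a = point_cloud(100.0, n=500, seed=1)
        assert cf.inflection_overlap(a, a).overlap == pytest.approx(1.0)

    def test_disjoint_supports_overlap_zero(self):
        rng = np.random.default_rng(2)
        a = rng.uniform(10, 20, 300)
        b = rng.uniform(200, 300, 300)
        assert cf.inflection_overlap(a, b).overlap == 0.0

    def test_matches_bruteforce_histogram_intersection(self):
        rng = np.random.default_rng(3)
        a = rng.normal(100, 8, 700)
        b = rng.normal(112, 8, 900)
        est = cf.inflection_overlap(a, b)
        # independent brute force: count per bin with explicit loops
        lo, hi = min(a.min(), b.min()), max(a.max(), b.max())
        edges = [lo + (hi - lo) * i / 100 for i in range(101)]
        total = 0.0
        for i in range(100):
            left, right = edges[i], edges[i + 1]
            if i < 99:
                ca = sum(1 for x in a if left <= x < right)
                cb = sum(1 for x in b if left <= x < right)
            else:
                ca = sum(1 for x in a if left <= x <= right)
                cb = sum(1 for x in b if left <= x <= right)
            total += min(ca / len(a), cb / len(b))
        assert est.overlap == pytest.approx(total, abs=1e-12)

    def test_fractions_normalized(self):
        rng = np.random.default_rng(4)
        est = cf.inflection_overlap(rng.normal(50, 5, 400),
                                    rng.normal(55, 5, 300))
        assert est.p_a.sum() == pytest.approx(1.0, abs=1e-12)
        assert est.p_b.sum() == pytest.approx(1.0, abs=1e-12)

    def test_degenerate_range_is_one(self):
        assert cf.inflection_overlap([5.0, 5.0], [5.0]).overlap == 1.0

    def test_symmetry(self):
        rng = np.random.default_rng(5)
        a, b = rng.normal(10, 2, 200), rng.normal(12, 3, 150)
        assert cf.inflection_overlap(a, b).overlap == \
            cf.inflection_overlap(b, a).overlap

    @given(shift=st.floats(-1e4, 1e4))
    def test_shift_invariance(self, shift):
        rng = np.random.default_rng(6)
        a, b = rng.normal(10, 2, 200), rng.normal(12, 3, 150)
        base = cf.inflection_overlap(a, b).overlap
        shifted = cf.inflection_overlap(a + shift, b + shift).overlap
        assert shifted == pytest.approx(base, abs=1e-9)


def _pair(sign_a, sign_b, overlap):
    if overlap:
        a = fake_fit_result("A", "sigmoidal",
                            point_cloud(100.0, spread=5, seed=1)[:, None],
                            [[sign_a]])
        b = fake_fit_result("B", "sigmoidal",
                            point_cloud(102.0, spread=5, seed=2)[:, None],
                            [[sign_b]])
    else:
        a = fake_fit_result("A", "sigmoidal",
                            point_cloud(100.0, spread=2, seed=1)[:, None],
                            [[sign_a]])
        b = fake_fit_result("B", "sigmoidal",
                            point_cloud(200.0, spread=2, seed=2)[:, None],
                            [[sign_b]])
    return a, b


class TestInferInteraction:
    def test_sequential_activation(self):
        fwd, rev = cf.infer_interaction(*_pair(+1, +1, overlap=False))
        assert (fwd.relation, rev.relation) == ("positive", "none")

    def test_activation_then_repression(self):
        fwd, rev = cf.infer_interaction(*_pair(+1, -1, overlap=False))
        assert (fwd.relation, rev.relation) == ("negative", "positive")

    def test_sequential_repression(self):
        fwd, rev = cf.infer_interaction(*_pair(-1, -1, overlap=False))
        assert (fwd.relation, rev.relation) == ("positive", "none")

    def test_repression_then_activation_no_call(self):
        fwd, rev = cf.infer_interaction(*_pair(-1, +1, overlap=False))
        assert (fwd.relation, rev.relation) == ("none", "none")

    def test_simultaneous_same_sign_mutual_positive(self):
        fwd, rev = cf.infer_interaction(*_pair(+1, +1, overlap=True))
        assert fwd.relation == rev.relation == "mutual_positive"
        assert fwd.overlap >= 0.01

    def test_simultaneous_opposite_sign_mutual_negative(self):
        fwd, rev = cf.infer_interaction(*_pair(+1, -1, overlap=True))
        assert fwd.relation == rev.relation == "mutual_negative"

    def test_antisymmetric_in_argument_order(self):
        a, b = _pair(+1, -1, overlap=False)
        fwd, rev = cf.infer_interaction(a, b)
        rev2, fwd2 = cf.infer_interaction(b, a)
        assert (fwd.relation, rev.relation) == (fwd2.relation, rev2.relation)
        assert fwd.source == fwd2.source and fwd.target == fwd2.target

    def test_uniform_gene_rejected(self):
        u = fake_fit_result("U", "uniform", np.empty((10, 0)),
                            np.empty((1, 0)), dynamic_class="none")
        a, _ = _pair(+1, +1, overlap=False)
        with pytest.raises(ValueError, match="uniform"):
            cf.infer_interaction(u, a)


class TestOrderCascade:
    def test_sorted_by_first_inflection_median(self):
        res = [fake_fit_result("g1", "sigmoidal", np.full((20, 1), 300.0),
                               [[1.0]]),
               fake_fit_result("g2", "sigmoidal", np.full((20, 1), 100.0),
                               [[1.0]]),
               fake_fit_result("g3", "sigmoidal", np.full((20, 1), 200.0),
                               [[-1.0]])]
        order = cf.order_cascade(res)
        assert order.genes == ["g2", "g3", "g1"]
        assert np.all(np.diff(order.first_inflection_medians) >= 0)

    def test_uniform_genes_excluded(self):
        res = [fake_fit_result("g1", "sigmoidal", np.full((20, 1), 100.0),
                               [[1.0]]),
               fake_fit_result("u", "uniform", np.empty((10, 0)),
                               np.empty((1, 0)), dynamic_class="none")]
        assert cf.order_cascade(res).genes == ["g1"]

    def test_ties_broken_by_gene_id(self):
        res = [fake_fit_result(g, "sigmoidal", np.full((20, 1), 100.0),
                               [[1.0]]) for g in ("zz", "aa", "mm")]
        assert cf.order_cascade(res).genes == ["aa", "mm", "zz"]

    def test_output_is_permutation(self):
        rng = np.random.default_rng(8)
        res = [fake_fit_result(f"g{i}", "sigmoidal",
                               point_cloud(rng.uniform(50, 350), n=30,
                                           seed=i)[:, None], [[1.0]])
               for i in range(10)]
        order = cf.order_cascade(res)
        assert sorted(order.genes) == sorted(r.gene for r in res)

    def test_gaussian_first_locus_orders(self):
        # gaussian gene with loci (120, 180): ordered by the earlier one
        g = fake_fit_result("g", "gaussian",
                            np.tile([120.0, 180.0], (20, 1)), [[1.0, -1.0]])
        s = fake_fit_result("s", "sigmoidal", np.full((20, 1), 150.0),
                            [[1.0]])
        assert cf.order_cascade([g, s]).genes == ["g", "s"]


class TestScreenUpstreamRegulators:
    def _target(self):
        return fake_fit_result("T", "sigmoidal",
                               point_cloud(150.0, spread=2, seed=0)[:, None],
                               [[1.0]])

    def test_positive_before_target_included(self):
        cand = fake_fit_result("A", "sigmoidal",
                               point_cloud(100.0, spread=2, seed=1)[:, None],
                               [[1.0]])
        assert cf.screen_upstream_regulators(self._target(), [cand]) == ["A"]

    def test_positive_after_target_excluded(self):
        cand = fake_fit_result("A", "sigmoidal",
                               point_cloud(300.0, spread=2, seed=1)[:, None],
                               [[1.0]])
        assert cf.screen_upstream_regulators(self._target(), [cand]) == []

    def test_negative_after_target_included(self):
        cand = fake_fit_result("A", "sigmoidal",
                               point_cloud(300.0, spread=2, seed=1)[:, None],
                               [[-1.0]])
        assert cf.screen_upstream_regulators(self._target(), [cand]) == ["A"]

    def test_negative_before_target_excluded(self):
        cand = fake_fit_result("A", "sigmoidal",
                               point_cloud(100.0, spread=2, seed=1)[:, None],
                               [[-1.0]])
        assert cf.screen_upstream_regulators(self._target(), [cand]) == []

    def test_simultaneous_positive_included(self):
        cand = fake_fit_result("A", "sigmoidal",
                               point_cloud(151.0, spread=2, seed=1)[:, None],
                               [[1.0]])
        assert cf.screen_upstream_regulators(self._target(), [cand]) == ["A"]

    def test_coregulator_requires_transient_up(self):
        tgt = self._target()
        coreg_ok = fake_fit_result(
            "C1", "gaussian", np.tile([100.0, 140.0], (50, 1)),
            [[1.0, -1.0]])
        coreg_wrong_class = fake_fit_result(
            "C2", "sigmoidal", point_cloud(100.0, spread=2, seed=3)[:, None],
            [[1.0]])
        coreg_late = fake_fit_result(
            "C3", "gaussian", np.tile([300.0, 340.0], (50, 1)),
            [[1.0, -1.0]])
        hits = cf.screen_upstream_regulators(
            tgt, [coreg_ok, coreg_wrong_class, coreg_late],
            coregulator_ids={"C1", "C2", "C3"})
        assert hits == ["C1"]

    def test_uniform_target_rejected(self):
        u = fake_fit_result("U", "uniform", np.empty((10, 0)),
                            np.empty((1, 0)), dynamic_class="none")
        with pytest.raises(ValueError, match="uniform"):
            cf.screen_upstream_regulators(u, [])
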