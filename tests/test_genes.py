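import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import cellpanel as cp
from cellpanel.exceptions import DegenerateCurveError, SingleClassError
from cellpanel.genes import (
    GeneSelectionConfig,
    RFECurve,
    aggregate_stable_panels,
    _standardize,
)


class TestEliminationSchedule:
    def test_small_n_one_per_step(self):
        assert cp.elimination_schedule(10, 0.03) == list(range(10, 0, -1))

    def test_three_percent_of_thousand(self):
        sched = cp.elimination_schedule(1000, 0.03)
        assert sched[0] == 1000 and sched[1] == 970

    @given(st.integers(min_value=1, max_value=5000))
    @settings(max_examples=60, deadline=None)
    def test_strictly_decreasing_and_terminates(self, n):
        sched = cp.elimination_schedule(n)
        assert sched[0] == n and sched[-1] == 1
        steps = np.diff(sched)
        assert (steps < 0).all()
        for cur, removed in zip(sched, -steps):
            assert removed == max(1, int(0.03 * cur))


class TestSvmRfeRank:
    @staticmethod
    def _toy(n=200, informative=(0,), n_genes=2, shift=3.0, seed=0):
        rng = np.random.default_rng(seed)
        y = rng.integers(0, 2, size=n)
        X = rng.standard_normal((n, n_genes))
        for g in informative:
            X[:, g] += shift * y
        Xs, _, _ = _standardize(X)
        return Xs, y

    def test_separator_ranked_first(self):
        X, y = self._toy()
        rank = cp.svm_rfe_rank(X, y)
        assert rank[0] == 1

    def test_ranking_is_permutation(self):
        X, y = self._toy(n_genes=9, informative=(1, 4))
        rank = cp.svm_rfe_rank(X, y)
        assert sorted(rank) == list(range(1, 10))

    def test_recovers_informative_pair(self):
        hits = 0
        for seed in range(20):
            X, y = self._toy(n_genes=6, informative=(2, 5), seed=seed)
            rank = cp.svm_rfe_rank(X, y)
            if set(np.argsort(rank)[:2]) == {2, 5}:
                hits += 1
        assert hits >= 19

    def test_single_class_rejected(self):
        X = np.random.default_rng(0).standard_normal((10, 3))
        with pytest.raises(SingleClassError):
            cp.svm_rfe_rank(X, np.ones(10, dtype=int))


def _curve(x, y):
    x = np.asarray(x, float)
    return RFECurve(
        gene_counts=x[::-1],
        mean_accuracy=np.asarray(y, float)[::-1],
        sd_accuracy=np.zeros(len(x)),
        k_folds=5,
        elimination_fraction=0.03,
    )


class TestFindElbow:
    def test_knee_of_saturating_curve(self):
        assert cp.find_elbow(_curve([1, 2, 3, 4, 5], [0.20, 0.80, 0.90, 0.92, 0.93])) == 2

    def test_collinear_returns_sparsest_with_warning(self):
        with pytest.warns(UserWarning, match="collinear"):
            assert cp.find_elbow(_curve([1, 2, 3, 4], [0.1, 0.2, 0.3, 0.4])) == 1

    def test_step_curve_elbow_at_jump(self):
        x = np.arange(1, 101)
        y = np.where(x >= 18, 0.9, 0.5)
        assert cp.find_elbow(_curve(x, y)) == 18

    def test_too_few_points(self):
        with pytest.raises(DegenerateCurveError):
            cp.find_elbow(_curve([1, 2], [0.5, 0.9]))

    def test_matches_brute_force(self):
        rng = np.random.default_rng(42)
        for _ in range(200):
            n = int(rng.integers(3, 40))
            x = np.sort(rng.choice(np.arange(1, 200), size=n, replace=False))
            y = np.clip(np.sort(rng.random(n)) + rng.normal(0, 0.05, n), 0, 1)
            got = cp.find_elbow(_curve(x, y))
            # independent point-by-point computation of the chord distances
            x1, y1, xn, yn = x[0], y[0], x[-1], y[-1]
            best_d, best_x = -1.0, None
            for xi, yi in zip(x, y):
                d = abs((yn - y1) * xi - (xn - x1) * yi + xn * y1 - yn * x1) / np.sqrt(
                    (yn - y1) ** 2 + (xn - x1) ** 2
                )
                if d > best_d:
                    best_d, best_x = d, xi
            assert got == best_x


class TestCvCurveAndPanel:
    def test_folds_partition_patients(self, tiny):
        ds, truth = tiny
        sub = cp.subset(ds, cell_types={truth.responsive_cell_type})
        curve = cp.cv_accuracy_curve(sub, k=4, cfg=GeneSelectionConfig(k_folds=4))
        assert curve.gene_counts[0] == sub.n_genes
        assert (np.diff(curve.gene_counts) < 0).all()
        assert ((curve.mean_accuracy >= 0) & (curve.mean_accuracy <= 1)).all()

    def test_two_folds_supported(self, tiny):
        ds, truth = tiny
        sub = cp.subset(ds, cell_types={truth.responsive_cell_type})
        curve = cp.cv_accuracy_curve(sub, k=2, cfg=GeneSelectionConfig(k_folds=2))
        assert curve.k_folds == 2

    def test_informative_region_beats_single_gene(self, tiny):
        ds, truth = tiny
        sub = cp.subset(ds, cell_types={truth.responsive_cell_type})
        curve = cp.cv_accuracy_curve(sub, k=4)
        n_markers = len(truth.marker_genes)
        plateau = curve.mean_accuracy[curve.gene_counts >= n_markers].mean()
        single = curve.mean_accuracy[curve.gene_counts == 1][0]
        assert plateau > 0.75
        assert plateau >= single - 0.02

    def test_panel_genes_subset_no_duplicates(self, tiny):
        ds, truth = tiny
        panel = cp.select_gene_panel(ds, truth.responsive_cell_type, k=4, seed=0)
        assert len(panel.genes) == len(set(panel.genes)) == panel.n_selected
        assert set(panel.genes) <= set(ds.gene_ids)
        assert 1 <= panel.n_selected <= ds.n_genes

    def test_panel_deterministic_under_seed(self, tiny):
        ds, truth = tiny
        a = cp.select_gene_panel(ds, truth.responsive_cell_type, k=4, seed=5)
        b = cp.select_gene_panel(ds, truth.responsive_cell_type, k=4, seed=5)
        assert a.genes == b.genes


class TestStableSelection:
    def test_threshold_is_strict(self):
        # 12/20 kept (0.6 > 0.5), 10/20 dropped (0.5 not > 0.5)
        panels = [["a", "b"]] * 10 + [["a"]] * 2 + [["c"]] * 8
        kept, freq = aggregate_stable_panels(panels, freq_threshold=0.5)
        assert freq["a"] == pytest.approx(0.6)
        assert freq["b"] == pytest.approx(0.5)
        assert "a" in kept and "b" not in kept

    def test_ordering_frequency_then_rank(self):
        panels = [["x", "y"], ["y", "x"], ["y"], ["z"]]
        kept, freq = aggregate_stable_panels(panels, freq_threshold=0.25)
        assert kept == ["y", "x"]  # y: 0.75 beats x: 0.5

    def test_bookkeeping_matches_recount(self, tiny):
        ds, truth = tiny
        panel = cp.stable_gene_panel(
            ds, truth.responsive_cell_type, n_subsets=6, k=3, seed=1
        )
        assert panel.subset_panels is not None and len(panel.subset_panels) == 6
        for g, f in panel.selection_frequency.items():
            recount = sum(g in p for p in panel.subset_panels) / 6
            assert f == pytest.approx(recount)
        union = set().union(*map(set, panel.subset_panels))
        assert set(panel.genes) <= union

    def test_reproducible_under_seed(self, tiny):
        ds, truth = tiny
        a = cp.stable_gene_panel(ds, truth.responsive_cell_type, n_subsets=4, k=3, seed=2)
        b = cp.stable_gene_panel(ds, truth.responsive_cell_type, n_subsets=4, k=3, seed=2)
        assert a.genes == b.genes and a.selection_frequency == b.selection_frequency
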