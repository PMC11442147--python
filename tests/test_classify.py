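import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from sklearn.metrics import roc_auc_score

import cellpanel as cp
from cellpanel.classify import EnsembleConfig, _holdout_mask
from cellpanel.exceptions import MissingGenesError, SingleClassError

from conftest import make_labeled_dataset


class TestCellWeights:
    def test_symmetric_cohort_equal_weights(self):
        pat = np.array(["A"] * 5 + ["B"] * 5 + ["C"] * 5 + ["D"] * 5)
        cond = np.array([0] * 10 + [1] * 10)
        w = cp.compute_cell_weights(pat, cond)
        assert np.allclose(w, w[0])

    def test_big_patient_downweighted_tenfold(self):
        pat = np.array(["A"] * 10 + ["B"] * 1 + ["C"] * 5)
        cond = np.array([0] * 11 + [1] * 5)
        w = cp.compute_cell_weights(pat, cond)
        wa = w[pat == "A"][0]
        wb = w[pat == "B"][0]
        assert wb == pytest.approx(10 * wa)

    def test_class_and_patient_conservation_random(self):
        rng = np.random.default_rng(1)
        for _ in range(30):
            pats, conds = [], []
            for c in (0, 1):
                for i in range(int(rng.integers(2, 6))):
                    n = int(rng.integers(1, 40))
                    pats += [f"{c}p{i}"] * n
                    conds += [c] * n
            pat, cond = np.array(pats), np.array(conds)
            w = cp.compute_cell_weights(pat, cond)
            s0, s1 = w[cond == 0].sum(), w[cond == 1].sum()
            assert s0 == pytest.approx(s1, rel=1e-10)
            for c in (0, 1):
                tot = [w[pat == p].sum() for p in np.unique(pat[cond == c])]
                assert np.allclose(tot, tot[0], rtol=1e-10)

    def test_single_class_rejected(self):
        with pytest.raises(SingleClassError):
            cp.compute_cell_weights(np.array(["A", "B"]), np.array([1, 1]))


class TestCellGraph:
    def test_min_degree_and_symmetry(self):
        X = np.random.default_rng(0).standard_normal((40, 3))
        adj = cp.build_cell_graph(X, k=5)
        assert (adj != adj.T).nnz == 0
        deg = np.asarray(adj.sum(axis=1)).ravel()
        assert (deg >= 5).all()
        assert adj.diagonal().sum() == 0

    def test_equidistant_tie_by_index(self):
        # three coincident points: every neighbour is equidistant, so each
        # node's 1-NN resolves to the lowest other index
        X = np.zeros((3, 2))
        adj = cp.build_cell_graph(X, k=1).toarray()
        assert adj[1, 0] == 1 and adj[2, 0] == 1
        assert adj[2, 1] == 0  # node 2 chose node 0, not 1; nobody chose 2->1
        assert (adj == adj.T).all()

    def test_duplicate_points_ok(self):
        X = np.zeros((5, 2))
        adj = cp.build_cell_graph(X, k=2)
        assert adj.nnz > 0

    def test_k_clipped_with_warning(self):
        X = np.random.default_rng(0).standard_normal((4, 2))
        with pytest.warns(UserWarning, match="clip"):
            cp.build_cell_graph(X, k=10)


class TestPatientAUC:
    def test_extremes_and_ties(self):
        assert cp.patient_auc([1.0, 1.0, 1.0]) == 1.0
        assert cp.patient_auc([0.5, 0.5]) == 0.5
        assert cp.patient_auc([0.9, 0.8, 0.3, 0.6]) == 0.75

    @given(st.lists(st.floats(0, 1), min_size=1, max_size=50))
    @settings(max_examples=100, deadline=None)
    def test_counting_oracle(self, probs):
        expected = (
            sum(p > 0.5 for p in probs) + 0.5 * sum(p == 0.5 for p in probs)
        ) / len(probs)
        assert cp.patient_auc(probs) == pytest.approx(expected)

    @given(
        st.lists(st.floats(0.01, 0.99), min_size=2, max_size=30),
        st.floats(0.3, 3.0),
    )
    @settings(max_examples=50, deadline=None)
    def test_invariant_under_monotone_transform_fixing_half(self, probs, gamma):
        """Any strictly monotone probability transform that fixes 0.5
        leaves the patient score unchanged — only the side of 0.5 matters."""
        p = np.asarray(probs)
        q = 0.5 + 0.5 * np.sign(p - 0.5) * np.abs(2 * p - 1) ** gamma
        assert cp.patient_auc(q) == pytest.approx(cp.patient_auc(p))


class TestBootstrap:
    def test_degenerate_all_ones(self):
        assert cp.bootstrap_pvalue(np.ones(30), B=1000, seed=0) == pytest.approx(
            1 / 1001
        )

    def test_all_half_is_null(self):
        assert cp.bootstrap_pvalue(np.full(10, 0.5), B=1000, seed=0) == 1.0

    def test_matches_independent_loop(self):
        probs = np.array([0.9, 0.7, 0.4, 0.8, 0.2, 0.9, 0.55])
        B, seed = 500, 42
        got = cp.bootstrap_pvalue(probs, B=B, seed=seed)
        # independent re-implementation sharing the seed
        rng = np.random.default_rng(seed)
        obs = cp.patient_auc(probs)
        extreme = 0
        draws = rng.integers(0, len(probs), size=(B, len(probs)))
        for b in range(B):
            rep = cp.patient_auc(probs[draws[b]])
            if (obs > 0.5 and rep <= 0.5) or (obs < 0.5 and rep >= 0.5):
                extreme += 1
        assert got == pytest.approx((1 + extreme) / (B + 1))

    def test_small_B_warns(self):
        with pytest.warns(UserWarning, match="unstable"):
            cp.bootstrap_pvalue(np.array([0.9, 0.8]), B=50, seed=0)


class TestConsensus:
    @staticmethod
    def _preds(matrix, members=("LR", "SVM", "RF", "kNN", "GAT")):
        m = pd.DataFrame(np.atleast_2d(matrix), columns=list(members))
        return m

    def test_median_of_five(self):
        m = self._preds([0.1, 0.2, 0.9, 0.8, 0.6])
        assert np.median(m.to_numpy(), axis=1)[0] == pytest.approx(0.6)

    def test_even_member_median(self):
        m = self._preds([0.1, 0.2, 0.9, 0.8], members=("LR", "SVM", "RF", "kNN"))
        assert np.median(m.to_numpy(), axis=1)[0] == pytest.approx(0.5)


class TestClassifyPatients:
    @staticmethod
    def _preds_for(aucs_by_patient):
        cells, pats, cons, conds = [], [], [], []
        i = 0
        for pat, (probs, cond) in aucs_by_patient.items():
            for p in probs:
                cells.append(f"c{i}")
                pats.append(pat)
                cons.append(p)
                conds.append(cond)
                i += 1
        return cp.CellPredictions(
            cell_ids=np.array(cells),
            patient=np.array(pats),
            member_probs=pd.DataFrame({"LR": cons}),
            consensus=np.array(cons),
            condition=np.array(conds),
        )

    def test_confusion_matrix_metrics(self):
        preds = self._preds_for(
            {
                "P1": ([0.9] * 4, 1),   # predicted 1, true 1
                "P2": ([0.1] * 4, 1),   # predicted 0, true 1
                "P3": ([0.2] * 4, 0),   # predicted 0, true 0
            }
        )
        rep = cp.classify_patients(preds, B=200, seed=0)
        m = rep.metrics
        assert m["accuracy"] == pytest.approx(2 / 3)
        assert m["sensitivity"] == pytest.approx(0.5)
        assert m["specificity"] == pytest.approx(1.0)
        assert m["precision"] == pytest.approx(1.0)
        assert m["f1"] == pytest.approx(2 / 3)

    def test_perfect_case(self):
        preds = self._preds_for({"P1": ([1.0] * 3, 1), "P2": ([0.99] * 3, 1)})
        rep = cp.classify_patients(preds, B=200, seed=0)
        assert all(v == 1.0 for v in rep.metrics.values())
        assert (rep.per_patient["auc"] == 1.0).all()

    def test_half_auc_flagged_undetermined_negative(self):
        preds = self._preds_for({"P1": ([0.5] * 4, 1), "P2": ([0.9] * 4, 1)})
        rep = cp.classify_patients(preds, B=200, seed=0)
        row = rep.per_patient.loc["P1"]
        assert row["undetermined"] and row["predicted_label"] == 0
        assert row["p_value"] == 1.0


class TestEnsemble:
    @pytest.fixture(scope="class")
    def strong_trained(self):
        """Ensemble on the full-signal cohort for performance checks."""
        ds, truth = cp.make_fixture("strong", seed=4)
        ds = cp.normalize_counts(ds)
        split = cp.split_by_patient(ds, seed=0)
        panel = sorted(truth.marker_genes)
        train = cp.subset(
            ds, patients=split.train_patients,
            cell_types={truth.responsive_cell_type}, genes=panel,
        )
        test = cp.subset(
            ds, patients=split.test_patients,
            cell_types={truth.responsive_cell_type}, genes=panel,
        )
        return cp.train_ensemble(train, seed=0), train, test

    @pytest.fixture(scope="class")
    def trained(self, tiny):
        ds, truth = tiny
        split = cp.split_by_patient(ds, seed=0)
        panel = sorted(truth.marker_genes)
        train = cp.subset(
            ds, patients=split.train_patients,
            cell_types={truth.responsive_cell_type}, genes=panel,
        )
        test = cp.subset(
            ds, patients=split.test_patients,
            cell_types={truth.responsive_cell_type}, genes=panel,
        )
        model = cp.train_ensemble(train, seed=0)
        return model, train, test

    def test_all_five_members_present(self, trained):
        model, _, _ = trained
        assert set(model.members) == {"LR", "SVM", "RF", "kNN", "GAT"}

    def test_members_discriminate_held_out_cells(self, strong_trained):
        model, _, test = strong_trained
        preds = cp.predict_cells(model, test)
        for name in model.members:
            auc = roc_auc_score(test.condition, preds.member_probs[name])
            assert auc > 0.8, name

    def test_consensus_bounded_by_members(self, trained):
        model, _, test = trained
        preds = cp.predict_cells(model, test)
        m = preds.member_probs.to_numpy()
        assert (preds.consensus >= m.min(axis=1) - 1e-12).all()
        assert (preds.consensus <= m.max(axis=1) + 1e-12).all()

    def test_consensus_invariant_to_member_order(self, trained):
        model, _, test = trained
        preds = cp.predict_cells(model, test)
        m = preds.member_probs.to_numpy()
        rng = np.random.default_rng(0)
        perm = rng.permutation(m.shape[1])
        np.testing.assert_allclose(
            np.median(m[:, perm], axis=1), preds.consensus
        )

    def test_training_reproducible_under_seed(self, trained):
        model, train, test = trained
        model2 = cp.train_ensemble(train, seed=0)
        p1 = cp.predict_cells(model, test).member_probs
        p2 = cp.predict_cells(model2, test).member_probs
        for name in ("LR", "SVM", "RF", "kNN"):
            np.testing.assert_array_equal(p1[name], p2[name])
        np.testing.assert_allclose(p1["GAT"], p2["GAT"], atol=1e-3)

    def test_missing_panel_gene_is_hard_error(self, trained):
        model, _, test = trained
        broken = cp.subset(test, genes=list(test.gene_ids[:-1]))
        with pytest.raises(MissingGenesError):
            cp.predict_cells(model, broken)

    def test_single_gene_panel_trains(self, tiny):
        ds, truth = tiny
        train = cp.subset(
            ds,
            cell_types={truth.responsive_cell_type},
            genes=[sorted(truth.marker_genes)[0]],
        )
        model = cp.train_ensemble(train, seed=1)
        preds = cp.predict_cells(model, train)
        assert preds.consensus.shape == (train.n_cells,)

    def test_member_subset_fallback_warns(self, tiny):
        ds, truth = tiny
        train = cp.subset(ds, cell_types={truth.responsive_cell_type})
        cfg = EnsembleConfig(members=("LR", "SVM", "RF", "kNN"))
        with pytest.warns(UserWarning, match="missing.*GAT"):
            model = cp.train_ensemble(train, seed=0, cfg=cfg)
        assert set(model.members) == {"LR", "SVM", "RF", "kNN"}


def test_holdout_mask_is_patient_stratified():
    rng = np.random.default_rng(0)
    pat = np.repeat([f"p{i}" for i in range(8)], 10)
    cond = np.repeat([0, 0, 0, 0, 1, 1, 1, 1], 10)
    mask = _holdout_mask(pat, cond, 0.25, rng)
    held = set(pat[mask])
    kept = set(pat[~mask])
    assert not held & kept
    held_conds = {0, 1} & {c for p, c in zip(pat, cond) if p in held}
    assert held_conds == {0, 1}
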