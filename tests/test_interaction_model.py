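"""Pair formation, sum-supervised training, ensemble prediction and the
linear interaction rescaling."""

import numpy as np
import pytest

import graphbnc as g
from graphbnc.interaction_model import (EnsembleModel, PairBatch, evaluate_cv,
                                        form_pairs, predict, scale_interactions,
                                        train)
from graphbnc.structures import RigidPose


class _ConstantNet:
    """Stub fold returning a fixed (coulomb, vdw) output per pair."""

    def __init__(self, value):
        self.value = value

    def forward(self, X, cache=False):
        return np.full((len(X), 2), self.value / 2.0)


def _stub_model(values, dim=4):
    return EnsembleModel(folds=[_ConstantNet(v) for v in values],
                         input_lo=np.zeros(dim), input_span=np.ones(dim),
                         output_scale=1.0)


class TestFormPairs:
    def test_formation_distance_boundary(self, featurized, cluster):
        ca0 = featurized.coarse.ca_coords[0]
        heads = cluster.model.head_centroids
        far = ca0 - featurized.coarse.ca_coords.mean(axis=0)
        far = far / np.linalg.norm(far)
        for offset, expected in ((9.9, True), (10.1, False)):
            # place head 0 exactly `offset` outward from residue 0
            shift = ca0 + offset * far - heads[0]
            pose = RigidPose(translation=shift, pivot=cluster.model.com)
            batch = form_pairs(featurized, cluster.model, pose)
            assert (0 in batch.pair_ids) == expected  # pair (ligand 0, node 0)

    def test_cartesian_pair_count(self):
        """2 ligand heads x 3 residues all in range -> 6 rows."""
        from graphbnc.protein_graph import featurize_protein
        from graphbnc.structures import ClusterModel, CoarseProtein, Ligand, \
            LigandTopology
        cp = CoarseProtein(np.array([[0, 0, 0], [4.0, 0, 0], [8.0, 0, 0.0]]),
                           [("A", i + 1, "GLY") for i in range(3)])
        pg = featurize_protein(cp)
        cm = ClusterModel(["Au", "C", "O", "O"],
                          np.array([[4.0, 6, 0], [4, 7, 0], [3, 8, 0], [5, 8, 0.0]]),
                          LigandTopology([Ligand([2], []), Ligand([3], [])]))
        g.featurize_cluster(cm)
        batch = form_pairs(pg, cm)
        assert len(batch) == 6

    def test_empty_batch_allowed(self, featurized, cluster):
        pose = RigidPose(translation=np.array([500.0, 0, 0]),
                         pivot=cluster.model.com)
        batch = form_pairs(featurized, cluster.model, pose)
        assert len(batch) == 0
        _, total = predict(_stub_model([1] * 5, dim=133), batch)
        assert total == 0.0


class TestPredict:
    def test_fold_mean(self):
        batch = PairBatch(0, np.zeros((1, 4)))
        per_pair, total = predict(_stub_model([1, 2, 3, 4, 5]), batch)
        assert total == pytest.approx(3.0)

    def test_duplicated_pair_doubles_total(self):
        one = PairBatch(0, np.zeros((1, 4)))
        two = PairBatch(0, np.zeros((2, 4)))
        m = _stub_model([2, 2, 2, 2, 2])
        assert predict(m, two)[1] == pytest.approx(2 * predict(m, one)[1])

    def test_dimension_mismatch_raises(self):
        with pytest.raises(ValueError):
            predict(_stub_model([1] * 5, dim=4), PairBatch(0, np.zeros((1, 7))))


class TestScaleInteractions:
    def test_strongest_maps_to_one_and_median_to_zero(self):
        table = scale_interactions(np.array([-10.0, -4.0, -2.0, 0.0]))
        med = np.median(table.energies)
        assert table.phi[0] == pytest.approx(1.0)
        # evaluate the affine map at the median energy via linear fit
        slope, intercept = np.polyfit(table.energies, table.phi, 1)
        assert slope * med + intercept == pytest.approx(0.0, abs=1e-12)

    def test_hand_computed_value(self):
        """phi(0) = (-3 - 0)/(-3 + 10) = -3/7 for the list [-10,-4,-2,0]."""
        table = scale_interactions(np.array([-10.0, -4.0, -2.0, 0.0]))
        assert table.phi[-1] == pytest.approx(-3.0 / 7.0)

    def test_monotone_decreasing_in_energy(self, rng):
        e = rng.normal(size=50)
        table = scale_interactions(e)
        order = np.argsort(e)
        assert np.all(np.diff(table.phi[order]) <= 1e-12)

    def test_degenerate_all_equal(self):
        with pytest.warns(UserWarning):
            table = scale_interactions(np.full(5, -3.0))
        np.testing.assert_array_equal(table.phi, 0.0)


class TestTraining:
    def _tiny_batches(self, rng, n_configs=24, label_fn=None):
        """Synthetic decomposable toy problem: 6-dim features, energy is a
        linear functional of each pair row."""
        w = np.array([1.0, -2.0, 0.5, 0.0, 1.5, -1.0])
        batches = []
        for i in range(n_configs):
            P = rng.integers(3, 9)
            X = rng.random((P, 6))
            e = X @ w
            if label_fn is not None:
                e = label_fn(e)
            batches.append(PairBatch(i, X, e_coul=e.sum(), e_vdw=0.0))
        return batches

    def test_fold_assignment_deterministic(self, rng):
        batches = self._tiny_batches(rng)
        m1 = train(batches, seed=9, min_updates=100)
        m2 = train(batches, seed=9, min_updates=100)
        assert m1.fold_assignment == m2.fold_assignment
        for a, b in zip(m1.folds, m2.folds):
            for W1, W2 in zip(a.W, b.W):
                np.testing.assert_array_equal(W1, W2)

    def test_null_labels_give_null_predictions(self, rng):
        batches = self._tiny_batches(rng, label_fn=lambda e: e * 0.0)
        m = train(batches, seed=9, min_updates=6000, hidden=(16, 8, 4))
        totals = [abs(predict(m, b)[1]) for b in batches]
        assert max(totals) < 0.05 * 2.0  # 5% of the [-1, 1] output range

    def test_sum_aggregation_additive_over_subsets(self, rng):
        batches = self._tiny_batches(rng)
        m = train(batches, seed=9, min_updates=200, hidden=(8, 4, 2))
        b = batches[0]
        half1 = PairBatch(0, b.features[:2])
        half2 = PairBatch(0, b.features[2:])
        assert predict(m, b)[1] == pytest.approx(
            predict(m, half1)[1] + predict(m, half2)[1], rel=1e-9)

    def test_requires_enough_configurations(self, rng):
        with pytest.raises(ValueError):
            train(self._tiny_batches(rng)[:3], seed=0)

    def test_checkpoint_roundtrip(self, rng, tmp_path):
        batches = self._tiny_batches(rng)
        m = train(batches, seed=9, min_updates=100, hidden=(8, 4, 2))
        g.save_model(m, tmp_path / "ckpt")
        back = g.load_model(tmp_path / "ckpt")
        b = batches[0]
        assert predict(back, b)[1] == pytest.approx(predict(m, b)[1], rel=1e-12)


class TestEvaluateCV:
    def test_perfect_predictor_zero_rmse(self):
        m = _stub_model([4.0] * 5, dim=3)  # every pair contributes 4
        batches = [PairBatch(i, np.zeros((2, 3)), e_coul=8.0) for i in range(4)]
        rep = evaluate_cv(m, batches)
        assert rep["rmse"] == pytest.approx(0.0)
        assert rep["mean_fold_std"] == pytest.approx(0.0)  # identical folds

    def test_constant_zero_predictor_rmse_equals_label_std(self, rng):
        m = _stub_model([0.0] * 5, dim=3)
        labels = rng.normal(size=40)
        labels -= labels.mean()  # population convention: RMSE = sigma
        batches = [PairBatch(i, np.zeros((1, 3)), e_coul=l)
                   for i, l in enumerate(labels)]
        rep = evaluate_cv(m, batches)
        assert rep["rmse"] == pytest.approx(labels.std())


class TestLearnability:
    """The central architectural claim: configuration-level (sum)
    supervision recovers per-pair energies on the exactly decomposable
    oracle."""

    def test_heldout_rmse_and_per_pair_correlation(self, oracle_dataset,
                                                   trained_model):
        dataset, batches = oracle_dataset
        held_batches = batches[200:]
        held_configs = dataset.configurations[200:]
        rep = evaluate_cv(trained_model, held_batches)
        assert rep["rmse"] < 0.25 * rep["label_std"]

        preds, trues = [], []
        for b, s in zip(held_batches, held_configs):
            if len(b) == 0:
                continue
            per_pair, _ = predict(trained_model, b)
            preds.append(per_pair.sum(axis=1))
            trues.append((s.oracle.per_pair_coul
                          + s.oracle.per_pair_vdw).ravel()[b.pair_ids])
        r = np.corrcoef(np.concatenate(preds), np.concatenate(trues))[0, 1]
        assert r > 0.7

    def test_ensemble_variance_not_larger_than_single_fold(self, oracle_dataset,
                                                           trained_model):
        """Averaging five folds cannot increase held-out squared error."""
        dataset, batches = oracle_dataset
        errs_ens, errs_fold = [], []
        for b in batches[200:]:
            if len(b) == 0:
                continue
            fold_totals = trained_model.fold_outputs(b.features).sum(axis=(1, 2))
            errs_ens.append((fold_totals.mean() - b.label) ** 2)
            errs_fold.append(((fold_totals - b.label) ** 2).mean())
        assert np.mean(errs_ens) <= np.mean(errs_fold) + 1e-12
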