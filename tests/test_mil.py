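"""MILES embedding, random forest training, LOPO CV, and operating point."""

from __future__ import annotations

import numpy as np
import pytest

from tadmil import (
    SVGenePair,
    compute_auc,
    leave_one_patient_out_cv,
    mean_instance,
    miles_embed,
    predict,
    rf_instance_importance,
    select_operating_point,
    subsample_bags,
    train_model,
)
from tadmil.features import Bag
from tadmil.mil import CVPrediction, _normalize_and_embed

from .oracles import brute_force_auc


def make_bag(X, label, patient="p0", sv_id="s0", gene="g0", sv_type="DEL"):
    pair = SVGenePair(sv_id=sv_id, patient=patient, gene_id=gene, sv_type=sv_type)
    return Bag(pair=pair, X=np.asarray(X, dtype=float), label=label)


def synthetic_bags(n_patients=8, bags_per_patient=6, n_features=5, effect=2.0, seed=0):
    """Separable synthetic bags: positive bags contain one instance with an
    elevated signature feature."""
    rng = np.random.default_rng(seed)
    bags = []
    for p in range(n_patients):
        for b in range(bags_per_patient):
            label = int(b % 2 == 0)
            X = rng.random((3, n_features)) * 0.2
            if label:
                X[0, 0] += effect
            bags.append(
                make_bag(X, label, patient=f"p{p}", sv_id=f"s{p}_{b}", gene=f"g{b}")
            )
    return bags


class TestEmbedding:
    def test_mean_instance(self):
        assert mean_instance(np.array([[0.0, 1.0], [1.0, 0.0]])).tolist() == [0.5, 0.5]
        assert mean_instance(np.array([[3.0, 4.0]])).tolist() == [3.0, 4.0]
        assert mean_instance(np.array([[0, 0], [0, 0], [3, 3.0]])).tolist() == [1.0, 1.0]

    def test_l1_distance_hand_computed(self):
        E = miles_embed([np.array([[0.0, 0.0], [1.0, 1.0]])], np.array([[0.0, 1.0]]))
        assert E.item() == pytest.approx(1.0)  # |0.5-0| + |0.5-1|

    def test_zero_distance_iff_instance_equals_mean(self):
        E = miles_embed([np.array([[0.2, 0.8]])], np.array([[0.2, 0.8], [0.3, 0.8]]))
        assert E[0, 0] == 0.0
        assert E[0, 1] > 0.0

    def test_shape(self):
        bags = [np.zeros((2, 3)), np.ones((4, 3))]
        refs = np.zeros((5, 3))
        assert miles_embed(bags, refs).shape == (2, 5)

    def test_dimension_mismatch_rejected(self):
        with pytest.raises(ValueError, match="dimension"):
            miles_embed([np.zeros((1, 3))], np.zeros((2, 4)))

    def test_distances_nonnegative_and_finite(self):
        rng = np.random.default_rng(3)
        E = miles_embed([rng.random((4, 6)) for _ in range(5)], rng.random((20, 6)))
        assert np.all(E >= 0) and np.all(np.isfinite(E))


class TestSubsample:
    def _bags(self, n_pos, n_neg):
        out = [make_bag(np.zeros((1, 2)), 1, sv_id=f"a{i}") for i in range(n_pos)]
        out += [make_bag(np.zeros((1, 2)), 0, sv_id=f"b{i}") for i in range(n_neg)]
        return out

    def test_cap_applied(self):
        res = subsample_bags(self._bags(600, 600), cap=700, seed=0)
        assert len(res) == 700
        assert abs(sum(b.label for b in res) - 350) <= 1

    def test_below_cap_unchanged(self):
        bags = self._bags(300, 300)
        assert subsample_bags(bags, cap=700, seed=0) == bags

    def test_deterministic(self):
        a = subsample_bags(self._bags(600, 600), cap=700, seed=3)
        b = subsample_bags(self._bags(600, 600), cap=700, seed=3)
        assert [x.pair_id for x in a] == [x.pair_id for x in b]


class TestTraining:
    def test_separable_bags_training_accuracy(self):
        bags = synthetic_bags(effect=3.0)
        bundle = train_model(bags, "DEL", seed=0)
        proba, _ = predict(bundle, bags)
        assert np.mean((proba >= 0.5) == np.array([b.label for b in bags])) == 1.0

    def test_single_class_rejected(self):
        bags = [make_bag(np.zeros((1, 2)), 1, sv_id=f"s{i}") for i in range(4)]
        with pytest.raises(ValueError, match="both classes"):
            train_model(bags, "DEL")

    def test_same_seed_identical_predictions(self):
        bags = synthetic_bags()
        p1, _ = predict(train_model(bags, "DEL", seed=5), bags)
        p2, _ = predict(train_model(bags, "DEL", seed=5), bags)
        assert np.array_equal(p1, p2)

    def test_shuffled_labels_give_chance_cv_auc(self):
        rng = np.random.default_rng(42)
        aucs = []
        for rep in range(10):
            bags = synthetic_bags(effect=3.0, seed=rep)
            labels = [b.label for b in bags]
            shuffled = rng.permutation(labels)
            for b, lab in zip(bags, shuffled):
                b.label = int(lab)
            cv = leave_one_patient_out_cv(bags, "DEL", seed=rep)
            aucs.append(compute_auc(cv))
        assert 0.4 < np.mean(aucs) < 0.6

    def test_auc_monotone_in_planted_effect_size(self):
        """Parameter recovery: CV AUC does not decrease as the planted
        signature gets stronger (three effect levels, fixed seeds)."""
        aucs = []
        for effect in (0.1, 1.0, 4.0):
            bags = synthetic_bags(effect=effect, seed=11)
            cv = leave_one_patient_out_cv(bags, "DEL", seed=11)
            aucs.append(compute_auc(cv))
        assert aucs[0] <= aucs[1] + 0.05 and aucs[1] <= aucs[2] + 0.05
        assert aucs[2] > 0.95

    def test_importances_sum_to_one_and_map_to_instances(self):
        bags = synthetic_bags()
        bundle = train_model(bags, "DEL", seed=0)
        ranked = rf_instance_importance(bundle)
        assert len(ranked) == bundle.reference_instances.shape[0]
        assert sum(v for v, _, _ in ranked) == pytest.approx(1.0)
        assert all(a >= b for (a, _, _), (b, _, _) in zip(ranked, ranked[1:]))


class TestLOPO:
    def test_every_bag_predicted_exactly_once(self):
        bags = synthetic_bags(n_patients=3)
        cv = leave_one_patient_out_cv(bags, "DEL", seed=0)
        assert sorted(p.pair_id for p in cv) == sorted(b.pair_id for b in bags)

    def test_reference_instances_exclude_test_patient(self):
        bags = synthetic_bags(n_patients=4)
        for patient in sorted({b.patient for b in bags}):
            train = [b for b in bags if b.patient != patient]
            test = [b for b in bags if b.patient == patient]
            _, _, refs, _, ref_ids = _normalize_and_embed(train, test, "l1")
            test_ids = {b.pair_id for b in test}
            assert not test_ids & {pid for pid, _ in ref_ids}
            assert refs.shape[0] == sum(b.X.shape[0] for b in train)

    def test_cv_uses_training_only_reference(self):
        """Recomputing each fold from scratch with a training-only embedding
        reproduces the CV predictions bit for bit."""
        from sklearn.ensemble import RandomForestClassifier

        bags = synthetic_bags(n_patients=4, seed=2)
        cv = {p.pair_id: p.proba for p in leave_one_patient_out_cv(bags, "DEL", seed=9)}
        for patient in sorted({b.patient for b in bags}):
            train = [b for b in bags if b.patient != patient]
            test = [b for b in bags if b.patient == patient]
            E_train, E_test, _, _, _ = _normalize_and_embed(train, test, "l1")
            rf = RandomForestClassifier(n_estimators=100, max_features="sqrt", random_state=9)
            rf.fit(E_train, [b.label for b in train])
            proba = rf.predict_proba(E_test)[:, list(rf.classes_).index(1)]
            for b, p in zip(test, proba):
                assert cv[b.pair_id] == pytest.approx(float(p), abs=0)


class TestAUC:
    def _preds(self, labels, scores):
        return [CVPrediction(f"b{i}", "p", y, s) for i, (y, s) in enumerate(zip(labels, scores))]

    def test_perfect_and_reversed(self):
        assert compute_auc(self._preds([0, 0, 1, 1], [0.1, 0.2, 0.8, 0.9])) == 1.0
        assert compute_auc(self._preds([1, 1, 0, 0], [0.1, 0.2, 0.8, 0.9])) == 0.0

    def test_ties_count_half(self):
        assert compute_auc(self._preds([1, 0], [0.8, 0.8])) == 0.5

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            compute_auc(self._preds([1, 1], [0.1, 0.2]))

    def test_matches_pairwise_brute_force_on_random_scores(self):
        rng = np.random.default_rng(17)
        for _ in range(25):
            n = int(rng.integers(4, 40))
            labels = rng.integers(0, 2, size=n)
            if len(set(labels.tolist())) < 2:
                continue
            scores = np.round(rng.random(n), 2)  # rounding forces ties
            got = compute_auc(self._preds(labels, scores))
            assert got == pytest.approx(brute_force_auc(labels, scores))


class TestOperatingPoint:
    def _preds(self, labels, scores):
        return [CVPrediction(f"b{i}", "p", y, s) for i, (y, s) in enumerate(zip(labels, scores))]

    def test_perfect_separation(self):
        preds = self._preds([0, 0, 1, 1], [0.1, 0.2, 0.7, 0.9])
        t = select_operating_point(preds)
        assert t == pytest.approx(0.7)  # lowest positive score: recall 1, precision 1

    def test_unreachable_precision_returns_none(self):
        preds = self._preds([1, 0, 0, 0, 0, 0, 0, 0, 0, 0], [0.5] * 10)
        assert select_operating_point(preds, min_precision=0.5) is None

    def test_matches_exhaustive_threshold_sweep(self):
        rng = np.random.default_rng(23)
        for _ in range(30):
            n = int(rng.integers(6, 50))
            labels = rng.integers(0, 2, size=n)
            scores = np.round(rng.random(n), 1)
            preds = self._preds(labels, scores)
            n_pos = labels.sum()
            if n_pos == 0:
                continue
            got = select_operating_point(preds, min_precision=0.5)
            # oracle: exhaustive sweep over all candidate thresholds,
            # maximizing recall, then precision, then preferring lower t
            best = None
            for t in sorted(set(scores.tolist())):
                calls = scores >= t
                if calls.sum() == 0:
                    continue
                tp = int((calls & (labels == 1)).sum())
                prec, rec = tp / calls.sum(), tp / n_pos
                if prec >= 0.5 and (best is None or (rec, prec, -t) > (best[0], best[1], -best[2])):
                    best = (rec, prec, t)
            assert got == (None if best is None else pytest.approx(best[2]))

    def test_empty_prediction_list_predicts_empty(self):
        bags = synthetic_bags()
        bundle = train_model(bags, "DEL", seed=0)
        proba, calls = predict(bundle, [])
        assert proba.size == 0 and calls.size == 0
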