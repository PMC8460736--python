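"""Cost-sensitive SVM wiring, multi-label combination, CV protocol."""

import numpy as np
import pytest

import kptmpred as kp
from kptmpred.alphabet import PTM_TYPES
from kptmpred.errors import DegenerateLabelsError, ShapeError
from kptmpred.model import (MultiLabelKPTMClassifier, SVMConfig,
                            indicator_to_label_sets, iterative_stratification,
                            label_sets_to_indicator, predict_multilabel,
                            train_binary)


@pytest.fixture(scope="module")
def balanced_corpus():
    """Balanced synthetic windows with strong planted motifs."""
    data = kp.generate(kp.GeneratorConfig(n_proteins=40, seed=11))
    ds = kp.build_benchmark(data.proteins, data.annotations, zeta=24)
    bal = kp.undersample_majority(ds, np.zeros(len(ds)), ratio=1.0)
    return bal.windows, label_sets_to_indicator(bal.label_sets)


class TestTrainBinary:
    def test_balanced_training_set_gets_unit_class_costs(self, rng):
        X = rng.normal(size=(40, 3))
        y = np.r_[np.zeros(20, int), np.ones(20, int)]
        clf = train_binary(X, y)
        assert np.allclose(clf.class_weight_, 1.0)

    def test_imbalanced_costs_follow_dec_weights(self, rng):
        X = rng.normal(size=(50, 3))
        y = np.r_[np.zeros(40, int), np.ones(10, int)]
        clf = train_binary(X, y)
        w = kp.dec_weights(10, 40)
        assert clf.class_weight_[0] == pytest.approx(w.w_neg)
        assert clf.class_weight_[1] == pytest.approx(w.w_pos)

    def test_separable_toy_set_fits_training_data(self, rng):
        X = np.vstack([rng.normal(-3, 0.2, (25, 2)),
                       rng.normal(3, 0.2, (25, 2))])
        y = np.r_[np.zeros(25, int), np.ones(25, int)]
        clf = train_binary(X, y)
        assert np.array_equal(clf.predict(X), y)

    def test_class_swap_flips_decision_scores(self, rng):
        X = rng.normal(size=(30, 4))
        y = np.r_[np.zeros(15, int), np.ones(15, int)]
        fwd = train_binary(X, y).decision_function(X)
        rev = train_binary(X, 1 - y).decision_function(X)
        # tolerance set by the delegated optimizer's stopping criterion
        assert np.allclose(fwd, -rev, atol=1e-2)

    def test_single_class_rejected(self, rng):
        with pytest.raises(DegenerateLabelsError):
            train_binary(rng.normal(size=(10, 2)), np.ones(10, int))

    def test_invalid_hyperparameters_rejected(self):
        with pytest.raises(ValueError):
            SVMConfig(C=0)
        with pytest.raises(ValueError):
            SVMConfig(gamma=-1.0)


class TestPredictMultilabel:
    @staticmethod
    def _handles(rng):
        """Well-separated per-label classifiers: class 0 near the origin,
        class 1 near (4, 4)."""
        handles, feats = {}, {}
        for i, ptm in enumerate(PTM_TYPES):
            X = rng.normal(0, 0.3, size=(30, 2)) + np.r_[np.zeros((15, 2)),
                                                         np.ones((15, 2)) * 4]
            y = np.r_[np.zeros(15, int), np.ones(15, int)]
            handles[ptm] = train_binary(X, y)
            feats[ptm] = X
        return handles, feats

    def test_all_negative_scores_give_empty_set(self, rng):
        handles, feats = self._handles(rng)
        probe = {ptm: np.zeros((1, 2)) for ptm in PTM_TYPES}
        assert predict_multilabel(handles, probe) == [frozenset()]

    def test_independent_heads_can_assign_two_labels(self, rng):
        handles, feats = self._handles(rng)
        probe = {ptm: (np.full((1, 2), 4.0)
                       if ptm in ("acetylation", "succinylation")
                       else np.zeros((1, 2)))
                 for ptm in PTM_TYPES}
        assert predict_multilabel(handles, probe) == \
            [frozenset({"acetylation", "succinylation"})]

    def test_column_mismatch_rejected(self, rng):
        handles, feats = self._handles(rng)
        feats["methylation"] = feats["methylation"][:, :1]
        with pytest.raises(ShapeError):
            predict_multilabel(handles, feats)


class TestIndicatorConversion:
    def test_round_trip(self, rng):
        sets = [frozenset({"acetylation", "glutarylation"}), frozenset(),
                frozenset({"methylation"})]
        Y = label_sets_to_indicator(sets)
        assert Y.shape == (3, 5)
        assert indicator_to_label_sets(Y) == sets


class TestIterativeStratification:
    def test_folds_partition_and_preserve_prevalence(self, rng):
        Y = (rng.random((400, 5)) < [0.4, 0.05, 0.08, 0.2, 0.05]).astype(int)
        folds = iterative_stratification(Y, 5, seed=3)
        assert folds.shape == (400,)
        assert set(folds) == set(range(5))
        sizes = np.bincount(folds)
        assert sizes.max() - sizes.min() <= 5
        for lab in range(5):
            per_fold = np.array([Y[folds == f, lab].sum() for f in range(5)])
            assert per_fold.max() - per_fold.min() <= 4

    def test_deterministic_for_a_seed(self, rng):
        Y = (rng.random((100, 5)) < 0.2).astype(int)
        a = iterative_stratification(Y, 4, seed=9)
        b = iterative_stratification(Y, 4, seed=9)
        assert np.array_equal(a, b)


class TestMultiLabelClassifier:
    def test_planted_motifs_recovered_on_heldout_windows(self, balanced_corpus):
        windows, Y = balanced_corpus
        order = np.random.default_rng(5).permutation(len(windows))
        windows = [windows[i] for i in order]
        Y = Y[order]
        split = int(0.8 * len(windows))
        clf = MultiLabelKPTMClassifier(n_features=100, random_state=0)
        clf.fit(windows[:split], Y[:split])
        report = kp.multilabel_metrics(
            indicator_to_label_sets(Y[split:]),
            clf.predict_label_sets(windows[split:]))
        assert report.accuracy > 0.6

    def test_prediction_multiplicity_tracks_truth(self, balanced_corpus):
        windows, Y = balanced_corpus
        clf = MultiLabelKPTMClassifier(n_features=100).fit(windows, Y)
        pred = clf.predict(windows)
        # training-set sanity: predicted label-count histogram close to truth
        assert abs(pred.sum() - Y.sum()) / Y.sum() < 0.2

    def test_decision_scores_align_with_predictions(self, balanced_corpus):
        windows, Y = balanced_corpus
        clf = MultiLabelKPTMClassifier(n_features=50).fit(windows, Y)
        scores = clf.decision_function(windows[:20])
        pred = clf.predict(windows[:20])
        assert np.array_equal(pred, (scores > 0).astype(int))

    def test_sklearn_param_round_trip(self):
        clf = MultiLabelKPTMClassifier(n_features=64, C=2.0)
        params = clf.get_params()
        assert params["n_features"] == 64
        clone = MultiLabelKPTMClassifier(**params)
        assert clone.get_params() == params


class TestCrossValidate:
    def test_fixed_seed_reproducible(self, balanced_corpus):
        windows, Y = balanced_corpus
        kwargs = dict(zeta=24, n_folds=3, n_repeats=1, seeds=[0],
                      n_features=60, encoders=("coupling", "be"))
        a = kp.cross_validate(windows, Y, **kwargs)
        b = kp.cross_validate(windows, Y, **kwargs)
        assert a.as_dict() == b.as_dict()

    def test_report_carries_one_value_per_repeat(self, balanced_corpus):
        windows, Y = balanced_corpus
        rep = kp.cross_validate(windows, Y, zeta=24, n_folds=3, n_repeats=2,
                                seeds=[0, 1], n_features=48,
                                encoders=("coupling",))
        assert len(rep.per_repeat["accuracy"]) == 2
        assert rep.seeds == [0, 1]
        assert set(rep.std) == set(rep.per_repeat)

    def test_perfectly_separable_labels_reach_metric_endpoints(self, rng):
        # the label is written directly into the window at offset −1
        windows, labels = [], []
        for i in range(120):
            flank = "".join(rng.choice(list("ACDEFGHILMNPQRSTVWY"), size=7))
            marker = "W" if i % 2 else "G"
            win = flank[:3] + marker + "K" + flank[3:]
            windows.append(win)
            labels.append(frozenset({"acetylation"}) if i % 2 else frozenset())
        Y = label_sets_to_indicator(labels)
        rep = kp.cross_validate(windows, Y, zeta=4, n_folds=3, n_repeats=1,
                                seeds=[0], n_features=20, k_values=(0, 1))
        assert rep.accuracy == rep.aiming == rep.coverage == rep.absolute_true == 1.0
        assert rep.absolute_false == 0.0

    def test_validation_labels_cannot_reach_trained_models(self, balanced_corpus):
        """Leakage canary: corrupting held-out labels must not change what
        the training fold produces."""
        windows, Y = balanced_corpus
        split = int(0.75 * len(windows))
        probe = windows[split:]
        clf_a = MultiLabelKPTMClassifier(n_features=80, random_state=0)
        clf_a.fit(windows[:split], Y[:split])
        corrupted = Y.copy()
        corrupted[split:] = 1 - corrupted[split:]
        clf_b = MultiLabelKPTMClassifier(n_features=80, random_state=0)
        clf_b.fit(windows[:split], corrupted[:split])
        assert np.array_equal(clf_a.decision_function(probe),
                              clf_b.decision_function(probe))
        for ptm in PTM_TYPES:
            assert np.array_equal(clf_a.supports_[ptm], clf_b.supports_[ptm])
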