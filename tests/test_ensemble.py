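import numpy as np
import pytest

from bitterfp.ensemble import (
    AverageModel,
    build_average_models,
    build_consensus,
    consensus_predict,
    ttest_compare,
)
from bitterfp.learners import TrainedModel
from bitterfp.metrics import NA


def stub_model(method="KNN", diameter=4, k=1024, feature=None, seed=0, f1=0.9):
    metrics = {"accuracy": f1, "precision": f1, "specificity": f1,
               "sensitivity": f1, "f1": f1, "mcc": 2 * f1 - 1}
    return TrainedModel(
        method=method, diameter=diameter, k=k, feature_subset=feature,
        params={}, estimator=None, cv_f1=f1, seed=seed, test_f1=f1,
        test_metrics=metrics,
    )


def stub_grid(methods, seeds, features=(None,), f1_of=None):
    models = []
    for method in methods:
        for seed in seeds:
            for feat in features:
                f1 = f1_of(method, seed) if f1_of else 0.9
                models.append(stub_model(method, feature=feat, seed=seed, f1=f1))
    return models


class TestAverageModels:
    def test_product_rule_on_scaled_grid(self):
        subset = np.arange(128)
        models = stub_grid(["KNN", "RF"], seeds=[0, 1], features=(None, subset))
        averages = build_average_models(models)
        assert len(averages) == 4  # 1 fingerprint x 2 methods x 2 feature settings
        assert all(len(a.members) == 2 for a in averages)

    def test_single_member_cell_has_zero_std(self):
        averages = build_average_models([stub_model(seed=0)])
        assert averages[0].metric_std["f1"] == 0.0

    def test_mean_is_arithmetic_mean_of_members(self):
        models = [stub_model(seed=0, f1=0.8), stub_model(seed=1, f1=1.0)]
        averages = build_average_models(models)
        assert averages[0].metric_mean["f1"] == pytest.approx(0.9)

    def test_incomplete_cell_raises(self):
        # one KNN cell has both schemes, the other is missing scheme 1
        bad = stub_grid(["KNN"], seeds=[0, 1], features=(None,))
        bad += [stub_model("KNN", feature=np.arange(64), seed=0)]
        with pytest.raises(ValueError, match="missing"):
            build_average_models(bad)


class TestConsensus:
    def test_cm01_selects_best_per_scheme(self):
        def f1_of(method, seed):
            return 0.95 if method == "RF" else 0.85

        models = stub_grid(["KNN", "RF"], seeds=[0, 1, 2], f1_of=f1_of)
        cm = build_consensus("CM01", models)
        assert len(cm.constituents) == 3
        assert all(m.method == "RF" for m in cm.constituents)

    def test_cm05_constituents_all_svm(self):
        models = stub_grid(["KNN", "SVM", "RF"], seeds=[0, 1],
                           features=(None, np.arange(128), np.arange(64),
                                     np.arange(32), np.arange(16), np.arange(8)))
        cm = build_consensus("CM05", models)
        assert len(cm.constituents) == 5
        assert all(a.method == "SVM" for a in cm.constituents)

    def test_cm02_groups_method_families(self):
        models = stub_grid(["KNN", "SVM", "GBM", "RF", "DNN2", "DNN3"], seeds=[0])
        cm = build_consensus("CM02", models)
        assert len(cm.constituents) == 5  # DNN2/DNN3 pooled into one family
        methods = {a.method for a in cm.constituents}
        assert {"KNN", "SVM", "GBM", "RF"} <= methods

    def test_unknown_id_raises(self):
        with pytest.raises(ValueError):
            build_consensus("CM99", [stub_model()])

    def test_summary_equals_mean_of_constituents(self):
        models = stub_grid(["KNN"], seeds=[0, 1, 2],
                           f1_of=lambda m, s: 0.8 + 0.05 * s)
        cm = build_consensus("CM01", models)
        f1s = [m.test_f1 for m in cm.constituents]
        assert cm.metric_mean["f1"] == pytest.approx(np.mean(f1s))


class _ProbModel:
    def __init__(self, p):
        self.p = p

    def predict_proba(self, X):
        return np.full(len(X), self.p)


class TestConsensusPredict:
    def _cm(self, probs):
        from bitterfp.ensemble import ConsensusModel

        return ConsensusModel("CM01", [_ProbModel(p) for p in probs])

    def test_unanimous(self):
        labels, probs = consensus_predict(self._cm([0.9, 0.9, 0.9]), np.zeros((1, 4)))
        assert labels[0] == 1 and probs[0] == pytest.approx(0.9)

    def test_mean_probability_rule(self):
        labels, probs = consensus_predict(
            self._cm([0.2, 0.3, 0.4, 0.9, 0.9]), np.zeros((1, 4))
        )
        assert probs[0] == pytest.approx(0.54)
        assert labels[0] == 1

    def test_exact_half_is_bitter(self):
        labels, _ = consensus_predict(self._cm([0.4, 0.6]), np.zeros((1, 4)))
        assert labels[0] == 1

    def test_permutation_invariance(self):
        probs = [0.1, 0.5, 0.9, 0.3]
        _, a = consensus_predict(self._cm(probs), np.zeros((2, 4)))
        _, b = consensus_predict(self._cm(probs[::-1]), np.zeros((2, 4)))
        assert np.allclose(a, b)


class TestTtestCompare:
    def test_identical_samples_not_significant(self):
        p, sig = ttest_compare([0.9] * 5, [0.9] * 5)
        assert p == 1.0 and not sig

    def test_decision_rule_threshold(self):
        # the p < 1e-4 criterion: 3.32e-1 -> N, 4.96e-5 -> Y
        assert not (3.3221497380e-01 < 1e-4)
        assert 4.9645296142e-05 < 1e-4

    def test_clearly_separated_samples_significant(self):
        rng = np.random.default_rng(1)
        a = 0.90 + 0.002 * rng.standard_normal(19)
        b = 0.80 + 0.002 * rng.standard_normal(19)
        p, sig = ttest_compare(a, b)
        assert sig and p < 1e-10

    def test_matches_scipy_student_t(self):
        from scipy import stats

        rng = np.random.default_rng(2)
        a, b = rng.random(19), rng.random(19)
        p, _ = ttest_compare(a, b)
        assert p == pytest.approx(stats.ttest_ind(a, b, equal_var=True).pvalue)

    def test_too_few_samples_raise(self):
        with pytest.raises(ValueError):
            ttest_compare([0.9], [0.8, 0.9])


class TestEnsembleOnTrainedCampaign:
    def test_consensus_not_much_worse_than_worst_constituent(self, study_campaign):
        """Ensemble sanity band: each consensus model's test F1 is at least
        the worst constituent's F1 minus 0.05."""
        from bitterfp.metrics import compute_metrics, confusion

        res = study_campaign
        X = res.matrices[(4, 1024)]
        scheme = res.schemes[0]
        for cid, cm in res.consensus.items():
            labels, _ = consensus_predict(cm, X[scheme.test_idx])
            rep = compute_metrics(*confusion(res.labels[scheme.test_idx], labels))
            worst = min(
                c.test_f1 if isinstance(c, TrainedModel) else c.metric_mean["f1"]
                for c in cm.constituents
            )
            assert rep.f1 >= worst - 0.05, cid
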