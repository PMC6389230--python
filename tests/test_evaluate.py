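import numpy as np
import pytest

from omibench import evaluate
from omibench.core import LabelVector, PredictionResult
from omibench.simulate import SimulationSpec, SourceSpec, generate_study


class TestConfusionMetrics:
    def test_printed_formula_example(self):
        pred = np.array([1] * 4 + [-1] * 6)
        truth = np.array([1, 1, 1, -1, 1, 1, -1, -1, -1, -1])
        counts = evaluate.confusion_metrics(pred, truth)
        assert (counts.tp, counts.fp, counts.fn, counts.tn) == (3, 1, 2, 4)
        assert counts.accuracy == pytest.approx(0.7)
        assert counts.f1 == pytest.approx(6 / 9)

    def test_perfect_prediction(self):
        truth = np.array([1, -1, 1, -1])
        counts = evaluate.confusion_metrics(truth, truth)
        assert (counts.accuracy, counts.f1) == (1.0, 1.0)
        assert (counts.sensitivity, counts.specificity) == (1.0, 1.0)

    def test_always_negative_predictor(self):
        truth = np.array([1, 1, -1, -1, -1])
        counts = evaluate.confusion_metrics(np.full(5, -1), truth)
        assert counts.f1 == 0.0
        assert counts.specificity == 1.0

    def test_accuracy_decomposes_by_class(self, rng):
        for _ in range(10):
            truth = rng.choice([-1, 1], size=30)
            if len(np.unique(truth)) < 2:
                continue
            pred = rng.choice([-1, 1], size=30)
            c = evaluate.confusion_metrics(pred, truth)
            decomposed = (c.sensitivity * c.P + c.specificity * c.N) / (c.P + c.N)
            assert c.accuracy == pytest.approx(decomposed, abs=1e-12)


class TestAUC:
    def test_perfect_separation(self):
        truth = np.array([1, 1, -1, -1])
        assert evaluate.auc(np.array([4.0, 3.0, 2.0, 1.0]), truth) == 1.0

    def test_all_tied_scores(self):
        truth = np.array([1, 1, -1, -1])
        assert evaluate.auc(np.zeros(4), truth) == 0.5

    def test_matches_brute_force_pair_counting(self, rng):
        for _ in range(25):
            truth = rng.choice([-1, 1], size=12)
            if len(np.unique(truth)) < 2:
                continue
            scores = np.round(rng.normal(size=12), 1)  # induces ties
            pos = scores[truth == 1]
            neg = scores[truth == -1]
            pairs = sum(
                1.0 if p > q else (0.5 if p == q else 0.0)
                for p in pos for q in neg
            )
            expected = pairs / (len(pos) * len(neg))
            assert evaluate.auc(scores, truth) == pytest.approx(expected, abs=1e-12)

    def test_negating_scores_flips_auc(self, rng):
        truth = np.array([1] * 6 + [-1] * 6)
        scores = rng.normal(size=12)
        assert evaluate.auc(scores, truth) == pytest.approx(
            1.0 - evaluate.auc(-scores, truth), abs=1e-12
        )

    def test_single_class_errors(self):
        with pytest.raises(ValueError, match="single class"):
            evaluate.auc(np.ones(3), np.array([1, 1, 1]))


class TestBootstrapCI:
    def test_constant_vector_is_degenerate(self):
        lo, hi = evaluate.percentile_bootstrap_ci(np.full(20, 0.83))
        assert lo == hi == pytest.approx(0.83)

    def test_brackets_the_mean(self, rng):
        v = rng.uniform(size=50)
        lo, hi = evaluate.percentile_bootstrap_ci(v, seed=1)
        assert lo <= v.mean() <= hi

    def test_width_tracks_clt_prediction(self):
        g = np.random.default_rng(4)
        v = g.normal(size=200)
        lo, hi = evaluate.percentile_bootstrap_ci(v, seed=2)
        clt_width = 2 * 1.96 * v.std(ddof=1) / np.sqrt(200)
        assert abs((hi - lo) - clt_width) / clt_width < 0.25


def _stub(label_source):
    """Algorithm stub; label_source(y_test, rng) -> predicted labels."""

    def fit_predict(study, train_idx, test_idx, seed):
        y = study.labels.labels[test_idx]
        g = np.random.default_rng(seed)
        labels = label_source(test_idx, g)
        return PredictionResult(labels, labels.astype(float), "decision_value")

    return fit_predict


class TestRepeatedHoldout:
    @pytest.fixture
    def study(self):
        return generate_study(SimulationSpec(40, [SourceSpec(6)], seed=0))

    def test_report_mean_is_mean_of_runs(self, study):
        truth = study.labels.labels
        algo = {"echo": lambda s, tr, te, seed: PredictionResult(
            truth[te], truth[te].astype(float), "decision_value")}
        report = evaluate.repeated_holdout(study, algo, n_runs=2, seed=0)
        runs = report.per_run["echo"]["accuracy"]
        assert len(runs) == 2
        assert report.summary()["echo"]["accuracy"]["mean"] == pytest.approx(np.mean(runs))
        assert report.summary()["echo"]["accuracy"]["mean"] == 1.0

    def test_constant_metric_gives_degenerate_ci(self, study):
        truth = study.labels.labels
        algo = {"echo": lambda s, tr, te, seed: PredictionResult(
            truth[te], truth[te].astype(float), "decision_value")}
        report = evaluate.repeated_holdout(study, algo, n_runs=3, seed=1)
        lo, hi = report.summary()["echo"]["accuracy"]["ci95"]
        assert lo == hi == 1.0

    def test_coin_flip_stub_near_half(self, study):
        algo = {"coin": _stub(lambda te, g: g.choice([-1, 1], size=len(te)))}
        report = evaluate.repeated_holdout(study, algo, n_runs=200, seed=3)
        mean_acc = report.summary()["coin"]["accuracy"]["mean"]
        assert abs(mean_acc - 0.5) < 0.06

    def test_split_is_stratified_three_to_one(self, study):
        seen = {}

        def probe(s, tr, te, seed):
            y = s.labels.labels
            seen["train_pos"] = int((y[tr] == 1).sum())
            seen["test_len"] = len(te)
            raise RuntimeError("stop")

        report = evaluate.repeated_holdout(study, {"probe": probe}, n_runs=1, seed=4)
        assert report.failures["probe"] == 1  # failures are excluded, not fatal
        assert seen["test_len"] == 10
        assert seen["train_pos"] == 15

    def test_test_labels_are_hidden_from_algorithms(self, study):
        """Leakage guard: the study handed to an algorithm carries 0 labels
        for every test sample."""

        def check(s, tr, te, seed):
            assert np.all(s.labels.labels[te] == 0)
            assert np.all(s.labels.labels[tr] != 0)
            labels = np.ones(len(te), dtype=int)
            return PredictionResult(labels, labels.astype(float), "decision_value")

        evaluate.repeated_holdout(study, {"check": check}, n_runs=2, seed=5)


class TestLeaveClusterOut:
    @pytest.fixture
    def clustered_study(self):
        return generate_study(
            SimulationSpec(170, [SourceSpec(6)], n_clusters=17, seed=2)
        )

    def test_twelve_train_clusters_leave_five_for_test(self, clustered_study):
        seen = []

        def probe(s, tr, te, seed):
            seen.append((set(s.clusters[tr]), set(s.clusters[te])))
            labels = np.ones(len(te), dtype=int)
            return PredictionResult(labels, labels.astype(float), "decision_value")

        evaluate.leave_cluster_out(clustered_study, {"p": probe},
                                   n_train_clusters=12, n_runs=5, seed=0)
        for train_clusters, test_clusters in seen:
            assert len(train_clusters) == 12
            assert len(test_clusters) == 5
            assert not train_clusters & test_clusters

    def test_two_cluster_partition_is_exactly_clusterwise(self):
        study = generate_study(
            SimulationSpec(40, [SourceSpec(5)], n_clusters=2, seed=6)
        )
        seen = {}

        def probe(s, tr, te, seed):
            seen["tr"], seen["te"] = set(tr), set(te)
            labels = np.ones(len(te), dtype=int)
            return PredictionResult(labels, labels.astype(float), "decision_value")

        evaluate.leave_cluster_out(study, {"p": probe}, n_train_clusters=1,
                                   n_runs=1, seed=1)
        assert not seen["tr"] & seen["te"]
        assert seen["tr"] | seen["te"] == set(range(40))
        for c in np.unique(study.clusters):
            members = set(np.flatnonzero(study.clusters == c))
            assert members <= seen["tr"] or members <= seen["te"]

    def test_missing_clusters_rejected(self):
        study = generate_study(SimulationSpec(20, [SourceSpec(4)], seed=3))
        with pytest.raises(ValueError, match="cluster"):
            evaluate.leave_cluster_out(study, {}, n_train_clusters=1, n_runs=1)


def test_imbalance_experiment_hits_exact_ratios():
    study = generate_study(
        SimulationSpec(160, [SourceSpec(5)], class_balance=0.75, seed=9)
    )
    def probe(s, tr, te, seed):
        labels = np.ones(len(te), dtype=int)
        return PredictionResult(labels, labels.astype(float), "decision_value")

    reports = evaluate.imbalance_experiment(study, {"p": probe},
                                            ratios=((5, 1), (5, 2)),
                                            n_runs=1, seed=0)
    assert set(reports) == {"5:1", "5:2"}
    from omibench.simulate import subsample_imbalance

    for ratio in ((5, 1), (5, 2)):
        sub = subsample_imbalance(study, ratio, seed=0)
        y = sub.labels.labels
        n_pos, n_neg = int((y == 1).sum()), int((y == -1).sum())
        assert n_pos * ratio[1] == n_neg * ratio[0]
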