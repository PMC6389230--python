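import numpy as np
import pytest
from scipy import stats

from omibench import bayesnet
from omibench.simulate import SimulationSpec, SourceSpec, generate_study


class TestFilterFeatures:
    def test_flat_feature_not_selected(self, rng):
        X = np.column_stack([rng.normal(size=100), np.zeros(100)])
        y = np.array([1] * 50 + [-1] * 50)
        X[:, 0] += 2.0 * y  # one real feature so the fallback never fires
        scorer = bayesnet.filter_features(X, y)
        assert 1 not in scorer.feature_idx

    def test_strong_feature_selected_with_positive_direction(self, rng):
        y = np.array([1] * 50 + [-1] * 50)
        X = rng.normal(size=(100, 1))
        X[:, 0] += 1.5 * y  # Delta = 3 sd between class means
        scorer = bayesnet.filter_features(X, y)
        assert list(scorer.feature_idx) == [0]
        assert scorer.directions[0] == 1.0

    def test_null_features_rarely_pass_bonferroni(self):
        """1000 pure-noise features: expected Bonferroni passes ~0.05, so the
        single-feature fallback should dominate; allow at most 2 picks."""
        small = 0
        for seed in range(20):
            g = np.random.default_rng(seed)
            X = g.normal(size=(80, 1000))
            y = np.array([1] * 40 + [-1] * 40)
            scorer = bayesnet.filter_features(X, y)
            small += int(len(scorer.feature_idx) <= 2)
        assert small >= 19

    def test_fallback_keeps_smallest_p_feature(self, rng):
        X = rng.normal(size=(30, 5))
        y = np.array([1] * 15 + [-1] * 15)
        scorer = bayesnet.filter_features(X, y)
        _, p = stats.ttest_ind(X[y == 1], X[y == -1], axis=0)
        assert len(scorer.feature_idx) >= 1
        if len(scorer.feature_idx) == 1:
            assert scorer.feature_idx[0] == np.argmin(p)


class TestScoresAndBinning:
    def test_single_feature_score_is_its_zvalue(self, rng):
        y = np.array([1] * 30 + [-1] * 30)
        X = rng.normal(size=(60, 1))
        X[:, 0] += 2.0 * y
        scorer = bayesnet.filter_features(X, y)
        s = scorer.score(X)
        z = (X[:, 0] - scorer.mean[0]) / scorer.sd[0]
        np.testing.assert_allclose(s, z * scorer.directions[0], atol=1e-12)

    def test_quartile_edges_linear_interpolation(self):
        edges, binned = bayesnet.discretize_quartiles(np.arange(1.0, 9.0))
        np.testing.assert_allclose(edges, [2.75, 4.5, 6.25])
        np.testing.assert_array_equal(np.bincount(binned), [2, 2, 2, 2])

    def test_boundary_value_falls_in_lower_bin(self):
        edges = np.array([2.75, 4.5, 6.25])
        assert bayesnet.apply_bins(np.array([2.75]), edges)[0] == 0
        assert bayesnet.apply_bins(np.array([4.5]), edges)[0] == 1

    def test_test_score_below_training_minimum_goes_to_first_bin(self):
        edges, _ = bayesnet.discretize_quartiles(np.arange(1.0, 9.0))
        assert bayesnet.apply_bins(np.array([-100.0]), edges)[0] == 0

    def test_constant_scores_collapse_to_single_bin(self):
        with pytest.warns(UserWarning, match="single bin"):
            edges, binned = bayesnet.discretize_quartiles(np.full(10, 3.3))
        assert edges.size == 0
        assert set(binned) == {0}


class TestStructure:
    def test_independent_sources_stay_disconnected(self):
        g = np.random.default_rng(0)
        scores = g.normal(size=(200, 2))
        y = np.array([1] * 100 + [-1] * 100)
        assert bayesnet.build_structure(scores, y) == []

    def test_duplicated_source_is_linked(self, rng):
        s = rng.normal(size=200)
        scores = np.column_stack([s, s])
        y = np.array([1] * 100 + [-1] * 100)
        assert bayesnet.build_structure(scores, y) == [(0, 1)]

    def test_unattainable_threshold_recovers_naive_model(self, rng):
        s = rng.normal(size=100)
        scores = np.column_stack([s, s])
        y = np.array([1] * 50 + [-1] * 50)
        assert bayesnet.build_structure(scores, y, threshold=1.1) == []


class TestPosteriorOdds:
    def _model(self, prior_odds, tables):
        m = len(tables)
        return bayesnet.BayesNetClassifier(
            scorers=[None] * m, bin_edges=[None] * m, structure=[],
            components=[[i] for i in range(m)],
            cpts={(i,): tables[i] for i in range(m)},
            prior_odds=prior_odds, n_bins=2, pseudocount=1.0,
        )

    def test_neutral_evidence_with_balanced_prior_classifies_negative(self):
        model = self._model(1.0, [{1: np.array([0.5, 0.5]), -1: np.array([0.5, 0.5])}])
        pred = bayesnet.posterior_odds_classify(model, np.array([[0]]))
        assert pred.scores[0] == pytest.approx(1.0)
        assert pred.predicted_labels[0] == -1  # odds = 1 is the tie rule

    def test_single_likelihood_ratio_arithmetic(self):
        model = self._model(1.0, [{1: np.array([0.8, 0.2]), -1: np.array([0.2, 0.8])}])
        pred = bayesnet.posterior_odds_classify(model, np.array([[0]]))
        assert pred.scores[0] == pytest.approx(4.0)
        assert pred.predicted_labels[0] == 1

    def test_independent_ratios_multiply_with_prior(self):
        tables = [{1: np.array([2 / 3, 1 / 3]), -1: np.array([1 / 3, 2 / 3])}] * 2
        model = self._model(0.5, tables)
        pred = bayesnet.posterior_odds_classify(model, np.array([[0, 0]]))
        assert pred.scores[0] == pytest.approx(0.5 * 2 * 2)
        assert pred.predicted_labels[0] == 1

    def test_simple_and_structured_agree_when_no_edges(self):
        study = generate_study(SimulationSpec(
            120, [SourceSpec(20, 5, 2.0), SourceSpec(20, 5, 2.0)], seed=4
        ))
        y = study.labels.labels
        mats = [s.values for s in study.sources]
        simple = bayesnet.fit_bayes_net(mats, y, variant="simple")
        structured = bayesnet.fit_bayes_net(mats, y, variant="structured",
                                            edge_threshold=1.1)
        binned = simple.transform(mats)
        np.testing.assert_allclose(
            bayesnet.posterior_odds(simple, binned),
            bayesnet.posterior_odds(structured, binned),
        )

    def test_all_bin_patterns_have_finite_odds(self):
        """The pseudocount guarantees finite odds even for unseen patterns."""
        import itertools

        study = generate_study(SimulationSpec(
            40, [SourceSpec(10, 3, 2.0), SourceSpec(10, 0)], seed=8
        ))
        model = bayesnet.fit_bayes_net([s.values for s in study.sources],
                                       study.labels.labels)
        patterns = np.array(list(itertools.product(range(4), repeat=2)))
        odds = bayesnet.posterior_odds(model, patterns)
        assert np.all(np.isfinite(odds)) and np.all(odds > 0)


def test_empirical_odds_converge_to_analytic_model():
    """On a known two-variable discrete generative model at n = 10,000 the
    empirical posterior odds land within 10% of the analytic odds."""
    g = np.random.default_rng(99)
    n = 10_000
    y = np.where(g.uniform(size=n) < 0.6, 1, -1)
    p_pos = np.array([0.1, 0.2, 0.3, 0.4])
    p_neg = np.array([0.4, 0.3, 0.2, 0.1])
    v1 = np.where(y[:, None] == 1, g.choice(4, size=(n, 1), p=p_pos),
                  g.choice(4, size=(n, 1), p=p_neg)).ravel()
    v2 = np.where(y[:, None] == 1, g.choice(4, size=(n, 1), p=p_neg),
                  g.choice(4, size=(n, 1), p=p_pos)).ravel()
    binned = np.column_stack([v1, v2])
    model = bayesnet.BayesNetClassifier(
        scorers=[None, None], bin_edges=[None, None], structure=[],
        components=[[0], [1]], cpts={}, prior_odds=0.0, n_bins=4,
        pseudocount=1e-9,
    )
    # estimate CPTs from the sample (pseudocount -> 0 limit)
    for i in (0, 1):
        tables = {}
        for cls in (1, -1):
            counts = np.bincount(binned[y == cls, i], minlength=4) + 1e-9
            tables[cls] = counts / counts.sum()
        model.cpts[(i,)] = tables
    model.prior_odds = (y == 1).sum() / (y == -1).sum()
    import itertools

    patterns = np.array(list(itertools.product(range(4), repeat=2)))
    empirical = bayesnet.posterior_odds(model, patterns)
    analytic = (0.6 / 0.4) * (p_pos[patterns[:, 0]] / p_neg[patterns[:, 0]]) \
        * (p_neg[patterns[:, 1]] / p_pos[patterns[:, 1]])
    rel_err = np.abs(empirical / analytic - 1.0)
    assert np.all(np.isfinite(empirical))
    assert rel_err.mean() < 0.10
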