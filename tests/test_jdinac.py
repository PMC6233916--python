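"""Pair densities, log density-ratio features and the JDINAC driver."""

import numpy as np
import pytest
from sklearn.metrics import roc_auc_score

from crdnet import jdinac, synthetic
from crdnet.cohort_io import CRDMatrix
from crdnet.jdinac import (
    BivariateKDE,
    DENSITY_FLOOR,
    NormalScoresTransform,
    density_ratio_features,
    extract_network,
    fit_pair_density,
    fit_pair_density_model,
    jdinac_fit,
    pair_list,
    predict,
)

from conftest import make_crd


class TestPairDensity:
    def test_integrates_to_one(self, rng):
        pts = rng.normal(size=(60, 2))
        kde = fit_pair_density(pts)
        grid = np.linspace(-6, 6, 161)
        gx, gy = np.meshgrid(grid, grid)
        dens = kde.evaluate(np.column_stack([gx.ravel(), gy.ravel()]))
        step = grid[1] - grid[0]
        assert dens.reshape(gx.shape).sum() * step**2 == pytest.approx(1.0, abs=0.02)

    def test_centroid_denser_than_far_point(self, rng):
        pts = rng.normal(size=(50, 2))
        kde = fit_pair_density(pts)
        centre = kde.evaluate(pts.mean(axis=0))
        far = kde.evaluate(pts.mean(axis=0) + 10 * kde.h)
        assert centre[0] > far[0]

    def test_duplication_invariance_with_fixed_bandwidth(self, rng):
        pts = rng.normal(size=(30, 2))
        doubled = np.vstack([pts, pts])
        kde1 = fit_pair_density(pts, bandwidth_rule="fixed", fixed_bandwidth=0.4)
        kde2 = fit_pair_density(doubled, bandwidth_rule="fixed", fixed_bandwidth=0.4)
        q = rng.normal(size=(7, 2))
        np.testing.assert_allclose(kde1.evaluate(q), kde2.evaluate(q), atol=1e-12)

    def test_too_few_points(self):
        with pytest.raises(ValueError, match="too few"):
            fit_pair_density(np.zeros((3, 2)), label="(Der p 1, Der p 2)/class 1")


class TestDensityRatioFeatures:
    def _model(self, x, y, **kw):
        return fit_pair_density_model(x, y, [f"c{i}" for i in range(x.shape[1])], **kw)

    def test_matches_manual_kde_oracle(self, rng):
        x = rng.normal(size=(40, 3))
        y = np.r_[np.zeros(20, int), np.ones(20, int)]
        model = self._model(x, y, bandwidth_rule="fixed", fixed_bandwidth=0.5)
        q = rng.normal(size=(5, 3))
        feats = density_ratio_features(q, model)
        for k, (i, j) in enumerate(pair_list(3)):
            for row in range(5):
                manual = {}
                for cls in (0, 1):
                    pts = x[y == cls][:, [i, j]]
                    h = 0.5
                    kern = np.exp(
                        -0.5 * (((q[row, i] - pts[:, 0]) / h) ** 2
                                + ((q[row, j] - pts[:, 1]) / h) ** 2)
                    )
                    manual[cls] = max(kern.mean() / (h * h * 2 * np.pi), DENSITY_FLOOR)
                assert feats[row, k] == pytest.approx(
                    np.log(manual[1] / manual[0]), abs=1e-8
                )

    def test_identical_classes_give_small_features(self, rng):
        x = rng.normal(size=(2000, 3))
        y = np.r_[np.zeros(1000, int), np.ones(1000, int)]  # same distribution
        model = self._model(x, y)
        feats = density_ratio_features(rng.normal(size=(200, 3)), model)
        assert np.abs(feats).mean() < 0.2

    def test_far_point_floors_to_zero(self, rng):
        x = rng.normal(size=(30, 2))
        y = np.r_[np.zeros(15, int), np.ones(15, int)]
        model = self._model(x, y)
        feats = density_ratio_features(np.full((1, 2), 1e3), model)
        np.testing.assert_array_equal(feats, np.zeros((1, 1)))

    def test_antisymmetric_under_class_swap(self, rng):
        x = rng.normal(size=(60, 4))
        y = np.r_[np.zeros(25, int), np.ones(35, int)]
        kw = dict(bandwidth_rule="fixed", fixed_bandwidth=0.4)
        q = np.linspace(-1, 1, 40).reshape(10, 4)
        feats = density_ratio_features(q, self._model(x, y, **kw))
        swapped = density_ratio_features(q, self._model(x, 1 - y, **kw))
        np.testing.assert_allclose(feats, -swapped, atol=1e-10)

    def test_component_mismatch(self, rng):
        x = rng.normal(size=(30, 3))
        y = np.r_[np.zeros(15, int), np.ones(15, int)]
        model = self._model(x, y)
        with pytest.raises(ValueError, match="mismatch"):
            density_ratio_features(rng.normal(size=(5, 4)), model)


class TestNormalScores:
    def test_ties_map_to_common_score_and_range_is_clamped(self):
        x = np.array([[0.0], [0.0], [0.0], [1.0], [2.0]])
        t = NormalScoresTransform.fit(x)
        out = t.apply(np.array([[0.0], [5.0], [-1.0]]))
        assert out[1, 0] == t.scores[0][-1]   # above range -> top score
        assert out[2, 0] == t.scores[0][0]    # below range -> bottom score
        zeros = t.apply(np.zeros((2, 1)))
        assert zeros[0, 0] == zeros[1, 0]

    def test_monotone(self, rng):
        x = rng.lognormal(size=(50, 1))
        t = NormalScoresTransform.fit(x)
        q = np.sort(rng.lognormal(size=(20, 1)), axis=0)
        out = t.apply(q)
        assert (np.diff(out[:, 0]) >= 0).all()


class TestJdinacFit:
    def _planted_cohort(self, seed=1, n=300, p=6):
        cfg = synthetic.CohortConfig(
            n_participants=n, n_components=p, outcome_prevalence=0.4,
            signal_regime="interaction_only",
            differential_pairs=[(0, 1, 0.7, -0.7)], seed=seed,
        )
        crd, out, _ = synthetic.generate_cohort(cfg)
        return crd, out.binary["asthma"].to_numpy()

    def test_fixed_seed_reproducible(self):
        crd, y = self._planted_cohort()
        a = jdinac_fit(crd, y, n_repetitions=3, seed=5)
        b = jdinac_fit(crd, y, n_repetitions=3, seed=5)
        np.testing.assert_array_equal(a.differential_weight, b.differential_weight)
        np.testing.assert_array_equal(a.averaged_probabilities, b.averaged_probabilities)

    def test_weights_bounded_and_probabilities_valid(self):
        crd, y = self._planted_cohort(seed=2)
        fit = jdinac_fit(crd, y, n_repetitions=4, seed=1)
        assert (fit.differential_weight <= fit.max_weight).all()
        assert (fit.differential_weight >= 0).all()
        probs = fit.averaged_probabilities
        assert ((probs >= 0) & (probs <= 1)).all()

    def test_planted_pair_dominates_and_predicts(self):
        crd, y = self._planted_cohort(seed=3, n=400)
        fit = jdinac_fit(crd, y, n_repetitions=10, seed=7)
        assert fit.pairs[int(fit.differential_weight.argmax())] == (0, 1)
        assert roc_auc_score(y, fit.averaged_probabilities) > 0.7

    def test_marginal_insensitivity_under_interaction_signal(self):
        """Pairwise features carry the class signal although no single
        component does — the central claim of the pairwise approach."""
        crd, y = self._planted_cohort(seed=4, n=1200, p=6)
        x = np.log1p(crd.to_numpy())
        uni_auc = [roc_auc_score(y, x[:, j]) for j in range(6)]
        assert all(0.45 <= a <= 0.55 for a in uni_auc)
        fit = jdinac_fit(crd, y, n_repetitions=6, seed=7)
        assert roc_auc_score(y, fit.averaged_probabilities) > 0.7

    def test_single_class_rejected(self):
        crd, _ = self._planted_cohort()
        with pytest.raises(ValueError, match="both outcome classes"):
            jdinac_fit(crd, np.zeros(crd.shape[0], int), n_repetitions=2)

    def test_predict_on_new_data(self, rng):
        crd, y = self._planted_cohort(seed=5, n=300)
        fit = jdinac_fit(crd, y, n_repetitions=5, seed=2)
        new_crd, new_y = self._planted_cohort(seed=6, n=300)
        probs = predict(fit, new_crd)
        assert ((probs >= 0) & (probs <= 1)).all()
        train_auc = roc_auc_score(y, fit.averaged_probabilities)
        new_auc = roc_auc_score(new_y, probs)
        assert abs(new_auc - train_auc) < 0.1

    def test_permuting_rows_permutes_predictions(self, rng):
        crd, y = self._planted_cohort(seed=7, n=200)
        fit = jdinac_fit(crd, y, n_repetitions=3, seed=3)
        perm = rng.permutation(crd.shape[0])
        shuffled = CRDMatrix(crd.data.iloc[perm])
        np.testing.assert_allclose(
            predict(fit, shuffled), predict(fit, crd)[perm], atol=1e-12
        )

    def test_predict_component_mismatch(self):
        crd, y = self._planted_cohort(seed=8, n=200, p=5)
        fit = jdinac_fit(crd, y, n_repetitions=2, seed=1)
        other = make_crd(np.ones((4, 4)))
        with pytest.raises(ValueError, match="mismatch"):
            predict(fit, other)


class TestExtractNetwork:
    def _fit(self):
        cfg = synthetic.CohortConfig(
            n_participants=250, n_components=5, outcome_prevalence=0.4,
            signal_regime="interaction_only",
            differential_pairs=[(1, 3, 0.7, -0.7)], seed=10,
        )
        crd, out, _ = synthetic.generate_cohort(cfg)
        return jdinac_fit(crd, out.binary["asthma"].to_numpy(),
                          n_repetitions=6, seed=4)

    def test_impossible_fraction_gives_empty_network(self):
        net = extract_network(self._fit(), min_fraction=1.01)
        assert len(net.edges) == 0

    def test_lowering_fraction_never_removes_edges(self):
        fit = self._fit()
        strict = extract_network(fit, min_fraction=0.5)
        loose = extract_network(fit, min_fraction=0.25)
        strict_edges = set(map(tuple, strict.edges[["comp_a", "comp_b"]].to_numpy()))
        loose_edges = set(map(tuple, loose.edges[["comp_a", "comp_b"]].to_numpy()))
        assert strict_edges <= loose_edges

    def test_planted_edge_present_with_risk_direction(self):
        fit = self._fit()
        net = extract_network(fit, min_fraction=0.25)
        names = {tuple(sorted(e)) for e in net.edges[["comp_a", "comp_b"]].to_numpy()}
        planted = tuple(sorted((fit.component_ids[1], fit.component_ids[3])))
        assert planted in names
        row = net.edges[(net.edges.comp_a == planted[0]) & (net.edges.comp_b == planted[1])]
        assert row.direction.iloc[0] == "risk"
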