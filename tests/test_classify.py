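import numpy as np
import pytest

from dyadeeg.classify import (
    GameFeatures,
    TickLikelihoods,
    classify_by_ratio,
    fit_gaussian_model,
    fuse,
    posterior_equality_threshold,
    run_regime,
    subsample_nulls,
    tick_likelihoods,
)
from dyadeeg.preprocess import TICK_CLASSES

CLASSES = TICK_CLASSES


def _toy_training(rng, n_per_class=200, k=2, spread=1.0):
    means = {c: rng.normal(0.0, 3.0, size=k) for c in CLASSES}
    X, y = [], []
    for c in CLASSES:
        X.append(means[c] + rng.normal(0.0, spread, size=(n_per_class, k)))
        y += [c] * n_per_class
    return np.concatenate(X), np.array(y, dtype=object), means


def _lik(values, ticks=None, source="Shooter"):
    values = np.atleast_2d(np.asarray(values, dtype=float))
    return TickLikelihoods(
        ticks=np.asarray(ticks if ticks is not None else np.arange(len(values))),
        classes=CLASSES,
        loglik=np.log(values),
        source=source,
    )


class TestFitGaussianModel:
    def test_recovers_means_and_identity_covariance(self, rng):
        X, y, means = _toy_training(rng, n_per_class=4000)
        model = fit_gaussian_model(X, y, shrinkage=0.0)
        for i, c in enumerate(CLASSES):
            np.testing.assert_allclose(model.means[i], means[c], atol=0.1)
        np.testing.assert_allclose(model.covariance, np.eye(2), atol=0.06)

    def test_full_shrinkage_gives_exactly_diagonal_covariance(self, rng):
        X, y, _ = _toy_training(rng)
        model = fit_gaussian_model(X, y, shrinkage=1.0)
        off = model.covariance - np.diag(np.diag(model.covariance))
        assert np.abs(off).max() == 0.0

    def test_missing_class_raises_naming_it(self, rng):
        X, y, _ = _toy_training(rng)
        with pytest.raises(ValueError, match="BaitDeath"):
            fit_gaussian_model(X[y != "BaitDeath"], y[y != "BaitDeath"])

    def test_mean_recovery_within_sampling_error(self, rng):
        # moderately high-dimensional check: elementwise 3-SE band
        k, n = 10, 5000
        true_means = rng.normal(0.0, 1.0, size=(4, k))
        X, y = [], []
        for i, c in enumerate(CLASSES):
            X.append(true_means[i] + rng.normal(0.0, 1.0, size=(n // 4, k)))
            y += [c] * (n // 4)
        model = fit_gaussian_model(np.concatenate(X), np.array(y, dtype=object))
        se = 1.0 / np.sqrt(n // 4)
        assert np.all(np.abs(model.means - true_means) < 3.5 * se + 1e-9)

    def test_priors_are_training_frequencies(self, rng):
        X, y, _ = _toy_training(rng, n_per_class=50)
        model = fit_gaussian_model(X, y)
        np.testing.assert_allclose(model.priors, 0.25)


class TestTickLikelihoods:
    def test_class_mean_attains_maximal_own_density(self, rng):
        X, y, means = _toy_training(rng, n_per_class=500)
        model = fit_gaussian_model(X, y)
        tl = tick_likelihoods(model, model.means.copy())
        assert all(np.argmax(tl.loglik[i]) == i for i in range(4))

    def test_equidistant_point_scores_classes_equally(self, rng):
        X = rng.normal(size=(200, 2))
        y = np.array(["Kill"] * 100 + ["Null"] * 100, dtype=object)
        model = fit_gaussian_model(X, y, classes=("Kill", "Null"))
        # exact shared spherical covariance and means for the closed form
        model.means = np.array([[0.0, 0.0], [1.0, 0.0]])
        model.covariance = np.eye(2)
        model._chol = None
        tl = tick_likelihoods(model, np.array([[0.5, 0.7]]))
        assert tl.loglik[0, 0] == pytest.approx(tl.loglik[0, 1], abs=1e-10)

    def test_one_dimensional_closed_form_log_ratio(self):
        # unit-variance means 0 and 1: llr(x) = 0.5 - x; at x = 0.3 -> 0.2
        model = fit_gaussian_model(
            np.concatenate(
                [np.random.default_rng(0).normal(0, 1, (20000, 1)),
                 1 + np.random.default_rng(1).normal(0, 1, (20000, 1))]
            ),
            np.array(["Kill"] * 20000 + ["Null"] * 20000, dtype=object),
            classes=("Kill", "Null"),
        )
        # overwrite with the exact parameters for a closed-form check
        model.means = np.array([[0.0], [1.0]])
        model.covariance = np.eye(1)
        model._chol = None
        tl = tick_likelihoods(model, np.array([[0.3]]))
        assert tl.llr("Kill", "Null")[0] == pytest.approx(0.2, abs=1e-12)

    def test_shared_covariance_makes_log_ratio_affine(self, rng):
        X, y, _ = _toy_training(rng, k=3)
        model = fit_gaussian_model(X, y)
        pts = rng.normal(size=(6, 3))
        tl = tick_likelihoods(model, pts)
        ratios = tl.llr("Kill", "Null")
        # affine: value at midpoint = mean of endpoint values
        mid = tick_likelihoods(model, (pts[:3] + pts[3:]) / 2.0)
        np.testing.assert_allclose(
            mid.llr("Kill", "Null"), (ratios[:3] + ratios[3:]) / 2.0, rtol=1e-8
        )

    def test_non_finite_features_rejected(self, rng):
        X, y, _ = _toy_training(rng)
        model = fit_gaussian_model(X, y)
        with pytest.raises(ValueError):
            tick_likelihoods(model, np.array([[np.nan, 0.0]]))


class TestFusion:
    def test_worked_example_exact(self):
        shooter = _lik([[0.8, 0.1, 0.05, 0.05]])
        bait = _lik([[0.4, 0.4, 0.1, 0.1]], source="Bait")
        combined = np.exp(fuse(shooter, bait).loglik[0])
        expected = np.array([0.32, 0.04, 0.005, 0.005]) / 0.37
        np.testing.assert_allclose(combined, expected, atol=1e-12)

    def test_uniform_sources_stay_uniform(self):
        u = _lik([[0.25] * 4])
        np.testing.assert_allclose(
            np.exp(fuse(u, _lik([[0.25] * 4], source="Bait")).loglik[0]), 0.25,
            atol=1e-12,
        )

    def test_uniform_partner_is_neutral(self):
        shooter = _lik([[0.8, 0.1, 0.05, 0.05]])
        uniform = _lik([[0.25] * 4], source="Bait")
        np.testing.assert_allclose(
            np.exp(fuse(shooter, uniform).loglik[0]),
            [0.8, 0.1, 0.05, 0.05],
            atol=1e-12,
        )

    def test_commutative_and_normalized(self, rng):
        a = _lik(rng.dirichlet(np.ones(4), size=20) * rng.uniform(0.1, 5))
        b = _lik(rng.dirichlet(np.ones(4), size=20), source="Bait")
        ab, ba = fuse(a, b), fuse(b, a)
        np.testing.assert_allclose(ab.loglik, ba.loglik, atol=1e-12)
        np.testing.assert_allclose(np.exp(ab.loglik).sum(axis=1), 1.0, atol=1e-12)

    def test_self_fusion_squares_likelihood_ratios(self):
        a = _lik([[0.5, 0.25, 0.15, 0.10]])
        fused = np.exp(fuse(a, _lik([[0.5, 0.25, 0.15, 0.10]], source="Bait")).loglik[0])
        assert fused[0] / fused[1] == pytest.approx((0.5 / 0.25) ** 2, rel=1e-12)

    def test_tick_misalignment_rejected(self):
        with pytest.raises(ValueError):
            fuse(_lik([[0.25] * 4], ticks=[5]), _lik([[0.25] * 4], ticks=[6]))


class TestThresholding:
    def test_tie_at_threshold_goes_to_b(self):
        assert not classify_by_ratio(np.log([2.0]), np.log([2.0]), 1.0)[0]

    def test_extreme_thresholds_saturate(self, rng):
        la, lb = rng.normal(size=50), rng.normal(size=50)
        assert classify_by_ratio(la, lb, 1e-300).all()
        assert not classify_by_ratio(la, lb, 1e300).any()

    def test_threshold_sweep_equals_rank_sweep(self, rng):
        # thresholds placed between consecutive sorted log-ratios pick out
        # exactly the top-m ticks: the ratio classifier's operating points
        # are the rank-order sweep
        la, lb = rng.normal(size=200), rng.normal(size=200)
        ratios = np.sort(la - lb)[::-1]
        for m in range(1, 200):
            theta = np.exp((ratios[m - 1] + ratios[m]) / 2.0)
            assert classify_by_ratio(la, lb, theta).sum() == m

    def test_posterior_equality_threshold_from_priors(self):
        theta = posterior_equality_threshold(
            {"Kill": 0.0013, "Null": 0.99}, "Kill", "Null"
        )
        assert theta == pytest.approx(0.99 / 0.0013)
        with pytest.raises(ValueError):
            classify_by_ratio(np.zeros(3), np.zeros(3), 0.0)


class TestRegimes:
    @staticmethod
    def _dataset(rng, n_teams=2, n_games=3, n=120, k=2):
        games = []
        for t in range(n_teams):
            for g in range(n_games):
                labels = np.array(
                    ["Null"] * (n - 6)
                    + ["Kill", "Kill", "ShooterDeath", "ShooterDeath", "BaitDeath", "BaitDeath"],
                    dtype=object,
                )
                rng.shuffle(labels)
                feats = {
                    role: rng.normal(size=(n, k))
                    + 2.0 * (labels != "Null")[:, None]
                    for role in ("Shooter", "Bait")
                }
                games.append(
                    GameFeatures(
                        team_id=t,
                        game_id=g,
                        ticks=np.arange(30, 30 + n),
                        labels=labels,
                        features=feats,
                    )
                )
        return games

    def test_within_team_excludes_target_game(self, rng):
        games = self._dataset(rng)
        target = games[0]
        out = run_regime(games, "within_team", target)
        assert set(out) == {"Shooter", "Bait"}
        assert len(out["Shooter"].ticks) == len(target.ticks)

    def test_between_team_trains_only_on_other_teams(self, rng):
        games = self._dataset(rng)
        target = games[0]
        # poison the other team's features: a constant offset the model
        # will absorb into its means, proving the training source
        for g in games:
            if g.team_id != 0:
                for role in g.features:
                    g.features[role] = g.features[role] + 100.0
        out = run_regime(games, "between_team", target)
        # target features are far below the poisoned training means
        assert out["Shooter"].loglik.max() < -1000

    def test_insufficient_folds_rejected(self, rng):
        games = [g for g in self._dataset(rng, n_teams=1, n_games=1)]
        with pytest.raises(ValueError, match="within_team"):
            run_regime(games, "within_team", games[0])
        with pytest.raises(ValueError, match="between_team"):
            run_regime(games, "between_team", games[0])
        with pytest.raises(ValueError, match="regime"):
            run_regime(games, "pooled", games[0])


class TestSubsampleNulls:
    def test_keeps_all_events_and_caps_nulls(self, rng):
        labels = np.array(["Null"] * 100 + ["Kill"] * 5, dtype=object)
        keep = subsample_nulls(labels, 10, rng)
        assert (labels[keep] == "Kill").sum() == 5
        assert (labels[keep] == "Null").sum() == 10

    def test_zero_cap_keeps_everything(self, rng):
        labels = np.array(["Null"] * 50 + ["Kill"] * 2, dtype=object)
        assert len(subsample_nulls(labels, 0, rng)) == 52
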