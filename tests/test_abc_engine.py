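"""ABC machinery: distances, rejection, model choice, estimation."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from coalabc.abc_engine import (
    ReferenceTable,
    bayes_factors,
    cross_validate_model_choice,
    estimate_parameters,
    goodness_of_fit,
    model_posterior_mnlogistic,
    normalize_and_distance,
    posterior_predictive_check,
    rejection_sample,
)
from coalabc.errors import ABCError

BOUNDS = {"theta": (0.0, 100.0)}


def _table(rng, n, code="X", stat_fn=None, bounds=None, n_stats=3):
    """Reference table with uniform theta and configurable statistics."""
    bounds = bounds or BOUNDS
    params = pd.DataFrame(
        {k: rng.uniform(lo, hi, n) for k, (lo, hi) in bounds.items()}
    )
    if stat_fn is None:
        stats_arr = rng.normal(size=(n, n_stats))
    else:
        stats_arr = stat_fn(params, rng)
    names = [f"s{i}" for i in range(stats_arr.shape[1])]
    return ReferenceTable(code, params, stats_arr, names, bounds)


class TestDistances:
    def test_zero_for_matching_row(self, rng):
        t = _table(rng, 50)
        d, _ = normalize_and_distance(t.stats[7], t.stats, t.stat_names)
        assert d[7] == 0.0

    def test_hand_computed_example(self):
        stats = np.array([[1.0, 10.0], [2.0, 20.0], [3.0, 30.0]])
        obs = np.array([2.0, 10.0])
        # MAD (normal-consistent) of col0 = 1*1.4826, col1 = 10*1.4826
        d, scales = normalize_and_distance(obs, stats, ["a", "b"])
        s0, s1 = 1.4826, 14.826
        expect = [
            np.hypot(1 / s0, 0.0),
            np.hypot(0.0, 10 / s1),
            np.hypot(1 / s0, 20 / s1),
        ]
        assert d == pytest.approx(expect, rel=1e-3)

    def test_column_rescaling_preserves_ranks(self, rng):
        t = _table(rng, 200)
        obs = rng.normal(size=3)
        d1, _ = normalize_and_distance(obs, t.stats, t.stat_names)
        scaled = t.stats * np.array([10.0, 0.5, 3.0])
        d2, _ = normalize_and_distance(
            obs * np.array([10.0, 0.5, 3.0]), scaled, t.stat_names
        )
        assert np.array_equal(np.argsort(d1), np.argsort(d2))

    def test_constant_statistic_dropped_with_warning(self, rng):
        t = _table(rng, 50)
        stats_arr = t.stats.copy()
        stats_arr[:, 1] = 5.0
        with pytest.warns(UserWarning, match="constant"):
            d, scales = normalize_and_distance(
                np.zeros(3), stats_arr, t.stat_names
            )
        assert scales[1] == 0.0 and np.all(np.isfinite(d))

    def test_dimension_mismatch(self, rng):
        t = _table(rng, 10)
        with pytest.raises(ABCError):
            normalize_and_distance(np.zeros(5), t.stats, t.stat_names)


class TestRejection:
    def test_tolerance_one_retains_all(self, rng):
        d = rng.random(1000)
        idx, w = rejection_sample(d, 1.0)
        assert idx.size == 1000 and w.size == 1000

    def test_million_rows_one_percent(self, rng):
        d = rng.random(1_000_000)
        idx, _ = rejection_sample(d, 0.01)
        assert idx.size == 10_000

    def test_boundary_ties_deterministic(self):
        d = np.array([0.5, 0.2, 0.5, 0.1, 0.5])
        idx1, _ = rejection_sample(d, 0.6)  # keep 3: 0.1, 0.2, first 0.5
        idx2, _ = rejection_sample(d.copy(), 0.6)
        assert idx1.tolist() == [3, 1, 0] and np.array_equal(idx1, idx2)

    @pytest.mark.parametrize("tol", [0.0, -0.1, 1.5])
    def test_bad_tolerance(self, tol):
        with pytest.raises(ABCError):
            rejection_sample(np.ones(10), tol)

    def test_epanechnikov_weights(self):
        d = np.array([0.0, 1.0, 2.0, 4.0])
        idx, w = rejection_sample(d, 0.75)
        assert w == pytest.approx([1.0, 1 - (1 / 2) ** 2, 0.0])


class TestBayesFactors:
    def test_even_odds(self):
        bf = bayes_factors({"A": 0.5, "B": 0.5})
        assert bf.loc["A", "B"] == 1.0

    def test_four_to_one(self):
        bf = bayes_factors({"A": 0.8, "B": 0.2})
        assert bf.loc["A", "B"] == pytest.approx(4.0)

    def test_transitivity(self):
        bf = bayes_factors({"A": 0.6, "B": 0.3, "C": 0.1})
        assert bf.loc["A", "B"] * bf.loc["B", "C"] == pytest.approx(
            bf.loc["A", "C"]
        )

    def test_zero_probability_flagged_infinite(self):
        bf = bayes_factors({"A": 1.0, "B": 0.0})
        assert np.isinf(bf.loc["A", "B"])


class TestModelChoice:
    def test_uninformative_statistics_give_uniform_posterior(self, rng):
        tables = {c: _table(rng, 800, c) for c in ("A", "B", "C")}
        post = model_posterior_mnlogistic(rng.normal(size=3), tables, 0.5)
        for p in post.values():
            assert p == pytest.approx(1 / 3, abs=0.1)
        assert sum(post.values()) == pytest.approx(1.0, abs=1e-9)

    def test_separable_statistics_identify_generator(self, rng):
        shift = lambda delta: (
            lambda params, r: r.normal(size=(len(params), 3)) + delta
        )
        tables = {
            "A": _table(rng, 800, "A", shift(0.0)),
            "B": _table(rng, 800, "B", shift(30.0)),
        }
        post = model_posterior_mnlogistic(np.full(3, 30.0), tables, 0.5)
        assert post["B"] > 0.95

    def test_probabilities_sum_to_one(self, rng):
        tables = {c: _table(rng, 300, c) for c in ("A", "B")}
        post = model_posterior_mnlogistic(np.zeros(3), tables, 0.2)
        assert sum(post.values()) == pytest.approx(1.0, abs=1e-9)


class TestCrossValidation:
    def test_separated_models_near_perfect_diagonal(self, rng):
        shift = lambda delta: (
            lambda params, r: r.normal(size=(len(params), 3)) + delta
        )
        tables = {
            "A": _table(rng, 500, "A", shift(0.0)),
            "B": _table(rng, 500, "B", shift(30.0)),
        }
        conf, soft = cross_validate_model_choice(tables, 0.2, 20, rng)
        assert conf.loc["A", "A"] >= 19 and conf.loc["B", "B"] >= 19
        assert soft.loc["A", "A"] > 0.9

    def test_identical_models_split_evenly(self, rng):
        tables = {c: _table(rng, 500, c) for c in ("A", "B")}
        conf, soft = cross_validate_model_choice(tables, 0.2, 30, rng)
        assert soft.loc["A", "A"] == pytest.approx(0.5, abs=0.15)
        assert soft.loc["B", "B"] == pytest.approx(0.5, abs=0.15)

    def test_rows_sum_to_n_pseudo(self, rng):
        tables = {c: _table(rng, 200, c) for c in ("A", "B")}
        conf, _ = cross_validate_model_choice(tables, 0.3, 10, rng)
        assert (conf.sum(axis=1) == 10).all()


class TestGoodnessOfFit:
    def test_p_in_unit_interval(self, rng):
        t = _table(rng, 400)
        p, null = goodness_of_fit(rng.normal(size=3), t, 0.1, 100, rng)
        assert 0.0 <= p <= 1.0 and null.size == 100

    def test_extreme_outlier_rejected(self, rng):
        t = _table(rng, 400)
        p, _ = goodness_of_fit(np.full(3, 10.0) * t.stats.std(), t, 0.1, 100, rng)
        assert p == 0.0

    def test_calibration_roughly_uniform(self, rng):
        """p-values for data drawn from the model follow ~U(0,1)."""
        t = _table(rng, 300)
        ps = []
        for _ in range(120):
            obs = rng.normal(size=3)  # same generating process as the table
            p, _ = goodness_of_fit(obs, t, 0.1, 100, rng)
            ps.append(p)
        assert stats.kstest(ps, "uniform").pvalue > 0.01


class TestEstimation:
    def test_prior_recovery_with_uninformative_stats(self, rng):
        bounds = {"N_c": (10.0, 100_000.0)}
        t = _table(rng, 4000, bounds=bounds)
        res = estimate_parameters(np.zeros(3), t, 1.0, method="rejection")
        med = res.summaries.loc["Weighted Median", "N_c"]
        assert med == pytest.approx(50_005.0, rel=0.05)
        # weighted draws reproduce the prior (weights independent of theta)
        w = res.weights / res.weights.sum()
        resampled = rng.choice(res.adjusted["N_c"], size=4000, p=w)
        ks = stats.kstest(resampled, "uniform", args=(10.0, 99_990.0))
        assert ks.pvalue > 0.01

    def test_loclinear_recovers_linear_signal(self, rng):
        bounds = {"theta": (0.0, 100.0)}
        fn = lambda params, r: np.column_stack(
            [params["theta"] + r.normal(0, 1, len(params)),
             r.normal(size=len(params))]
        )
        t = _table(rng, 3000, stat_fn=fn, bounds=bounds)
        truth = 42.0
        obs = np.array([truth, 0.0])
        res = estimate_parameters(obs, t, 0.2, method="loclinear")
        med = res.summaries.loc["Weighted Median", "theta"]
        assert med == pytest.approx(truth, abs=1.0)
        lo, hi = res.interval("theta")
        assert hi - lo < 8.0  # adjustment sharpens far below the prior width

    @pytest.mark.parametrize("method", ["rejection", "loclinear", "neuralnet"])
    def test_summaries_respect_prior_bounds(self, rng, method):
        fn = lambda params, r: np.column_stack(
            [params["theta"], r.normal(size=len(params))]
        )
        t = _table(rng, 1000, stat_fn=fn)
        res = estimate_parameters(
            np.array([99.9, 0.0]), t, 0.1, method=method,
            rng=np.random.default_rng(3), nnet_restarts=2,
        )
        lo, hi = BOUNDS["theta"]
        assert (res.adjusted["theta"] >= lo).all()
        assert (res.adjusted["theta"] <= hi).all()
        s = res.summaries["theta"]
        assert s["Weighted 2.5%"] <= s["Weighted Median"] <= s["Weighted 97.5%"]

    def test_neuralnet_seed_reproducible(self, rng):
        t = _table(np.random.default_rng(0), 800)
        kw = dict(method="neuralnet", nnet_restarts=2)
        r1 = estimate_parameters(
            np.zeros(3), t, 0.2, rng=np.random.default_rng(5), **kw
        )
        r2 = estimate_parameters(
            np.zeros(3), t, 0.2, rng=np.random.default_rng(5), **kw
        )
        pd.testing.assert_frame_equal(r1.summaries, r2.summaries)

    def test_unknown_method(self, rng):
        with pytest.raises(ABCError):
            estimate_parameters(np.zeros(3), _table(rng, 100), 0.5, method="bogus")


class TestPosteriorPredictive:
    def test_tail_probabilities_shape_and_extremes(self, rng):
        fn = lambda params, r: np.column_stack(
            [params["theta"] + r.normal(0, 1, len(params)),
             r.normal(size=len(params))]
        )
        t = _table(rng, 1500, stat_fn=fn)
        obs = np.array([50.0, 0.0])
        res = estimate_parameters(obs, t, 0.1, method="rejection")

        def simulate(params, r):
            return np.array([params["theta"] + r.normal(), r.normal()])

        tails = posterior_predictive_check(res, obs, simulate, 200, rng)
        assert tails.size == 2
        assert 0.05 < tails.iloc[0] < 0.95  # obs central under its posterior
        # an impossible observation lands in the far tail
        tails2 = posterior_predictive_check(
            res, np.array([1e6, 0.0]), simulate, 50, rng
        )
        assert tails2.iloc[0] == 0.0
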