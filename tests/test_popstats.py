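import numpy as np
import pandas as pd
import pytest

from rrow.behavior import parse_visits
from rrow.popstats import (
    delay_window_rates,
    linger_window_rates,
    net_choice_rate,
    proportion_test,
    rate_behavior_correlation,
    restrict_visits,
    session_blocks,
    signed_rank_timecourse,
    stepwise_fixed,
    stepwise_percell,
    subsample_match,
    windowed_rate_correlation,
    zone_mean_rates,
)
from rrow.synthetic import (
    CellGains,
    EnsembleConfig,
    SessionConfig,
    SpikeTrain,
    simulate_ensemble,
    simulate_session,
)


def _tuned_train(rng, intervals, slope, base=2.0, duration=3600.0, values=None):
    """Poisson train whose rate in interval i is base + slope * values[i]."""
    times = [rng.uniform(0, duration, rng.poisson(0.5 * duration))]
    for (a, b), v in zip(intervals, values):
        rate = max(base + slope * v, 0.0)
        times.append(rng.uniform(a, b, rng.poisson(rate * (b - a))))
    return SpikeTrain(0, np.sort(np.concatenate(times)), duration)


class TestRateBehaviorCorrelation:
    def test_perfect_linear_relationship(self, rng):
        values = rng.uniform(1, 30, 80)
        starts = np.sort(rng.uniform(10, 3500, 80))
        intervals = [(s, s + 2.0) for s in starts]
        train = _tuned_train(rng, intervals, slope=2.0, base=1.0, values=values)
        res = rate_behavior_correlation(train, intervals, values, n_shuffles=5,
                                        rng=np.random.default_rng(0))
        assert res.r > 0.9

    def test_untuned_cell_null_spans_observed(self, poisson_train_factory, rng):
        train = poisson_train_factory(5.0, 3600.0, seed=1)
        starts = np.sort(rng.uniform(10, 3500, 60))
        intervals = [(s, s + 2.0) for s in starts]
        values = rng.uniform(1, 30, 60)
        res = rate_behavior_correlation(train, intervals, values, n_shuffles=20,
                                        rng=np.random.default_rng(1))
        assert abs(res.r) < 0.3
        # observed r is of the same magnitude as the shuffled-spike null
        assert abs(res.r) <= np.abs(res.null_rs).max() + 0.15

    def test_constant_variable_flagged(self, poisson_train_factory, rng):
        train = poisson_train_factory(5.0, 3600.0, seed=2)
        starts = np.sort(rng.uniform(10, 3500, 10))
        intervals = [(s, s + 2.0) for s in starts]
        res = rate_behavior_correlation(train, intervals, np.full(10, 3.0))
        assert not res.defined and np.isnan(res.r)


class TestStepwise:
    def _make_data(self, rng, n=300):
        v1 = rng.uniform(0, 10, n)
        v2 = rng.uniform(0, 10, n)
        return v1, v2

    def test_rate_on_second_variable_only(self, rng):
        v1, v2 = self._make_data(rng)
        rates = 3.0 * v2 + rng.normal(0, 0.5, 300)
        ladder = stepwise_fixed(rates, {"v1": v1, "v2": v2}, ["v1", "v2"])
        assert abs(ladder.steps[0].coef) < 0.3
        assert ladder.steps[1].coef == pytest.approx(3.0, abs=0.2)

    def test_independent_variables_slopes_recovered_any_order(self, rng):
        v1, v2 = self._make_data(rng)
        rates = 2.0 * v1 + 0.7 * v2 + rng.normal(0, 0.3, 300)
        for order in (["v1", "v2"], ["v2", "v1"]):
            ladder = stepwise_fixed(rates, {"v1": v1, "v2": v2}, order)
            coefs = {s.variable: s.coef for s in ladder.steps}
            assert coefs["v1"] == pytest.approx(2.0, abs=0.2)
            assert coefs["v2"] == pytest.approx(0.7, abs=0.2)

    def test_noise_cell_mostly_nonsignificant(self):
        sig = 0
        n_seeds = 40
        for seed in range(n_seeds):
            r = np.random.default_rng(seed)
            v1, v2 = self._make_data(r)
            rates = r.normal(5, 1, 300)
            ladder = stepwise_fixed(rates, {"v1": v1, "v2": v2}, ["v1", "v2"])
            sig += ladder.steps[0].p < 0.05
        assert sig <= 0.05 * n_seeds * 3 + 2  # ~alpha of seeds, with slack

    def test_residual_variance_nonincreasing(self, rng):
        v1, v2 = self._make_data(rng)
        v3 = rng.uniform(0, 5, 300)
        rates = 1.5 * v1 + rng.normal(0, 1, 300)
        for ladder in (
            stepwise_fixed(rates, {"v1": v1, "v2": v2, "v3": v3}, ["v3", "v1", "v2"]),
            stepwise_percell(rates, {"v1": v1, "v2": v2, "v3": v3}),
        ):
            rv = [s.residual_var for s in ladder.steps]
            assert all(b <= a + 1e-12 for a, b in zip(rv, rv[1:]))

    def test_percell_dominant_variable_first(self, rng):
        v1, v2 = self._make_data(rng)
        rates = 5.0 * v2 + rng.normal(0, 0.5, 300)
        ladder = stepwise_percell(rates, {"v1": v1, "v2": v2})
        assert ladder.order[0] == "v2"

    def test_percell_tie_break_uses_config_order(self, rng):
        v = rng.uniform(0, 10, 300)
        rates = 2.0 * v
        # identical variable twice: tie on explained variance
        ladder = stepwise_percell(rates, {"a": v, "b": v})
        assert ladder.order[0] == "a"

    def test_degenerate_constant_variable(self, rng):
        v1 = np.full(50, 2.0)
        v2 = rng.uniform(0, 10, 50)
        rates = v2 + rng.normal(0, 0.1, 50)
        ladder = stepwise_fixed(rates, {"v1": v1, "v2": v2}, ["v1", "v2"])
        assert ladder.steps[0].degenerate and ladder.steps[0].coef == 0.0

    def test_order_must_cover_variables(self, rng):
        with pytest.raises(ValueError):
            stepwise_fixed(np.ones(10), {"v1": np.ones(10)}, ["v2"])


class TestNetChoiceRate:
    def test_skip_only_cell_positive(self):
        rates = np.array([5.0, 6.0, 0.0, 0.0])
        choices = np.array(["skip", "skip", "accept", "accept"])
        res = net_choice_rate(rates, choices)
        assert res.net_rate > 0 and res.preference == "skip"

    def test_symmetric_cell_near_zero(self, rng):
        nets = []
        for _ in range(50):
            rates = rng.poisson(5, 60).astype(float)
            choices = np.where(rng.uniform(size=60) < 0.5, "skip", "accept")
            if len(set(choices)) < 2:
                continue
            nets.append(net_choice_rate(rates, choices).net_rate)
        assert abs(np.mean(nets)) < 0.3

    def test_missing_category_raises(self):
        with pytest.raises(ValueError):
            net_choice_rate([1.0, 2.0], ["skip", "skip"])

    def test_planted_population_proportion_rejects(self, rng):
        n_cells = 100
        prefer_skip = rng.uniform(size=n_cells) < 0.68
        n_skip = int(prefer_skip.sum())
        chi2, p = proportion_test(n_skip, n_cells)
        assert p < 0.05

    def test_balanced_population_fails_to_reject(self):
        chi2, p = proportion_test(50, 100)
        assert p > 0.9


class TestSignedRankTimecourse:
    def test_positive_bins_detected_with_bonferroni(self, rng):
        values = rng.normal(0, 0.1, size=(60, 10))
        values[:, 5:] += 1.0
        sig, pvals = signed_rank_timecourse(values)
        assert not sig[:5].any()
        assert sig[5:].all()


class TestSubsample:
    def test_identity_at_full_population(self, rng):
        pop = list(range(30))
        out = subsample_match(pop, lambda s: sum(s), target_n=30, n_iter=3,
                              rng=np.random.default_rng(0))
        assert out == [sum(pop)] * 3

    def test_reproducible_with_seed(self):
        pop = list(range(100))
        a = subsample_match(pop, tuple, target_n=10, n_iter=5,
                            rng=np.random.default_rng(42))
        b = subsample_match(pop, tuple, target_n=10, n_iter=5,
                            rng=np.random.default_rng(42))
        assert a == b

    def test_oversample_requires_replacement(self):
        with pytest.raises(ValueError):
            subsample_match([1, 2, 3], tuple, target_n=5, n_iter=1)
        out = subsample_match([1, 2, 3], list, target_n=5, n_iter=2, replace=True,
                              rng=np.random.default_rng(0))
        assert all(len(s) == 5 for s in out)


class TestSessionBlocks:
    def test_partition(self):
        for n in (3, 5):
            blocks = session_blocks(3600.0, n)
            assert len(blocks) == n
            assert blocks[0][0] == 0.0 and blocks[-1][1] == 3600.0
            for (a1, b1), (a2, b2) in zip(blocks, blocks[1:]):
                assert b1 == a2

    def test_invalid_count_rejected(self):
        with pytest.raises(ValueError):
            session_blocks(3600.0, 4)

    def test_stationary_ensemble_flat_blocks(self, poisson_train_factory):
        train = poisson_train_factory(6.0, 3600.0, seed=5)
        rates = zone_mean_rates(train, session_blocks(3600.0, 3))
        assert np.ptp(rates) < 0.5

    def test_planted_early_elevation(self, default_session):
        gains = [CellGains(time_slope=-1.2)]
        trains, _ = simulate_ensemble(
            default_session,
            EnsembleConfig(n_cells=1, base_rate_range=(6.0, 6.0), gains=gains, seed=6),
        )
        rates = zone_mean_rates(trains[0], session_blocks(3600.0, 3))
        assert rates[0] > rates[2]

    def test_restrict_visits_partition(self, default_visits):
        blocks = session_blocks(3600.0, 3)
        parts = [restrict_visits(default_visits, b) for b in blocks]
        assert sum(len(p) for p in parts) == len(default_visits)


class TestWindowedRateCorrelation:
    @pytest.fixture(scope="class")
    def delay_tuned_rats(self):
        """Four subjects whose cells fire ~ delay, only in the first 3 s of
        the wait zone (accept_noise 0 -> all delays accepted equally)."""
        frames = []
        for rat in range(4):
            events = simulate_session(
                SessionConfig(seed=55 + rat, accept_noise=0.0, quit_hazard_scale=0.0)
            )
            visits = parse_visits(events)
            accepted = [v for v in visits if v.outcome in ("quit", "earn")]
            rng = np.random.default_rng(560 + rat)
            times = [rng.uniform(0, 3600.0, rng.poisson(1.0 * 3600))]
            for v in accepted:
                hi = min(v.wz_enter + 3.0, v.wz_exit)
                rate = 1.5 * v.offer_delay
                times.append(rng.uniform(v.wz_enter, hi, rng.poisson(rate * (hi - v.wz_enter))))
            train = SpikeTrain(0, np.sort(np.concatenate(times)), 3600.0)
            frames.append(delay_window_rates([train], visits))
        return frames

    def test_early_wz_correlation(self, delay_tuned_rats):
        corr = windowed_rate_correlation(delay_tuned_rats)
        r_early, _, n_early = corr["EarlyWZ"]
        r_pre, _, _ = corr["PreWZ"]
        assert r_early > 0.8
        assert abs(r_pre) < 0.5
        assert n_early <= 24  # up to 4 rats x 6 bins

    def test_untuned_ensemble_flat(self, poisson_train_factory):
        # pool several subjects so each window has ~36 points
        frames = []
        for rat in range(6):
            events = simulate_session(SessionConfig(seed=100 + rat, accept_noise=0.0,
                                                    quit_hazard_scale=0.0))
            visits = parse_visits(events)
            trains = [poisson_train_factory(5.0, 3600.0, seed=10 * rat + s) for s in range(3)]
            frames.append(delay_window_rates(trains, visits))
        corr = windowed_rate_correlation(frames)
        for r, p, n in corr.values():
            assert abs(r) < 0.4

    def test_six_points_per_rat(self, default_visits, poisson_train_factory):
        trains = [poisson_train_factory(5.0, 3600.0, seed=9)]
        frame = delay_window_rates(trains, default_visits)
        assert frame.groupby("window").size().max() <= 6

    def test_linger_rates_shape(self, default_visits, poisson_train_factory):
        trains = [poisson_train_factory(5.0, 3600.0, seed=10)]
        frame = linger_window_rates(trains, default_visits)
        assert set(frame["window"]) <= {"PreRZ", "EarlyRZ", "LateRZ", "PostRZ"}
        assert frame["linger_bin"].max() <= 5
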