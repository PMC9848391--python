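import numpy as np
import pandas as pd
import pytest

from rrow.behavior import parse_visits, phase_intervals
from rrow.infoflow import (
    DVProfile,
    SubregionBounds,
    assign_subregions,
    bin_spikes,
    diagonal_profile,
    find_boundaries,
    intervals_to_mask,
    region_te_stats,
    te_by_phase,
    te_matrix,
    te_normalized,
    te_spatial_map,
    transfer_entropy,
)
from rrow.synthetic import (
    EnsembleConfig,
    SessionConfig,
    SpikeTrain,
    simulate_ensemble,
    simulate_session,
)


def brute_force_te(x, y):
    """Independent oracle: enumerate all 8 (x0, y0, y1) patterns explicitly."""
    x = np.asarray(x)
    y = np.asarray(y)
    n = len(x) - 1
    counts = {}
    for t in range(1, len(x)):
        key = (y[t], y[t - 1], x[t - 1])
        counts[key] = counts.get(key, 0) + 1
    te = 0.0
    for (y1, y0, x0), c in counts.items():
        p_joint = c / n
        n_y0x0 = sum(v for (a, b, d), v in counts.items() if b == y0 and d == x0)
        n_y0y1 = sum(v for (a, b, d), v in counts.items() if a == y1 and b == y0)
        n_y0 = sum(v for (a, b, d), v in counts.items() if b == y0)
        p_cond_full = c / n_y0x0
        p_cond_self = n_y0y1 / n_y0
        te += p_joint * np.log2(p_cond_full / p_cond_self)
    return te


class TestBinSpikes:
    def test_basic_binning(self):
        train = SpikeTrain(0, np.array([0.005, 0.012]), 1.0)
        bins = bin_spikes(train)
        assert bins[0] == 1 and bins[1] == 1 and bins[2:].sum() == 0

    def test_empty_train(self):
        assert bin_spikes(SpikeTrain(0, np.empty(0), 1.0)).sum() == 0

    def test_multi_spike_bins_collapse(self):
        times = np.sort(np.random.default_rng(0).uniform(0.0, 0.01, 5))
        bins = bin_spikes(SpikeTrain(0, times, 1.0))
        assert bins[0] == 1 and bins.sum() == 1


class TestTransferEntropy:
    def test_lag_copy_limit(self, rng):
        x = rng.integers(0, 2, 100000)
        y = np.r_[0, x[:-1]]
        assert transfer_entropy(x, y) == pytest.approx(1.0, abs=0.02)

    def test_self_deterministic_y_exactly_zero(self, rng):
        x = rng.integers(0, 2, 1000)
        y = np.ones(1000, dtype=int)  # y_t = y_{t-1} always
        assert transfer_entropy(x, y) == 0.0

    def test_constant_x_exactly_zero(self, rng):
        y = rng.integers(0, 2, 1000)
        assert transfer_entropy(np.zeros(1000, dtype=int), y) == 0.0

    def test_matches_brute_force_on_fixed_pair(self):
        x = np.array([0, 1, 1, 0, 1, 0, 0, 1, 1, 1, 0, 1, 0, 0, 1, 0, 1, 1, 0, 0])
        y = np.array([1, 0, 1, 1, 0, 1, 0, 0, 1, 0, 1, 1, 1, 0, 0, 1, 0, 1, 1, 0])
        assert transfer_entropy(x, y) == pytest.approx(brute_force_te(x, y), abs=1e-12)

    def test_matches_brute_force_on_random_pairs(self, rng):
        for _ in range(200):
            n = int(rng.integers(3, 21))
            x = rng.integers(0, 2, n)
            y = rng.integers(0, 2, n)
            assert transfer_entropy(x, y) == pytest.approx(
                brute_force_te(x, y), abs=1e-12
            )

    def test_asymmetry_on_lag_copy(self, rng):
        x = rng.integers(0, 2, 5000)
        y = np.r_[0, x[:-1]]
        assert transfer_entropy(x, y) != transfer_entropy(y, x)

    def test_relabeling_x_invariance(self, rng):
        x = rng.integers(0, 2, 2000)
        y = rng.integers(0, 2, 2000)
        assert transfer_entropy(x, y) == pytest.approx(
            transfer_entropy(1 - x, y), abs=1e-12
        )

    def test_too_short_raises(self):
        with pytest.raises(ValueError):
            transfer_entropy([0, 1], [1, 0])

    def test_nonnegative(self, rng):
        for _ in range(50):
            n = int(rng.integers(3, 100))
            assert transfer_entropy(rng.integers(0, 2, n), rng.integers(0, 2, n)) >= 0


class TestTENormalized:
    def test_zero_spike_input_zero(self, poisson_train_factory):
        x = SpikeTrain(0, np.empty(0), 600.0)
        y = poisson_train_factory(5.0, 600.0, seed=1, cell_id=1)
        pair = te_normalized(x, y, n_shuffles=3, shift_range=(10, 590),
                             rng=np.random.default_rng(0))
        assert pair.raw_te == 0.0 and pair.norm_te == 0.0

    def test_independent_pairs_centered(self, poisson_train_factory):
        vals = []
        for seed in range(30):
            x = poisson_train_factory(6.0, 600.0, seed=2 * seed, cell_id=0)
            y = poisson_train_factory(6.0, 600.0, seed=2 * seed + 1, cell_id=1)
            pair = te_normalized(x, y, n_shuffles=10, shift_range=(10, 590),
                                 rng=np.random.default_rng(seed))
            vals.append(pair.norm_te)
        se = np.std(vals, ddof=1) / np.sqrt(len(vals))
        assert abs(np.mean(vals)) <= 2 * se + 1e-7

    def test_coupled_pair_positive(self, rng):
        hits = 0
        for seed in range(10):
            r = np.random.default_rng(seed)
            x_times = np.sort(r.uniform(0, 600.0, r.poisson(8 * 600)))
            extra = x_times[r.uniform(size=x_times.size) < 0.3] + 0.01
            y_base = np.sort(r.uniform(0, 600.0, r.poisson(5 * 600)))
            y_times = np.sort(np.r_[y_base, extra[extra <= 600.0]])
            x = SpikeTrain(0, x_times, 600.0)
            y = SpikeTrain(1, y_times, 600.0)
            pair = te_normalized(x, y, n_shuffles=10, shift_range=(10, 590),
                                 rng=np.random.default_rng(seed + 100))
            hits += pair.norm_te > 0
        assert hits >= 9

    def test_batch_matches_single(self, poisson_train_factory):
        trains = [poisson_train_factory(5.0, 300.0, seed=s, cell_id=s) for s in range(3)]
        res = te_matrix(trains, n_shuffles=2, rng=np.random.default_rng(0))
        for i in range(3):
            for j in range(3):
                if i == j:
                    assert np.isnan(res.raw[i, j])
                else:
                    expected = transfer_entropy(
                        bin_spikes(trains[i]), bin_spikes(trains[j])
                    )
                    assert res.raw[i, j] == pytest.approx(expected, abs=1e-12)


class TestTEByPhase:
    @pytest.fixture(scope="class")
    def session_and_trains(self):
        events = simulate_session(SessionConfig(session_duration=600.0, seed=31))
        visits = parse_visits(events)
        trains, _ = simulate_ensemble(
            events,
            EnsembleConfig(n_cells=4, base_rate_range=(4.0, 8.0),
                           coupling=[(0, 1, 1, 0.3)], seed=32),
            session_duration=600.0,
        )
        return events, visits, trains

    def test_identity_mask_equals_unmasked(self, session_and_trains):
        _, visits, trains = session_and_trains
        full = te_matrix(trains, n_shuffles=2, shift_range=(10, 590),
                         rng=np.random.default_rng(5))
        masked = te_matrix(trains, n_shuffles=2, shift_range=(10, 590),
                           rng=np.random.default_rng(5),
                           mask=np.ones(60000, dtype=bool))
        assert np.allclose(full.raw, masked.raw, equal_nan=True)
        assert np.allclose(full.norm, masked.norm, equal_nan=True)

    def test_empty_phase_raises(self, session_and_trains):
        _, visits, trains = session_and_trains
        with pytest.raises(ValueError):
            te_by_phase(trains, {"OZ": []}, "OZ", n_shuffles=2)

    def test_phase_restriction_uses_fewer_bins(self, session_and_trains):
        _, visits, trains = session_and_trains
        iv = phase_intervals(visits, 600.0)
        res = te_by_phase(trains, iv, "TZ", n_shuffles=2, min_bins=100,
                          shift_range=(10, 590), rng=np.random.default_rng(6))
        assert res.n_bins_used < 60000 - 1
        assert res.phase == "TZ"

    def test_oz_only_coupling_stronger_in_oz(self):
        # coupling active only during OZ occupancy: build trains by hand
        events = simulate_session(SessionConfig(session_duration=900.0, seed=41))
        visits = parse_visits(events)
        iv = phase_intervals(visits, 900.0)
        r = np.random.default_rng(7)
        x_times = np.sort(r.uniform(0, 900.0, r.poisson(8 * 900)))
        oz_mask_fn = np.zeros(90000, dtype=bool)
        oz_mask_fn = intervals_to_mask(iv["OZ"], 900.0)
        in_oz = oz_mask_fn[np.minimum((x_times / 0.01).astype(int), 89999)]
        extra = x_times[in_oz & (r.uniform(size=x_times.size) < 0.5)] + 0.01
        y_times = np.sort(np.r_[np.sort(r.uniform(0, 900.0, r.poisson(5 * 900))),
                                extra[extra <= 900.0]])
        trains = [SpikeTrain(0, x_times, 900.0), SpikeTrain(1, y_times, 900.0)]
        oz = te_by_phase(trains, iv, "OZ", n_shuffles=5, min_bins=500,
                         shift_range=(10, 890), rng=np.random.default_rng(8))
        tz = te_by_phase(trains, iv, "TZ", n_shuffles=5, min_bins=500,
                         shift_range=(10, 890), rng=np.random.default_rng(9))
        assert oz.norm[0, 1] > tz.norm[0, 1]
        assert oz.norm[0, 1] > 0


class TestSpatialMap:
    def _pairs(self, rows):
        return pd.DataFrame(rows, columns=["input_id", "recipient_id", "norm_te"])

    def test_single_bin_mean(self):
        pairs = self._pairs([(0, 1, 1.0), (1, 0, 3.0)])
        depths = {0: 50.0, 1: 60.0}
        m = te_spatial_map(pairs, depths, span=(0.0, 100.0))
        assert m.values.shape == (1, 1)
        assert m.values[0, 0] == pytest.approx(2.0)
        assert m.counts[0, 0] == 2

    def test_direction_distinguishes_bins(self):
        pairs = self._pairs([(0, 1, 1.0), (1, 0, 2.0)])
        depths = {0: 50.0, 1: 250.0}
        m = te_spatial_map(pairs, depths, span=(0.0, 300.0))
        assert m.values[0, 2] == pytest.approx(1.0)
        assert m.values[2, 0] == pytest.approx(2.0)

    def test_pair_conservation(self, rng):
        n = 30
        depths = {i: float(rng.uniform(0, 1000)) for i in range(n)}
        rows = [(i, j, float(rng.normal())) for i in range(n) for j in range(n) if i != j]
        m = te_spatial_map(self._pairs(rows), depths)
        assert m.counts.sum() == n * (n - 1)

    def test_out_of_span_dropped_with_warning(self, caplog):
        pairs = self._pairs([(0, 1, 1.0), (1, 2, 5.0)])
        depths = {0: 50.0, 1: 60.0, 2: 5000.0}
        with caplog.at_level("WARNING"):
            m = te_spatial_map(pairs, depths, span=(0.0, 100.0))
        assert m.counts.sum() == 1


class TestDiagonalProfile:
    def test_constant_map_constant_profile(self):
        pairs = pd.DataFrame(
            [(i, j, 2.5) for i in range(8) for j in range(8) if i != j],
            columns=["input_id", "recipient_id", "norm_te"],
        )
        depths = {i: 100.0 * i + 50.0 for i in range(8)}
        m = te_spatial_map(pairs, depths, span=(0.0, 800.0))
        prof = diagonal_profile(m)
        ok = np.isfinite(prof.values)
        assert np.allclose(prof.values[ok], 2.5)

    def test_single_occupied_bin(self):
        pairs = pd.DataFrame([(0, 1, 4.0)], columns=["input_id", "recipient_id", "norm_te"])
        depths = {0: 450.0, 1: 440.0}
        m = te_spatial_map(pairs, depths, span=(0.0, 1000.0))
        prof = diagonal_profile(m, window=200.0)
        near = np.abs(prof.depths - 450.0) <= 200.0
        assert np.all(prof.values[near] == pytest.approx(4.0))
        assert np.all(np.isnan(prof.values[~near]))

    def test_max_block_attains_profile_max(self, rng):
        # one high-TE block in the middle of the depth axis
        depths = {i: float(d) for i, d in enumerate(rng.uniform(0, 1000, 40))}
        rows = []
        for i in range(40):
            for j in range(40):
                if i == j:
                    continue
                mid_i = 300 <= depths[i] <= 700
                mid_j = 300 <= depths[j] <= 700
                rows.append((i, j, 1.0 if (mid_i and mid_j) else 0.0))
        m = te_spatial_map(
            pd.DataFrame(rows, columns=["input_id", "recipient_id", "norm_te"]),
            depths, span=(0.0, 1000.0),
        )
        prof = diagonal_profile(m)
        best = prof.depths[np.nanargmax(prof.values)]
        assert 300 <= best <= 700


class TestFindBoundaries:
    def test_alternating_profile_minima(self):
        vals = np.array([3.0, 1.0, 3.0, 1.0, 3.0, 1.0, 3.0])
        prof = DVProfile(depths=np.arange(7) * 200.0, values=vals)
        b = find_boundaries(prof)
        assert b.boundary_depths.tolist() == [200.0, 600.0, 1000.0]
        assert len(b.labels) == 4

    def test_monotone_profile_no_boundaries(self):
        prof = DVProfile(depths=np.arange(6) * 100.0,
                         values=np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0]))
        b = find_boundaries(prof)
        assert b.single_region
        assert b.boundary_depths.size == 0

    def test_too_few_points_raises(self):
        prof = DVProfile(depths=np.arange(4) * 100.0, values=np.ones(4))
        with pytest.raises(ValueError):
            find_boundaries(prof)


class TestAssignSubregions:
    def test_partition_with_three_bounds(self, rng):
        bounds = SubregionBounds(boundary_depths=np.array([250.0, 500.0, 750.0]))
        depths = pd.Series(rng.uniform(0, 1000, 100))
        labels = assign_subregions(depths, bounds)
        assert set(labels.unique()) <= set(bounds.labels)
        assert len(labels) == 100

    def test_cell_on_boundary_goes_dorsal(self):
        bounds = SubregionBounds(boundary_depths=np.array([250.0]))
        labels = assign_subregions(pd.Series({0: 250.0, 1: 250.1}), bounds)
        assert labels[0] == "region_1"
        assert labels[1] == "region_2"


class TestRegionStats:
    def test_planted_block_structure(self, rng):
        labels = pd.Series(
            ["region_1"] * 10 + ["region_2"] * 10 + ["region_3"] * 10 + ["region_4"] * 10
        )
        rows = []
        for i in range(40):
            for j in range(40):
                if i == j:
                    continue
                same = labels[i] == labels[j]
                rows.append((i, j, rng.normal(0.5 if same else 0.0, 0.05)))
        pairs = pd.DataFrame(rows, columns=["input_id", "recipient_id", "norm_te"])
        stats = region_te_stats(pairs, labels, [f"region_{k}" for k in range(1, 5)])
        assert stats.step_means[0] > max(stats.step_means[s] for s in (1, 2, 3))
        assert stats.intra_vs_inter_p < 1e-6

    def test_single_region_inter_empty(self, rng):
        labels = pd.Series(["region_1"] * 5)
        rows = [(i, j, rng.normal()) for i in range(5) for j in range(5) if i != j]
        pairs = pd.DataFrame(rows, columns=["input_id", "recipient_id", "norm_te"])
        stats = region_te_stats(pairs, labels, ["region_1"])
        assert 0 in stats.step_groups and len(stats.step_groups) == 1
        assert np.isnan(stats.intra_vs_inter_p)
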