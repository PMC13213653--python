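import numpy as np
import pytest
from scipy import stats

from dyadeeg.durations import DurationModel
from dyadeeg.hsmm import (
    EmptySegmentError,
    SegmentSpec,
    death_prior,
    place_death,
    place_kills,
    placement_score,
)
from oracles import brute_force_place_kills, score_placement


def _toy_models(T):
    start = DurationModel.gamma_from_mean(mean=T / 3.0, shape=2.0, shift=5.0)
    between = DurationModel.gamma_from_mean(mean=T / 2.5, shape=2.0, shift=8.0)
    return start, between


def _random_toy(rng, max_ticks=300):
    T = int(rng.integers(80, max_ticks + 1))
    ticks = np.arange(5, T - 5)
    llr = rng.normal(-1.0, 1.0, size=ticks.size)
    # a few candidate spikes so nontrivial placements win sometimes
    for _ in range(int(rng.integers(0, 4))):
        llr[rng.integers(0, ticks.size)] += rng.uniform(3.0, 12.0)
    return T, ticks, llr


class TestPlaceKills:
    def test_single_spike_near_start_mode_is_chosen(self):
        T = 600
        start, between = _toy_models(T)
        ticks = np.arange(5, T - 5)
        llr = np.full(ticks.size, -1.0)
        spike = int(start.mean)
        llr[spike - 5] = 50.0
        placed = place_kills(ticks, llr, start, between, T)
        assert placed.tolist() == [spike]

    def test_flat_emissions_match_brute_force_duration_only_optimum(self, rng):
        T = 200
        start, between = _toy_models(T)
        ticks = np.arange(5, T - 5)
        llr = np.zeros(ticks.size)
        placed = place_kills(ticks, llr, start, between, T)
        ref_score, _ = brute_force_place_kills(ticks, llr, start, between, T)
        got = score_placement(
            placed, dict(zip(ticks.tolist(), llr)), start, between, T
        )
        assert got == pytest.approx(ref_score, abs=1e-9)

    def test_dp_equals_exhaustive_enumeration_on_random_toys(self, rng):
        # exhaustive over all placements of <= 3 kills
        for _ in range(25):
            T, ticks, llr = _random_toy(rng, max_ticks=150)
            start, between = _toy_models(T)
            placed = place_kills(ticks, llr, start, between, T)
            if placed.size > 3:
                continue  # oracle only enumerates up to 3 kills
            ref_score, _ = brute_force_place_kills(ticks, llr, start, between, T)
            llr_map = dict(zip(ticks.tolist(), llr))
            got = score_placement(placed, llr_map, start, between, T)
            assert got == pytest.approx(ref_score, abs=1e-9)

    def test_strengthening_a_placed_kill_keeps_it(self, rng):
        T, ticks, llr = _random_toy(rng)
        start, between = _toy_models(T)
        llr[ticks.size // 2] += 8.0
        placed = place_kills(ticks, llr, start, between, T)
        if placed.size == 0:
            pytest.skip("degenerate toy: nothing placed")
        target = placed[0]
        llr2 = llr.copy()
        llr2[np.where(ticks == target)[0][0]] += 5.0
        placed2 = place_kills(ticks, llr2, start, between, T)
        assert target in placed2

    def test_strongly_negative_emissions_give_empty_placement(self):
        T = 300
        start, between = _toy_models(T)
        ticks = np.arange(5, T - 5)
        placed = place_kills(ticks, np.full(ticks.size, -1000.0), start, between, T)
        assert placed.size == 0

    def test_d_max_bound_respected_when_large_enough(self, rng):
        T, ticks, llr = _random_toy(rng)
        start, between = _toy_models(T)
        full = place_kills(ticks, llr, start, between, T)
        bounded = place_kills(ticks, llr, start, between, T, d_max=T)
        np.testing.assert_array_equal(full, bounded)

    def test_internal_score_definition_matches_oracle(self, rng):
        T = 250
        start, between = _toy_models(T)
        ticks = np.arange(5, T - 5)
        llr = rng.normal(size=ticks.size)
        llr_map = dict(zip(ticks.tolist(), llr))
        for kills in ([], [60], [40, 130], [30, 100, 190]):
            assert placement_score(kills, llr_map, start, between, T) == pytest.approx(
                score_placement(kills, llr_map, start, between, T), abs=1e-12
            )

    def test_empty_candidates_rejected(self):
        start, between = _toy_models(100)
        with pytest.raises(ValueError):
            place_kills([], [], start, between, 100)


class TestDeathPrior:
    def test_symmetric_models_give_symmetric_prior(self):
        m = DurationModel.gamma_from_mean(mean=120.0, shape=2.0, shift=30.0)
        offsets, lp = death_prior(400, m, m, margin=30)
        np.testing.assert_allclose(lp, lp[::-1], atol=1e-10)
        # mode in the middle
        assert abs(offsets[np.argmax(lp)] - 200) <= 1

    def test_point_mass_start_pins_the_prior(self):
        start = DurationModel.fixed(60.0)
        end = DurationModel.gamma_from_mean(mean=300.0, shape=1.5, shift=10.0)
        offsets, lp = death_prior(500, start, end, margin=30)
        assert offsets[np.argmax(lp)] == 60

    def test_matches_direct_normalization(self):
        start = DurationModel("gamma", (2.0, 80.0), shift=40.0)
        end = DurationModel("gamma", (3.0, 60.0), shift=50.0)
        L, margin = 900, 30
        offsets, lp = death_prior(L, start, end, margin)
        assert np.exp(lp).sum() == pytest.approx(1.0, abs=1e-10)
        # independent evaluation via scipy densities
        t = offsets.astype(float)
        direct = stats.gamma.pdf(t - 40.0, 2.0, scale=80.0) * stats.gamma.pdf(
            (L - t) - 50.0, 3.0, scale=60.0
        )
        np.testing.assert_allclose(np.exp(lp), direct / direct.sum(), atol=1e-12)

    def test_zero_outside_minimum_durations(self):
        start = DurationModel("gamma", (2.0, 30.0), shift=60.0)
        end = DurationModel("gamma", (2.0, 30.0), shift=80.0)
        L = 400
        offsets, lp = death_prior(L, start, end, margin=30)
        assert np.all(lp[offsets <= 60] == -np.inf)
        assert np.all(lp[offsets >= L - 80] == -np.inf)

    def test_too_short_segment_raises(self):
        m = DurationModel("gamma", (2.0, 30.0), shift=100.0)
        with pytest.raises(EmptySegmentError):
            death_prior(150, m, m, margin=30)  # shifts leave no support


class TestPlaceDeath:
    def test_emission_spike_beats_flat_prior(self):
        seg = SegmentSpec(start=1000, end=1400, margin=30)
        ticks = seg.admissible_ticks
        lp = np.zeros(ticks.size)  # flat (unnormalized) prior
        llr = np.zeros(ticks.size)
        llr[123] = 40.0
        assert place_death(seg, lp, llr) == ticks[123]

    def test_flat_emissions_return_prior_mode(self):
        m = DurationModel.gamma_from_mean(mean=120.0, shape=2.0, shift=30.0)
        seg = SegmentSpec(start=600, end=1000, margin=30)
        offsets, lp = death_prior(seg.length, m, m, margin=30)
        assert place_death(seg, lp, np.zeros(lp.size)) == 600 + offsets[np.argmax(lp)]

    def test_equals_exhaustive_argmax_on_random_segments(self, rng):
        for _ in range(30):
            L = int(rng.integers(150, 301))
            seg = SegmentSpec(start=int(rng.integers(0, 5000)), end=0, margin=30)
            seg = SegmentSpec(start=seg.start, end=seg.start + L, margin=30)
            ticks = seg.admissible_ticks
            lp = rng.normal(size=ticks.size)
            llr = rng.normal(size=ticks.size)
            expected = ticks[int(np.argmax(lp + llr))]
            assert place_death(seg, lp, llr) == expected

    def test_tie_breaks_to_earlier_tick(self):
        seg = SegmentSpec(start=0, end=160, margin=30)
        n = seg.admissible_ticks.size
        assert place_death(seg, np.zeros(n), np.zeros(n)) == seg.admissible_ticks[0]

    def test_misaligned_scores_rejected(self):
        seg = SegmentSpec(start=0, end=200, margin=30)
        with pytest.raises(ValueError):
            place_death(seg, np.zeros(3), np.zeros(3))
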