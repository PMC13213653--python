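import numpy as np
import pytest

from dyadeeg.durations import DurationModel
from dyadeeg.montage import CENTRAL_ELECTRODES, DEFAULT_MONTAGE
from dyadeeg.simulate import (
    DyadEEGConfig,
    ErpTemplate,
    EventTimeline,
    GameConfig,
    generate_dataset,
    simulate_dyad_eeg,
    simulate_game_timeline,
    template_waveform,
)


def _point_mass_config(start=600.0, between=720.0, deaths=0.0):
    return GameConfig(
        start_to_kill=DurationModel.fixed(start),
        kill_to_kill=DurationModel.fixed(between),
        death_rate_per_game=deaths,
    )


class TestTimeline:
    def test_point_mass_durations_give_regular_kills(self):
        tl = simulate_game_timeline(_point_mass_config(), rng_seed=0)
        assert tl.n_ticks == 10_800
        expected = np.arange(600, 10_800, 720)
        np.testing.assert_array_equal(tl.kill_ticks, expected)
        assert len(tl.events) == len(expected)  # kills only

    def test_zero_death_rate_yields_only_kills(self):
        tl = simulate_game_timeline(GameConfig(death_rate_per_game=0.0), rng_seed=3)
        assert all(cls == "Kill" for _, cls in tl.events)

    def test_deterministic_given_seed(self):
        a = simulate_game_timeline(GameConfig(), rng_seed=7)
        b = simulate_game_timeline(GameConfig(), rng_seed=7)
        assert a.events == b.events

    def test_deaths_fall_strictly_inside_segments_with_minimum_offsets(self):
        cfg = GameConfig(death_rate_per_game=3.0)
        for seed in range(12):
            tl = simulate_game_timeline(cfg, rng_seed=seed)
            bounds = [0, *tl.kill_ticks.tolist(), tl.n_ticks]
            for cls in ("ShooterDeath", "BaitDeath"):
                start_m, end_m = cfg.death_models[cls]
                for d in tl.death_ticks(cls):
                    seg = next(
                        (lo, hi)
                        for lo, hi in zip(bounds[:-1], bounds[1:])
                        if lo < d < hi
                    )
                    assert d - seg[0] > start_m.shift
                    assert seg[1] - d > end_m.shift

    def test_at_most_one_death_per_segment_per_role(self):
        cfg = GameConfig(death_rate_per_game=5.0)
        tl = simulate_game_timeline(cfg, rng_seed=11)
        bounds = [0, *tl.kill_ticks.tolist(), tl.n_ticks]
        for cls in ("ShooterDeath", "BaitDeath"):
            for lo, hi in zip(bounds[:-1], bounds[1:]):
                inside = [(t) for t in tl.death_ticks(cls) if lo < t < hi]
                assert len(inside) <= 1

    def test_monte_carlo_event_statistics_match_configuration(self):
        # kills/game and the empirical start-to-kill mean should agree
        # with the configured duration models over many simulated games
        cfg = GameConfig()
        n = 1000
        counts, starts = [], []
        for seed in range(n):
            tl = simulate_game_timeline(cfg, rng_seed=seed)
            counts.append(len(tl.kill_ticks))
            if len(tl.kill_ticks):
                starts.append(tl.kill_ticks[0])
        # renewal-process expectation: 1 + (T - E[start]) / E[between]
        implied = 1.0 + (cfg.n_ticks - cfg.start_to_kill.mean) / cfg.kill_to_kill.mean
        assert np.mean(counts) == pytest.approx(implied, abs=0.5)
        se = cfg.start_to_kill.sd / np.sqrt(len(starts))
        assert np.mean(starts) == pytest.approx(cfg.start_to_kill.mean, abs=2 * se)

    def test_unusable_config_rejected(self):
        with pytest.raises(ValueError):
            GameConfig(
                game_length_s=2.0,
                start_to_kill=DurationModel.gamma_from_mean(600.0, 3.0, shift=300.0),
            )
        with pytest.raises(ValueError):
            GameConfig(game_length_s=1.007)

    def test_timeline_invariants_enforced(self):
        with pytest.raises(ValueError):
            EventTimeline(0, 0, 100, [(120, "Kill")])
        with pytest.raises(ValueError):
            EventTimeline(0, 0, 100, [(10, "Kill"), (10, "ShooterDeath")])


class TestDyadEEG:
    def test_zero_noise_single_kill_is_exactly_the_template(self):
        tl = EventTimeline(0, 0, 600, [(200, "Kill")])
        cfg = DyadEEGConfig(noise_sd=0.0, latency_jitter_sd_s=0.0)
        shooter, bait = simulate_dyad_eeg(tl, cfg, rng_seed=0)
        for rec, role in ((shooter, "Shooter"), (bait, "Bait")):
            wave = template_waveform(cfg.templates[(role, "Kill")], 600, 200)
            cz = rec.data[:, rec.electrode_index("CZ")]
            fp1 = rec.data[:, rec.electrode_index("FP1")]
            np.testing.assert_allclose(cz, wave, atol=1e-12)
            np.testing.assert_allclose(fp1, cfg.spatial_falloff * wave, atol=1e-12)
            assert np.max(cz) == pytest.approx(
                cfg.templates[(role, "Kill")].amplitude_uv, abs=0.05
            )

    def test_zero_amplitude_templates_leave_pure_noise(self):
        tl = simulate_game_timeline(GameConfig(), rng_seed=1)
        cfg = DyadEEGConfig().scaled(0.0)
        shooter, _ = simulate_dyad_eeg(tl, cfg, rng_seed=4)
        assert shooter.data.mean() == pytest.approx(0.0, abs=0.05)
        assert shooter.data.std() == pytest.approx(9.0, rel=0.01)

    def test_ar1_noise_is_autocorrelated_with_stationary_sd(self):
        tl = EventTimeline(0, 0, 10_800, [])
        cfg = DyadEEGConfig(noise_model="ar1", ar_coef=0.9)
        rec, _ = simulate_dyad_eeg(tl, cfg, rng_seed=2)
        x = rec.data[:, 0]
        assert x.std() == pytest.approx(9.0, rel=0.05)
        lag1 = np.corrcoef(x[:-1], x[1:])[0, 1]
        assert lag1 == pytest.approx(0.9, abs=0.02)

    def test_template_defaults_respect_reported_orderings(self):
        t = DyadEEGConfig().templates
        for role, own in (("Shooter", "ShooterDeath"), ("Bait", "BaitDeath")):
            others = [c for c in ("Kill", "ShooterDeath", "BaitDeath") if c != own]
            assert all(
                t[(role, own)].amplitude_uv > t[(role, o)].amplitude_uv - 1e-12
                for o in others
            )
            # kills are registered earliest
            assert t[(role, "Kill")].latency_s < min(
                t[(role, "ShooterDeath")].latency_s, t[(role, "BaitDeath")].latency_s
            )
        # Shooters more positive after Kills and own deaths, Baits after theirs
        assert t[("Shooter", "Kill")].amplitude_uv > t[("Bait", "Kill")].amplitude_uv
        assert (
            t[("Shooter", "ShooterDeath")].amplitude_uv
            > t[("Bait", "ShooterDeath")].amplitude_uv
        )
        assert (
            t[("Bait", "BaitDeath")].amplitude_uv
            > t[("Shooter", "BaitDeath")].amplitude_uv
        )

    def test_unknown_central_electrode_rejected(self):
        with pytest.raises(ValueError):
            DyadEEGConfig(electrodes=("O1", "O2"), central_electrodes=("CZ",))


class TestGenerateDataset:
    def test_counts_and_determinism(self, short_game_config, quiet_eeg_config):
        a = generate_dataset(2, 2, short_game_config, quiet_eeg_config, master_seed=9)
        b = generate_dataset(2, 2, short_game_config, quiet_eeg_config, master_seed=9)
        assert len(a) == 4
        for ga, gb in zip(a, b):
            assert ga.timeline.events == gb.timeline.events
            np.testing.assert_array_equal(ga.shooter.data, gb.shooter.data)
            np.testing.assert_array_equal(ga.bait.data, gb.bait.data)

    def test_games_differ_across_teams_and_seeds(self, short_game_config, quiet_eeg_config):
        a = generate_dataset(2, 1, short_game_config, quiet_eeg_config, master_seed=9)
        c = generate_dataset(2, 1, short_game_config, quiet_eeg_config, master_seed=10)
        assert not np.array_equal(a[0].shooter.data, a[1].shooter.data)
        assert not np.array_equal(a[0].shooter.data, c[0].shooter.data)

    def test_invalid_counts_rejected(self):
        with pytest.raises(ValueError):
            generate_dataset(0, 5)
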