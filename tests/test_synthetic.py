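"""Synthetic study generator: roster, traces, contacts, RPE, whole studies."""

import numpy as np
import pandas as pd
import pytest

from sevensload.config import GroundTruthParams, MovementProfile, StudyConfig
from sevensload.kinematics import compute_acceleration
from sevensload.synthetic import (
    AthleteProfile,
    MatchConfig,
    simulate_contacts,
    simulate_roster,
    simulate_rpe,
    simulate_study,
    simulate_trace,
)

from conftest import make_trace


class TestSimulateRoster:
    def test_roster_size_and_mass_distribution(self):
        roster = simulate_roster(19, 69.7, 6.24, seed=1)
        assert len(roster) == 19
        masses = np.array([p.mass_kg for p in roster])
        se = 6.24 / np.sqrt(19)
        assert abs(masses.mean() - 69.7) < 3 * se

    def test_zero_variance_masses_are_exact(self):
        roster = simulate_roster(2, 70.0, 0.0, seed=0)
        assert [p.mass_kg for p in roster] == [70.0, 70.0]

    def test_seeded_determinism(self):
        a = simulate_roster(19, 69.7, 6.24, seed=1, sigma_u=5.0)
        b = simulate_roster(19, 69.7, 6.24, seed=1, sigma_u=5.0)
        assert a == b

    def test_single_athlete_rejected(self):
        with pytest.raises(ValueError):
            simulate_roster(1, 70.0, 5.0, seed=0)

    def test_sprint_thresholds_exceed_walk_boundary(self):
        roster = simulate_roster(50, 69.7, 6.24, seed=3, sprint_entry_sd_mps=2.0)
        assert all(p.sprint_entry_mps > 1.5 for p in roster)

    def test_athlete_ids_unique(self):
        roster = simulate_roster(19, 69.7, 6.24, seed=1)
        assert len({p.athlete_id for p in roster}) == 19


class TestAthleteProfileInvariants:
    def test_nonpositive_mass_rejected(self):
        with pytest.raises(ValueError):
            AthleteProfile("A", mass_kg=0.0, sprint_entry_mps=5.0)

    def test_walkpace_sprint_threshold_rejected(self):
        with pytest.raises(ValueError):
            AthleteProfile("A", mass_kg=70.0, sprint_entry_mps=1.4)


class TestSimulateTrace:
    def test_length_covers_both_halves_and_halftime(self, athlete, match):
        trace = simulate_trace(athlete, match, MovementProfile(), seed=0)
        assert len(trace) == int((2 * 420 + 120) * 10)

    def test_stand_only_chain_never_moves(self, athlete, match):
        movement = MovementProfile(
            transition_probs={"stand": {"stand": 1.0}},
            mean_dwell_s={"stand": 5.0},
            target_speed_mps={"stand": (0.0, 0.0)},
            p_full_match=1.0,
            p_partial=0.0,
        )
        trace = simulate_trace(athlete, match, movement, seed=1)
        assert np.all(trace.speed_mps == 0.0)

    def test_halftime_flagged_on_field(self, athlete, match):
        trace = simulate_trace(athlete, match, MovementProfile(), seed=2)
        ht = trace.period == "HT"
        assert ht.sum() == 1200
        assert np.all(trace.on_field[ht])

    def test_off_field_speed_is_zero(self, athlete, match):
        movement = MovementProfile(p_full_match=0.0, p_partial=0.0)  # cameo only
        trace = simulate_trace(athlete, match, movement, seed=3)
        off = ~trace.on_field
        assert off.sum() > 0
        assert np.all(trace.speed_mps[off] == 0.0)

    def test_no_speed_jumps_beyond_hard_ramp(self, athlete, match):
        movement = MovementProfile()
        hardest = max(
            movement.hard_ramp_range_mps2[1], movement.contact_ramp_range_mps2[1]
        )
        for seed in range(5):
            trace = simulate_trace(athlete, match, movement, seed=seed)
            dv = np.abs(np.diff(trace.speed_mps))
            assert dv.max() <= hardest * trace.dt_s + 1e-9

    def test_playing_time_within_match_length(self, athlete, match):
        for seed in range(10):
            trace = simulate_trace(athlete, match, MovementProfile(), seed=seed)
            assert trace.playing_time_min() <= 14.0 + 1e-9

    def test_mean_playing_time_calibrated(self, athlete, match):
        """Long-run mean on-field time sits in the calibrated band around the
        descriptive reference of 11.8 min (within the accepted +/-10%)."""
        movement = MovementProfile()
        times = [
            simulate_trace(athlete, match, movement, seed=s).playing_time_min()
            for s in range(300)
        ]
        assert np.mean(times) == pytest.approx(11.8, rel=0.10)

    def test_seeded_determinism(self, athlete, match):
        t1 = simulate_trace(athlete, match, MovementProfile(), seed=9)
        t2 = simulate_trace(athlete, match, MovementProfile(), seed=9)
        assert np.array_equal(t1.speed_mps, t2.speed_mps)
        assert np.array_equal(t1.on_field, t2.on_field)


class TestSimulateContacts:
    def test_zero_rate_means_zero_contacts(self):
        trace = make_trace([1.0] * 600)
        assert simulate_contacts(trace, 0.0, 7.11, seed=1) == 0

    def test_negative_rate_rejected(self):
        trace = make_trace([1.0] * 10)
        with pytest.raises(ValueError):
            simulate_contacts(trace, -1.0, 7.11, seed=1)

    def test_seeded_determinism(self):
        trace = make_trace([1.0] * 600)
        assert simulate_contacts(trace, 0.3, 7.11, seed=5) == simulate_contacts(
            trace, 0.3, 7.11, seed=5
        )

    def test_calibrated_mean_and_overdispersion(self):
        """At the reference playing time, 2000 draws match the 4 +/- 2.5
        contact distribution (mean within 5%, SD within 10%)."""
        cfg = StudyConfig()
        # 7560 samples = 12.6 min, so rate x time = 4.0 at the calibrated rate
        trace = make_trace([1.0] * 7560)
        draws = np.array(
            [
                simulate_contacts(
                    trace, cfg.contact_rate_per_min, cfg.contact_dispersion, seed=s
                )
                for s in range(2000)
            ]
        )
        assert draws.mean() == pytest.approx(
            cfg.contact_rate_per_min * trace.playing_time_min(), rel=0.05
        )
        assert draws.mean() == pytest.approx(4.0, rel=0.05)
        assert draws.std() == pytest.approx(2.5, rel=0.10)


class TestSimulateRpe:
    def _features(self, duration=10.0, game=0):
        feats = {t: 0.0 for t in GroundTruthParams().beta}
        feats["playing_time_min"] = duration
        feats["game_number"] = game
        return feats

    def test_noise_free_arithmetic(self, athlete):
        truth = GroundTruthParams(
            beta={**{t: 0.0 for t in GroundTruthParams().beta}, "intercept": 70.0},
            sigma_u=0.0,
            sigma_e=0.0,
            game_effect={},
            rpe_missing_prob=0.0,
        )
        rpe = simulate_rpe(self._features(duration=10.0), athlete, truth, seed=0)
        assert rpe == 7.0

    def test_always_missing_when_probability_one(self, athlete):
        truth = GroundTruthParams(rpe_missing_prob=0.999999999)
        for seed in range(20):
            assert np.isnan(
                simulate_rpe(self._features(), athlete, truth, seed=seed)
            )

    def test_zero_duration_rejected(self, athlete):
        with pytest.raises(ValueError):
            simulate_rpe(self._features(duration=0.0), athlete, GroundTruthParams(), 0)

    def test_discretized_reports_are_integers_on_scale(self, athlete):
        truth = GroundTruthParams(rpe_missing_prob=0.0)
        vals = [
            simulate_rpe(self._features(duration=12.0, game=1), athlete, truth, s)
            for s in range(200)
        ]
        arr = np.array(vals)
        assert np.all(arr == np.round(arr))
        assert arr.min() >= 0 and arr.max() <= 10

    def test_continuous_mode_is_linear_in_the_latent(self, athlete):
        truth = GroundTruthParams(
            sigma_u=0.0, sigma_e=0.0, rpe_missing_prob=0.0,
            game_effect={}, residual_skew=0.0,
        )
        feats = self._features(duration=12.0)
        feats["contacts"] = 3.0
        expected = (truth.beta["intercept"] + 3.0 * truth.beta["contacts"]) / 12.0
        got = simulate_rpe(feats, athlete, truth, seed=0, discretize=False)
        assert got == pytest.approx(expected)


class TestSimulateStudy:
    def test_row_count_forced_by_config(self):
        ds = simulate_study(StudyConfig(n_matches=4, fielded_per_match=12), seed=1)
        assert len(ds) == 48

    def test_two_player_single_match(self):
        ds = simulate_study(StudyConfig(n_matches=1, fielded_per_match=2), seed=1)
        assert len(ds) == 2

    def test_bit_identical_under_same_seed(self):
        a = simulate_study(StudyConfig(n_matches=3), seed=11)
        b = simulate_study(StudyConfig(n_matches=3), seed=11)
        pd.testing.assert_frame_equal(a.records, b.records)

    def test_different_seeds_differ(self):
        a = simulate_study(StudyConfig(n_matches=3), seed=1)
        b = simulate_study(StudyConfig(n_matches=3), seed=2)
        assert not a.records["total_m"].equals(b.records["total_m"])

    def test_playing_time_never_exceeds_match_length(self, small_study):
        assert (small_study.records["playing_time_min"] <= 14.0 + 1e-9).all()

    def test_keys_unique_and_game_numbers_valid(self, small_study):
        df = small_study.records
        assert not df.duplicated(subset=["athlete_id", "match_id"]).any()
        assert df["game_number"].between(1, 6).all()

    def test_missingness_confined_to_rpe_and_srpe(self, small_study):
        df = small_study.records
        non_rpe = df.drop(columns=["rpe_au", "srpe_au"])
        assert non_rpe.notna().all().all()
        assert df["rpe_au"].isna().equals(df["srpe_au"].isna())

    def test_srpe_is_rpe_times_time(self, small_study):
        df = small_study.records.dropna(subset=["rpe_au"])
        assert np.allclose(
            df["srpe_au"], df["rpe_au"] * df["playing_time_min"], atol=1e-9
        )

    def test_schedule_covers_tournaments_of_five_or_six_games(self):
        cfg = StudyConfig()
        schedule = cfg.schedule()
        assert len(schedule) == 99
        games = pd.DataFrame(schedule, columns=["t", "g"]).groupby("t")["g"].max()
        assert set(games.unique()) <= {5, 6}


class TestMatchConfigInvariants:
    def test_game_number_bounds(self):
        with pytest.raises(ValueError):
            MatchConfig(tournament_id="T", game_number=7)

    def test_sample_rate_fixed(self):
        with pytest.raises(ValueError):
            MatchConfig(tournament_id="T", game_number=1, sample_rate_hz=20.0)
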