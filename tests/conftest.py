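import numpy as np
import pytest

from sevensload.config import GroundTruthParams, MovementProfile, StudyConfig
from sevensload.kinematics import SpeedTrace, ZoneThresholds
from sevensload.synthetic import AthleteProfile, MatchConfig


@pytest.fixture(scope="session")
def thresholds():
    return ZoneThresholds(sprint_entry_mps=5.0)


@pytest.fixture
def athlete():
    return AthleteProfile(
        athlete_id="A01", mass_kg=70.0, sprint_entry_mps=5.2, random_intercept_au=0.0
    )


@pytest.fixture
def match():
    return MatchConfig(tournament_id="T01", game_number=1, match_id="M001")


def make_trace(
    speeds,
    on_field=None,
    period=None,
    athlete_id="A01",
    match_id="M001",
    sample_rate_hz=10.0,
):
    """Hand-build a SpeedTrace from a speed list (all on-field H1 by default)."""
    speeds = np.asarray(speeds, dtype=float)
    n = len(speeds)
    if on_field is None:
        on_field = np.ones(n, dtype=bool)
    if period is None:
        period = np.array(["H1"] * n, dtype=object)
    return SpeedTrace(
        athlete_id=athlete_id,
        match_id=match_id,
        time_s=np.arange(n) / sample_rate_hz,
        speed_mps=speeds,
        on_field=np.asarray(on_field, dtype=bool),
        period=np.asarray(period, dtype=object),
        sample_rate_hz=sample_rate_hz,
    )


def random_trace(rng, n=600, max_speed=8.0, off_field_prob=0.1, ht_block=False):
    """A random (not physically smooth) trace for oracle comparisons."""
    speeds = rng.uniform(0.0, max_speed, size=n)
    on_field = rng.random(n) > off_field_prob
    period = np.array(["H1"] * n, dtype=object)
    if ht_block:
        lo, hi = n // 3, n // 2
        period[lo:hi] = "HT"
        on_field[lo:hi] = True
    return make_trace(speeds, on_field=on_field, period=period)


@pytest.fixture(scope="session")
def small_study():
    """A reduced but fully featured simulated study (shared across tests)."""
    from sevensload.synthetic import simulate_study

    return simulate_study(StudyConfig(n_matches=12), seed=7)


@pytest.fixture
def zero_noise_config():
    """Study config whose response is an exact linear function of the design."""
    truth = GroundTruthParams(
        beta={
            "intercept": 40.0,
            "mass_kg": -0.5,
            "contacts": 1.0,
            "total_m": 0.05,
            "HA_total": 0.0,
            "LD_total": -0.02,
            "HD_total": 0.0,
            "HA_LS": 0.0,
            "HA_HS": 0.0,
            "LD_LS": 0.02,
            "LD_HS": 0.03,
            "HD_LS": 0.0,
            "HD_HS": 0.0,
        },
        sigma_u=0.0,
        sigma_e=0.0,
        game_effect={g: 0.0 for g in range(1, 7)},
        rpe_missing_prob=0.0,
    )
    return StudyConfig(n_matches=15, truth=truth, discretize_rpe=False)
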