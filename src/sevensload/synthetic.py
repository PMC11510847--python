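"""Seeded synthetic stand-ins for a women's rugby sevens GNSS study.

The real study data (10 Hz speed traces, contact counts, post-match RPE
reports for one international squad) are not publicly available, so this
module generates statistically calibrated substitutes from a known
ground-truth model:

* a roster of athletes with body mass, an individual sprint-entry threshold
  and a latent athlete intercept;
* per player-match 10 Hz speed traces realized from a five-state
  semi-Markov movement model with linear speed ramps;
* per player-match contact counts (negative binomial, overdispersed);
* per player-match RPE reports derived from a latent linear session-load
  model, discretized to the 0-10 scale athletes actually use and missing
  completely at random.

Because the generating coefficients are known, the downstream model fit can
be validated by parameter recovery, which is impossible with the real data.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd

from .config import MODEL_TERMS, GroundTruthParams, MovementProfile, StudyConfig
from .features import StudyDataset, build_records, design_features
from .kinematics import (
    SpeedTrace,
    ZoneThresholds,
    accumulate_zone_distances,
    compute_acceleration,
)

__all__ = [
    "AthleteProfile",
    "MatchConfig",
    "simulate_roster",
    "simulate_trace",
    "simulate_contacts",
    "simulate_rpe",
    "simulate_study",
]


@dataclass(frozen=True)
class AthleteProfile:
    """One athlete: identity, mass, sprint threshold, latent intercept."""

    athlete_id: str
    mass_kg: float
    sprint_entry_mps: float
    random_intercept_au: float = 0.0

    def __post_init__(self):
        if self.mass_kg <= 0:
            raise ValueError("mass_kg must be positive")
        if self.sprint_entry_mps <= 1.5:
            raise ValueError("sprint_entry_mps must exceed the walk/run boundary")


@dataclass(frozen=True)
class MatchConfig:
    """Timing and fielding of one match (two 7-minute halves by default)."""

    tournament_id: str
    game_number: int
    match_id: str = ""
    half_length_s: float = 420.0
    halftime_s: float = 120.0
    sample_rate_hz: float = 10.0
    fielded_athletes: tuple[str, ...] = ()

    def __post_init__(self):
        if not 1 <= self.game_number <= 6:
            raise ValueError("game_number must be between 1 and 6")
        if self.sample_rate_hz != 10.0:
            raise ValueError("sample_rate_hz is fixed at 10")

    @property
    def n_samples(self) -> int:
        return int(
            round((2 * self.half_length_s + self.halftime_s) * self.sample_rate_hz)
        )


def _rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def simulate_roster(
    n_athletes: int,
    mass_mean_kg: float,
    mass_sd_kg: float,
    seed,
    sprint_entry_mean_mps: float = 5.2,
    sprint_entry_sd_mps: float = 0.3,
    sigma_u: float = 0.0,
) -> list[AthleteProfile]:
    """Draw a roster of athlete profiles.

    Masses are normal with the given mean/SD; sprint-entry thresholds are
    normal truncated above the 1.5 m/s walk/run boundary; the latent athlete
    intercept ``u_j`` is ``N(0, sigma_u)``.
    """
    if n_athletes < 2:
        raise ValueError("a mixed model needs at least 2 athletes (groups)")
    if mass_sd_kg < 0:
        raise ValueError("mass_sd_kg must be non-negative")
    rng = _rng(seed)
    masses = rng.normal(mass_mean_kg, mass_sd_kg, size=n_athletes)
    masses = np.clip(masses, 40.0, None)  # guard against absurd tail draws
    thresholds = rng.normal(sprint_entry_mean_mps, sprint_entry_sd_mps, size=n_athletes)
    while np.any(thresholds <= 1.5):  # truncation by redraw
        bad = thresholds <= 1.5
        thresholds[bad] = rng.normal(
            sprint_entry_mean_mps, sprint_entry_sd_mps, size=int(bad.sum())
        )
    intercepts = rng.normal(0.0, sigma_u, size=n_athletes)
    return [
        AthleteProfile(
            athlete_id=f"A{i + 1:02d}",
            mass_kg=float(masses[i]),
            sprint_entry_mps=float(thresholds[i]),
            random_intercept_au=float(intercepts[i]),
        )
        for i in range(n_athletes)
    ]


# ---------------------------------------------------------------------------
# Speed-trace simulation
# ---------------------------------------------------------------------------


def _draw_exposure(
    movement: MovementProfile, match: MatchConfig, rng: np.random.Generator
) -> list[tuple[float, float]]:
    """On-field intervals in wall-clock seconds (halftime excluded).

    Returns intervals within [0, H1) and [H1+HT, end). The mixture produces
    mostly full matches, some one-and-a-bit-half exposures, and rare cameos.
    """
    h1 = (0.0, match.half_length_s)
    h2_start = match.half_length_s + match.halftime_s
    h2 = (h2_start, h2_start + match.half_length_s)
    u = rng.random()
    which = rng.random() < 0.5  # which half is shortened / used
    late = rng.random() < 0.5  # enter late vs leave early
    if u < movement.p_full_match:
        return [h1, h2]
    if u < movement.p_full_match + movement.p_partial:
        lo, hi = movement.partial_extra_min_range
        extra_s = min(rng.uniform(lo, hi) * 60.0, match.half_length_s)
        if which:  # H1 partial, H2 full
            part = (h1[1] - extra_s, h1[1]) if late else (h1[0], h1[0] + extra_s)
            return [part, h2]
        part = (h2[1] - extra_s, h2[1]) if late else (h2[0], h2[0] + extra_s)
        return [h1, part]
    lo, hi = movement.cameo_min_range
    dur_s = min(rng.uniform(lo, hi) * 60.0, match.half_length_s)
    half = h1 if which else h2
    start = half[0] + rng.uniform(0.0, match.half_length_s - dur_s)
    return [(start, start + dur_s)]


def _merge_spans(
    intervals: list[tuple[float, float]], match: MatchConfig
) -> list[tuple[float, float]]:
    """Join H1-end and H2-start intervals across halftime into one active span.

    Players who finish the first half and start the second stay on the field
    through the break, so their movement chain continues (restricted to
    standing/walking) rather than stopping and restarting.
    """
    ht_start = match.half_length_s
    ht_end = match.half_length_s + match.halftime_s
    spans = sorted(intervals)
    if (
        len(spans) == 2
        and abs(spans[0][1] - ht_start) < 1e-9
        and abs(spans[1][0] - ht_end) < 1e-9
    ):
        return [(spans[0][0], spans[1][1])]
    return spans


_STOP_RAMP_MPS2 = 1.6  # gentle pull-up used to end a span at zero speed


def _draw_hard_weight(
    movement: MovementProfile, rng: np.random.Generator
) -> float:
    """Per-trace hard-ramp share, Beta-distributed around the profile mean."""
    m, sd = movement.hard_ramp_weight, movement.hard_ramp_weight_sd
    if sd <= 0:
        return m
    nu = m * (1.0 - m) / min(sd**2, 0.9 * m * (1.0 - m)) - 1.0
    return float(rng.beta(m * nu, (1.0 - m) * nu))


def _chain_breakpoints(
    span: tuple[float, float],
    profile: AthleteProfile,
    match: MatchConfig,
    movement: MovementProfile,
    rng: np.random.Generator,
    tempo: float = 1.0,
    w_hard_trace: float | None = None,
) -> tuple[list[float], list[float]]:
    """Piecewise-linear (time, speed) breakpoints for one active span.

    The chain starts and ends at zero speed so that masking the surrounding
    off-field samples to zero never creates a speed discontinuity.
    """
    t0, t1 = span
    ht_lo, ht_hi = match.half_length_s, match.half_length_s + match.halftime_s
    trans_to = {s: list(p.keys()) for s, p in movement.transition_probs.items()}
    trans_cum = {
        s: np.cumsum(list(p.values())) for s, p in movement.transition_probs.items()
    }

    times = [t0]
    speeds = [0.0]
    t = t0
    v = 0.0
    state = "stand"
    while True:
        # reserve time to brake to zero before the span closes
        reserve = v / _STOP_RAMP_MPS2
        remaining = t1 - t - reserve
        if remaining <= 0.05:
            break
        # dwell in current state at constant speed
        mean_dwell = movement.mean_dwell_s[state] * tempo
        dwell = rng.exponential(mean_dwell)
        dwell = min(max(dwell, 0.4), 5.0 * mean_dwell, remaining)
        t += dwell
        times.append(t)
        speeds.append(v)
        reserve = v / _STOP_RAMP_MPS2
        if t1 - t - reserve <= 0.05:
            break
        # pick the next state; during halftime only stand or walk
        in_halftime = ht_lo <= t < ht_hi
        calm_states = [s for s in ("stand", "walk") if s in trans_to]
        if in_halftime and calm_states:
            # players mill about at the break: stand or walk only
            if len(calm_states) == 2 and rng.random() < 0.45:
                nxt = "walk"
            else:
                nxt = calm_states[0]
        else:
            cum = trans_cum[state]
            nxt = trans_to[state][int(np.searchsorted(cum, rng.random() * cum[-1]))]
        # target speed for the next visit
        if nxt == "sprint":
            mu, sd = movement.sprint_speed_above_threshold_mps
            target = profile.sprint_entry_mps + rng.normal(mu, sd)
        else:
            mu, sd = movement.target_speed_mps[nxt]
            target = rng.normal(mu, sd) if sd > 0 else mu
        floor = {"stand": 0.0, "walk": 0.2, "jog": 1.6, "contact": 0.0}.get(nxt, 0.0)
        target = max(target, floor)
        # ramp magnitude: mild/hard mixture, with maximal efforts biased hard
        if nxt == "contact":
            ramp = rng.uniform(*movement.contact_ramp_range_mps2)
        else:
            if nxt == "sprint":
                w_hard = movement.hard_ramp_weight_into_sprint
            elif state == "sprint":
                w_hard = movement.hard_ramp_weight_from_sprint
            elif state == "contact":
                w_hard = movement.hard_ramp_weight_from_contact
            elif nxt in ("walk", "stand") and target > v:
                # gentle pick-ups from a standstill or walk are rarely hard
                w_hard = movement.hard_ramp_weight_into_walk_stand
            elif w_hard_trace is not None:
                w_hard = w_hard_trace
            else:
                w_hard = movement.hard_ramp_weight
            if rng.random() < w_hard:
                if state == "sprint":
                    ramp = rng.uniform(*movement.sprint_exit_ramp_range_mps2)
                else:
                    ramp = rng.uniform(*movement.hard_ramp_range_mps2)
            else:
                ramp = rng.uniform(*movement.mild_ramp_range_mps2)
        ramp_dur = abs(target - v) / ramp
        reserve_next = target / _STOP_RAMP_MPS2
        if t + ramp_dur + reserve_next >= t1 - 0.05:
            break  # no room to reach the target and still stop in time
        t += ramp_dur
        v = target
        times.append(t)
        speeds.append(v)
        state = nxt
    # final pull-up to zero
    if v > 0:
        t = min(t + v / _STOP_RAMP_MPS2, t1)
        v = 0.0
        times.append(t)
        speeds.append(v)
    if times[-1] < t1:
        times.append(t1)
        speeds.append(0.0)
    return times, speeds


def simulate_trace(
    profile: AthleteProfile,
    match: MatchConfig,
    movement: MovementProfile,
    seed,
) -> SpeedTrace:
    """Simulate one player-match 10 Hz speed trace.

    The trace covers first half, halftime and second half at exactly 10 Hz.
    Halftime samples are flagged ``period="HT"`` with ``on_field=True``
    (players stay on the field through the break); substituted spans are
    ``on_field=False`` with zero speed. Speed is a continuous piecewise-ramp
    realization of the movement-state chain, so consecutive samples never
    differ by more than the hardest ramp magnitude times the sample interval.
    """
    rng = _rng(seed)
    n = match.n_samples
    dt = 1.0 / match.sample_rate_hz
    time_s = np.arange(n) * dt
    speed = np.zeros(n)

    intervals = _draw_exposure(movement, match, rng)
    spans = _merge_spans(intervals, match)
    # per-trace tempo factor: scales every dwell mean, leaving occupancy
    # shares unchanged but varying how often the player transitions
    tempo = float(np.exp(rng.normal(0.0, movement.tempo_sd_log)))
    w_hard_trace = _draw_hard_weight(movement, rng)
    for span in spans:
        bp_t, bp_v = _chain_breakpoints(
            span, profile, match, movement, rng, tempo, w_hard_trace
        )
        lo = int(np.ceil(span[0] / dt - 1e-9))
        hi = min(int(np.floor(span[1] / dt + 1e-9)) + 1, n)
        seg = slice(lo, hi)
        speed[seg] = np.interp(time_s[seg], bp_t, bp_v)

    on_field = np.zeros(n, dtype=bool)
    for lo_s, hi_s in intervals:
        on_field[(time_s >= lo_s - 1e-9) & (time_s < hi_s - 1e-9)] = True

    ht_lo, ht_hi = match.half_length_s, match.half_length_s + match.halftime_s
    period = np.where(
        time_s < ht_lo, "H1", np.where(time_s < ht_hi, "HT", "H2")
    ).astype(object)
    on_field[period == "HT"] = True  # everyone is on the field at the break

    return SpeedTrace(
        athlete_id=profile.athlete_id,
        match_id=match.match_id or f"{match.tournament_id}-G{match.game_number}",
        time_s=time_s,
        speed_mps=speed,
        on_field=on_field,
        period=period,
        sample_rate_hz=match.sample_rate_hz,
    )


def simulate_contacts(
    trace: SpeedTrace, rate_per_min: float, dispersion: float, seed
) -> int:
    """Draw a contact count for one player-match.

    Negative binomial with mean ``rate_per_min x playing_time_min`` and shape
    ``dispersion`` (smaller = more overdispersed); a Poisson count cannot
    carry the overdispersion observed in match contacts.
    """
    if rate_per_min < 0:
        raise ValueError("rate_per_min must be non-negative")
    if dispersion <= 0:
        raise ValueError("dispersion must be positive")
    rng = _rng(seed)
    lam = rate_per_min * trace.playing_time_min()
    if lam == 0:
        return 0
    p = dispersion / (dispersion + lam)
    return int(rng.negative_binomial(dispersion, p))


def _skew_residual(rng: np.random.Generator, sigma: float, alpha: float) -> float:
    """One draw from a skew-normal standardized to mean 0 and SD ``sigma``.

    ``alpha`` is the usual skew-normal shape; negative values thin the upper
    tail. ``alpha = 0`` reduces to a plain normal draw.
    """
    if sigma <= 0:
        return 0.0
    if alpha == 0:
        return float(rng.normal(0.0, sigma))
    delta = alpha / np.sqrt(1.0 + alpha**2)
    z0, z1 = rng.normal(size=2)
    x = delta * abs(z0) + np.sqrt(1.0 - delta**2) * z1
    mean = delta * np.sqrt(2.0 / np.pi)
    sd = np.sqrt(1.0 - 2.0 * delta**2 / np.pi)
    return float(sigma * (x - mean) / sd)


def simulate_rpe(
    record_features: Mapping[str, float],
    profile: AthleteProfile,
    truth: GroundTruthParams,
    seed,
    discretize: bool = True,
) -> float:
    """Generate one reported RPE (or NaN for a missing report).

    The latent session load is ``sRPE* = X beta + game_effect + u_j + eps``;
    the athlete reports ``RPE = clamp(round(sRPE*/duration), 0, 10)`` with
    half-up rounding. With ``discretize=False`` the raw latent ratio
    ``sRPE*/duration`` is returned instead -- no rounding and no 0-10
    clamping -- which keeps the response an exact linear function of the
    generating model; this diagnostic scale is what parameter-recovery
    studies should use, since the bounded reporting scale censors extreme
    latent loads. The report goes missing completely at random with
    probability ``truth.rpe_missing_prob``.
    """
    duration = float(record_features["playing_time_min"])
    if duration <= 0:
        raise ValueError("playing time must be positive to report an RPE")
    rng = _rng(seed)
    latent = truth.beta["intercept"]
    for term in MODEL_TERMS[1:]:
        latent += truth.beta[term] * float(record_features[term])
    game = int(record_features.get("game_number", 0))
    latent += truth.game_effect.get(game, 0.0)
    latent += profile.random_intercept_au
    latent += _skew_residual(rng, truth.sigma_e, truth.residual_skew)
    missing = rng.random() < truth.rpe_missing_prob
    if missing:
        return float("nan")
    rpe = latent / duration
    if discretize:
        rpe = float(np.clip(np.floor(rpe + 0.5), 0.0, 10.0))
    return float(rpe)


# ---------------------------------------------------------------------------
# Whole-study simulation
# ---------------------------------------------------------------------------


def simulate_study(
    config: StudyConfig,
    seed,
    trace_sink: Callable[[SpeedTrace], None] | None = None,
) -> StudyDataset:
    """Simulate a full study and assemble analysis-ready records.

    One record per fielded player per match: traces are simulated, run
    through the zone kinematics, fused with contacts, mass and the generated
    RPE reports via :func:`sevensload.features.build_records`. ``trace_sink``
    (if given) receives every simulated trace, e.g. to write CSVs.

    Identical ``config`` and ``seed`` give a bit-identical dataset.
    """
    if isinstance(seed, np.random.SeedSequence):
        root = seed
    else:
        root = np.random.SeedSequence(seed)
    ss_roster, ss_field, ss_match = root.spawn(3)

    roster = simulate_roster(
        config.n_athletes,
        config.mass_mean_kg,
        config.mass_sd_kg,
        np.random.default_rng(ss_roster),
        sprint_entry_mean_mps=config.sprint_entry_mean_mps,
        sprint_entry_sd_mps=config.sprint_entry_sd_mps,
        sigma_u=config.truth.sigma_u,
    )
    by_id = {p.athlete_id: p for p in roster}
    field_rng = np.random.default_rng(ss_field)
    match_seeds = ss_match.spawn(config.n_matches)

    schedule = config.schedule()
    zone_rows: list[dict] = []
    contact_rows: list[dict] = []
    rpe_rows: list[dict] = []
    match_meta: list[dict] = []

    for m_idx, (tournament_id, game_number) in enumerate(schedule):
        match_id = f"M{m_idx + 1:03d}"
        match = MatchConfig(
            tournament_id=tournament_id,
            game_number=game_number,
            match_id=match_id,
            half_length_s=config.half_length_s,
            halftime_s=config.halftime_s,
            sample_rate_hz=config.sample_rate_hz,
        )
        match_meta.append(
            {
                "match_id": match_id,
                "tournament_id": tournament_id,
                "game_number": game_number,
            }
        )
        fielded_idx = field_rng.choice(
            config.n_athletes, size=config.fielded_per_match, replace=False
        )
        player_seeds = match_seeds[m_idx].spawn(config.fielded_per_match)
        for p_pos, a_idx in enumerate(sorted(fielded_idx)):
            profile = roster[a_idx]
            prng = np.random.default_rng(player_seeds[p_pos])
            trace = simulate_trace(profile, match, config.movement, prng)
            if trace_sink is not None:
                trace_sink(trace)
            accel = compute_acceleration(trace)
            zones = accumulate_zone_distances(
                trace, accel, ZoneThresholds(sprint_entry_mps=profile.sprint_entry_mps)
            )
            row = {"athlete_id": profile.athlete_id, "match_id": match_id}
            row.update(zones.as_series().to_dict())
            zone_rows.append(row)
            contacts = simulate_contacts(
                trace, config.contact_rate_per_min, config.contact_dispersion, prng
            )
            contact_rows.append(
                {
                    "athlete_id": profile.athlete_id,
                    "match_id": match_id,
                    "contacts": contacts,
                }
            )
            feats = dict(row)
            feats.update(design_features(pd.Series(row)).to_dict())
            feats["contacts"] = contacts
            feats["mass_kg"] = profile.mass_kg
            feats["game_number"] = game_number
            rpe = simulate_rpe(
                feats, profile, config.truth, prng, discretize=config.discretize_rpe
            )
            rpe_rows.append(
                {
                    "athlete_id": profile.athlete_id,
                    "match_id": match_id,
                    "rpe_au": rpe,
                }
            )

    roster_frame = pd.DataFrame(
        {
            "athlete_id": [p.athlete_id for p in roster],
            "mass_kg": [p.mass_kg for p in roster],
            "sprint_entry_mps": [p.sprint_entry_mps for p in roster],
        }
    )
    dataset = build_records(
        zone_summaries=pd.DataFrame(zone_rows),
        contacts=pd.DataFrame(contact_rows),
        roster=roster_frame,
        rpe_reports=pd.DataFrame(rpe_rows),
        match_meta=pd.DataFrame(match_meta),
        validate_rpe_scale=config.discretize_rpe,
    )
    dataset.provenance = {
        "seed": int(seed) if isinstance(seed, (int, np.integer)) else "seed-sequence",
        "n_matches": config.n_matches,
        "fielded_per_match": config.fielded_per_match,
        "n_athletes": config.n_athletes,
    }
    dataset.roster = roster
    return dataset
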