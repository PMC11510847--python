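"""Configuration objects and the calibrated study defaults.

Every tunable surface of the pipeline lives here: the movement-state profile
driving the synthetic speed traces, the ground-truth workload coefficients
behind the simulated RPE reports, zone thresholds, the study layout
(athletes, matches, tournament structure) and the model/evaluation settings.
The defaults constitute the calibrated study profile: simulating with them
reproduces the descriptive statistics the pipeline targets (per-zone
distances, contacts, playing time, RPE, sRPE, completeness and the share of
sRPE variance the workload model explains). See ``docs/methods.md`` for how
the calibration was performed and why individual values were chosen.

All objects round-trip through plain dictionaries (and therefore YAML).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import yaml

from .errors import ConfigError

STATES = ("stand", "walk", "jog", "sprint", "contact")

#: Fixed-effect term names of the workload model, in design-matrix order.
MODEL_TERMS = (
    "intercept",
    "mass_kg",
    "contacts",
    "total_m",
    "HA_total",
    "LD_total",
    "HD_total",
    "HA_LS",
    "HA_HS",
    "LD_LS",
    "LD_HS",
    "HD_LS",
    "HD_HS",
)


@dataclass
class MovementProfile:
    """Semi-Markov movement model generating one on-field speed trajectory.

    A player alternates between five locomotor states. Dwell times are
    exponential with the given means; on each transition the speed ramps
    linearly to the next state's target at a rate drawn from a two-component
    mixture of mild (<2 m/s^2) and hard (>2 m/s^2) magnitudes, so that all
    twelve speed x acceleration zones receive distance. Sprint target speeds
    are expressed relative to the athlete's individual sprint-entry
    threshold so that sprints actually register as sprinting for fast and
    slow athletes alike.
    """

    mean_dwell_s: dict[str, float] = field(
        default_factory=lambda: {
            "stand": 7.8,
            "walk": 9.9,
            "jog": 19.0,
            "sprint": 4.4,
            "contact": 1.5,
        }
    )
    # (mean, sd) of the target speed drawn on each visit, m/s. The sprint
    # entry is relative to the athlete threshold; others are absolute.
    target_speed_mps: dict[str, tuple[float, float]] = field(
        default_factory=lambda: {
            "stand": (0.0, 0.0),
            "walk": (1.05, 0.12),
            "jog": (2.65, 0.35),
            "contact": (0.25, 0.10),
        }
    )
    sprint_speed_above_threshold_mps: tuple[float, float] = (0.40, 0.23)
    transition_probs: dict[str, dict[str, float]] = field(
        default_factory=lambda: {
            "stand": {"walk": 0.75, "jog": 0.25},
            "walk": {"stand": 0.64, "jog": 0.28, "sprint": 0.08},
            "jog": {"walk": 0.41, "stand": 0.34, "sprint": 0.11, "contact": 0.14},
            "sprint": {"jog": 0.45, "walk": 0.20, "contact": 0.25, "stand": 0.10},
            "contact": {"stand": 0.50, "walk": 0.30, "jog": 0.20},
        }
    )
    # Ramp-magnitude mixture, m/s^2. Hard ramps exceed the 2 m/s^2 zone
    # threshold, mild ramps stay below it.
    mild_ramp_range_mps2: tuple[float, float] = (1.3, 1.95)
    hard_ramp_range_mps2: tuple[float, float] = (2.35, 3.75)
    hard_ramp_weight: float = 0.34
    # Between-performance spread of the mild/hard mix: the per-trace hard
    # weight is Beta-distributed with this SD around hard_ramp_weight, so the
    # mild- and hard-ramp distance totals vary independently across
    # player-matches instead of tracking each other exactly.
    hard_ramp_weight_sd: float = 0.24
    # Maximal efforts are overwhelmingly hard, easing off to walk or a
    # standstill rarely is: overrides by origin/destination state.
    hard_ramp_weight_into_sprint: float = 0.83
    hard_ramp_weight_from_sprint: float = 1.0
    hard_ramp_weight_from_contact: float = 0.30
    hard_ramp_weight_into_walk_stand: float = 0.16
    # Sprint pull-ups are hard but sustained, sitting just over the threshold.
    sprint_exit_ramp_range_mps2: tuple[float, float] = (2.05, 2.85)
    contact_ramp_range_mps2: tuple[float, float] = (3.0, 4.6)
    # Per-trace tempo heterogeneity: all dwell means are scaled by a
    # log-normal factor exp(N(0, tempo_sd_log)) drawn once per player-match.
    # Occupancy shares (hence mild-deceleration distance) are unchanged in
    # expectation, but transition frequency -- and with it the distance spent
    # ramping -- varies between player-matches, as it does between real
    # performances.
    tempo_sd_log: float = 0.38
    # Expected kinematic contact-brake events per on-field minute (mirrors the
    # contact-count rate; the analysed count is drawn separately).
    contact_rate_per_min: float = 0.318
    # On-field exposure mixture: full match; one full half plus part of the
    # other (7 + U(a, b) minutes); or a brief cameo (U(c, d) minutes).
    p_full_match: float = 0.48
    p_partial: float = 0.50
    partial_extra_min_range: tuple[float, float] = (3.2, 6.2)
    cameo_min_range: tuple[float, float] = (2.0, 5.0)

    def __post_init__(self):
        for s, probs in self.transition_probs.items():
            total = sum(probs.values())
            if abs(total - 1.0) > 1e-9:
                raise ConfigError(f"transition probabilities from {s!r} sum to {total}")
            if any(p < 0 for p in probs.values()):
                raise ConfigError(f"negative transition probability from {s!r}")
        if any(d <= 0 for d in self.mean_dwell_s.values()):
            raise ConfigError("all dwell times must be positive")
        for s, (m, sd) in self.target_speed_mps.items():
            if m < 0 or sd < 0:
                raise ConfigError(f"target speed for {s!r} must be non-negative")
        if not 0 <= self.hard_ramp_weight <= 1:
            raise ConfigError("hard_ramp_weight must be in [0, 1]")
        p_cameo = 1.0 - self.p_full_match - self.p_partial
        if self.p_full_match < 0 or self.p_partial < 0 or p_cameo < -1e-9:
            raise ConfigError("exposure mixture probabilities must be non-negative")

    @property
    def p_cameo(self) -> float:
        return max(0.0, 1.0 - self.p_full_match - self.p_partial)


@dataclass
class GroundTruthParams:
    """Generating coefficients and noise scales of the simulated workload.

    The latent session load is ``sRPE* = X beta + game_effect + u_j + eps``
    with athlete intercepts ``u_j ~ N(0, sigma_u)`` and a standardized
    skew-normal residual ``eps`` (mean 0, SD ``sigma_e``, shape
    ``residual_skew``), all in arbitrary units (au). The reported RPE is
    ``clamp(round(sRPE* / playing_time_min), 0, 10)`` and goes missing
    completely at random with probability ``rpe_missing_prob``.

    ``beta`` is keyed by :data:`MODEL_TERMS` on raw predictor scales
    (au per kg, per contact, per metre). The sign pattern encodes the
    substantive structure the pipeline studies: mass negative, contacts and
    total distance positive, mild-deceleration distance negative with
    positive low- and high-speed interactions, and all acceleration terms
    zero.
    """

    beta: dict[str, float] = field(
        default_factory=lambda: {
            "intercept": 48.5,
            "mass_kg": -0.9,
            "contacts": 1.7,
            "total_m": 0.28,
            "HA_total": 0.0,
            "LD_total": -0.218,
            "HD_total": 0.0,
            "HA_LS": 0.0,
            "HA_HS": 0.0,
            "LD_LS": 0.035,
            "LD_HS": 0.09,
            "HD_LS": 0.0,
            "HD_HS": 0.0,
        }
    )
    sigma_u: float = 4.0
    sigma_e: float = 18.5
    # Shape of the standardized skew-normal residual (mean 0, SD sigma_e).
    # Negative skew thins the upper tail, reflecting the compressed top of
    # the bounded effort scale; 0 gives a plain normal residual.
    residual_skew: float = -3.0
    game_effect: dict[int, float] = field(
        default_factory=lambda: {1: -21.0, 2: -21.0, 3: 10.5, 4: 10.5, 5: 10.5, 6: 13.0}
    )
    rpe_missing_prob: float = 0.1565

    def __post_init__(self):
        if self.sigma_u < 0 or self.sigma_e < 0:
            raise ConfigError("variance components must be non-negative")
        if not 0 <= self.rpe_missing_prob < 1:
            raise ConfigError("rpe_missing_prob must be in [0, 1)")
        missing = [t for t in MODEL_TERMS if t not in self.beta]
        if missing:
            raise ConfigError(f"beta missing terms: {missing}")

    def beta_vector(self) -> list[float]:
        return [self.beta[t] for t in MODEL_TERMS]


@dataclass
class StudyConfig:
    """Layout of one simulated study (roster, schedule, reporting)."""

    n_athletes: int = 19
    mass_mean_kg: float = 69.7
    mass_sd_kg: float = 6.24
    sprint_entry_mean_mps: float = 5.2
    sprint_entry_sd_mps: float = 0.3
    n_matches: int = 99
    fielded_per_match: int = 12
    # Tournament blocks: 99 matches = 9 six-game + 9 five-game tournaments.
    tournament_games: tuple[int, ...] = (6, 5) * 9
    half_length_s: float = 420.0
    halftime_s: float = 120.0
    sample_rate_hz: float = 10.0
    contact_rate_per_min: float = 0.318
    contact_dispersion: float = 7.11
    movement: MovementProfile = field(default_factory=MovementProfile)
    truth: GroundTruthParams = field(default_factory=GroundTruthParams)
    # Reported RPE is an integer 0-10 by default; the continuous latent scale
    # (no rounding) is exposed for estimator diagnostics.
    discretize_rpe: bool = True

    def __post_init__(self):
        if self.n_athletes < 2:
            raise ConfigError("a mixed model needs at least 2 athletes")
        if self.fielded_per_match < 1 or self.fielded_per_match > self.n_athletes:
            raise ConfigError("fielded_per_match must be in [1, n_athletes]")
        if sum(self.tournament_games) < self.n_matches:
            raise ConfigError("tournament_games must cover n_matches")
        if any(not 1 <= g <= 6 for g in self.tournament_games):
            raise ConfigError("tournaments play between 1 and 6 games")
        if self.sample_rate_hz != 10.0:
            raise ConfigError("the trace contract is fixed at 10 Hz")

    def match_length_min(self) -> float:
        return 2.0 * self.half_length_s / 60.0

    def schedule(self) -> list[tuple[str, int]]:
        """(tournament_id, game_number) for each match, in order."""
        out: list[tuple[str, int]] = []
        for t_idx, games in enumerate(self.tournament_games):
            for g in range(1, games + 1):
                if len(out) == self.n_matches:
                    return out
                out.append((f"T{t_idx + 1:02d}", g))
        return out


@dataclass
class ModelSpec:
    """Fixed/random structure of the workload model.

    The reference acceleration type is LA (absorbed in total distance) and
    the reference speed zone within each acceleration type is MS, which makes
    the design identifiable despite total distance being the sum of all
    twelve cells.
    """

    standardize: bool = True
    reml: bool = True
    alpha: float = 0.01


@dataclass
class EvalConfig:
    alpha: float = 0.01


@dataclass
class RunConfig:
    """Everything one reproducible run needs, including a seed."""

    seed: int = 1
    study: StudyConfig = field(default_factory=StudyConfig)
    model: ModelSpec = field(default_factory=ModelSpec)
    evaluation: EvalConfig = field(default_factory=EvalConfig)
    output_dir: str = "results"
    write_traces: bool = False

    # -- (de)serialization -------------------------------------------------
    def to_dict(self) -> dict:
        return _asdict(self)

    @classmethod
    def from_dict(cls, data: Mapping) -> "RunConfig":
        data = dict(data)
        if "study" in data and isinstance(data["study"], Mapping):
            study = dict(data["study"])
            if isinstance(study.get("movement"), Mapping):
                study["movement"] = _movement_from_dict(study["movement"])
            if isinstance(study.get("truth"), Mapping):
                study["truth"] = _truth_from_dict(study["truth"])
            if isinstance(study.get("tournament_games"), list):
                study["tournament_games"] = tuple(study["tournament_games"])
            data["study"] = StudyConfig(**study)
        if isinstance(data.get("model"), Mapping):
            data["model"] = ModelSpec(**data["model"])
        if isinstance(data.get("evaluation"), Mapping):
            data["evaluation"] = EvalConfig(**data["evaluation"])
        try:
            return cls(**data)
        except TypeError as exc:
            raise ConfigError(str(exc)) from exc

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        path = Path(path)
        if not path.exists():
            raise ConfigError(f"config file not found: {path}")
        data = yaml.safe_load(path.read_text())
        if not isinstance(data, Mapping):
            raise ConfigError(f"config file {path} is not a mapping")
        return cls.from_dict(data)

    def config_hash(self) -> str:
        """Stable short hash of the full configuration, for provenance stamps."""
        payload = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


def _asdict(obj) -> dict:
    def convert(x):
        if dataclasses.is_dataclass(x) and not isinstance(x, type):
            return {k: convert(v) for k, v in dataclasses.asdict(x).items()}
        if isinstance(x, dict):
            return {k: convert(v) for k, v in x.items()}
        if isinstance(x, tuple):
            return [convert(v) for v in x]
        if isinstance(x, list):
            return [convert(v) for v in x]
        return x

    return convert(obj)


def _movement_from_dict(d: Mapping) -> MovementProfile:
    d = dict(d)
    for key in (
        "mild_ramp_range_mps2",
        "hard_ramp_range_mps2",
        "contact_ramp_range_mps2",
        "sprint_speed_above_threshold_mps",
        "partial_extra_min_range",
        "cameo_min_range",
    ):
        if key in d and isinstance(d[key], list):
            d[key] = tuple(d[key])
    if "target_speed_mps" in d:
        d["target_speed_mps"] = {
            k: tuple(v) for k, v in dict(d["target_speed_mps"]).items()
        }
    return MovementProfile(**d)


def _truth_from_dict(d: Mapping) -> GroundTruthParams:
    d = dict(d)
    if "game_effect" in d:
        d["game_effect"] = {int(k): float(v) for k, v in dict(d["game_effect"]).items()}
    return GroundTruthParams(**d)
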