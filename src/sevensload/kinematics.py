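"""Zone kinematics for 10 Hz GNSS speed traces.

A worn GNSS unit reports speed at 10 Hz. This module turns one player-match
speed series into acceleration (first difference of speed), per-sample
speed-zone / acceleration-type labels, distances accumulated in the twelve
resulting zones, and on-field playing time. Three comparator summaries used
elsewhere in the sports-science literature (absolute-value acceleration
distance, acceleration/deceleration ratio, four speed-agnostic bins) are
provided for methodological comparison.

Conventions
-----------
Speed zones (half-open, lower-inclusive):

* ``LS`` walking, ``[0, 1.5)`` m/s
* ``MS`` running, ``[1.5, sprint_entry)`` m/s
* ``HS`` sprinting, ``[sprint_entry, inf)`` m/s, with the sprint-entry
  threshold individualized per athlete from a 0-10 m sprint split.

Acceleration types at the +/-2 m/s^2 threshold (inclusive on the
low-magnitude side; ``a = 0`` counts as mild deceleration, so distance
covered at constant speed accrues to ``LD``):

* ``HA`` hard acceleration, ``a > 2``
* ``LA`` mild acceleration, ``0 < a <= 2``
* ``LD`` mild deceleration, ``-2 <= a <= 0``
* ``HD`` hard deceleration, ``a < -2``
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import SchemaError, ThresholdUnusableError

SPEED_ZONES = ("LS", "MS", "HS")
ACCEL_TYPES = ("LA", "HA", "LD", "HD")
#: Cell order follows the descriptive table layout: speed-major, then LA, HA, LD, HD.
ZONE_CELLS = tuple(f"{s}_{a}" for s in SPEED_ZONES for a in ACCEL_TYPES)

WALK_UPPER_MPS = 1.5
ACCEL_THRESHOLD_MPS2 = 2.0

PERIODS = ("H1", "HT", "H2")

_TRACE_COLUMNS = ["time_s", "speed_mps", "on_field", "period"]


@dataclass(frozen=True)
class ZoneThresholds:
    """Boundaries of the 12-zone grid for one athlete."""

    sprint_entry_mps: float
    walk_upper_mps: float = WALK_UPPER_MPS
    accel_threshold_mps2: float = ACCEL_THRESHOLD_MPS2

    def __post_init__(self):
        if not 0 < self.walk_upper_mps < self.sprint_entry_mps:
            raise ValueError(
                "thresholds must satisfy 0 < walk_upper < sprint_entry, got "
                f"walk_upper={self.walk_upper_mps}, sprint_entry={self.sprint_entry_mps}"
            )
        if self.accel_threshold_mps2 <= 0:
            raise ValueError("accel_threshold_mps2 must be positive")


@dataclass
class SpeedTrace:
    """One player-match 10 Hz speed series with on-field/period annotation."""

    athlete_id: str
    match_id: str
    time_s: np.ndarray
    speed_mps: np.ndarray
    on_field: np.ndarray
    period: np.ndarray
    sample_rate_hz: float = 10.0

    def __post_init__(self):
        self.time_s = np.asarray(self.time_s, dtype=float)
        self.speed_mps = np.asarray(self.speed_mps, dtype=float)
        self.on_field = np.asarray(self.on_field, dtype=bool)
        self.period = np.asarray(self.period, dtype=object)
        n = len(self.time_s)
        if not (len(self.speed_mps) == len(self.on_field) == len(self.period) == n):
            raise ValueError("all per-sample sequences must have equal length")
        if n == 0:
            raise ValueError("trace must contain at least one sample")
        if np.any(self.speed_mps < 0):
            raise ValueError("speeds must be non-negative")
        dt = np.diff(self.time_s)
        if n > 1 and not np.allclose(dt, 1.0 / self.sample_rate_hz, rtol=0.0, atol=1e-9):
            raise ValueError(
                "time must be strictly increasing with spacing "
                f"{1.0 / self.sample_rate_hz} s (tolerance 1e-9 s)"
            )
        unknown = set(self.period) - set(PERIODS)
        if unknown:
            raise ValueError(f"unknown period labels: {sorted(unknown)}")

    def __len__(self) -> int:
        return len(self.time_s)

    @property
    def dt_s(self) -> float:
        return 1.0 / self.sample_rate_hz

    def play_mask(self) -> np.ndarray:
        """Samples that count toward zones and playing time (on field, not halftime)."""
        return self.on_field & (self.period != "HT")

    def playing_time_min(self) -> float:
        return float(self.play_mask().sum()) / (60.0 * self.sample_rate_hz)

    # -- CSV dialect -------------------------------------------------------
    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time_s": self.time_s,
                "speed_mps": self.speed_mps,
                "on_field": self.on_field.astype(int),
                "period": self.period,
            }
        )

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False, float_format="%.4f")

    @classmethod
    def from_frame(
        cls,
        frame: pd.DataFrame,
        athlete_id: str,
        match_id: str,
        sample_rate_hz: float = 10.0,
        column_map: dict[str, str] | None = None,
    ) -> "SpeedTrace":
        """Build a trace from a table; ``column_map`` renames foreign dialects."""
        if column_map:
            frame = frame.rename(columns=column_map)
        missing = [c for c in _TRACE_COLUMNS if c not in frame.columns]
        if missing:
            raise SchemaError(f"trace table missing columns: {missing}")
        return cls(
            athlete_id=athlete_id,
            match_id=match_id,
            time_s=frame["time_s"].to_numpy(dtype=float),
            speed_mps=frame["speed_mps"].to_numpy(dtype=float),
            on_field=frame["on_field"].to_numpy().astype(bool),
            period=frame["period"].to_numpy(dtype=object),
            sample_rate_hz=sample_rate_hz,
        )

    @classmethod
    def from_csv(
        cls,
        path: str | Path,
        athlete_id: str,
        match_id: str,
        sample_rate_hz: float = 10.0,
        column_map: dict[str, str] | None = None,
    ) -> "SpeedTrace":
        return cls.from_frame(
            pd.read_csv(path), athlete_id, match_id, sample_rate_hz, column_map
        )


@dataclass
class ZoneDistances:
    """The 12-cell distance summary plus totals for one player-match."""

    cells: dict[str, float]
    total_m: float
    playing_time_min: float

    def __post_init__(self):
        missing = [c for c in ZONE_CELLS if c not in self.cells]
        if missing:
            raise ValueError(f"missing zone cells: {missing}")
        if any(v < 0 for v in self.cells.values()):
            raise ValueError("zone distances must be non-negative")
        if self.playing_time_min < 0:
            raise ValueError("playing time must be non-negative")
        if abs(sum(self.cells.values()) - self.total_m) > 1e-6:
            raise ValueError("zone cells must sum to total_m (tolerance 1e-6 m)")

    def as_series(self) -> pd.Series:
        out = {c: self.cells[c] for c in ZONE_CELLS}
        out["total_m"] = self.total_m
        out["playing_time_min"] = self.playing_time_min
        return pd.Series(out)


def sprint_threshold_from_split(split_distance_m: float, split_time_s: float) -> float:
    """Sprint-entry threshold from the opening split of a maximal sprint.

    The threshold is the mean velocity over the split (distance / time); it
    must exceed the 1.5 m/s walk/run boundary to be usable as a zone boundary.
    """
    if split_distance_m <= 0 or split_time_s <= 0:
        raise ValueError("split distance and time must both be positive")
    v = split_distance_m / split_time_s
    if v <= WALK_UPPER_MPS:
        raise ThresholdUnusableError(
            f"split velocity {v:.3f} m/s does not exceed the walk/run boundary "
            f"({WALK_UPPER_MPS} m/s)"
        )
    return v


def compute_acceleration(trace: SpeedTrace, smoothing_window: int = 1) -> np.ndarray:
    """Acceleration as the backward first difference of speed.

    ``a[t] = (v[t] - v[t-1]) * sample_rate`` for ``t >= 1`` and ``a[0] = 0``
    (the first sample has no predecessor). With ``smoothing_window > 1``
    (odd), speed is first smoothed by a centred moving average with edge
    truncation; the default applies no smoothing.
    """
    if smoothing_window < 1 or smoothing_window % 2 == 0:
        raise ValueError("smoothing_window must be odd and >= 1")
    v = trace.speed_mps
    if smoothing_window > 1:
        half = smoothing_window // 2
        csum = np.cumsum(np.concatenate(([0.0], v)))
        n = len(v)
        idx = np.arange(n)
        lo = np.maximum(idx - half, 0)
        hi = np.minimum(idx + half, n - 1)
        v = (csum[hi + 1] - csum[lo]) / (hi - lo + 1)
    accel = np.empty_like(v)
    accel[0] = 0.0
    accel[1:] = np.diff(v) * trace.sample_rate_hz
    return accel


def assign_zone(
    speed_mps: float, accel_mps2: float, thresholds: ZoneThresholds
) -> tuple[str, str]:
    """Label a single (speed, acceleration) sample; total and single-valued."""
    if speed_mps < 0:
        raise ValueError("speed must be non-negative")
    if speed_mps < thresholds.walk_upper_mps:
        speed_zone = "LS"
    elif speed_mps < thresholds.sprint_entry_mps:
        speed_zone = "MS"
    else:
        speed_zone = "HS"
    thr = thresholds.accel_threshold_mps2
    if accel_mps2 > thr:
        accel_type = "HA"
    elif accel_mps2 > 0:
        accel_type = "LA"
    elif accel_mps2 >= -thr:
        accel_type = "LD"
    else:
        accel_type = "HD"
    return speed_zone, accel_type


def _zone_codes(
    speed: np.ndarray, accel: np.ndarray, thresholds: ZoneThresholds
) -> np.ndarray:
    """Vectorized zone labels as integer codes ``4*speed_zone + accel_type``.

    Index order matches :data:`ZONE_CELLS`.
    """
    sz = np.where(
        speed < thresholds.walk_upper_mps,
        0,
        np.where(speed < thresholds.sprint_entry_mps, 1, 2),
    )
    thr = thresholds.accel_threshold_mps2
    at = np.where(accel > thr, 1, np.where(accel > 0, 0, np.where(accel >= -thr, 2, 3)))
    return sz * 4 + at


def accumulate_zone_distances(
    trace: SpeedTrace,
    accel: np.ndarray,
    thresholds: ZoneThresholds,
    include_halftime: bool = False,
) -> ZoneDistances:
    """Integrate per-sample distance ``v * dt`` into the 12 zone cells.

    Only on-field samples outside halftime contribute (halftime is treated as
    non-play even though players remain on the field; set
    ``include_halftime=True`` to count it). Playing time is the count of
    contributing samples divided by the sample rate.
    """
    accel = np.asarray(accel, dtype=float)
    if len(accel) != len(trace):
        raise ValueError(
            f"acceleration length {len(accel)} does not match trace length {len(trace)}"
        )
    if include_halftime:
        mask = trace.on_field
    else:
        mask = trace.play_mask()
    v = trace.speed_mps[mask]
    a = accel[mask]
    codes = _zone_codes(v, a, thresholds)
    dist = np.bincount(codes, weights=v * trace.dt_s, minlength=12)
    cells = {cell: float(dist[i]) for i, cell in enumerate(ZONE_CELLS)}
    return ZoneDistances(
        cells=cells,
        total_m=float(dist.sum()),
        playing_time_min=float(mask.sum()) / (60.0 * trace.sample_rate_hz),
    )


def comparator_summaries(
    trace: SpeedTrace, accel: np.ndarray, thresholds: ZoneThresholds
) -> dict[str, object]:
    """Alternative acceleration-processing summaries from the literature.

    Returns a mapping with three strategies computed over the same on-field,
    non-halftime samples as the 12-zone grid:

    * ``"absolute_total_m"`` -- distance covered while ``|a|`` exceeds the
      threshold, treating accelerations and decelerations alike.
    * ``"accel_decel_ratio"`` -- supra-threshold acceleration distance divided
      by supra-threshold deceleration distance; ``None`` with
      ``"ratio_defined" = False`` when no deceleration distance exists.
    * ``"four_bins_m"`` -- the four acceleration-type distances without a
      speed split (the speed-marginalized rows of the 12-cell grid).
    """
    accel = np.asarray(accel, dtype=float)
    if len(accel) != len(trace):
        raise ValueError("acceleration series does not align with trace")
    mask = trace.play_mask()
    v = trace.speed_mps[mask]
    a = accel[mask]
    dt = trace.dt_s
    thr = thresholds.accel_threshold_mps2

    absolute_total = float(np.sum(v[np.abs(a) > thr]) * dt)
    accel_dist = float(np.sum(v[a > thr]) * dt)
    decel_dist = float(np.sum(v[a < -thr]) * dt)
    if decel_dist > 0.0:
        ratio, defined = accel_dist / decel_dist, True
    else:
        ratio, defined = None, False

    codes = _zone_codes(v, a, thresholds) % 4
    bins = np.bincount(codes, weights=v * dt, minlength=4)
    four_bins = {at: float(bins[i]) for i, at in enumerate(ACCEL_TYPES)}

    return {
        "absolute_total_m": absolute_total,
        "accel_decel_ratio": ratio,
        "ratio_defined": defined,
        "four_bins_m": four_bins,
    }
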