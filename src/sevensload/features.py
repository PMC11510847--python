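"""Fusing kinematic summaries, contacts, mass and RPE into analysis records.

The analysis row is one fielded player in one match: the twelve zone
distances with totals and playing time, the athlete's mass, the match
contact count, the game number within the tournament, the reported RPE and
the derived session RPE (sRPE = RPE x playing time in minutes). Missing RPE
reports propagate to missing sRPE and are removed by listwise deletion
before modelling; no imputation is attempted.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import (
    DuplicateRecordError,
    EmptyDatasetError,
    JoinKeyError,
    SchemaError,
)
from .kinematics import ZONE_CELLS

logger = logging.getLogger(__name__)

KEY_COLUMNS = ["athlete_id", "match_id"]
META_COLUMNS = ["tournament_id", "game_number"]
#: Columns the workload model needs; rows missing any of them are dropped.
MODEL_COLUMNS = (
    ["mass_kg", "contacts", "playing_time_min"]
    + list(ZONE_CELLS)
    + ["total_m", "rpe_au", "srpe_au"]
)
RECORD_COLUMNS = KEY_COLUMNS + META_COLUMNS + MODEL_COLUMNS

#: Data dictionary for the records CSV, shipped alongside written files.
DATA_DICTIONARY = {
    "athlete_id": "opaque athlete identifier, unique within the roster",
    "match_id": "opaque match identifier, unique within the study",
    "tournament_id": "tournament the match belongs to",
    "game_number": "game number within the tournament, 1-6",
    "mass_kg": "athlete body mass, kilograms",
    "contacts": "summed count of contact events in the match",
    "playing_time_min": "on-field, non-halftime playing time, minutes",
    **{
        cell: f"distance in the {cell.split('_')[0]} speed zone / "
        f"{cell.split('_')[1]} acceleration type, metres"
        for cell in ZONE_CELLS
    },
    "total_m": "total on-field distance (sum of the 12 zone cells), metres",
    "rpe_au": "self-reported rating of perceived exertion, 0-10 (may be missing)",
    "srpe_au": "session RPE = rpe_au x playing_time_min, arbitrary units",
}


@dataclass
class StudyDataset:
    """Player-match records plus provenance of how they were produced."""

    records: pd.DataFrame
    provenance: dict = field(default_factory=dict)
    roster: list = field(default_factory=list)

    def __post_init__(self):
        missing = [c for c in RECORD_COLUMNS if c not in self.records.columns]
        if missing:
            raise SchemaError(f"records missing columns: {missing}")
        dup = self.records.duplicated(subset=KEY_COLUMNS)
        if dup.any():
            pairs = self.records.loc[dup, KEY_COLUMNS].to_records(index=False)
            raise DuplicateRecordError(
                f"duplicate (athlete, match) pairs: {list(pairs)[:5]}"
            )

    def __len__(self) -> int:
        return len(self.records)

    def to_csv(self, path: str | Path, with_dictionary: bool = True) -> None:
        path = Path(path)
        self.records.to_csv(path, index=False)
        if with_dictionary:
            dict_path = path.with_name(path.stem + "_dictionary.csv")
            pd.DataFrame(
                {"column": list(DATA_DICTIONARY), "description": list(DATA_DICTIONARY.values())}
            ).to_csv(dict_path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path, provenance: dict | None = None) -> "StudyDataset":
        return cls(records=pd.read_csv(path), provenance=provenance or {})


def compute_srpe(rpe_au: float, playing_time_min: float) -> float:
    """Session RPE: the product of reported effort and playing time."""
    if not 0 <= rpe_au <= 10:
        raise ValueError(f"rpe must be on the 0-10 scale, got {rpe_au}")
    if playing_time_min < 0:
        raise ValueError("playing time must be non-negative")
    return float(rpe_au) * float(playing_time_min)


def design_features(record: pd.Series | pd.DataFrame):
    """Acceleration-type sums and accel x speed interaction distances.

    Maps the 12 record cells (speed-major names like ``MS_LD``) onto the
    model's terms: per-type totals over all three speed zones (``HA_total``,
    ``LD_total``, ``HD_total``; LA is the reference type, absorbed in total
    distance) and the low/high-speed cells of each non-reference type
    (``LD_LS`` etc.; MS is the reference speed zone).
    """
    get = record.__getitem__
    out = {
        "HA_total": get("LS_HA") + get("MS_HA") + get("HS_HA"),
        "LD_total": get("LS_LD") + get("MS_LD") + get("HS_LD"),
        "HD_total": get("LS_HD") + get("MS_HD") + get("HS_HD"),
        "HA_LS": get("LS_HA"),
        "HA_HS": get("HS_HA"),
        "LD_LS": get("LS_LD"),
        "LD_HS": get("HS_LD"),
        "HD_LS": get("LS_HD"),
        "HD_HS": get("HS_HD"),
    }
    if isinstance(record, pd.DataFrame):
        return pd.DataFrame(out)
    return pd.Series(out)


def build_records(
    zone_summaries: pd.DataFrame,
    contacts: pd.DataFrame,
    roster: pd.DataFrame,
    rpe_reports: pd.DataFrame,
    match_meta: pd.DataFrame,
    validate_rpe_scale: bool = True,
) -> StudyDataset:
    """Join all sources into one record per (athlete, match).

    sRPE is computed wherever the RPE report is present; a missing report
    yields a missing sRPE. Athletes appearing in summaries but not in the
    roster raise a :class:`JoinKeyError` naming the offending key, and
    duplicated (athlete, match) pairs raise :class:`DuplicateRecordError`.
    """
    for name, frame, cols in [
        ("zone_summaries", zone_summaries, KEY_COLUMNS + list(ZONE_CELLS)),
        ("contacts", contacts, KEY_COLUMNS + ["contacts"]),
        ("roster", roster, ["athlete_id", "mass_kg"]),
        ("rpe_reports", rpe_reports, KEY_COLUMNS + ["rpe_au"]),
        ("match_meta", match_meta, ["match_id", "tournament_id", "game_number"]),
    ]:
        missing = [c for c in cols if c not in frame.columns]
        if missing:
            raise SchemaError(f"{name} missing columns: {missing}")

    if zone_summaries.duplicated(subset=KEY_COLUMNS).any():
        dup = zone_summaries[zone_summaries.duplicated(subset=KEY_COLUMNS)]
        raise DuplicateRecordError(
            f"duplicate (athlete, match) in zone summaries: "
            f"{dup[KEY_COLUMNS].iloc[0].tolist()}"
        )

    unknown = set(zone_summaries["athlete_id"]) - set(roster["athlete_id"])
    if unknown:
        raise JoinKeyError(f"athletes missing from roster: {sorted(unknown)}")
    unknown_m = set(zone_summaries["match_id"]) - set(match_meta["match_id"])
    if unknown_m:
        raise JoinKeyError(f"matches missing from match metadata: {sorted(unknown_m)}")

    df = zone_summaries.merge(
        roster[["athlete_id", "mass_kg"]], on="athlete_id", how="left"
    )
    df = df.merge(contacts[KEY_COLUMNS + ["contacts"]], on=KEY_COLUMNS, how="left")
    df = df.merge(rpe_reports[KEY_COLUMNS + ["rpe_au"]], on=KEY_COLUMNS, how="left")
    df = df.merge(
        match_meta[["match_id", "tournament_id", "game_number"]],
        on="match_id",
        how="left",
    )

    rpe = df["rpe_au"]
    if validate_rpe_scale:
        bad = rpe.dropna()[(rpe.dropna() < 0) | (rpe.dropna() > 10)]
        if len(bad):
            raise ValueError(f"RPE outside the 0-10 scale: {bad.iloc[0]}")
    df["srpe_au"] = rpe * df["playing_time_min"]
    df = df[RECORD_COLUMNS]
    return StudyDataset(records=df.reset_index(drop=True))


def drop_incomplete(dataset: StudyDataset) -> StudyDataset:
    """Listwise deletion: keep only records with every model variable present.

    Logs the count dropped per field; raises :class:`EmptyDatasetError` if
    nothing survives (the model cannot be fitted). Idempotent.
    """
    df = dataset.records
    present = df[MODEL_COLUMNS].notna()
    for col in MODEL_COLUMNS:
        n_missing = int((~present[col]).sum())
        if n_missing:
            logger.info("drop_incomplete: %d records missing %s", n_missing, col)
    keep = present.all(axis=1)
    out = df[keep].reset_index(drop=True)
    logger.info("drop_incomplete: %d of %d records retained", len(out), len(df))
    if len(out) == 0:
        raise EmptyDatasetError("no complete records remain after listwise deletion")
    return StudyDataset(
        records=out,
        provenance={**dataset.provenance, "complete_records": len(out)},
        roster=dataset.roster,
    )
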