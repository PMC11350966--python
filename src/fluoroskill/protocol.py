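"""Study task structure and record plumbing.

A complete assessment is 2 sessions x 3 repetitions; each repetition is
one full fluoroscopic control of the plated wrist, ending with exactly 5
transferred images -- one per standard view (PA, AP, LAT, FACET, TANG).
Participants may take any number of images per view; only the last saved
image of each view survives the transfer step (unsaved images are
discarded as soon as a new one is made).  The simulator also logs the
total image count and the task time for every repetition.

Records flow to and from a long-format CSV (one row per transferred
image) that feeds the scoring and validity modules directly.
"""

from __future__ import annotations

import io
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .kinematics import (
    AngleRecord,
    ArticulationState,
    CArmGeometry,
    ForearmPhantom,
    JOINT_LIMITS,
    nominal_state,
    recorded_angles,
)

__all__ = [
    "VIEWS",
    "ViewSpec",
    "RepetitionRecord",
    "ParticipantRecord",
    "run_repetition",
    "transfer_images",
    "read_records",
    "write_records",
    "records_to_frame",
    "IncompleteRepetitionError",
    "SchemaError",
]

GROUPS = ("novice", "experienced")

N_SESSIONS = 2
N_REPETITIONS = 3
N_TOTAL_REPS = N_SESSIONS * N_REPETITIONS


@dataclass(frozen=True)
class ViewSpec:
    view_id: str
    angle_names: tuple


#: The five standard wrist projections; the dorsal tangential view is the
#: only one that additionally records the wrist angle.
VIEWS = (
    ViewSpec("PA", ("elbow", "rotation")),
    ViewSpec("AP", ("elbow", "rotation")),
    ViewSpec("LAT", ("elbow", "rotation")),
    ViewSpec("FACET", ("elbow", "rotation")),
    ViewSpec("TANG", ("elbow", "rotation", "wrist")),
)

VIEW_ORDER = tuple(v.view_id for v in VIEWS)
VIEW_BY_ID = {v.view_id: v for v in VIEWS}


class IncompleteRepetitionError(ValueError):
    """Raised when the saved-image pool lacks one or more required views."""


class SchemaError(ValueError):
    """Raised when a CSV file violates the record schema."""


@dataclass(frozen=True)
class RepetitionRecord:
    participant_id: str
    session: int
    repetition: int
    images: dict  # view_id -> AngleRecord, exactly one per view
    n_images_total: int
    time_s: float

    def __post_init__(self):
        if self.session not in (1, 2):
            raise ValueError(f"session must be 1 or 2, got {self.session}")
        if self.repetition not in (1, 2, 3):
            raise ValueError(f"repetition must be 1..3, got {self.repetition}")
        missing = [v for v in VIEW_ORDER if v not in self.images]
        if missing:
            raise IncompleteRepetitionError(
                f"missing transferred views: {', '.join(missing)}"
            )
        extra = set(self.images) - set(VIEW_ORDER)
        if extra:
            raise ValueError(f"unknown views: {sorted(extra)}")
        for vid, rec in self.images.items():
            want_wrist = vid == "TANG"
            if (rec.wrist_angle_deg is not None) != want_wrist:
                raise ValueError(
                    f"view {vid}: wrist angle must be "
                    f"{'present' if want_wrist else 'absent'}"
                )
        if self.n_images_total < len(VIEW_ORDER):
            raise ValueError("n_images_total cannot be below 5")
        if not (self.time_s > 0):
            raise ValueError("time_s must be positive")


@dataclass(frozen=True)
class ParticipantRecord:
    participant_id: str
    group: str
    repetitions: tuple

    def __post_init__(self):
        if self.group not in GROUPS:
            raise ValueError(f"group must be one of {GROUPS}, got {self.group!r}")
        object.__setattr__(self, "repetitions", tuple(self.repetitions))
        keys = [(r.session, r.repetition) for r in self.repetitions]
        if len(keys) != len(set(keys)):
            raise ValueError("duplicate (session, repetition) pair")

    @property
    def complete(self) -> bool:
        return len(self.repetitions) == N_TOTAL_REPS


def transfer_images(saved_pool) -> dict:
    """Reduce the saved-image pool to the 5 transferred records.

    ``saved_pool`` is a sequence of ``(view_id, AngleRecord)`` in save
    order; the last saved image per view wins.  Raises
    ``IncompleteRepetitionError`` naming any missing view.
    """
    if not saved_pool:
        raise IncompleteRepetitionError("saved-image pool is empty")
    out: dict = {}
    for vid, rec in saved_pool:
        if vid not in VIEW_BY_ID:
            raise ValueError(f"unknown view {vid!r}")
        out[vid] = rec
    missing = [v for v in VIEW_ORDER if v not in out]
    if missing:
        raise IncompleteRepetitionError(
            f"missing transferred views: {', '.join(missing)}"
        )
    return {v: out[v] for v in VIEW_ORDER}


def _clamp_state(elbow, rotation, wrist) -> ArticulationState:
    lo, hi = JOINT_LIMITS["elbow_flexion_deg"]
    e = float(np.clip(elbow, lo, hi))
    lo, hi = JOINT_LIMITS["forearm_rotation_deg"]
    r = float(np.clip(rotation, lo, hi))
    lo, hi = JOINT_LIMITS["wrist_flexion_deg"]
    w = float(np.clip(wrist, lo, hi))
    return ArticulationState(e, r, w)


def run_repetition(
    profile,
    phantom: ForearmPhantom,
    carm: CArmGeometry,
    rng: np.random.Generator,
    participant_id: str = "p0",
    session: int = 1,
    repetition: int = 1,
    participant: dict | None = None,
) -> RepetitionRecord:
    """Simulate one complete repetition under a behaviour profile.

    For every view at least one image is attempted; each attempt aims at
    the view's nominal configuration with the profile's error model, the
    achieved state is clamped to the joint limits, and the last saved
    image is the one transferred.  Image count and task time come from
    the profile's retake and time models.  ``participant`` carries the
    stable participant effects (``profile.sample_participant``); when
    omitted, a fresh participant is drawn.
    """
    for spec in VIEWS:
        if spec.view_id not in profile.angle_params_by_view():
            raise ValueError(f"behavior profile missing view {spec.view_id}")
    if participant is None:
        participant = profile.sample_participant(rng)
    pool = []
    n_total = 0
    rep_shock = rng.standard_normal()
    for spec in VIEWS:
        n_attempts = 1 + profile.sample_extra_images(rng, participant)
        n_total += n_attempts
        nom = nominal_state(spec.view_id)
        err = None
        for _ in range(n_attempts):
            err = profile.sample_angle_errors(
                spec.view_id, rng, rep_shock, participant, session
            )
        # only the last saved image survives the transfer step, so only
        # its achieved state needs converting to recorded angles
        state = _clamp_state(
            nom.elbow_flexion_deg + err["elbow"],
            nom.forearm_rotation_deg + err["rotation"],
            nom.wrist_flexion_deg + err.get("wrist", 0.0),
        )
        pool.append((spec.view_id, recorded_angles(state, carm, spec.view_id)))
    time_s = profile.sample_time(rng, participant)
    return RepetitionRecord(
        participant_id,
        session,
        repetition,
        transfer_images(pool),
        n_total,
        time_s,
    )


# ---------------------------------------------------------------------------
# CSV IO

CSV_COLUMNS = [
    "participant_id",
    "group",
    "session",
    "repetition",
    "view",
    "elbow_deg",
    "rotation_deg",
    "wrist_deg",
    "n_images_total",
    "time_s",
]


def records_to_frame(records) -> pd.DataFrame:
    """Long-format table: one row per transferred image."""
    rows = []
    for part in records:
        for rep in part.repetitions:
            for vid in VIEW_ORDER:
                rec = rep.images[vid]
                rows.append(
                    {
                        "participant_id": part.participant_id,
                        "group": part.group,
                        "session": rep.session,
                        "repetition": rep.repetition,
                        "view": vid,
                        "elbow_deg": rec.elbow_flexion_deg,
                        "rotation_deg": rec.forearm_rotation_deg,
                        "wrist_deg": rec.wrist_angle_deg,
                        "n_images_total": rep.n_images_total,
                        "time_s": rep.time_s,
                    }
                )
    return pd.DataFrame(rows, columns=CSV_COLUMNS)


def write_records(records, path) -> None:
    """Write the record hierarchy as UTF-8 CSV (header, '.' decimal)."""
    records_to_frame(records).to_csv(path, index=False, float_format="%.10g")


def _schema_fail(row, msg):
    raise SchemaError(f"row {row}: {msg}")


def read_records(path) -> list:
    """Read records back from CSV; schema violations name the row."""
    if isinstance(path, (str, Path)):
        df = pd.read_csv(path)
    else:
        df = pd.read_csv(io.StringIO(path.read()))
    missing_cols = set(CSV_COLUMNS) - set(df.columns)
    if missing_cols:
        raise SchemaError(f"missing columns: {sorted(missing_cols)}")

    for idx, row in df.iterrows():
        rownum = int(idx) + 2  # header is line 1
        if row["group"] not in GROUPS:
            _schema_fail(rownum, f"bad group {row['group']!r}")
        if int(row["session"]) not in (1, 2):
            _schema_fail(rownum, f"bad session {row['session']!r}")
        if int(row["repetition"]) not in (1, 2, 3):
            _schema_fail(rownum, f"bad repetition {row['repetition']!r}")
        if row["view"] not in VIEW_BY_ID:
            _schema_fail(rownum, f"bad view {row['view']!r}")
        has_wrist = not pd.isna(row["wrist_deg"])
        if has_wrist != (row["view"] == "TANG"):
            _schema_fail(rownum, "wrist_deg present iff view is TANG")
        for col in ("elbow_deg", "rotation_deg", "n_images_total", "time_s"):
            if pd.isna(row[col]) or not math.isfinite(float(row[col])):
                _schema_fail(rownum, f"non-finite {col}")

    participants = []
    for pid, pgrp in df.groupby("participant_id", sort=False):
        groups = pgrp["group"].unique()
        if len(groups) != 1:
            raise SchemaError(f"participant {pid!r} has inconsistent group labels")
        reps = []
        for (sess, rep), sub in pgrp.groupby(["session", "repetition"], sort=True):
            images = {}
            for _, row in sub.iterrows():
                wrist = None if pd.isna(row["wrist_deg"]) else float(row["wrist_deg"])
                images[row["view"]] = AngleRecord(
                    float(row["elbow_deg"]), float(row["rotation_deg"]), wrist
                )
            reps.append(
                RepetitionRecord(
                    str(pid),
                    int(sess),
                    int(rep),
                    images,
                    int(sub["n_images_total"].iloc[0]),
                    float(sub["time_s"].iloc[0]),
                )
            )
        participants.append(ParticipantRecord(str(pid), groups[0], tuple(reps)))
    return participants
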