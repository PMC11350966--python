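"""Expert-referenced proficiency scoring.

The scoring chain mirrors how the simulator test quantifies aiming
accuracy:

1.  Every recorded angle of every transferred image is converted to an
    absolute z-score ``|x - m| / s`` where ``m`` and ``s`` are the mean
    and SD of the experienced cohort for that (view, angle), pooled over
    all repetitions of both sessions.
2.  A per-image total z-score sums the angular z-scores of that image
    (two angles per view; three for the tangential view).
3.  A composite score per repetition sums the total z-scores of the
    discriminating views (chosen upstream by the validity analysis).
4.  A participant-level mean composite averages the 6 repetition
    composites; participants with fewer than 6 repetitions are excluded
    listwise and never receive a partial mean.

Lower scores mean better performance throughout.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .protocol import (
    N_TOTAL_REPS,
    VIEW_BY_ID,
    VIEW_ORDER,
    records_to_frame,
)

__all__ = [
    "ReferenceStats",
    "fit_reference",
    "absolute_z",
    "total_image_z",
    "composite",
    "mean_composite",
    "score_records",
    "participant_mean_composites",
    "DegenerateReferenceError",
    "EXCLUDED",
]

#: Marker returned for participants removed by listwise exclusion.
EXCLUDED = None


class DegenerateReferenceError(ValueError):
    """Reference cohort has zero variance for at least one angle."""


_ANGLE_COLS = {"elbow": "elbow_deg", "rotation": "rotation_deg", "wrist": "wrist_deg"}


@dataclass(frozen=True)
class ReferenceStats:
    """Per-(view, angle) mean/SD of the experienced cohort."""

    stats: dict  # (view_id, angle_name) -> (mean, sd)
    n_images: int

    def mean_sd(self, view_id: str, angle: str):
        return self.stats[(view_id, angle)]

    def to_json(self) -> str:
        return json.dumps(
            {
                f"{v}:{a}": {"mean": m, "sd": s, "n_images": self.n_images}
                for (v, a), (m, s) in self.stats.items()
            },
            indent=2,
        )

    @classmethod
    def from_json(cls, text: str) -> "ReferenceStats":
        raw = json.loads(text)
        stats = {}
        n = 0
        for key, d in raw.items():
            v, a = key.split(":")
            stats[(v, a)] = (float(d["mean"]), float(d["sd"]))
            n = int(d.get("n_images", 0))
        return cls(stats, n)


def fit_reference(experienced_records) -> ReferenceStats:
    """Pooled per-angle moments of the experienced cohort.

    Pools every transferred image across all repetitions of both
    sessions.  Requires at least 2 experienced participants and non-zero
    variance for every angle (sample SD, ddof=1).
    """
    records = [r for r in experienced_records if r.group == "experienced"]
    if len(records) < 2:
        raise ValueError("need at least 2 experienced participants for a reference")
    df = records_to_frame(records)
    stats = {}
    for spec in VIEW_BY_ID.values():
        sub = df[df["view"] == spec.view_id]
        for angle in spec.angle_names:
            x = sub[_ANGLE_COLS[angle]].to_numpy(dtype=float)
            if x.size < 2:
                raise ValueError(
                    f"too few reference images for {spec.view_id}:{angle}"
                )
            m = float(np.mean(x))
            s = float(np.std(x, ddof=1))
            if s <= 0:
                raise DegenerateReferenceError(
                    f"zero variance in reference for {spec.view_id}:{angle}"
                )
            stats[(spec.view_id, angle)] = (m, s)
    return ReferenceStats(stats, int(len(df)))


def absolute_z(x: float, ref_mean: float, ref_sd: float) -> float:
    """Absolute z-score |x - mean| / sd (non-negative)."""
    if not math.isfinite(float(x)):
        raise ValueError("angle must be finite")
    if not ref_sd > 0:
        raise ValueError("reference SD must be positive")
    return abs(float(x) - ref_mean) / ref_sd


def total_image_z(angle_zs, view_id: str | None = None) -> float:
    """Per-image total z-score: sum of the angular absolute z-scores."""
    zs = [float(z) for z in angle_zs]
    if any(z < 0 for z in zs):
        raise ValueError("absolute z-scores cannot be negative")
    if view_id is not None:
        want = len(VIEW_BY_ID[view_id].angle_names)
        if len(zs) != want:
            raise ValueError(f"view {view_id} expects {want} angle z-scores, got {len(zs)}")
    elif len(zs) not in (2, 3):
        raise ValueError("a view carries 2 or 3 angle z-scores")
    return float(sum(zs))


def composite(view_totals: dict, selected_views) -> float:
    """Composite score: sum of total z-scores over the selected views."""
    selected = list(selected_views)
    unknown = [v for v in selected if v not in VIEW_ORDER]
    if unknown:
        raise ValueError(f"unknown views {unknown}")
    missing = [v for v in selected if v not in view_totals]
    if missing:
        raise ValueError(f"missing totals for views {missing}")
    return float(sum(float(view_totals[v]) for v in selected))


def mean_composite(repetition_composites):
    """Participant mean composite over exactly 6 repetitions.

    Returns ``EXCLUDED`` (None) when fewer than 6 repetition composites
    are available -- the listwise rule never produces a partial mean.
    """
    vals = [float(c) for c in repetition_composites]
    if len(vals) != N_TOTAL_REPS:
        return EXCLUDED
    return float(np.mean(vals))


def score_records(
    records, reference: ReferenceStats, selected_views=None
) -> pd.DataFrame:
    """Score a cohort into the per-repetition table.

    One row per (participant, session, repetition) with columns
    ``z_PA .. z_TANG`` (per-view total z-scores), ``n_images_total``,
    ``time_s`` and -- when ``selected_views`` is given -- ``composite``.
    """
    df = records_to_frame(records)
    rows = []
    key_cols = ["participant_id", "group", "session", "repetition"]
    for key, sub in df.groupby(key_cols, sort=False):
        row = dict(zip(key_cols, key))
        for spec in VIEW_BY_ID.values():
            img = sub[sub["view"] == spec.view_id]
            if len(img) != 1:
                raise ValueError(
                    f"expected exactly one {spec.view_id} image per repetition"
                )
            img = img.iloc[0]
            zs = []
            for angle in spec.angle_names:
                m, s = reference.mean_sd(spec.view_id, angle)
                zs.append(absolute_z(float(img[_ANGLE_COLS[angle]]), m, s))
            row[f"z_{spec.view_id}"] = total_image_z(zs, spec.view_id)
        row["n_images_total"] = float(sub["n_images_total"].iloc[0])
        row["time_s"] = float(sub["time_s"].iloc[0])
        rows.append(row)
    table = pd.DataFrame(rows)
    if selected_views is not None:
        table["composite"] = [
            composite(
                {v: r[f"z_{v}"] for v in VIEW_ORDER}, selected_views
            )
            for r in rows
        ]
    return table


def participant_mean_composites(score_table: pd.DataFrame) -> pd.DataFrame:
    """Participant-level mean composites with listwise exclusion.

    Returns one row per participant with columns participant_id, group,
    mean_composite (NaN for excluded participants) and excluded flag.
    """
    if "composite" not in score_table.columns:
        raise ValueError("score table has no composite column; pass selected_views")
    out = []
    for (pid, grp), sub in score_table.groupby(
        ["participant_id", "group"], sort=False
    ):
        mc = mean_composite(sub["composite"].tolist())
        out.append(
            {
                "participant_id": pid,
                "group": grp,
                "mean_composite": np.nan if mc is EXCLUDED else mc,
                "excluded": mc is EXCLUDED,
            }
        )
    return pd.DataFrame(out)
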