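"""CSV schemas for exposure logs, serum draws and prediction exports.

Exposures: subject_id, day, avg_bop_psi, shots, training_start
(decimal hours or HH:MM), training_hours.  Serum: subject_id,
draw_label (d1_pre ... d3_post) or free time_h, abeta42_pg_ml.
Malformed rows are reported with their line numbers.
"""

from __future__ import annotations

import re
from pathlib import Path

import numpy as np
import pandas as pd

from .config import ModelConfig
from .exposure import InputError, TrainingSchedule
from .simulate import SubjectScenario, scenario_from_schedule

DRAW_LABEL_RE = re.compile(r"^d(\d+)_(pre|post)$")


def _numeric(frame: pd.DataFrame, col: str, path) -> pd.Series:
    raw = frame[col]
    vals = pd.to_numeric(raw, errors="coerce")
    bad = (vals.isna() & raw.notna()).to_numpy()
    if bad.any():
        lines = [int(i) + 2 for i in np.flatnonzero(bad)]  # +2: header + 1-based
        raise InputError(f"{path}: non-numeric {col!r} on line(s) {lines}")
    return vals


def _parse_start(value, path, line) -> float:
    if isinstance(value, str) and ":" in value:
        try:
            hh, mm = value.split(":")
            return int(hh) + int(mm) / 60.0
        except ValueError as exc:
            raise InputError(f"{path}: bad training_start on line {line}") from exc
    try:
        return float(value)
    except (TypeError, ValueError) as exc:
        raise InputError(f"{path}: bad training_start on line {line}") from exc


def read_exposures_csv(path) -> dict[str, TrainingSchedule]:
    """Parse per-subject training schedules from an exposure log."""
    path = Path(path)
    frame = pd.read_csv(path, dtype={"subject_id": str})
    required = {"subject_id", "day", "avg_bop_psi"}
    if not required.issubset(frame.columns):
        raise InputError(f"{path}: missing columns {sorted(required - set(frame.columns))}")
    frame["day"] = _numeric(frame, "day", path).astype(int)
    frame["avg_bop_psi"] = _numeric(frame, "avg_bop_psi", path)
    dup = frame.duplicated(subset=["subject_id", "day"]).to_numpy()
    if dup.any():
        raise InputError(
            f"{path}: duplicated subject_id+day on line(s) {[int(i) + 2 for i in np.flatnonzero(dup)]}"
        )
    schedules: dict[str, TrainingSchedule] = {}
    for sid, grp in frame.groupby("subject_id", sort=False):
        grp = grp.sort_values("day")
        days = grp["day"].tolist()
        if days != list(range(1, len(days) + 1)):
            raise InputError(f"{path}: subject {sid!r} days must be 1..n, got {days}")
        first = grp.iloc[0]
        start = (
            _parse_start(first["training_start"], path, int(first.name) + 2)
            if "training_start" in grp.columns and pd.notna(first.get("training_start"))
            else 9.0
        )
        duration = (
            float(first["training_hours"])
            if "training_hours" in grp.columns and pd.notna(first.get("training_hours"))
            else 6.0
        )
        shots = None
        if "shots" in grp.columns and grp["shots"].notna().all():
            shots = tuple(int(s) for s in _numeric(grp.reset_index(drop=True), "shots", path))
        schedules[str(sid)] = TrainingSchedule(
            n_days=len(days),
            daily_bop=tuple(grp["avg_bop_psi"]),
            shots_per_day=shots,
            training_start_hour=start,
            training_duration=duration,
        )
    return schedules


def read_serum_csv(path) -> pd.DataFrame:
    """Parse and validate a serum draw log."""
    path = Path(path)
    frame = pd.read_csv(path, dtype={"subject_id": str, "draw_label": str})
    required = {"subject_id", "draw_label", "abeta42_pg_ml"}
    if not required.issubset(frame.columns):
        raise InputError(f"{path}: missing columns {sorted(required - set(frame.columns))}")
    frame["abeta42_pg_ml"] = _numeric(frame, "abeta42_pg_ml", path)
    bad = (~frame["draw_label"].astype(str).str.match(DRAW_LABEL_RE)).to_numpy()
    if bad.any():
        raise InputError(
            f"{path}: bad draw_label on line(s) {[int(i) + 2 for i in np.flatnonzero(bad)]}"
        )
    dup = frame.duplicated(subset=["subject_id", "draw_label"]).to_numpy()
    if dup.any():
        raise InputError(
            f"{path}: duplicated subject_id+draw_label on line(s) "
            f"{[int(i) + 2 for i in np.flatnonzero(dup)]}"
        )
    nonpos = (frame["abeta42_pg_ml"] <= 0).to_numpy()
    if nonpos.any():
        lines = [int(i) + 2 for i in np.flatnonzero(nonpos)]
        raise InputError(f"{path}: non-positive concentration on line(s) {lines}")
    if "time_h" in frame.columns:
        frame["time_h"] = _numeric(frame, "time_h", path)
    return frame


def load_cohort_tables(
    exposures_csv, serum_csv, config: ModelConfig
) -> tuple[list[SubjectScenario], dict[str, dict[str, float]]]:
    """Join exposure schedules and serum draws into model inputs.

    Draw times come from the serum file's ``time_h`` column when
    present, otherwise from the schedule's average pre/post offsets.
    """
    schedules = read_exposures_csv(exposures_csv)
    serum = read_serum_csv(serum_csv)
    observations: dict[str, dict[str, float]] = {}
    for row in serum.itertuples():
        observations.setdefault(row.subject_id, {})[row.draw_label] = row.abeta42_pg_ml

    scenarios = []
    for sid, schedule in schedules.items():
        if sid not in observations:
            raise InputError(f"subject {sid!r} has exposures but no serum draws")
        if "time_h" in serum.columns and serum["time_h"].notna().all():
            sub = serum[serum["subject_id"] == sid].copy()
            sub["_day"] = sub["draw_label"].str.extract(DRAW_LABEL_RE)[0].astype(int)
            sub = sub.sort_values("time_h")
            scenarios.append(
                SubjectScenario(
                    sid,
                    schedule,
                    tuple(sub["time_h"]),
                    tuple(sub["draw_label"]),
                )
            )
        else:
            scenarios.append(scenario_from_schedule(sid, schedule))
    return scenarios, observations


def write_predictions_csv(predictions, path) -> None:
    """Concatenate per-subject prediction series into one CSV."""
    frames = [series.to_frame() for series in predictions.values()]
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)
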