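"""Reader/writer for the multi-box per-minute activity log (TSV) and the
JSON schedule file.

Log dialect: one header row, then one row per minute. Column 1 is the time
(HH:MM:SS, seconds fixed at 00 because the logger emits on the exact
minute), column 2 the date (ISO YYYY-MM-DD); from column 3 onward the
columns alternate LED state and PIR count per box, through box 5:

    Time  Date  LED01  PIR01  LED02  PIR02  ...  LED05  PIR05

Files with fewer trailing boxes are accepted (the absent boxes are marked
absent, never silently zero-filled). Headerless files are accepted by
positional fallback.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from datetime import datetime, time, timedelta
from typing import Optional

import numpy as np
import pandas as pd

from .schedule import BoxSchedule, SchedulePhase, validate_schedule

N_BOX_SLOTS = 5


class LogFormatError(ValueError):
    """Malformed activity-log file; carries the offending 1-based line."""

    def __init__(self, message: str, line: Optional[int] = None):
        self.line = line
        super().__init__(f"line {line}: {message}" if line is not None else message)


class ScheduleSchemaError(ValueError):
    """Schedule JSON violates the schema; message carries the JSON path."""


@dataclass
class BoxChannel:
    """LED state and PIR count series for one box."""

    led: np.ndarray
    pir: np.ndarray

    def __post_init__(self):
        self.led = np.asarray(self.led, dtype=np.uint8)
        self.pir = np.asarray(self.pir, dtype=np.int64)

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, BoxChannel)
            and np.array_equal(self.led, other.led)
            and np.array_equal(self.pir, other.pir)
        )


@dataclass
class ActivityLog:
    """Per-minute records for up to 5 boxes on a contiguous 60-s grid.

    ``boxes`` maps box id (1-5) to its channel; ids not present in the file
    are simply absent from the mapping.
    """

    start: datetime
    boxes: dict[int, BoxChannel] = field(default_factory=dict)

    @property
    def n_minutes(self) -> int:
        if not self.boxes:
            return 0
        return len(next(iter(self.boxes.values())).led)

    def times(self) -> pd.DatetimeIndex:
        return pd.date_range(self.start, periods=self.n_minutes, freq="1min")

    def validate(self) -> None:
        if self.start.second != 0:
            raise ValueError("log must start on an exact minute")
        lengths = {len(ch.led) for ch in self.boxes.values()}
        lengths |= {len(ch.pir) for ch in self.boxes.values()}
        if len(lengths) > 1:
            raise ValueError("box channels have unequal lengths")
        for b, ch in self.boxes.items():
            if not np.isin(ch.led, (0, 1)).all():
                raise ValueError(f"box {b}: LED values must be 0 or 1")
            if (ch.pir < 0).any():
                raise ValueError(f"box {b}: PIR counts must be non-negative")

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, ActivityLog)
            and self.start == other.start
            and self.boxes == other.boxes
        )


def _header(box_ids: list[int]) -> list[str]:
    cols = ["Time", "Date"]
    for b in box_ids:
        cols += [f"LED{b:02d}", f"PIR{b:02d}"]
    return cols


def write_log(log: ActivityLog, path, allow_gaps: bool = False) -> None:
    """Write a log as tab-separated text with one header row.

    Timestamps are written with seconds fixed at 00 on a contiguous 60-s
    grid. Present boxes must be contiguous from box 1 (absent boxes may only
    trail); ``allow_gaps`` is accepted for symmetry with truncated real logs
    but gaps inside the record grid itself never occur for generated logs.
    """
    log.validate()
    box_ids = sorted(log.boxes)
    if box_ids and box_ids != list(range(1, len(box_ids) + 1)):
        raise ValueError(
            f"present boxes {box_ids} are not contiguous from 1; "
            "absent boxes may only trail"
        )
    n = log.n_minutes
    times = log.times()
    data: dict[str, object] = {
        "Time": times.strftime("%H:%M:%S") if n else [],
        "Date": times.strftime("%Y-%m-%d") if n else [],
    }
    for b in box_ids:
        data[f"LED{b:02d}"] = log.boxes[b].led
        data[f"PIR{b:02d}"] = log.boxes[b].pir
    frame = pd.DataFrame(data, columns=_header(box_ids))
    frame.to_csv(path, sep="\t", index=False, lineterminator="\n")


def read_log(path, allow_gaps: bool = False) -> ActivityLog:
    """Parse an activity log; the first malformed line is reported.

    Fewer than 5 box column pairs are tolerated (trailing boxes marked
    absent). Unless ``allow_gaps`` is set, a gap or disorder in the 60-s
    grid raises with the line where the grid breaks.
    """
    raw = pd.read_csv(path, sep="\t", header=None, dtype=str, skip_blank_lines=False)
    if raw.empty:
        raise LogFormatError("empty file")
    has_header = str(raw.iloc[0, 0]).strip().lower() == "time"
    first_data_line = 2 if has_header else 1  # 1-based file lines
    body = raw.iloc[1:] if has_header else raw
    body = body.reset_index(drop=True)

    ncols = raw.shape[1]
    if ncols < 2 or (ncols - 2) % 2 != 0:
        raise LogFormatError(f"expected 2 + 2*k columns, found {ncols}")
    n_boxes = (ncols - 2) // 2
    if n_boxes > N_BOX_SLOTS:
        raise LogFormatError(f"more than {N_BOX_SLOTS} box column pairs ({n_boxes})")

    if body.empty:
        raise LogFormatError("no data rows")

    def fail_at(mask: np.ndarray, message: str) -> None:
        idx = int(np.argmax(mask))
        raise LogFormatError(message, line=first_data_line + idx)

    times = pd.to_datetime(
        body.iloc[:, 1].str.strip() + " " + body.iloc[:, 0].str.strip(),
        format="%Y-%m-%d %H:%M:%S",
        errors="coerce",
    )
    if times.isna().any():
        fail_at(times.isna().to_numpy(), "malformed timestamp")

    deltas = times.diff().dropna()
    if not allow_gaps and len(deltas) and (deltas != timedelta(minutes=1)).any():
        bad = (deltas != timedelta(minutes=1)).to_numpy()
        # +1: delta i refers to row i+1
        fail_at(np.concatenate([[False], bad]), "records not on a contiguous 60-s grid")

    boxes: dict[int, BoxChannel] = {}
    for k in range(n_boxes):
        box_id = k + 1
        led_col = body.iloc[:, 2 + 2 * k].str.strip()
        pir_col = body.iloc[:, 3 + 2 * k].str.strip()
        led = pd.to_numeric(led_col, errors="coerce")
        pir = pd.to_numeric(pir_col, errors="coerce")
        for name, series in ((f"LED{box_id:02d}", led), (f"PIR{box_id:02d}", pir)):
            if series.isna().any():
                fail_at(series.isna().to_numpy(), f"non-numeric value in {name}")
            if (series != series.astype(np.int64)).any():
                fail_at(
                    (series != series.astype(np.int64)).to_numpy(),
                    f"non-integer value in {name}",
                )
        led = led.astype(np.int64)
        pir = pir.astype(np.int64)
        if ((led != 0) & (led != 1)).any():
            fail_at(((led != 0) & (led != 1)).to_numpy(), f"LED{box_id:02d} value not 0/1")
        if (pir < 0).any():
            fail_at((pir < 0).to_numpy(), f"negative count in PIR{box_id:02d}")
        boxes[box_id] = BoxChannel(led=led.to_numpy(), pir=pir.to_numpy())

    return ActivityLog(start=times.iloc[0].to_pydatetime(), boxes=boxes)


# --------------------------------------------------------------------------
# JSON schedule files
#
# Schema: {"boxes": [{"box_id": int,
#                     "phases": [{"mode": "LD|DD|LL",
#                                 "from": "YYYY-MM-DD HH:MM",
#                                 "on": "HH:MM", "off": "HH:MM",
#                                 "T": float}]}]}
# "on"/"off" are required for LD only; "T" defaults to 24.0.
# --------------------------------------------------------------------------

_DT_FMT = "%Y-%m-%d %H:%M"


def _parse_clock(value: str, path: str) -> time:
    try:
        h, m = value.split(":")
        return time(int(h), int(m))
    except (ValueError, AttributeError):
        raise ScheduleSchemaError(f"{path}: invalid clock time {value!r}") from None


def load_schedule(path) -> list[BoxSchedule]:
    """Load and validate a JSON schedule file for one or more boxes."""
    with open(path) as fh:
        doc = json.load(fh)
    return schedules_from_dict(doc)


def schedules_from_dict(doc: dict) -> list[BoxSchedule]:
    if not isinstance(doc, dict) or "boxes" not in doc:
        raise ScheduleSchemaError("$: top-level object must contain 'boxes'")
    schedules = []
    for i, box in enumerate(doc["boxes"]):
        bpath = f"boxes[{i}]"
        if "box_id" not in box:
            raise ScheduleSchemaError(f"{bpath}: missing box_id")
        phases = []
        for j, ph in enumerate(box.get("phases", [])):
            ppath = f"{bpath}.phases[{j}]"
            mode = ph.get("mode")
            if mode not in ("LD", "DD", "LL"):
                raise ScheduleSchemaError(f"{ppath}.mode: invalid mode {mode!r}")
            if "from" not in ph:
                raise ScheduleSchemaError(f"{ppath}: missing 'from'")
            try:
                initiation = datetime.strptime(ph["from"], _DT_FMT)
            except ValueError:
                raise ScheduleSchemaError(
                    f"{ppath}.from: expected 'YYYY-MM-DD HH:MM', got {ph['from']!r}"
                ) from None
            on = off = None
            if mode == "LD":
                if "on" not in ph or "off" not in ph:
                    raise ScheduleSchemaError(f"{ppath}: LD phase requires 'on' and 'off'")
                on = _parse_clock(ph["on"], f"{ppath}.on")
                off = _parse_clock(ph["off"], f"{ppath}.off")
            T = ph.get("T", 24.0)
            if not isinstance(T, (int, float)) or T <= 0:
                raise ScheduleSchemaError(f"{ppath}.T: must be a positive number")
            phases.append(
                SchedulePhase(
                    mode=mode, initiation=initiation, on_time=on, off_time=off,
                    cycle_length_T=float(T),
                )
            )
        schedule = BoxSchedule(box_id=int(box["box_id"]), phases=phases)
        problems = validate_schedule(schedule)
        if problems:
            raise ScheduleSchemaError(f"{bpath}: " + "; ".join(problems))
        schedules.append(schedule)
    return schedules


def save_schedule(schedules: list[BoxSchedule], path) -> None:
    """Write schedules back to the JSON schema (lossless round trip)."""
    doc = {"boxes": []}
    for sched in schedules:
        phases = []
        for ph in sched.phases:
            entry: dict[str, object] = {
                "mode": ph.mode,
                "from": ph.initiation.strftime(_DT_FMT),
            }
            if ph.mode == "LD":
                entry["on"] = ph.on_time.strftime("%H:%M")
                entry["off"] = ph.off_time.strftime("%H:%M")
            entry["T"] = ph.cycle_length_T
            phases.append(entry)
        doc["boxes"].append({"box_id": sched.box_id, "phases": phases})
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=2)
        fh.write("\n")
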