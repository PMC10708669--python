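"""End-to-end reproducible runs: schedule -> simulated log -> analyses.

A run takes a JSON schedule, simulates one virtual mouse per box for a
fixed number of days, writes the per-minute TSV log, and (optionally)
renders actograms and computes spectrograms/periodograms per box. Every
output is a pure function of the schedule file and the RunConfig (seed
included), recorded in a machine-readable manifest.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass
from datetime import timedelta
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .actogram import build_actogram, render_actogram
from .analysis import chi_square_periodogram, preprocess_activity, stft_spectrogram
from .logio import ActivityLog, BoxChannel, load_schedule, write_log
from .mouse import MouseParams, simulate_activity, simulate_population
from .schedule import generate_light_trace


@dataclass
class RunConfig:
    """Everything needed to reproduce a run byte for byte."""

    schedule_path: str
    days: int
    seed: int = 0
    tau: float = 23.7
    tau_sd: float = 10.0 / 60.0
    out_dir: str = "run_out"
    fold_period: float = 24.0
    make_actograms: bool = True
    make_spectrograms: bool = False
    make_periodograms: bool = False
    periodogram_skip_days: int = 0


def simulate_log(config: RunConfig) -> ActivityLog:
    """Simulate every box in the schedule into one activity log."""
    schedules = load_schedule(config.schedule_path)
    start = min(s.phases[0].initiation for s in schedules)
    end = start + timedelta(days=config.days)
    base = MouseParams(tau=config.tau, seed=config.seed)
    population = simulate_population(base, n=len(schedules), tau_sd=config.tau_sd)
    boxes = {}
    for sched, params in zip(schedules, population):
        trace = generate_light_trace(sched, start, end)
        sim = simulate_activity(params, trace)
        boxes[sched.box_id] = BoxChannel(led=trace.states, pir=sim.counts)
    return ActivityLog(start=start, boxes=boxes)


def run_experiment(config: RunConfig) -> dict:
    """Execute a run and return the manifest (also written to disk)."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log = simulate_log(config)
    outputs: list[str] = []

    log_path = out / "activity_log.tsv"
    write_log(log, log_path)
    outputs.append(log_path.name)

    for box_id, ch in sorted(log.boxes.items()):
        if config.make_actograms:
            grid = build_actogram(ch.pir, ch.led, fold_period=config.fold_period)
            act_path = out / f"actogram_box{box_id}.svg"
            render_actogram(grid, act_path, title=f"box {box_id}")
            outputs.append(act_path.name)
        if config.make_spectrograms:
            detrended = preprocess_activity(ch.pir.astype(float))
            spec = stft_spectrogram(detrended)
            spec_path = out / f"spectrogram_box{box_id}.tsv"
            frame = pd.DataFrame(
                spec.psd,
                index=np.round(spec.periods, 6),
                columns=[f"day{d}" for d in spec.window_starts_days],
            )
            frame.index.name = "period_h"
            frame.to_csv(spec_path, sep="\t", lineterminator="\n")
            outputs.append(spec_path.name)
        if config.make_periodograms:
            skip = config.periodogram_skip_days * 1440
            pg = chi_square_periodogram(ch.pir[skip:].astype(float))
            pg_path = out / f"periodogram_box{box_id}.tsv"
            pd.DataFrame(
                {
                    "period_h": pg.periods,
                    "qp": pg.qp,
                    "significance": pg.significance_line,
                }
            ).to_csv(pg_path, sep="\t", index=False, lineterminator="\n")
            outputs.append(pg_path.name)

    manifest = {
        "package": "circabox",
        "version": __version__,
        "config": asdict(config),
        "schedule_sha256": _sha256(config.schedule_path),
        "log_sha256": _sha256(log_path),
        "outputs": outputs,
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return manifest


def _sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()
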