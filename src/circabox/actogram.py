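"""Double-plotted actograms with light-state background shading.

Activity is binned per day (one row per fold period, default 24 h), and
each rendered row shows two consecutive days side by side (day i left, day
i+1 right), so any periodicity away from the fold period appears as a
slanted band while folding at the true period straightens it vertical.
Background shading encodes the LED state: white where the light was on,
grey where it was off.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import matplotlib
import numpy as np

matplotlib.use("Agg")
import matplotlib.pyplot as plt


@dataclass
class ActogramGrid:
    """Binned activity (rows = fold periods) plus per-bin LED shading.

    counts[i, j] is total activity in bin j of day i; led[i, j] is the
    majority LED state of that bin. ``padded`` flags a partial trailing day
    padded with zeros and unlit shading.
    """

    fold_period: float  # hours
    bin_minutes: int
    counts: np.ndarray  # (n_days, bins_per_day)
    led: np.ndarray  # (n_days, bins_per_day) in {0, 1}
    padded: bool = False

    @property
    def n_days(self) -> int:
        return self.counts.shape[0]

    @property
    def bins_per_day(self) -> int:
        return self.counts.shape[1]

    def double_rows(self):
        """Yield (left, right, led_left, led_right) per rendered row; the
        right half of row i is the left half of row i+1 (the defining
        double-plot identity), empty for the last row."""
        empty = np.zeros(self.bins_per_day)
        for i in range(self.n_days):
            if i + 1 < self.n_days:
                yield self.counts[i], self.counts[i + 1], self.led[i], self.led[i + 1]
            else:
                yield self.counts[i], empty, self.led[i], np.ones(self.bins_per_day)


def build_actogram(
    activity: np.ndarray,
    led: np.ndarray,
    fold_period: float = 24.0,
    bin_minutes: int = 6,
) -> ActogramGrid:
    """Bin aligned per-minute activity and LED series into an actogram grid.

    Days are delimited every ``fold_period`` hours of external clock from
    the start of the series. Counts are summed per bin; shading is the
    per-bin majority LED state (ties resolved unlit). A partial trailing
    day is zero-padded and shaded unlit.
    """
    activity = np.asarray(activity, dtype=float)
    led = np.asarray(led, dtype=float)
    if activity.shape != led.shape:
        raise ValueError(
            f"activity ({activity.shape}) and led ({led.shape}) are not aligned"
        )
    mins_per_day = fold_period * 60.0
    if abs(mins_per_day / bin_minutes - round(mins_per_day / bin_minutes)) > 1e-9:
        raise ValueError(
            f"fold period of {fold_period} h is not a whole number of "
            f"{bin_minutes}-min bins"
        )
    bins_per_day = int(round(mins_per_day / bin_minutes))
    mins_per_day = int(round(mins_per_day))
    n_days = int(np.ceil(len(activity) / mins_per_day)) if len(activity) else 0
    padded = n_days * mins_per_day != len(activity)
    pad = n_days * mins_per_day - len(activity)
    activity = np.pad(activity, (0, pad))
    led = np.pad(led, (0, pad))
    by_bin_counts = activity.reshape(n_days, bins_per_day, bin_minutes).sum(axis=2)
    by_bin_led = led.reshape(n_days, bins_per_day, bin_minutes).mean(axis=2)
    return ActogramGrid(
        fold_period=fold_period,
        bin_minutes=bin_minutes,
        counts=by_bin_counts,
        led=(by_bin_led > 0.5).astype(np.uint8),
        padded=padded,
    )


def render_actogram(
    grid: ActogramGrid,
    path,
    last_days: int | None = None,
    title: str | None = None,
) -> None:
    """Render the grid as stacked bar-chart rows (two days per row).

    ``last_days`` restricts the plot to the final N days (the online-
    monitoring mode uses N = 10 to keep redraws cheap on long recordings).
    Vector (SVG) output is byte-deterministic for a given grid.
    """
    n_days = grid.n_days
    rows = list(grid.double_rows())
    if last_days is not None and last_days < n_days:
        rows = rows[n_days - last_days:]
    n_rows = len(rows)
    width_h = 2 * grid.fold_period
    bin_h = grid.bin_minutes / 60.0

    with plt.rc_context({"svg.hashsalt": "circabox"}):
        fig, ax = plt.subplots(figsize=(8, max(2.0, 0.28 * n_rows + 0.8)))
        peak = max((max(l.max(), r.max()) for l, r, *_ in rows), default=0.0) or 1.0
        edges = np.arange(grid.bins_per_day * 2 + 1) * bin_h
        for r, (left, right, led_l, led_r) in enumerate(rows):
            y0 = n_rows - 1 - r  # first day on top
            vals = np.concatenate([left, right]) / peak * 0.9
            shade = np.concatenate([led_l, led_r])
            # grey background where the light is off
            dark = np.where(shade == 0)[0]
            for start, stop in _runs(dark):
                ax.add_patch(
                    plt.Rectangle(
                        (edges[start], y0), edges[stop + 1] - edges[start], 1.0,
                        facecolor="0.82", edgecolor="none", zorder=1,
                    )
                )
            ax.bar(
                edges[:-1], vals, width=bin_h, bottom=y0, align="edge",
                color="black", linewidth=0, zorder=2,
            )
        ax.set_xlim(0, width_h)
        ax.set_ylim(0, max(n_rows, 1))
        ax.set_xticks(np.arange(0, width_h + 1e-9, grid.fold_period / 2))
        first_shown = n_days - n_rows
        ax.set_yticks(np.arange(n_rows) + 0.5)
        ax.set_yticklabels([str(first_shown + n_rows - r) for r in range(n_rows)])
        ax.set_xlabel("time (h, double-plotted)")
        ax.set_ylabel("day")
        if title:
            ax.set_title(title)
        fig.tight_layout()
        fig.savefig(path, metadata=_clean_metadata(path))
        plt.close(fig)


def _runs(indices: np.ndarray):
    """Contiguous runs in a sorted integer index array as (start, stop)."""
    if len(indices) == 0:
        return
    breaks = np.where(np.diff(indices) > 1)[0]
    starts = np.concatenate([[0], breaks + 1])
    stops = np.concatenate([breaks, [len(indices) - 1]])
    for s, e in zip(starts, stops):
        yield int(indices[s]), int(indices[e])


def _clean_metadata(path) -> dict | None:
    """Strip creation dates so identical grids give identical files."""
    suffix = str(path).lower()
    if suffix.endswith(".svg"):
        return {"Date": None}
    if suffix.endswith(".png"):
        return {"Software": None}
    return None
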