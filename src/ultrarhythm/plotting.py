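"""Double-plotted actogram rendering with dark-phase shading."""
from __future__ import annotations

import warnings
from pathlib import Path

import matplotlib

matplotlib.use("Agg", force=False)
import matplotlib.pyplot as plt
import numpy as np

from .schedule import ActivityRecord, LightSchedule, clock_hours


def render_actogram(
    record: ActivityRecord,
    schedule: LightSchedule,
    path=None,
    double_plot: bool = True,
):
    """Raster actogram: 48 h per row, successive days offset by 24 h.

    Dark spans are shaded grey. With fewer than 2 days of data a single-plot
    fallback is drawn with a warning. Returns the matplotlib Figure (and
    saves to ``path`` when given).
    """
    bins_per_day = record.bins_per_day
    # rows are 24 h slices starting at the record's first bin, so a D-day
    # record yields D rows (D - 1 when double plotted)
    start_clock = float(clock_hours(record.t[:1])[0])
    n_days = int(np.ceil(len(record) / bins_per_day))
    grid = np.full(n_days * bins_per_day, np.nan)
    grid[: len(record)] = record.counts
    days = grid.reshape(n_days, bins_per_day)

    if n_days < 2 and double_plot:
        warnings.warn("fewer than 2 days of data: falling back to single plot")
        double_plot = False

    n_rows = n_days - 1 if double_plot else n_days
    width_h = 48.0 if double_plot else 24.0
    fig, axes = plt.subplots(
        n_rows, 1, sharex=True, figsize=(8, 0.45 * n_rows + 1.2), squeeze=False
    )
    hours = np.arange(bins_per_day * (2 if double_plot else 1)) * record.bin_minutes / 60.0
    top = np.nanmax(days) if np.isfinite(days).any() else 1.0
    top = max(top, 1.0)

    # dark onset expressed in hours from the row origin (the record start)
    dark_start = (schedule.lights_off - start_clock) % 24.0
    dark_len = schedule.dark_hours
    spans = []
    for rep in range(2 if double_plot else 1):
        s = dark_start + 24.0 * rep
        spans.append((s, min(s + dark_len, width_h)))
        if s + dark_len > width_h:
            spans.append((0.0, s + dark_len - width_h))
    for r in range(n_rows):
        ax = axes[r, 0]
        row = np.concatenate([days[r], days[r + 1]]) if double_plot else days[r]
        ax.bar(hours, np.nan_to_num(row), width=record.bin_minutes / 60.0,
               color="black", align="edge")
        for s, e in spans:
            ax.axvspan(s, e, color="0.85", zorder=0)
        ax.set_xlim(0, width_h)
        ax.set_ylim(0, top)
        ax.set_yticks([])
        ax.set_ylabel(str(r + 1), rotation=0, va="center", fontsize=7)
    ticks = np.arange(0, width_h + 0.1, 6.0)
    axes[-1, 0].set_xticks(ticks)
    axes[-1, 0].set_xticklabels([f"{(start_clock + h) % 24:g}" for h in ticks])
    axes[-1, 0].set_xlabel("clock time (h)")
    fig.suptitle(record.animal_id, fontsize=9)
    fig.tight_layout()
    if path is not None:
        fig.savefig(Path(path), dpi=120)
    return fig
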