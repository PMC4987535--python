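"""Gaze preprocessing: ROI assignment, event building, cleaning, statistics.

Raw 1000-Hz samples are mapped to four rectangular regions of interest
(two choice symbols, two transition-cue bars), run-length encoded into
gaze events, and cleaned: a gap between two gazes on the *same* ROI is
treated as a blink and merged into one gaze (gap time excluded from dwell
by default), while gaps between different ROIs are simply dropped.  Trials
with no on-ROI gaze are excluded from all downstream statistics.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

ROIS = ("left_symbol", "right_symbol", "left_bar", "right_bar")
SYMBOL_ROIS = ("left_symbol", "right_symbol")
BAR_ROIS = ("left_bar", "right_bar")


@dataclass(frozen=True)
class ScreenGeometry:
    """Display layout of the first-stage choice screen.

    Defaults follow the recorded setup: 1920x1080 screen, 400x290-px
    symbol boxes separated by 460 px edge-to-edge and centred vertically at
    33% from the top, cue bars of the same footprint at 80% from the top,
    and a 50-px ROI margin around each box.
    """

    screen_w: int = 1920
    screen_h: int = 1080
    symbol_w: int = 400
    symbol_h: int = 290
    roi_margin: int = 50
    symbol_gap: int = 460  # edge-to-edge horizontal distance between boxes
    symbol_y_frac: float = 0.33
    bar_y_frac: float = 0.80
    viewing_distance_cm: float = 65.0  # metadata only

    def roi_boxes(self) -> dict[str, tuple[float, float, float, float]]:
        """ROI rectangles as (x0, y0, x1, y1), margin included."""
        half_w = self.symbol_w / 2 + self.roi_margin
        half_h = self.symbol_h / 2 + self.roi_margin
        cx = self.screen_w / 2
        dx = self.symbol_gap / 2 + self.symbol_w / 2
        sym_y = self.symbol_y_frac * self.screen_h
        bar_y = self.bar_y_frac * self.screen_h
        boxes = {
            "left_symbol": (cx - dx - half_w, sym_y - half_h, cx - dx + half_w, sym_y + half_h),
            "right_symbol": (cx + dx - half_w, sym_y - half_h, cx + dx + half_w, sym_y + half_h),
            "left_bar": (cx - dx - half_w, bar_y - half_h, cx - dx + half_w, bar_y + half_h),
            "right_bar": (cx + dx - half_w, bar_y - half_h, cx + dx + half_w, bar_y + half_h),
        }
        return boxes

    def roi_center(self, roi: str) -> tuple[float, float]:
        x0, y0, x1, y1 = self.roi_boxes()[roi]
        return (x0 + x1) / 2, (y0 + y1) / 2


@dataclass
class GazeEvent:
    """A contiguous dwell inside one ROI.

    ``dwell`` can be shorter than ``offset - onset`` after blink merging,
    because merged gap time is excluded from dwell by default.
    """

    roi: str
    onset: float
    offset: float
    dwell: float = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.offset <= self.onset:
            raise ValueError("offset must exceed onset")
        if self.dwell is None:
            self.dwell = self.offset - self.onset


def assign_roi(x: float, y: float, geometry: ScreenGeometry) -> str | None:
    """ROI containing the sample, or None (off-ROI or off-screen)."""
    if not (0 <= x <= geometry.screen_w and 0 <= y <= geometry.screen_h):
        return None
    for roi, (x0, y0, x1, y1) in geometry.roi_boxes().items():
        if x0 <= x <= x1 and y0 <= y <= y1:
            return roi
    return None


def samples_to_events(
    samples: pd.DataFrame, geometry: ScreenGeometry
) -> list[GazeEvent]:
    """Run-length encode ROI labels of time-ordered samples into raw events.

    ``samples`` needs columns ``t_ms``, ``x_px``, ``y_px``.  Off-ROI runs
    become gaps.  Event offsets extend one sample period past the last
    sample of the run.
    """
    if len(samples) == 0:
        return []
    t = samples["t_ms"].to_numpy(dtype=float)
    if np.any(np.diff(t) < 0):
        raise ValueError("samples must be time-ordered within a trial")
    labels = [
        assign_roi(x, y, geometry)
        for x, y in zip(samples["x_px"].to_numpy(), samples["y_px"].to_numpy())
    ]
    dt = float(np.median(np.diff(t))) if len(t) > 1 else 1.0
    events: list[GazeEvent] = []
    run_start = 0
    for i in range(1, len(labels) + 1):
        if i == len(labels) or labels[i] != labels[run_start]:
            roi = labels[run_start]
            if roi is not None:
                events.append(GazeEvent(roi=roi, onset=t[run_start], offset=t[i - 1] + dt))
            run_start = i
    return events


def clean_events(
    events: Sequence[GazeEvent], gap_inclusive: bool = False
) -> list[GazeEvent]:
    """Merge same-ROI gazes across gaps; drop cross-ROI gaps.

    A gap separating two gazes on the same ROI is read as a blink or
    tracker dropout and the two gazes become one, with dwell equal to the
    sum of on-ROI time (or the full span if ``gap_inclusive``).  Idempotent.
    """
    cleaned: list[GazeEvent] = []
    for ev in events:
        if cleaned and cleaned[-1].roi == ev.roi:
            prev = cleaned[-1]
            dwell = (
                ev.offset - prev.onset
                if gap_inclusive
                else prev.dwell + ev.dwell
            )
            cleaned[-1] = GazeEvent(
                roi=prev.roi, onset=prev.onset, offset=ev.offset, dwell=dwell
            )
        else:
            cleaned.append(GazeEvent(ev.roi, ev.onset, ev.offset, ev.dwell))
    return cleaned


def exclude_trials(
    trial_events: dict[int, Sequence[GazeEvent]]
) -> pd.DataFrame:
    """Flag trials with no on-ROI gaze as excluded.

    Returns one row per trial with ``kept`` flags and the event count.
    """
    rows = [
        {"trial": trial, "n_events": len(evs), "kept": len(evs) > 0}
        for trial, evs in trial_events.items()
    ]
    return pd.DataFrame(rows, columns=["trial", "n_events", "kept"])


def _symbol_of(roi: str, side_of_A: str) -> str | None:
    if roi == f"{side_of_A}_symbol":
        return "A"
    if roi.endswith("_symbol"):
        return "B"
    return None


def gaze_statistics(
    events: Sequence[GazeEvent], side_of_A: str = "left"
) -> dict[str, object]:
    """Per-trial gaze summary over the cleaned symbol gazes of one trial.

    Bar-ROI dwells are totalled separately and do not count as gazes for
    the first/middle/last bookkeeping.
    """
    sym_events = [
        (sym, ev)
        for ev in events
        if (sym := _symbol_of(ev.roi, side_of_A)) is not None
    ]
    dwell = {"A": 0.0, "B": 0.0}
    for sym, ev in sym_events:
        dwell[sym] += ev.dwell
    bar_dwell = sum(ev.dwell for ev in events if ev.roi in BAR_ROIS)
    n = len(sym_events)
    stats: dict[str, object] = {
        "n_gazes": n,
        "first_symbol": sym_events[0][0] if n else None,
        "last_symbol": sym_events[-1][0] if n else None,
        "dwell_A": dwell["A"],
        "dwell_B": dwell["B"],
        "bar_dwell": bar_dwell,
        "unique_symbols_viewed": len({s for s, _ in sym_events}),
        "middle_dwells": [ev.dwell for _, ev in sym_events[1:-1]] if n >= 3 else [],
        "last_dwell": sym_events[-1][1].dwell if n else np.nan,
    }
    if n:
        last = stats["last_symbol"]
        other = "B" if last == "A" else "A"
        stats["last_dwell_advantage"] = dwell[last] - dwell[other]
    else:
        stats["last_dwell_advantage"] = np.nan
    return stats


def bar_gaze_share(events: Sequence[GazeEvent]) -> float:
    """Share of on-ROI dwell spent on the cue bars (condition 2).

    NaN when the trial has no on-ROI dwell at all.
    """
    bar = sum(ev.dwell for ev in events if ev.roi in BAR_ROIS)
    sym = sum(ev.dwell for ev in events if ev.roi in SYMBOL_ROIS)
    total = bar + sym
    if total == 0:
        return float("nan")
    return bar / total


def events_to_frame(
    trial_events: dict[int, Sequence[GazeEvent]], subject_id: str = "s0"
) -> pd.DataFrame:
    rows = []
    for trial, evs in trial_events.items():
        for ev in evs:
            rows.append(
                {
                    "subject_id": subject_id,
                    "trial": trial,
                    "roi": ev.roi,
                    "onset_ms": ev.onset,
                    "offset_ms": ev.offset,
                    "dwell_ms": ev.dwell,
                }
            )
    return pd.DataFrame(
        rows,
        columns=["subject_id", "trial", "roi", "onset_ms", "offset_ms", "dwell_ms"],
    )


def frame_to_events(frame: pd.DataFrame) -> dict[int, list[GazeEvent]]:
    """Load pre-parsed eye-tracker events, bypassing the sample pipeline."""
    out: dict[int, list[GazeEvent]] = {}
    for trial, grp in frame.groupby("trial"):
        grp = grp.sort_values("onset_ms")
        out[int(trial)] = [
            GazeEvent(
                roi=row["roi"],
                onset=float(row["onset_ms"]),
                offset=float(row["offset_ms"]),
                dwell=float(row["dwell_ms"]) if "dwell_ms" in grp.columns else None,
            )
            for _, row in grp.iterrows()
        ]
    return out


def gaze_stats_table(
    trial_events: dict[int, Sequence[GazeEvent]],
    side_of_A: dict[int, str] | str = "left",
    subject_id: str = "s0",
) -> pd.DataFrame:
    """Clean, exclude and summarise all trials of one subject."""
    rows = []
    for trial, evs in trial_events.items():
        cleaned = clean_events(evs)
        if not cleaned:
            continue
        side = side_of_A if isinstance(side_of_A, str) else side_of_A.get(trial, "left")
        stats = gaze_statistics(cleaned, side_of_A=side)
        stats["middle_dwell_mean"] = (
            float(np.mean(stats["middle_dwells"])) if stats["middle_dwells"] else np.nan
        )
        del stats["middle_dwells"]
        stats["bar_share"] = bar_gaze_share(cleaned)
        stats["subject_id"] = subject_id
        stats["trial"] = trial
        rows.append(stats)
    cols = [
        "subject_id", "trial", "n_gazes", "first_symbol", "last_symbol",
        "dwell_A", "dwell_B", "bar_dwell", "unique_symbols_viewed",
        "last_dwell", "last_dwell_advantage", "middle_dwell_mean", "bar_share",
    ]
    return pd.DataFrame(rows, columns=cols)
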