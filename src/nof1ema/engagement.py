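"""Behavioural engagement outcomes from raw app screen-view logs.

Three outcomes are derived per 12-hour measurement window:

* **frequency** — number of log-ins, where a log-in (session) starts at the
  first screen view and at any screen view following at least 30 minutes of
  inactivity;
* **amount** — seconds between the first and last screen view of each
  session, summed over the sessions of the window;
* **depth** — fraction of the app's distinct components viewed in the
  window (7 components for the alcohol-reduction app studied here).

Compliance descriptives (percentage of the 56 expected EMA responses
returned) are computed per participant and summarized across participants.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from datetime import datetime, time, timedelta
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Session",
    "MeasurementWindow",
    "sessionize",
    "build_windows",
    "windowed_summary",
    "compliance_stats",
    "round_half_away",
]

logger = logging.getLogger(__name__)

DEFAULT_GAP = timedelta(minutes=30)
DEFAULT_COMPONENT_SET_SIZE = 7


@dataclass(frozen=True)
class Session:
    """One app session: a maximal run of views with gaps under the threshold."""

    first_event: pd.Timestamp
    last_event: pd.Timestamp
    n_views: int
    components: frozenset

    @property
    def duration_seconds(self) -> float:
        return (self.last_event - self.first_event).total_seconds()


@dataclass(frozen=True)
class MeasurementWindow:
    """Half-open 12-hour window [start, end) indexed 1..56."""

    start: pd.Timestamp
    end: pd.Timestamp
    label: str
    index: int


def sessionize(events: pd.DataFrame, gap_threshold: timedelta = DEFAULT_GAP) -> list[Session]:
    """Split an event log into sessions at inactivity gaps >= ``gap_threshold``.

    ``events`` needs a ``timestamp`` column and optionally ``component``;
    rows are sorted defensively. A gap of exactly the threshold starts a new
    session ("at least 30 min of inactivity"). Empty input gives [].
    """
    if len(events) == 0:
        return []
    df = events.sort_values("timestamp", kind="stable")
    ts = pd.to_datetime(df["timestamp"]).to_numpy()
    comp = (df["component"].astype(str).to_numpy()
            if "component" in df.columns else np.array(["?"] * len(df)))
    gap = np.timedelta64(gap_threshold)
    breaks = np.flatnonzero(np.diff(ts) >= gap) + 1
    sessions = []
    for chunk in np.split(np.arange(len(ts)), breaks):
        sessions.append(Session(
            first_event=pd.Timestamp(ts[chunk[0]]),
            last_event=pd.Timestamp(ts[chunk[-1]]),
            n_views=len(chunk),
            components=frozenset(comp[chunk]),
        ))
    return sessions


def build_windows(first_morning: datetime, n_days: int = 28,
                  morning_time: time | None = None) -> list[MeasurementWindow]:
    """Abutting 12-hour morning/evening windows anchored at the morning EMA time.

    ``first_morning`` is the start of window 1; if ``morning_time`` is given
    it overrides the clock time (default anchors are each participant's
    configured EMA times, 10:00/22:00 when unspecified).
    """
    start = pd.Timestamp(first_morning)
    if morning_time is not None:
        start = start.normalize() + pd.Timedelta(hours=morning_time.hour,
                                                 minutes=morning_time.minute)
    half = pd.Timedelta(hours=12)
    out = []
    for i in range(2 * n_days):
        s = start + i * half
        out.append(MeasurementWindow(
            start=s, end=s + half,
            label="morning" if i % 2 == 0 else "evening",
            index=i + 1,
        ))
    return out


def round_half_away(x) -> np.ndarray | float:
    """Round half away from zero (the convention of the printed percentages)."""
    x = np.asarray(x, dtype=float)
    out = np.sign(x) * np.floor(np.abs(x) + 0.5)
    return float(out) if out.ndim == 0 else out


def windowed_summary(sessions: Sequence[Session],
                     windows: Sequence[MeasurementWindow],
                     component_set_size: int = DEFAULT_COMPONENT_SET_SIZE) -> pd.DataFrame:
    """Per-window frequency, amount and depth of engagement.

    A session belongs to the window containing its *first* event (a log-in
    happens when the app is opened); sessions outside all windows are
    logged and dropped.
    """
    starts = np.array([w.start.to_datetime64() for w in windows])
    ends = np.array([w.end.to_datetime64() for w in windows])
    freq = np.zeros(len(windows), dtype=int)
    amount = np.zeros(len(windows))
    comps: list[set] = [set() for _ in windows]
    for s in sessions:
        t = s.first_event.to_datetime64()
        j = int(np.searchsorted(starts, t, side="right")) - 1
        if j < 0 or t >= ends[j]:
            logger.warning("session starting %s falls outside all windows; dropped",
                           s.first_event)
            continue
        freq[j] += 1
        amount[j] += s.duration_seconds
        comps[j].update(s.components)
    depth = np.array([len(c) / component_set_size for c in comps])
    return pd.DataFrame({
        "window_index": [w.index for w in windows],
        "label": [w.label for w in windows],
        "window_start": [w.start for w in windows],
        "window_end": [w.end for w in windows],
        "frequency": freq,
        "amount": amount,
        "depth": depth,
        "depth_pct": round_half_away(100 * depth),
    })


def compliance_stats(response_counts: Iterable[int],
                     n_expected: int = 56) -> dict:
    """Per-participant compliance percentages with mean/SD across participants.

    Each participant's percentage is rounded half-away-from-zero to an
    integer; the cross-participant mean and (population) SD of these rounded
    percentages are reported, matching the descriptive convention of the
    printed tables.
    """
    counts = np.asarray(list(response_counts), dtype=float)
    if np.any(counts < 0) or np.any(counts > n_expected):
        raise ValueError(f"response counts must lie in [0, {n_expected}]")
    pct = round_half_away(100.0 * counts / n_expected)
    return {
        "per_participant_pct": pct,
        "mean_pct": float(np.mean(pct)),
        "sd_pct": float(np.std(pct)),
        "missing_pct": round_half_away(100.0 - pct),
    }
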