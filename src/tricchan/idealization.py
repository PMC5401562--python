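"""Multi-level idealization of current traces into dwell sequences.

Each sample is assigned to the conductance level whose mean current is
nearest -- equivalent to half-amplitude thresholding at the midpoints
between adjacent level means.  Runs shorter than the dead time (events the
low-pass filter cannot resolve) are merged into the temporally preceding
event; the default dead time is 0.3/filter_cutoff, twice the nominal filter
rise time.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .channel_sim import Trace

__all__ = ["IdealizedRecord", "idealize", "extract_dwells", "default_dead_time"]


def default_dead_time(filter_cutoff: float) -> float:
    """Dead time (s) for a given -3 dB low-pass cutoff: 0.3 / f_c."""
    return 0.3 / filter_cutoff


@dataclass
class IdealizedRecord:
    """Level-labelled dwell sequence: contiguous events covering the record."""

    levels: np.ndarray
    starts: np.ndarray
    durations: np.ndarray
    n_levels: int
    dead_time: float
    total_time: float

    def __post_init__(self):
        self.levels = np.asarray(self.levels, dtype=int)
        self.starts = np.asarray(self.starts, dtype=float)
        self.durations = np.asarray(self.durations, dtype=float)
        if len(self.levels) == 0:
            raise ValueError("record must contain at least one event")
        if self.levels.min() < 0 or self.levels.max() >= self.n_levels:
            raise ValueError("event level outside [0, n_levels-1]")
        ends = self.starts + self.durations
        if not np.allclose(ends[:-1], self.starts[1:], rtol=0, atol=1e-9):
            raise ValueError("events must be contiguous and non-overlapping")
        if not np.isclose(self.durations.sum(), self.total_time, rtol=1e-9, atol=1e-9):
            raise ValueError("durations must sum to total_time")

    @property
    def events(self) -> list:
        """Events as (level, start_s, duration_s) tuples."""
        return list(zip(self.levels.tolist(), self.starts.tolist(), self.durations.tolist()))

    @property
    def n_events(self) -> int:
        return len(self.levels)

    def level_time_fractions(self) -> np.ndarray:
        out = np.bincount(self.levels, weights=self.durations, minlength=self.n_levels)
        return out / self.total_time

    def level_at(self, times) -> np.ndarray:
        """Level occupied at each queried time (s)."""
        edges = np.concatenate([self.starts, [self.total_time]])
        idx = np.clip(np.searchsorted(edges, np.asarray(times), side="right") - 1, 0, self.n_events - 1)
        return self.levels[idx]


def _run_length_encode(assign: np.ndarray):
    change = np.flatnonzero(np.diff(assign)) + 1
    starts = np.concatenate([[0], change])
    ends = np.concatenate([change, [len(assign)]])
    return assign[starts], starts, ends - starts


def idealize(trace: Trace, level_means, dead_time: float | None = None) -> IdealizedRecord:
    """Idealize a trace given known level means.

    Samples exactly at a midpoint threshold assign to the lower level.  When
    ``dead_time`` is None it defaults to 0.3/filter_cutoff for a filtered
    trace and 0 for an unfiltered one.  Sub-dead-time runs are absorbed into
    the temporally preceding event (the leading event, having no
    predecessor, absorbs into its successor); merging repeats until every
    event is at least one dead time long.
    """
    means = np.asarray(level_means, dtype=float)
    if means.ndim != 1 or len(means) < 2:
        raise ValueError("need at least two level means")
    if np.any(np.diff(means) <= 0):
        raise ValueError("level means must be strictly increasing")
    if dead_time is None:
        dead_time = default_dead_time(trace.filter_cutoff) if trace.filter_cutoff else 0.0
    if dead_time < 0:
        raise ValueError("dead_time must be non-negative")

    midpoints = 0.5 * (means[:-1] + means[1:])
    # right=True: a sample equal to a midpoint falls in the lower bin
    assign = np.digitize(trace.samples, midpoints, right=True)
    rle_levels, _, lengths = _run_length_encode(assign)
    raw = list(zip(rle_levels.tolist(), (lengths * trace.dt).tolist()))

    # single left-to-right pass: coalesce same-level neighbours, absorb
    # sub-dead-time runs into the event on the stack top (leading shorts,
    # having no predecessor, carry forward into the next kept event)
    levels: list[int] = []
    durations: list[float] = []
    pending = 0.0
    last_level = raw[-1][0]
    for lv, d in raw:
        d += pending
        pending = 0.0
        if levels and lv == levels[-1]:
            durations[-1] += d
        elif dead_time > 0 and d < dead_time:
            if levels:
                durations[-1] += d
            else:
                pending = d
        else:
            levels.append(lv)
            durations.append(d)
    if not levels:  # every run was sub-dead-time: keep one event
        levels, durations = [last_level], [pending]

    total_time = len(trace.samples) * trace.dt
    durations = np.asarray(durations)
    starts = np.concatenate([[0.0], np.cumsum(durations)[:-1]])
    return IdealizedRecord(
        levels=np.asarray(levels),
        starts=starts,
        durations=durations,
        n_levels=len(means),
        dead_time=dead_time,
        total_time=total_time,
    )


def extract_dwells(record: IdealizedRecord, level: int, drop_censored: bool = False) -> np.ndarray:
    """Durations of all maximal runs at ``level``, in temporal order.

    ``drop_censored`` removes the first and last events of the record (their
    durations are truncated by the recording window) before selecting.
    """
    if not 0 <= level < record.n_levels:
        raise ValueError(f"level {level} outside [0, {record.n_levels - 1}]")
    mask = record.levels == level
    if drop_censored and record.n_events > 1:
        mask = mask.copy()
        mask[0] = False
        mask[-1] = False
    return record.durations[mask]
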