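"""Inter-event interval series: construction, normality filtering,
stitching, transit-time matching, and variability statistics.

Interval kinds and their validity windows (all values in seconds):

========  ==========================================  ================
kind      definition                                  validity window
========  ==========================================  ================
RRI       successive ECG R peaks                      (0.33, 2.0)
PPI       successive PPG pulse arrivals               (0.33, 2.0)
BBI       successive airflow breath maxima            (2.0, 8.0)
PTT       R peak -> matched pulse arrival delay       (0.1, 0.8)
========  ==========================================  ================

RRI/PPI/BBI additionally require each interval to lie within a factor
window of its predecessor (0.7 * prev < value < 1.6 * prev); values
failing any rule are discarded and the surviving runs stitched together,
with segment boundaries recorded so that increment statistics and
detrending never straddle a gap.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "IntervalSeries",
    "SeriesStats",
    "VALIDITY",
    "RATIO_WINDOW",
    "intervals_from_events",
    "filter_intervals",
    "match_ptt",
    "series_stats",
]

#: Absolute validity windows (s); comparisons are strict on both sides.
VALIDITY: dict[str, tuple[float, float]] = {
    "RRI": (0.33, 2.0),
    "PPI": (0.33, 2.0),
    "BBI": (2.0, 8.0),
    "PTT": (0.1, 0.8),
}

#: Relative window against the previous interval (RRI/PPI/BBI only).
RATIO_WINDOW: tuple[float, float] = (0.7, 1.6)

#: PTT matching window after an R peak (s); strict bounds.
PTT_WINDOW: tuple[float, float] = (0.1, 0.8)


@dataclass
class IntervalSeries:
    """Accepted intervals with timestamps and stitched-segment markers.

    ``times[k]`` is the time of the later defining event of ``values[k]``;
    ``segment_id[k]`` labels the maximal run of consecutively accepted
    values it belongs to (a discarded value starts a new segment).
    """

    values: np.ndarray
    times: np.ndarray
    segment_id: np.ndarray
    kind: str

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.times = np.asarray(self.times, dtype=float)
        self.segment_id = np.asarray(self.segment_id, dtype=int)
        if not (self.values.size == self.times.size == self.segment_id.size):
            raise ValueError("values, times, segment_id must align")
        if self.kind not in VALIDITY:
            raise ValueError(f"unknown interval kind {self.kind!r}")

    def __len__(self) -> int:
        return self.values.size

    @property
    def n_segments(self) -> int:
        return int(np.unique(self.segment_id).size)

    def segments(self) -> list[np.ndarray]:
        """Value arrays of the stitched segments, in order."""
        if self.values.size == 0:
            return []
        return [self.values[self.segment_id == sid]
                for sid in np.unique(self.segment_id)]


@dataclass
class SeriesStats:
    """Mean, SDNN-style and RMSSD-style variability of an interval series."""

    mean: float
    sd: float
    sd_increments: float
    n: int
    low_n: bool = False


def intervals_from_events(times: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Raw intervals between successive events.

    Returns ``(values, timestamps)`` with ``values[k] = t[k+1] - t[k]``
    stamped at the later event ``t[k+1]``.  Fewer than two events yield
    empty arrays.
    """
    times = np.asarray(times, dtype=float)
    if times.size < 2:
        return np.empty(0), np.empty(0)
    return np.diff(times), times[1:]


def filter_intervals(values: np.ndarray, times: np.ndarray, kind: str,
                     ratio_ref: str = "accepted") -> IntervalSeries:
    """Keep only normal intervals; stitch surviving runs into segments.

    An interval is normal when it lies strictly inside the kind's absolute
    window and, when a predecessor exists, strictly inside
    ``0.7 * prev < value < 1.6 * prev``.  ``ratio_ref`` selects whether
    ``prev`` is the previous *accepted* interval (default; a single
    artifact then cannot cascade into rejecting its valid successors) or
    the previous *raw* interval.  The first interval of a recording has no
    predecessor, so only the absolute bounds apply to it.
    """
    if kind not in VALIDITY:
        raise ValueError(f"unknown interval kind {kind!r}")
    if ratio_ref not in ("accepted", "raw"):
        raise ValueError("ratio_ref must be 'accepted' or 'raw'")
    values = np.asarray(values, dtype=float)
    times = np.asarray(times, dtype=float)
    lo, hi = VALIDITY[kind]
    r_lo, r_hi = RATIO_WINDOW
    keep = np.zeros(values.size, dtype=bool)
    seg = np.zeros(values.size, dtype=int)
    prev: float | None = None
    seg_id = 0
    in_gap = False
    any_accepted = False
    for i, v in enumerate(values):
        ok = lo < v < hi
        if ok and prev is not None:
            ok = r_lo * prev < v < r_hi * prev
        if ok:
            if in_gap and any_accepted:
                seg_id += 1
            keep[i] = True
            seg[i] = seg_id
            in_gap = False
            any_accepted = True
            if ratio_ref == "accepted":
                prev = v
        else:
            in_gap = True
        if ratio_ref == "raw":
            prev = v
    return IntervalSeries(values[keep], times[keep], seg[keep], kind=kind)


def match_ptt(r_times: np.ndarray, pulse_times: np.ndarray,
              window: tuple[float, float] = PTT_WINDOW) -> IntervalSeries:
    """Pulse transit times: R peak to first pulse arrival in the window.

    For each R peak the earliest not-yet-used pulse arrival strictly
    inside ``(R + 0.1, R + 0.8)`` s defines one transit time (later
    arrivals within the window are treated as reflections and ignored).
    R peaks without a match are skipped and break the stitched segment.
    """
    r_times = np.asarray(r_times, dtype=float)
    pulse_times = np.asarray(pulse_times, dtype=float)
    w_lo, w_hi = window
    vals, stamps, segs = [], [], []
    seg_id = 0
    in_gap = False
    any_matched = False
    j = 0
    for r in r_times:
        while j < pulse_times.size and pulse_times[j] <= r + w_lo:
            j += 1
        if j < pulse_times.size and pulse_times[j] < r + w_hi:
            if in_gap and any_matched:
                seg_id += 1
            vals.append(pulse_times[j] - r)
            stamps.append(pulse_times[j])
            segs.append(seg_id)
            in_gap = False
            any_matched = True
            j += 1
        else:
            in_gap = True
    return IntervalSeries(np.array(vals), np.array(stamps),
                          np.array(segs, dtype=int), kind="PTT")


def series_stats(series: IntervalSeries) -> SeriesStats:
    """Mean, SD (SDNN analogue) and RMS of successive increments (RMSSD
    analogue), increments taken within stitched segments only — a gap is
    a recording artifact, not a physiological transition, so no increment
    ever straddles one.
    """
    v = series.values
    n = v.size
    if n < 2:
        return SeriesStats(float(v.mean()) if n else np.nan, np.nan, np.nan,
                           n, low_n=True)
    incs = [np.diff(seg) for seg in series.segments() if seg.size >= 2]
    d = np.concatenate(incs) if incs else np.empty(0)
    sd_inc = float(np.sqrt(np.mean(d**2))) if d.size else np.nan
    return SeriesStats(float(v.mean()), float(v.std()), sd_inc, n,
                       low_n=d.size < 2)
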