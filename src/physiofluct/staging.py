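"""Hypnogram handling: sleep-opportunity cropping, stage episodes, and
stage-wise slicing of interval and 1 Hz amplitude series.

Sleep stages are scored externally in 30-second epochs with AASM labels
W, N1, N2, N3, R.  N1 episodes are disregarded for the fluctuation
analysis (they are typically too short), but an N1 run still terminates
the adjacent episodes.  All intervals are half-open, [start, end), so
episodes partition the night and every value lands in exactly one bin.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np

from .intervals import IntervalSeries

__all__ = [
    "Hypnogram",
    "StageEpisode",
    "STAGES",
    "ANALYZED_STAGES",
    "crop_to_lights",
    "stage_episodes",
    "slice_by_episode",
]

STAGES = ("W", "N1", "N2", "N3", "R")
#: Stages entering the fluctuation analysis (N1 is disregarded).
ANALYZED_STAGES = ("W", "N2", "N3", "R")

EPOCH_LEN = 30.0

#: Common aliases mapped onto the canonical AASM labels on load.
STAGE_ALIASES = {
    "REM": "R", "WAKE": "W", "S1": "N1", "S2": "N2", "S3": "N3",
    "S4": "N3", "1": "N1", "2": "N2", "3": "N3", "4": "N3", "0": "W",
}


def canonical_stage(label: str) -> str:
    lab = str(label).strip().upper()
    lab = STAGE_ALIASES.get(lab, lab)
    if lab not in STAGES:
        raise ValueError(f"unknown sleep stage label {label!r}")
    return lab


@dataclass
class Hypnogram:
    """30 s epoch stage labels plus the lights-off/lights-on window.

    Epoch k covers [start + 30k, start + 30(k+1)).
    """

    stages: list[str]
    lights_off: float
    lights_on: float
    start: float = 0.0
    epoch_len: float = field(default=EPOCH_LEN)

    def __post_init__(self) -> None:
        if self.epoch_len != EPOCH_LEN:
            raise ValueError("epoch length is fixed at 30 s")
        if not self.lights_off < self.lights_on:
            raise ValueError("lights_off must precede lights_on")
        self.stages = [canonical_stage(s) for s in self.stages]

    @property
    def end(self) -> float:
        return self.start + self.epoch_len * len(self.stages)

    def duration(self) -> float:
        return self.epoch_len * len(self.stages)


@dataclass
class StageEpisode:
    """A maximal run of one stage, clipped to the lights window."""

    stage: str
    start: float
    end: float

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError("episode must have positive duration")

    @property
    def duration(self) -> float:
        return self.end - self.start


def crop_to_lights(x, hyp: Hypnogram):
    """Restrict events, samples or intervals to [lights_off, lights_on).

    Accepts an event-time array, an :class:`IntervalSeries`, or a
    :class:`~physiofluct.preproc.SampledSignal`; returns the same type.
    """
    off, on = hyp.lights_off, hyp.lights_on
    if isinstance(x, IntervalSeries):
        keep = (x.times >= off) & (x.times < on)
        if not keep.any():
            warnings.warn("no intervals inside the lights window",
                          stacklevel=2)
        return IntervalSeries(x.values[keep], x.times[keep],
                              x.segment_id[keep], kind=x.kind)
    if isinstance(x, np.ndarray) or (
            isinstance(x, (list, tuple)) and not hasattr(x, "fs")):
        t = np.asarray(x, dtype=float)
        out = t[(t >= off) & (t < on)]
        if out.size == 0 and t.size:
            warnings.warn("no events inside the lights window", stacklevel=2)
        return out
    # sampled signal (duck-typed: values / fs / t0)
    t = x.t0 + np.arange(len(x.values)) / x.fs
    keep = (t >= off) & (t < on)
    if not keep.any():
        warnings.warn("no samples inside the lights window", stacklevel=2)
        return replace(x, values=np.asarray(x.values)[keep], t0=off)
    vals = np.asarray(x.values)[keep]
    return replace(x, values=vals, t0=float(t[keep][0]))


def stage_episodes(hyp: Hypnogram,
                   include_n1: bool = False) -> list[StageEpisode]:
    """Maximal same-stage runs as episodes, clipped to the lights window.

    N1 runs are omitted (unless ``include_n1``) but still terminate the
    adjacent episodes — two N2 runs separated by N1 remain two episodes.
    """
    episodes: list[StageEpisode] = []
    if not hyp.stages:
        return episodes
    run_start = 0
    labels = hyp.stages
    for i in range(1, len(labels) + 1):
        if i == len(labels) or labels[i] != labels[run_start]:
            stage = labels[run_start]
            t0 = hyp.start + hyp.epoch_len * run_start
            t1 = hyp.start + hyp.epoch_len * i
            # clip to lights window
            a = max(t0, hyp.lights_off)
            b = min(t1, hyp.lights_on)
            if (stage != "N1" or include_n1) and b > a:
                episodes.append(StageEpisode(stage, a, b))
            run_start = i
    return episodes


def slice_by_episode(series, ep: StageEpisode):
    """Series fragment whose timestamps fall in [ep.start, ep.end).

    Interval values are assigned by the time of their later defining
    event; 1 Hz amplitude samples by their bin timestamp.  Fragments
    inherit the stitched-segment structure of the parent series.
    """
    if isinstance(series, IntervalSeries):
        keep = (series.times >= ep.start) & (series.times < ep.end)
        return IntervalSeries(series.values[keep], series.times[keep],
                              series.segment_id[keep], kind=series.kind)
    # sampled signal (e.g. the 1 Hz EEG alpha-amplitude series)
    t = series.t0 + np.arange(len(series.values)) / series.fs
    keep = (t >= ep.start) & (t < ep.end)
    vals = np.asarray(series.values)[keep]
    new_t0 = float(t[keep][0]) if keep.any() else ep.start
    return replace(series, values=vals, t0=new_t0)
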