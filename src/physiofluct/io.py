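"""Plain-text readers and writers for signals, events, hypnograms,
interval series and synthetic-subject bundles.

All formats are simple columnar CSV so recordings can be inspected and
produced by any tool; an EDF channel can be converted to the signal CSV
with any standard reader.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .intervals import IntervalSeries
from .preproc import EventSeries, SampledSignal
from .staging import Hypnogram
from .synth import SyntheticSubject

__all__ = [
    "write_signal_csv", "read_signal_csv",
    "write_events_csv", "read_events_csv",
    "write_hypnogram_csv", "read_hypnogram_csv",
    "write_intervals_csv", "read_intervals_csv",
    "write_subject", "read_subject",
]


def write_signal_csv(path, signal: SampledSignal) -> None:
    """Two-column CSV: time (s), value."""
    df = pd.DataFrame({"time": signal.times, "value": signal.values})
    df.to_csv(path, index=False, float_format="%.8g")


def read_signal_csv(path, fs: float | None = None) -> SampledSignal:
    """Load a time,value CSV; the sampling rate is inferred from the time
    column unless given explicitly."""
    df = pd.read_csv(path)
    t = df["time"].to_numpy(dtype=float)
    if fs is None:
        if t.size < 2:
            raise ValueError("cannot infer fs from fewer than two samples")
        dt = np.diff(t)
        if not np.allclose(dt, dt[0], rtol=1e-6):
            raise ValueError("time column is not uniformly sampled")
        fs = 1.0 / dt[0]
    return SampledSignal(df["value"].to_numpy(dtype=float), fs=float(fs),
                         t0=float(t[0]) if t.size else 0.0)


def write_events_csv(path, events: EventSeries) -> None:
    pd.DataFrame({"time_s": events.times, "kind": events.kind}).to_csv(
        path, index=False, float_format="%.8g")


def read_events_csv(path) -> EventSeries:
    df = pd.read_csv(path)
    kind = str(df["kind"].iloc[0]) if len(df) else "r_peak"
    return EventSeries(df["time_s"].to_numpy(dtype=float), kind=kind)


def write_hypnogram_csv(path, hyp: Hypnogram) -> None:
    """Epoch table plus a JSON sidecar with the lights window and start."""
    pd.DataFrame({"epoch_index": np.arange(len(hyp.stages)),
                  "stage": hyp.stages}).to_csv(path, index=False)
    meta = {"lights_off": hyp.lights_off, "lights_on": hyp.lights_on,
            "start": hyp.start, "epoch_len": hyp.epoch_len}
    Path(str(path) + ".json").write_text(json.dumps(meta, indent=1))


def read_hypnogram_csv(path, lights_off: float | None = None,
                       lights_on: float | None = None,
                       start: float | None = None) -> Hypnogram:
    df = pd.read_csv(path)
    stages = [str(s) for s in df["stage"]]
    sidecar = Path(str(path) + ".json")
    meta = json.loads(sidecar.read_text()) if sidecar.exists() else {}
    start = start if start is not None else meta.get("start", 0.0)
    if lights_off is None:
        lights_off = meta.get("lights_off", start)
    if lights_on is None:
        lights_on = meta.get("lights_on", start + 30.0 * len(stages))
    return Hypnogram(stages, lights_off=lights_off, lights_on=lights_on,
                     start=start)


def write_intervals_csv(path, series: IntervalSeries) -> None:
    pd.DataFrame({"timestamp_s": series.times, "value_s": series.values,
                  "segment_id": series.segment_id}).to_csv(
        path, index=False, float_format="%.10g")


def read_intervals_csv(path, kind: str) -> IntervalSeries:
    df = pd.read_csv(path)
    return IntervalSeries(df["value_s"].to_numpy(dtype=float),
                          df["timestamp_s"].to_numpy(dtype=float),
                          df["segment_id"].to_numpy(dtype=int), kind=kind)


def write_subject(subject: SyntheticSubject, out_dir) -> None:
    """Write a synthetic subject: event CSVs, hypnogram CSV, 1 Hz EEG
    envelope CSV, and a JSON sidecar with ground truth and seed."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_events_csv(out / "r_peaks.csv",
                     EventSeries(subject.r_times, kind="r_peak"))
    write_events_csv(out / "pulse_arrivals.csv",
                     EventSeries(subject.pulse_times, kind="pulse_arrival"))
    write_events_csv(out / "breath_maxima.csv",
                     EventSeries(subject.breath_times, kind="breath_max"))
    write_hypnogram_csv(out / "hypnogram.csv", subject.hypnogram)
    write_signal_csv(out / "eeg_alpha_amplitude.csv",
                     SampledSignal(subject.eeg_envelope_truth, fs=1.0,
                                   t0=subject.hypnogram.lights_off))
    truth = {
        "seed": subject.seed,
        "subject_id": subject.subject_id,
        "alpha_truth": {k: {st: list(v) for st, v in d.items()}
                        for k, d in subject.alpha_truth.items()},
        "ptt_truth": [float(v) for v in subject.ptt_truth],
        "clipped_fraction": subject.clipped_fraction,
        "covariates": subject.covariates,
    }
    (out / "ground_truth.json").write_text(json.dumps(truth, indent=1))


def read_subject(in_dir) -> SyntheticSubject:
    p = Path(in_dir)
    truth = json.loads((p / "ground_truth.json").read_text())
    hyp = read_hypnogram_csv(p / "hypnogram.csv")
    env = read_signal_csv(p / "eeg_alpha_amplitude.csv")
    return SyntheticSubject(
        hypnogram=hyp,
        r_times=read_events_csv(p / "r_peaks.csv").times,
        pulse_times=read_events_csv(p / "pulse_arrivals.csv").times,
        breath_times=read_events_csv(p / "breath_maxima.csv").times,
        ptt_truth=np.asarray(truth["ptt_truth"], dtype=float),
        eeg_envelope_truth=env.values,
        alpha_truth={k: {st: tuple(v) for st, v in d.items()}
                     for k, d in truth["alpha_truth"].items()},
        seed=truth.get("seed"),
        clipped_fraction=truth.get("clipped_fraction", {}),
        subject_id=truth.get("subject_id", "synthetic"),
        covariates=truth.get("covariates", {}),
    )
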