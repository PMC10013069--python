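"""Raw-waveform preprocessing: event detection and EEG band amplitudes.

Converts sampled PPG, airflow, ECG and EEG channels into the event times
and 1 Hz alpha-band amplitude series that the interval and fluctuation
analyses consume.

* Pulse arrivals: the intersecting-tangents method — the arrival is the
  intersection of the tangent at the maximal-upstroke point with the
  horizontal tangent at the preceding pulse minimum, after offset
  correction (3 s moving average subtracted) and 0.1 s moving-average
  smoothing of both the signal and its derivative.
* Breath maxima: local maxima of the flow signal after subtracting a
  10 s moving average and smoothing with a 1 s moving average.
* R peaks: a simple baseline-removal + adaptive-threshold peak picker is
  provided; externally detected R-peak times can be supplied verbatim.
* EEG alpha amplitude: Fourier filtering to the 7-12 Hz band, Hilbert
  instantaneous amplitude, reduced to one value per second.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numpy.fft import irfft, rfft, rfftfreq
from scipy.signal import find_peaks, hilbert

__all__ = [
    "SampledSignal",
    "EventSeries",
    "moving_average",
    "detect_pulse_arrivals",
    "detect_breath_maxima",
    "detect_r_peaks",
    "eeg_alpha_amplitude",
    "ALPHA_BAND",
]

ALPHA_BAND = (7.0, 12.0)


@dataclass
class SampledSignal:
    """Uniformly sampled channel: values, sampling rate (Hz), start time."""

    values: np.ndarray
    fs: float
    t0: float = 0.0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        if np.isnan(self.values).any():
            raise ValueError("signal contains NaNs; mark gaps before loading")

    @property
    def duration(self) -> float:
        return self.values.size / self.fs

    @property
    def times(self) -> np.ndarray:
        return self.t0 + np.arange(self.values.size) / self.fs


@dataclass
class EventSeries:
    """Strictly increasing event times of one kind."""

    times: np.ndarray
    kind: str  # r_peak | pulse_arrival | breath_max

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        if self.times.size > 1 and np.any(np.diff(self.times) <= 0):
            raise ValueError("event times must be strictly increasing")

    def __len__(self) -> int:
        return self.times.size


def moving_average(signal: SampledSignal | np.ndarray, window_s: float,
                   fs: float | None = None) -> SampledSignal | np.ndarray:
    """Centred moving average; windows shrink (truncate) at the edges.

    Truncation keeps the output the same length as the input with no NaN
    padding, so downstream detectors see valid values everywhere.
    """
    if isinstance(signal, SampledSignal):
        out = moving_average(signal.values, window_s, fs=signal.fs)
        return SampledSignal(out, fs=signal.fs, t0=signal.t0)
    if fs is None:
        raise ValueError("fs required for a bare array")
    x = np.asarray(signal, dtype=float)
    w = max(1, int(round(window_s * fs)))
    if w > x.size:
        raise ValueError("window longer than the signal")
    if w == 1:
        return x.copy()
    kernel = np.ones(w)
    num = np.convolve(x, kernel, mode="same")
    cnt = np.convolve(np.ones(x.size), kernel, mode="same")
    return num / cnt


def _upstroke_candidates(d: np.ndarray, thr: float) -> list[tuple[int, int]]:
    """Contiguous runs where the smoothed derivative exceeds thr."""
    above = d > thr
    if not above.any():
        return []
    edges = np.flatnonzero(np.diff(above.astype(int)))
    starts = list(edges[~above[edges]] + 1)
    ends = list(edges[above[edges]] + 1)
    if above[0]:
        starts.insert(0, 0)
    if above[-1]:
        ends.append(above.size)
    return list(zip(starts, ends))


def detect_pulse_arrivals(ppg: SampledSignal, min_spacing_s: float = 0.3,
                          upstroke_frac: float = 0.3) -> EventSeries:
    """Pulse arrival times by the intersecting-tangents method.

    The PPG is offset-corrected (3 s moving average subtracted) and
    low-pass filtered (0.1 s moving average); its first derivative is
    smoothed again with a 0.1 s moving average.  Candidate upstrokes are
    runs where the derivative exceeds ``upstroke_frac`` of its 90th
    percentile; within each, the maximal-slope point defines the steep
    tangent, and the last local minimum of the corrected PPG before that
    point defines the horizontal tangent.  Their intersection is the
    arrival time.
    """
    if ppg.fs < 64:
        raise ValueError("PPG sampling rate must be >= 64 Hz")
    if ppg.duration < 10:
        raise ValueError("PPG shorter than 10 s")
    fs = ppg.fs
    x = ppg.values - moving_average(ppg.values, 3.0, fs=fs)
    x = moving_average(x, 0.1, fs=fs)
    d = np.gradient(x) * fs
    d = moving_average(d, 0.1, fs=fs)
    pos = d[d > 0]
    if pos.size == 0:
        return EventSeries(np.empty(0), kind="pulse_arrival")
    # percentile over the positive part keeps the threshold meaningful for
    # sparse signals (long flat stretches would drag the plain 90th
    # percentile to zero)
    thr = upstroke_frac * np.percentile(pos, 90)
    if thr <= 0:
        return EventSeries(np.empty(0), kind="pulse_arrival")
    arrivals: list[float] = []
    for lo, hi in _upstroke_candidates(d, thr):
        i_max = lo + int(np.argmax(d[lo:hi]))
        if d[i_max] <= 0:
            continue
        # walk back to the last local minimum of the corrected PPG
        j = i_max
        while j > 0 and x[j - 1] < x[j]:
            j -= 1
        t_arr = i_max / fs + (x[j] - x[i_max]) / d[i_max]
        if 0 <= t_arr < ppg.duration:
            arrivals.append(ppg.t0 + t_arr)
    arrivals.sort()
    out: list[float] = []
    for t in arrivals:
        if not out or t - out[-1] >= min_spacing_s:
            out.append(t)
    return EventSeries(np.asarray(out), kind="pulse_arrival")


def detect_breath_maxima(flow: SampledSignal,
                         min_spacing_s: float = 1.5) -> EventSeries:
    """Respiratory-cycle maxima of the filtered airflow signal.

    Preprocessing: subtract a 10 s moving average, then smooth with a
    1 s moving average.  One event per cycle at each local maximum; a
    1.5 s refractory spacing (below the 2 s breath-interval validity
    floor) suppresses double detections on noisy plateaus without
    pre-empting the interval filter.
    """
    if flow.fs < 8:
        raise ValueError("airflow sampling rate must be >= 8 Hz")
    fs = flow.fs
    y = flow.values - moving_average(flow.values, 10.0, fs=fs)
    y = moving_average(y, 1.0, fs=fs)
    sd = y.std()
    if sd == 0:
        return EventSeries(np.empty(0), kind="breath_max")
    peaks, _ = find_peaks(y, distance=max(1, int(round(min_spacing_s * fs))),
                          prominence=0.25 * sd, height=0.0)
    return EventSeries(flow.t0 + peaks / fs, kind="breath_max")


def detect_r_peaks(ecg: SampledSignal | None = None,
                   times: np.ndarray | None = None,
                   min_spacing_s: float = 0.25) -> EventSeries:
    """R-peak times from a raw ECG, or externally supplied times verbatim.

    The built-in detector is deliberately simple (baseline removal with a
    0.6 s moving average, adaptive amplitude threshold, refractory local
    maxima); for clinical-grade morphology a dedicated QRS detector
    should supply ``times`` directly.
    """
    if times is not None:
        return EventSeries(np.asarray(times, dtype=float), kind="r_peak")
    if ecg is None:
        raise ValueError("either an ECG signal or explicit times required")
    if ecg.values.size == 0:
        return EventSeries(np.empty(0), kind="r_peak")
    if ecg.fs < 128:
        raise ValueError("ECG sampling rate must be >= 128 Hz")
    fs = ecg.fs
    y = ecg.values - moving_average(ecg.values, 0.6, fs=fs)
    ref = np.percentile(np.abs(y), 99.5)
    if ref <= 0:
        return EventSeries(np.empty(0), kind="r_peak")
    peaks, _ = find_peaks(y, height=0.4 * ref,
                          distance=max(1, int(round(min_spacing_s * fs))))
    return EventSeries(ecg.t0 + peaks / fs, kind="r_peak")


def eeg_alpha_amplitude(eeg: SampledSignal,
                        band: tuple[float, float] = ALPHA_BAND,
                        reducer: str = "mean") -> SampledSignal:
    """1 Hz alpha-band amplitude series from a raw EEG channel.

    Fourier filtering (zeroing all spectral bins outside ``band``),
    Hilbert-transform instantaneous amplitude, then one value per second.
    The per-second reducer defaults to the mean of the instantaneous
    amplitudes within each 1 s bin, which is robust to carrier phase; set
    ``reducer='sample'`` to take the first sample of each bin instead.
    Returns a :class:`SampledSignal` with fs = 1 Hz, value k covering
    second [t0 + k, t0 + k + 1).
    """
    if eeg.fs < 64:
        raise ValueError("EEG sampling rate must be >= 64 Hz")
    if eeg.duration < 10:
        raise ValueError("EEG shorter than 10 s")
    x = eeg.values
    n = x.size
    spec = rfft(x)
    f = rfftfreq(n, d=1.0 / eeg.fs)
    spec[(f < band[0]) | (f > band[1])] = 0.0
    band_sig = irfft(spec, n)
    amp = np.abs(hilbert(band_sig))
    n_sec = int(n // eeg.fs)
    sec_idx = (np.arange(n) / eeg.fs).astype(int)
    mask = sec_idx < n_sec  # full seconds only
    if reducer == "mean":
        vals = (np.bincount(sec_idx[mask], weights=amp[mask])
                / np.bincount(sec_idx[mask]))
    elif reducer == "sample":
        first = np.searchsorted(sec_idx, np.arange(n_sec))
        vals = amp[first]
    else:
        raise ValueError("reducer must be 'mean' or 'sample'")
    return SampledSignal(vals, fs=1.0, t0=eeg.t0)
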