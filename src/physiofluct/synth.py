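"""Synthetic physiological signals with exactly known ground truth.

Everything downstream — event detection, interval filtering, stage slicing,
DFA — can be verified against these generators: noise series with
prescribed scaling exponents (Fourier filtering / spectral synthesis),
two-regime noise with a controlled crossover scale, pulse/airflow/EEG
waveforms with known event times and envelopes, hypnograms with a planned
episode structure, and complete in-memory subjects combining all of them.

All generators are pure functions of their seed and parameters.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from numpy.fft import irfft, rfft, rfftfreq

from .intervals import VALIDITY
from .staging import Hypnogram

__all__ = [
    "ScalingNoiseSpec",
    "SyntheticSubject",
    "gen_scaling_noise",
    "gen_crossover_noise",
    "gen_event_times",
    "gen_ppg",
    "gen_resp_flow",
    "gen_eeg",
    "gen_hypnogram",
    "gen_subject",
    "SubjectConfig",
    "StageTargets",
    "pulse_template",
    "PULSE_RISE_S",
]

_ALPHA_RANGE = (0.1, 1.5)


def _check_alpha(alpha: float, name: str = "alpha") -> None:
    lo, hi = _ALPHA_RANGE
    if not lo < alpha < hi:
        raise ValueError(
            f"{name}={alpha} outside ({lo}, {hi}); spectral synthesis with "
            f"beta = 2*alpha - 1 is only meaningful in this range")


@dataclass
class ScalingNoiseSpec:
    """Parameters of a long-range-correlated Gaussian noise series.

    The target DFA exponent ``alpha_target`` maps to the spectral exponent
    via beta = 2*alpha - 1, i.e. P(f) ~ f**-beta.
    """

    alpha_target: float
    n: int
    mean: float = 0.0
    sd: float = 1.0
    seed: int | None = None

    def __post_init__(self) -> None:
        _check_alpha(self.alpha_target, "alpha_target")
        if self.n < 64:
            raise ValueError("n must be >= 64")
        if self.sd <= 0:
            raise ValueError("sd must be > 0")


def _rescale(x: np.ndarray, mean: float, sd: float) -> np.ndarray:
    s = x.std()
    if s == 0:
        raise ValueError("degenerate series; cannot rescale")
    return mean + sd * (x - x.mean()) / s


def _spectral_noise(n: int, amp: np.ndarray,
                    rng: np.random.Generator) -> np.ndarray:
    """Shape white Gaussian noise by the one-sided amplitude profile `amp`."""
    white = rng.standard_normal(n)
    spec = rfft(white) * amp
    spec[0] = 0.0  # remove DC before inverting
    return irfft(spec, n)


def gen_scaling_noise(spec: ScalingNoiseSpec | None = None, *,
                      alpha: float | None = None, n: int | None = None,
                      mean: float = 0.0, sd: float = 1.0,
                      seed: int | None = None,
                      rng: np.random.Generator | None = None) -> np.ndarray:
    """Gaussian noise with power spectrum P(f) ~ f**-(2*alpha-1).

    Fourier filtering: the spectrum of white noise is multiplied by
    f**(-beta/2) with beta = 2*alpha_target - 1, inverse-transformed, and
    rescaled to the requested mean and standard deviation.  alpha = 0.5
    reduces to white noise; alpha = 1.0 gives 1/f-type noise.
    """
    if spec is None:
        spec = ScalingNoiseSpec(alpha, n, mean=mean, sd=sd, seed=seed)
    beta = 2.0 * spec.alpha_target - 1.0
    f = rfftfreq(spec.n)
    amp = np.ones_like(f)
    amp[1:] = f[1:] ** (-beta / 2.0)
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    x = _spectral_noise(spec.n, amp, rng)
    return _rescale(x, spec.mean, spec.sd)


def gen_crossover_noise(alpha1: float, alpha2: float, s_cross: float, n: int,
                        seed: int | None = None, mean: float = 0.0,
                        sd: float = 1.0,
                        rng: np.random.Generator | None = None) -> np.ndarray:
    """Noise whose DFA exponent crosses over from alpha1 (small scales)
    to alpha2 (large scales) near scale ``s_cross``.

    The amplitude spectrum is a piecewise power law, continuous at the
    break frequency: slope -beta1/2 above it (fast fluctuations, short
    scales) and -beta2/2 below it (slow fluctuations, long scales).
    """
    _check_alpha(alpha1, "alpha1")
    _check_alpha(alpha2, "alpha2")
    if not 8 < s_cross < n / 8:
        raise ValueError(f"s_cross={s_cross} must lie in (8, n/8)")
    b1 = 2.0 * alpha1 - 1.0
    b2 = 2.0 * alpha2 - 1.0
    f = rfftfreq(n)
    fc = 1.0 / s_cross  # spectral break at the reciprocal of the crossover scale
    amp = np.ones_like(f)
    hi = f >= fc
    lo = (f > 0) & ~hi
    amp[hi] = (f[hi] / fc) ** (-b1 / 2.0)
    amp[lo] = (f[lo] / fc) ** (-b2 / 2.0)
    if rng is None:
        rng = np.random.default_rng(seed)
    x = _spectral_noise(n, amp, rng)
    return _rescale(x, mean, sd)


def gen_event_times(intervals: np.ndarray, t0: float = 0.0) -> np.ndarray:
    """Event times as the cumulative sum of positive intervals from t0."""
    intervals = np.asarray(intervals, dtype=float)
    if intervals.size == 0:
        return np.empty(0)
    if np.any(intervals <= 0):
        raise ValueError("all intervals must be positive")
    return t0 + np.cumsum(intervals)


# ---------------------------------------------------------------------------
# waveform generators

PULSE_RISE_S = 0.08  # template rise time (foot to systolic peak)
_PULSE_SHAPE = 2.0   # gamma shape; peak at _PULSE_SHAPE * theta


def pulse_template(fs: float, rise_s: float = PULSE_RISE_S,
                   duration_s: float = 0.7) -> tuple[np.ndarray, float]:
    """Asymmetric pulse template (fast upstroke, slow decay), peak 1.

    Returns ``(template, foot_offset_s)`` where ``foot_offset_s`` is the
    time from the template start to its intersecting-tangents foot — the
    intersection of the tangent at the maximal-upstroke point with the
    horizontal tangent at the preceding minimum (the zero baseline).
    Generators shift the template by this offset so that a tangent-based
    detector recovers the nominal arrival times.
    """
    a = _PULSE_SHAPE
    theta = rise_s / a
    t = np.arange(int(round(duration_s * fs))) / fs
    u = t / theta
    tpl = (u**a) * np.exp(a - u) / (a**a)
    # tangent foot, computed on the continuous template: max slope at
    # u* = a - sqrt(a); foot = t* - p(t*)/p'(t*)
    u_star = a - np.sqrt(a)
    p = (u_star**a) * np.exp(a - u_star) / (a**a)
    dp = p * (a / u_star - 1.0) / theta
    foot = u_star * theta - p / dp
    return tpl, float(foot)


_FOOT_CACHE: dict[float, float] = {}


def _detector_foot_offset(fs: float) -> float:
    """Time from template start to the detector-reported tangent foot.

    The intersecting-tangents detector smooths the signal and its
    derivative (0.1 s moving averages), which shifts the apparent foot of
    the pulse relative to the continuous template's analytic foot.  The
    offset is measured once per sampling rate by detecting a single,
    noise-free rendered template; it is a deterministic function of fs.
    """
    if fs not in _FOOT_CACHE:
        from .preproc import SampledSignal, detect_pulse_arrivals
        tpl, _ = pulse_template(fs)
        x = np.zeros(int(14 * fs))
        i0 = int(round(6.0 * fs))
        x[i0:i0 + tpl.size] = tpl
        det = detect_pulse_arrivals(SampledSignal(x, fs=fs))
        if len(det) != 1:
            raise RuntimeError("foot calibration failed for fs=%g" % fs)
        _FOOT_CACHE[fs] = float(det.times[0] - i0 / fs)
    return _FOOT_CACHE[fs]


def gen_ppg(arrival_times: np.ndarray, fs: float,
            duration_s: float | None = None, amplitude: float = 1.0,
            snr_db: float | None = None,
            seed: int | None = None) -> np.ndarray:
    """PPG-like waveform: one pulse template per arrival time.

    The template is positioned so that its intersecting-tangents foot falls
    exactly on each arrival time; with no noise, a tangent-based arrival
    detector recovers the input times to within about a sample.
    """
    if fs < 64:
        raise ValueError("fs must be >= 64 Hz for pulse waveforms")
    arrival_times = np.asarray(arrival_times, dtype=float)
    tpl, _ = pulse_template(fs)
    foot = _detector_foot_offset(fs)
    if duration_s is None:
        duration_s = (arrival_times[-1] + 1.5) if arrival_times.size else 1.0
    n = int(round(duration_s * fs))
    x = np.zeros(n)
    if arrival_times.size and np.any(np.diff(arrival_times) < PULSE_RISE_S):
        warnings.warn("arrival times closer than the template rise time; "
                      "pulses will overlap strongly", stacklevel=2)
    for t_a in arrival_times:
        i0 = int(round((t_a - foot) * fs))
        lo = max(i0, 0)
        hi = min(i0 + tpl.size, n)
        if hi > lo:
            x[lo:hi] += amplitude * tpl[lo - i0:hi - i0]
    if snr_db is not None:
        x = _add_noise(x, snr_db, np.random.default_rng(seed))
    return x


def _add_noise(x: np.ndarray, snr_db: float,
               rng: np.random.Generator) -> np.ndarray:
    p_sig = np.mean(x**2)
    sd = np.sqrt(p_sig / 10 ** (snr_db / 10.0)) if p_sig > 0 else 0.0
    return x + rng.standard_normal(x.size) * sd


def gen_resp_flow(breath_times: np.ndarray, fs: float,
                  duration_s: float | None = None, amplitude: float = 1.0,
                  snr_db: float | None = None,
                  seed: int | None = None) -> np.ndarray:
    """Smooth respiratory-flow-like oscillation with maxima at breath_times.

    A monotone phase is interpolated through the breath times (one cycle
    per breath) and the waveform is its cosine, so each listed time is a
    local maximum.
    """
    if fs < 8:
        raise ValueError("fs must be >= 8 Hz for airflow waveforms")
    breath_times = np.asarray(breath_times, dtype=float)
    if duration_s is None:
        duration_s = (breath_times[-1] + 3.0) if breath_times.size else 1.0
    n = int(round(duration_s * fs))
    t = np.arange(n) / fs
    if breath_times.size == 0:
        return np.zeros(n)
    if breath_times.size == 1:
        period = 4.0
        knots = np.array([breath_times[0] - period, breath_times[0],
                          breath_times[0] + period])
        phases = 2 * np.pi * np.array([-1.0, 0.0, 1.0])
    else:
        first_iv = breath_times[1] - breath_times[0]
        last_iv = breath_times[-1] - breath_times[-2]
        knots = np.concatenate([[breath_times[0] - first_iv], breath_times,
                                [breath_times[-1] + last_iv]])
        phases = 2 * np.pi * np.arange(-1, breath_times.size + 1,
                                       dtype=float)
    # linear phase extrapolation beyond the knots
    phi = np.interp(t, knots, phases)
    left = t < knots[0]
    right = t > knots[-1]
    phi[left] = phases[0] + 2 * np.pi * (t[left] - knots[0]) / (knots[1] - knots[0])
    phi[right] = phases[-1] + 2 * np.pi * (t[right] - knots[-1]) / (knots[-1] - knots[-2])
    x = amplitude * np.cos(phi)
    if snr_db is not None:
        x = _add_noise(x, snr_db, np.random.default_rng(seed))
    return x


def gen_eeg(envelope_1hz: np.ndarray, fs: float, f_carrier: float = 10.0,
            snr_db: float | None = None,
            seed: int | None = None) -> np.ndarray:
    """EEG-like waveform: an alpha-band carrier amplitude-modulated by a
    1 Hz envelope, optionally plus broadband noise."""
    if fs < 64:
        raise ValueError("fs must be >= 64 Hz for EEG waveforms")
    envelope_1hz = np.asarray(envelope_1hz, dtype=float)
    if np.any(envelope_1hz < 0):
        raise ValueError("envelope must be non-negative")
    n = int(round(envelope_1hz.size * fs))
    t = np.arange(n) / fs
    # envelope value k applies to second [k, k+1); interpolate between
    # bin centres for smooth modulation
    centers = np.arange(envelope_1hz.size) + 0.5
    env = np.interp(t, centers, envelope_1hz)
    x = env * np.sin(2 * np.pi * f_carrier * t)
    if snr_db is not None:
        x = _add_noise(x, snr_db, np.random.default_rng(seed))
    return x


# ---------------------------------------------------------------------------
# whole-subject generation

def gen_hypnogram(stage_plan: list[tuple[str, float]],
                  lights_off: float = 0.0) -> Hypnogram:
    """Hypnogram from a plan of (stage, minutes) blocks; 30 s epochs."""
    if not stage_plan:
        raise ValueError("stage plan is empty")
    stages: list[str] = []
    for stage, minutes in stage_plan:
        n_ep = int(round(minutes * 60 / 30.0))
        if n_ep < 1:
            raise ValueError(f"stage block {stage!r} shorter than one epoch")
        stages.extend([stage] * n_ep)
    lights_on = lights_off + 30.0 * len(stages)
    return Hypnogram(stages, lights_off=lights_off, lights_on=lights_on,
                     start=lights_off)


@dataclass
class StageTargets:
    """Per-stage ground-truth scaling exponents for one interval kind."""

    alpha1: float = 0.8
    alpha2: float = 0.8


# Default per-stage exponent targets: persistent short-term dynamics in
# every stage, with long-term persistence high in wake/REM and reduced
# (more random-walk-breaking, weakly correlated) in non-REM sleep — the
# qualitative sleep-stage contrast these analyses are designed to resolve.
_DEFAULT_RRI_TARGETS = {
    "W": StageTargets(1.1, 1.0),
    "N2": StageTargets(0.9, 0.7),
    "N3": StageTargets(0.8, 0.6),
    "R": StageTargets(1.1, 1.0),
}


@dataclass
class SubjectConfig:
    """Recipe for a synthetic subject.

    The stage plan is a list of (stage, minutes) episodes.  Interval means
    and SDs are chosen at rest-typical values; generated intervals are
    clipped to their physiological validity windows so that the normality
    filters pass essentially all synthetic beats.
    """

    stage_plan: list[tuple[str, float]] = field(default_factory=lambda: [
        ("W", 10), ("N2", 40), ("N3", 30), ("N2", 20), ("R", 25),
        ("N2", 30), ("N3", 20), ("R", 30),
    ])
    rri_targets: dict[str, StageTargets] = field(
        default_factory=lambda: dict(_DEFAULT_RRI_TARGETS))
    bbi_targets: dict[str, StageTargets] = field(default_factory=dict)
    ptt_targets: dict[str, StageTargets] = field(default_factory=dict)
    eeg_targets: dict[str, StageTargets] = field(default_factory=dict)
    rri_mean: float = 0.9
    rri_sd: float = 0.05
    bbi_mean: float = 4.0
    bbi_sd: float = 0.35
    ptt_mean: float = 0.25
    ptt_sd: float = 0.015
    eeg_mean: float = 15.0
    eeg_sd: float = 4.0
    s_cross: float = 25.0
    default_targets: StageTargets = field(
        default_factory=lambda: StageTargets(0.9, 0.8))


@dataclass
class SyntheticSubject:
    """A complete in-memory subject with its generating ground truth."""

    hypnogram: Hypnogram
    r_times: np.ndarray
    pulse_times: np.ndarray
    breath_times: np.ndarray
    ptt_truth: np.ndarray
    eeg_envelope_truth: np.ndarray
    alpha_truth: dict[str, dict[str, tuple[float, float]]]
    seed: int | None = None
    clipped_fraction: dict[str, float] = field(default_factory=dict)
    subject_id: str = "synthetic"
    covariates: dict = field(default_factory=dict)


def _episode_intervals(targets: StageTargets, n: int, mean: float, sd: float,
                       window: tuple[float, float], s_cross: float,
                       rng: np.random.Generator) -> tuple[np.ndarray, int]:
    """Clipped interval noise with the stage's two-regime exponents."""
    n_gen = max(n, 64)
    if abs(targets.alpha1 - targets.alpha2) < 1e-12:
        x = gen_scaling_noise(ScalingNoiseSpec(targets.alpha1, n_gen,
                                               mean=mean, sd=sd), rng=rng)
    else:
        x = gen_crossover_noise(targets.alpha1, targets.alpha2,
                                min(s_cross, n_gen / 8 - 1e-9), n_gen,
                                mean=mean, sd=sd, rng=rng)
    lo, hi = window
    margin = 0.01 * (hi - lo)
    clipped = int(np.sum((x <= lo + margin) | (x >= hi - margin)))
    return np.clip(x, lo + margin, hi - margin)[:n], clipped


def gen_subject(config: SubjectConfig | None = None,
                seed: int | None = None) -> SyntheticSubject:
    """Compose a full synthetic subject from per-stage interval noise.

    Each planned episode receives its own interval series generated with
    the stage's (alpha1, alpha2) targets; event times accumulate within
    the episode.  Pulse arrivals are R times plus a transit-time series
    with its own targets; breath times and the 1 Hz EEG alpha-amplitude
    envelope are built the same way.  Ground truth (event times, transit
    times, envelope, per-stage exponent targets) is retained.
    """
    if config is None:
        config = SubjectConfig()
    if not config.stage_plan:
        raise ValueError("stage plan is empty")
    per_stage_min: dict[str, float] = {}
    for stage, minutes in config.stage_plan:
        per_stage_min[stage] = per_stage_min.get(stage, 0.0) + minutes
    for stage, total in per_stage_min.items():
        if stage != "N1" and total < 30:
            warnings.warn(
                f"stage {stage!r} has only {total:g} min in the plan; "
                "long-regime fits may be unreliable", stacklevel=2)
    rng = np.random.default_rng(seed)
    hyp = gen_hypnogram(config.stage_plan)

    def targets_for(table: dict[str, StageTargets], stage: str) -> StageTargets:
        return table.get(stage, config.default_targets)

    r_times: list[np.ndarray] = []
    breath_times: list[np.ndarray] = []
    ptt_vals: list[np.ndarray] = []
    eeg_env: list[np.ndarray] = []
    clipped = {"RRI": 0, "BBI": 0, "PTT": 0}
    totals = {"RRI": 0, "BBI": 0, "PTT": 0}
    t_cursor = hyp.lights_off
    for stage, minutes in config.stage_plan:
        dur = minutes * 60.0
        # heartbeat intervals
        n_beats = int(np.ceil(dur / config.rri_mean * 1.3)) + 8
        rri, c = _episode_intervals(
            targets_for(config.rri_targets, stage), n_beats,
            config.rri_mean, config.rri_sd, VALIDITY["RRI"],
            config.s_cross, rng)
        clipped["RRI"] += c
        totals["RRI"] += rri.size
        times = gen_event_times(rri, t0=t_cursor)
        times = times[times < t_cursor + dur]
        r_times.append(times)
        # transit times, one per beat
        ptt, c = _episode_intervals(
            targets_for(config.ptt_targets, stage), times.size,
            config.ptt_mean, config.ptt_sd, VALIDITY["PTT"],
            config.s_cross, rng)
        clipped["PTT"] += c
        totals["PTT"] += ptt.size
        ptt_vals.append(ptt[:times.size])
        # breath intervals
        n_br = int(np.ceil(dur / config.bbi_mean * 1.4)) + 8
        bbi, c = _episode_intervals(
            targets_for(config.bbi_targets, stage), n_br,
            config.bbi_mean, config.bbi_sd, VALIDITY["BBI"],
            config.s_cross, rng)
        clipped["BBI"] += c
        totals["BBI"] += bbi.size
        btimes = gen_event_times(bbi, t0=t_cursor)
        breath_times.append(btimes[btimes < t_cursor + dur])
        # EEG alpha-band envelope, one value per second
        n_sec = int(round(dur))
        tg = targets_for(config.eeg_targets, stage)
        env, _ = _episode_intervals(
            tg, n_sec, config.eeg_mean, config.eeg_sd,
            (0.05 * config.eeg_mean, 10.0 * config.eeg_mean),
            config.s_cross, rng)
        eeg_env.append(env)
        t_cursor += dur

    r_all = np.concatenate(r_times) if r_times else np.empty(0)
    ptt_all = np.concatenate(ptt_vals) if ptt_vals else np.empty(0)
    alpha_truth = {
        "RRI": {st: (targets_for(config.rri_targets, st).alpha1,
                     targets_for(config.rri_targets, st).alpha2)
                for st in per_stage_min},
        "BBI": {st: (targets_for(config.bbi_targets, st).alpha1,
                     targets_for(config.bbi_targets, st).alpha2)
                for st in per_stage_min},
        "PTT": {st: (targets_for(config.ptt_targets, st).alpha1,
                     targets_for(config.ptt_targets, st).alpha2)
                for st in per_stage_min},
        "EEG": {st: (targets_for(config.eeg_targets, st).alpha1,
                     targets_for(config.eeg_targets, st).alpha2)
                for st in per_stage_min},
    }
    return SyntheticSubject(
        hypnogram=hyp,
        r_times=r_all,
        pulse_times=r_all + ptt_all,
        breath_times=np.concatenate(breath_times) if breath_times else np.empty(0),
        ptt_truth=ptt_all,
        eeg_envelope_truth=np.concatenate(eeg_env) if eeg_env else np.empty(0),
        alpha_truth=alpha_truth,
        seed=seed,
        clipped_fraction={k: clipped[k] / totals[k] if totals[k] else 0.0
                          for k in clipped},
    )
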