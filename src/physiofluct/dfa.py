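"""Second-order detrended fluctuation analysis (DFA2) with two-regime fits.

DFA quantifies the fluctuation magnitude F(s) of the cumulated,
piecewise-detrended series as a function of window size s.  A power law
F(s) ~ s**alpha indicates scaling; for stationary long-range correlated
noise the exponent relates to the power-spectral exponent via
beta = 2*alpha - 1 and to the autocorrelation decay via gamma = 2*(1 - alpha).

The short-term exponent (alpha1) and long-term exponent (alpha2) are fitted
over fixed scale windows: 6-16 and 50-200 intervals (or seconds) for beat,
transit-time and 1 Hz EEG-amplitude series, and 4-16 / 12-50 breaths for
breath-to-breath intervals.  A fit is accepted only when its coefficient of
determination exceeds 0.9.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "FluctuationFunction",
    "ScalingFit",
    "profile",
    "dfa_fluct",
    "stage_fluct",
    "fit_exponent",
    "alpha12",
    "default_scales",
    "FIT_RANGES",
    "R2_GATE",
]

R2_GATE = 0.9

#: (short regime, long regime) scale windows per series kind.
#: Beat-indexed and 1 Hz series use 6-16 / 50-200; breath series use
#: 4-16 / 12-50 (short window widened because 6-16 s corresponds to fewer
#: breaths than second-order detrending can resolve).
FIT_RANGES: dict[str, tuple[tuple[float, float], tuple[float, float]]] = {
    "RRI": ((6, 16), (50, 200)),
    "PPI": ((6, 16), (50, 200)),
    "PTT": ((6, 16), (50, 200)),
    "EEG": ((6, 16), (50, 200)),
    "BBI": ((4, 16), (12, 50)),
}


@dataclass
class FluctuationFunction:
    """Fluctuation values F(s) on a grid of integer scales."""

    scales: np.ndarray
    F: np.ndarray
    order: int = 2
    kind: str | None = None
    stage: str | None = None
    weights_used: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.scales = np.asarray(self.scales, dtype=int)
        self.F = np.asarray(self.F, dtype=float)
        if self.scales.size != self.F.size:
            raise ValueError("scales and F must have equal length")
        if self.scales.size and np.any(np.diff(self.scales) <= 0):
            raise ValueError("scales must be strictly increasing")
        if self.scales.size and self.scales[0] < self.order + 2:
            raise ValueError(f"min scale must be >= order+2 = {self.order + 2}")
        if np.any(self.F < 0):
            raise ValueError("F must be non-negative")


@dataclass
class ScalingFit:
    """Log-log slope of F(s) over one scale regime."""

    alpha: float
    s_lo: float
    s_hi: float
    r2: float
    regime: str
    valid: bool = True
    n_points: int = 0
    accepted: bool = field(init=False)

    def __post_init__(self) -> None:
        self.accepted = bool(self.valid and self.r2 > R2_GATE)

    @property
    def beta(self) -> float:
        """Power-spectral exponent, beta = 2*alpha - 1."""
        return 2.0 * self.alpha - 1.0

    @property
    def gamma(self) -> float:
        """Autocorrelation decay exponent, gamma = 2*(1 - alpha)."""
        return 2.0 * (1.0 - self.alpha)


def profile(x: np.ndarray) -> np.ndarray:
    """Cumulated, mean-centred series ("profile"); its last value is ~0."""
    x = np.asarray(x, dtype=float)
    if x.size < 4:
        raise ValueError("series too short for a profile (need >= 4 values)")
    return np.cumsum(x - x.mean())


def default_scales(n: int, s_min: int = 4, num: int = 20) -> np.ndarray:
    """~`num` log-spaced integer scales from `s_min` to n//4, deduplicated."""
    s_max = n // 4
    if s_max < s_min:
        raise ValueError(f"series of length {n} supports no scale >= {s_min}")
    grid = np.geomspace(s_min, s_max, num)
    return np.unique(np.round(grid).astype(int))


def _window_msq(prof: np.ndarray, s: int, order: int) -> np.ndarray:
    """Per-window mean squared residual after polynomial detrending.

    Windows of length s are taken from both the start and the end of the
    profile so the leftover tail (when len(prof) % s != 0) is used too.
    """
    n = prof.size
    m = n // s
    # centred local coordinate for conditioning
    t = (np.arange(s) - (s - 1) / 2.0) / s
    A = np.vander(t, order + 1, increasing=True)  # (s, order+1)
    pinv = np.linalg.pinv(A)  # (order+1, s)
    fwd = prof[: m * s].reshape(m, s)
    bwd = prof[n - m * s:].reshape(m, s)
    Y = np.concatenate([fwd, bwd], axis=0).T  # (s, 2m)
    resid = Y - A @ (pinv @ Y)
    return np.mean(resid**2, axis=0)


def dfa_fluct(
    x: np.ndarray,
    scales: np.ndarray | None = None,
    order: int = 2,
    kind: str | None = None,
    stage: str | None = None,
) -> FluctuationFunction:
    """Detrended fluctuation function of a series.

    For each scale s the profile is split into non-overlapping windows of
    length s (taken from both ends of the profile, so no data are wasted
    when the length is not a multiple of s); an order-`order` polynomial is
    subtracted within each window and the remaining mean-square fluctuations
    are averaged:  F(s) = sqrt(<MSQ residual>).

    Scales with fewer than one full window, or below order+2, are dropped.
    """
    x = np.asarray(x, dtype=float)
    if scales is None:
        scales = default_scales(x.size)
    scales = np.unique(np.asarray(scales, dtype=int))
    scales = scales[(scales >= order + 2) & (scales <= x.size)]
    if scales.size == 0:
        raise ValueError("no usable scale for this series length")
    prof = profile(x)
    F = np.empty(scales.size)
    for i, s in enumerate(scales):
        F[i] = np.sqrt(np.mean(_window_msq(prof, int(s), order)))
    return FluctuationFunction(scales, F, order=order, kind=kind, stage=stage)


def stage_fluct(
    fragments: list[np.ndarray],
    durations: np.ndarray | list[float],
    scales: np.ndarray,
    order: int = 2,
    kind: str | None = None,
    stage: str | None = None,
) -> FluctuationFunction:
    """Episode-duration-weighted fluctuation function for one sleep stage.

    Each fragment (one stage episode's series) contributes its squared
    fluctuation function with statistical weight equal to the episode
    duration:  F_stage(s) = sqrt( sum_e w_e F_e(s)^2 / sum_e w_e ),
    restricted, per scale, to fragments long enough to be detrended there
    (at least s + order + 1 values).  Scales where no fragment qualifies
    are absent from the result.
    """
    durations = np.asarray(durations, dtype=float)
    fragments = [np.asarray(f, dtype=float) for f in fragments]
    if len(fragments) != durations.size:
        raise ValueError("one duration per fragment required")
    scales = np.unique(np.asarray(scales, dtype=int))
    scales = scales[scales >= order + 2]
    num = np.zeros(scales.size)
    den = np.zeros(scales.size)
    used_w = []
    for f, w in zip(fragments, durations):
        # a fragment enters scale s only with >= s + order + 1 values
        sc = scales[scales + order + 1 <= f.size]
        if sc.size == 0:
            continue
        ff = dfa_fluct(f, sc, order=order)
        pos = np.searchsorted(scales, ff.scales)
        num[pos] += w * ff.F**2
        den[pos] += w
        used_w.append(w)
    keep = den > 0
    return FluctuationFunction(
        scales[keep], np.sqrt(num[keep] / den[keep]), order=order,
        kind=kind, stage=stage, weights_used=np.asarray(used_w),
    )


def fit_exponent(F: FluctuationFunction, s_lo: float, s_hi: float,
                 regime: str = "short") -> ScalingFit:
    """OLS fit of log10 F on log10 s over scales in [s_lo, s_hi] (inclusive).

    Requires >= 3 scales in range; returns an invalid fit otherwise.  A flat
    fluctuation function (zero variance of log F) is assigned r^2 = 0 so it
    cannot pass the acceptance gate.
    """
    if s_lo >= s_hi:
        raise ValueError("s_lo must be < s_hi")
    mask = (F.scales >= s_lo) & (F.scales <= s_hi) & (F.F > 0)
    n_pts = int(mask.sum())
    if n_pts < 3:
        return ScalingFit(np.nan, s_lo, s_hi, 0.0, regime=regime,
                          valid=False, n_points=n_pts)
    lx = np.log10(F.scales[mask].astype(float))
    ly = np.log10(F.F[mask])
    slope, intercept = np.polyfit(lx, ly, 1)
    ss_tot = np.sum((ly - ly.mean()) ** 2)
    if ss_tot == 0.0:
        return ScalingFit(float(slope), s_lo, s_hi, 0.0, regime=regime,
                          valid=True, n_points=n_pts)
    ss_res = np.sum((ly - (slope * lx + intercept)) ** 2)
    r2 = 1.0 - ss_res / ss_tot
    return ScalingFit(float(slope), s_lo, s_hi, float(r2), regime=regime,
                      valid=True, n_points=n_pts)


def alpha12(F: FluctuationFunction,
            kind: str | None = None) -> tuple[ScalingFit, ScalingFit]:
    """Short- and long-regime scaling fits using the kind's fit windows."""
    kind = kind or F.kind
    if kind not in FIT_RANGES:
        raise ValueError(f"unknown series kind {kind!r}; expected one of "
                         f"{sorted(FIT_RANGES)}")
    (lo1, hi1), (lo2, hi2) = FIT_RANGES[kind]
    return (fit_exponent(F, lo1, hi1, regime="short"),
            fit_exponent(F, lo2, hi2, regime="long"))
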