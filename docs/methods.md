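# Methods

## The analysis model

The package treats a night of polysomnography as a set of event-indexed
or 1 Hz-sampled series — heartbeat intervals (RRI), pulse-wave intervals
(PPI), pulse transit times (PTT), breath-to-breath intervals (BBI), and
EEG alpha-band amplitudes — and characterises their temporal correlation
structure separately within each sleep stage with second-order detrended
fluctuation analysis (DFA2).

DFA2 cumulates the mean-centred series into a profile, splits the
profile into non-overlapping windows of length *s*, subtracts a
quadratic least-squares fit inside each window, and averages the
residual mean squares; the square root is the fluctuation function
F(*s*). Windows are taken from both the start and the end of the
profile, so the leftover tail when the length is not a multiple of *s*
is used rather than discarded (at these record lengths the forward-only
convention differs negligibly; the pooled convention is what the
implementation and its brute-force test oracle both use). For scaling
noise F(*s*) ∼ *s*^α; for stationary series α maps to the spectral
exponent by β = 2α − 1 and to the autocorrelation decay by γ = 2(1 − α).

Two effective exponents are fitted by ordinary least squares on the
log–log plot: α₁ over scales 6–16 and α₂ over 50–200 (intervals for beat
series, seconds for the 1 Hz EEG amplitude series). For BBI the long
window is 12–50 breaths. The BBI short window is not uniquely implied by
the 6–16 s convention (6–16 s is fewer breaths than a second-order
polynomial window can resolve); the default is 4–16 breaths and it is
configurable — results for BBI α₁ should be interpreted with that choice
in mind. A fit needs at least three scale points in its window and is
*accepted* only when its coefficient of determination exceeds 0.9; a
flat fluctuation function is assigned r² = 0 by convention so it cannot
pass the gate.

Stage-level fluctuation functions combine episodes with statistical
weights equal to episode duration. The weighted average is taken on F²
(the variance-like, additive quantity), not on F; averaging F directly
would change results by well under the fit tolerances but F² is the
principled choice and the behaviour is covered by an arithmetic unit
test. At scale *s* an episode fragment contributes only if it holds at
least *s* + 3 values (a quadratic needs three degrees of freedom beyond
the window length); scales where no fragment qualifies are absent.

## Preprocessing decisions

Moving averages use centred windows that shrink (truncate) at the
boundaries, so no NaNs enter the detectors. The pulse-arrival detector
follows the intersecting-tangents geometry: offset correction (3 s
moving average subtracted), 0.1 s smoothing, smoothed first derivative;
candidate upstrokes are runs where the derivative exceeds 30 % of its
90th percentile — computed over the positive part of the derivative so
sparse signals with long flat stretches keep a meaningful threshold —
and the arrival is the intersection of the tangent at the maximal-slope
point with the horizontal through the preceding local minimum. The
breath detector subtracts a 10 s moving average, smooths with a 1 s
moving average, and picks local maxima with a 1.5 s refractory spacing
(below the 2 s BBI validity floor, so it never pre-empts the interval
filter). The 1 Hz reduction of the Hilbert alpha-band amplitude is the
mean of the instantaneous amplitudes within each second (configurable to
first-sample); the mean is robust to carrier phase.

## Interval filtering decisions

All validity comparisons are strict, exactly as the bounds are printed
(330/2000 ms, 2/8 s, ratios 0.7/1.6, PTT window 0.1–0.8 s). The ratio
rule's reference is the previous **accepted** interval by default
(configurable to previous raw): a single artifact then cannot cascade
into rejecting its valid successors. The first interval of a recording
has no predecessor, so only the absolute bounds apply to it. For PTT,
the earliest pulse arrival inside the window is taken (later in-window
peaks are treated as reflections), each arrival is used at most once,
and an unmatched R peak breaks the stitched segment. Increment
statistics (RMSSD-style) are pooled over stitched segments but never
straddle a gap or an episode boundary; the increment statistic is the
root mean square of successive differences, the standard
heart-rate-variability definition of RMSSD. Means and SDs use the
population convention (ddof 0).

Re-filtering an already-filtered series never changes values or
timestamps; segment labels can only merge, because gap positions are not
encoded in the surviving values — this is the precise form of the
idempotence property the tests assert.

## Synthetic data: what it emulates and what it does not

The noise generator uses Fourier spectral synthesis: white Gaussian
noise is shaped by f^(−β/2) with β = 2α − 1, the DC bin zeroed, and the
inverse transform rescaled to the requested mean and SD. Two-regime
noise uses a piecewise power-law amplitude spectrum, continuous at the
break frequency 1/s_cross; ensemble checks confirm that with this direct
placement the 6–16 and 50–200 fit windows recover both exponents within
their tolerances for a crossover at scale 30, so no empirical shift
factor is applied. Valid target exponents are 0.1 < α < 1.5, the range
where this stationary-increment synthesis is meaningful.

Synthetic subjects compose per-episode interval series (per-stage α₁/α₂
targets; defaults encode persistent short-term dynamics everywhere with
long-term persistence high in wake/REM and reduced in non-REM), clipped
just inside the physiological validity windows so the normality filters
pass ≥ 99 % of beats (the clipped fraction is recorded on the subject).
Rest-typical levels are used: RRI 0.90 ± 0.05 s, BBI 4.0 ± 0.35 s,
PTT 0.25 ± 0.015 s, EEG envelope 15 ± 4 (arbitrary amplitude units).
Waveform rendering superposes a gamma-shaped pulse template (80 ms rise)
at each arrival, a phase-interpolated cosine for airflow, and an
amplitude-modulated 10 Hz carrier for EEG, each with additive white
Gaussian noise at a configurable SNR (default 20 dB). The pulse template
is positioned so that its intersecting-tangents foot — measured once per
sampling rate through the detector's own smoothing chain — falls exactly
on the nominal arrival time; the zero-noise round trip is then accurate
to within about one sample.

What the generator does **not** emulate: ECG morphology (R times are
events, not waveforms), pulse-wave amplitude or shape changes, apnea
events, movement artifacts, electrode noise, or non-stationarity within
an episode beyond the prescribed power law. Passing tests therefore
demonstrate that the chain recovers known scaling structure through
detection, filtering, stitching and staging — not that any specific
physiological effect size in real recordings is reproduced.

## Cohort aggregation

Group summaries average accepted exponents only (mean, standard error
sd/√n with the sample convention, cell count n, total cell size so
exclusions are visible); an n = 1 cell reports se = 0 with a flag. Age
bins are literal decades (10·⌊age/10⌋); BMI classes are <25, 25–30, >30
kg/m²; AHI classes are <5, 5–15, 15–30, >30 events/h. Exponents are
always reported per stage; no duration-weighted whole-night average
across stages is ever produced. Subjects missing a grouping covariate
are skipped for that grouping and logged. Multivariable regression and
significance testing over clinical covariates are out of scope.

## Problem sizes and determinism

Unit and acceptance checks run on series of 2¹⁶–2¹⁷ samples with 20–50
seed ensembles and synthetic nights of 70–215 minutes; the full suite
completes in well under a minute of compute. Every generator and the
whole pipeline are pure functions of their seeds and configuration;
rerunning a pipeline config reproduces its output tables bytewise.
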