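"""Per-subject orchestration and cohort aggregation.

``analyze_subject`` runs the full chain for every available channel —
crop to the lights window, detect events, build and filter interval
series, slice by sleep-stage episode, episode-weighted DFA2, two-regime
exponent fits with the r² > 0.9 acceptance gate — and returns one tidy
row per (signal kind, stage).  ``aggregate`` averages subject rows over
cohort grouping keys (10-year age bins, sex, BMI class, smoking, alcohol,
AHI class) using accepted exponents only.  Exponents are always reported
per stage; no weighted whole-night average across stages is ever formed.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__ as _pkg_version
from .dfa import FIT_RANGES, alpha12, stage_fluct
from .intervals import (IntervalSeries, filter_intervals,
                        intervals_from_events, match_ptt, series_stats)
from .preproc import (SampledSignal, detect_breath_maxima,
                      detect_pulse_arrivals, detect_r_peaks,
                      eeg_alpha_amplitude)
from .staging import (ANALYZED_STAGES, Hypnogram, crop_to_lights,
                      slice_by_episode, stage_episodes)
from .synth import StageTargets, SubjectConfig, SyntheticSubject, gen_subject

logger = logging.getLogger("physiofluct")

__all__ = [
    "SubjectBundle", "AnalysisConfig", "analyze_subject", "aggregate",
    "run_pipeline", "bundle_from_synthetic", "stage_scales",
    "RESULT_COLUMNS",
]

RESULT_COLUMNS = [
    "subject", "signal", "stage", "n_values", "n_episodes",
    "mean", "sd", "sd_increments",
    "alpha1", "r2_1", "accepted1", "alpha2", "r2_2", "accepted2",
]


@dataclass
class SubjectBundle:
    """Everything known about one subject's night.

    Event times, when provided, take precedence over raw waveforms; raw
    waveforms are run through the matching detector.
    """

    subject_id: str
    hypnogram: Hypnogram
    r_times: np.ndarray | None = None
    pulse_times: np.ndarray | None = None
    breath_times: np.ndarray | None = None
    eeg_amplitude: SampledSignal | None = None  # precomputed 1 Hz series
    ecg: SampledSignal | None = None
    ppg: SampledSignal | None = None
    flow: SampledSignal | None = None
    eeg: SampledSignal | None = None
    covariates: dict = field(default_factory=dict)


@dataclass
class AnalysisConfig:
    """Configurable decisions of the analysis chain."""

    ratio_ref: str = "accepted"      # interval-filter predecessor convention
    eeg_reducer: str = "mean"        # 1 Hz reduction of Hilbert amplitudes
    dfa_order: int = 2
    signals: tuple[str, ...] = ("RRI", "PPI", "PTT", "BBI", "EEG")
    min_stage_values: int = 10       # below this, skip the stage entirely


def stage_scales(kind: str) -> np.ndarray:
    """Log-spaced integer DFA scale grid covering both fit windows."""
    if kind == "BBI":
        grid = np.geomspace(4, 80, 18)
    else:
        grid = np.geomspace(4, 220, 26)
    return np.unique(np.round(grid).astype(int))


def _event_series(bundle: SubjectBundle) -> dict[str, np.ndarray]:
    """Resolve event times for each channel, detecting where needed."""
    out: dict[str, np.ndarray] = {}
    if bundle.r_times is not None:
        out["r"] = np.asarray(bundle.r_times, dtype=float)
    elif bundle.ecg is not None:
        out["r"] = detect_r_peaks(bundle.ecg).times
    if bundle.pulse_times is not None:
        out["pulse"] = np.asarray(bundle.pulse_times, dtype=float)
    elif bundle.ppg is not None:
        out["pulse"] = detect_pulse_arrivals(bundle.ppg).times
    if bundle.breath_times is not None:
        out["breath"] = np.asarray(bundle.breath_times, dtype=float)
    elif bundle.flow is not None:
        out["breath"] = detect_breath_maxima(bundle.flow).times
    return out


def _interval_inputs(bundle: SubjectBundle,
                     config: AnalysisConfig) -> dict[str, IntervalSeries | SampledSignal]:
    """Cropped, filtered series per signal kind."""
    hyp = bundle.hypnogram
    ev = _event_series(bundle)
    out: dict[str, IntervalSeries | SampledSignal] = {}

    def cropped(name: str) -> np.ndarray | None:
        if name not in ev:
            return None
        return crop_to_lights(ev[name], hyp)

    r = cropped("r")
    pulse = cropped("pulse")
    breath = cropped("breath")
    if "RRI" in config.signals and r is not None:
        out["RRI"] = filter_intervals(*intervals_from_events(r), "RRI",
                                      ratio_ref=config.ratio_ref)
    if "PPI" in config.signals and pulse is not None:
        out["PPI"] = filter_intervals(*intervals_from_events(pulse), "PPI",
                                      ratio_ref=config.ratio_ref)
    if "PTT" in config.signals and r is not None and pulse is not None:
        out["PTT"] = match_ptt(r, pulse)
    if "BBI" in config.signals and breath is not None:
        out["BBI"] = filter_intervals(*intervals_from_events(breath), "BBI",
                                      ratio_ref=config.ratio_ref)
    if "EEG" in config.signals:
        amp = bundle.eeg_amplitude
        if amp is None and bundle.eeg is not None:
            amp = eeg_alpha_amplitude(bundle.eeg, reducer=config.eeg_reducer)
        if amp is not None:
            out["EEG"] = crop_to_lights(amp, hyp)
    return out


def _merge_fragments(frags: list[IntervalSeries], kind: str) -> IntervalSeries:
    """Concatenate episode fragments with segment ids kept distinct, so
    increment statistics never straddle an episode boundary or a gap."""
    vals, times, segs = [], [], []
    offset = 0
    for f in frags:
        if len(f) == 0:
            continue
        vals.append(f.values)
        times.append(f.times)
        segs.append(f.segment_id - f.segment_id.min() + offset)
        offset = segs[-1].max() + 1
    if not vals:
        return IntervalSeries(np.empty(0), np.empty(0),
                              np.empty(0, dtype=int), kind=kind)
    return IntervalSeries(np.concatenate(vals), np.concatenate(times),
                          np.concatenate(segs), kind=kind)


def analyze_subject(bundle: SubjectBundle,
                    config: AnalysisConfig | None = None) -> pd.DataFrame:
    """Full per-subject analysis; one row per (signal kind, sleep stage).

    Stages without usable data produce no row.  Exponent fits failing the
    r² > 0.9 gate are reported with ``accepted`` False; downstream
    aggregation excludes them but they remain visible per subject.
    """
    config = config or AnalysisConfig()
    if bundle.hypnogram is None:
        raise ValueError("a hypnogram is required")
    episodes = stage_episodes(bundle.hypnogram)
    series = _interval_inputs(bundle, config)
    rows = []
    for kind, data in series.items():
        for stage in ANALYZED_STAGES:
            eps = [ep for ep in episodes if ep.stage == stage]
            if not eps:
                continue
            if isinstance(data, IntervalSeries):
                frags = [slice_by_episode(data, ep) for ep in eps]
                frag_values = [f.values for f in frags]
                merged = _merge_fragments(frags, kind)
                n_vals = len(merged)
                stats = series_stats(merged) if n_vals >= 2 else None
            else:  # 1 Hz EEG amplitude series
                frag_sig = [slice_by_episode(data, ep) for ep in eps]
                frag_values = [np.asarray(f.values) for f in frag_sig]
                all_vals = (np.concatenate(frag_values)
                            if frag_values else np.empty(0))
                n_vals = all_vals.size
                stats = None
                if n_vals >= 2:
                    incs = [np.diff(v) for v in frag_values if v.size >= 2]
                    d = np.concatenate(incs) if incs else np.empty(0)
                    stats = type("S", (), {})()
                    stats.mean = float(all_vals.mean())
                    stats.sd = float(all_vals.std())
                    stats.sd_increments = (float(np.sqrt(np.mean(d**2)))
                                           if d.size else np.nan)
            if n_vals < config.min_stage_values:
                logger.info("subject %s: %s/%s has only %d values; skipped",
                            bundle.subject_id, kind, stage, n_vals)
                continue
            F = stage_fluct(frag_values, [ep.duration for ep in eps],
                            stage_scales(kind), order=config.dfa_order,
                            kind=kind, stage=stage)
            fit1, fit2 = alpha12(F, kind)
            rows.append({
                "subject": bundle.subject_id, "signal": kind, "stage": stage,
                "n_values": n_vals, "n_episodes": len(eps),
                "mean": stats.mean if stats else np.nan,
                "sd": stats.sd if stats else np.nan,
                "sd_increments": stats.sd_increments if stats else np.nan,
                "alpha1": fit1.alpha, "r2_1": fit1.r2,
                "accepted1": fit1.accepted,
                "alpha2": fit2.alpha, "r2_2": fit2.r2,
                "accepted2": fit2.accepted,
            })
    df = pd.DataFrame(rows, columns=RESULT_COLUMNS)
    for cov, val in bundle.covariates.items():
        df[cov] = val
    return df


# ---------------------------------------------------------------------------
# cohort aggregation

def _age_bin(age: float) -> str:
    lo = int(10 * np.floor(age / 10.0))
    return f"{lo}-{lo + 9}"


def _bmi_class(bmi: float) -> str:
    if bmi < 25:
        return "<25"
    if bmi <= 30:
        return "25-30"
    return ">30"


def _ahi_class(ahi: float) -> str:
    if ahi < 5:
        return "<5"
    if ahi < 15:
        return "5-15"
    if ahi < 30:
        return "15-30"
    return ">30"


_GROUPERS = {
    "age": _age_bin,
    "bmi": _bmi_class,
    "ahi": _ahi_class,
    "sex": str,
    "smoking": str,
    "alcohol": str,
}


def aggregate(results: pd.DataFrame, by: str) -> pd.DataFrame:
    """Group means with standard errors per (signal, stage, group cell).

    Exponent cells use accepted fits only (mean, se = sd/sqrt(n), n);
    ``n_total`` counts all subjects in the cell so the number of excluded
    fits is visible.  Subjects missing the grouping covariate are skipped.
    An n = 1 cell reports se = 0 with the ``single`` flag set.
    """
    if by not in _GROUPERS:
        raise ValueError(f"unknown grouping key {by!r}; "
                         f"expected one of {sorted(_GROUPERS)}")
    if by not in results.columns:
        raise ValueError(f"results carry no {by!r} covariate")
    df = results.dropna(subset=[by]).copy()
    df["group"] = df[by].map(_GROUPERS[by])
    out = []
    for (signal, stage, group), cell in df.groupby(["signal", "stage",
                                                    "group"]):
        for metric, acc in (("alpha1", "accepted1"), ("alpha2", "accepted2")):
            vals = cell.loc[cell[acc].astype(bool), metric].to_numpy(float)
            vals = vals[np.isfinite(vals)]
            n = vals.size
            row = {"signal": signal, "stage": stage, "group": group,
                   "metric": metric, "n": n, "n_total": len(cell),
                   "single": n == 1}
            if n == 0:
                row.update(mean=np.nan, se=np.nan)
            elif n == 1:
                row.update(mean=float(vals[0]), se=0.0)
            else:
                row.update(mean=float(vals.mean()),
                           se=float(vals.std(ddof=1) / np.sqrt(n)))
            out.append(row)
    return pd.DataFrame(out, columns=["signal", "stage", "group", "metric",
                                      "mean", "se", "n", "n_total",
                                      "single"])


# ---------------------------------------------------------------------------
# end-to-end runs

def bundle_from_synthetic(subj: SyntheticSubject,
                          use_waveforms: bool = False,
                          fs_ppg: float = 128.0, fs_flow: float = 32.0,
                          fs_eeg: float = 128.0,
                          snr_db: float | None = 20.0) -> SubjectBundle:
    """Subject bundle from a synthetic subject.

    With ``use_waveforms`` the pulse, airflow and EEG channels are
    rendered as sampled waveforms (default SNR 20 dB) and re-detected by
    the preprocessing chain; otherwise the ground-truth event times and
    envelope enter the analysis directly.
    """
    hyp = subj.hypnogram
    if not use_waveforms:
        return SubjectBundle(
            subject_id=subj.subject_id, hypnogram=hyp,
            r_times=subj.r_times, pulse_times=subj.pulse_times,
            breath_times=subj.breath_times,
            eeg_amplitude=SampledSignal(subj.eeg_envelope_truth, fs=1.0,
                                        t0=hyp.lights_off),
            covariates=dict(subj.covariates))
    from .synth import gen_eeg, gen_ppg, gen_resp_flow
    dur = hyp.end - hyp.lights_off
    seed = subj.seed if subj.seed is not None else 0
    ppg = SampledSignal(
        gen_ppg(subj.pulse_times - hyp.lights_off, fs_ppg, duration_s=dur,
                snr_db=snr_db, seed=seed + 101), fs=fs_ppg, t0=hyp.lights_off)
    flow = SampledSignal(
        gen_resp_flow(subj.breath_times - hyp.lights_off, fs_flow,
                      duration_s=dur, snr_db=snr_db, seed=seed + 102),
        fs=fs_flow, t0=hyp.lights_off)
    eeg = SampledSignal(
        gen_eeg(subj.eeg_envelope_truth, fs_eeg, snr_db=snr_db,
                seed=seed + 103), fs=fs_eeg, t0=hyp.lights_off)
    return SubjectBundle(
        subject_id=subj.subject_id, hypnogram=hyp, r_times=subj.r_times,
        ppg=ppg, flow=flow, eeg=eeg, covariates=dict(subj.covariates))


def _random_covariates(rng: np.random.Generator) -> dict:
    return {
        "age": float(rng.uniform(20, 80)),
        "sex": str(rng.choice(["F", "M"])),
        "bmi": float(np.clip(rng.normal(28, 6), 17, 52)),
        "smoking": str(rng.choice(["no", "yes"], p=[0.75, 0.25])),
        "alcohol": str(rng.choice(["none", "moderate", "regular"])),
        "ahi": float(rng.exponential(12)),
    }


def run_pipeline(config: dict | str | Path, out_dir) -> dict:
    """Run a full (synthetic) cohort analysis and write result tables.

    The config (dict or YAML path) lists either a synthetic cohort
    (``n_subjects``, ``seed``, optional generator settings) or explicit
    subject bundle directories.  Writes ``subject_results.csv``, one
    ``group_<key>.csv`` per requested grouping, and ``run_log.json``
    recording the seed, package version and every configurable decision.
    Failures of individual subjects are logged and isolated.
    """
    if not isinstance(config, dict):
        import yaml
        config = yaml.safe_load(Path(config).read_text())
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    analysis = AnalysisConfig(**config.get("analysis", {}))
    groupings = config.get("groupings", ["age"])
    bundles: list[SubjectBundle] = []
    if "subjects" in config:  # directories of per-subject CSV bundles
        from .io import read_subject
        for d in config["subjects"]:
            subj = read_subject(d)
            bundles.append(bundle_from_synthetic(subj))
    else:
        n_sub = int(config.get("n_subjects", 5))
        if n_sub < 1:
            raise ValueError("n_subjects must be >= 1")
        seed = int(config.get("seed", 0))
        use_wave = bool(config.get("use_waveforms", False))
        ss = np.random.SeedSequence(seed)
        for i, child in enumerate(ss.spawn(n_sub)):
            sub_seed = int(child.generate_state(1, np.uint32)[0] % (2**31))
            subj_cfg = _subject_config_from(config.get("subject", {}))
            subj = gen_subject(subj_cfg, seed=sub_seed)
            subj.subject_id = f"synth{i:03d}"
            subj.covariates = _random_covariates(
                np.random.default_rng(sub_seed + 7))
            bundles.append(bundle_from_synthetic(subj,
                                                 use_waveforms=use_wave))
    frames = []
    failures = []
    for b in bundles:
        try:
            frames.append(analyze_subject(b, analysis))
        except Exception as exc:  # isolate per-subject failures
            logger.exception("subject %s failed", b.subject_id)
            failures.append({"subject": b.subject_id, "error": str(exc)})
    if not frames:
        raise RuntimeError("no subject produced results")
    results = pd.concat(frames, ignore_index=True)
    results.to_csv(out / "subject_results.csv", index=False,
                   float_format="%.10g")
    written = {"subject_results": str(out / "subject_results.csv")}
    for key in groupings:
        if key in results.columns:
            table = aggregate(results, key)
            path = out / f"group_{key}.csv"
            table.to_csv(path, index=False, float_format="%.10g")
            written[f"group_{key}"] = str(path)
        else:
            logger.warning("grouping %s skipped: covariate absent", key)
    log = {
        "version": _pkg_version,
        "config": {k: v for k, v in config.items()},
        "analysis": vars(analysis) | {"signals": list(analysis.signals)},
        "fit_ranges": {k: [list(r) for r in v] for k, v in FIT_RANGES.items()},
        "n_subjects": len(bundles),
        "failures": failures,
        "outputs": written,
    }
    (out / "run_log.json").write_text(json.dumps(log, indent=1, default=str))
    return {"results": results, "outputs": written, "failures": failures}


def _subject_config_from(cfg: dict) -> SubjectConfig:
    kwargs = dict(cfg)
    if "stage_plan" in kwargs:
        kwargs["stage_plan"] = [(s, float(m)) for s, m in kwargs["stage_plan"]]
    for key in ("rri_targets", "bbi_targets", "ptt_targets", "eeg_targets"):
        if key in kwargs:
            kwargs[key] = {st: StageTargets(*v)
                           for st, v in kwargs[key].items()}
    return SubjectConfig(**kwargs)
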