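"""Slice electrophysiology analysis.

Cell-attached template spike detection with artifact, noise and
relative-peak exclusion rules; current-clamp action-potential detection on
voltage velocity; AP/AHP feature extraction against a sliding mean
baseline; firing input-output curves with response-duration
normalization; rheobase search at 10 pA resolution; passive membrane
properties from subthreshold test pulses; paired-pulse ratio and
spontaneous-EPSC summaries.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import log2

import numpy as np
from scipy import optimize, signal
from scipy.ndimage import uniform_filter1d

from .core import Template, Trace
from .imaging import EventList, correlation_scores

__all__ = [
    "Sweep",
    "APFeatures",
    "IOCurve",
    "PassiveProps",
    "detect_aps_cell_attached",
    "detect_aps_current_clamp",
    "ap_features",
    "firing_io_curve",
    "rheobase",
    "passive_props",
    "ppr",
    "sepsc_summary",
]

#: post-stimulus analysis windows (s) by putative cell type
DETECTION_WINDOWS = {"FSI": (0.001, 0.100), "SPN": (0.001, 0.600)}


@dataclass
class Sweep:
    """One recorded sweep with its stimulus/step metadata."""

    trace: Trace
    stimulus_time: float = 0.0
    cell_type: str = "FSI"
    step_amplitude: float | None = None  # pA, current clamp
    step_onset: float | None = None  # s
    step_duration: float | None = None  # s

    def __post_init__(self) -> None:
        t_end = self.trace.t0 + self.trace.duration
        if not (self.trace.t0 <= self.stimulus_time <= t_end):
            raise ValueError("stimulus_time must lie within the sweep")


@dataclass
class APFeatures:
    """Action-potential and afterhyperpolarization features of one spike.

    Times are in seconds, voltages in mV; ``ahp_integral`` is the AHP
    waveform integrated over the sliding baseline (mV·s) and
    ``ahp_current`` its amplitude converted to pA through the input
    resistance.
    """

    onset: float
    peak: float
    offset: float
    half_width: float
    amplitude: float
    ahp_onset: float
    ahp_offset: float
    ahp_amplitude: float
    ahp_integral: float
    ahp_current: float

    def __post_init__(self) -> None:
        if not (self.onset < self.peak < self.offset <= self.ahp_onset < self.ahp_offset):
            raise ValueError("feature times must be ordered onset < peak < offset <= AHP")
        if self.half_width <= 0:
            raise ValueError("half_width must be positive")


@dataclass
class IOCurve:
    """Firing input-output relation over a series of current steps."""

    step_amplitudes: np.ndarray  # pA
    rates: np.ndarray  # Hz, spikes / step duration
    response_durations: np.ndarray  # s, first-to-last AP peak
    normalized_rates: np.ndarray  # Hz, spikes / response duration

    @property
    def max_response_duration(self) -> float:
        return float(np.max(self.response_durations)) if self.response_durations.size else 0.0


@dataclass
class PassiveProps:
    """Passive membrane properties from a subthreshold test pulse."""

    r_in: float  # MΩ
    c_m: float  # pF
    r_s: float  # MΩ
    excluded: bool  # series resistance above the 30 MΩ ceiling


def detect_aps_cell_attached(
    sweep: Sweep,
    template: Template,
    threshold_frac: float = 0.25,
    window: tuple[float, float] | None = None,
    noise_k: float = 10.0,
    peak_frac: float = 0.25,
) -> EventList:
    """Template cross-correlation spike detection in a cell-attached sweep.

    Candidate events are running-dot-product maxima scoring at least
    ``threshold_frac`` of the template's perfect fit, restricted to the
    post-stimulus window (1-100 ms for FSIs, 1-600 ms for SPNs).  Events
    are rejected when their absolute amplitude is below ``noise_k`` times
    the sweep noise SD (computed with the stimulus artifact span blanked)
    or when their score falls below ``peak_frac`` of the sweep's maximum
    score.
    """
    if window is None:
        if sweep.cell_type not in DETECTION_WINDOWS:
            raise ValueError(f"no default window for cell type {sweep.cell_type!r}")
        window = DETECTION_WINDOWS[sweep.cell_type]
    tr = sweep.trace
    w0 = sweep.stimulus_time + window[0]
    w1 = sweep.stimulus_time + window[1]
    if w1 > tr.t0 + tr.duration:
        raise ValueError("detection window extends past the sweep")

    tmpl = template.resampled(tr.dt)
    scores = correlation_scores(tr, tmpl)
    # noise SD with ±1 ms around the stimulus blanked
    times = tr.times
    artifact = np.abs(times - sweep.stimulus_time) <= 0.001
    noise_sd = float(np.std(tr.values[~artifact]))

    peaks, _ = signal.find_peaks(scores)
    if scores.size >= 2 and scores[0] > scores[1]:
        peaks = np.concatenate([[0], peaks])
    peaks = peaks[scores[peaks] >= threshold_frac]
    if peaks.size:
        max_score = float(scores[peaks].max())
        peaks = peaks[scores[peaks] >= peak_frac * max_score]
    kept_t, kept_s = [], []
    half_span = tmpl.values.size
    for p in peaks:
        t = tr.t0 + p * tr.dt
        if not (w0 <= t <= w1):
            continue
        seg = tr.values[p : p + half_span]
        amp = float(np.max(np.abs(seg))) if seg.size else 0.0
        if noise_sd > 0 and amp < noise_k * noise_sd:
            continue
        kept_t.append(t)
        kept_s.append(float(scores[p]))
    return EventList(
        trial_id="",
        stimulus_time=sweep.stimulus_time,
        event_times=np.asarray(kept_t),
        scores=np.asarray(kept_s),
        evoked=np.ones(len(kept_t), dtype=bool),
    )


def detect_aps_current_clamp(
    v: Trace, dvdt_threshold: float = 1e4, min_distance: float = 0.002
) -> np.ndarray:
    """AP peak times from voltage velocity.

    Spikes are peaks of dV/dt above ``dvdt_threshold`` (V/s) separated by
    at least ``min_distance`` seconds (the larger peak wins); each is then
    refined to the voltage maximum within 2 ms.
    """
    dist = int(round(min_distance / v.dt))
    if dist < 2:
        raise ValueError("sampling too coarse to resolve the minimum peak distance")
    dvdt = np.gradient(v.values, v.dt) * 1e-3  # mV/s -> V/s
    peaks, _ = signal.find_peaks(dvdt, height=dvdt_threshold, distance=dist)
    ap_times = []
    for p in peaks:
        w = v.values[p : p + dist]
        ap_times.append(v.t0 + (p + int(np.argmax(w))) * v.dt)
    return np.asarray(sorted(set(ap_times)))


def _crossing(t0: float, t1: float, a: float, b: float) -> float:
    """Linear-interpolated zero crossing between samples (a, b)."""
    if a == b:
        return t0
    return t0 + (t1 - t0) * (-a) / (b - a)


def sliding_baseline(v: Trace, step_duration: float) -> np.ndarray:
    """Sliding mean baseline: centered moving average whose window is 10%
    of the current-injection length."""
    w = max(1, int(round(0.1 * step_duration / v.dt)))
    return uniform_filter1d(v.values, size=w, mode="nearest")


def ap_features(
    v: Trace,
    ap_peak: float,
    step: tuple[float, float],
    r_in: float,
    baseline: np.ndarray | None = None,
) -> APFeatures:
    """AP and AHP features of the spike peaking at ``ap_peak``.

    Onset and offset are the waveform's intersections with the sliding
    mean baseline before and after the peak; AHP onset/offset are the next
    two intersections after the peak (the AHP starts where the AP ends).
    Half-width is half the onset-to-peak time; amplitude is peak voltage
    over baseline.  The AHP amplitude (most negative voltage over
    baseline), its integral and its current equivalent through ``r_in``
    (MΩ) are measured between the AHP bounds.  ``baseline`` overrides the
    sliding mean with a precomputed baseline array (same length as the
    sweep).
    """
    onset_t, dur = step
    if not (onset_t <= ap_peak <= onset_t + dur):
        raise ValueError("AP peak must lie inside the current step")
    base = sliding_baseline(v, dur) if baseline is None else np.asarray(baseline, float)
    rel = v.values - base
    times = v.times
    ip = int(np.argmin(np.abs(times - ap_peak)))
    if rel[ip] <= 0:
        raise ValueError("no depolarization above baseline at the AP peak")

    # onset: last point at or below baseline before the peak
    idx = np.nonzero(rel[: ip + 1] <= 0)[0]
    if idx.size == 0:
        raise ValueError("no baseline crossing before the AP peak")
    i_on = idx[-1]
    onset = _crossing(times[i_on], times[i_on + 1], rel[i_on], rel[i_on + 1])
    # offset: first point at or below baseline after the peak
    idx = np.nonzero(rel[ip:] <= 0)[0]
    if idx.size == 0:
        raise ValueError("no baseline crossing after the AP peak")
    i_off = ip + idx[0]
    offset = _crossing(times[i_off - 1], times[i_off], rel[i_off - 1], rel[i_off])
    # the AHP is the hyperpolarized stretch that follows; it ends at the
    # first return to (or above) baseline after its trough
    neg = np.nonzero(rel[i_off:] < 0)[0]
    if neg.size == 0:
        raise ValueError("no afterhyperpolarization after the AP offset")
    i_neg = i_off + neg[0]
    rest = rel[i_neg:]
    i_tr = i_neg + int(np.argmin(rest))
    ret = np.nonzero(rel[i_tr:] >= 0)[0]
    if ret.size == 0:
        raise ValueError("AHP does not return to baseline within the sweep")
    i_ret = i_tr + ret[0]
    ahp_offset = _crossing(times[i_ret - 1], times[i_ret], rel[i_ret - 1], rel[i_ret])

    span = slice(i_off, i_ret + 1)
    ahp_amplitude = float(np.min(rel[span])) if rel[span].size else 0.0
    ahp_integral = float(np.trapezoid(np.minimum(rel[span], 0.0), dx=v.dt))
    if r_in <= 0:
        raise ValueError("input resistance must be positive")
    ahp_current = 1000.0 * ahp_amplitude / r_in  # mV / MΩ -> pA
    return APFeatures(
        onset=onset,
        peak=float(times[ip]),
        offset=offset,
        half_width=(float(times[ip]) - onset) / 2.0,
        amplitude=float(rel[ip]),
        ahp_onset=offset,
        ahp_offset=ahp_offset,
        ahp_amplitude=ahp_amplitude,
        ahp_integral=ahp_integral,
        ahp_current=ahp_current,
    )


def firing_io_curve(
    step_amplitudes,
    ap_times_per_step: list[np.ndarray],
    step_duration: float = 0.5,
) -> IOCurve:
    """Firing rates and response durations over a current-step series.

    Rate is spikes per step duration; response duration is the span from
    first to last AP peak within a step (0 when fewer than two spikes);
    the normalized rate divides the spike count by the response duration
    where one exists.
    """
    amps = np.asarray(step_amplitudes, dtype=float)
    if amps.size != len(ap_times_per_step):
        raise ValueError("need AP times for every step amplitude")
    if step_duration <= 0:
        raise ValueError("step_duration must be positive")
    rates = np.empty(amps.size)
    durations = np.empty(amps.size)
    norm = np.full(amps.size, np.nan)
    for i, aps in enumerate(ap_times_per_step):
        aps = np.asarray(aps, dtype=float)
        rates[i] = aps.size / step_duration
        durations[i] = float(aps[-1] - aps[0]) if aps.size >= 2 else 0.0
        if durations[i] > 0:
            norm[i] = aps.size / durations[i]
    return IOCurve(
        step_amplitudes=amps,
        rates=rates,
        response_durations=durations,
        normalized_rates=norm,
    )


def rheobase(
    spike_count,
    coarse_range: tuple[float, float] = (-400.0, 2000.0),
    coarse_step: float = 200.0,
    fine_step: float = 10.0,
) -> float | None:
    """Smallest current (pA) eliciting at least one AP.

    ``spike_count`` maps an injected current (pA) to a spike count (a
    callable, or a mapping queried at the needed currents).  The coarse
    grid locates the first interval with firing, which is then scanned at
    ``fine_step`` resolution.  Returns None when the cell never fires at
    the top of the range.
    """
    fn = spike_count if callable(spike_count) else lambda a: spike_count[a]
    lo, hi = coarse_range
    amps = np.arange(lo, hi + 0.5 * coarse_step, coarse_step)
    first = None
    for a in amps:
        if fn(float(a)) >= 1:
            first = float(a)
            break
    if first is None:
        return None
    start = first - coarse_step
    for a in np.arange(start + fine_step, first + 0.5 * fine_step, fine_step):
        if fn(float(a)) >= 1:
            return float(a)
    return first


def _double_exp(t, a1, tau1, a2, tau2):
    return a1 * np.exp(-t / tau1) + a2 * np.exp(-t / tau2)


def passive_props(
    test_pulse: Trace,
    current: float,
    step_onset: float,
    step_duration: float,
    r_s_max: float = 30.0,
) -> PassiveProps:
    """Passive membrane properties from a subthreshold test pulse.

    The decay after the step offset is fitted with a double exponential
    (multi-start nonlinear least squares).  The fast component is the
    access (electrode) transient and the slow component the membrane:
    input resistance is the membrane voltage deflection over the injected
    current (R_in = dV/I), capacitance integrates the membrane decay and
    divides by the discharge voltage and R_in (C_m = ∫V_decay/(ΔV·R_in) =
    τ_slow/R_in), and series resistance follows from the fast time
    constant (R_s = τ_fast/C_m).  Cells with R_s above ``r_s_max`` (MΩ)
    are flagged excluded.

    ``current`` is in pA, the trace in mV; resistances come out in MΩ and
    capacitance in pF.
    """
    if current == 0:
        raise ValueError("test-pulse current must be non-zero")
    t_off = step_onset + step_duration
    i0 = test_pulse.index_at(t_off)
    decay = test_pulse.values[i0:]
    if decay.size < 10:
        raise ValueError("too few samples after the step offset to fit the decay")
    sign = 1.0 if current > 0 else -1.0
    y = sign * decay
    t = test_pulse.dt * np.arange(y.size)
    amp0 = float(y[0])
    best = None
    for tau_f0, tau_s0 in [(2e-4, 1e-2), (1e-3, 2e-2), (5e-4, 5e-3), (2e-3, 5e-2)]:
        try:
            popt, _ = optimize.curve_fit(
                _double_exp,
                t,
                y,
                p0=(0.2 * amp0, tau_f0, 0.8 * amp0, tau_s0),
                bounds=([0, 1e-6, 0, 1e-6], [np.inf, 1.0, np.inf, 10.0]),
                maxfev=20_000,
            )
        except RuntimeError:
            continue
        resid = float(np.sum((_double_exp(t, *popt) - y) ** 2))
        if best is None or resid < best[1]:
            best = (popt, resid)
    if best is None:
        raise RuntimeError("double-exponential fit of the decay failed")
    a1, tau1, a2, tau2 = best[0]
    (a_f, tau_f), (a_s, tau_s) = sorted([(a1, tau1), (a2, tau2)], key=lambda p: p[1])
    r_in = 1000.0 * a_s / abs(current)  # mV / pA -> MΩ
    if r_in <= 0:
        raise RuntimeError("non-positive fitted input resistance")
    c_m = 1e6 * tau_s / r_in  # s / MΩ -> pF
    r_s = 1e6 * tau_f / c_m  # s / pF -> MΩ
    return PassiveProps(r_in=r_in, c_m=c_m, r_s=r_s, excluded=r_s > r_s_max)


def ppr(epsc1: float, epsc2: float) -> float:
    """Paired-pulse ratio, log2 of the second EPSC amplitude over the first
    (amplitudes as positive magnitudes, pA)."""
    if epsc1 <= 0 or epsc2 <= 0:
        raise ValueError("EPSC amplitudes must be positive magnitudes")
    return log2(epsc2 / epsc1)


def sepsc_summary(event_amplitudes, record_duration: float) -> tuple[float, float]:
    """Frequency (Hz) and mean amplitude (pA) of detected spontaneous
    EPSCs; the amplitude is NaN for an empty event list."""
    if record_duration <= 0:
        raise ValueError("record duration must be positive")
    amps = np.asarray(event_amplitudes, dtype=float)
    freq = amps.size / record_duration
    mean_amp = float(np.mean(amps)) if amps.size else float("nan")
    return freq, mean_amp
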