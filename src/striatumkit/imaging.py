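"""Two-photon calcium-imaging analysis chain.

ΔF/F₀ over a trailing 2 s baseline, rigid frame drift correction,
template cross-correlation event detection with an evoked window and a
lockout, ROI- and slice-level quality control, and per-cell response
metrics (spike probability, transient amplitude, detection latency and
direct/indirect pathway timing).

Detection follows the matched-filter convention used in the slice
experiments this package models: the running dot product of the ΔF/F₀
trace with an un-normalized single-action-potential template is compared
against the template's "perfect fit" score (its dot product with itself);
peaks scoring at least half the perfect fit are events, only events within
375 ms of stimulation count as evoked, and no event may follow another
within 1 s.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal

from .core import Template, Trace

__all__ = [
    "Trace",
    "Template",
    "EventList",
    "RoiRecord",
    "QCReport",
    "CellResponse",
    "compute_dff",
    "correct_drift",
    "detect_calcium_events",
    "qc_roi",
    "qc_slice",
    "response_metrics",
    "pathway_timing",
]


@dataclass
class EventList:
    """Detected events for one trial, referenced to the stimulus time."""

    trial_id: str
    stimulus_time: float
    event_times: np.ndarray
    scores: np.ndarray
    evoked: np.ndarray

    def __post_init__(self) -> None:
        self.event_times = np.asarray(self.event_times, dtype=float)
        self.scores = np.asarray(self.scores, dtype=float)
        self.evoked = np.asarray(self.evoked, dtype=bool)
        if not (self.event_times.size == self.scores.size == self.evoked.size):
            raise ValueError("event_times, scores and evoked must align")
        if self.event_times.size >= 2 and np.any(np.diff(self.event_times) <= 0):
            raise ValueError("event times must be strictly increasing")

    @property
    def n_evoked(self) -> int:
        return int(self.evoked.sum())

    @property
    def n_nonevoked(self) -> int:
        return int((~self.evoked).sum())


@dataclass
class QCReport:
    """ROI inclusion decision with the reasons for exclusion."""

    included: bool
    reasons: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.included != (len(self.reasons) == 0):
            raise ValueError("included must mirror an empty reason list")


@dataclass
class RoiRecord:
    """One region of interest: its trials, subtype label and QC state."""

    roi_id: str
    centroid: tuple[float, float]
    cell_type: str  # dSPN | iSPN | unknown
    trials: list[Trace]
    saturating: bool = False
    drifted: bool = False
    qc: QCReport | None = None

    def __post_init__(self) -> None:
        if self.cell_type not in ("dSPN", "iSPN", "unknown"):
            raise ValueError(f"unknown cell_type {self.cell_type!r}")
        if self.trials:
            dt0 = self.trials[0].dt
            if any(not np.isclose(tr.dt, dt0) for tr in self.trials):
                raise ValueError("all trials must share the sampling interval")


@dataclass
class CellResponse:
    """Per-ROI response summary across trials."""

    roi_id: str
    cell_type: str
    spike_probability: float
    amplitude: float  # ΔF/F₀; NaN when no trial responded
    latency: float  # s post-stimulus; NaN when no trial responded

    @property
    def responded(self) -> bool:
        return not np.isnan(self.amplitude)


def compute_dff(raw: Trace, window: float = 2.0) -> Trace:
    """ΔF/F₀ with F₀ the mean over a trailing window ending just before
    each sample (truncated at the trace start; the very first sample uses
    itself as baseline)."""
    if window <= 0:
        raise ValueError("window must be positive")
    f = raw.values
    if np.any(f <= 0):
        raise ValueError("raw fluorescence must be strictly positive")
    w = max(1, int(round(window / raw.dt)))
    csum = np.concatenate([[0.0], np.cumsum(f)])
    i = np.arange(f.size)
    start = np.maximum(0, i - w)
    count = i - start
    f0 = np.where(count > 0, (csum[i] - csum[start]) / np.maximum(count, 1), f)
    return Trace(t0=raw.t0, dt=raw.dt, values=(f - f0) / f0)


def correct_drift(frames: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Rigid integer-pixel drift correction against the first frame.

    Shifts are estimated by maximizing the circular spatial
    cross-correlation of each mean-subtracted frame with the first frame;
    ties are broken toward the smallest shift.  Returns ``(shifts,
    corrected)`` where ``shifts[i]`` is the (row, col) translation applied
    to frame i.
    """
    frames = np.asarray(frames, dtype=float)
    if frames.ndim != 3 or frames.shape[0] < 1:
        raise ValueError("need a stack of >= 1 frames with a common shape")
    n, h, w = frames.shape
    ref = frames[0] - frames[0].mean()
    f_ref = np.fft.rfft2(ref)
    shifts = np.zeros((n, 2), dtype=int)
    corrected = np.empty_like(frames)
    corrected[0] = frames[0]
    for i in range(1, n):
        cur = frames[i] - frames[i].mean()
        xcorr = np.fft.irfft2(f_ref * np.conj(np.fft.rfft2(cur)), s=(h, w))
        best = xcorr.max()
        rows, cols = np.nonzero(xcorr >= best - 1e-9 * max(1.0, abs(best)))
        # wrap circular lags into signed shifts, tie-break toward zero
        srows = np.where(rows > h // 2, rows - h, rows)
        scols = np.where(cols > w // 2, cols - w, cols)
        order = np.lexsort((np.abs(scols), np.abs(srows), np.abs(srows) + np.abs(scols)))
        dy, dx = int(srows[order[0]]), int(scols[order[0]])
        shifts[i] = (dy, dx)
        corrected[i] = np.roll(frames[i], (dy, dx), axis=(0, 1))
    return shifts, corrected


def correlation_scores(dff: Trace, template: Template) -> np.ndarray:
    """Running dot product of the trace with the template, as a fraction of
    the template's perfect-fit score; entry i corresponds to the template
    starting at sample i."""
    tmpl = template.resampled(dff.dt)
    if tmpl.values.size > dff.values.size:
        raise ValueError("template longer than trace")
    # zero-padded at the end so transients that run off the trace still get
    # scored (with correspondingly reduced dot products)
    raw = np.correlate(dff.values, tmpl.values, mode="full")[tmpl.values.size - 1 :]
    return raw / tmpl.self_dot


def detect_calcium_events(
    dff: Trace,
    template: Template,
    stimulus_time: float,
    threshold_frac: float = 0.5,
    evoked_window: float = 0.375,
    lockout: float = 1.0,
    trial_id: str = "",
) -> EventList:
    """Template-matching event detection on a ΔF/F₀ trace.

    Local maxima of the running dot product scoring at least
    ``threshold_frac`` of the perfect fit become events, taken greedily in
    time with no event allowed within ``lockout`` seconds of the previous
    one.  Events are flagged evoked when they fall within
    ``evoked_window`` after the stimulus, starting one sample after it
    (the stimulus sample itself is skipped).
    """
    scores = correlation_scores(dff, template)
    peaks, _ = signal.find_peaks(scores)
    # a template aligned at the very first sample has no left neighbour but
    # can still be the best match
    if scores.size >= 2 and scores[0] > scores[1]:
        peaks = np.concatenate([[0], peaks])
    peaks = peaks[scores[peaks] >= threshold_frac]
    times, kept_scores = [], []
    last = -np.inf
    for p in peaks:
        t = dff.t0 + p * dff.dt
        if t - last >= lockout:
            times.append(t)
            kept_scores.append(scores[p])
            last = t
    times = np.asarray(times)
    evoked = (times >= stimulus_time + dff.dt) & (times <= stimulus_time + evoked_window)
    return EventList(
        trial_id=trial_id,
        stimulus_time=stimulus_time,
        event_times=times,
        scores=np.asarray(kept_scores),
        evoked=evoked,
    )


def qc_roi(
    roi: RoiRecord,
    suprathreshold_trials: list[EventList],
    sd_max: float = 0.0575,
    ratio_max: float = 4.5,
) -> QCReport:
    """ROI inclusion check.

    Excluded when the ΔF/F₀ SD (pooled over trials) reaches ``sd_max``,
    when no evoked response occurred in any suprathreshold trial, when the
    non-evoked/evoked event ratio at suprathreshold stimulation exceeds
    ``ratio_max``, or when the ROI was flagged saturating or drifted.
    """
    reasons: list[str] = []
    if roi.trials:
        pooled = np.concatenate([tr.values for tr in roi.trials])
        if float(np.std(pooled)) >= sd_max:
            reasons.append("noise_sd_exceeded")
    n_evoked = sum(ev.n_evoked for ev in suprathreshold_trials)
    n_nonevoked = sum(ev.n_nonevoked for ev in suprathreshold_trials)
    if n_evoked == 0:
        reasons.append("unresponsive_suprathreshold")
    elif n_nonevoked / n_evoked > ratio_max:
        reasons.append("nonevoked_ratio_exceeded")
    if roi.saturating:
        reasons.append("saturating")
    if roi.drifted:
        reasons.append("drifted")
    report = QCReport(included=not reasons, reasons=reasons)
    roi.qc = report
    return report


def qc_slice(rois: list[RoiRecord], min_per_subtype: int = 12) -> bool:
    """Slice passes when at least ``min_per_subtype`` included SPNs of each
    subtype survive ROI-level QC."""
    counts = {"dSPN": 0, "iSPN": 0}
    for roi in rois:
        if roi.qc is None:
            raise ValueError(f"ROI {roi.roi_id} has no QC report")
        if roi.qc.included and roi.cell_type in counts:
            counts[roi.cell_type] += 1
    return counts["dSPN"] >= min_per_subtype and counts["iSPN"] >= min_per_subtype


def response_metrics(
    roi: RoiRecord,
    events: list[EventList],
    template: Template,
    threshold_frac: float = 0.5,
) -> CellResponse:
    """Spike probability, amplitude and latency for one ROI.

    Spike probability is the fraction of trials with an evoked event.
    Amplitude is the maximum ΔF/F₀ within the first evoked event's
    transient window, averaged over responding trials.  Latency is the
    post-stimulus time at which the running dot product first reaches
    ``threshold_frac`` of the perfect fit, averaged over responding
    trials; both are NaN when no trial responded.
    """
    if not roi.trials or len(events) != len(roi.trials):
        raise ValueError("need one EventList per trial")
    amplitudes, latencies = [], []
    n_responding = 0
    for tr, ev in zip(roi.trials, events):
        if ev.n_evoked == 0:
            continue
        n_responding += 1
        t_first = ev.event_times[ev.evoked][0]
        i0 = tr.index_at(t_first)
        i1 = min(i0 + template.resampled(tr.dt).values.size, tr.values.size)
        amplitudes.append(float(np.max(tr.values[max(i0, 0) : i1])))
        scores = correlation_scores(tr, template)
        i_stim = max(0, tr.index_at(ev.stimulus_time) + 1)
        crossed = np.nonzero(scores[i_stim:] >= threshold_frac)[0]
        if crossed.size:
            latencies.append((i_stim + crossed[0]) * tr.dt + tr.t0 - ev.stimulus_time)
    spike_probability = n_responding / len(roi.trials)
    return CellResponse(
        roi_id=roi.roi_id,
        cell_type=roi.cell_type,
        spike_probability=spike_probability,
        amplitude=float(np.mean(amplitudes)) if amplitudes else float("nan"),
        latency=float(np.mean(latencies)) if latencies else float("nan"),
    )


def pathway_timing(
    dspn: list[CellResponse], ispn: list[CellResponse], seed=None
) -> np.ndarray:
    """Paired dSPN-iSPN latency differences (s) from a seeded random,
    non-reusing pairing; positive values mean the indirect pathway leads."""
    if not dspn or not ispn:
        raise ValueError("both cell lists must be non-empty")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    d_lat = np.array([c.latency for c in dspn])
    i_lat = np.array([c.latency for c in ispn])
    if np.any(np.isnan(d_lat)) or np.any(np.isnan(i_lat)):
        raise ValueError("latencies must be defined for all cells")
    k = min(d_lat.size, i_lat.size)
    d_idx = rng.permutation(d_lat.size)[:k]
    i_idx = rng.permutation(i_lat.size)[:k]
    return d_lat[d_idx] - i_lat[i_idx]
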