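"""Synthetic-data generators with known ground truth.

Every input the analysis pipeline consumes can be generated here: calcium
ΔF/F₀ transients as stereotyped kernels at known spike times under Gaussian
noise at imaging frame rates (12-15 Hz), cell-attached sweeps with a brief
stimulus artifact plus action-potential waveforms, Poisson or bursty spike
trains with a controlled fraction of gamma-band (30-100 Hz) interspike
intervals, RC test-pulse sweeps for passive-property recovery, operant
sessions under RI/RR reinforcement, devaluation probes for habitual or
goal-directed agents, and 3-D head-position tracks.

All generators draw from an explicit ``numpy.random.Generator`` (or a seed)
and attach a :class:`GroundTruth` record, so downstream detectors and
statistics can be scored against the truth.  Identical configuration and
seed give bit-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np

from .behavior import ProbeResult, Session, Track3D, apply_schedule
from .core import Template, Trace

__all__ = [
    "SimConfig",
    "GroundTruth",
    "make_calcium_kernel",
    "make_ap_kernel",
    "simulate_roi_trace",
    "simulate_sweep",
    "simulate_spike_train",
    "simulate_test_pulse",
    "simulate_operant_session",
    "simulate_devaluation",
    "simulate_track3d",
]

#: gamma band in seconds of ISI: rates in [30, 100) Hz
_GAMMA_ISI = (0.010, 1.0 / 30.0)


@dataclass(frozen=True)
class SimConfig:
    """Acquisition and kernel parameters for trace/sweep simulation.

    Defaults emulate two-photon calcium imaging of striatal projection
    neurons: 15 Hz frames, single-action-potential transients of 0.08
    ΔF/F₀ peak with ~50 ms rise and ~500 ms decay, and Gaussian noise
    well below the 0.0575 ΔF/F₀ QC ceiling.
    """

    seed: int = 0
    sampling_rate: float = 15.0
    duration: float = 10.0
    noise_sd: float = 0.01
    kernel_rise: float = 0.05
    kernel_decay: float = 0.5
    kernel_peak: float = 0.08

    def __post_init__(self) -> None:
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")
        if self.duration <= 0:
            raise ValueError("duration must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")

    @property
    def dt(self) -> float:
        return 1.0 / self.sampling_rate

    @property
    def n_samples(self) -> int:
        return int(round(self.duration * self.sampling_rate))

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


@dataclass
class GroundTruth:
    """What a generator actually put into a simulated record."""

    true_event_times: np.ndarray
    true_label: str
    true_parameters: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.true_event_times = np.asarray(self.true_event_times, dtype=float)
        if self.true_event_times.size >= 2 and np.any(np.diff(self.true_event_times) <= 0):
            raise ValueError("event times must be strictly increasing")


def make_calcium_kernel(
    rise: float, decay: float, peak: float, sampling_rate: float
) -> Template:
    """Stereotyped calcium-transient kernel as a difference of exponentials.

    ``k(t) = A (exp(-t/decay) - exp(-t/rise))`` scaled so its maximum equals
    ``peak`` (ΔF/F₀ units); the kernel is truncated once it has decayed to
    below 1% of the peak.  Stands in for an empirically recorded
    single-action-potential template.
    """
    if rise <= 0 or decay <= 0 or peak <= 0 or sampling_rate <= 0:
        raise ValueError("rise, decay, peak and sampling_rate must be positive")
    if rise >= decay:
        raise ValueError("rise must be shorter than decay")
    dt = 1.0 / sampling_rate
    # analytic peak time of the double exponential
    t_peak = rise * decay / (decay - rise) * np.log(decay / rise)
    t_end = t_peak + decay * np.log(250.0)
    t = np.arange(0.0, t_end + dt, dt)
    shape = np.exp(-t / decay) - np.exp(-t / rise)
    shape_peak = np.exp(-t_peak / decay) - np.exp(-t_peak / rise)
    values = peak * shape / shape_peak
    # guarantee the sampled maximum is exactly the requested peak
    values *= peak / values.max()
    return Template(dt=dt, values=values)


def make_ap_kernel(
    width: float = 0.001, amplitude: float = 1.0, sampling_rate: float = 20_000.0
) -> Template:
    """Biphasic extracellular-style action-potential waveform.

    A negative-going Gaussian derivative of total width ~``width`` seconds,
    scaled to ``amplitude`` peak absolute deflection, for cell-attached
    sweep simulation.
    """
    if width <= 0 or amplitude <= 0 or sampling_rate <= 0:
        raise ValueError("width, amplitude and sampling_rate must be positive")
    dt = 1.0 / sampling_rate
    sigma = width / 4.0
    t = np.arange(0.0, 2.0 * width + dt, dt)
    centred = t - width
    values = -centred * np.exp(-(centred**2) / (2.0 * sigma**2))
    values *= amplitude / np.max(np.abs(values))
    return Template(dt=dt, values=values)


def _add_kernels(values: np.ndarray, kernel: Template, event_times, dt: float, t0: float) -> None:
    k = kernel.values
    for et in np.asarray(event_times, dtype=float):
        i0 = int(round((et - t0) / dt))
        i1 = min(i0 + k.size, values.size)
        if i1 > i0 >= 0:
            values[i0:i1] += k[: i1 - i0]


def simulate_roi_trace(
    event_times, kernel: Template, cfg: SimConfig, rng: np.random.Generator | None = None
) -> tuple[Trace, GroundTruth]:
    """ΔF/F₀ trace = kernel copies at ``event_times`` + Gaussian noise."""
    events = np.sort(np.asarray(event_times, dtype=float))
    if events.size and (events[0] < 0 or events[-1] >= cfg.duration):
        raise ValueError("event times must lie within [0, duration)")
    if rng is None:
        rng = cfg.rng()
    values = np.zeros(cfg.n_samples)
    _add_kernels(values, kernel.resampled(cfg.dt), events, cfg.dt, 0.0)
    if cfg.noise_sd > 0:
        values += rng.normal(0.0, cfg.noise_sd, values.size)
    truth = GroundTruth(
        true_event_times=events,
        true_label="roi_trace",
        true_parameters={"noise_sd": cfg.noise_sd, "peak": cfg.kernel_peak},
    )
    return Trace(t0=0.0, dt=cfg.dt, values=values), truth


def simulate_sweep(
    ap_times,
    ap_kernel: Template,
    artifact_amp: float,
    cfg: SimConfig,
    rng: np.random.Generator | None = None,
) -> tuple[Trace, GroundTruth]:
    """Cell-attached sweep: stimulus artifact at t=0 plus APs at ``ap_times``.

    The artifact is a single-sample-rise biphasic transient confined to
    <1 ms around the stimulus; the sweep runs from t=0 (stimulus) for
    ``cfg.duration`` seconds.
    """
    aps = np.sort(np.asarray(ap_times, dtype=float))
    if aps.size and (aps[0] < 0 or aps[-1] >= cfg.duration):
        raise ValueError("AP times must lie within [0, duration)")
    if rng is None:
        rng = cfg.rng()
    values = np.zeros(cfg.n_samples)
    # artifact: one-sample positive spike then negative rebound, < 1 ms total
    n_art = max(1, int(round(0.0005 / cfg.dt)))
    values[:n_art] += artifact_amp
    values[n_art : 2 * n_art] -= 0.5 * artifact_amp
    _add_kernels(values, ap_kernel.resampled(cfg.dt), aps, cfg.dt, 0.0)
    if cfg.noise_sd > 0:
        values += rng.normal(0.0, cfg.noise_sd, values.size)
    truth = GroundTruth(
        true_event_times=aps,
        true_label="sweep",
        true_parameters={"artifact_amp": artifact_amp, "noise_sd": cfg.noise_sd},
    )
    return Trace(t0=0.0, dt=cfg.dt, values=values), truth


def simulate_spike_train(
    kind: str,
    rate: float,
    duration: float,
    seed=None,
    gamma_fraction: float = 0.5,
) -> tuple[np.ndarray, GroundTruth]:
    """Spike times of a homogeneous Poisson or bursty unit.

    ``kind="poisson"`` draws i.i.d. exponential ISIs with mean 1/rate.
    ``kind="bursty"`` draws a mixture: with probability ``gamma_fraction``
    a within-burst ISI uniform on (10, 33.3] ms (instantaneous rate in the
    gamma band), otherwise an inter-burst ISI of 250 ms plus an exponential
    chosen so the overall mean ISI stays 1/rate.  The expected fraction of
    ISIs in the gamma band is therefore ``gamma_fraction``.
    """
    if rate <= 0:
        raise ValueError("rate must be positive")
    if duration < 0:
        raise ValueError("duration must be non-negative")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    mean_isi = 1.0 / rate
    if kind == "poisson":
        draw = lambda n: rng.exponential(mean_isi, n)  # noqa: E731
        params = {"rate": rate}
    elif kind == "bursty":
        if not 0.0 < gamma_fraction < 1.0:
            raise ValueError("gamma_fraction must lie in (0, 1)")
        lo, hi = _GAMMA_ISI
        mean_burst = 0.5 * (lo + hi)
        floor = 0.25
        mean_ib_exp = (mean_isi - gamma_fraction * mean_burst) / (1.0 - gamma_fraction) - floor
        if mean_ib_exp <= 0:
            raise ValueError(
                f"rate {rate} Hz too high for gamma_fraction {gamma_fraction} with a "
                "250 ms inter-burst floor"
            )

        def draw(n: int) -> np.ndarray:
            burst = rng.random(n) < gamma_fraction
            isis = floor + rng.exponential(mean_ib_exp, n)
            isis[burst] = rng.uniform(lo, hi, int(burst.sum()))
            return isis

        params = {"rate": rate, "gamma_fraction": gamma_fraction}
    else:
        raise ValueError(f"unknown spike-train kind {kind!r}")

    times: list[np.ndarray] = []
    t = 0.0
    # draw ISIs in blocks until the duration is covered
    expect = max(16, int(duration * rate * 1.2) + 16)
    while t < duration:
        block = draw(expect)
        cum = t + np.cumsum(block)
        times.append(cum)
        t = float(cum[-1])
    spikes = np.concatenate(times) if times else np.empty(0)
    spikes = spikes[spikes < duration]
    truth = GroundTruth(true_event_times=spikes, true_label=kind, true_parameters=params)
    return spikes, truth


def simulate_test_pulse(
    r_in: float,
    c_m: float,
    r_s: float,
    current: float,
    step_onset: float = 0.1,
    step_duration: float = 0.5,
    duration: float = 1.2,
    sampling_rate: float = 20_000.0,
    noise_sd: float = 0.0,
    seed=None,
) -> Trace:
    """Forward-simulated subthreshold test pulse of a two-compartment cell.

    The voltage response to a current step ``current`` (pA) through series
    resistance ``r_s`` (MΩ) into a membrane of input resistance ``r_in``
    (MΩ) and capacitance ``c_m`` (pF): a fast access transient with
    τ_fast = R_s·C_m stacked on the membrane charging curve with
    τ_slow = R_in·C_m.  Voltage is returned in mV relative to rest.
    """
    if min(r_in, c_m, r_s, sampling_rate) <= 0:
        raise ValueError("r_in, c_m, r_s and sampling_rate must be positive")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    dt = 1.0 / sampling_rate
    t = np.arange(0.0, duration, dt)
    tau_f = r_s * c_m * 1e-6  # MΩ·pF -> s
    tau_s = r_in * c_m * 1e-6
    v_s = r_s * current * 1e-3  # MΩ·pA -> mV
    v_m = r_in * current * 1e-3
    v = np.zeros_like(t)
    on = (t >= step_onset) & (t < step_onset + step_duration)
    ts = t[on] - step_onset
    v[on] = v_s * (1 - np.exp(-ts / tau_f)) + v_m * (1 - np.exp(-ts / tau_s))
    off = t >= step_onset + step_duration
    toff = t[off] - (step_onset + step_duration)
    a_f = v_s * (1 - np.exp(-step_duration / tau_f))
    a_s = v_m * (1 - np.exp(-step_duration / tau_s))
    v[off] = a_f * np.exp(-toff / tau_f) + a_s * np.exp(-toff / tau_s)
    if noise_sd > 0:
        v += rng.normal(0.0, noise_sd, v.size)
    return Trace(t0=0.0, dt=dt, values=v)


def simulate_operant_session(
    schedule: str, press_rate: float, duration: float, seed=None
) -> tuple[Session, GroundTruth]:
    """Operant session with Poisson pressing reinforced by ``schedule``."""
    if press_rate < 0:
        raise ValueError("press_rate must be non-negative")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    lam = press_rate / 60.0  # presses/min -> presses/s
    n = rng.poisson(lam * duration)
    presses = np.sort(rng.uniform(0.0, duration, n))
    rewards = apply_schedule(presses, schedule, duration=duration, seed=rng)
    session = Session(
        press_times=presses, reward_times=rewards, schedule=schedule, duration=duration
    )
    truth = GroundTruth(
        true_event_times=presses,
        true_label="operant_session",
        true_parameters={"press_rate": press_rate, "schedule": schedule},
    )
    return session, truth


def simulate_devaluation(
    agent: str,
    base_rate: float,
    effect: float,
    seed=None,
    noise_sd: float = 0.0,
) -> ProbeResult:
    """Devaluation-probe press rates for a simulated agent.

    A goal-directed agent suppresses pressing under devaluation by
    ``effect`` log2 units (devalued rate = base·2^-effect); a habitual
    agent does not (expected NDLPr = 0).  ``noise_sd`` adds independent
    multiplicative log2-normal noise to both probe rates, leaving the
    expected NDLPr unchanged.
    """
    if base_rate <= 0:
        raise ValueError("base_rate must be positive")
    if agent == "goal_directed":
        if effect <= 0:
            raise ValueError("goal_directed agents need effect > 0")
        shift = -effect
    elif agent == "habitual":
        if effect < 0:
            raise ValueError("effect must be non-negative")
        shift = 0.0
    else:
        raise ValueError(f"unknown agent kind {agent!r}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    e_dev = rng.normal(0.0, noise_sd) if noise_sd > 0 else 0.0
    e_non = rng.normal(0.0, noise_sd) if noise_sd > 0 else 0.0
    dev = base_rate * 2.0 ** (shift + e_dev)
    nondev = base_rate * 2.0**e_non
    return ProbeResult(lpr_devalued=dev, lpr_nondevalued=nondev)


def simulate_track3d(
    mode: str, step: float, n: int, seed=None, sampling_rate: float = 100.0
) -> Track3D:
    """3-D head-position track: stationary, straight line, or random walk.

    ``step`` is the per-sample displacement in mm; the random walk takes
    fixed-length steps in uniformly random 3-D directions.
    """
    if n < 1:
        raise ValueError("need n >= 1 samples")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    t = np.arange(n) / sampling_rate
    if mode == "stationary":
        xyz = np.zeros((n, 3))
    elif mode == "line":
        xyz = np.zeros((n, 3))
        xyz[:, 0] = step * np.arange(n)
    elif mode == "random_walk":
        d = rng.normal(size=(n - 1, 3)) if n > 1 else np.zeros((0, 3))
        norms = np.linalg.norm(d, axis=1, keepdims=True)
        norms[norms == 0] = 1.0
        steps = step * d / norms
        xyz = np.vstack([np.zeros(3), np.cumsum(steps, axis=0)])
    else:
        raise ValueError(f"unknown track mode {mode!r}")
    return Track3D(t=t, x=xyz[:, 0], y=xyz[:, 1], z=xyz[:, 2])
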