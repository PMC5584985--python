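"""In vivo single-unit spike-train analysis.

Unit quality control and FSI/SPN classification from waveform width and
baseline rate; interspike-interval (ISI) frequency-band fractions; a
rate-matched Poisson surrogate null for the band distribution, giving the
"excess gamma" statistic (observed minus expected gamma-band ISI
fraction); pre/post firing-rate modulation; and the regression of rate
modulation on baseline gamma content.

Each ISI is converted to an instantaneous firing rate (1/ISI) and
assigned to canonical bands: delta 0-4 Hz, theta 4-8 Hz, alpha 8-13 Hz,
beta 13-30 Hz and gamma 30-100 Hz, half-open ``[low, high)``.  Rates of
100 Hz and above fall outside the named bands but stay in the
denominator.  The surrogate draws, for a unit with N ISIs and mean ISI
λ, N ISIs from the ISI law of a rate-matched Poisson process
(exponential with mean λ); each unit's expectation averages the
normalized band counts of 20 such simulations.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from math import log2

import numpy as np

from . import stats as _stats

__all__ = [
    "BAND_EDGES",
    "SpikeTrain",
    "BandFractions",
    "NullEstimate",
    "ModulationRecord",
    "unit_qc",
    "classify_unit",
    "isi_band_fractions",
    "poisson_null",
    "rate_modulation",
    "modulation_regression",
    "firing_rate_timecourse",
]

#: frequency bands in Hz, half-open [low, high)
BAND_EDGES: dict[str, tuple[float, float]] = {
    "delta": (0.0, 4.0),
    "theta": (4.0, 8.0),
    "alpha": (8.0, 13.0),
    "beta": (13.0, 30.0),
    "gamma": (30.0, 100.0),
}


@dataclass
class SpikeTrain:
    """Spike times of one sorted unit, with optional classification info."""

    unit_id: str
    spike_times: np.ndarray
    epoch: str | None = None  # pre | post
    putative_type: str | None = None  # FSI | SPN
    waveform_width: float | None = None  # ms
    duration: float | None = None  # s, recording span when known

    def __post_init__(self) -> None:
        self.spike_times = np.asarray(self.spike_times, dtype=float)
        if self.spike_times.size >= 2 and np.any(np.diff(self.spike_times) <= 0):
            raise ValueError("spike times must be strictly increasing")

    @property
    def n_spikes(self) -> int:
        return int(self.spike_times.size)

    @property
    def mean_rate(self) -> float:
        """Spikes per second: count/duration when the recording span is
        known, otherwise (count − 1)/span of the spikes."""
        if self.duration is not None and self.duration > 0:
            return self.n_spikes / self.duration
        if self.n_spikes < 2:
            return 0.0
        return (self.n_spikes - 1) / float(self.spike_times[-1] - self.spike_times[0])

    @property
    def isis(self) -> np.ndarray:
        return np.diff(self.spike_times)


@dataclass
class BandFractions:
    """Fraction of ISIs per frequency band, over the total ISI count."""

    fractions: dict[str, float]
    n_isis: int
    out_of_band: float = 0.0

    def __getitem__(self, band: str) -> float:
        return self.fractions[band]

    @property
    def vector(self) -> np.ndarray:
        return np.array([self.fractions[b] for b in BAND_EDGES])


@dataclass
class NullEstimate:
    """Rate-matched Poisson expectation for one unit's band fractions."""

    observed: BandFractions
    expected_fractions: dict[str, float]
    n_sims: int
    mean_isi: float
    excess: dict[str, float] = field(init=False)

    def __post_init__(self) -> None:
        self.excess = {
            b: self.observed.fractions[b] - self.expected_fractions[b] for b in BAND_EDGES
        }

    @property
    def excess_gamma(self) -> float:
        return self.excess["gamma"]


@dataclass
class ModulationRecord:
    """Firing-rate change of one unit between epochs."""

    pre_rate: float
    post_rate: float
    fold_change: float = field(init=False)  # log2(post/pre); NaN if pre = 0
    pct_baseline: float = field(init=False)  # 100 * post/pre; NaN if pre = 0

    def __post_init__(self) -> None:
        if self.pre_rate > 0:
            self.fold_change = (
                log2(self.post_rate / self.pre_rate) if self.post_rate > 0 else float("-inf")
            )
            self.pct_baseline = 100.0 * self.post_rate / self.pre_rate
        else:
            self.fold_change = float("nan")
            self.pct_baseline = float("nan")

    @property
    def defined(self) -> bool:
        return self.pre_rate > 0


def unit_qc(waveform_amplitude: float, noise_band_amplitude: float, ratio_min: float = 5.0) -> bool:
    """Include a unit only when its AP amplitude is at least ``ratio_min``
    times the noise band."""
    if noise_band_amplitude <= 0:
        raise ValueError("noise band amplitude must be positive")
    return waveform_amplitude / noise_band_amplitude >= ratio_min


def classify_unit(
    width: float, rate: float, width_max: float = 0.5, rate_min: float = 5.0
) -> str:
    """FSI/SPN call from spike width (ms) and baseline rate (Hz).

    FSIs have narrow spikes and high rates: FSI iff width < ``width_max``
    and rate > ``rate_min`` (both strict); otherwise SPN.  The default
    thresholds are working values, not a published boundary -- pass the
    thresholds appropriate to the recording setup.
    """
    if width < 0 or rate < 0:
        raise ValueError("width and rate must be non-negative")
    return "FSI" if (width < width_max and rate > rate_min) else "SPN"


def _band_fractions_from_isis(isis: np.ndarray) -> BandFractions:
    rates = 1.0 / isis
    n = isis.size
    fractions = {}
    in_band = np.zeros(n, dtype=bool)
    for band, (lo, hi) in BAND_EDGES.items():
        mask = (rates >= lo) & (rates < hi)
        fractions[band] = float(mask.sum()) / n
        in_band |= mask
    return BandFractions(
        fractions=fractions, n_isis=n, out_of_band=float((~in_band).sum()) / n
    )


def isi_band_fractions(train: SpikeTrain) -> BandFractions:
    """Band fractions of a unit's ISIs (instantaneous rate = 1/ISI)."""
    if train.n_spikes < 2:
        raise ValueError("need at least 2 spikes to form ISIs")
    return _band_fractions_from_isis(train.isis)


def poisson_null(
    train: SpikeTrain,
    n_sims: int = 20,
    seed=None,
    isi_law: str = "exponential",
) -> NullEstimate:
    """Rate-matched surrogate expectation of the band fractions.

    For a unit with N ISIs and mean ISI λ, each simulation draws N
    surrogate ISIs with mean λ, bins them like the data and the
    normalized counts are averaged across the ``n_sims`` simulations.
    ``isi_law="exponential"`` (default) uses the ISI distribution of a
    Poisson process; ``"poisson-ms"`` instead draws literal integer
    Poisson counts with mean λ expressed in milliseconds (a
    millisecond-quantized reading, available for comparison only).
    """
    if n_sims < 1:
        raise ValueError("need at least one simulation")
    if train.n_spikes < 2:
        raise ValueError("need at least 2 spikes")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    observed = isi_band_fractions(train)
    lam = float(np.mean(train.isis))
    n = observed.n_isis
    acc = np.zeros(len(BAND_EDGES))
    for _ in range(n_sims):
        if isi_law == "exponential":
            isis = rng.exponential(lam, n)
        elif isi_law == "poisson-ms":
            isis = rng.poisson(lam * 1000.0, n) / 1000.0
            isis = isis[isis > 0]
            if isis.size == 0:
                continue
        else:
            raise ValueError(f"unknown isi_law {isi_law!r}")
        acc += _band_fractions_from_isis(isis).vector
    expected = dict(zip(BAND_EDGES, acc / n_sims))
    return NullEstimate(
        observed=observed, expected_fractions=expected, n_sims=n_sims, mean_isi=lam
    )


def rate_modulation(pre: SpikeTrain, post: SpikeTrain) -> ModulationRecord:
    """Fold change (log2 post/pre) and percent-of-baseline firing rate."""
    return ModulationRecord(pre_rate=pre.mean_rate, post_rate=post.mean_rate)


def modulation_regression(predictor, response) -> _stats.TestResult:
    """Pearson correlation of per-unit rate modulation on a baseline
    predictor (gamma fraction or excess gamma)."""
    return _stats.pearson(predictor, response)


def firing_rate_timecourse(
    train: SpikeTrain, bin_width: float, t_range: tuple[float, float]
) -> tuple[np.ndarray, np.ndarray]:
    """Firing rate per time bin (Hz): spike count / bin width.

    Returns ``(bin_edges, rates)``; the final bin may be shorter than
    ``bin_width`` and is normalized by its actual length.
    """
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    t0, t1 = t_range
    if t1 <= t0:
        raise ValueError("empty time range")
    edges = np.arange(t0, t1 + bin_width * 1e-9, bin_width)
    if edges[-1] < t1:
        edges = np.append(edges, t1)
    counts, _ = np.histogram(train.spike_times, bins=edges)
    widths = np.diff(edges)
    return edges, counts / widths
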