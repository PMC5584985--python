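"""Operant-behavior analysis.

Press-rate and learning-curve summaries of lever-press sessions,
reinforcement bookkeeping for random-interval (RI) and random-ratio (RR)
schedules, the outcome-devaluation statistic NDLPr with habit
classification, and locomotion distance from 3-D head-tracking.

Habit is quantified per subject as the log2 ratio of lever-press rates
under reward devaluation versus the non-devalued control probe
(``NDLPr = log2(devalued LPr / non-devalued LPr)``): RI-trained subjects
with NDLPr >= 0 are insensitive to devaluation and labelled habitual,
abbreviated-RR ("RRshort") subjects with NDLPr < 0 are goal-directed, and
every other combination is excluded.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from math import log2

import numpy as np

__all__ = [
    "Session",
    "ProbeResult",
    "Track3D",
    "parse_schedule",
    "press_rate",
    "apply_schedule",
    "ndlpr",
    "classify_habit",
    "locomotion_distance",
    "learning_curve",
]

_SCHEDULE_RE = re.compile(r"^(RI|RR)-?(\d+(?:\.\d+)?)$", re.IGNORECASE)


@dataclass
class Session:
    """One operant session: press and reward times under a schedule."""

    press_times: np.ndarray
    reward_times: np.ndarray
    schedule: str
    duration: float

    def __post_init__(self) -> None:
        self.press_times = np.sort(np.asarray(self.press_times, dtype=float))
        self.reward_times = np.sort(np.asarray(self.reward_times, dtype=float))
        if self.duration <= 0:
            raise ValueError("session duration must be positive")
        parse_schedule(self.schedule)


@dataclass
class ProbeResult:
    """Devaluation probe outcome for one subject."""

    lpr_devalued: float
    lpr_nondevalued: float
    ndlpr: float = field(init=False)
    label: str = field(default="", init=False)

    def __post_init__(self) -> None:
        self.ndlpr = ndlpr(self.lpr_devalued, self.lpr_nondevalued)


@dataclass
class Track3D:
    """Head-position track in Cartesian coordinates (mm), sampled in time."""

    t: np.ndarray
    x: np.ndarray
    y: np.ndarray
    z: np.ndarray

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        self.z = np.asarray(self.z, dtype=float)
        if not (self.t.size == self.x.size == self.y.size == self.z.size):
            raise ValueError("t, x, y, z must have equal length")
        if self.t.size >= 2 and np.any(np.diff(self.t) <= 0):
            raise ValueError("t must be strictly increasing")


def parse_schedule(schedule: str) -> tuple[str, float]:
    """Parse a schedule string like ``"RI-60"`` or ``"RR-20"``.

    Returns the kind (``"RI"`` or ``"RR"``) and the parameter X: mean
    presses per reward for RR-X, the arming-check period in seconds for
    RI-X.
    """
    m = _SCHEDULE_RE.match(schedule.strip())
    if m is None:
        raise ValueError(f"unknown schedule {schedule!r}; expected RI-X or RR-X")
    x = float(m.group(2))
    if x <= 0:
        raise ValueError("schedule parameter X must be positive")
    return m.group(1).upper(), x


def press_rate(session: Session, window: tuple[float, float] | None = None) -> float:
    """Lever presses per minute within ``window`` (whole session if None)."""
    if window is None:
        window = (0.0, session.duration)
    start, end = window
    if end <= start:
        raise ValueError("window must have positive length")
    n = int(np.sum((session.press_times >= start) & (session.press_times < end)))
    return 60.0 * n / (end - start)


def apply_schedule(
    press_times,
    schedule: str,
    duration: float | None = None,
    seed=None,
    arm_probability: float = 0.1,
) -> np.ndarray:
    """Reward times earned by ``press_times`` under an RI or RR schedule.

    RR-X rewards each press independently with probability 1/X.  RI-X runs
    an arming clock from session start: at every X-second tick reward
    availability is armed with probability ``arm_probability`` (at most one
    reward pending), and the first press while armed collects it and
    disarms.
    """
    kind, x = parse_schedule(schedule)
    presses = np.sort(np.asarray(press_times, dtype=float))
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if kind == "RR":
        won = rng.random(presses.size) < 1.0 / x
        return presses[won]
    if duration is None:
        duration = float(presses[-1]) if presses.size else 0.0
    n_ticks = int(np.floor(duration / x))
    ticks = x * np.arange(1, n_ticks + 1)
    arm_draws = rng.random(n_ticks) < arm_probability
    rewards = []
    armed = False
    pi = 0
    for tick, arms in zip(ticks, arm_draws):
        # presses before this tick see the previous arming state
        while pi < presses.size and presses[pi] < tick:
            if armed:
                rewards.append(presses[pi])
                armed = False
            pi += 1
        if arms:
            armed = True
    while pi < presses.size and armed:
        rewards.append(presses[pi])
        armed = False
        pi += 1
    return np.asarray(rewards, dtype=float)


def ndlpr(lpr_devalued: float, lpr_nondevalued: float) -> float:
    """Normalized devalued lever-press rate, log2(devalued / non-devalued).

    Returns NaN when either rate is non-positive (no pseudocount is
    imputed); downstream classification treats NaN as excluded.
    """
    if lpr_devalued <= 0 or lpr_nondevalued <= 0:
        return float("nan")
    return log2(lpr_devalued / lpr_nondevalued)


def classify_habit(schedule_kind: str, ndlpr_value: float) -> str:
    """Habit label from training schedule and devaluation statistic.

    RI-trained subjects with NDLPr >= 0 are habitual; RRshort-trained
    subjects with NDLPr < 0 are goal-directed; everything else (including
    an undefined NDLPr) is excluded.
    """
    kind = schedule_kind.strip().upper()
    if kind not in ("RI", "RRSHORT", "RR"):
        raise ValueError(f"unknown schedule kind {schedule_kind!r}")
    if np.isnan(ndlpr_value):
        return "excluded"
    if kind == "RI" and ndlpr_value >= 0:
        return "habitual"
    if kind in ("RRSHORT", "RR") and ndlpr_value < 0:
        return "goal_directed"
    return "excluded"


def locomotion_distance(track: Track3D, window: tuple[float, float] | None = None) -> float:
    """Total 3-D path length (mm) of the track within ``window``."""
    if window is None:
        mask = np.ones(track.t.size, dtype=bool)
    else:
        mask = (track.t >= window[0]) & (track.t < window[1])
    if int(mask.sum()) < 2:
        return 0.0
    p = np.column_stack([track.x[mask], track.y[mask], track.z[mask]])
    return float(np.sum(np.linalg.norm(np.diff(p, axis=0), axis=1)))


def learning_curve(sessions: list[Session]) -> np.ndarray:
    """Whole-session press rates (presses/min), in the order given."""
    if not sessions:
        raise ValueError("need at least one session")
    return np.array([press_rate(s) for s in sessions])
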