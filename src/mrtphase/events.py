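"""Event extraction: from trajectories and counting curves to interval sequences.

Events are *completed rotations*: first passages of the lifted rotation
progress through successive 2*pi levels.  Counting first passages (rather than
raw curve crossings) avoids the infinitely-many-crossings pathology of
white-noise trajectories at a curve; re-crossings of an already-passed level
never create events.  All crossing times are linearly interpolated within the
straddling sample step.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .isochrons import CountingCurve, TWO_PI

#: default burn-in, in units of the mean period, discarded from the start of
#: every stochastic run before statistics
BURN_IN_PERIODS = 10.0
#: events discarded from the head of every train before statistics
BURN_IN_EVENTS = 5


@dataclass
class EventTrain:
    """Strictly increasing event (crossing) times within an observation window."""

    times: np.ndarray
    curve_kind: str
    t_start: float
    t_end: float

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        if self.times.size and np.any(np.diff(self.times) <= 0):
            raise ValueError("event times must be strictly increasing")

    def __len__(self):
        return self.times.size


@dataclass
class IntervalSequence:
    """Ordered positive intervals between adjacent events (ISIs or IPIs)."""

    intervals: np.ndarray
    label: str = "ISI"

    def __post_init__(self):
        self.intervals = np.asarray(self.intervals, dtype=float)
        if np.any(self.intervals <= 0):
            raise ValueError("intervals must be positive")

    def __len__(self):
        return self.intervals.size


def lift_phase(traj, curve: CountingCurve) -> np.ndarray:
    """Continuous lifted phase series of a trajectory under a counting curve.

    Curves whose natural output is a mod-2*pi phase (the tabulated isochron
    phases) are unwrapped by nearest-integer winding, so resets produce no
    jump in the lift.  Raises if the sampling is too coarse to unwrap (any
    per-step increment above pi).
    """
    lift = curve.lift(traj)
    if curve.kind not in ("alif_threshold",):
        inc = np.abs(np.diff(lift))
        if inc.size and inc.max() > np.pi:
            raise ValueError("phase increment > pi in one sample step; "
                             "sampling too coarse for unambiguous unwrapping")
    return lift


class FirstPassageAccumulator:
    """Streaming first-passage detector for 2*pi levels of a lifted phase.

    Feed successive (t, lift) chunks of one continuous series; collects the
    interpolated first-passage times of level0 + 2*pi*n for n = 1, 2, ...
    """

    def __init__(self, level0: float | None = None, period: float = TWO_PI):
        self.level0 = level0
        self.period = period
        self.times: list[np.ndarray] = []
        self._runmax = -np.inf
        self._n_next = 1
        self._prev_t = None
        self._prev_lift = None

    def update(self, t: np.ndarray, lift: np.ndarray) -> None:
        t = np.asarray(t, float)
        lift = np.asarray(lift, float)
        if self.level0 is None:
            self.level0 = float(lift[0])
        if self._prev_t is not None:
            t = np.concatenate(([self._prev_t], t))
            lift = np.concatenate(([self._prev_lift], lift))
        runmax = np.maximum.accumulate(lift)
        runmax = np.maximum(runmax, self._runmax)
        top = runmax[-1]
        n_top = int(np.floor((top - self.level0) / self.period))
        if n_top >= self._n_next:
            levels = self.level0 + self.period * np.arange(
                self._n_next, n_top + 1)
            idx = np.searchsorted(runmax, levels, side="left")
            # runmax attains a new record at idx, so lift[idx] >= level and
            # lift[idx-1] < level: interpolate inside the straddling step
            lo = lift[idx - 1]
            hi = lift[idx]
            frac = (levels - lo) / (hi - lo)
            self.times.append(t[idx - 1] + frac * (t[idx] - t[idx - 1]))
            self._n_next = n_top + 1
        self._runmax = runmax[-1]
        self._prev_t = t[-1]
        self._prev_lift = lift[-1]

    def train(self, curve_kind: str = "", t_start: float = 0.0,
              t_end: float | None = None) -> EventTrain:
        times = (np.concatenate(self.times) if self.times
                 else np.empty(0))
        if t_end is None:
            t_end = self._prev_t if self._prev_t is not None else t_start
        return EventTrain(times=times, curve_kind=curve_kind,
                          t_start=t_start, t_end=t_end)


def first_passage_events(t: np.ndarray, lift: np.ndarray,
                         level0: float | None = None,
                         curve_kind: str = "") -> EventTrain:
    """Events as first passages of successive 2*pi levels above `level0`.

    `level0` defaults to the initial lift value.  One event per level
    level0 + 2*pi*n (n >= 1), at the linearly interpolated first-passage
    time; an empty train is allowed.
    """
    t = np.asarray(t, float)
    lift = np.asarray(lift, float)
    acc = FirstPassageAccumulator(level0=level0)
    acc.update(t, lift)
    return acc.train(curve_kind=curve_kind, t_start=float(t[0]),
                     t_end=float(t[-1]))


def threshold_upcrossings(t: np.ndarray, v: np.ndarray, v_th: float,
                          curve_kind: str = "threshold") -> EventTrain:
    """Events at linearly interpolated upcrossings of v_th.

    Suitable for continuously differentiable signals (the HH voltage carries
    no direct noise), where every upcrossing is an unambiguous spike.
    """
    t = np.asarray(t, float)
    v = np.asarray(v, float)
    up = np.flatnonzero((v[:-1] < v_th) & (v[1:] >= v_th))
    frac = (v_th - v[up]) / (v[up + 1] - v[up])
    times = t[up] + frac * (t[up + 1] - t[up])
    return EventTrain(times=times, curve_kind=curve_kind,
                      t_start=float(t[0]), t_end=float(t[-1]))


def to_intervals(train: EventTrain, label: str = "ISI") -> IntervalSequence:
    """Successive differences of the event times."""
    if len(train) < 2:
        raise ValueError("need at least two events to form intervals")
    return IntervalSequence(intervals=np.diff(train.times), label=label)


def events_from_trajectory(traj, curve: CountingCurve) -> EventTrain:
    """Event train of a trajectory under a counting curve.

    Threshold-type curves detect events directly (ALIF resets are recorded
    exactly by the simulator; HH spikes are V_th upcrossings); all other
    kinds go through the lifted phase and first-passage counting.
    """
    if curve.kind == "alif_threshold":
        return EventTrain(times=traj.spike_times, curve_kind=curve.kind,
                          t_start=float(traj.t0),
                          t_end=float(traj.t[-1]))
    if curve.kind == "hh_voltage_threshold":
        v_th = curve.params.get("V_th", -20.0)
        return threshold_upcrossings(traj.t, traj.V, v_th,
                                     curve_kind=curve.kind)
    lift = lift_phase(traj, curve)
    return first_passage_events(traj.t, lift, curve_kind=curve.kind)


def discard_burn_in(train: EventTrain, mean_period: float | None = None,
                    n_periods: float = BURN_IN_PERIODS,
                    n_events: int = BURN_IN_EVENTS) -> EventTrain:
    """Drop the transient head of a train before computing statistics.

    Removes all events earlier than t_start + n_periods * mean_period (the
    mean period is estimated from the train itself when not given) and then
    the first n_events of what remains.
    """
    times = train.times
    t_start = train.t_start
    if times.size > 1:
        if mean_period is None:
            mean_period = float(np.mean(np.diff(times)))
        t_start = train.t_start + n_periods * mean_period
        times = times[times >= t_start]
    if times.size > n_events:
        # the observation window opens at the last discarded event
        t_start = float(times[n_events - 1]) if n_events > 0 else t_start
    times = times[n_events:]
    return EventTrain(times=times, curve_kind=train.curve_kind,
                      t_start=t_start, t_end=train.t_end)


def intervals_to_csv(seq: IntervalSequence, path) -> None:
    """Single-column CSV with a header line carrying the label."""
    np.savetxt(path, seq.intervals, fmt="%.17g",
               header=f"label={seq.label}", comments="# ")


def intervals_from_csv(path) -> IntervalSequence:
    label = "ISI"
    with open(path) as fh:
        first = fh.readline()
        if first.startswith("#") and "label=" in first:
            label = first.split("label=")[1].strip()
    data = np.loadtxt(path, comments="#")
    return IntervalSequence(intervals=np.atleast_1d(data), label=label)


def train_to_csv(train: EventTrain, path) -> None:
    np.savetxt(path, train.times, fmt="%.17g",
               header=(f"curve={train.curve_kind} t_start={train.t_start!r} "
                       f"t_end={train.t_end!r}"), comments="# ")
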