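"""Joint-angle stimulus protocols and their segmentation into labelled intervals.

The stimulus variable throughout the package is the scape–pedicel (Sc-Pd)
joint angle of an insect antenna, in degrees, dorsal positive.  Two protocols
are provided:

* a *staircase* of ramp-and-hold deflections spanning the full working range
  (plateaus −extreme → 0 → +extreme → 0 → −extreme, so each trial contains two
  upward and two downward ramps separated by five hold phases), the protocol
  used to characterise descending interneurons; and
* a single deflect-and-return pulse used to probe one hair-field sensillum.

Traces are sampled at the mid-points of uniform ``dt`` bins, which makes each
staircase trial an exact palindrome (reversing it in time reproduces it
sample for sample) and keeps ramp slopes exactly constant between samples.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import InvalidParameterError, SegmentationError

#: interval labels
RAMP_UP = "ramp_up"
RAMP_DOWN = "ramp_down"
HOLD_VENTRAL = "hold_ventral"
HOLD_REST = "hold_rest"
HOLD_DORSAL = "hold_dorsal"
RAMP_LABELS = (RAMP_UP, RAMP_DOWN)
HOLD_LABELS = (HOLD_VENTRAL, HOLD_REST, HOLD_DORSAL)

#: half-range tags for ramps
LOWER = "lower"
UPPER = "upper"


@dataclass
class JointAngleTrace:
    """Uniformly sampled Sc-Pd joint angle (degrees, dorsal positive)."""

    angle: np.ndarray
    dt: float = 0.001
    t0: float = 0.0

    def __post_init__(self) -> None:
        self.angle = np.asarray(self.angle, dtype=float)
        if self.dt <= 0:
            raise InvalidParameterError("dt must be positive")

    @property
    def n(self) -> int:
        return self.angle.size

    @property
    def duration(self) -> float:
        return self.n * self.dt

    @property
    def times(self) -> np.ndarray:
        """Bin mid-point times."""
        return self.t0 + (np.arange(self.n) + 0.5) * self.dt

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame({"time_s": self.times, "angle_deg": self.angle})


@dataclass
class IntervalLabels:
    """Per-sample interval classification of a staircase trace.

    ``labels[k]`` is one of the five ramp/hold labels; ``half[k]`` tags ramp
    samples with the half-range they traverse (``lower`` for [−extreme, 0],
    ``upper`` for [0, +extreme]) and is empty for holds.
    """

    labels: np.ndarray
    half: np.ndarray
    dt: float
    runs: list = field(default_factory=list)  # (label, half, start, stop) per interval

    def mask(self, *labels: str, half: str | None = None) -> np.ndarray:
        m = np.isin(self.labels, labels)
        if half is not None:
            m &= self.half == half
        return m

    def counts(self) -> dict:
        out: dict = {}
        for lab, hf, _, _ in self.runs:
            out[lab] = out.get(lab, 0) + 1
        return out


def _staircase_breakpoints(velocity: float, hold_duration: float, extreme: float):
    plateaus = [-extreme, 0.0, extreme, 0.0, -extreme]
    ramp = extreme / velocity
    t, a = [0.0], [plateaus[0]]
    cur = 0.0
    for i, p in enumerate(plateaus):
        cur += hold_duration
        t.append(cur)
        a.append(p)
        if i < len(plateaus) - 1:
            cur += ramp
            t.append(cur)
            a.append(plateaus[i + 1])
    return np.array(t), np.array(a), cur


def build_staircase(
    velocity: float,
    hold_duration: float = 1.0,
    extreme: float = 50.0,
    dt: float = 0.001,
    n_trials: int = 1,
) -> JointAngleTrace:
    """Ramp-and-hold staircase −extreme → 0 → +extreme → 0 → −extreme.

    Per trial: five holds of ``hold_duration`` at the plateau sequence above,
    joined by four constant-velocity ramps (two up, two down) of slope
    ±``velocity``.  Trials are concatenated back to back (the trace ends and
    restarts at the ventral extreme, so concatenation is seamless).

    Total duration per trial is ``4*extreme/velocity + 5*hold_duration``.
    """
    if velocity <= 0 or dt <= 0:
        raise InvalidParameterError("velocity and dt must be positive")
    if extreme <= 0 or hold_duration <= 0 or n_trials < 1:
        raise InvalidParameterError("extreme, hold_duration must be positive; n_trials >= 1")
    bt, ba, total = _staircase_breakpoints(velocity, hold_duration, extreme)
    n = int(round(total / dt))
    tmid = (np.arange(n) + 0.5) * dt
    trial = np.interp(tmid, bt, ba)
    return JointAngleTrace(np.tile(trial, n_trials), dt=dt)


def build_single_hair_protocol(
    amplitude: float,
    velocity: float,
    hold_duration: float = 1.0,
    dt: float = 0.001,
    lead_duration: float = 0.5,
) -> JointAngleTrace:
    """Deflect-and-return pulse for one sensillum.

    Zero baseline (``lead_duration``), ramp up at ``velocity`` to
    ``amplitude``, hold for ``hold_duration``, ramp back down, zero tail of
    ``lead_duration``.  ``amplitude == 0`` yields a constant-zero trace.
    """
    if amplitude < 0:
        raise InvalidParameterError("amplitude must be non-negative")
    if velocity <= 0 or dt <= 0 or hold_duration <= 0:
        raise InvalidParameterError("velocity, hold_duration and dt must be positive")
    ramp = amplitude / velocity
    bt = np.array([0.0, lead_duration, lead_duration + ramp,
                   lead_duration + ramp + hold_duration,
                   lead_duration + 2 * ramp + hold_duration,
                   2 * lead_duration + 2 * ramp + hold_duration])
    ba = np.array([0.0, 0.0, amplitude, amplitude, 0.0, 0.0])
    n = int(round(bt[-1] / dt))
    tmid = (np.arange(n) + 0.5) * dt
    return JointAngleTrace(np.interp(tmid, bt, ba), dt=dt)


def segment_intervals(
    trace: JointAngleTrace,
    slope_tolerance: float = 0.5,
    angle_tolerance: float = 1.0,
) -> IntervalLabels:
    """Label every sample of a piecewise-linear trace as ramp or hold.

    A sample is a ramp sample when both its forward and backward finite
    differences exceed ``slope_tolerance`` (°/s) in magnitude with a common
    sign; this assigns breakpoint-straddling samples to the hold side and
    makes the labelled ramp length exact on generated staircases.  Holds are
    classified by plateau angle (ventral < −``angle_tolerance`` < rest <
    +``angle_tolerance`` < dorsal); ramps are tagged ``lower``/``upper`` by
    the half-range they traverse.

    Raises
    ------
    SegmentationError
        If the trace is not piecewise linear (ramp slopes not constant).
    """
    a = trace.angle
    if a.size < 3:
        raise SegmentationError("trace too short to segment")
    d = np.diff(a) / trace.dt
    fwd = np.concatenate([d, d[-1:]])
    bwd = np.concatenate([d[:1], d])
    is_ramp = (np.abs(fwd) > slope_tolerance) & (np.abs(bwd) > slope_tolerance) \
        & (np.sign(fwd) == np.sign(bwd))

    labels = np.empty(a.size, dtype="<U12")
    half = np.full(a.size, "", dtype="<U5")
    runs = []
    start = 0
    for stop in list(np.flatnonzero(np.diff(is_ramp.astype(np.int8))) + 1) + [a.size]:
        seg = slice(start, stop)
        med = float(np.median(a[seg]))
        if is_ramp[start]:
            # constant-slope check: interior slopes must agree
            interior = d[start:stop - 1]
            if interior.size:
                ref = float(np.median(interior))
                if np.abs(interior - ref).max() > max(slope_tolerance, 0.02 * abs(ref)):
                    raise SegmentationError("ramp slope is not constant; trace is not piecewise linear")
            lab = RAMP_UP if np.median(d[start:max(stop - 1, start + 1)]) > 0 else RAMP_DOWN
            hf = LOWER if med < 0 else UPPER
        else:
            if med < -angle_tolerance:
                lab = HOLD_VENTRAL
            elif med > angle_tolerance:
                lab = HOLD_DORSAL
            else:
                lab = HOLD_REST
            hf = ""
        labels[seg] = lab
        half[seg] = hf
        runs.append((lab, hf, start, stop))
        start = stop
    return IntervalLabels(labels=labels, half=half, dt=trace.dt, runs=runs)
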