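"""Hair-field mechanoreceptor model: joint angle → hair deflection → spikes.

Two rows of proprioceptive hairs (one dorsal, one ventral) flank the Sc-Pd
joint.  Hairs in a row are spaced so that the number of deflected hairs grows
linearly with joint excursion into that row's half-range: hair *i* starts
deflecting once the joint passes its onset angle ``(i-1) * onset_spacing`` and
its deflection then grows 1:1 with the joint angle (``slope``) up to a
saturation angle ``max_deflection``.

Each hair's afferent converts deflection into an activation — a lead-lag sum
of a low-pass (tonic, position) and a high-pass (phasic, velocity) filtered
copy of the deflection, minus an offset, divided by a normalisation — which
approximates the afferent membrane potential.  A noisy spike generator turns
activation into spikes: at every 1-ms step a spike is fired when
``act * dt * Rmax`` exceeds a uniform random draw, subject to an absolute
refractory period.  The phasic-tonic structure of real hair-plate afferents
(sustained rate ∝ amplitude, peak rate ∝ velocity) emerges from the default
constants: LPF 10 ms / ×2, HPF 30 ms / ×20, offset 35, norm 100,
Rmax 300 s⁻¹, refractory 3 ms.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import GridMismatchError, InvalidParameterError
from .filters import highpass, lowpass
from .stimulus import JointAngleTrace, build_single_hair_protocol

DORSAL = "dorsal"
VENTRAL = "ventral"


@dataclass(frozen=True)
class HairRowConfig:
    """Geometry of one hair row."""

    side: str
    n_hairs: int = 20
    onset_spacing: float = 2.5  # degrees of joint angle between hair onsets
    slope: float = 1.0          # d(hair deflection)/d(joint angle) past onset
    max_deflection: float = 50.0  # saturation angle of a single hair

    def __post_init__(self) -> None:
        if self.side not in (DORSAL, VENTRAL):
            raise InvalidParameterError(f"side must be '{DORSAL}' or '{VENTRAL}'")
        if self.n_hairs < 1 or self.onset_spacing <= 0 or self.max_deflection <= 0:
            raise InvalidParameterError("n_hairs, onset_spacing, max_deflection must be positive")

    @property
    def onsets(self) -> np.ndarray:
        """Onset joint angles (magnitude on this row's side) of each hair."""
        return np.arange(self.n_hairs) * self.onset_spacing


def default_rows() -> tuple[HairRowConfig, HairRowConfig]:
    return HairRowConfig(DORSAL), HairRowConfig(VENTRAL)


@dataclass(frozen=True)
class AfferentParams:
    """Filter/spike-generator parameters shared by all hair afferents."""

    lpf_tau: float = 0.010
    lpf_weight: float = 2.0
    hpf_tau: float = 0.030
    hpf_weight: float = 20.0
    offset: float = 35.0
    norm: float = 100.0
    rmax: float = 300.0
    dt: float = 0.001
    refractory: float = 0.003

    def __post_init__(self) -> None:
        if min(self.lpf_tau, self.hpf_tau, self.norm, self.rmax, self.dt) <= 0:
            raise InvalidParameterError("taus, norm, rmax and dt must be positive")
        if self.refractory < 0:
            raise InvalidParameterError("refractory must be non-negative")


@dataclass
class ActivationTrace:
    """Dimensionless activation (abstracted membrane potential) over time."""

    values: np.ndarray
    dt: float

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)

    @property
    def n(self) -> int:
        return self.values.size


@dataclass
class SpikeTrain:
    """Ordered spike times on a fixed time grid.

    Spikes live at bin mid-points ``(index + 0.5) * dt`` so they align with
    the stimulus sampling convention.
    """

    spike_times: np.ndarray
    duration: float
    dt: float

    def __post_init__(self) -> None:
        self.spike_times = np.asarray(self.spike_times, dtype=float)
        if self.spike_times.size and (
            np.any(np.diff(self.spike_times) <= 0)
            or self.spike_times[0] < 0
            or self.spike_times[-1] >= self.duration
        ):
            raise InvalidParameterError("spike times must be strictly increasing within [0, duration)")

    @classmethod
    def from_indices(cls, indices: np.ndarray, dt: float, duration: float) -> "SpikeTrain":
        return cls((np.asarray(indices) + 0.5) * dt, duration, dt)

    @property
    def indices(self) -> np.ndarray:
        return np.floor(self.spike_times / self.dt).astype(int)

    @property
    def n_spikes(self) -> int:
        return self.spike_times.size

    def mean_rate(self) -> float:
        return self.n_spikes / self.duration

    def counts(self, n_bins: int) -> np.ndarray:
        """Spike count per grid bin."""
        return np.bincount(self.indices, minlength=n_bins).astype(float)


def deflect_hairs(trace: JointAngleTrace, row: HairRowConfig) -> np.ndarray:
    """Per-hair deflection angle (degrees), shape ``(n_hairs, n_samples)``.

    A hair deflects only when the joint is on its row's side and past the
    hair's onset angle; beyond that the deflection grows with ``slope`` until
    it saturates at ``max_deflection``.
    """
    onside = np.maximum(trace.angle if row.side == DORSAL else -trace.angle, 0.0)
    defl = row.slope * (onside[None, :] - row.onsets[:, None])
    return np.clip(defl, 0.0, row.max_deflection)


def lead_lag_activation(
    deflection: np.ndarray, params: AfferentParams, dt: float | None = None
) -> ActivationTrace:
    """Lead-lag activation of one afferent from its deflection trace.

    ``act = (w_l·LPF_τl(θ) + w_h·HPF_τh(θ) − offset) / norm``; filters start
    in steady state for the first sample so a protocol that begins mid-hold
    produces no spurious onset transient.
    """
    dt = params.dt if dt is None else dt
    if abs(dt - params.dt) > 1e-12:
        raise GridMismatchError(f"deflection grid dt={dt} does not match params.dt={params.dt}")
    return ActivationTrace(_lead_lag(np.asarray(deflection, dtype=float), params), dt=params.dt)


def _lead_lag(deflection: np.ndarray, params: AfferentParams) -> np.ndarray:
    lp = lowpass(deflection, params.lpf_tau, params.dt)
    hp = highpass(deflection, params.hpf_tau, params.dt)
    return (params.lpf_weight * lp + params.hpf_weight * hp - params.offset) / params.norm


def spike_probability(act: np.ndarray, rmax: float, dt: float) -> np.ndarray:
    """Per-step spike probability ``min(max(act, 0) * dt * rmax, 1)``."""
    return np.minimum(np.clip(act, 0.0, None) * dt * rmax, 1.0)


def generate_spike_train(
    act: ActivationTrace | np.ndarray,
    rmax: float,
    dt: float | None = None,
    refractory: float = 0.0,
    rng: np.random.Generator | int | None = None,
) -> SpikeTrain:
    """Noisy spike generator with an absolute refractory period.

    At each step a spike is fired when ``act*dt*rmax`` exceeds a uniform
    random number (probability capped at 1); after a spike, further spikes
    are blocked until more than ``refractory`` seconds have elapsed.
    Negative activation yields zero probability.  Identical seeds yield
    identical trains.
    """
    if isinstance(act, ActivationTrace):
        dt = act.dt if dt is None else dt
        values = act.values
    else:
        values = np.asarray(act, dtype=float)
        if dt is None:
            raise InvalidParameterError("dt required when act is a bare array")
    if rmax <= 0 or dt <= 0:
        raise InvalidParameterError("rmax and dt must be positive")
    rng = np.random.default_rng(rng)
    p = spike_probability(values, rmax, dt)
    draws = rng.random(values.size)
    idx = _apply_refractory(np.flatnonzero(draws < p), refractory, dt)
    return SpikeTrain.from_indices(idx, dt, values.size * dt)


def _apply_refractory(candidates: np.ndarray, refractory: float, dt: float) -> np.ndarray:
    if refractory <= 0 or candidates.size == 0:
        return candidates
    min_gap = int(np.floor(refractory / dt + 1e-9)) + 1  # (j - i) * dt must exceed refractory
    keep = []
    last = -min_gap
    for j in candidates:
        if j - last >= min_gap:
            keep.append(j)
            last = j
    return np.asarray(keep, dtype=int)


def expected_rate(
    act: np.ndarray, rmax: float, dt: float, refractory: float = 0.0
) -> np.ndarray:
    """Mean-field firing rate (Hz) of the generator for slowly varying activation.

    The inter-spike interval is refractory-plus-geometric, so the stationary
    rate at per-step probability p is ``1 / (floor(refractory/dt)*dt + dt/p)``.
    """
    p = spike_probability(np.asarray(act, dtype=float), rmax, dt)
    dead = np.floor(refractory / dt + 1e-9) * dt
    with np.errstate(divide="ignore"):
        return np.where(p > 0, 1.0 / (dead + dt / np.where(p > 0, p, 1.0)), 0.0)


@dataclass
class Afferent:
    """One hair afferent's identity and simulated response."""

    side: str
    index: int
    onset: float
    activation: ActivationTrace
    spikes: SpikeTrain | None


@dataclass
class AfferentPopulationResponse:
    """Responses of the full 2×n_hairs afferent population to one stimulus."""

    afferents: list
    stimulus: JointAngleTrace
    params: AfferentParams
    rows: tuple = field(default_factory=default_rows)

    def row(self, side: str) -> list:
        return [a for a in self.afferents if a.side == side]

    def spike_count_train(self, side: str) -> np.ndarray:
        """Summed spike counts per grid step across one row."""
        n = self.stimulus.n
        out = np.zeros(n)
        for a in self.row(side):
            if a.spikes is None:
                raise InvalidParameterError("population was simulated without spike trains")
            out += a.spikes.counts(n)
        return out

    def expected_count_train(self, side: str) -> np.ndarray:
        """Summed expected spike counts per step (refractory-corrected)."""
        out = np.zeros(self.stimulus.n)
        p = self.params
        for a in self.row(side):
            out += expected_rate(a.activation.values, p.rmax, p.dt, p.refractory) * p.dt
        return out

    def to_spike_frame(self) -> pd.DataFrame:
        rows = []
        for a in self.afferents:
            if a.spikes is None:
                continue
            for t in a.spikes.spike_times:
                rows.append((f"{a.side[0]}{a.index:02d}", a.side, a.onset, t))
        return pd.DataFrame(rows, columns=["afferent_id", "side", "onset_deg", "spike_time_s"])


def simulate_hair_fields(
    trace: JointAngleTrace,
    rows: tuple[HairRowConfig, HairRowConfig] | None = None,
    params: AfferentParams | None = None,
    rng: np.random.Generator | np.random.SeedSequence | int | None = None,
    generate_spikes: bool = True,
) -> AfferentPopulationResponse:
    """Simulate both hair rows: deflection → activation → spike trains.

    Per-afferent random streams are spawned from the master seed in the order
    the rows are passed, then in hair order, so swapping the two rows (with a
    mirrored stimulus) swaps the streams with them — mirror-symmetric stimuli
    give bit-identical, side-swapped output.
    """
    if rows is None:
        rows = default_rows()
    if len(rows) != 2 or {r.side for r in rows} != {DORSAL, VENTRAL}:
        raise InvalidParameterError("exactly one dorsal and one ventral row are required")
    params = params or AfferentParams()
    if abs(trace.dt - params.dt) > 1e-12:
        raise GridMismatchError("stimulus dt must match afferent params dt")
    seeds = _spawn_seeds(rng, sum(r.n_hairs for r in rows)) if generate_spikes else None

    afferents = []
    k = 0
    for row_cfg in rows:
        defl = deflect_hairs(trace, row_cfg)
        acts = _lead_lag(defl, params)
        for i in range(row_cfg.n_hairs):
            act = ActivationTrace(acts[i], dt=params.dt)
            spikes = None
            if generate_spikes:
                spikes = generate_spike_train(
                    act, params.rmax, refractory=params.refractory,
                    rng=np.random.default_rng(seeds[k]),
                )
            afferents.append(Afferent(row_cfg.side, i, float(row_cfg.onsets[i]), act, spikes))
            k += 1
    return AfferentPopulationResponse(afferents, trace, params, tuple(rows))


def _spawn_seeds(rng, n: int):
    if isinstance(rng, np.random.SeedSequence):
        return rng.spawn(n)
    if isinstance(rng, np.random.Generator):
        return rng.bit_generator.seed_seq.spawn(n)
    return np.random.SeedSequence(rng).spawn(n)


def single_sensillum_tuning(
    amplitudes=(5.0, 10.0, 15.0, 20.0, 25.0),
    velocities=(25.0, 50.0, 90.0, 150.0, 250.0),
    params: AfferentParams | None = None,
    n_reps: int = 10,
    rng=None,
    amplitude_sweep_velocity: float = 50.0,
    velocity_sweep_amplitude: float = 25.0,
    hold_duration: float = 1.0,
    psth_window: float = 0.020,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Deflect-and-return tuning of a single sensillum.

    Returns two tables: mean sustained rate (during the hold at amplitude)
    per deflection amplitude, and peak rate (PSTH maximum over ``n_reps``
    repetitions, boxcar-smoothed over ``psth_window``) per deflection
    velocity.  Mirrors the classic single-hair characterisation in which the
    sustained rate tracks amplitude and the peak rate tracks velocity.
    """
    if len(amplitudes) == 0 or len(velocities) == 0:
        raise InvalidParameterError("amplitude and velocity sweeps must be non-empty")
    params = params or AfferentParams()
    seq = rng if isinstance(rng, np.random.SeedSequence) else np.random.SeedSequence(rng)
    amp_seeds, vel_seeds = seq.spawn(2)

    amp_rows = []
    for a_i, amp in enumerate(amplitudes):
        trace = build_single_hair_protocol(amp, amplitude_sweep_velocity,
                                           hold_duration=hold_duration, dt=params.dt)
        act = lead_lag_activation(deflect_hairs_single(trace), params)
        hold = _hold_mask(trace, amp)
        rates = []
        for r, seed in enumerate(amp_seeds.spawn(n_reps)):
            st = generate_spike_train(act, params.rmax, refractory=params.refractory,
                                      rng=np.random.default_rng(seed))
            dur = hold.sum() * params.dt
            rates.append((hold[st.indices].sum() / dur) if dur > 0 else 0.0)
        amp_rows.append((amp, float(np.mean(rates))))
    amp_table = pd.DataFrame(amp_rows, columns=["amplitude_deg", "sustained_rate_hz"])

    vel_rows = []
    win = max(1, int(round(psth_window / params.dt)))
    kernel = np.ones(win) / (win * params.dt)
    for v_i, vel in enumerate(velocities):
        trace = build_single_hair_protocol(velocity_sweep_amplitude, vel,
                                           hold_duration=hold_duration, dt=params.dt)
        act = lead_lag_activation(deflect_hairs_single(trace), params)
        counts = np.zeros(trace.n)
        for seed in vel_seeds.spawn(n_reps):
            st = generate_spike_train(act, params.rmax, refractory=params.refractory,
                                      rng=np.random.default_rng(seed))
            counts += st.counts(trace.n)
        psth = np.convolve(counts / n_reps, kernel, mode="same")
        ramp_up = np.gradient(trace.angle, params.dt) > 0.5
        peak = float(psth[ramp_up].max()) if ramp_up.any() else 0.0
        vel_rows.append((vel, peak))
    vel_table = pd.DataFrame(vel_rows, columns=["velocity_deg_s", "peak_rate_hz"])
    return amp_table, vel_table


def deflect_hairs_single(trace: JointAngleTrace) -> np.ndarray:
    """Deflection of one isolated hair driven directly by the protocol angle."""
    return np.clip(trace.angle, 0.0, None)


def _hold_mask(trace: JointAngleTrace, amplitude: float) -> np.ndarray:
    if amplitude == 0:
        return np.zeros(trace.n, dtype=bool)
    slope = np.gradient(trace.angle, trace.dt)
    return (np.abs(slope) < 0.5) & (trace.angle > 0.5 * amplitude)
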