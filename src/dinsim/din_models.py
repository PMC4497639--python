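"""Descending-interneuron (DIN) models driven by the hair-field afferents.

All DIN variants share one computational skeleton.  Afferent activity from
each hair row is integrated by a short low-pass filter (τ_L1 = 5 ms; one unit
impulse per spike, a crude postsynaptic potential), scaled by per-row gains
W_d / W_v and summed into the lumped synaptic input.  From there two branches
exist:

* **direct** (simple position-sensitive DINs, SP): the input is divided by
  the normalisation and fed straight into the spike generator — the DIN
  fires tonically whenever its hair row is deflected.
* **band-pass** (ON, OFF, dynamic position-sensitive DP, and dynamic
  extreme-position ExDP DINs): the input passes a series band-pass
  (low-pass τ = 50 ms ×2, then high-pass τ = 40 ms ×20), is rectified
  (none / abs / −abs), divided by the normalisation, and shifted by an
  offset.  The band-pass extracts transients of afferent activity, so these
  DINs respond to joint *movement*; full-wave rectification makes movement
  in both directions excitatory (ON/DP) or inhibitory (OFF, whose activation
  is ``1 − |b|/40``, i.e. the ON drive inverted, halved and riding on a
  baseline of 1 → a 30-Hz resting rate with Rmax = 30).

By default the afferent drive is the *expected* per-step spike count of each
afferent (mean-field, refractory-corrected) rather than one stochastic spike
realisation; stochasticity then enters only through the DIN's own spike
generator.  This represents the massed convergence of many afferents per
hair (the model collapses four hair fields into two 20-hair rows) and is the
regime in which the printed offsets and normalisations yield the documented
hold-phase silence of movement-sensitive DINs.  ``drive="spikes"`` switches
to single-realisation input.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .errors import GridMismatchError, InvalidParameterError
from .filters import lowpass, psc_filter
from .hair_afferents import (
    ActivationTrace,
    AfferentParams,
    AfferentPopulationResponse,
    SpikeTrain,
    generate_spike_train,
    simulate_hair_fields,
)
from .stimulus import (
    RAMP_LABELS,
    IntervalLabels,
    JointAngleTrace,
    build_staircase,
    segment_intervals,
)

DIRECT = "direct"
BANDPASS = "bandpass"
RANDOM_BRANCH = "random"
RECTIFY_MODES = ("none", "abs", "neg_abs")


@dataclass(frozen=True)
class DINParams:
    """Parameter record for one DIN model variant."""

    label: str
    branch: str = BANDPASS
    wd: float = 1.0
    wv: float = 1.0
    lpf1_tau: float = 0.005
    lpf2_tau: float = 0.050
    lpf2_weight: float = 2.0
    hpf_tau: float = 0.040
    hpf_weight: float = 20.0
    offset: float = 0.0
    rectify: str = "none"
    norm: float = 20.0
    rmax: float = 100.0
    const_activation: float = 0.2  # used only by the random branch

    def __post_init__(self) -> None:
        if self.norm <= 0 or self.rmax <= 0:
            raise InvalidParameterError("norm and rmax must be positive")
        if self.wd < 0 or self.wv < 0:
            raise InvalidParameterError("input weights must be non-negative")
        if self.rectify not in RECTIFY_MODES:
            raise InvalidParameterError(f"unknown rectify mode {self.rectify!r}; one of {RECTIFY_MODES}")
        if self.branch not in (DIRECT, BANDPASS, RANDOM_BRANCH):
            raise InvalidParameterError(f"unknown branch {self.branch!r}")


#: Presets for the modelled DIN types.
PRESETS: dict[str, DINParams] = {
    "SP_d": DINParams("SP_d", branch=DIRECT, wd=1.0, wv=0.0, norm=4.0, rmax=10.0),
    "SP_v": DINParams("SP_v", branch=DIRECT, wd=0.0, wv=1.0, norm=4.0, rmax=10.0),
    "ExDP": DINParams("ExDP", wd=1.0, wv=1.0, offset=-0.2, rectify="none", norm=20.0, rmax=100.0),
    "ON": DINParams("ON", wd=1.0, wv=1.0, offset=-0.2, rectify="abs", norm=20.0, rmax=120.0),
    "DP_d": DINParams("DP_d", wd=1.0, wv=0.0, offset=-0.2, rectify="abs", norm=20.0, rmax=100.0),
    "DP_v": DINParams("DP_v", wd=0.0, wv=1.0, offset=-0.2, rectify="abs", norm=20.0, rmax=100.0),
    "OFF": DINParams("OFF", wd=1.0, wv=1.0, offset=1.0, rectify="neg_abs", norm=40.0, rmax=30.0),
    "RANDOM": DINParams("RANDOM", branch=RANDOM_BRANCH, wd=0.0, wv=0.0, norm=1.0,
                        rmax=100.0, const_activation=0.2),
}


def preset(label: str, **overrides) -> DINParams:
    """Look up a preset by label, optionally overriding fields."""
    try:
        base = PRESETS[label]
    except KeyError:
        raise InvalidParameterError(
            f"unknown DIN preset {label!r}; valid labels: {', '.join(PRESETS)}"
        ) from None
    return replace(base, **overrides) if overrides else base


@dataclass
class DINResponse:
    """Result of simulating one DIN for one stimulus."""

    params: DINParams
    input: ActivationTrace
    activation: ActivationTrace
    spikes: SpikeTrain
    stimulus: JointAngleTrace


def integrate_afferent_input(
    pop: AfferentPopulationResponse,
    wd: float,
    wv: float,
    lpf1_tau: float = 0.005,
) -> ActivationTrace:
    """Lumped synaptic input from sampled afferent spike trains.

    Every afferent spike contributes a unit impulse to a first-order leaky
    integrator (τ = ``lpf1_tau``); row sums are weighted by ``wd``/``wv`` and
    added.  For k afferents firing steadily at rate r the mean input is
    ≈ ``k·r·lpf1_tau``.
    """
    return _integrate(pop, wd, wv, lpf1_tau, source="spikes")


def afferent_drive(
    pop: AfferentPopulationResponse,
    wd: float,
    wv: float,
    lpf1_tau: float = 0.005,
    source: str = "rate",
) -> ActivationTrace:
    """Lumped synaptic input; ``source`` selects sampled spikes or mean-field rates."""
    return _integrate(pop, wd, wv, lpf1_tau, source=source)


def _integrate(pop, wd, wv, lpf1_tau, source):
    dt = pop.params.dt
    if source == "spikes":
        d = pop.spike_count_train("dorsal")
        v = pop.spike_count_train("ventral")
    elif source == "rate":
        d = pop.expected_count_train("dorsal")
        v = pop.expected_count_train("ventral")
    else:
        raise InvalidParameterError("source must be 'rate' or 'spikes'")
    counts = wd * d + wv * v
    return ActivationTrace(psc_filter(counts, lpf1_tau, dt), dt=dt)


def din_branch(inp: ActivationTrace, params: DINParams) -> ActivationTrace:
    """Apply a DIN variant's output branch to the lumped input."""
    x, dt = inp.values, inp.dt
    if params.branch == DIRECT:
        return ActivationTrace(x / params.norm, dt=dt)
    if params.branch == RANDOM_BRANCH:
        return ActivationTrace(np.full(x.size, params.const_activation), dt=dt)
    l2 = params.lpf2_weight * lowpass(x, params.lpf2_tau, dt, y0=x[0])
    b = params.hpf_weight * (l2 - lowpass(l2, params.hpf_tau, dt, y0=l2[0]))
    if params.rectify == "abs":
        b = np.abs(b)
    elif params.rectify == "neg_abs":
        b = -np.abs(b)
    return ActivationTrace(b / params.norm + params.offset, dt=dt)


def simulate_din(
    pop: AfferentPopulationResponse,
    params: DINParams,
    rng=None,
    drive: str = "rate",
) -> DINResponse:
    """Full DIN simulation: afferent integration → branch → spike generation.

    DIN spike generation has no refractory period (Rmax alone caps the rate).
    """
    if params.branch == RANDOM_BRANCH:
        inp = ActivationTrace(np.zeros(pop.stimulus.n), dt=pop.params.dt)
    else:
        inp = afferent_drive(pop, params.wd, params.wv, params.lpf1_tau, source=drive)
    act = din_branch(inp, params)
    spikes = generate_spike_train(act, params.rmax, rng=np.random.default_rng(_as_seed(rng)))
    return DINResponse(params, inp, act, spikes, pop.stimulus)


def _as_seed(rng):
    return rng if not isinstance(rng, np.random.SeedSequence) else rng


def run_staircase_din(
    params: DINParams,
    velocity: float,
    n_trials: int = 1,
    rng=None,
    afferent_params: AfferentParams | None = None,
    hold_duration: float = 1.0,
    extreme: float = 50.0,
    drive: str = "rate",
    afferent_rng=None,
) -> tuple[list[SpikeTrain], IntervalLabels, JointAngleTrace]:
    """Convenience runner: staircase stimulus → hair fields → one DIN.

    Returns one spike train per trial (each trial re-draws only the DIN spike
    generator when ``drive='rate'``; with ``drive='spikes'`` the afferent
    realisation is shared across trials unless ``afferent_rng`` provides
    fresh entropy).
    """
    aff = afferent_params or AfferentParams()
    trace = build_staircase(velocity, hold_duration=hold_duration, extreme=extreme, dt=aff.dt)
    labels = segment_intervals(trace)
    pop = simulate_hair_fields(trace, params=aff, rng=afferent_rng,
                               generate_spikes=(drive == "spikes"))
    seq = rng if isinstance(rng, np.random.SeedSequence) else np.random.SeedSequence(rng)
    trains = []
    for child in seq.spawn(n_trials):
        trains.append(simulate_din(pop, params, rng=np.random.default_rng(child), drive=drive).spikes)
    return trains, labels, trace


def velocity_tuning(
    params: DINParams,
    velocities=(12.0, 50.0, 150.0, 400.0),
    n_sweeps: int = 4,
    rng=None,
    afferent_params: AfferentParams | None = None,
    hold_duration: float = 1.0,
    extreme: float = 50.0,
    drive: str = "rate",
    window: str = "ramps",
) -> pd.DataFrame:
    """Mean spike rate of a DIN versus staircase ramp velocity.

    The rate is measured over the movement (ramp) intervals of the staircase
    by default — for ON/DP types that is where they fire; for the OFF type
    it is where its tonic background is suppressed, so its ramp-window rate
    falls from near the 30-Hz baseline toward zero as velocity grows.
    ``window="whole_trial"`` instead reports the rate over the entire trial.
    Rates are averaged over ``n_sweeps`` repeated trials; the measurement
    window is reported in the ``measure`` column.
    """
    if min(velocities) < 1.0 or max(velocities) > 800.0:
        raise InvalidParameterError("velocities must lie within [1, 800] deg/s")
    if window not in ("ramps", "whole_trial"):
        raise InvalidParameterError("window must be 'ramps' or 'whole_trial'")
    seq = rng if isinstance(rng, np.random.SeedSequence) else np.random.SeedSequence(rng)
    measure = window
    rows = []
    for vel, child in zip(velocities, seq.spawn(len(velocities))):
        trains, labels, trace = run_staircase_din(
            params, vel, n_trials=n_sweeps, rng=child,
            afferent_params=afferent_params, hold_duration=hold_duration,
            extreme=extreme, drive=drive,
        )
        if measure == "ramps":
            mask = labels.mask(*RAMP_LABELS)
            dur = mask.sum() * trace.dt
            rates = [t.counts(trace.n)[mask].sum() / dur for t in trains]
        else:
            rates = [t.mean_rate() for t in trains]
        rows.append((vel, float(np.mean(rates)), float(np.std(rates)), measure))
    return pd.DataFrame(rows, columns=["velocity_deg_s", "rate_hz", "rate_sd_hz", "measure"])
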