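"""Populations of modelled DINs: parameter sweeps and a synthetic reference set.

Two populations are built here:

* the *sweep* population — for each DIN variant a single model parameter is
  varied continuously (ON: offset; OFF: normalisation via divisors of 40;
  SP/DP: the W_d:W_v weight proportion), plus one input-less DIN firing at
  random — used to trace trajectories through the coding-space; and
* a *synthetic reference* population standing in for a recorded DIN sample
  (which is not publicly available): five groups (SP, DP, ON, OFF, and an
  unspecific movement-type stand-in, UNSP) whose members scatter along the
  same parameter axes the sweeps use, scaled by a ``jitter`` factor, so the
  groups reproduce the characteristic layout of the recorded population
  (tight ON cluster, stripe-shaped OFF cluster, dispersed SP/DP clouds).

``run_population`` pushes every entry through the full pipeline — hair-field
simulation, DIN model, selectivity characterisation at four staircase
velocities with four trials each — and returns the neurons × 12 selectivity
matrix.  All neurons within one run listen to the same simulated sensory
periphery (one hair-field simulation per velocity), as the biological DINs
do.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .din_models import DINParams, RANDOM_BRANCH, afferent_drive, din_branch, preset
from .errors import InvalidParameterError
from .hair_afferents import AfferentParams, generate_spike_train, simulate_hair_fields
from .selectivity import (
    DEFAULT_VELOCITIES,
    SCORE_COLUMNS,
    SelectivityVector,
    interval_class_masks,
    interval_rates,
    scores_from_rates,
)
from .stimulus import build_staircase, segment_intervals

#: sweep values: a single model parameter varied per DIN variant
ON_OFFSET_SWEEP = (-0.2, -0.1, 0.0, 0.05, 0.01)
OFF_NORM_DIVISORS = (0.1, 0.4, 0.7, 1.3)
WEIGHT_RATIO_SWEEP = (0.0, 0.2, 0.4, 0.6, 0.8)
REFERENCE_GROUPS = ("SP", "DP", "ON", "OFF", "UNSP")


@dataclass
class PopulationEntry:
    name: str
    group: str
    params: DINParams
    sweep_param: str | None = None
    sweep_value: float | None = None


@dataclass
class PopulationSpec:
    entries: list
    description: str = ""

    def __len__(self) -> int:
        return len(self.entries)

    def labels(self) -> np.ndarray:
        return np.array([e.group for e in self.entries])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([
            {"name": e.name, "group": e.group, "sweep_param": e.sweep_param,
             "sweep_value": e.sweep_value, **{
                 k: getattr(e.params, k)
                 for k in ("branch", "wd", "wv", "offset", "rectify", "norm", "rmax")}}
            for e in self.entries
        ]).set_index("name")


def build_sweep_population() -> PopulationSpec:
    """Single-parameter sweeps of each DIN variant plus the random-spiking DIN.

    ON: offsets (−0.2 original, −0.1, 0, 0.05, 0.01); OFF: normalisation
    40/divisor for divisors (0.1, 0.4, 0.7, 1.3) — the most sensitive OFF
    norm, 40/1.3 ≈ 30.8, stays 1.5× the ON norm of 20; SP and DP: dorsal-
    major weight proportion 1:r for r in (0, 0.2, 0.4, 0.6, 0.8).  The
    dynamic extreme-position variant is excluded from coding-space sweeps
    (the selectivity scores cannot distinguish it from other DP types).
    """
    entries = []
    for off in ON_OFFSET_SWEEP:
        entries.append(PopulationEntry(
            f"ON_off{off:+.2f}", "ON", preset("ON", offset=off), "offset", off))
    for d in OFF_NORM_DIVISORS:
        entries.append(PopulationEntry(
            f"OFF_div{d:.1f}", "OFF", preset("OFF", norm=40.0 / d), "norm_divisor", d))
    for r in WEIGHT_RATIO_SWEEP:
        entries.append(PopulationEntry(
            f"SP_ratio{r:.1f}", "SP", preset("SP_d", wd=1.0, wv=r), "wv_ratio", r))
    for r in WEIGHT_RATIO_SWEEP:
        entries.append(PopulationEntry(
            f"DP_ratio{r:.1f}", "DP", preset("DP_d", wd=1.0, wv=r), "wv_ratio", r))
    entries.append(PopulationEntry("RANDOM", "RANDOM", preset("RANDOM"), None, None))
    return PopulationSpec(entries, "single-parameter model sweeps + random-spiking DIN")


def build_reference_population(
    n_per_group: int = 15,
    jitter: float = 1.0,
    rng=None,
) -> PopulationSpec:
    """Synthetic stand-in for a recorded DIN sample (~5 groups × 15 neurons).

    Members of each group scatter along that variant's sensitivity axis —
    the same axis the parameter sweeps traverse — with jittered *stratified*
    draws (member i covers stratum i of the span, so every sample covers the
    group's full spread), scaled by ``jitter`` (0 → every neuron identical
    to its preset):

    * ON: offset uniform in [−0.2, −0.2 + 0.25·j];
    * OFF: norm = 40/divisor, divisor uniform in [1 − 0.9·j, 1 + 0.3·j];
    * SP/DP: dorsal/ventral specimens drawn as mirrored twin pairs (same
      weight ratio and jitter), so the signed position scores are symmetric
      by construction and cannot leak into the movement axis; minor:major
      weight ratio stratified over [0.15·j, 0.8·j] — recorded position-
      sensitive DINs receive at least some input from the second hair field
      (the single-field original models sit at the top edge of the recorded
      clusters), and the sweeps' 1:0 endpoint probes that edge;
    * all of the above with ±20%·j multiplicative jitter on norm;
    * UNSP: high background rate with a weak movement response (band-pass
      variant with a large positive offset and weak gain).
    """
    if n_per_group < 1:
        raise InvalidParameterError("n_per_group must be >= 1")
    rng = np.random.default_rng(rng)
    j = float(jitter)
    entries = []

    def njit(base):  # multiplicative norm jitter, resampled if non-positive
        while True:
            v = base * (1.0 + 0.2 * j * rng.uniform(-1, 1))
            if v > 0:
                return v

    def stratified(lo: float, span: float, i: int, n: int) -> float:
        # jittered stratified draw: stratum i of n over [lo, lo + span*j]
        return lo + span * j * (i + rng.uniform()) / n

    for i in range(n_per_group):
        off = stratified(-0.2, 0.25, i, n_per_group)
        entries.append(PopulationEntry(
            f"refON_{i:02d}", "ON", preset("ON", offset=off, norm=njit(20.0)), "offset", off))
    for i in range(n_per_group):
        # stratum over the divisor span [1.3 .. 0.1], anchored at 1 for j = 0
        full = 1.3 - 1.2 * (i + rng.uniform()) / n_per_group
        div = 1.0 + j * (full - 1.0)
        entries.append(PopulationEntry(
            f"refOFF_{i:02d}", "OFF", preset("OFF", norm=njit(40.0 / div)), "norm_divisor", div))
    for grp, base_d, base_v in (("SP", "SP_d", "SP_v"), ("DP", "DP_d", "DP_v")):
        n_pairs = (n_per_group + 1) // 2
        r = norm = None
        for i in range(n_per_group):
            dorsal = (i % 2 == 0)
            if dorsal or r is None:  # draw once per dorsal/ventral twin pair
                r = stratified(0.15 * j, 0.65, i // 2, n_pairs)
                norm = njit(preset(base_d).norm)
            base = preset(base_d if dorsal else base_v)
            wd, wv = (1.0, r) if dorsal else (r, 1.0)
            entries.append(PopulationEntry(
                f"ref{grp}_{i:02d}", grp,
                replace(base, wd=wd, wv=wv, norm=norm), "wv_ratio", r))
    for i in range(n_per_group):
        # high background, few extra spikes during fast movement
        off = 0.15 * (1.0 + 0.2 * j * rng.uniform(-1, 1))
        entries.append(PopulationEntry(
            f"refUNSP_{i:02d}", "UNSP",
            replace(preset("ON"), label="UNSP", offset=off, norm=njit(200.0), rmax=100.0),
            "offset", off))
    return PopulationSpec(entries, f"synthetic reference population, {n_per_group} per group")


def run_population(
    spec: PopulationSpec,
    rng=None,
    velocities=DEFAULT_VELOCITIES,
    n_trials: int = 4,
    afferent_params: AfferentParams | None = None,
    hold_duration: float = 2.0,
    extreme: float = 50.0,
    drive: str = "rate",
) -> pd.DataFrame:
    """Characterise every entry of a population through the full pipeline.

    Returns a neurons × 12 selectivity DataFrame (columns ``SCORE_COLUMNS``)
    with a ``group`` column.  One hair-field simulation per velocity is
    shared by all neurons (they listen to the same periphery); per-neuron,
    per-trial randomness enters through the DIN spike generators, with
    streams spawned deterministically from the master seed.
    """
    aff = afferent_params or AfferentParams()
    seq = rng if isinstance(rng, np.random.SeedSequence) else np.random.SeedSequence(rng)
    aff_seq, din_seq = seq.spawn(2)

    stages = []  # per velocity: (masks, labels, drives dict, n, dt)
    for vel, aseed in zip(velocities, aff_seq.spawn(len(velocities))):
        trace = build_staircase(vel, hold_duration=hold_duration, extreme=extreme, dt=aff.dt)
        labels = segment_intervals(trace)
        pop = simulate_hair_fields(trace, params=aff, rng=aseed,
                                   generate_spikes=(drive == "spikes"))
        drives = {}
        for wd, wv in {(e.params.wd, e.params.wv) for e in spec.entries
                       if e.params.branch != RANDOM_BRANCH}:
            drives[(wd, wv)] = afferent_drive(pop, wd, wv, source=drive)
        stages.append((interval_class_masks(labels), labels, drives, trace.n, trace.dt))

    rows, valid_rows = [], []
    for entry, eseed in zip(spec.entries, din_seq.spawn(len(spec.entries))):
        p = entry.params
        scores = np.zeros((3, 4))
        valid = np.zeros((3, 4), dtype=bool)
        for jv, ((masks, labels, drives, n, dt), vseed) in enumerate(
                zip(stages, eseed.spawn(len(stages)))):
            if p.branch == RANDOM_BRANCH:
                act = din_branch(_zero_input(n, dt), p)
            else:
                act = din_branch(drives[(p.wd, p.wv)], p)
            acc: dict[str, list] = {}
            for tseed in vseed.spawn(n_trials):
                st = generate_spike_train(act, p.rmax, rng=np.random.default_rng(tseed))
                for k, r in interval_rates(st, labels, masks).items():
                    acc.setdefault(k, []).append(r)
            mean_rates = {k: float(np.mean(v)) for k, v in acc.items()}
            scores[:, jv], valid[:, jv] = scores_from_rates(mean_rates)
        vec = SelectivityVector(scores, valid, tuple(velocities))
        rows.append(vec.to_series(entry.name))
        valid_rows.append(valid.ravel())

    df = pd.DataFrame(rows)
    df.columns = SCORE_COLUMNS
    df["group"] = spec.labels()
    df.attrs["valid"] = np.asarray(valid_rows)
    return df


def _zero_input(n: int, dt: float):
    from .hair_afferents import ActivationTrace

    return ActivationTrace(np.zeros(n), dt=dt)
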