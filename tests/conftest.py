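"""Shared fixtures: small simulated objects reused across the suite."""

from __future__ import annotations

import warnings

import numpy as np
import pytest

import dinsim as ds


@pytest.fixture(scope="session")
def staircase40():
    """One 40 deg/s staircase trial with labels (the raster showcase stimulus)."""
    trace = ds.build_staircase(40.0)
    return trace, ds.segment_intervals(trace)


@pytest.fixture(scope="session")
def afferent_field40(staircase40):
    """Hair-field response (activations only) to the 40 deg/s staircase."""
    trace, _ = staircase40
    return ds.simulate_hair_fields(trace, rng=1234, generate_spikes=False)


@pytest.fixture(scope="session")
def coding_bundle():
    """Reference population + fitted coding-space + projected sweeps.

    One fixed master seed; n_trials = 8 for the recorded-like reference,
    n = 4 sweeps for the modelled parameter sweeps.
    """
    seq = np.random.SeedSequence(0)
    s_ref, s_run, s_sweep = seq.spawn(3)
    ref = ds.build_reference_population(n_per_group=15, rng=np.random.default_rng(s_ref))
    scores = ds.run_population(ref, rng=s_run, n_trials=8)
    x = scores[ds.SCORE_COLUMNS]
    groups = scores["group"].to_numpy()
    model = ds.fit_coding_space(x)
    coords = ds.project(x, model)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        accuracy = ds.fit_thresholds(coords, groups, model)
    sweeps = ds.build_sweep_population()
    swept = ds.run_population(sweeps, rng=s_sweep, n_trials=4)
    swept_coords = ds.project(swept[ds.SCORE_COLUMNS], model)
    return {
        "ref": ref, "scores": scores, "groups": groups, "model": model,
        "coords": coords, "accuracy": accuracy,
        "sweeps": sweeps, "swept": swept, "swept_coords": swept_coords,
    }
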