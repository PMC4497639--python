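"""Selectivity scores: signed rate contrasts characterising one neuron.

A neuron's response to the ramp-and-hold staircase is summarised by three
signed contrast scores, each ``s = (A − B) / (A + B)`` of mean spike rates
over two sets of stimulus intervals:

* **direction** — A: upward ramps (levation), B: downward ramps (depression);
* **position**  — A: upper-half ramps plus the dorsal hold, B: lower-half
  ramps plus the ventral holds (rest holds excluded);
* **motion**    — A: all ramps (movement), B: all holds (rest).

Scores lie in [−1, 1]; +1 means the neuron fired only in A, −1 only in B.
Evaluating the three scores at four staircase velocities yields the
12-dimensional selectivity vector that the coding-space analysis consumes.
When neither interval set contains a spike the score is undefined and is
reported as 0 with its validity flag cleared.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import InvalidParameterError
from .stimulus import (
    HOLD_DORSAL,
    HOLD_LABELS,
    HOLD_VENTRAL,
    LOWER,
    RAMP_DOWN,
    RAMP_LABELS,
    RAMP_UP,
    UPPER,
    IntervalLabels,
)

SCORE_TYPES = ("direction", "position", "motion")
DEFAULT_VELOCITIES = (12.0, 50.0, 150.0, 400.0)

#: column order of the neurons×12 selectivity matrix
SCORE_COLUMNS = [f"{s}_v{i + 1}" for s in SCORE_TYPES for i in range(4)]


def selectivity_score(rate_a: float, rate_b: float) -> tuple[float, bool]:
    """Signed contrast ``(A − B)/(A + B)`` with a validity flag.

    Returns ``(0.0, False)`` when both rates are zero (the contrast is then
    undefined; zero is the neutral value).
    """
    if rate_a < 0 or rate_b < 0:
        raise InvalidParameterError("rates must be non-negative")
    if rate_a + rate_b == 0:
        return 0.0, False
    return (rate_a - rate_b) / (rate_a + rate_b), True


def interval_class_masks(labels: IntervalLabels) -> dict[str, np.ndarray]:
    """Boolean sample masks for the six A/B interval classes.

    The settling hold at the start of the trace — the hold no ramp precedes,
    during which the preparation sits at the ventral extreme before
    stimulation begins — is excluded from every score.  This makes the
    interval sets exactly dorsoventrally symmetric: each contrast compares
    equal durations with identical transient structure (with the settling
    hold included, the lower/hold sets would span more time than their
    counterparts and a perfectly symmetric movement-sensitive neuron would
    score position up to +1/3, a pure protocol artifact).
    """
    settling = np.zeros(labels.labels.size, dtype=bool)
    if labels.runs and labels.runs[0][0] in HOLD_LABELS:
        settling[labels.runs[0][2]:labels.runs[0][3]] = True
    return {
        "up": labels.mask(RAMP_UP),
        "down": labels.mask(RAMP_DOWN),
        "upper_pos": labels.mask(RAMP_UP, RAMP_DOWN, half=UPPER) | labels.mask(HOLD_DORSAL),
        "lower_pos": (labels.mask(RAMP_UP, RAMP_DOWN, half=LOWER)
                      | labels.mask(HOLD_VENTRAL)) & ~settling,
        "ramps": labels.mask(*RAMP_LABELS),
        "holds": labels.mask(*HOLD_LABELS) & ~settling,
    }


def interval_rates(spikes, labels: IntervalLabels, masks=None) -> dict[str, float]:
    """Mean spike rate (Hz) within each interval class."""
    masks = masks or interval_class_masks(labels)
    n = labels.labels.size
    counts = spikes.counts(n)
    out = {}
    for name, m in masks.items():
        dur = m.sum() * labels.dt
        if dur == 0:
            raise InvalidParameterError(f"stimulus contains no samples of interval class {name!r}")
        out[name] = counts[m].sum() / dur
    return out


def scores_from_rates(rates: dict[str, float]):
    """(direction, position, motion) scores and validity flags from class rates."""
    d, dv = selectivity_score(rates["up"], rates["down"])
    p, pv = selectivity_score(rates["upper_pos"], rates["lower_pos"])
    m, mv = selectivity_score(rates["ramps"], rates["holds"])
    return np.array([d, p, m]), np.array([dv, pv, mv])


def score_response(spikes, labels: IntervalLabels):
    """Score one spike train against one staircase's interval labels."""
    return scores_from_rates(interval_rates(spikes, labels))


@dataclass
class SelectivityVector:
    """3 score types × 4 velocities characterisation of one neuron."""

    scores: np.ndarray          # shape (3, 4), rows follow SCORE_TYPES
    valid: np.ndarray           # shape (3, 4) bool
    velocities: tuple = DEFAULT_VELOCITIES

    def to_series(self, name=None) -> pd.Series:
        return pd.Series(self.scores.ravel(), index=SCORE_COLUMNS, name=name)

    @property
    def motion(self) -> np.ndarray:
        return self.scores[SCORE_TYPES.index("motion")]

    @property
    def position(self) -> np.ndarray:
        return self.scores[SCORE_TYPES.index("position")]

    @property
    def direction(self) -> np.ndarray:
        return self.scores[SCORE_TYPES.index("direction")]


def characterize_neuron(
    simulate_trial,
    velocities=DEFAULT_VELOCITIES,
    n_trials: int = 4,
    rng=None,
) -> SelectivityVector:
    """Run the staircase at each velocity and score the averaged responses.

    ``simulate_trial(velocity, rng) -> (SpikeTrain, IntervalLabels)`` is
    called ``n_trials`` times per velocity; per-class mean rates are averaged
    across trials *before* scoring, matching the trial-averaging convention
    of the physiological analysis.
    """
    velocities = tuple(velocities)
    if len(velocities) != 4:
        raise InvalidParameterError("exactly four analysis velocities are required")
    if any(v < 12.0 or v > 400.0 for v in velocities):
        raise InvalidParameterError("analysis velocities must lie within [12, 400] deg/s")
    seq = rng if isinstance(rng, np.random.SeedSequence) else np.random.SeedSequence(rng)
    scores = np.zeros((3, 4))
    valid = np.zeros((3, 4), dtype=bool)
    for j, (vel, child) in enumerate(zip(velocities, seq.spawn(len(velocities)))):
        acc: dict[str, list] = {}
        for trial_seed in child.spawn(n_trials):
            spikes, labels = simulate_trial(vel, np.random.default_rng(trial_seed))
            for k, r in interval_rates(spikes, labels).items():
                acc.setdefault(k, []).append(r)
        mean_rates = {k: float(np.mean(v)) for k, v in acc.items()}
        scores[:, j], valid[:, j] = scores_from_rates(mean_rates)
    return SelectivityVector(scores, valid, velocities)
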