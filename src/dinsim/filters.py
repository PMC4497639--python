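"""Discrete first-order filters shared by the afferent and interneuron models.

All filters operate on uniformly sampled traces (grid step ``dt``) and use the
exact exponential-integrator update

    y[k] = y[k-1] + (1 - exp(-dt/tau)) * (x[k] - y[k-1])

which matches the continuous first-order response at the sample points for
piecewise-constant input and is unconditionally stable.  The high-pass filter
is the complement ``x - LPF(x)``.  Spike trains are integrated with a
unit-impulse low-pass (`psc_filter`): each spike adds 1 to the state, which
then decays with time constant ``tau`` — a crude postsynaptic-current kernel.
"""

from __future__ import annotations

import numpy as np
from scipy import signal


def lowpass(x: np.ndarray, tau: float, dt: float, y0: float | np.ndarray | None = None) -> np.ndarray:
    """First-order low-pass along the last axis.

    Parameters
    ----------
    x : array, shape (..., n)
    tau : time constant in seconds (> 0)
    dt : sample step in seconds
    y0 : initial filter state; defaults to ``x[..., 0]`` (steady state for the
        first sample, so a trace that starts mid-hold starts transient-free).
    """
    if tau <= 0 or dt <= 0:
        raise ValueError("tau and dt must be positive")
    x = np.asarray(x, dtype=float)
    a = 1.0 - np.exp(-dt / tau)
    if y0 is None:
        y0 = x[..., 0]
    zi = ((1.0 - a) * np.asarray(y0, dtype=float))[..., None]
    y, _ = signal.lfilter([a], [1.0, a - 1.0], x, axis=-1, zi=zi)
    return y


def highpass(x: np.ndarray, tau: float, dt: float, y0: float | np.ndarray | None = None) -> np.ndarray:
    """First-order high-pass: identity minus the matched low-pass."""
    return np.asarray(x, dtype=float) - lowpass(x, tau, dt, y0=y0)


def psc_filter(
    counts: np.ndarray, tau: float, dt: float, y0: float | np.ndarray | None = None
) -> np.ndarray:
    """Leaky integration of a spike-count (or expected-count) train.

    Each count adds its value to the state, which decays exponentially with
    ``tau``; for a stationary train of rate r the mean output is
    ``r * dt / (1 - exp(-dt/tau))`` (≈ ``r * tau`` for dt << tau).  The
    initial state defaults to the steady-state mean for the first count, so
    a stimulus that starts mid-hold starts transient-free.
    """
    if tau <= 0 or dt <= 0:
        raise ValueError("tau and dt must be positive")
    counts = np.asarray(counts, dtype=float)
    d = np.exp(-dt / tau)
    if y0 is None:
        y0 = counts[..., 0] / (1.0 - d)
    zi = (d * np.asarray(y0, dtype=float))[..., None] * np.ones(counts.shape[:-1] + (1,))
    y, _ = signal.lfilter([1.0], [1.0, -d], counts, axis=-1, zi=zi)
    return y


def psc_mean_gain(tau: float, dt: float) -> float:
    """Steady-state mean of `psc_filter` output per unit input rate (in Hz)."""
    return dt / (1.0 - np.exp(-dt / tau))
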