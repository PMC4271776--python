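"""Shared fixtures and the independent fixed-step Euler oracle.

The Euler integrator below is deliberately naive — a plain forward-Euler
loop over the raw flux expressions — so it shares no code path with the
package's adaptive Runge-Kutta integration and can serve as an independent
oracle for trajectory values.
"""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import settings

from carrierflux import CompartmentState, TransporterParams

settings.register_profile("ci", derandomize=True, max_examples=50,
                          deadline=None)
settings.load_profile("ci")


def euler_timecourse(initial: CompartmentState, params: TransporterParams,
                     times: np.ndarray, dt: float = 1e-5):
    """Fixed-step forward-Euler solution of the coupled (A_in, B_in) system.

    Returns (A_in, B_in) arrays at the requested ``times`` (minutes).
    Flux expressions are written out locally, independent of the package's
    right-hand side.
    """
    times = np.asarray(times, dtype=float)
    V, K, h = params.V, params.K, params.h
    Ao, Bo = initial.A_out, initial.B_out
    a, b = initial.A_in, initial.B_in
    tot_o = Ao + Bo

    out_a = np.empty_like(times)
    out_b = np.empty_like(times)
    t = 0.0
    i = 0
    n_steps = int(round(times[-1] / dt))
    for step in range(n_steps + 1):
        t = step * dt
        while i < times.size and times[i] <= t + dt / 2:
            out_a[i] = a
            out_b[i] = b
            i += 1
        if i >= times.size:
            break
        tot_i = a + b
        den = 2 * tot_o * tot_i + K * (h + 1) * (tot_o + tot_i) + 2 * h * K * K
        if den == 0.0:
            da = db = 0.0
        else:
            da = 2 * V * (Ao * (b + K * h) - a * (Bo + K * h)) / den
            db = 2 * V * (Bo * (a + K * h) - b * (Ao + K * h)) / den
        a += dt * da
        b += dt * db
    return out_a, out_b


@pytest.fixture
def generic_params():
    """The dimensionless illustration parameters used for model behaviour."""
    return TransporterParams(V=1.0, K=0.5, h=0.5)


@pytest.fixture
def rng():
    return np.random.default_rng(20240117)
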