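"""Synthetic periodic time series with known ground truth.

These generators validate the rhythm-analysis layer (peak finding, period
estimation, actograms) independently of the ODE model: each series has a
known period, phase and noise level, so recovery can be asserted exactly.
"""

from __future__ import annotations

import numpy as np

__all__ = ["synth_fixture"]


def synth_fixture(kind: str, *, period: float = 24.0, phase: float = 0.0,
                  n_days: float = 30.0, dt: float = 0.1,
                  amplitude: float = 1.0, offset: float = 2.0,
                  noise_sd: float = 0.0, drift_h_per_day: float = 0.0,
                  duty: float = 0.5, seed: int = 0):
    """Generate a (t, x) pair of a known rhythmic signal.

    Parameters
    ----------
    kind : 'sinusoid' | 'square' | 'drifting'
        ``sinusoid`` peaks at ``phase`` (h) each cycle; ``square`` is high
        for ``duty`` of each cycle starting at ``phase``; ``drifting`` is a
        sinusoid whose daily peak moves earlier by ``drift_h_per_day``
        (i.e. instantaneous period ``24 - drift`` on a 24-h raster).
    noise_sd : additive white Gaussian noise, drawn from ``seed``.
    """
    t = np.arange(0.0, n_days * 24.0, dt)
    if kind == "sinusoid":
        x = offset + amplitude * np.cos(2 * np.pi * (t - phase) / period)
    elif kind == "square":
        u = ((t - phase) % period) / period
        x = offset + amplitude * (u < duty)
    elif kind == "drifting":
        eff = period - drift_h_per_day * period / 24.0
        x = offset + amplitude * np.cos(2 * np.pi * (t - phase) / eff)
    else:
        raise ValueError("kind must be 'sinusoid', 'square' or 'drifting'")
    if noise_sd > 0:
        x = x + np.random.default_rng(seed).normal(0.0, noise_sd, t.shape)
    return t, x
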