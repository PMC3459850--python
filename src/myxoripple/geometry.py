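"""Angle and periodic-domain helpers shared across the simulator.

Angles are radians, counter-clockwise from +x, wrapped to [0, 2π).
"""

from __future__ import annotations

import numpy as np

TWO_PI = 2.0 * np.pi

__all__ = ["TWO_PI", "wrap_angle", "signed_angle_diff", "nematic_diff",
           "min_image", "nematic_order"]


def wrap_angle(theta):
    """Wrap angle(s) to [0, 2π)."""
    return np.mod(theta, TWO_PI)


def signed_angle_diff(a, b):
    """Signed circular difference a − b mapped to (−π, π]."""
    d = np.mod(np.asarray(a) - np.asarray(b) + np.pi, TWO_PI) - np.pi
    # mod maps exact +π to −π; keep the (−π, π] convention
    return np.where(d == -np.pi, np.pi, d)


def nematic_diff(a, b):
    """Head–tail-symmetric difference a − b mapped to [−π/2, π/2)."""
    return np.mod(np.asarray(a) - np.asarray(b) + np.pi / 2, np.pi) - np.pi / 2


def min_image(delta, length):
    """Minimum-image displacement for a periodic axis of the given length."""
    return delta - length * np.round(np.asarray(delta) / length)


def nematic_order(theta) -> float:
    """Nematic order parameter S = |⟨exp(2iθ)⟩| of an orientation sample.

    1 for a perfectly aligned (head–tail symmetric) population, ~0 for
    isotropic orientations.
    """
    theta = np.asarray(theta, dtype=float)
    return float(np.hypot(np.mean(np.cos(2 * theta)), np.mean(np.sin(2 * theta))))
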