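"""Planar geometry helpers shared across the package.

Conventions used everywhere in icebear:

* positions are km on a local projected plane (x east, y north);
* angles are radians, counter-clockwise positive, 0 along +x;
* wrapped angles live in (-pi, pi].
"""

from __future__ import annotations

import numpy as np

TWO_PI = 2.0 * np.pi


def wrap_angle(a):
    """Wrap angle(s) to (-pi, pi]."""
    a = np.asarray(a, dtype=float)
    w = np.mod(a + np.pi, TWO_PI) - np.pi
    # mod gives [-pi, pi); move the closed end to +pi
    w = np.where(w == -np.pi, np.pi, w)
    if w.ndim == 0:
        return float(w)
    return w


def bearing(dx, dy):
    """Bearing of displacement(s), ccw from +x, in (-pi, pi]."""
    return wrap_angle(np.arctan2(dy, dx))


def rotate(u, v, theta):
    """Rotate vector(s) (u, v) counter-clockwise by theta radians."""
    c, s = np.cos(theta), np.sin(theta)
    return c * u - s * v, s * u + c * v


def speed(u, v):
    return np.hypot(u, v)
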