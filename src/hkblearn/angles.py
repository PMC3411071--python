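"""Angle conventions.

Public interfaces speak degrees (the convention of the bimanual-coordination
literature); all numerics run in radians.  Wrapped angles live on the
half-open interval (-180, 180] degrees, i.e. (-pi, pi] radians, so that the
anti-phase pattern is reported as +180 rather than -180.
"""

from __future__ import annotations

import numpy as np

__all__ = ["wrap_deg", "wrap_rad", "circular_distance_deg"]


def wrap_rad(phi):
    """Wrap angle(s) in radians onto (-pi, pi]."""
    phi = np.asarray(phi, dtype=float)
    wrapped = -((-phi + np.pi) % (2.0 * np.pi) - np.pi)
    return wrapped if wrapped.ndim else float(wrapped)


def wrap_deg(phi):
    """Wrap angle(s) in degrees onto (-180, 180]."""
    phi = np.asarray(phi, dtype=float)
    wrapped = -((-phi + 180.0) % 360.0 - 180.0)
    return wrapped if wrapped.ndim else float(wrapped)


def circular_distance_deg(a, b):
    """Shortest angular distance |a - b| on the circle, in degrees (0..180)."""
    return np.abs(wrap_deg(np.asarray(a, dtype=float) - np.asarray(b, dtype=float)))
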