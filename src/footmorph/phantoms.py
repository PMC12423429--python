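"""Analytic muscle phantoms with closed-form true volumes.

A phantom is a solid of revolution defined by a radius profile r(x) on
[0, L]; its cross-sectional area at x is pi*r(x)^2.  Phantoms provide an
exact oracle against which the slice-sum volume estimators are validated:

========================  ==============================  =======================
family                    radius profile                  true volume
========================  ==============================  =======================
cylinder                  r_max                           pi*r_max^2*L
cone                      r_max*x/L (apex at x=0)         (1/3)*pi*r_max^2*L
linear_frustum            r_min + (r_max-r_min)*x/L       (pi*L/3)*(r_min^2 +
                                                          r_min*r_max + r_max^2)
fusiform_sine             r_max*sin(pi*x/L)               pi*r_max^2*L/2
========================  ==============================  =======================

The fusiform (spindle-shaped) phantom mimics a belly-shaped muscle such as
the flexor digitorum brevis; its volume follows from the half-period
average of sin^2 being 1/2.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .morphometry import CSASeries

__all__ = ["ShapeSpec", "FAMILIES", "csa_profile", "true_volume", "sample_slices"]

FAMILIES = ("cylinder", "cone", "linear_frustum", "fusiform_sine")


@dataclass(frozen=True)
class ShapeSpec:
    """Geometry of one muscle phantom.

    Parameters
    ----------
    family : {"cylinder", "cone", "linear_frustum", "fusiform_sine"}
    length : float
        Axial length L, cm, > 0.
    r_max : float
        Maximum radius, cm, > 0.
    r_min : float
        Smaller end radius, cm (linear_frustum only), 0 <= r_min <= r_max.
    """

    family: str
    length: float
    r_max: float
    r_min: float = 0.0

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ValueError(f"unknown phantom family {self.family!r}; choose from {FAMILIES}")
        if self.length <= 0:
            raise ValueError("length must be > 0")
        if self.r_max <= 0:
            raise ValueError("r_max must be > 0")
        if not (0.0 <= self.r_min <= self.r_max):
            raise ValueError("r_min must satisfy 0 <= r_min <= r_max")

    def radius_at(self, position):
        """Radius r(x) of the phantom, cm; vectorized over position."""
        x = np.asarray(position, dtype=float)
        if np.any(x < 0) or np.any(x > self.length):
            raise ValueError(f"position outside [0, {self.length}]")
        if self.family == "cylinder":
            r = np.full_like(x, self.r_max)
        elif self.family == "cone":
            r = self.r_max * x / self.length
        elif self.family == "linear_frustum":
            r = self.r_min + (self.r_max - self.r_min) * x / self.length
        else:  # fusiform_sine
            r = self.r_max * np.sin(math.pi * x / self.length)
        return float(r) if r.ndim == 0 else r


def csa_profile(shape: ShapeSpec, position):
    """Cross-sectional area pi*r(x)^2 of a phantom at ``position`` (cm^2)."""
    r = shape.radius_at(position)
    a = math.pi * np.square(r)
    return float(a) if np.ndim(a) == 0 else a


def true_volume(shape: ShapeSpec) -> float:
    """Closed-form volume of a phantom, cm^3."""
    L, rmax, rmin = shape.length, shape.r_max, shape.r_min
    if shape.family == "cylinder":
        return math.pi * rmax**2 * L
    if shape.family == "cone":
        return math.pi * rmax**2 * L / 3.0
    if shape.family == "linear_frustum":
        return (math.pi * L / 3.0) * (rmin**2 + rmin * rmax + rmax**2)
    # integral of pi*r_max^2*sin^2(pi x/L) dx over [0, L]
    return math.pi * rmax**2 * L / 2.0


def sample_slices(shape: ShapeSpec, spacing: float, offset: float = 0.0) -> CSASeries:
    """Sample a phantom on a regular slice grid, emulating serial imaging.

    Slices sit at ``offset, offset+spacing, ...`` up to the phantom length;
    areas are the exact ``csa_profile`` values at those positions.

    Parameters
    ----------
    spacing : float
        Inter-slice distance, cm; must satisfy 0 < spacing < length.
    offset : float
        Position of the first slice, cm, in [0, spacing).
    """
    if not (0 < spacing < shape.length):
        raise ValueError("spacing must satisfy 0 < spacing < length (too few slices otherwise)")
    if not (0 <= offset < spacing):
        raise ValueError("offset must satisfy 0 <= offset < spacing")
    n = int(math.floor((shape.length - offset) / spacing + GRID_EPS)) + 1
    positions = offset + spacing * np.arange(n)
    areas = csa_profile(shape, positions)
    return CSASeries(positions=positions, areas=np.asarray(areas, dtype=float), spacing=spacing)


# guard against float drop-off of the final slice (e.g. 10/0.5 -> 19.999...)
GRID_EPS = 1e-9
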