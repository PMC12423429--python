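"""Muscle volume estimation from serial cross-sectional areas.

A muscle imaged every ``h`` cm yields an ordered series of cross-sectional
areas (CSAs).  Two classical estimators turn such a series into a volume:

* **truncated cone** — each pair of consecutive slices bounds a conical
  frustum whose radii are the equivalent-circle radii ``sqrt(A/pi)`` of the
  two slice areas; the muscle volume is the sum of the N-1 frustum volumes
  ``(1/3)*pi*h*(r^2 + r*R + R^2)``.
* **Cavalieri (cylinder)** — each slice contributes a disc of volume
  ``A*h``; the muscle volume is the plain slice sum ``sum(A_i)*h`` over all
  N slices.

The truncated-cone sum is exact whenever the radius profile is piecewise
linear between the sampled positions; the Cavalieri sum spans one extra
slice thickness of axial extent, so on a constant-area series the two
estimates differ by exactly one slice volume ``B*h``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

__all__ = [
    "CSASeries",
    "FrustumSegment",
    "VolumeEstimate",
    "VolumeEstimator",
    "area_to_radius",
    "frustum_volume",
    "truncated_cone_volume",
    "cavalieri_volume",
    "thickness_from_pair",
]

#: absolute tolerance for the strict slice-grid check (cm)
GRID_TOL = 1e-9


@dataclass(frozen=True)
class CSASeries:
    """Ordered serial cross-sectional areas for one foot/modality/trial.

    Parameters
    ----------
    positions : array-like of float
        Slice positions along the muscle axis, cm, strictly increasing.
    areas : array-like of float
        Cross-sectional areas at each position, cm^2, all >= 0.
    spacing : float
        Nominal inter-slice spacing, cm (protocol default 0.5).
    unit, modality, trial
        Optional identifying labels carried through the pipeline.
    strict_grid : bool
        If True (default) consecutive gaps must equal ``spacing`` to within
        1e-9 cm; if False, arbitrary strictly-increasing positions are
        accepted and estimators use the per-pair actual gaps.
    """

    positions: np.ndarray
    areas: np.ndarray
    spacing: float = 0.5
    unit: str = ""
    modality: str = ""
    trial: int = 0
    strict_grid: bool = True

    def __post_init__(self) -> None:
        pos = np.asarray(self.positions, dtype=float)
        area = np.asarray(self.areas, dtype=float)
        object.__setattr__(self, "positions", pos)
        object.__setattr__(self, "areas", area)
        if pos.ndim != 1 or area.ndim != 1 or pos.size != area.size:
            raise ValueError("positions and areas must be 1-D and equal length")
        if pos.size < 2:
            raise ValueError("a CSA series needs at least 2 slices")
        if self.spacing <= 0:
            raise ValueError("spacing must be > 0")
        gaps = np.diff(pos)
        if np.any(gaps <= 0):
            raise ValueError("slice positions must be strictly increasing")
        if self.strict_grid and np.any(np.abs(gaps - self.spacing) > GRID_TOL):
            raise ValueError(
                f"slice gaps deviate from the nominal {self.spacing} cm grid "
                f"(max deviation {np.max(np.abs(gaps - self.spacing)):.3g} cm); "
                "pass strict_grid=False to accept irregular spacing"
            )
        if np.any(area < 0):
            raise ValueError("areas must be non-negative")

    @property
    def n_slices(self) -> int:
        return int(self.positions.size)

    @property
    def length(self) -> float:
        """Axial extent from first to last slice, cm."""
        return float(self.positions[-1] - self.positions[0])


@dataclass(frozen=True)
class FrustumSegment:
    """One conical frustum between two adjacent slices.

    ``r`` and ``R`` are the equivalent-circle radii of the two bounding
    slices (cm, order irrelevant), ``h`` the inter-slice distance (cm).
    """

    r: float
    R: float
    h: float

    def __post_init__(self) -> None:
        if self.r < 0 or self.R < 0:
            raise ValueError("frustum radii must be non-negative")
        if self.h <= 0:
            raise ValueError("frustum height must be positive")

    @property
    def volume(self) -> float:
        return frustum_volume(self.r, self.R, self.h)


@dataclass(frozen=True)
class VolumeEstimate:
    """A muscle volume (cm^3) together with the estimator that produced it."""

    value: float
    method: str  # "truncated_cone" | "cavalieri"
    n_slices: int


def area_to_radius(area):
    """Equivalent-circle radius (cm) of a cross-sectional area (cm^2).

    ``r = sqrt(A / pi)`` — the radius of the circle with the same area,
    which is how a CSA enters the radius-based frustum formula.
    """
    area = np.asarray(area, dtype=float)
    if np.any(area < 0):
        raise ValueError("area must be non-negative")
    r = np.sqrt(area / math.pi)
    return float(r) if r.ndim == 0 else r


def frustum_volume(r: float, R: float, h: float) -> float:
    """Volume of a conical frustum, ``(1/3)*pi*h*(r^2 + r*R + R^2)`` cm^3.

    Symmetric in ``(r, R)``; reduces to a cylinder for ``r == R`` and to a
    full cone for ``r == 0``.
    """
    if r < 0 or R < 0:
        raise ValueError("radii must be non-negative")
    if h <= 0:
        raise ValueError("height must be positive")
    lo, hi = (r, R) if r <= R else (R, r)  # fixed evaluation order keeps f(r,R) == f(R,r) bitwise
    return (1.0 / 3.0) * math.pi * h * (lo * lo + lo * hi + hi * hi)


def truncated_cone_volume(series: CSASeries, end_caps: bool = False) -> VolumeEstimate:
    """Truncated-cone (frustum-sum) volume of a CSA series.

    Sums the exact frustum volume over the N-1 consecutive slice pairs,
    converting each area to its equivalent-circle radius.  No axial
    extrapolation beyond the first/last slice unless ``end_caps`` is set,
    in which case a cone of one slice-spacing height tapering to zero is
    appended at each end.
    """
    radii = area_to_radius(series.areas)
    gaps = np.diff(series.positions)
    r, R = radii[1:], radii[:-1]
    vol = float(np.sum((math.pi / 3.0) * gaps * (r * r + r * R + R * R)))
    if end_caps:
        vol += (math.pi / 3.0) * series.spacing * (radii[0] ** 2 + radii[-1] ** 2)
    return VolumeEstimate(value=vol, method="truncated_cone", n_slices=series.n_slices)


def cavalieri_volume(series: CSASeries) -> VolumeEstimate:
    """Cavalieri (cylinder) volume: ``sum(A_i) * spacing`` over all N slices.

    Each slice is treated as a disc of thickness one nominal spacing; this
    is the slice-sum used by semi-automatic volume segmenters.
    """
    vol = float(np.sum(series.areas) * series.spacing)
    return VolumeEstimate(value=vol, method="cavalieri", n_slices=series.n_slices)


def thickness_from_pair(m1: float, m2: float) -> float:
    """Plantar fascia thickness (mm) as the mean of two image measurements."""
    if m1 < 0 or m2 < 0:
        raise ValueError("thickness measurements must be non-negative")
    return 0.5 * (m1 + m2)


class VolumeEstimator(TransformerMixin, BaseEstimator):
    """Transformer mapping CSA series to muscle volumes (cm^3).

    Parameters
    ----------
    method : {"truncated_cone", "cavalieri"}
        Which slice-sum estimator to apply.
    end_caps : bool
        Truncated-cone only: append tapering end cones (default off).

    Stateless: ``fit`` only validates parameters.  ``transform`` accepts an
    iterable of :class:`CSASeries` and returns an array of volumes.
    """

    def __init__(self, method: str = "truncated_cone", end_caps: bool = False):
        self.method = method
        self.end_caps = end_caps

    def fit(self, X: Iterable[CSASeries] | None = None, y=None) -> "VolumeEstimator":
        if self.method not in ("truncated_cone", "cavalieri"):
            raise ValueError(f"unknown volume method {self.method!r}")
        self.n_features_in_ = 1
        return self

    def transform(self, X: Sequence[CSASeries]) -> np.ndarray:
        self.fit()
        if self.method == "truncated_cone":
            return np.array(
                [truncated_cone_volume(s, end_caps=self.end_caps).value for s in X]
            )
        return np.array([cavalieri_volume(s).value for s in X])
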