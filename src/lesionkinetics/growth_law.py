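"""Mechanistic link between cell-cycle kinetics and linear radial tumour growth.

A solid tumour whose proliferation is confined to a thin outer rim of
dividing cells (thickness ``d_layer``) around a necrotic/quiescent core
expands linearly in radius: the rim volume is ``V_p = 4 pi r^2 d`` and grows
at rate ``a V_p`` with ``a = ln 2 / t_d`` (``t_d`` the cell-cycle length),
while the core volume is constant, giving ``dr/dt = a d`` and hence
``r(t) = R0 + a d t``.  Linear diameter growth translates to cubic — not
exponential — growth of total volume, which is why a piecewise *linear*
model of the longest diameter is the natural structural form for lesion
time-series of intermediate-size tumours.

This module implements that derivation as plain functions so the structural
model used downstream can be cross-checked against it.  It deliberately
excludes saturation at large volumes and the exponential regime of very
small tumours.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = [
    "GrowthLawParams",
    "growth_rate_from_doubling",
    "shell_volume",
    "radius_trajectory",
    "diameter_slope",
]


@dataclass(frozen=True)
class GrowthLawParams:
    """Parameters of the proliferating-rim growth law.

    Parameters
    ----------
    t_d:
        Cell-cycle length in hours; the proliferating-cell population
        doubles every ``t_d`` hours.
    d_layer:
        Thickness of the proliferating rim, mm.  Assumed small relative
        to the tumour radius; ``thin_rim_ok`` is False when it is not.
    r0:
        Initial tumour radius, mm.
    """

    t_d: float
    d_layer: float
    r0: float

    def __post_init__(self) -> None:
        if self.t_d <= 0:
            raise ValueError(f"cell-cycle length t_d must be > 0, got {self.t_d}")
        if self.d_layer <= 0:
            raise ValueError(f"rim thickness d_layer must be > 0, got {self.d_layer}")
        if self.r0 < 0:
            raise ValueError(f"initial radius r0 must be >= 0, got {self.r0}")

    @property
    def a(self) -> float:
        """Exponential growth rate of the proliferating cells, per hour."""
        return growth_rate_from_doubling(self.t_d)

    @property
    def thin_rim_ok(self) -> bool:
        """Whether the thin-rim assumption (d_layer < r0) holds."""
        return self.d_layer < self.r0


def growth_rate_from_doubling(t_d: float) -> float:
    """Exponential growth rate ``a = ln 2 / t_d`` for doubling time ``t_d`` hours."""
    if t_d <= 0:
        raise ValueError(f"doubling time must be > 0, got {t_d}")
    return math.log(2.0) / t_d


def shell_volume(r: float, d_layer: float) -> float:
    """Volume of a thin spherical shell, ``4 pi r^2 d_layer`` (mm^3).

    Thin-rim approximation of the exact shell difference
    ``(4/3) pi [r^3 - (r - d_layer)^3]``; relative error is O(d_layer / r).
    """
    if r <= 0:
        raise ValueError(f"radius must be > 0, got {r}")
    if d_layer <= 0:
        raise ValueError(f"layer thickness must be > 0, got {d_layer}")
    return 4.0 * math.pi * r * r * d_layer


def radius_trajectory(params: GrowthLawParams, times) -> np.ndarray:
    """Radius ``r(t) = R0 + a d_layer t`` at the given times (hours).

    This is the exact solution of ``dr/dt = a d_layer`` with ``r(0) = R0``:
    constant-speed radial expansion driven by the proliferating rim.
    """
    t = np.asarray(times, dtype=float)
    if np.any(t < 0):
        raise ValueError("times must be non-negative")
    return params.r0 + params.a * params.d_layer * t


def diameter_slope(params: GrowthLawParams) -> float:
    """Diameter growth rate implied by the rim model, mm per hour.

    Lesion data are longest *diameters*, while the derivation works in
    radius space; the diameter slope is ``2 a d_layer``.  The piecewise
    structural model downstream operates entirely in diameter space.
    """
    return 2.0 * params.a * params.d_layer
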