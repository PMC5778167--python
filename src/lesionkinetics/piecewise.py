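"""Piecewise-linear structural model for one lesion's longest-diameter course.

Under treatment a lesion's longest diameter first shrinks linearly (decay
rate ``d``, mm/day) and, once a resistant phenotype takes over at the switch
point ``sp`` (days), re-grows linearly (re-growth rate ``g``, mm/day):

    L(t) = bsl + d * t                      for t < sp
    L(t) = bsl + d * sp + g * (t - sp)      for t >= sp

The parameterisation is continuous at ``sp``: the re-growth slope acts on
time since the switch.  (The discontinuous variant in which the re-growth
term multiplies absolute time is available through ``literal_form=True``
for comparison; it jumps by ``g * sp`` at the switch.)  No sign constraint
is placed on either slope — a minority of lesions genuinely grow under
treatment or shrink after the switch, and the fitting machinery must be
able to express that.

Structural predictions may go negative under strong shrinkage; clipping at
0 mm is applied only in the observation model (:func:`observe`) so that the
model stays linear in ``(bsl, d, g)`` at fixed ``sp``, which is what the
mixed-effects likelihood machinery relies on.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["PiecewiseParams", "predict", "predict_matrix", "observe"]


@dataclass(frozen=True)
class PiecewiseParams:
    """Structural parameters of one lesion's piecewise-linear trajectory.

    bsl : baseline longest diameter at day 0, mm (> 0)
    decay : slope before the switch point, mm/day (typically <= 0)
    regrowth : slope after the switch point, mm/day (typically >= 0)
    sp : switch point from decay to re-growth, days (> 0)
    """

    bsl: float
    decay: float
    regrowth: float
    sp: float

    def __post_init__(self) -> None:
        if self.bsl <= 0:
            raise ValueError(f"baseline diameter must be > 0, got {self.bsl}")
        if self.sp <= 0:
            raise ValueError(f"switch point must be > 0, got {self.sp}")


def predict(params: PiecewiseParams, t, *, literal_form: bool = False) -> np.ndarray:
    """Structural diameter at time(s) ``t`` (days since treatment start).

    ``t = sp`` belongs to the re-growth branch.  The result may be negative;
    see module docstring.
    """
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("times must be non-negative")
    if literal_form:
        before = params.bsl + params.decay * t
        after = params.bsl + params.decay * params.sp + params.regrowth * t
        out = np.where(t < params.sp, before, after)
    else:
        design = predict_matrix(params.sp, np.atleast_1d(t))
        out = design @ np.array([params.bsl, params.decay, params.regrowth])
        out = out.reshape(np.shape(t))
    return out if out.ndim else float(out)


def predict_matrix(sp: float, times) -> np.ndarray:
    """Design matrix of the continuous piecewise model at fixed switch point.

    Row ``[1, min(t, sp), max(t - sp, 0)]`` per time, so that
    ``design @ (bsl, decay, regrowth)`` equals :func:`predict`.  ``t = sp``
    falls on the boundary where the re-growth column is exactly 0.
    """
    t = np.asarray(times, dtype=float)
    if sp <= 0:
        raise ValueError(f"switch point must be > 0, got {sp}")
    return np.column_stack([
        np.ones_like(t),
        np.minimum(t, sp),
        np.maximum(t - sp, 0.0),
    ])


def observe(params: PiecewiseParams, t, residual_sd: float,
            rng: np.random.Generator) -> np.ndarray:
    """Noisy measurement: structural prediction + N(0, residual_sd), clipped at 0 mm.

    Diameters cannot be negative, so the additive-Gaussian measurement is
    truncated at zero here — and only here.
    """
    if residual_sd < 0:
        raise ValueError(f"residual SD must be >= 0, got {residual_sd}")
    mu = np.atleast_1d(predict(params, t))
    noise = rng.normal(0.0, residual_sd, size=mu.shape) if residual_sd > 0 else 0.0
    out = np.maximum(mu + noise, 0.0)
    return out if np.ndim(t) else float(out[0])
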