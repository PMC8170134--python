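"""Zero-load geometry recovery (preshrink) and stiffness calibration.

In-vivo CMR contours are acquired under load; the approximate zero-load
geometry is obtained by shrinking the endocardial contours toward their
centroids by a small rate (2-3%), compressing the slice stack along the
long axis (3%), and rescaling the epicardial contours so the total
ventricular wall volume is conserved (wall mass conservation).

The material stiffness is then calibrated: a joint multiplicative scale on
(c1, D1, K1) of the ventricular tissue is adjusted per anchor phase with a
secant iteration until the pressurized cavity volume matches the in-vivo
target volume to 0.2% relative error (end-systole under the minimum RV
pressure with the systolic parameter set; end-diastole under the peak
pressure with the diastolic set).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq

from .errors import ConvergenceError, ValidationError
from .geometry import ContourStack

DEFAULT_TOLERANCE = 0.002  # relative cavity-volume error


@dataclass
class ShrinkSpec:
    """Preshrink rates: endocardial, long-axis, and the solved epicardial."""

    inner_rate: float = 0.03  # 2-3% endocardial shrink
    long_axis_rate: float = 0.03
    outer_rate: float | None = None  # solved for wall-volume conservation

    def validate(self) -> None:
        for r in (self.inner_rate, self.long_axis_rate):
            if not (-0.1 < r < 0.1):
                raise ValidationError("shrink rates must lie in (-0.1, 0.1)")


def wall_volume(stack: ContourStack) -> float:
    """Total ventricular wall volume (ml) by Simpson's method."""
    return stack.wall_volume_ml()


def _scale_ring(points: np.ndarray, factor: float) -> np.ndarray:
    c = points.mean(axis=0)
    return c + factor * (points - c)


def preshrink_contours(stack: ContourStack, spec: ShrinkSpec | None = None) -> ContourStack:
    """Shrink a contour stack to its approximate zero-load geometry.

    Endocardial contours shrink by ``inner_rate`` toward their centroids and
    the slice spacing by ``long_axis_rate``; a single epicardial scale
    factor (applied to the LV epicardium and the RV free-wall outer arc) is
    solved so the total wall volume is conserved to well below 0.1%.  The
    crescent RV contours share the septal arc with the scaled LV epicardium,
    so the stack stays meshable after shrinking.
    """
    spec = spec or ShrinkSpec()
    spec.validate()
    target_wall = stack.wall_volume_ml()
    fi = 1.0 - spec.inner_rate
    fz = 1.0 - spec.long_axis_rate

    def build(fo: float) -> ContourStack:
        from .geometry import ring_radius_function

        out = stack.copy()
        z = stack.z_positions()
        z0 = z.mean()
        for k, sl in enumerate(out.slices):
            sl.z = z0 + fz * (z[k] - z0)
            lv_out_old = stack.slices[k].lv_outer
            c = lv_out_old.mean(axis=0)
            sl.lv_inner = _scale_ring(stack.slices[k].lv_inner, fi)
            sl.lv_outer = _scale_ring(lv_out_old, fo)
            if sl.rv_inner is not None:
                # crescent rings: the septal radius follows the scaled
                # epicardium; the free-wall bulge above it scales with the
                # endocardial rate (inner arc) / epicardial factor (outer)
                r_sep = ring_radius_function(lv_out_old, c)
                for name, fac in (("rv_inner", fi), ("rv_outer", fo)):
                    ring_old = getattr(stack.slices[k], name)
                    rel = ring_old - c
                    theta = np.arctan2(rel[:, 1], rel[:, 0])
                    r = np.hypot(rel[:, 0], rel[:, 1])
                    bulge = np.maximum(r - r_sep(theta), 0.0)
                    r_new = fo * r_sep(theta) + fac * bulge
                    setattr(
                        sl,
                        name,
                        c + r_new[:, None] * np.column_stack([np.cos(theta), np.sin(theta)]),
                    )
        out.slice_spacing = stack.slice_spacing * fz
        return out

    def err(fo: float) -> float:
        return build(fo).wall_volume_ml() - target_wall

    lo, hi = 0.9, 1.2
    if err(lo) * err(hi) > 0:
        raise ValidationError("wall-volume conservation has no epicardial scale root")
    fo = brentq(err, lo, hi, xtol=1e-12)
    out = build(fo)
    out.validate()
    return out


@dataclass
class CalibrationState:
    """Result of the secant stiffness calibration for one anchor phase."""

    phase: str
    scale: float
    history: list = field(default_factory=list)  # (scale, volume_ml, rel_error)
    tolerance: float = DEFAULT_TOLERANCE

    @property
    def converged(self) -> bool:
        return bool(self.history) and abs(self.history[-1][2]) < self.tolerance


def secant_calibrate(
    simulate,
    target_ml: float,
    phase: str,
    s0: float = 1.0,
    tolerance: float = DEFAULT_TOLERANCE,
    max_iter: int = 25,
) -> CalibrationState:
    """Solve simulate(scale) = target with a secant iteration on log-scale.

    ``simulate`` maps a joint (c1, D1, K1) stiffness multiplier to the
    pressurized cavity volume (ml); volume decreases monotonically in the
    scale, which keeps the secant well behaved.
    """
    if target_ml <= 0:
        raise ValidationError("target volume must be positive")
    history = []

    def step(s):
        v = simulate(s)
        rel = (v - target_ml) / target_ml
        history.append((s, v, rel))
        return rel

    x0 = np.log(s0)
    f0 = step(s0)
    if abs(f0) < tolerance:
        return CalibrationState(phase, s0, history, tolerance)
    # stiffer tissue -> smaller volume: move the scale with the error sign
    x1 = x0 + np.clip(3.0 * f0, -0.5, 0.5)
    f1 = step(float(np.exp(x1)))
    it = 2
    while abs(f1) >= tolerance:
        if it >= max_iter:
            raise ConvergenceError(
                f"calibration did not converge in {max_iter} iterations",
                history=history,
            )
        denom = f1 - f0
        if denom == 0:
            raise ConvergenceError("secant stalled (flat response)", history=history)
        x2 = x1 - f1 * (x1 - x0) / denom
        x2 = float(np.clip(x2, x1 - 1.5, x1 + 1.5))
        x0, f0 = x1, f1
        x1 = x2
        f1 = step(float(np.exp(x1)))
        it += 1
    return CalibrationState(phase, float(np.exp(x1)), history, tolerance)


def calibrate_materials(
    model,
    target_edv: float,
    target_esv: float,
    tolerance: float = DEFAULT_TOLERANCE,
    max_iter: int = 25,
) -> dict[str, CalibrationState]:
    """Calibrate the two anchor-phase stiffness scales of a BiventModel.

    The systolic (end-ejection) scale is fitted so the RV volume under the
    minimum RV pressure matches the end-systolic target; the diastolic
    (end-filling) scale so the volume under the peak pressure matches the
    end-diastolic target.  The model's ``scales`` are updated in place and
    the warm-started displacement fields are cached on the model as
    ``anchor_states``.
    """
    sched = getattr(model, "pressure_schedule", None)
    if sched is None:
        raise ValidationError("model needs a pressure_schedule for calibration")
    p_min = float(sched.p_rv[sched.begin_filling])
    p_max = float(sched.p_rv[sched.begin_ejection])
    p_lv_min = float(sched.p_lv[sched.begin_filling])
    p_lv_max = float(sched.p_lv[sched.begin_ejection])

    out = {}
    anchors = {}
    for phase, (w, p_rv, p_lv, target) in {
        "end_ejection": (1.0, p_min, p_lv_min, target_esv),
        "end_filling": (0.0, p_max, p_lv_max, target_edv),
    }.items():
        cache = {"u": None}

        def simulate(scale, _phase=phase, _w=w, _p=p_rv, _pl=p_lv, _cache=cache):
            model.scales[_phase] = scale
            u = model.solve_state(_p, _pl, _w, u0=_cache["u"])
            _cache["u"] = u
            return model.cavity_volume(u, "RV")

        state = secant_calibrate(
            simulate, target, phase, tolerance=tolerance, max_iter=max_iter
        )
        model.scales[phase] = state.scale
        anchors[phase] = cache["u"]
        out[phase] = state
    model.anchor_states = anchors
    return out


def calibration_report(states: dict) -> "list[dict]":
    """Flatten calibration histories to rows (phase, iteration, scale,
    volume_ml, rel_error) for CSV export."""
    rows = []
    for phase, st in states.items():
        for i, (s, v, e) in enumerate(st.history):
            rows.append(
                {"phase": phase, "iteration": i, "scale": s, "volume_ml": v, "rel_error": e}
            )
    return rows
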