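"""Synthetic bi-ventricular geometry and loading schedules.

This module generates idealized stand-ins for segmented short-axis CMR data:
a truncated-ellipsoid left ventricle (LV) with a crescent-shaped right
ventricle (RV) wrapped around it, represented as stacked closed contours
(:class:`ContourStack`), plus a two-phase ventricular pressure waveform
(:class:`PressureSchedule`).

Conventions
-----------
* Long axis is +z; slices are ordered apex -> base.
* Lengths in mm, volumes in ml (1 ml = 1000 mm^3).
* Pressures are converted from mmHg to kPa at this module's boundary
  (1 mmHg = 0.133322 kPa).
* The RV cavity cross-section on each slice is the crescent between the LV
  epicardial circle (septal side) and an outward-bulged free-wall arc; the
  ``rv_inner`` contour is the closed polygon bounding that cavity, and
  ``rv_outer`` closes the free-wall epicardium through the same septal arc,
  so ``area(rv_outer) - area(rv_inner)`` is the RV free-wall area.
"""

from __future__ import annotations

import csv
import json
import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
from scipy.integrate import simpson
from scipy.optimize import brentq
from shapely.geometry import Polygon

from .errors import ParseError, ValidationError

MMHG_TO_KPA = 0.133322
MM3_PER_ML = 1000.0

RING_NAMES = ("lv_inner", "lv_outer", "rv_inner", "rv_outer")


# ---------------------------------------------------------------------------
# small planar-polygon helpers


def shoelace_area(points: np.ndarray) -> float:
    """Unsigned area of a closed planar polygon given as (n, 2) vertices."""
    pts = np.asarray(points, dtype=float)
    x, y = pts[:, 0], pts[:, 1]
    return 0.5 * abs(np.dot(x, np.roll(y, -1)) - np.dot(np.roll(x, -1), y))


def polygon_is_simple(points: np.ndarray) -> bool:
    return Polygon(np.asarray(points)).is_valid


def ring_radius_function(points: np.ndarray, center: np.ndarray):
    """Return a callable r(theta) for a ring star-shaped about ``center``."""
    pts = np.asarray(points, dtype=float) - np.asarray(center, dtype=float)
    theta = np.mod(np.arctan2(pts[:, 1], pts[:, 0]), 2 * np.pi)
    r = np.hypot(pts[:, 0], pts[:, 1])
    order = np.argsort(theta)
    theta, r = theta[order], r[order]
    # periodic padding for interpolation across the wrap
    theta_p = np.concatenate([theta - 2 * np.pi, theta, theta + 2 * np.pi])
    r_p = np.concatenate([r, r, r])

    def radius(q):
        return np.interp(np.mod(q, 2 * np.pi), theta_p, r_p)

    return radius


def _smoothstep(x):
    x = np.clip(x, 0.0, 1.0)
    return x * x * (3.0 - 2.0 * x)


# ---------------------------------------------------------------------------
# contour stack


@dataclass
class ContourSlice:
    """Closed contours of one short-axis slice (coordinates in mm)."""

    z: float
    lv_inner: np.ndarray
    lv_outer: np.ndarray
    rv_inner: np.ndarray | None = None
    rv_outer: np.ndarray | None = None

    def ring(self, name: str) -> np.ndarray | None:
        return getattr(self, name)


@dataclass
class ContourStack:
    """Stacked short-axis contours of a bi-ventricle (the CMR stand-in)."""

    slices: list[ContourSlice]
    slice_spacing: float
    orientation: np.ndarray = field(default_factory=lambda: np.array([0.0, 0.0, 1.0]))

    # -- validation ---------------------------------------------------------

    def validate(self) -> None:
        if len(self.slices) < 3:
            raise ValidationError("a contour stack needs at least 3 slices")
        z = self.z_positions()
        if not np.all(np.diff(z) > 0):
            raise ValidationError("slice z positions must be strictly increasing")
        for k, sl in enumerate(self.slices):
            lv_in = Polygon(sl.lv_inner)
            lv_out = Polygon(sl.lv_outer)
            for name in ("lv_inner", "lv_outer"):
                if not Polygon(sl.ring(name)).is_valid:
                    raise ValidationError(f"slice {k}: {name} is self-intersecting")
            if lv_in.area > 1e-9 and not lv_out.buffer(1e-9).contains(lv_in):
                raise ValidationError(f"slice {k}: lv_inner not inside lv_outer")
            if sl.rv_inner is not None:
                rv_in = Polygon(sl.rv_inner)
                rv_out = Polygon(sl.rv_outer)
                if not rv_in.is_valid or not rv_out.is_valid:
                    raise ValidationError(f"slice {k}: RV contour self-intersects")
                # shared septal boundary: use a tolerant cover test
                if not rv_out.buffer(1e-6).covers(rv_in):
                    raise ValidationError(f"slice {k}: rv_inner not inside rv_outer")

    # -- measurements -------------------------------------------------------

    def z_positions(self) -> np.ndarray:
        return np.array([sl.z for sl in self.slices])

    def ring_areas(self, name: str) -> np.ndarray:
        out = []
        for sl in self.slices:
            ring = sl.ring(name)
            out.append(0.0 if ring is None else shoelace_area(ring))
        return np.array(out)

    def cavity_volume_ml(self, ring: str = "rv_inner") -> float:
        """Simpson's-method cavity volume (slice areas integrated over z)."""
        if len(self.slices) < 3:
            raise ValidationError("Simpson volume needs at least 3 slices")
        areas = self.ring_areas(ring)
        return float(simpson(areas, x=self.z_positions())) / MM3_PER_ML

    def wall_volume_ml(self) -> float:
        """Total ventricular wall volume (LV wall incl. septum + RV free wall)."""
        if len(self.slices) < 3:
            raise ValidationError("wall volume needs at least 3 slices")
        a = self.ring_areas("lv_outer") - self.ring_areas("lv_inner")
        a += self.ring_areas("rv_outer") - self.ring_areas("rv_inner")
        return float(simpson(a, x=self.z_positions())) / MM3_PER_ML

    def has_rv(self) -> bool:
        return any(sl.rv_inner is not None for sl in self.slices)

    def copy(self) -> "ContourStack":
        slices = [
            ContourSlice(
                z=sl.z,
                lv_inner=sl.lv_inner.copy(),
                lv_outer=sl.lv_outer.copy(),
                rv_inner=None if sl.rv_inner is None else sl.rv_inner.copy(),
                rv_outer=None if sl.rv_outer is None else sl.rv_outer.copy(),
            )
            for sl in self.slices
        ]
        return ContourStack(slices, self.slice_spacing, self.orientation.copy())


# ---------------------------------------------------------------------------
# generator


@dataclass
class GeometryParams:
    """Parameters of the idealized bi-ventricle.

    The LV endocardium is a truncated ellipsoid of revolution with equatorial
    radius ``lv_radius`` and long semi-axis ``lv_long_axis``; the epicardium
    offsets both axes by ``lv_wall_thickness``.  The RV free wall bulges off
    the LV epicardium over an angular span of ``rv_span_deg`` with a bulge
    amplitude solved so the crescent cavity's Simpson volume matches
    ``rv_edv_ml`` (or ``rv_esv_ml`` for the end-systolic stack).  Dilated RVs
    (the repaired-TOF presentation) are obtained simply by large target
    volumes.
    """

    lv_radius: float = 25.0
    lv_long_axis: float = 60.0
    lv_wall_thickness: float = 10.0
    rv_wall_thickness: float = 5.0
    rv_span_deg: float = 150.0
    rv_center_deg: float = 0.0
    rv_edv_ml: float | None = 204.17
    rv_esv_ml: float | None = 121.26
    base_fraction: float = 0.5
    apex_fraction: float = 0.9
    rv_bottom_fraction: float = -0.5
    lv_es_scale: float = 0.85
    n_slices: int = 11

    def validate(self) -> None:
        if self.lv_radius <= 0 or self.lv_long_axis <= 0:
            raise ValidationError("ellipsoid axes must be positive")
        if self.lv_wall_thickness <= 0 or self.rv_wall_thickness <= 0:
            raise ValidationError("wall thicknesses must be positive")
        if self.n_slices < 3:
            raise ValidationError("need at least 3 slices")
        if self.rv_edv_ml is not None and self.rv_edv_ml <= 0:
            raise ValidationError("RV cavity volume must be positive")
        if not (0 < self.base_fraction <= 1) or not (0 < self.apex_fraction <= 1):
            raise ValidationError("truncation fractions must lie in (0, 1]")


def truncated_ellipsoid_volume_ml(
    a: float, c: float, base_fraction: float, apex_fraction: float = 1.0
) -> float:
    """Analytic cavity volume of an ellipsoid of revolution truncated at
    z = -apex_fraction*c and z = +base_fraction*c (closed-form oracle)."""
    f, g = base_fraction, apex_fraction
    integral = (f + g) - (f**3 + g**3) / 3.0
    return math.pi * a * a * c * integral * 1e-3


def _ellipse_radius(z, a, c):
    return a * np.sqrt(np.clip(1.0 - (z / c) ** 2, 0.0, None))


def _crescent_profile(theta_grid, span, bulge, g_exponent=0.7):
    s = np.clip(theta_grid / span, 0.0, 1.0)
    return bulge * np.sin(np.pi * s) ** g_exponent


def _thickness_taper(s):
    # full thickness over the crescent interior, smoothly collapsing to zero
    # at the junctions with the septum (first/last 12% of the span)
    return _smoothstep(s / 0.12) * _smoothstep((1.0 - s) / 0.12)


def generate_contour_stack(
    params: GeometryParams, phase: str = "ED", n_points: int = 100
) -> ContourStack:
    """Generate the idealized contour stack at end diastole or end systole.

    ``n_points`` controls contour sampling density (points per full LV ring);
    the RV free-wall arc is sampled proportionally to its angular span.
    """
    params.validate()
    if phase not in ("ED", "ES"):
        raise ValidationError(f"unknown phase {phase!r}")
    if n_points < 12:
        raise ValidationError("need at least 12 contour points per slice")

    a, c = params.lv_radius, params.lv_long_axis
    t_lv, t_rv = params.lv_wall_thickness, params.rv_wall_thickness
    rv_target = params.rv_edv_ml
    if phase == "ES":
        s = params.lv_es_scale
        a, c = a * s, c * s
        t_lv, t_rv = t_lv / s, t_rv / s  # roughly conserves wall volume
        rv_target = params.rv_esv_ml

    z = np.linspace(-params.apex_fraction * c, params.base_fraction * c, params.n_slices)
    r_in = np.maximum(_ellipse_radius(z, a, c), 1e-6)
    r_out = np.maximum(_ellipse_radius(z, a + t_lv, c + t_lv), 1e-6)

    span = math.radians(params.rv_span_deg)
    theta0 = math.radians(params.rv_center_deg) - span / 2.0

    bulge_z = None
    if rv_target is not None:
        z_bot = params.rv_bottom_fraction * c
        ramp = 0.25 * (z[-1] - z_bot)
        h = _smoothstep((z - z_bot) / ramp)

        tq = np.linspace(0.0, span, 400)

        def crescent_area(k, B):
            prof = _crescent_profile(tq, span, B * h[k])
            rin = r_out[k] + prof
            return float(np.trapezoid(0.5 * (rin**2 - r_out[k] ** 2), tq))

        def volume_err(B):
            areas = np.array([crescent_area(k, B) for k in range(len(z))])
            return float(simpson(areas, x=z)) / MM3_PER_ML - rv_target

        if volume_err(200.0) < 0:
            raise ValidationError("RV volume target too large for this geometry")
        bulge = brentq(volume_err, 1e-3, 200.0, xtol=1e-10)
        bulge_z = bulge * h

    theta_full = np.linspace(0.0, 2 * np.pi, n_points, endpoint=False)
    m_arc = max(9, int(round(n_points * span / (2 * np.pi))))
    theta_arc = np.linspace(0.0, span, m_arc)

    slices = []
    for k, zk in enumerate(z):
        lv_in = np.column_stack(
            [r_in[k] * np.cos(theta_full), r_in[k] * np.sin(theta_full)]
        )
        lv_out = np.column_stack(
            [r_out[k] * np.cos(theta_full), r_out[k] * np.sin(theta_full)]
        )
        rv_in = rv_out = None
        if bulge_z is not None and bulge_z[k] > 0.05:
            prof = _crescent_profile(theta_arc, span, bulge_z[k])
            thick = t_rv * _thickness_taper(theta_arc / span)
            ang = theta0 + theta_arc
            fw_in = np.column_stack(
                [(r_out[k] + prof) * np.cos(ang), (r_out[k] + prof) * np.sin(ang)]
            )
            fw_out = np.column_stack(
                [
                    (r_out[k] + prof + thick) * np.cos(ang),
                    (r_out[k] + prof + thick) * np.sin(ang),
                ]
            )
            septal = np.column_stack(
                [r_out[k] * np.cos(ang[::-1]), r_out[k] * np.sin(ang[::-1])]
            )[1:-1]
            rv_in = np.vstack([fw_in, septal])
            rv_out = np.vstack([fw_out, septal])
        slices.append(ContourSlice(zk, lv_in, lv_out, rv_in, rv_out))

    stack = ContourStack(slices, slice_spacing=float(z[1] - z[0]))
    stack.validate()
    return stack


# ---------------------------------------------------------------------------
# pressure schedule


@dataclass
class PressureSchedule:
    """Ventricular pressure loading over one cardiac cycle (kPa).

    ``times`` are cycle fractions in [0, 1] including both periodic
    endpoints; index 0 is the begin-ejection anchor (maximum pressure, EDV)
    and ``begin_filling`` the minimum-pressure anchor (ESV).
    """

    times: np.ndarray
    p_rv: np.ndarray
    p_lv: np.ndarray
    begin_ejection: int = 0
    begin_filling: int = 0
    systole_fraction: float = 0.4

    def validate(self) -> None:
        if abs(self.p_rv[0] - self.p_rv[-1]) > 1e-12:
            raise ValidationError("pressure waveform must be periodic")
        if np.any(self.p_rv < 0) or np.any(self.p_lv < 0):
            raise ValidationError("pressures must be non-negative")

    def phase_weight(self, t) -> np.ndarray:
        """Systolic weight in [0, 1]: 0 at begin ejection, 1 at begin filling."""
        return _two_phase_weight(np.asarray(t, dtype=float), self.systole_fraction)


def _two_phase_weight(t, ts):
    """Piecewise half-cosine weight: 0 at t=0 and t=1, 1 at t=ts."""
    t = np.mod(t, 1.0)
    w = np.where(
        t <= ts,
        0.5 * (1.0 - np.cos(np.pi * t / ts)),
        0.5 * (1.0 + np.cos(np.pi * (t - ts) / (1.0 - ts))),
    )
    return w


def generate_pressure_schedule(
    p_rv_max: float,
    p_rv_min: float = 4.0,
    p_lv_max: float = 120.0,
    n_points: int = 30,
    p_lv_min: float = 8.0,
    systole_fraction: float = 0.4,
) -> PressureSchedule:
    """Two-phase pressure waveform from peak/minimum pressures in mmHg.

    The waveform starts at the maximum (begin ejection / end diastole),
    falls to the minimum along a half-cosine over the systolic fraction of
    the cycle, and rises back along a half-cosine over the filling phase,
    so it is smooth, periodic, and attains the configured extrema exactly.
    """
    if p_rv_max <= p_rv_min or p_lv_max <= p_lv_min:
        raise ValidationError("maximum pressure must exceed minimum pressure")
    if p_rv_min < 0 or p_lv_min < 0:
        raise ValidationError("pressures must be non-negative")
    if n_points < 4:
        raise ValidationError("need at least 4 time points")
    t = np.linspace(0.0, 1.0, n_points)
    w = _two_phase_weight(t, systole_fraction)
    p_rv = (p_rv_max - (p_rv_max - p_rv_min) * w) * MMHG_TO_KPA
    p_lv = (p_lv_max - (p_lv_max - p_lv_min) * w) * MMHG_TO_KPA
    sched = PressureSchedule(
        times=t,
        p_rv=p_rv,
        p_lv=p_lv,
        begin_ejection=0,
        begin_filling=int(np.argmin(p_rv)),
        systole_fraction=systole_fraction,
    )
    sched.validate()
    return sched


# ---------------------------------------------------------------------------
# IO: CSV and JSON contour-stack interchange


def stack_to_csv(stack: ContourStack, path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["slice_id", "ring", "point_index", "x", "y", "z"])
        for k, sl in enumerate(stack.slices):
            for ring in RING_NAMES:
                pts = sl.ring(ring)
                if pts is None:
                    continue
                for i, (x, y) in enumerate(pts):
                    writer.writerow([k, ring, i, repr(float(x)), repr(float(y)), repr(float(sl.z))])


def stack_from_csv(path) -> ContourStack:
    rows: dict[int, dict[str, list]] = {}
    zs: dict[int, float] = {}
    with open(path, newline="") as fh:
        reader = csv.reader(fh)
        header = next(reader, None)
        if header != ["slice_id", "ring", "point_index", "x", "y", "z"]:
            raise ParseError(f"{path}: unexpected header {header}")
        for ln, row in enumerate(reader, start=2):
            if len(row) != 6:
                raise ParseError(f"{path}:{ln}: expected 6 fields, got {len(row)}")
            try:
                k = int(row[0])
                ring = row[1]
                x, y, z = float(row[3]), float(row[4]), float(row[5])
            except ValueError as exc:
                raise ParseError(f"{path}:{ln}: {exc}") from exc
            if ring not in RING_NAMES:
                raise ParseError(f"{path}:{ln}: unknown ring {ring!r}")
            rows.setdefault(k, {r: [] for r in RING_NAMES})[ring].append((x, y))
            zs[k] = z
    if not rows:
        raise ParseError(f"{path}: no contour rows")
    slices = []
    for k in sorted(rows):
        r = rows[k]
        slices.append(
            ContourSlice(
                z=zs[k],
                lv_inner=np.array(r["lv_inner"]),
                lv_outer=np.array(r["lv_outer"]),
                rv_inner=np.array(r["rv_inner"]) if r["rv_inner"] else None,
                rv_outer=np.array(r["rv_outer"]) if r["rv_outer"] else None,
            )
        )
    spacing = slices[1].z - slices[0].z if len(slices) > 1 else 0.0
    return ContourStack(slices, slice_spacing=spacing)


def stack_to_json(stack: ContourStack, path) -> None:
    doc = {
        "slice_spacing": stack.slice_spacing,
        "orientation": [float(v) for v in stack.orientation],
        "slices": [
            {
                "z": sl.z,
                **{
                    ring: (None if sl.ring(ring) is None else sl.ring(ring).tolist())
                    for ring in RING_NAMES
                },
            }
            for sl in stack.slices
        ],
    }
    Path(path).write_text(json.dumps(doc))


def stack_from_json(path) -> ContourStack:
    try:
        doc = json.loads(Path(path).read_text())
        slices = [
            ContourSlice(
                z=float(sd["z"]),
                **{
                    ring: (None if sd[ring] is None else np.array(sd[ring], dtype=float))
                    for ring in RING_NAMES
                },
            )
            for sd in doc["slices"]
        ]
        return ContourStack(
            slices,
            slice_spacing=float(doc["slice_spacing"]),
            orientation=np.array(doc["orientation"], dtype=float),
        )
    except (json.JSONDecodeError, KeyError, TypeError) as exc:
        raise ParseError(f"{path}: {exc}") from exc
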