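"""Structured two-layer hexahedral meshing of bi-ventricular contour stacks.

The mesher resamples every slice onto a common angular grid about the LV
centroid, builds two through-wall element layers (inner/outer) for the LV
wall and the RV free wall, and closes the crescent RV cavity by collapsing
the free wall onto the LV epicardium at the septal junction columns and at
the RV's apical extent (wedge-degenerate hexahedra, valid as long as the
Gauss-point Jacobians stay positive).

Cell labels:

* ``layer``  in {inner, outer} — through-wall position (fiber assignment).
* ``region`` in {LV, RV, septum, scar, patch} — LV wall elements facing the
  RV cavity are the septum; scar/patch are relabeled RV free-wall windows.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .errors import MeshingError, ValidationError
from .fem import element_volumes, reference_gradients, scaled_jacobians
from .geometry import ContourStack, ring_radius_function

LAYER_NAMES = ("inner", "outer")
REGION_NAMES = ("LV", "RV", "septum", "scar", "patch")


@dataclass
class VentricleMesh:
    """Volumetric bi-ventricle mesh with per-element labels and fibers."""

    nodes: np.ndarray  # (n, 3) mm
    elements: np.ndarray  # (ne, 8) hex8 connectivity
    layer: np.ndarray  # (ne,) str
    region: np.ndarray  # (ne,) str
    fiber: np.ndarray | None = None  # (ne, 3) unit vectors
    info: dict = field(default_factory=dict)

    @property
    def n_nodes(self) -> int:
        return self.nodes.shape[0]

    @property
    def n_elements(self) -> int:
        return self.elements.shape[0]

    def element_centers(self) -> np.ndarray:
        return self.nodes[self.elements].mean(axis=1)

    def wall_volume_ml(self) -> float:
        return float(element_volumes(self.nodes[self.elements]).sum()) / 1000.0

    def min_scaled_jacobian(self) -> float:
        return float(scaled_jacobians(self.nodes[self.elements]).min())


# ---------------------------------------------------------------------------
# RV free-wall / septum split of a crescent contour


def _split_crescent(points: np.ndarray, center: np.ndarray, r_lvout) -> np.ndarray:
    """Boolean mask: True where a crescent-polygon point lies on the septal
    (LV epicardial) arc rather than the free wall."""
    pts = points - center
    theta = np.arctan2(pts[:, 1], pts[:, 0])
    r = np.hypot(pts[:, 0], pts[:, 1])
    r_sep = r_lvout(theta)
    tol = np.maximum(0.02 * r_sep, 0.05)
    return np.abs(r - r_sep) <= tol


def _free_arc(points, center, r_lvout):
    """Ordered free-wall arc points of a crescent contour (may be empty)."""
    septal = _split_crescent(points, center, r_lvout)
    free_idx = np.where(~septal)[0]
    if free_idx.size == 0:
        return points[:0]
    # rotate so the free run is contiguous
    n = len(points)
    breaks = np.where(np.diff(free_idx) > 1)[0]
    if breaks.size:
        start = free_idx[breaks[0] + 1]
        order = [(start + i) % n for i in range(n)]
        free = [i for i in order if not septal[i]]
    else:
        free = list(free_idx)
    return points[free]


# ---------------------------------------------------------------------------
# mesh construction


def build_mesh(stack: ContourStack, resolution: float = 8.0) -> VentricleMesh:
    """Build a two-layer hex mesh from a contour stack.

    ``resolution`` is the target circumferential edge length in mm; radial
    resolution is fixed at two element layers through each wall and axial
    resolution follows the slice spacing.
    """
    try:
        stack.validate()
    except ValidationError as exc:
        raise MeshingError(str(exc)) from exc
    K = len(stack.slices)
    z = stack.z_positions()

    centroids = np.array([sl.lv_outer.mean(axis=0) for sl in stack.slices])
    circumference = np.mean(
        [2 * math.pi * np.hypot(*(sl.lv_outer - c).T).mean() for sl, c in zip(stack.slices, centroids)]
    )
    N = max(12, int(round(circumference / resolution)))
    theta = 2 * np.pi * np.arange(N) / N
    dirs = np.column_stack([np.cos(theta), np.sin(theta)])
    # area-preserving sampling compensation: an inscribed N-gon of a circle
    # underestimates its area by sinc(2*pi/N); inflate sampled radii so the
    # discrete cross-sections carry the continuum areas
    comp = math.sqrt((2 * math.pi / N) / math.sin(2 * math.pi / N))

    r_in = np.empty((K, N))
    r_out = np.empty((K, N))
    r_out_funcs = []
    for k, sl in enumerate(stack.slices):
        f_in = ring_radius_function(sl.lv_inner, centroids[k])
        f_out = ring_radius_function(sl.lv_outer, centroids[k])
        r_in[k] = comp * f_in(theta)
        r_out[k] = comp * f_out(theta)
        r_out_funcs.append(f_out)
        if np.any(r_in[k] >= r_out[k]):
            raise MeshingError(f"slice {k}: inner contour crosses outer contour")

    # ---- RV free-wall stations -------------------------------------------
    rv_slices = [k for k in range(K) if stack.slices[k].rv_inner is not None]
    rv = None
    if rv_slices:
        k_lo = min(rv_slices)
        if sorted(rv_slices) != list(range(k_lo, K)):
            raise MeshingError("RV contours must appear on contiguous slices up to the base")
        if k_lo == 0:
            raise MeshingError("RV contours reach the apical slice; cannot close the cavity")
        # station set from the basal slice (largest crescent)
        arc = _free_arc(stack.slices[-1].rv_inner, centroids[-1], r_out_funcs[-1])
        if len(arc) < 3:
            raise MeshingError("could not identify the RV free-wall arc on the basal slice")
        rel = arc - centroids[-1]
        ang = np.arctan2(rel[:, 1], rel[:, 0])
        mid = math.atan2(np.sin(ang).mean(), np.cos(ang).mean())
        phi = np.mod(ang - mid + np.pi, 2 * np.pi) - np.pi
        phi1, phi2 = phi.min(), phi.max()
        offs = np.mod(theta - mid + np.pi, 2 * np.pi) - np.pi
        stations = np.where((offs >= phi1) & (offs <= phi2))[0]
        stations = stations[np.argsort(offs[stations])]
        if len(stations) < 4:
            raise MeshingError("mesh resolution too coarse for the RV crescent span")
        # extend one station beyond each junction so the crescent margins
        # between the detected span and the grid are not discarded
        ext_lo = (stations[0] - 1) % N
        ext_hi = (stations[-1] + 1) % N
        if ext_lo not in stations and ext_hi not in stations and ext_lo != ext_hi:
            stations = np.concatenate([[ext_lo], stations, [ext_hi]])
        M = len(stations)
        # free-wall inner/outer radii at the stations, per slice
        rfw_in = np.tile(r_out[:, stations], 1).copy()
        rfw_out = rfw_in.copy()
        for k in rv_slices:
            c = centroids[k]
            for which, target in (("rv_inner", rfw_in), ("rv_outer", rfw_out)):
                pts = _free_arc(getattr(stack.slices[k], which), c, r_out_funcs[k])
                if len(pts) < 3:
                    continue
                rel = pts - c
                a = np.mod(np.arctan2(rel[:, 1], rel[:, 0]) - mid + np.pi, 2 * np.pi) - np.pi
                r = np.hypot(rel[:, 0], rel[:, 1])
                order = np.argsort(a)
                target[k] = comp * np.interp(
                    offs[stations], a[order], r[order],
                    left=r_out[k, stations[0]] / comp,
                    right=r_out[k, stations[-1]] / comp,
                )
        sep = r_out[:, stations]
        rfw_in = np.maximum(rfw_in, sep)
        rfw_out = np.maximum(rfw_out, rfw_in)
        # collapse columns: junction stations and the ring below the RV extent
        k_bot = k_lo - 1
        rfw_in[: k_bot + 1] = sep[: k_bot + 1]
        rfw_out[: k_bot + 1] = sep[: k_bot + 1]
        rfw_in[:, [0, M - 1]] = sep[:, [0, M - 1]]
        rfw_out[:, [0, M - 1]] = sep[:, [0, M - 1]]
        rv = {"stations": stations, "k_bot": k_bot, "M": M,
              "rfw_in": rfw_in, "rfw_out": rfw_out}

    # ---- nodes ------------------------------------------------------------
    nodes = []
    lv_ids = np.empty((K, N, 3), dtype=np.int64)
    for k in range(K):
        for j in range(N):
            radii = (r_in[k, j], 0.5 * (r_in[k, j] + r_out[k, j]), r_out[k, j])
            for l, r in enumerate(radii):
                lv_ids[k, j, l] = len(nodes)
                nodes.append((*(centroids[k] + r * dirs[j]), z[k]))

    rv_ids = None
    if rv is not None:
        M, k_bot = rv["M"], rv["k_bot"]
        stations = rv["stations"]
        rv_ids = np.empty((K, M, 3), dtype=np.int64)
        rv_ids.fill(-1)
        for k in range(k_bot, K):
            for m in range(M):
                j = stations[m]
                collapsed = k == k_bot or m in (0, M - 1)
                if collapsed:
                    rv_ids[k, m, :] = lv_ids[k, j, 2]
                    continue
                ri, ro = rv["rfw_in"][k, m], rv["rfw_out"][k, m]
                for l, r in enumerate((ri, 0.5 * (ri + ro), ro)):
                    rv_ids[k, m, l] = len(nodes)
                    nodes.append((*(centroids[k] + r * dirs[j]), z[k]))
    nodes = np.asarray(nodes, dtype=float)

    # ---- elements ---------------------------------------------------------
    elems, wall, kjl = [], [], []

    def add_hex(ids, k, j, l, w):
        # bottom quad (radial then circumferential) + top quad, right-handed
        elems.append(
            [
                ids[k, j, l], ids[k, j, l + 1], ids[k, jp(j, w), l + 1], ids[k, jp(j, w), l],
                ids[k + 1, j, l], ids[k + 1, j, l + 1], ids[k + 1, jp(j, w), l + 1], ids[k + 1, jp(j, w), l],
            ]
        )
        wall.append(w)
        kjl.append((k, j, l))

    def jp(j, w):
        if w == 0:
            return (j + 1) % N
        return j + 1

    for k in range(K - 1):
        for j in range(N):
            for l in (0, 1):
                add_hex(lv_ids, k, j, l, 0)
    if rv is not None:
        for k in range(rv["k_bot"], K - 1):
            for m in range(rv["M"] - 1):
                for l in (0, 1):
                    add_hex(rv_ids, k, m, l, 1)

    elements = np.asarray(elems, dtype=np.int64)
    wall = np.asarray(wall)
    kjl = np.asarray(kjl)

    # drop fully collapsed cells (zero volume: both columns on the septum)
    vols = _hex_volumes_safe(nodes, elements)
    keep = vols > 1e-9
    elements, wall, kjl = elements[keep], wall[keep], kjl[keep]

    try:
        reference_gradients(nodes[elements])
    except ValueError as exc:
        raise MeshingError(f"degenerate element: {exc}") from exc

    layer = np.where(kjl[:, 2] == 0, "inner", "outer").astype("<U8")
    region = np.empty(len(elements), dtype="<U8")
    region[:] = "LV"
    region[wall == 1] = "RV"
    if rv is not None:
        in_span = np.isin(kjl[:, 1], rv["stations"][:-1]) if rv else np.zeros(len(elements), bool)
        septal = (wall == 0) & in_span & (kjl[:, 0] >= rv["k_bot"])
        region[septal] = "septum"

    info = {
        "n_theta": N,
        "theta": theta,
        "z": z,
        "centroids": centroids,
        "lv_ids": lv_ids,
        "rv": None,
        "elem_wall": wall,
        "elem_kjl": kjl,
    }
    if rv is not None:
        info["rv"] = {
            "stations": rv["stations"],
            "k_bot": rv["k_bot"],
            "M": rv["M"],
            "ids": rv_ids,
        }
    mesh = VentricleMesh(nodes, elements, layer, region, None, info)
    _build_surfaces(mesh)
    return mesh


def _hex_volumes_safe(nodes, elements):
    coords = nodes[elements]
    from .fem import GAUSS_POINTS, shape_gradients

    dN = shape_gradients(GAUSS_POINTS)
    J = np.einsum("eai,gaj->egij", coords, dN)
    return np.abs(np.linalg.det(J)).sum(axis=1)


def _build_surfaces(mesh: VentricleMesh) -> None:
    """Register cavity / outer surface quads and cap rings in ``mesh.info``.

    Cavity quads are oriented with the right-hand normal pointing out of the
    cavity (into the wall), which is the orientation both the follower
    pressure load and the divergence-theorem volume expect.
    """
    info = mesh.info
    K, N = len(info["z"]), info["n_theta"]
    lv = info["lv_ids"]
    rv = info["rv"]

    lv_endo = []
    outer = []
    rv_endo = []
    rv_station_set = set(rv["stations"][:-1]) if rv else set()
    for k in range(K - 1):
        for j in range(N):
            jn = (j + 1) % N
            lv_endo.append([lv[k, j, 0], lv[k, jn, 0], lv[k + 1, jn, 0], lv[k + 1, j, 0]])
            septal_face = rv and j in rv_station_set and k >= rv["k_bot"]
            if septal_face:
                # septum seen from the RV cavity: normal flipped inward to LV
                rv_endo.append([lv[k, jn, 2], lv[k, j, 2], lv[k + 1, j, 2], lv[k + 1, jn, 2]])
            else:
                outer.append([lv[k, j, 2], lv[k, jn, 2], lv[k + 1, jn, 2], lv[k + 1, j, 2]])
    if rv:
        ids, M = rv["ids"], rv["M"]
        for k in range(rv["k_bot"], K - 1):
            for m in range(M - 1):
                q_in = [ids[k, m, 0], ids[k, m + 1, 0], ids[k + 1, m + 1, 0], ids[k + 1, m, 0]]
                q_out = [ids[k, m, 2], ids[k, m + 1, 2], ids[k + 1, m + 1, 2], ids[k + 1, m, 2]]
                if len(set(q_in)) >= 3:
                    rv_endo.append(q_in)
                if len(set(q_out)) >= 3:
                    outer.append(q_out)

    info["lv_endo_quads"] = np.asarray(lv_endo, dtype=np.int64)
    info["rv_endo_quads"] = (
        np.asarray(rv_endo, dtype=np.int64) if rv_endo else np.empty((0, 4), np.int64)
    )
    info["outer_quads"] = np.asarray(outer, dtype=np.int64)

    info["lv_apex_ring"] = lv[0, :, 0].copy()  # ordered, CCW seen from +z
    info["lv_base_ring"] = lv[K - 1, :, 0].copy()
    if rv:
        info["rv_base_sep"] = lv[K - 1, rv["stations"], 2].copy()
        info["rv_base_fw"] = rv["ids"][K - 1, :, 0].copy()
        loops = []
        for k in range(rv["k_bot"] + 1, K):
            fw = rv["ids"][k, :, 0]
            sep = lv[k, rv["stations"][::-1], 2]
            loops.append(np.concatenate([fw, sep[1:-1]]))
        info["rv_endo_loops"] = loops
    basal = set(lv[K - 1].reshape(-1).tolist())
    if rv:
        basal |= set(rv["ids"][K - 1].reshape(-1).tolist())
    info["basal_nodes"] = np.array(sorted(basal), dtype=np.int64)


# ---------------------------------------------------------------------------
# fibers


def _rotation_angle(region: str, layer: str, lv_angles, rv_angles) -> float:
    outer_deg, inner_deg = lv_angles if region in ("LV", "septum") else rv_angles
    return math.radians(inner_deg if layer == "inner" else outer_deg)


def assign_fibers(
    mesh: VentricleMesh,
    lv_angles: tuple[float, float] = (-60.0, 80.0),
    rv_angles: tuple[float, float] = (-45.0, 40.0),
) -> VentricleMesh:
    """Assign per-element fiber directions as helix angles from circumferential.

    The local circumferential direction is the mean of the element's four
    circumferential edges, the longitudinal direction the mean of its axial
    edges (orthogonalized); the fiber is the circumferential direction
    rotated toward the long axis by the layer/region helix angle.  Angle
    pairs are given as (outer, inner) in degrees.
    """
    if mesh.layer is None or mesh.region is None:
        raise ValidationError("mesh must carry layer and region labels")
    x = mesh.nodes[mesh.elements]  # (ne, 8, 3)
    # node order: bottom (r, r, theta+, theta+) -> circumferential edges 3-0,
    # 2-1, 7-4, 6-5; axial edges 4-0 .. 7-3 (see build_mesh.add_hex)
    e_c = (x[:, 3] - x[:, 0]) + (x[:, 2] - x[:, 1]) + (x[:, 7] - x[:, 4]) + (x[:, 6] - x[:, 5])
    e_l = (x[:, 4] - x[:, 0]) + (x[:, 5] - x[:, 1]) + (x[:, 6] - x[:, 2]) + (x[:, 7] - x[:, 3])
    e_c /= np.linalg.norm(e_c, axis=1, keepdims=True)
    e_l -= (np.einsum("ei,ei->e", e_l, e_c))[:, None] * e_c
    e_l /= np.linalg.norm(e_l, axis=1, keepdims=True)
    fiber = np.empty((mesh.n_elements, 3))
    for i in range(mesh.n_elements):
        a = _rotation_angle(mesh.region[i], mesh.layer[i], lv_angles, rv_angles)
        fiber[i] = math.cos(a) * e_c[i] + math.sin(a) * e_l[i]
    fiber /= np.linalg.norm(fiber, axis=1, keepdims=True)
    mesh.fiber = fiber
    return mesh


# ---------------------------------------------------------------------------
# scar / patch labeling


@dataclass(frozen=True)
class RegionSpec:
    """Angular/axial window on the RV free wall, as fractions of the
    crescent span (theta) and of the RV axial extent (z), each in [0, 1]."""

    theta_lo: float
    theta_hi: float
    z_lo: float
    z_hi: float

    def validate(self) -> None:
        vals = (self.theta_lo, self.theta_hi, self.z_lo, self.z_hi)
        if not all(0.0 <= v <= 1.0 for v in vals):
            raise ValidationError("region window must lie on the RV free wall (fractions in [0,1])")
        if self.theta_lo > self.theta_hi or self.z_lo > self.z_hi:
            raise ValidationError("region window bounds out of order")

    def overlaps(self, other: "RegionSpec") -> bool:
        return not (
            self.theta_hi <= other.theta_lo
            or other.theta_hi <= self.theta_lo
            or self.z_hi <= other.z_lo
            or other.z_hi <= self.z_lo
        )


def label_regions(
    mesh: VentricleMesh,
    scar_spec: RegionSpec | None = None,
    patch_spec: RegionSpec | None = None,
) -> VentricleMesh:
    """Relabel RV free-wall element windows as scar / patch."""
    if scar_spec:
        scar_spec.validate()
    if patch_spec:
        patch_spec.validate()
    if scar_spec and patch_spec and scar_spec.overlaps(patch_spec):
        raise ValidationError("scar and patch windows overlap")
    rv = mesh.info["rv"]
    if rv is None and (scar_spec or patch_spec):
        raise ValidationError("mesh has no RV free wall")
    if rv is None:
        return mesh
    K = len(mesh.info["z"])
    M, k_bot = rv["M"], rv["k_bot"]
    wall = mesh.info["elem_wall"]
    kjl = mesh.info["elem_kjl"]
    for name, spec in (("scar", scar_spec), ("patch", patch_spec)):
        if spec is None or spec.theta_hi == spec.theta_lo or spec.z_hi == spec.z_lo:
            continue
        for i in np.where(wall == 1)[0]:
            k, m, _ = kjl[i]  # RV elements index stations arc-locally
            tf = (m + 0.5) / (M - 1)
            zf = (k + 0.5 - k_bot) / (K - 1 - k_bot)
            if spec.theta_lo <= tf <= spec.theta_hi and spec.z_lo <= zf <= spec.z_hi:
                mesh.region[i] = name
    return mesh


def rv_freewall_node(mesh: VentricleMesh, theta_frac: float, z_frac: float) -> int:
    """Node id on the RV free-wall endocardium nearest the given fractions
    of the crescent span and axial extent (used for band attachment)."""
    rv = mesh.info["rv"]
    if rv is None:
        raise ValidationError("mesh has no RV free wall")
    K = len(mesh.info["z"])
    M, k_bot = rv["M"], rv["k_bot"]
    m = int(round(theta_frac * (M - 1)))
    m = min(max(m, 1), M - 2)
    k = int(round(k_bot + 1 + z_frac * (K - 2 - k_bot)))
    k = min(max(k, k_bot + 1), K - 1)
    return int(rv["ids"][k, m, 0])


# ---------------------------------------------------------------------------
# VTK export (legacy ASCII unstructured grid)


def write_vtk(mesh: VentricleMesh, path, point_data=None, cell_data=None) -> None:
    """Write the mesh as a legacy-ASCII VTK unstructured grid.

    ``point_data`` / ``cell_data`` are dicts name -> array (scalars (n,) or
    vectors (n, 3)).  Layer/region labels and fibers are always included.
    """
    cd = {"layer": np.array([LAYER_NAMES.index(v) for v in mesh.layer], float),
          "region": np.array([REGION_NAMES.index(v) for v in mesh.region], float)}
    if mesh.fiber is not None:
        cd["fiber"] = mesh.fiber
    if cell_data:
        cd.update(cell_data)
    with open(path, "w") as fh:
        fh.write("# vtk DataFile Version 3.0\nventriband mesh\nASCII\n")
        fh.write("DATASET UNSTRUCTURED_GRID\n")
        fh.write(f"POINTS {mesh.n_nodes} double\n")
        np.savetxt(fh, mesh.nodes, fmt="%.9g")
        ne = mesh.n_elements
        fh.write(f"CELLS {ne} {ne * 9}\n")
        np.savetxt(
            fh,
            np.column_stack([np.full(ne, 8), mesh.elements]),
            fmt="%d",
        )
        fh.write(f"CELL_TYPES {ne}\n")
        np.savetxt(fh, np.full(ne, 12), fmt="%d")
        if point_data:
            fh.write(f"POINT_DATA {mesh.n_nodes}\n")
            _write_fields(fh, point_data)
        if cd:
            fh.write(f"CELL_DATA {ne}\n")
            _write_fields(fh, cd)


def _write_fields(fh, fields: dict) -> None:
    for name, arr in fields.items():
        arr = np.asarray(arr, dtype=float)
        if arr.ndim == 2 and arr.shape[1] == 3:
            fh.write(f"VECTORS {name} double\n")
            np.savetxt(fh, arr, fmt="%.9g")
        else:
            fh.write(f"SCALARS {name} double 1\nLOOKUP_TABLE default\n")
            np.savetxt(fh, arr.reshape(-1, 1), fmt="%.9g")
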