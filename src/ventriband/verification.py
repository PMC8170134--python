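"""Verification problems with classical closed-form solutions.

The pressurized thick-walled incompressible sphere is the standard
benchmark for finite-strain pressure loading: for an incompressible
neo-Hookean material (W = c1 (I1 - 3)) the inflation pressure follows from
radial equilibrium as

    P(r_i) = integral_{R_i}^{R_o} 4 c1 (lam^2 - lam^-4) R^2 / r^3 dR

with r(R)^3 = R^3 + (r_i^3 - R_i^3) and hoop stretch lam = r/R.  The
quadrature below is independent of the finite-element machinery and serves
as its oracle; the octant mesh (symmetry boundary conditions on the three
coordinate planes) avoids artificial rigid-body constraints.
"""

from __future__ import annotations

import numpy as np
from scipy.integrate import quad
from scipy.optimize import brentq

from .materials import MaterialParams
from .solver import PressurizedBody


def sphere_inflation_pressure(c1: float, R_i: float, R_o: float, r_i: float) -> float:
    """Closed-form pressure (kPa) that inflates the inner radius to r_i."""
    a = r_i**3 - R_i**3

    def integrand(R):
        r = (R**3 + a) ** (1.0 / 3.0)
        lam = r / R
        return 4.0 * c1 * (lam**2 - lam**-4) * R**2 / r**3

    val, _ = quad(integrand, R_i, R_o, limit=200)
    return float(val)


def sphere_inflation_radius(c1: float, R_i: float, R_o: float, p: float) -> float:
    """Inverse of :func:`sphere_inflation_pressure`: deformed inner radius.

    The pressure-radius curve of a neo-Hookean sphere has a limit point
    (snap-through); the inversion returns the stable (rising) branch, so
    ``p`` must lie below the limit pressure.
    """
    f = lambda ri: sphere_inflation_pressure(c1, R_i, R_o, ri) - p  # noqa: E731
    grid = R_i * (1.0 + np.linspace(1e-9, 2.0, 200))
    vals = np.array([f(r) for r in grid])
    cross = np.where(vals > 0)[0]
    if vals[0] > 0 or cross.size == 0:
        raise ValueError("pressure outside the stable inflation branch")
    hi = grid[cross[0]]
    lo = grid[cross[0] - 1]
    return float(brentq(f, lo, hi, xtol=1e-12))


def octant_sphere_mesh(R_i: float, R_o: float, n_lat: int = 8, n_lon: int = 8, n_rad: int = 3):
    """Structured hex mesh of one octant of a thick spherical shell.

    Returns (nodes, elements, fixed_dofs, inner_quads, equator_inner_ids).
    The polar row collapses to a single node per radial layer (wedge
    elements); symmetry planes x=0, y=0, z=0 carry the normal-displacement
    constraints.  ``inner_quads`` are oriented with normals pointing out of
    the cavity (radially outward).
    """
    lat = np.linspace(0.0, np.pi / 2.0, n_lat + 1)  # 0 = equator, pi/2 = pole
    lon = np.linspace(0.0, np.pi / 2.0, n_lon + 1)
    rad = np.linspace(R_i, R_o, n_rad + 1)

    ids = -np.ones((n_lat + 1, n_lon + 1, n_rad + 1), dtype=np.int64)
    nodes = []
    for i, ph in enumerate(lat):
        for j, th in enumerate(lon):
            if i == n_lat and j > 0:
                ids[i, j, :] = ids[i, 0, :]  # collapsed pole
                continue
            for k, r in enumerate(rad):
                ids[i, j, k] = len(nodes)
                nodes.append(
                    (
                        r * np.cos(ph) * np.cos(th),
                        r * np.cos(ph) * np.sin(th),
                        r * np.sin(ph),
                    )
                )
    nodes = np.asarray(nodes)

    elements = []
    for i in range(n_lat):
        for j in range(n_lon):
            for k in range(n_rad):
                e = [
                    ids[i, j, k], ids[i, j, k + 1], ids[i, j + 1, k + 1], ids[i, j + 1, k],
                    ids[i + 1, j, k], ids[i + 1, j, k + 1], ids[i + 1, j + 1, k + 1], ids[i + 1, j + 1, k],
                ]
                if len(set(e)) >= 6:  # drop fully collapsed pole cells
                    elements.append(e)
    elements = np.asarray(elements, dtype=np.int64)

    tol = 1e-9 * R_o
    fixed = []
    for n, (x, y, z) in enumerate(nodes):
        if abs(x) < tol:
            fixed.append(3 * n + 0)
        if abs(y) < tol:
            fixed.append(3 * n + 1)
        if abs(z) < tol:
            fixed.append(3 * n + 2)

    inner = []
    for i in range(n_lat):
        for j in range(n_lon):
            q = [ids[i, j, 0], ids[i, j + 1, 0], ids[i + 1, j + 1, 0], ids[i + 1, j, 0]]
            if len(set(q)) >= 3:
                inner.append(q)
    inner = np.asarray(inner, dtype=np.int64)

    equator_inner = [int(ids[0, j, 0]) for j in range(n_lon + 1)]
    return nodes, elements, np.asarray(fixed), inner, equator_inner


def solve_sphere_inflation(
    c1: float = 10.0,
    R_i: float = 10.0,
    R_o: float = 15.0,
    p: float = 10.0,
    n_lat: int = 8,
    n_lon: int = 8,
    n_rad: int = 3,
    kappa_factor: float = 2000.0,
):
    """FE inflation of the octant shell; returns (r_i FE, r_i closed form)."""
    nodes, elements, fixed, inner, eq = octant_sphere_mesh(R_i, R_o, n_lat, n_lon, n_rad)
    params = MaterialParams(c1=c1, region="shell")
    body = PressurizedBody(
        nodes, elements, params, fixed, inner, kappa=kappa_factor * c1
    )
    u = body.solve(p)
    x = nodes + u
    r_fe = float(np.mean(np.linalg.norm(x[eq], axis=1)))
    r_exact = sphere_inflation_radius(c1, R_i, R_o, p)
    return r_fe, r_exact
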