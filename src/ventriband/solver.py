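"""Quasi-static large-deformation mechanics of the bi-ventricle + bands.

The ventricle wall is loaded by prescribed cavity pressures (follower loads
on the deformed endocardial surfaces, traction-free epicardium) and solved
to equilibrium with Newton iteration and adaptive load stepping.  Myocardial
"active contraction" enters through the phase-dependent material parameter
sets (stiff systolic / compliant diastolic rows of the material table),
blended smoothly over the cycle; inertia is dropped (the loading is a
sequence of pressure states, 30 per cycle, and only configuration states
are reported).

Contracting bands are tension-only cable elements spanning the RV cavity
whose zero-stress length follows a periodic schedule: the diastolic
zero-stress length equals the band's length L in the baseline begin-filling
state, shortening to (1 - r) L at peak systole for active contraction ratio
r.  An active band additionally "relaxes" in diastole by following the
phase-blended band material (stiff in systole, compliant in diastole),
whereas a passive band (r = 0) keeps the stiff material all cycle and
therefore resists diastolic expansion.

Boundary conditions: the basal ring is fixed longitudinally with in-plane
freedom, plus minimal in-plane pins that remove the rigid-body modes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .errors import ConvergenceError, ValidationError
from .fem import HexBlock, pressure_forces, pressure_load_stiffness
from .geometry import PressureSchedule, _two_phase_weight
from .materials import default_materials
from .meshing import VentricleMesh

MAT_KEYS = ("c1", "c2", "D1", "D2", "K1", "K2")


# ---------------------------------------------------------------------------
# bands


@dataclass
class BandSpec:
    """One contracting band: attachment path, reference length, schedule."""

    plan: str
    path: tuple[int, ...]  # ordered attachment node ids across the RV cavity
    in_vivo_length: float  # L, mm: path length in the baseline begin-filling state
    contraction_ratio: float = 0.0  # r: 0 (passive), 0.10, 0.15, 0.20
    cross_section_area: float = 10.0  # mm^2

    def __post_init__(self):
        if not (0.0 <= self.contraction_ratio <= 0.3):
            raise ValidationError("contraction ratio must lie in [0, 0.3]")
        if len(self.path) < 2:
            raise ValidationError("band path needs at least two attachment nodes")
        if self.in_vivo_length <= 0:
            raise ValidationError("band length must be positive")

    @property
    def passive(self) -> bool:
        return self.contraction_ratio == 0.0


def band_zero_stress_schedule(band: BandSpec, cycle_phase, systole_fraction=0.4):
    """Zero-stress length factor in [1 - r, 1] over the cycle.

    Equals 1 at the diastolic anchor (begin ejection, cycle phase 0) and
    1 - r at the peak-systole anchor (begin filling); the transition is the
    same half-cosine blend as the pressure waveform, so the schedule is
    smooth and periodic.  A passive band (r = 0) keeps factor 1 everywhere.
    """
    w = _two_phase_weight(np.asarray(cycle_phase, dtype=float), systole_fraction)
    return 1.0 - band.contraction_ratio * w


def path_length(nodes_def: np.ndarray, path) -> float:
    p = nodes_def[list(path)]
    return float(np.linalg.norm(np.diff(p, axis=0), axis=1).sum())


# ---------------------------------------------------------------------------
# shared Newton core


def _residual(block, nodes, u, mats, kappa, fibers, pressure_loads, band_contrib):
    """Residual vector and external-force norm (no tangent)."""
    f_int = np.zeros_like(u)
    f_el = block.internal_force(u, mats, fibers, kappa)
    np.add.at(f_int, block.elements.reshape(-1), f_el.reshape(-1, 3))
    x = nodes + u
    f_ext = np.zeros_like(u)
    for quads, p in pressure_loads:
        if p > 0 and len(quads):
            ids, ff = pressure_forces(x, quads, p)
            np.add.at(f_ext, ids, ff)
    r = f_int - f_ext
    if band_contrib is not None:
        grad, _ = band_contrib(u)
        r = r + grad
    return r.reshape(-1), float(np.linalg.norm(f_ext))


def _assemble(block, nodes, u, mats, kappa, fibers, pressure_loads, band_contrib):
    """Residual, tangent (csc, incl. follower-load stiffness), f_ext norm."""
    f_el, K_el = block.force_and_stiffness(u, mats, fibers, kappa)
    f_int = np.zeros_like(u)
    np.add.at(f_int, block.elements.reshape(-1), f_el.reshape(-1, 3))

    dofs = (3 * block.elements[:, :, None] + np.arange(3)).reshape(-1, 24)
    rows = [np.repeat(dofs, 24, axis=1).reshape(-1)]
    cols = [np.tile(dofs, (1, 24)).reshape(-1)]
    data = [K_el.reshape(-1)]

    x = nodes + u
    f_ext = np.zeros_like(u)
    for quads, p in pressure_loads:
        if p > 0 and len(quads):
            ids, ff = pressure_forces(x, quads, p)
            np.add.at(f_ext, ids, ff)
            pr, pc, pv = pressure_load_stiffness(x, quads, p)
            rows.append(pr)
            cols.append(pc)
            data.append(-pv)  # K = dr/du and r = f_int - f_ext

    r = f_int - f_ext
    if band_contrib is not None:
        grad, blocks = band_contrib(u)
        r = r + grad
        for a, b, H in blocks:
            for (na, nb, s) in ((a, a, 1.0), (b, b, 1.0), (a, b, -1.0), (b, a, -1.0)):
                ra = 3 * na + np.arange(3)
                cb = 3 * nb + np.arange(3)
                rows.append(np.repeat(ra, 3))
                cols.append(np.tile(cb, 3))
                data.append(s * H.reshape(-1))

    n_dof = 3 * nodes.shape[0]
    K = sp.coo_matrix(
        (np.concatenate(data), (np.concatenate(rows), np.concatenate(cols))),
        shape=(n_dof, n_dof),
    ).tocsc()
    return r.reshape(-1), K, float(np.linalg.norm(f_ext))


def _newton(
    block,
    nodes,
    free_dofs,
    u0,
    mats,
    kappa,
    fibers,
    pressure_loads,
    band_contrib=None,
    tol=1e-6,
    max_iter=22,
):
    import warnings

    u = u0.copy()
    res = np.inf
    res0 = None
    with np.errstate(over="ignore", invalid="ignore"):
        for it in range(max_iter):
            try:
                r, K, f_ext_norm = _assemble(
                    block, nodes, u, mats, kappa, fibers, pressure_loads, band_contrib
                )
            except ValueError as exc:  # e.g. inverted element in the material law
                raise ConvergenceError(f"assembly failed: {exc}")
            scale = max(f_ext_norm, 1.0)
            res = np.linalg.norm(r[free_dofs]) / scale
            if not np.isfinite(res):
                raise ConvergenceError("residual diverged (non-finite)")
            if res < tol:
                return u, res
            if res0 is None:
                res0 = res
            elif it >= 8 and res > 2.0 * res0:
                # diverging; let the load stepping cut the increment
                raise ConvergenceError(f"Newton diverging at residual {res:.3e}")
            Kff = K[free_dofs][:, free_dofs]
            with warnings.catch_warnings():
                warnings.simplefilter("error", spla.MatrixRankWarning)
                try:
                    du = spla.spsolve(Kff, -r[free_dofs])
                except (RuntimeError, spla.MatrixRankWarning) as exc:
                    raise ConvergenceError(f"linear solve failed: {exc}")
            if not np.all(np.isfinite(du)):
                raise ConvergenceError("Newton update is not finite")
            step = np.zeros(3 * nodes.shape[0])
            step[free_dofs] = du
            # backtracking line search on the residual norm
            alpha, accepted = 1.0, None
            for _ls in range(5):
                u_try = u + alpha * step.reshape(-1, 3)
                try:
                    r_try, _ = _residual(
                        block, nodes, u_try, mats, kappa, fibers, pressure_loads, band_contrib
                    )
                    res_try = np.linalg.norm(r_try[free_dofs]) / scale
                except ValueError:
                    res_try = np.inf
                if np.isfinite(res_try) and (res_try < res or alpha < 0.2):
                    accepted = u_try
                    break
                alpha *= 0.5
            if accepted is None:
                raise ConvergenceError(f"line search failed at residual {res:.3e}")
            u = accepted
    raise ConvergenceError(f"Newton stalled at residual {res:.3e}", history=[res])


def _ramped_solve(solve_at, u0, dlam0=1.0):
    """Adaptive load stepping: ``solve_at(lam, u)`` solves at load fraction
    ``lam`` starting from ``u``; halves the step on failure."""
    u, lam_done, dlam = u0, 0.0, dlam0
    history = []
    while lam_done < 1.0 - 1e-12:
        lam = min(1.0, lam_done + dlam)
        try:
            u_new, res = solve_at(lam, u)
            u, lam_done = u_new, lam
            history.append((lam, res))
            dlam = min(dlam * 2.0, max(1.0 - lam_done, 1e-12))
        except ConvergenceError:
            dlam *= 0.5
            if dlam < 1e-3:
                raise ConvergenceError(
                    f"load stepping failed at fraction {lam_done:.3f}", history=history
                )
    return u


class PressurizedBody:
    """Generic pressurized hyperelastic body (verification problems).

    Homogeneous material; ``pressure_quads`` oriented with normals out of
    the pressurized cavity; ``fixed_dofs`` are global dof indices.
    """

    def __init__(self, nodes, elements, params, fixed_dofs, pressure_quads, kappa=None, fibers=None):
        self.nodes = np.asarray(nodes, dtype=float)
        self.block = HexBlock(self.nodes, elements)
        ne = self.block.ne
        self.mats = {k: np.full(ne, getattr(params, k)) for k in MAT_KEYS}
        self.kappa = np.full(ne, kappa if kappa is not None else 1000.0 * params.c1)
        self.fibers = (
            np.asarray(fibers, dtype=float)
            if fibers is not None
            else np.tile([1.0, 0.0, 0.0], (ne, 1))
        )
        all_dofs = np.arange(3 * self.nodes.shape[0])
        self.free_dofs = np.setdiff1d(all_dofs, np.asarray(fixed_dofs, dtype=np.int64))
        self.pressure_quads = pressure_quads

    def solve(self, p, u0=None, tol=1e-6):
        u0 = u0 if u0 is not None else np.zeros_like(self.nodes)

        def solve_at(lam, u):
            return _newton(
                self.block,
                self.nodes,
                self.free_dofs,
                u,
                self.mats,
                self.kappa,
                self.fibers,
                [(self.pressure_quads, lam * p)],
                tol=tol,
            )

        return _ramped_solve(solve_at, u0)


# ---------------------------------------------------------------------------
# results


@dataclass
class SimulationResult:
    """Fields and cavity volumes over the recorded (final) cycle."""

    times: np.ndarray
    displacements: np.ndarray  # (nt, n_nodes, 3)
    rv_volume_ml: np.ndarray
    lv_volume_ml: np.ndarray
    stress_p1: np.ndarray  # (nt, ne) element-mean max principal Cauchy stress
    strain_p1: np.ndarray  # (nt, ne) element-mean max principal Green-Lagrange strain
    n_cycles: int = 0
    convergence: list = field(default_factory=list)
    element_volumes: np.ndarray | None = None
    rv_domain: np.ndarray | None = None  # bool mask of RV-domain elements


def cycle_convergence(
    prev: SimulationResult, curr: SimulationResult, fields=("stress_p1", "strain_p1")
) -> float:
    """Relative space-time L2 difference between consecutive cycles.

    || S(t) - S(t+T) || / || S(t+T) || with the L2 norm taken over the RV
    domain and one cycle (element volumes as spatial weights, trapezoidal
    weights in time); returns the max over the requested fields (maximum
    principal stress and strain by default).
    """
    if prev.times.shape != curr.times.shape or not np.allclose(prev.times, curr.times):
        raise ValidationError("cycle results must share the same time grid")
    if curr.rv_domain is not None:
        mask = curr.rv_domain
    else:
        mask = np.ones(curr.stress_p1.shape[1], dtype=bool)
    w_el = (
        curr.element_volumes
        if curr.element_volumes is not None
        else np.ones(curr.stress_p1.shape[1])
    )[mask]
    wt = np.gradient(curr.times)
    out = 0.0
    for name in fields:
        a = getattr(prev, name)[:, mask]
        b = getattr(curr, name)[:, mask]
        num = np.sqrt(np.sum(wt[:, None] * w_el[None, :] * (a - b) ** 2))
        den = np.sqrt(np.sum(wt[:, None] * w_el[None, :] * b**2))
        out = max(out, num / max(den, 1e-300))
    return float(out)


# ---------------------------------------------------------------------------
# bi-ventricle model


class BiventModel:
    """Assembled bi-ventricle model ready for equilibrium solves.

    Parameters
    ----------
    mesh : VentricleMesh with fibers assigned.
    materials : (region, phase) -> MaterialParams table; defaults to the
        packaged reference table.
    bands : iterable of BandSpec.
    kappa_factor : bulk penalty = kappa_factor * c1 per element (near
        incompressibility).
    scales : stiffness calibration multipliers applied jointly to
        (c1, D1, K1) of the ventricular tissue, one per anchor phase.
    """

    def __init__(
        self,
        mesh: VentricleMesh,
        materials=None,
        bands=(),
        kappa_factor: float = 1000.0,
        scales: dict | None = None,
        pressure_schedule: PressureSchedule | None = None,
    ):
        if mesh.fiber is None:
            raise ValidationError("mesh needs fibers (assign_fibers) before solving")
        self.mesh = mesh
        self.pressure_schedule = pressure_schedule
        self.materials = materials or default_materials()
        self.bands = list(bands)
        self.kappa_factor = kappa_factor
        self.scales = dict(scales or {"end_ejection": 1.0, "end_filling": 1.0})
        self.block = HexBlock(mesh.nodes, mesh.elements)
        self._mat_phase = {
            ph: self._phase_arrays(ph) for ph in ("end_ejection", "end_filling")
        }
        self._setup_bc()
        self._myo = np.isin(mesh.region, ("LV", "RV", "septum"))

    # -- materials ----------------------------------------------------------

    def _phase_arrays(self, phase: str) -> dict:
        mesh = self.mesh
        out = {k: np.empty(mesh.n_elements) for k in MAT_KEYS}
        for i in range(mesh.n_elements):
            region = mesh.region[i]
            if region in ("LV", "RV", "septum"):
                key = ("myocardium_" + mesh.layer[i], phase)
            else:
                key = (region, phase)
            p = self.materials[key]
            for k in MAT_KEYS:
                out[k][i] = getattr(p, k)
        return out

    def material_arrays(self, systolic_weight: float) -> tuple[dict, np.ndarray]:
        """Per-element constants blended between the anchor phases.

        The calibration scale of each phase multiplies (c1, D1, K1) of the
        ventricular tissue before blending; patch and scar are phase
        independent and unscaled.
        """
        w = float(systolic_weight)
        myo = self._myo
        blended = {}
        for k in MAT_KEYS:
            ee = self._mat_phase["end_ejection"][k].copy()
            ef = self._mat_phase["end_filling"][k].copy()
            if k in ("c1", "D1", "K1"):
                ee[myo] *= self.scales["end_ejection"]
                ef[myo] *= self.scales["end_filling"]
            blended[k] = w * ee + (1.0 - w) * ef
        kappa = self.kappa_factor * np.maximum(blended["c1"], 1.0)
        return blended, kappa

    def band_c1(self, band: BandSpec, systolic_weight: float) -> float:
        ee = self.materials[("band", "end_ejection")].c1
        ef = self.materials[("band", "end_filling")].c1
        if band.passive:
            return ee  # a passive band cannot actively relax in diastole
        w = float(systolic_weight)
        return w * ee + (1.0 - w) * ef

    # -- boundary conditions ------------------------------------------------

    def _setup_bc(self):
        mesh = self.mesh
        fixed = np.zeros((mesh.n_nodes, 3), dtype=bool)
        fixed[mesh.info["basal_nodes"], 2] = True  # longitudinal fixation
        ring = mesh.info["lv_base_ring"]
        a, b = ring[0], ring[len(ring) // 2]
        fixed[a, 0] = fixed[a, 1] = True  # in-plane pins (rigid modes only)
        fixed[b, 1] = True
        self.fixed_dofs = np.where(fixed.reshape(-1))[0]
        self.free_dofs = np.where(~fixed.reshape(-1))[0]

    # -- band contribution ---------------------------------------------------

    def _band_contrib(self, factors, systolic_weight):
        if not self.bands:
            return None

        def contrib(u):
            x = self.mesh.nodes + u
            grad = np.zeros_like(u)
            blocks = []
            for band, fac in zip(self.bands, factors):
                c1 = self.band_c1(band, systolic_weight)
                A0 = band.cross_section_area
                nseg = len(band.path) - 1
                for a, b in zip(band.path[:-1], band.path[1:]):
                    l0 = fac * band.in_vivo_length / nseg
                    g = x[b] - x[a]
                    l = float(np.linalg.norm(g))
                    lam = l / l0
                    if lam <= 1.0:
                        continue  # slack cable carries no compression
                    e = g / l
                    N = 2.0 * c1 * A0 * (lam - lam**-2)
                    dNdl = 2.0 * c1 * A0 * (1.0 + 2.0 * lam**-3) / l0
                    grad[a] -= N * e
                    grad[b] += N * e
                    H = dNdl * np.outer(e, e) + (N / l) * (np.eye(3) - np.outer(e, e))
                    blocks.append((a, b, H))
            return grad, blocks

        return contrib

    def band_states(self, u: np.ndarray, factors, systolic_weight):
        """Per-band (stretch, Cauchy stress kPa, strain) diagnostics."""
        x = self.mesh.nodes + u
        out = []
        for band, fac in zip(self.bands, factors):
            c1 = self.band_c1(band, systolic_weight)
            lam = path_length(x, band.path) / (fac * band.in_vivo_length)
            stress = 2.0 * c1 * (lam**2 - 1.0 / lam) if lam > 1 else 0.0
            out.append(
                {"stretch": lam, "stress_kpa": stress, "strain": 0.5 * (lam**2 - 1.0)}
            )
        return out

    # -- equilibrium ---------------------------------------------------------

    def external_force(self, u, p_rv, p_lv):
        """Assembled follower-pressure nodal forces at the given state."""
        x = self.mesh.nodes + u
        f = np.zeros_like(u)
        for quads, p in (
            (self.mesh.info["lv_endo_quads"], p_lv),
            (self.mesh.info["rv_endo_quads"], p_rv),
        ):
            if p > 0 and len(quads):
                ids, ff = pressure_forces(x, quads, p)
                np.add.at(f, ids, ff)
        return f

    def residual_norms(self, u, p_rv, p_lv, systolic_weight, band_factors=None):
        """Nodal residual force array (n, 3) at a given state (diagnostics)."""
        factors = list(band_factors or [1.0] * len(self.bands))
        mats, kappa = self.material_arrays(systolic_weight)
        loads = [
            (self.mesh.info["lv_endo_quads"], p_lv),
            (self.mesh.info["rv_endo_quads"], p_rv),
        ]
        r, _, _ = _assemble(
            self.block,
            self.mesh.nodes,
            u,
            mats,
            kappa,
            self.mesh.fiber,
            loads,
            self._band_contrib(factors, systolic_weight),
        )
        return r.reshape(-1, 3)

    def solve_state(
        self,
        p_rv: float,
        p_lv: float,
        systolic_weight: float,
        band_factors=None,
        u0: np.ndarray | None = None,
        tol: float = 1e-6,
        from_load: tuple | None = None,
    ) -> np.ndarray:
        """Equilibrium displacement field at one loading state.

        Pressures in kPa; ``systolic_weight`` in [0, 1] selects the material
        blend (0 = diastolic/end-filling, 1 = systolic/end-ejection);
        ``band_factors`` are zero-stress length factors per band.  When the
        full step does not converge the load is ramped adaptively from
        ``from_load`` = (p_rv, p_lv, weight, factors) — by default the
        unloaded state — toward the target, so warm starts from a nearby
        solved state remain cheap.
        """
        if p_rv < 0 or p_lv < 0:
            raise ValidationError("pressures must be non-negative")
        factors = list(band_factors) if band_factors is not None else [1.0] * len(self.bands)
        if from_load is None:
            from_load = (0.0, 0.0, systolic_weight, [1.0] * len(self.bands))
        p0, pl0, w0, f0 = from_load
        u0 = u0.copy() if u0 is not None else np.zeros_like(self.mesh.nodes)

        def solve_at(lam, u):
            w = w0 + lam * (systolic_weight - w0)
            mats, kappa = self.material_arrays(w)
            fac_lam = [a + lam * (b - a) for a, b in zip(f0, factors)]
            loads = [
                (self.mesh.info["lv_endo_quads"], pl0 + lam * (p_lv - pl0)),
                (self.mesh.info["rv_endo_quads"], p0 + lam * (p_rv - p0)),
            ]
            return _newton(
                self.block,
                self.mesh.nodes,
                self.free_dofs,
                u,
                mats,
                kappa,
                self.mesh.fiber,
                loads,
                self._band_contrib(fac_lam, w),
                tol=tol,
            )

        return _ramped_solve(solve_at, u0)

    # -- cavity volumes ------------------------------------------------------

    def cavity_volume(self, u: np.ndarray, cavity: str) -> float:
        return cavity_volume(self.mesh, u, cavity)

    # -- cycle simulation ----------------------------------------------------

    def run_cycle(self, pressures: PressureSchedule, u_start, record=True, from_load=None):
        times = pressures.times
        nt = len(times)
        ne = self.mesh.n_elements
        disp = np.zeros((nt, self.mesh.n_nodes, 3))
        rv_v = np.zeros(nt)
        lv_v = np.zeros(nt)
        s_p1 = np.zeros((nt, ne))
        e_p1 = np.zeros((nt, ne))
        u = u_start
        has_rv = self.mesh.info["rv"] is not None
        prev_load = from_load
        for i, t in enumerate(times):
            w = float(pressures.phase_weight(t))
            factors = [
                float(band_zero_stress_schedule(b, t, pressures.systole_fraction))
                for b in self.bands
            ]
            u = self.solve_state(
                pressures.p_rv[i], pressures.p_lv[i], w, factors, u0=u, from_load=prev_load
            )
            prev_load = (float(pressures.p_rv[i]), float(pressures.p_lv[i]), w, factors)
            disp[i] = u
            rv_v[i] = self.cavity_volume(u, "RV") if has_rv else np.nan
            lv_v[i] = self.cavity_volume(u, "LV")
            if record:
                mats, kappa = self.material_arrays(w)
                sig, E = self.block.gauss_cauchy(u, mats, self.mesh.fiber, kappa)
                s_p1[i] = np.linalg.eigvalsh(sig.mean(axis=1))[:, -1]
                e_p1[i] = np.linalg.eigvalsh(E.mean(axis=1))[:, -1]
        from .fem import element_volumes

        return SimulationResult(
            times=times,
            displacements=disp,
            rv_volume_ml=rv_v,
            lv_volume_ml=lv_v,
            stress_p1=s_p1,
            strain_p1=e_p1,
            element_volumes=element_volumes(self.mesh.nodes[self.mesh.elements]),
            rv_domain=np.isin(self.mesh.region, ("RV", "septum", "scar", "patch")),
        )

    def simulate_cycle(
        self,
        pressures: PressureSchedule,
        max_cycles: int = 10,
        convergence_tol: float = 1e-3,
    ) -> SimulationResult:
        """Repeat cardiac cycles until periodic convergence (< 0.1% in the
        relative space-time L2 metric by default), then return the final
        recorded cycle with its convergence history."""
        prev = None
        # starting from the calibrated end-diastolic anchor (the begin-
        # ejection state, which is also t = 0 of the schedule) when
        # available saves the expensive cold inflation
        anchors = getattr(self, "anchor_states", None) or {}
        u = anchors.get("end_filling")
        u = u.copy() if u is not None else np.zeros_like(self.mesh.nodes)
        metrics = []
        last_load = None
        for cyc in range(max_cycles):
            curr = self.run_cycle(pressures, u, from_load=last_load)
            u = curr.displacements[-1]
            i_last = len(pressures.times) - 1
            last_load = (
                float(pressures.p_rv[i_last]),
                float(pressures.p_lv[i_last]),
                float(pressures.phase_weight(pressures.times[i_last])),
                [
                    float(band_zero_stress_schedule(b, pressures.times[i_last], pressures.systole_fraction))
                    for b in self.bands
                ],
            )
            if prev is not None:
                m = cycle_convergence(prev, curr)
                metrics.append(m)
                if m < convergence_tol:
                    curr.n_cycles = cyc + 1
                    curr.convergence = metrics
                    return curr
            prev = curr
        raise ConvergenceError(
            f"no periodic convergence in {max_cycles} cycles", history=metrics
        )


def export_cycle_result(
    mesh: VentricleMesh, result: SimulationResult, pressures: PressureSchedule, outdir
) -> None:
    """Write a simulated cycle as a VTK time series plus a metrics CSV.

    One legacy-VTK file per time point (displacement point data, principal
    stress/strain cell data) and ``volumes.csv`` with time, phase weight,
    pressures and cavity volumes.
    """
    import csv
    from pathlib import Path

    from .meshing import write_vtk

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for i, t in enumerate(result.times):
        write_vtk(
            mesh,
            outdir / f"cycle_{i:03d}.vtk",
            point_data={"displacement": result.displacements[i]},
            cell_data={"stress_p1": result.stress_p1[i], "strain_p1": result.strain_p1[i]},
        )
    with open(outdir / "volumes.csv", "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["time", "phase_weight", "p_rv_kpa", "p_lv_kpa", "rv_volume_ml", "lv_volume_ml"])
        for i, t in enumerate(result.times):
            w.writerow(
                [
                    t,
                    float(pressures.phase_weight(t)),
                    pressures.p_rv[i],
                    pressures.p_lv[i],
                    result.rv_volume_ml[i],
                    result.lv_volume_ml[i],
                ]
            )


# ---------------------------------------------------------------------------
# free functions (operation surface)


def solve_equilibrium(
    mesh: VentricleMesh,
    materials,
    p_rv: float,
    p_lv: float,
    systolic_weight: float = 0.0,
    bands=(),
    band_factors=None,
    **kwargs,
) -> np.ndarray:
    """One-shot equilibrium solve; see :meth:`BiventModel.solve_state`."""
    model = BiventModel(mesh, materials=materials, bands=bands, **kwargs)
    return model.solve_state(p_rv, p_lv, systolic_weight, band_factors)


def cavity_volume(mesh: VentricleMesh, u: np.ndarray, cavity: str) -> float:
    """Cavity volume (ml) of the deformed mesh by the divergence theorem.

    The endocardial surface is closed with flat caps at the base (and at
    the apical truncation for the LV); the RV cavity closes onto the septum
    through the collapsed free-wall boundary.
    """
    if cavity not in ("RV", "LV"):
        raise ValidationError(f"unknown cavity {cavity!r}")
    info = mesh.info
    if cavity == "RV" and info["rv"] is None:
        raise ValidationError("mesh has no RV cavity")
    x = mesh.nodes + u
    vol = 0.0
    if cavity == "LV":
        vol += _quad_volume(x, info["lv_endo_quads"])
        vol += _fan_volume(x, info["lv_base_ring"], up=True)
        vol += _fan_volume(x, info["lv_apex_ring"], up=False)
    else:
        vol += _quad_volume(x, info["rv_endo_quads"])
        sep = x[info["rv_base_sep"]]
        fw = x[info["rv_base_fw"]]
        for m in range(len(fw) - 1):
            # basal cap strip [fw_m, fw_m+1, sep_m+1, sep_m], normal +z
            vol += _tri_det(fw[m], fw[m + 1], sep[m + 1])
            vol += _tri_det(fw[m], sep[m + 1], sep[m])
    if vol <= 0:
        raise ValidationError(f"non-positive {cavity} cavity volume: {vol / 1000.0:.3f} ml")
    return vol / 1000.0


def _tri_det(a, b, c):
    return float(np.dot(a, np.cross(b, c))) / 6.0


def _quad_volume(x, quads):
    if len(quads) == 0:
        return 0.0
    a, b, c, d = (x[quads[:, i]] for i in range(4))
    v = np.einsum("ij,ij->i", a, np.cross(b, c)).sum()
    v += np.einsum("ij,ij->i", a, np.cross(c, d)).sum()
    return float(v) / 6.0


def _fan_volume(x, ring, up: bool):
    pts = x[ring]
    centroid = pts.mean(axis=0)
    vol = 0.0
    n = len(ring)
    for i in range(n):
        a, b = pts[i], pts[(i + 1) % n]
        vol += _tri_det(centroid, a, b) if up else _tri_det(centroid, b, a)
    return vol
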