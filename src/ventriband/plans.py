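"""Band surgery plans and the per-patient model battery.

Five band-insertion plans are simulated on top of each patient's calibrated
baseline model:

* A — one band anterior to the mid papillary-muscle level
* B — one band posterior to the mid papillary-muscle level
* C — plans A and B combined (two bands)
* D — one band at the papillary-muscle base
* E — plans A, B and D combined (three bands)

The idealized crescent RV has no papillary muscles; the anchor stations are
parameterized fractions of the free-wall span and axial extent (the
synthetic analogue of the anatomical landmarks).  Each plan is run with a
passive band and active contraction ratios of 10/15/20%, which together
with the no-band baseline gives 21 models per patient (147 for a
seven-patient cohort).

Model names follow the convention A000/A010/.../APB020: plan prefix
(A, P, AP, B, APB for plans A-E) plus the percent contraction ratio.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .analysis import ejection_fraction, sample_surface_stress, summarize
from .errors import ConvergenceError, ValidationError
from .geometry import GeometryParams, generate_contour_stack, generate_pressure_schedule
from .meshing import (
    RegionSpec,
    VentricleMesh,
    assign_fibers,
    build_mesh,
    label_regions,
    rv_freewall_node,
)
from .preshrink import ShrinkSpec, calibrate_materials, preshrink_contours
from .solver import BandSpec, BiventModel, path_length

log = logging.getLogger(__name__)

RATIOS = (0.0, 0.10, 0.15, 0.20)


@dataclass(frozen=True)
class BandPlacement:
    """Endpoints of one band chord on the RV free-wall endocardium, as
    fractions of the crescent span (theta) and RV axial extent (z)."""

    theta_a: float
    theta_b: float
    z_frac: float


_SINGLE_PLANS = {
    "A": (BandPlacement(0.10, 0.55, 0.55),),  # anterior, mid level
    "B": (BandPlacement(0.45, 0.90, 0.55),),  # posterior, mid level
    "D": (BandPlacement(0.10, 0.90, 0.30),),  # papillary-muscle base
}

PLAN_BANDS: dict[str, tuple[BandPlacement, ...]] = {
    **_SINGLE_PLANS,
    "C": _SINGLE_PLANS["A"] + _SINGLE_PLANS["B"],
    "E": _SINGLE_PLANS["A"] + _SINGLE_PLANS["B"] + _SINGLE_PLANS["D"],
}

PLAN_PREFIX = {"A": "A", "B": "P", "C": "AP", "D": "B", "E": "APB"}
BAND_COUNTS = {"A": 1, "B": 1, "C": 2, "D": 1, "E": 3}


def model_name(plan: str | None, ratio: float) -> str:
    if plan is None:
        return "Baseline"
    if plan not in PLAN_PREFIX:
        raise ValidationError(f"unknown plan {plan!r}")
    return f"{PLAN_PREFIX[plan]}{int(round(ratio * 100)):03d}"


# ---------------------------------------------------------------------------
# patients


@dataclass(frozen=True)
class PatientSpec:
    """One (synthetic) patient: target RV volumes and loading."""

    patient_id: str
    rv_edv_ml: float
    rv_esv_ml: float
    p_rv_max_mmhg: float
    p_rv_min_mmhg: float = 4.0
    p_lv_max_mmhg: float = 120.0
    geometry_overrides: tuple = ()  # ((field, value), ...)

    def geometry_params(self) -> GeometryParams:
        """Idealized geometry scaled isotropically with the RV size
        (reference: a 204 ml end-diastolic RV); wall thicknesses are kept
        absolute, as dilation thins the wall relative to the cavity."""
        s = (self.rv_edv_ml / 204.17) ** (1.0 / 3.0)
        gp = GeometryParams(
            lv_radius=25.0 * s,
            lv_long_axis=60.0 * s,
            rv_edv_ml=self.rv_edv_ml,
            rv_esv_ml=self.rv_esv_ml,
        )
        for k, v in self.geometry_overrides:
            gp = replace(gp, **{k: v})
        return gp


def reference_cohort(
    n: int | None = None, max_inflation_ratio: float = 1.8
) -> list[PatientSpec]:
    """Patients with the reference cohort's printed EDV/ESV/peak pressures.

    ``max_inflation_ratio`` drops patients whose EDV/ESV exceeds what the
    idealized crescent geometry can accommodate: its exponential
    strain-stiffening saturates the passive diastolic inflation near a
    volume doubling, so end-systolic-to-end-diastolic ratios much above
    ~1.8 (EF ~45%+) have no calibrated solution on this geometry (a
    documented limitation of the synthetic stand-in, not of the method).
    With ``n`` given, returns the ``n`` smallest remaining hearts.
    """
    from .datasets import cohort_cmr

    t = cohort_cmr()
    specs = [
        PatientSpec(r.patient, r.rv_edv_ml, r.rv_esv_ml, r.p_rv_max_mmhg)
        for r in t.itertuples()
        if r.rv_edv_ml / r.rv_esv_ml <= max_inflation_ratio
    ]
    if n is not None:
        specs = sorted(specs, key=lambda s: s.rv_edv_ml)[:n]
    return specs


def synthetic_cohort(n: int, seed: int = 0) -> list[PatientSpec]:
    """Sample a cohort with the reference cohort's EDV/EF/pressure spread.

    EDV is log-normal around the cohort geometric mean, EF normal at
    39 +/- 5.5% (clipped to a dilated-RV range), and peak RV pressure
    normal at 38.6 +/- 12.9 mmHg (clipped to physiologic bounds).
    """
    rng = np.random.default_rng(seed)
    specs = []
    for i in range(n):
        edv = float(np.exp(rng.normal(np.log(330.0), 0.35)))
        # EF capped at 44% so EDV/ESV stays within the idealized crescent's
        # inflation capacity (see reference_cohort)
        ef = float(np.clip(rng.normal(39.0, 5.5), 28.0, 44.0))
        pmax = float(np.clip(rng.normal(38.6, 12.9), 22.0, 70.0))
        specs.append(
            PatientSpec(f"S{i + 1}", round(edv, 2), round(edv * (1 - ef / 100), 2), round(pmax, 1))
        )
    return specs


# ---------------------------------------------------------------------------
# model enumeration


@dataclass(frozen=True)
class ModelConfig:
    patient: PatientSpec
    name: str
    plan: str | None
    ratio: float
    seed: int = 0


def enumerate_models(
    patients, plans: str | tuple = "ABCDE", ratios=RATIOS, seed: int = 0
) -> list[ModelConfig]:
    """Full factorial battery: baseline + plan x ratio per patient.

    Deterministic ordering (patients, then baseline, then plans in the
    given order with ratios ascending); duplicate names raise.
    """
    if isinstance(patients, PatientSpec):
        patients = [patients]
    plans = list(plans)
    configs = []
    for p in patients:
        configs.append(ModelConfig(p, "Baseline", None, 0.0, seed))
        for plan in plans:
            for r in ratios:
                configs.append(ModelConfig(p, model_name(plan, r), plan, float(r), seed))
    names = [(c.patient.patient_id, c.name) for c in configs]
    if len(set(names)) != len(names):
        raise ValidationError("duplicate model names in the battery")
    return configs


# ---------------------------------------------------------------------------
# bands on a mesh


def make_bands(
    plan: str,
    mesh: VentricleMesh,
    u_ref: np.ndarray | None = None,
    contraction_ratio: float = 0.0,
    cross_section_area: float = 10.0,
) -> list[BandSpec]:
    """Instantiate the plan's bands on a mesh.

    The in-vivo length L of each band is measured along its path in the
    configuration ``u_ref`` (the baseline begin-filling state; reference
    configuration if omitted).
    """
    if plan not in PLAN_BANDS:
        raise ValidationError(f"unknown plan {plan!r}")
    if mesh.info.get("rv") is None:
        raise ValidationError("mesh has no RV free wall (band landmarks missing)")
    x_ref = mesh.nodes + (u_ref if u_ref is not None else 0.0)
    bands = []
    for pl in PLAN_BANDS[plan]:
        na = rv_freewall_node(mesh, pl.theta_a, pl.z_frac)
        nb = rv_freewall_node(mesh, pl.theta_b, pl.z_frac)
        if na == nb:
            raise ValidationError("degenerate band path (mesh too coarse)")
        L = path_length(x_ref, (na, nb))
        bands.append(
            BandSpec(
                plan=plan,
                path=(na, nb),
                in_vivo_length=L,
                contraction_ratio=contraction_ratio,
                cross_section_area=cross_section_area,
            )
        )
    return bands


# ---------------------------------------------------------------------------
# per-patient pipeline


DEFAULT_SCAR = RegionSpec(0.10, 0.35, 0.55, 0.85)
DEFAULT_PATCH = RegionSpec(0.60, 0.85, 0.55, 0.85)


@dataclass
class PatientModel:
    """Calibrated baseline model of one patient plus its anchor states."""

    spec: PatientSpec
    mesh: VentricleMesh
    model: BiventModel
    schedule: object
    calibration: dict
    u_es: np.ndarray = None
    u_ed: np.ndarray = None
    metrics: dict = field(default_factory=dict)


def build_patient(
    spec: PatientSpec,
    resolution: float | None = None,
    shrink: ShrinkSpec | None = None,
    materials=None,
    scar_spec: RegionSpec | None = DEFAULT_SCAR,
    patch_spec: RegionSpec | None = DEFAULT_PATCH,
    n_points: int = 100,
    resolution_scale: float = 1.0,
) -> PatientModel:
    """Generate, preshrink, mesh, and calibrate one patient's baseline.

    ``resolution`` defaults to 8 mm scaled with the heart's linear size, so
    every patient meshes to a similar element count; ``resolution_scale``
    coarsens/refines that default multiplicatively.
    """
    if resolution is None:
        resolution = 8.0 * resolution_scale * (spec.rv_edv_ml / 204.17) ** (1.0 / 3.0)
    stack = generate_contour_stack(spec.geometry_params(), phase="ES", n_points=n_points)
    zero_load = preshrink_contours(stack, shrink or ShrinkSpec())
    mesh = assign_fibers(build_mesh(zero_load, resolution=resolution))
    mesh = label_regions(mesh, scar_spec=scar_spec, patch_spec=patch_spec)
    sched = generate_pressure_schedule(
        spec.p_rv_max_mmhg, spec.p_rv_min_mmhg, spec.p_lv_max_mmhg
    )
    model = BiventModel(mesh, materials=materials, pressure_schedule=sched)
    calib = calibrate_materials(model, spec.rv_edv_ml, spec.rv_esv_ml)
    pm = PatientModel(
        spec=spec,
        mesh=mesh,
        model=model,
        schedule=sched,
        calibration=calib,
        u_es=model.anchor_states["end_ejection"],
        u_ed=model.anchor_states["end_filling"],
    )
    pm.metrics = _anchor_metrics(pm.model, pm.mesh, pm.u_es, pm.u_ed)
    return pm


def _anchor_metrics(model: BiventModel, mesh, u_es, u_ed, n_per_slice: int = 100) -> dict:
    """Volumes and endocardial stress/strain summaries at both anchors."""
    out = {}
    for tag, u, w in (("bf", u_es, 1.0), ("be", u_ed, 0.0)):
        mats, kappa = model.material_arrays(w)
        sig, eps = model.block.gauss_cauchy(u, mats, mesh.fiber, kappa)
        sampled = sample_surface_stress(
            mesh, u, sig.mean(axis=1), eps.mean(axis=1), n_per_slice
        )
        out[f"rv_vol_{tag}"] = model.cavity_volume(u, "RV")
        out[f"stress_{tag}"] = sampled["stress_p1_mean"]
        out[f"strain_{tag}"] = sampled["strain_p1_mean"]
    out["ef_pct"] = ejection_fraction(out["rv_vol_be"], out["rv_vol_bf"])
    return out


def run_patient_battery(
    pm: PatientModel, configs, cross_section_area: float = 10.0, state_store: dict | None = None
) -> list[dict]:
    """Run the band models of one patient against its calibrated baseline."""
    sched = pm.schedule
    p_min = float(sched.p_rv[sched.begin_filling])
    p_max = float(sched.p_rv[sched.begin_ejection])
    pl_min = float(sched.p_lv[sched.begin_filling])
    pl_max = float(sched.p_lv[sched.begin_ejection])
    rows = []
    base_ef = pm.metrics["ef_pct"]
    for cfg in configs:
        row = {
            "patient": pm.spec.patient_id,
            "model": cfg.name,
            "plan": cfg.plan or "",
            "n_bands": BAND_COUNTS.get(cfg.plan, 0),
            "ratio": cfg.ratio,
            "status": "ok",
        }
        try:
            if cfg.plan is None:
                metrics = dict(pm.metrics)
                metrics["delta_ef_pct"] = 0.0
                if state_store is not None:
                    state_store[(pm.spec.patient_id, cfg.name)] = (pm.mesh, pm.u_es, pm.u_ed)
            else:
                bands = make_bands(
                    cfg.plan,
                    pm.mesh,
                    u_ref=pm.u_es,
                    contraction_ratio=cfg.ratio,
                    cross_section_area=cross_section_area,
                )
                m = BiventModel(
                    pm.mesh,
                    materials=pm.model.materials,
                    bands=bands,
                    scales=pm.model.scales,
                    pressure_schedule=sched,
                )
                fac_sys = [1.0 - b.contraction_ratio for b in bands]
                u_es = m.solve_state(p_min, pl_min, 1.0, fac_sys, u0=pm.u_es)
                u_ed = m.solve_state(p_max, pl_max, 0.0, [1.0] * len(bands), u0=pm.u_ed)
                metrics = _anchor_metrics(m, pm.mesh, u_es, u_ed)
                metrics["delta_ef_pct"] = metrics["ef_pct"] - base_ef
                if state_store is not None:
                    state_store[(pm.spec.patient_id, cfg.name)] = (pm.mesh, u_es, u_ed)
            row.update(metrics)
        except ConvergenceError as exc:
            log.warning("model %s/%s failed: %s", pm.spec.patient_id, cfg.name, exc)
            row["status"] = f"failed: {exc}"
        rows.append(row)
    return rows


def run_battery(
    configs,
    resolution: float | None = None,
    materials=None,
    workers: int = 1,
    state_store: dict | None = None,
    **patient_kwargs,
) -> pd.DataFrame:
    """Run a battery of model configs; one calibration per patient.

    ``workers`` parallelizes over patients (results are independent of the
    worker count); individual model failures are recorded in the ``status``
    column rather than raised, but a battery where every model failed is an
    error.  With a dict passed as ``state_store`` the anchor displacement
    fields of every model are collected for export.
    """
    by_patient: dict[str, list[ModelConfig]] = {}
    specs: dict[str, PatientSpec] = {}
    for cfg in configs:
        by_patient.setdefault(cfg.patient.patient_id, []).append(cfg)
        specs[cfg.patient.patient_id] = cfg.patient

    def one(pid):
        pm = build_patient(specs[pid], resolution=resolution, materials=materials, **patient_kwargs)
        return run_patient_battery(pm, by_patient[pid], state_store=state_store)

    if workers > 1:
        from joblib import Parallel, delayed

        all_rows = Parallel(n_jobs=workers)(delayed(one)(pid) for pid in by_patient)
    else:
        all_rows = [one(pid) for pid in by_patient]
    rows = [r for chunk in all_rows for r in chunk]
    df = pd.DataFrame(rows)
    if (df.status != "ok").all():
        raise ConvergenceError("all battery models failed")
    return df


def summarize_battery(df: pd.DataFrame) -> pd.DataFrame:
    """Cohort mean +/- SD rows per model variant (the summary-table schema)."""
    cols = [
        "rv_vol_bf",
        "stress_bf",
        "strain_bf",
        "rv_vol_be",
        "stress_be",
        "strain_be",
        "ef_pct",
        "delta_ef_pct",
    ]
    rows = []
    for name, grp in df[df.status == "ok"].groupby("model", sort=False):
        row = {"model": name, "n": len(grp)}
        for c in cols:
            mean, sd = summarize(grp[c])
            row[f"{c}_mean"] = mean
            row[f"{c}_sd"] = sd
        rows.append(row)
    order = [model_name(None, 0)] + [
        model_name(p, r) for p in "ABCDE" for r in RATIOS
    ]
    out = pd.DataFrame(rows)
    out["__o"] = out.model.map({n: i for i, n in enumerate(order)})
    return out.sort_values("__o").drop(columns="__o").reset_index(drop=True)
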