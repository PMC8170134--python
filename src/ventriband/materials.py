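"""Anisotropic modified Mooney-Rivlin material laws for ventricular tissue.

The strain energy density is

    W = c1 (I1 - 3) + c2 (I2 - 3) + D1 [exp(D2 (I1 - 3)) - 1]
        + (K1/K2) [exp(K2 (I4 - 1)^2) - 1]

with I1, I2 the first two invariants of the right Cauchy-Green tensor
C = F^T F and I4 = n_f . C n_f the squared stretch along the fiber
direction n_f.  The fiber term uses the convention with K2 inside the
exponential (K2 is dimensionless, ~3); set ``k2_in_exponent=False`` for the
variant with a bare exponent.  Fibers are assumed to bear no compressive
load: the anisotropic term is active only for I4 > 1.

For the nearly incompressible continuum the deviatoric part of W is
evaluated on isochoric invariants (J^{-2/3}-scaled), with a volumetric
penalty U = kappa/2 (J - 1)^2, so the reference configuration is exactly
stress free.  On incompressible states (det C = 1) the isochoric and plain
invariants coincide and W reduces to the form above.

Units: stresses and energy densities in kPa; c2 = 0 for every shipped
parameter set but is kept for generality.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, replace
from importlib import resources
from pathlib import Path

import numpy as np

from .errors import ValidationError

# cycle-phase tags: "end_ejection" is the contracted (systolic) parameter
# set governing begin filling / ESV; "end_filling" is the relaxed
# (diastolic) set governing begin ejection / EDV.
PHASES = ("end_ejection", "end_filling")


@dataclass(frozen=True)
class MaterialParams:
    """One (region, phase) row of the material table (kPa where dimensional)."""

    c1: float
    c2: float = 0.0
    D1: float = 0.0
    D2: float = 0.0
    K1: float = 0.0
    K2: float = 1.0
    phase: str = "end_ejection"
    region: str = ""

    def __post_init__(self):
        if self.c1 < 0 or self.D1 < 0 or self.K1 < 0 or self.D2 < 0:
            raise ValidationError("material constants c1, D1, D2, K1 must be >= 0")
        if self.K1 > 0 and self.K2 <= 0:
            raise ValidationError("K2 must be positive when K1 > 0")

    def scaled(self, factor: float) -> "MaterialParams":
        """Jointly scale the stiffness-like constants (c1, D1, K1)."""
        return replace(self, c1=self.c1 * factor, D1=self.D1 * factor, K1=self.K1 * factor)


@dataclass
class DeformationState:
    """Deformation gradient F, C = F^T F, and reference fiber direction."""

    F: np.ndarray
    n_f: np.ndarray | None = None

    def __post_init__(self):
        self.F = np.asarray(self.F, dtype=float)
        if np.linalg.det(self.F) <= 0:
            raise ValidationError("det F must be positive")
        if self.n_f is not None:
            self.n_f = np.asarray(self.n_f, dtype=float)
            self.n_f = self.n_f / np.linalg.norm(self.n_f)

    @property
    def C(self) -> np.ndarray:
        return self.F.T @ self.F


@dataclass(frozen=True)
class Invariants:
    I1: float
    I2: float
    I4: float


def invariants(state: DeformationState) -> Invariants:
    """I1 = tr C, I2 = (I1^2 - C:C)/2, I4 = n_f . C n_f (1 if no fiber)."""
    C = state.C
    w = np.linalg.eigvalsh(C)
    if w[0] <= 0:
        raise ValidationError("C must be symmetric positive definite")
    i1 = float(np.trace(C))
    i2 = 0.5 * (i1 * i1 - float(np.tensordot(C, C)))
    i4 = 1.0 if state.n_f is None else float(state.n_f @ C @ state.n_f)
    return Invariants(i1, i2, i4)


def strain_energy(
    params: MaterialParams,
    inv: Invariants,
    k2_in_exponent: bool = True,
    fiber_compression_cutoff: bool = True,
) -> float:
    """Strain energy density W (kPa) at the given invariants."""
    w = params.c1 * (inv.I1 - 3.0) + params.c2 * (inv.I2 - 3.0)
    if params.D1 > 0:
        w += params.D1 * (np.exp(params.D2 * (inv.I1 - 3.0)) - 1.0)
    if params.K1 > 0:
        q = inv.I4 - 1.0
        if fiber_compression_cutoff:
            q = max(q, 0.0)
        expo = params.K2 * q * q if k2_in_exponent else q * q
        w += params.K1 / params.K2 * (np.exp(expo) - 1.0)
    return float(w)


# ---------------------------------------------------------------------------
# stress (vectorized kernels shared with the FE solver)


def pk2_stress_batch(
    C: np.ndarray,
    n_f: np.ndarray,
    c1,
    c2,
    D1,
    D2,
    K1,
    K2,
    kappa,
    k2_in_exponent: bool = True,
    pvol=None,
) -> np.ndarray:
    """Second Piola-Kirchhoff stress S = 2 dW/dC for batched inputs.

    ``C`` has shape (..., 3, 3); material constants broadcast over the
    leading axes.  Deviatoric energy on isochoric invariants + kappa/2
    (J-1)^2 volumetric penalty.  When ``pvol`` is given it replaces the
    pointwise penalty pressure kappa (J - 1) — the mean-dilatation
    treatment the FE kernels use to avoid volumetric locking.
    """
    C = np.asarray(C, dtype=float)
    I = np.broadcast_to(np.eye(3), C.shape)
    detC = np.linalg.det(C)
    J = np.sqrt(detC)
    Cinv = np.linalg.inv(C)
    i1 = np.trace(C, axis1=-2, axis2=-1)
    i2 = 0.5 * (i1 * i1 - np.einsum("...ij,...ij->...", C, C))
    nn = np.einsum("...i,...j->...ij", n_f, n_f)
    i4 = np.einsum("...ij,...ij->...", C, nn)

    d13 = detC ** (-1.0 / 3.0)
    d23 = detC ** (-2.0 / 3.0)
    i1b, i2b, i4b = i1 * d13, i2 * d23, i4 * d13

    f1 = c1 + D1 * D2 * np.exp(D2 * (i1b - 3.0))
    f2 = np.broadcast_to(np.asarray(c2, dtype=float), i1b.shape)
    q = np.maximum(i4b - 1.0, 0.0)  # fibers carry no compression
    expo = K2 * q * q if k2_in_exponent else q * q
    f4 = 2.0 * K1 * q * np.exp(expo)

    dI1b = d13[..., None, None] * (I - (i1 / 3.0)[..., None, None] * Cinv)
    dI2b = d23[..., None, None] * (
        i1[..., None, None] * I - C - (2.0 * i2 / 3.0)[..., None, None] * Cinv
    )
    dI4b = d13[..., None, None] * (nn - (i4 / 3.0)[..., None, None] * Cinv)

    S = 2.0 * (
        np.asarray(f1)[..., None, None] * dI1b
        + f2[..., None, None] * dI2b
        + np.asarray(f4)[..., None, None] * dI4b
    )
    pressure = kappa * (J - 1.0) if pvol is None else np.broadcast_to(pvol, J.shape)
    S = S + (pressure * J)[..., None, None] * Cinv
    return S


def material_tangent_batch(C, n_f, c1, c2, D1, D2, K1, K2, kappa, h=1e-7, S0=None, pvol=None):
    """dS/dC (minor-symmetric, shape (..., 3, 3, 3, 3)) by finite differences.

    Forward differences against the analytic S (optionally pre-evaluated as
    ``S0``) keep the tangent consistent with the stress to ~1e-7 relative,
    which preserves Newton convergence down to the solver's residual
    tolerances at a cost of six extra stress evaluations.
    """
    C = np.asarray(C, dtype=float)
    if S0 is None:
        S0 = pk2_stress_batch(C, n_f, c1, c2, D1, D2, K1, K2, kappa, pvol=pvol)
    D = np.empty(C.shape + (3, 3))
    for p in range(3):
        for q in range(p, 3):
            dC = np.zeros((3, 3))
            dC[p, q] += 0.5 * h
            dC[q, p] += 0.5 * h
            Sp = pk2_stress_batch(C + dC, n_f, c1, c2, D1, D2, K1, K2, kappa, pvol=pvol)
            # the symmetric perturbation totals h, so this is the true dS/dC
            D[..., p, q] = (Sp - S0) / h
            D[..., q, p] = D[..., p, q]
    return D


def cauchy_stress(
    state: DeformationState, params: MaterialParams, bulk_penalty: float = 0.0
) -> np.ndarray:
    """Cauchy stress sigma = (1/J) F S F^T (kPa), symmetric, zero at identity."""
    F = state.F
    J = np.linalg.det(F)
    n = state.n_f if state.n_f is not None else np.array([1.0, 0.0, 0.0])
    S = pk2_stress_batch(
        state.C[None],
        n[None],
        params.c1,
        params.c2,
        params.D1,
        params.D2,
        params.K1,
        params.K2,
        bulk_penalty,
    )[0]
    sig = F @ S @ F.T / J
    return 0.5 * (sig + sig.T)


def uniaxial_stress_curve(
    params: MaterialParams,
    stretch_range=(0.95, 1.4),
    n: int = 46,
    direction: str = "fiber",
) -> tuple[np.ndarray, np.ndarray]:
    """Incompressible uniaxial Cauchy stress vs stretch.

    The lateral pressure is eliminated exactly by the traction-free lateral
    faces (plane-stress condition of a uniaxial test), i.e. the Lagrange
    pressure is chosen so the transverse Cauchy stress vanishes.  The fiber
    lies along the loading axis for ``direction='fiber'`` and transverse to
    it for ``direction='cross_fiber'``.
    """
    if direction not in ("fiber", "cross_fiber"):
        raise ValidationError(f"unknown direction {direction!r}")
    lam = np.linspace(*stretch_range, n)
    stress = np.empty_like(lam)
    for i, L in enumerate(lam):
        i1 = L * L + 2.0 / L
        # dW_iso/dI1 at the incompressible uniaxial state
        f1 = params.c1 + params.D1 * params.D2 * np.exp(params.D2 * (i1 - 3.0))
        f2 = params.c2
        # sigma_axial - sigma_lateral for an incompressible I1/I2 material
        s = 2.0 * (L * L - 1.0 / L) * (f1 + f2 / L)
        if params.K1 > 0:
            i4 = L * L if direction == "fiber" else 1.0 / L
            q = max(i4 - 1.0, 0.0)
            f4 = 2.0 * params.K1 * q * np.exp(params.K2 * q * q)
            if direction == "fiber":
                s += 2.0 * f4 * L * L
            # cross-fiber: the fiber term acts laterally; with the fiber
            # compression cutoff (i4 = 1/L < 1 for L > 1) it vanishes
            elif q > 0:
                s -= 2.0 * f4 / L
        stress[i] = s
    return lam, stress


def phase_interpolate(
    params_ee: MaterialParams, params_ef: MaterialParams, weight: float
) -> MaterialParams:
    """Blend the end-ejection and end-filling parameter sets.

    ``weight`` is the systolic weight in [0, 1]: 0 returns the end-filling
    (diastolic) set exactly, 1 the end-ejection (systolic) set.  Intermediate
    values blend each constant linearly in the weight; driving the weight
    with the half-cosine cycle profile makes the variation smooth and
    periodic over the cycle.
    """
    if params_ee.region != params_ef.region:
        raise ValidationError(
            f"region mismatch: {params_ee.region!r} vs {params_ef.region!r}"
        )
    w = float(weight)
    mix = lambda a, b: (1.0 - w) * b + w * a  # noqa: E731
    return MaterialParams(
        c1=mix(params_ee.c1, params_ef.c1),
        c2=mix(params_ee.c2, params_ef.c2),
        D1=mix(params_ee.D1, params_ef.D1),
        D2=mix(params_ee.D2, params_ef.D2),
        K1=mix(params_ee.K1, params_ef.K1),
        K2=mix(params_ee.K2, params_ef.K2),
        phase=params_ee.phase if w >= 0.5 else params_ef.phase,
        region=params_ee.region,
    )


# ---------------------------------------------------------------------------
# material tables


def load_material_table(path=None) -> dict[tuple[str, str], MaterialParams]:
    """Load a (region, phase) -> MaterialParams table from CSV or YAML.

    Defaults to the packaged reference table (repaired-TOF ventricle, patch,
    scar, and band parameter sets at the two anchor phases).  The YAML
    dialect is a list of row mappings with the same keys as the CSV columns
    (region, phase, c1, c2, D1, D2, K1, K2; kPa where dimensional).
    """
    if path is None:
        src = resources.files("ventriband.data") / "materials.csv"
        text = src.read_text()
        rows = list(csv.DictReader(text.splitlines()))
    elif str(path).endswith((".yaml", ".yml")):
        import yaml

        rows = yaml.safe_load(Path(path).read_text())
    else:
        rows = list(csv.DictReader(Path(path).read_text().splitlines()))
    table = {}
    for row in rows:
        p = MaterialParams(
            c1=float(row["c1"]),
            c2=float(row["c2"]),
            D1=float(row["D1"]),
            D2=float(row["D2"]),
            K1=float(row["K1"]),
            K2=float(row["K2"]),
            phase=row["phase"],
            region=row["region"],
        )
        table[(row["region"], row["phase"])] = p
    return table


def default_materials() -> dict[tuple[str, str], MaterialParams]:
    return load_material_table()
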