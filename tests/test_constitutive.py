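import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from ventriband.errors import ValidationError
from ventriband.materials import (
    DeformationState,
    Invariants,
    MaterialParams,
    cauchy_stress,
    default_materials,
    invariants,
    phase_interpolate,
    pk2_stress_batch,
    strain_energy,
    uniaxial_stress_curve,
)

MYO_EE = MaterialParams(c1=7.64, D1=2.41, D2=3.0, K1=36.55, K2=3.0,
                        phase="end_ejection", region="myo")
MYO_EF = MaterialParams(c1=2.78, D1=0.87, D2=3.0, K1=13.29, K2=3.0,
                        phase="end_filling", region="myo")
BAND = MaterialParams(c1=900.0, region="band")


def random_spd_state(rng, scale=0.2):
    F = np.eye(3) + rng.normal(size=(3, 3)) * scale
    if np.linalg.det(F) < 0.3:
        F = np.eye(3) + 0.1 * rng.normal(size=(3, 3))
    n = rng.normal(size=3)
    return DeformationState(F, n_f=n / np.linalg.norm(n))


class TestInvariants:
    def test_identity(self):
        inv = invariants(DeformationState(np.eye(3), n_f=[1, 0, 0]))
        assert (inv.I1, inv.I2, inv.I4) == (3.0, 3.0, 1.0)

    def test_incompressible_uniaxial(self):
        lam = 1.2
        F = np.diag([lam, lam**-0.5, lam**-0.5])
        inv = invariants(DeformationState(F, n_f=[1, 0, 0]))
        assert inv.I1 == pytest.approx(3.10667, abs=1e-5)
        assert inv.I4 == pytest.approx(1.44, abs=1e-12)

    def test_fiber_orthogonal_to_stretch(self):
        lam = 1.2
        F = np.diag([lam, lam**-0.5, lam**-0.5])
        inv = invariants(DeformationState(F, n_f=[0, 1, 0]))
        assert inv.I4 == pytest.approx(1 / 1.2, abs=1e-12)

    def test_non_positive_det_rejected(self):
        with pytest.raises(ValidationError):
            DeformationState(np.diag([1.0, 1.0, -1.0]))


class TestStrainEnergy:
    def test_zero_at_identity_for_all_table_rows(self):
        for p in default_materials().values():
            assert strain_energy(p, Invariants(3, 3, 1)) == 0.0

    def test_isotropic_example(self):
        p = MaterialParams(c1=7.64, c2=0, D1=2.41, D2=3.0, K1=0, region="m")
        w = strain_energy(p, Invariants(3.1, 3.1, 1.0))
        assert w == pytest.approx(0.764 + 2.41 * (np.exp(0.3) - 1), abs=1e-6)
        assert w == pytest.approx(1.6072, abs=1e-4)

    def test_anisotropic_example(self):
        p = MaterialParams(c1=0, D1=0, K1=36.55, K2=3.0, region="m")
        w = strain_energy(p, Invariants(3, 3, 1.1))
        assert w == pytest.approx(36.55 / 3 * (np.exp(3 * 0.01) - 1), abs=1e-6)
        assert w == pytest.approx(0.3711, abs=2e-4)

    def test_printed_exponent_variant(self):
        p = MaterialParams(c1=0, D1=0, K1=36.55, K2=3.0, region="m")
        w = strain_energy(p, Invariants(3, 3, 1.1), k2_in_exponent=False)
        assert w == pytest.approx(36.55 / 3 * (np.exp(0.01) - 1), abs=1e-9)

    def test_positive_on_incompressible_states(self):
        """W >= 0 for all shipped parameter sets on det C = 1 stretches."""
        for p in default_materials().values():
            for lam in np.linspace(0.85, 1.5, 14):
                F = np.diag([lam, lam**-0.5, lam**-0.5])
                inv = invariants(DeformationState(F, n_f=[1, 0, 0]))
                assert strain_energy(p, inv) >= -1e-12


class TestCauchyStress:
    def test_zero_at_identity(self):
        sig = cauchy_stress(DeformationState(np.eye(3), n_f=[1, 0, 0]), MYO_EE, 1e4)
        assert np.abs(sig).max() == 0.0

    def test_band_uniaxial_closed_form(self):
        """Incompressible uniaxial stretch of the band material: the axial
        Cauchy stress (lateral faces traction free) is 2 c1 (lam^2 - 1/lam)."""
        lam = 1.2
        F = np.diag([lam, lam**-0.5, lam**-0.5])
        sig = cauchy_stress(DeformationState(F), BAND, 0.0)
        assert sig[0, 0] - sig[1, 1] == pytest.approx(1092.0, rel=1e-9)
        lam_grid, s = uniaxial_stress_curve(BAND, (1.2, 1.2), 1)
        assert s[0] == pytest.approx(1092.0, rel=1e-9)

    def test_stress_is_energy_derivative(self):
        """S = 2 dW/dC against central finite differences of W at random
        SPD states (isochoric-split energy, fiber term included)."""
        rng = np.random.default_rng(11)
        kappa = 150.0

        def W(C, n, p):
            detC = np.linalg.det(C)
            J = np.sqrt(detC)
            i1 = np.trace(C)
            i2 = 0.5 * (i1**2 - np.sum(C * C))
            i4 = n @ C @ n
            i1b, i2b, i4b = i1 * detC ** (-1 / 3), i2 * detC ** (-2 / 3), i4 * detC ** (-1 / 3)
            w = p.c1 * (i1b - 3) + p.c2 * (i2b - 3)
            if p.D1 > 0:
                w += p.D1 * (np.exp(p.D2 * (i1b - 3)) - 1)
            q = max(i4b - 1, 0)
            if p.K1 > 0:
                w += p.K1 / p.K2 * (np.exp(p.K2 * q * q) - 1)
            return w + kappa / 2 * (J - 1) ** 2

        for _ in range(20):
            state = random_spd_state(rng)
            C, n = state.C, state.n_f
            S = pk2_stress_batch(
                C[None], n[None], MYO_EE.c1, MYO_EE.c2, MYO_EE.D1, MYO_EE.D2,
                MYO_EE.K1, MYO_EE.K2, kappa,
            )[0]
            h = 1e-6
            Sfd = np.zeros((3, 3))
            for i in range(3):
                for j in range(3):
                    dC = np.zeros((3, 3))
                    dC[i, j] += h / 2
                    dC[j, i] += h / 2
                    Sfd[i, j] = (W(C + dC, n, MYO_EE) - W(C - dC, n, MYO_EE)) / h
            assert np.abs(S - Sfd).max() / np.abs(S).max() < 1e-6

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(st.integers(0, 10_000))
    def test_frame_indifference(self, seed):
        """W(QF) = W(F) and sigma rotates objectively for random rotations."""
        rng = np.random.default_rng(seed)
        state = random_spd_state(rng)
        from scipy.spatial.transform import Rotation

        Q = Rotation.random(random_state=np.random.RandomState(seed)).as_matrix()
        inv0 = invariants(state)
        inv1 = invariants(DeformationState(Q @ state.F, n_f=state.n_f))
        assert strain_energy(MYO_EE, inv1) == pytest.approx(
            strain_energy(MYO_EE, inv0), rel=1e-12, abs=1e-12
        )

    def test_isotropy_when_k1_zero(self):
        """With K1 = 0 the energy is invariant under fiber rotation."""
        rng = np.random.default_rng(3)
        p = MaterialParams(c1=13.26, D1=13.26, D2=9.0, K1=0, region="scar")
        state = random_spd_state(rng)
        w = [
            strain_energy(p, invariants(DeformationState(state.F, n_f=n)))
            for n in ([1, 0, 0], [0, 1, 0], rng.normal(size=3))
        ]
        assert max(w) - min(w) < 1e-12


class TestStressCurves:
    def test_monotone_and_fiber_stiffer(self):
        lam, s_f = uniaxial_stress_curve(MYO_EE, (1.0, 1.4), 41, "fiber")
        _, s_c = uniaxial_stress_curve(MYO_EE, (1.0, 1.4), 41, "cross_fiber")
        assert np.all(np.diff(s_f) > 0)
        assert np.all(s_f[1:] >= s_c[1:])

    def test_zero_stress_at_unit_stretch(self):
        for p in default_materials().values():
            _, s = uniaxial_stress_curve(p, (1.0, 1.0), 1)
            assert s[0] == pytest.approx(0.0, abs=1e-12)

    def test_scar_is_half_of_patch(self):
        """Scar parameters are exactly half the patch's, and W is linear in
        (c1, D1), so the stress curves scale by 0.5 pointwise."""
        mats = default_materials()
        lam, s_scar = uniaxial_stress_curve(mats[("scar", "end_ejection")], (1.0, 1.4), 21)
        _, s_patch = uniaxial_stress_curve(mats[("patch", "end_ejection")], (1.0, 1.4), 21)
        assert np.allclose(s_scar, 0.5 * s_patch, rtol=1e-12, atol=1e-12)

    def test_systolic_curve_above_diastolic(self):
        lam, s_ee = uniaxial_stress_curve(MYO_EE, (1.01, 1.3), 30)
        _, s_ef = uniaxial_stress_curve(MYO_EF, (1.01, 1.3), 30)
        assert np.all(s_ee > s_ef)


class TestPhaseInterpolation:
    def test_anchor_endpoints(self):
        assert phase_interpolate(MYO_EE, MYO_EF, 0.0).c1 == 2.78
        assert phase_interpolate(MYO_EE, MYO_EF, 1.0).c1 == 7.64

    def test_midpoint_blend(self):
        assert phase_interpolate(MYO_EE, MYO_EF, 0.5).c1 == pytest.approx(5.21)

    def test_region_mismatch_raises(self):
        other = MaterialParams(c1=1.0, region="other")
        with pytest.raises(ValidationError):
            phase_interpolate(MYO_EE, other, 0.5)


def test_material_constant_validation():
    with pytest.raises(ValidationError):
        MaterialParams(c1=-1.0, region="x")
    with pytest.raises(ValidationError):
        MaterialParams(c1=1.0, K1=5.0, K2=0.0, region="x")


def test_material_table_yaml_and_csv_agree(tmp_path):
    import yaml

    from ventriband.materials import load_material_table

    table = default_materials()
    rows = [
        {"region": r, "phase": ph, **{k: getattr(p, k) for k in ("c1", "c2", "D1", "D2", "K1", "K2")}}
        for (r, ph), p in table.items()
    ]
    ypath = tmp_path / "materials.yaml"
    ypath.write_text(yaml.safe_dump(rows))
    assert load_material_table(ypath) == table
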