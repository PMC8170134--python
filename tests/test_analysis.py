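import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from ventriband.analysis import (
    delta_ef,
    ejection_fraction,
    max_principal,
    sample_surface_stress,
    simpson_volume,
    summarize,
    wilcoxon_signed_rank_exact,
)
from ventriband.datasets import (
    baseline_ef,
    cohort_cmr,
    reported_band_models_r20,
    reported_plan_e_ratios,
)
from ventriband.errors import ValidationError
from ventriband.geometry import ContourSlice, ContourStack


class TestEjectionFraction:
    @pytest.mark.parametrize(
        "edv,esv,expected",
        [
            (406.91, 254.49, 37.46),  # printed 37.5
            (204.64, 113.82, 44.38),
            (100.0, 100.0, 0.0),
        ],
    )
    def test_examples(self, edv, esv, expected):
        assert ejection_fraction(edv, esv) == pytest.approx(expected, abs=0.005)

    def test_esv_above_edv_rejected(self):
        with pytest.raises(ValidationError):
            ejection_fraction(100.0, 120.0)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(
        st.floats(1.0, 1000.0), st.floats(0.0, 1.0), st.floats(0.01, 100.0)
    )
    def test_scale_invariance(self, edv, frac, k):
        esv = edv * frac
        assert ejection_fraction(k * edv, k * esv) == pytest.approx(
            ejection_fraction(edv, esv), rel=1e-9, abs=1e-9
        )

    def test_delta_ef_examples(self):
        assert delta_ef(41.58, 37.38) == pytest.approx(4.20)
        assert delta_ef(33.78, 37.38) == pytest.approx(-3.60)
        assert delta_ef(40.0, 40.0) == 0.0


class TestSimpsonVolume:
    def test_cylinder(self):
        th = np.linspace(0, 2 * np.pi, 256, endpoint=False)
        ring = np.column_stack([20 * np.cos(th), 20 * np.sin(th)])
        slices = [
            ContourSlice(float(z), ring.copy(), 1.5 * ring.copy())
            for z in np.linspace(0, 60, 7)
        ]
        st_ = ContourStack(slices, 10.0)
        assert simpson_volume(st_, "lv_inner") == pytest.approx(75.40, abs=0.1)

    def test_half_ellipsoid(self):
        a, c = 25.0, 50.0
        zs = np.linspace(-c, 0.0, 21)
        th = np.linspace(0, 2 * np.pi, 256, endpoint=False)
        slices = []
        for z in zs:
            r = max(a * np.sqrt(max(1 - (z / c) ** 2, 0.0)), 1e-9)
            ring = np.column_stack([r * np.cos(th), r * np.sin(th)])
            slices.append(ContourSlice(float(z), ring, 1.2 * ring))
        v = simpson_volume(ContourStack(slices, float(zs[1] - zs[0])), "lv_inner")
        exact = 2.0 / 3.0 * np.pi * a * a * c / 1000.0
        assert v == pytest.approx(exact, rel=0.005)

    def test_non_monotone_z_rejected(self):
        th = np.linspace(0, 2 * np.pi, 32, endpoint=False)
        ring = np.column_stack([np.cos(th), np.sin(th)])
        slices = [ContourSlice(z, ring, 2 * ring) for z in (0.0, 10.0, 5.0)]
        with pytest.raises(ValidationError):
            simpson_volume(ContourStack(slices, 5.0), "lv_inner")


class TestMaxPrincipal:
    def test_diagonal(self):
        assert max_principal(np.diag([3.0, 1.0, -2.0])) == 3.0
        assert max_principal(np.zeros((3, 3))) == 0.0

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(st.integers(0, 10_000))
    def test_rotation_invariance(self, seed):
        from scipy.spatial.transform import Rotation

        Q = Rotation.random(random_state=np.random.RandomState(seed)).as_matrix()
        t = Q @ np.diag([3.0, 1.0, -2.0]) @ Q.T
        assert max_principal(t) == pytest.approx(3.0, abs=1e-10)

    def test_asymmetric_rejected(self):
        t = np.diag([1.0, 2.0, 3.0])
        t[0, 1] = 0.5
        with pytest.raises(ValidationError):
            max_principal(t)


class TestSummarize:
    def test_plan_e_ef_column(self):
        vals = [41.58, 40.46, 33.58, 45.40, 46.28, 51.75, 41.29]
        mean, sd = summarize(vals)
        assert mean == pytest.approx(42.90, abs=0.01)
        assert sd == pytest.approx(5.68, abs=0.01)

    def test_clinical_ef_column(self):
        mean, sd = summarize([37.5, 37.7, 30.2, 40.4, 40.6, 48.8, 37.8])
        assert mean == pytest.approx(39.00, abs=0.005)
        assert sd == pytest.approx(5.53, abs=0.005)

    def test_constant_list_zero_sd(self):
        assert summarize([5.0, 5.0, 5.0]) == (5.0, 0.0)

    def test_empty_rejected(self):
        with pytest.raises(ValidationError):
            summarize([])


class TestWilcoxonExact:
    def test_all_positive_n7(self):
        t4 = reported_band_models_r20()
        e = t4[t4.plan == "E"].set_index("patient").ef_pct
        base = baseline_ef()
        res = wilcoxon_signed_rank_exact(e, base)
        assert res["p"] == pytest.approx(2.0 / 128.0)
        assert res["p"] == pytest.approx(0.015625)
        assert res["n"] == 7

    def test_equal_samples_p_one(self):
        with pytest.warns(UserWarning):
            res = wilcoxon_signed_rank_exact([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res["p"] == 1.0

    def test_distribution_sums_to_one(self):
        from ventriband.analysis import _signed_rank_distribution

        support, probs = _signed_rank_distribution(np.arange(1.0, 8.0))
        assert probs.sum() == pytest.approx(1.0, abs=1e-12)
        assert support[-1] == 28.0  # W+ in 0..28

    def test_against_brute_force_enumeration(self):
        """Exact p matches full 2^n enumeration of sign assignments for
        random tie-free data at n <= 10."""
        rng = np.random.default_rng(7)
        for n in (4, 6, 8, 10):
            x = rng.normal(size=n)
            y = rng.normal(size=n)
            d = x - y
            ranks = np.argsort(np.argsort(np.abs(d))) + 1.0
            w_obs = ranks[d > 0].sum()
            count_le = count_ge = 0
            for signs in itertools.product([0, 1], repeat=n):
                w = sum(r for r, s in zip(ranks, signs) if s)
                count_le += w <= w_obs + 1e-9
                count_ge += w >= w_obs - 1e-9
            p_brute = min(1.0, 2 * min(count_le, count_ge) / 2**n)
            assert wilcoxon_signed_rank_exact(x, y)["p"] == pytest.approx(
                p_brute, abs=1e-12
            )

    def test_against_scipy_exact(self):
        from scipy.stats import wilcoxon as scipy_wilcoxon

        rng = np.random.default_rng(1)
        for n in (5, 7, 9, 12):
            x = rng.normal(size=n)
            y = rng.normal(size=n)
            assert wilcoxon_signed_rank_exact(x, y)["p"] == pytest.approx(
                scipy_wilcoxon(x, y, mode="exact").pvalue, abs=1e-12
            )


class TestSurfaceSampling:
    def test_point_count_and_uniform_field(self, biv_mesh):
        """100 points per slice on every RV endocardial loop; a uniform
        tensor field samples to exactly the field value."""
        ne = biv_mesh.n_elements
        t = np.diag([2.0, 1.0, 0.5])
        field = np.tile(t, (ne, 1, 1))
        out = sample_surface_stress(
            biv_mesh, np.zeros_like(biv_mesh.nodes), field, field, n_per_slice=100
        )
        n_loops = len(biv_mesh.info["rv_endo_loops"])
        assert out["stress_tensors"].shape == (100 * n_loops, 3, 3)
        assert np.allclose(out["stress_tensors"], t, atol=1e-12)
        assert out["stress_p1_mean"] == pytest.approx(2.0, abs=1e-12)

    def test_sampling_density_robustness(self, patient_coarse):
        """Halving the per-slice sampling density changes the mean by <1%
        for the smooth anchor-state stress field."""
        pm = patient_coarse
        mats, kappa = pm.model.material_arrays(0.0)
        sig, eps = pm.model.block.gauss_cauchy(pm.u_ed, mats, pm.mesh.fiber, kappa)
        full = sample_surface_stress(
            pm.mesh, pm.u_ed, sig.mean(axis=1), eps.mean(axis=1), 100
        )
        half = sample_surface_stress(
            pm.mesh, pm.u_ed, sig.mean(axis=1), eps.mean(axis=1), 50
        )
        assert half["stress_p1_mean"] == pytest.approx(
            full["stress_p1_mean"], rel=0.01
        )


def test_cohort_table_consistency():
    """Reported per-patient EF columns agree with EF recomputed from the
    printed volumes at the printed (two-decimal) precision."""
    t4 = reported_band_models_r20()
    for r in t4.itertuples():
        assert ejection_fraction(r.rv_vol_be_ml, r.rv_vol_bf_ml) == pytest.approx(
            r.ef_pct, abs=0.011
        )
    t1 = cohort_cmr()
    for r in t1.itertuples():
        # clinical EF printed at one decimal (one cell carries an extra
        # last-digit slip in the source)
        assert ejection_fraction(r.rv_edv_ml, r.rv_esv_ml) == pytest.approx(
            r.rv_ef_pct, abs=0.1
        )
    t5 = reported_plan_e_ratios()
    for r in t5.itertuples():
        assert ejection_fraction(r.rv_vol_be_ml, r.rv_vol_bf_ml) == pytest.approx(
            r.ef_pct, abs=0.011
        )
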