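import numpy as np
import pytest

from ventriband.geometry import (
    ContourSlice,
    ContourStack,
    GeometryParams,
    generate_contour_stack,
)
from ventriband.meshing import assign_fibers, build_mesh, label_regions
from ventriband.plans import DEFAULT_PATCH, DEFAULT_SCAR, build_patient, reference_cohort


def circle_ring(r, n=64):
    th = np.linspace(0, 2 * np.pi, n, endpoint=False)
    return np.column_stack([r * np.cos(th), r * np.sin(th)])


@pytest.fixture(scope="session")
def annulus_stack():
    """Concentric-cylinder stack: r_in 20, r_out 30 mm, height 60 mm."""
    slices = [
        ContourSlice(float(z), circle_ring(20.0, 256), circle_ring(30.0, 256))
        for z in np.linspace(0, 60, 7)
    ]
    return ContourStack(slices, 10.0)


@pytest.fixture(scope="session")
def es_stack():
    """Default end-systolic bi-ventricle stack (204/121 ml RV targets)."""
    return generate_contour_stack(GeometryParams(), phase="ES")


@pytest.fixture(scope="session")
def biv_mesh(es_stack):
    mesh = assign_fibers(build_mesh(es_stack, resolution=8.0))
    return label_regions(mesh, scar_spec=DEFAULT_SCAR, patch_spec=DEFAULT_PATCH)


@pytest.fixture(scope="session")
def patient_coarse():
    """Calibrated coarse baseline of the smallest reference-cohort heart.

    Shared across the solver/calibration/cycle tests; tests that mutate the
    model's scales must restore them.
    """
    spec = reference_cohort(1)[0]
    return build_patient(spec, resolution=12.0)
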