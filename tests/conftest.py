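import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from keratrace.cohort import CohortConfig, cohort_to_table, generate_cohort
from keratrace.cornea import ConicSurface, CornealModel
from keratrace.tracing import GridSpec

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


def physiologic_model(rng: np.random.Generator, pupil_offset=(0.0, 0.0)) -> CornealModel:
    """One random cornea in the physiologic range of radii and asphericities."""
    r1 = rng.uniform(7.0, 8.6)
    r2 = rng.uniform(0.78, 0.86) * r1
    q1 = rng.uniform(-0.4, 0.3)
    q2 = rng.uniform(-0.4, 0.1)
    cct = rng.uniform(0.45, 0.60)
    return CornealModel(
        anterior=ConicSurface(r1, q1, 0.0),
        posterior=ConicSurface(r2, q2, cct),
        central_thickness=cct,
        pupil_offset=pupil_offset,
    )


@pytest.fixture(scope="session")
def standard_model() -> CornealModel:
    return CornealModel(
        anterior=ConicSurface(7.7, 0.0, 0.0),
        posterior=ConicSurface(6.4, 0.0, 0.5),
        central_thickness=0.5,
    )


@pytest.fixture(scope="session")
def study_cohort_table():
    """Full synthetic pipeline at the study's size (40 eyes)."""
    cfg = CohortConfig(n=40, seed=7)
    return cohort_to_table(generate_cohort(cfg))


@pytest.fixture(scope="session")
def small_cohort_table():
    """Tiny cohort on a coarse grid, for report/IO/CLI plumbing tests."""
    cfg = CohortConfig(n=8, seed=11)
    grid = GridSpec(radial_step=0.1, meridians=16, max_radius=4.0)
    return cohort_to_table(generate_cohort(cfg, grid=grid))
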