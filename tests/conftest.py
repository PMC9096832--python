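import numpy as np
import pytest

from discountclass.core import Cohort, DiscountingSeries, TaskSpec, hcp_task
from discountclass.synthgen import ClassRecipe, CohortRecipe


@pytest.fixture(scope="session")
def task200() -> TaskSpec:
    return hcp_task(200)


@pytest.fixture(scope="session")
def task40k() -> TaskSpec:
    return hcp_task(40000)


def make_series(task: TaskSpec, values, pid: str = "p1") -> DiscountingSeries:
    return DiscountingSeries(pid, task, np.asarray(values, dtype=float))


@pytest.fixture
def decreasing_series(task200):
    return make_series(task200, [180, 150, 120, 90, 60, 30])


@pytest.fixture(scope="session")
def two_class_linear_recipe(task200) -> CohortRecipe:
    """Well-separated planted mixture of a flat and a rising class.

    Both shapes are exactly linear in normalized delay, so the linear
    latent-class model is correctly specified; trajectories differ by at
    least 0.15*A at every delay against a residual SD of 0.02*A
    (> 5 residual SDs of separation).
    """
    return CohortRecipe(
        n_subjects=300,
        task=task200,
        classes=(
            ClassRecipe("flat", 0.5, {"c0": 0.75}, noise_sd=0.02, subject_sd=0.03),
            ClassRecipe("riser", 0.5, {"c0": 0.2, "c1": 0.4},
                        noise_sd=0.02, subject_sd=0.03),
        ),
        snap_to_grid=False,
        seed=101,
    )


@pytest.fixture(scope="session")
def one_class_recipe(task200) -> CohortRecipe:
    return CohortRecipe(
        n_subjects=300,
        task=task200,
        classes=(
            ClassRecipe("riser", 1.0, {"c0": 0.3, "c1": 0.3},
                        noise_sd=0.03, subject_sd=0.03),
        ),
        snap_to_grid=False,
        seed=202,
    )


def random_cohort(task: TaskSpec, n: int, rng: np.random.Generator) -> Cohort:
    """Arbitrary complete cohort with values uniform in [0, A]."""
    mat = rng.uniform(0, task.magnitude, size=(n, task.n_delays))
    series = [make_series(task, row, pid=f"r{i}") for i, row in enumerate(mat)]
    return Cohort(task=task, series=series)
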