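import numpy as np
import pytest

from ineqrad import (
    InequalityScheme,
    LocationTable,
    SyntheticSystemConfig,
    compute_distances,
    generate_system,
)


@pytest.fixture
def collinear_system() -> LocationTable:
    """Four collinear locations: origin, A (pop 7, class 1) at 1 km,
    j (pop 5, class 1) at 2 km, B (pop 9, class 2) at 3 km."""
    return LocationTable(
        ids=np.array(["i", "A", "j", "B"], dtype=object),
        coords=np.array([[0.0, 0.0], [1.0, 0.0], [2.0, 0.0], [3.0, 0.0]]),
        populations=np.array([4, 7, 5, 9]),
        classes=np.array([1, 1, 1, 2]),
        coord_system="planar",
    )


@pytest.fixture
def small_system():
    """A 10-location two-class synthetic system with moderate populations."""
    cfg = SyntheticSystemConfig(L=10, p_max=500, penalized_fraction=0.3)
    table, _ = generate_system(cfg, seed=101)
    return table


@pytest.fixture
def small_distances(small_system):
    return compute_distances(small_system)


@pytest.fixture
def scheme_delta2():
    return InequalityScheme.two_class(2.0)


def random_two_class_system(rng: np.random.Generator, L: int, p_max: int = 500) -> LocationTable:
    """A random planar two-class system (helper for randomized tests)."""
    pops = rng.integers(1, p_max + 1, size=L)
    classes = np.ones(L, dtype=np.int64)
    classes[rng.choice(L, size=max(1, L // 3), replace=False)] = 2
    if not (classes == 1).any():
        classes[0] = 1
    return LocationTable(
        ids=np.array([f"n{i}" for i in range(L)], dtype=object),
        coords=rng.uniform(0, 300, size=(L, 2)),
        populations=pops,
        classes=classes,
        coord_system="planar",
    )
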