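import numpy as np
import pytest

from rvskill import (
    Path3D,
    RepetitionSet,
    flat_profile,
    make_standard_path,
    simulate_repetitions,
)


@pytest.fixture(scope="session")
def helix_standard() -> Path3D:
    return make_standard_path("helix", scale=1.0, n_points=200)


@pytest.fixture()
def small_repset(helix_standard) -> RepetitionSet:
    """10 noisy repetitions of the helix, fixed seed."""
    return simulate_repetitions(helix_standard, flat_profile(0.5, 10, seed=42))


def shifted_repset(standard: Path3D, offsets) -> RepetitionSet:
    """Repetitions that are rigid x-shifts of the standard.

    Each repetition's deviation is its shift magnitude at every index, so
    per-path maxima equal the given offsets exactly.
    """
    reps = tuple(
        Path3D(standard.points + np.array([a, 0.0, 0.0]), label=f"shift{a}")
        for a in offsets
    )
    return RepetitionSet(standard, reps, len(standard))


@pytest.fixture()
def line_standard() -> Path3D:
    return Path3D(np.array([[0.0, 0.0, 0.0], [0.0, 0.0, 2.0]]), label="std")
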