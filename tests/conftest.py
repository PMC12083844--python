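import pytest

import casevac as cv


@pytest.fixture(scope="session")
def lushan():
    return cv.lushan_instance()


def small_params(seed: int) -> cv.GeneratorParams:
    """Tiny instances whose per-vehicle formulation stays tractable."""
    return cv.GeneratorParams(
        n_areas=3,
        n_temp=2,
        n_general=2,
        seed=seed,
        serious_range=(1, 6),
        moderate_range=(3, 12),
        fleet_override=(12, 12),
        # worst-case inflation with per-cell ceil rounding on single-digit
        # counts exceeds the generator's default slack
        capacity_slack=1.5,
    )


@pytest.fixture
def small_instance():
    return cv.generate_instance(small_params(0))
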