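import numpy as np
import pytest

from grazemark.deposit_io import MarkedPointPattern, StudyWindow


@pytest.fixture
def toy_pattern() -> MarkedPointPattern:
    """Collinear 3-point pattern with hand-checkable statistics."""
    window = StudyWindow(-1.0, 11.0, -1.0, 1.0)
    return MarkedPointPattern(
        window, [[0.0, 0.0], [1.0, 0.0], [10.0, 0.0]], [2.0, 4.0, 6.0]
    )


@pytest.fixture
def make_random_pattern():
    """Factory for small random marked patterns."""

    def _make(n: int, seed: int, side: float = 30.0) -> MarkedPointPattern:
        rng = np.random.default_rng(seed)
        window = StudyWindow(0.0, side, 0.0, side)
        points = rng.uniform(0.0, side, size=(n, 2))
        marks = rng.gamma(1.5, 10.0, size=n)
        return MarkedPointPattern(window, points, marks)

    return _make
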