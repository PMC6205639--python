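import numpy as np
import pytest

from quadcount import BoundingBox, PointPattern, generate


@pytest.fixture
def bbox() -> BoundingBox:
    return BoundingBox(width=640.0, height=480.0)


@pytest.fixture
def uniform_pattern(bbox) -> PointPattern:
    return generate("uniform", 1120, bbox=bbox, seed=1120)


def pattern_seed(kind: str, N: int) -> int:
    """Fixed seeding rule so every test regenerates the same patterns."""
    return N + 10_000 * (1 + ["uniform", "gradient", "clustered", "lattice"].index(kind))


def make_pattern(kind: str, N: int, bbox: BoundingBox) -> PointPattern:
    return generate(kind, N, bbox=bbox, seed=pattern_seed(kind, N))
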