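from fractions import Fraction

import pytest

from efmx.fixtures import toy_branch
from efmx.geometry import GeneralHRep
from efmx.model import BoundsTable

F = Fraction


@pytest.fixture
def toy():
    return toy_branch()


@pytest.fixture
def toy_bounds():
    return BoundsTable((("R1", "<=", F(10)), ("R4", ">=", F(1))))


@pytest.fixture
def tetrahedron():
    """x >= 0, x1 + x2 + x3 <= 1 in 3 variables: 4 vertices, no rays."""
    A = (
        (F(1), F(0), F(0)),
        (F(0), F(1), F(0)),
        (F(0), F(0), F(1)),
        (F(-1), F(-1), F(-1)),
    )
    return GeneralHRep(A, (F(0), F(0), F(0), F(-1)), name="tetra")


@pytest.fixture
def square_pyramid():
    """z >= 0, +-x + z <= 1, +-y + z <= 1: 5 vertices, apex degenerate."""
    A = (
        (F(0), F(0), F(1)),
        (F(-1), F(0), F(-1)),
        (F(1), F(0), F(-1)),
        (F(0), F(-1), F(-1)),
        (F(0), F(1), F(-1)),
    )
    return GeneralHRep(A, (F(0), F(-1), F(-1), F(-1), F(-1)), name="pyramid")
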