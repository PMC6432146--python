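"""Shared fixtures: force fields, straight chains, tied knotted chains.

Expensive constructions (tied chains) are session-scoped; tests must not
mutate them in place — copy first.
"""

from __future__ import annotations

import numpy as np
import pytest

from knotswap.init_config import tie_knots_on_chain
from knotswap.model import BeadChain, ForceField


@pytest.fixture(scope="session")
def ff() -> ForceField:
    return ForceField()


@pytest.fixture(scope="session")
def ff_ideal() -> ForceField:
    return ForceField(excluded_volume=False)


def make_straight(n: int, bond: float = 0.97) -> BeadChain:
    pts = np.zeros((n, 3))
    pts[:, 2] = np.arange(n) * bond
    return BeadChain(pts)


@pytest.fixture()
def straight_chain():
    return make_straight


@pytest.fixture(scope="session")
def composite_chain() -> BeadChain:
    """N=400 chain with a trefoil near 0.3 and a figure-eight near 0.7."""
    return tie_knots_on_chain(400, [("3_1", 0.3), ("4_1", 0.7)], seed=1)


@pytest.fixture(scope="session")
def nested_chain() -> BeadChain:
    """Intertwined start: trefoil tied inside a large figure-eight arc."""
    return tie_knots_on_chain(500, [("3_1", 0.5, 50), ("4_1", 0.5, 120)],
                              seed=2)
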