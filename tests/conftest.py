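"""Shared fixtures: the two reference worked examples, built exactly.

All data is constructed programmatically from exact rationals; nothing is
read from disk.
"""

import pytest
import sympy as sp
from sympy import Rational as Q

from lvsoliton import MetaModelSystem, assemble_full


@pytest.fixture(scope="session")
def example2_system() -> MetaModelSystem:
    """The reference order-3 target system (construction example)."""
    return MetaModelSystem(
        a0=(Q(5, 3), Q(30, 7)),
        a1=(Q(-16, 9), Q(-172, 63)),
        a2=(Q(-68, 5), Q(68, 315)),
        lam=(Q(617, 135), Q(7, 180)),
        b0=(Q(153745, 31467), Q(-740, 153)),
        b1=(Q(-656207, 377604), Q(6317, 3213)),
        b2=(Q(617, 135), Q(7, 180)),
        mu=(Q(-68, 5), Q(68, 315)),
        gam=(Q(-243, 41956), Q(2468, 459)),
    )


@pytest.fixture(scope="session")
def example2_gauge() -> dict:
    return {"x1": 1, "y1": 3, "x2": 2, "y2": 4, "eta": 1}


@pytest.fixture(scope="session")
def example2_triple():
    """Forward-assembled triple matching the reference example-2 data."""
    free = {"A11": Q(4, 5), "A12": Q(2, 5), "h12": Q(-25), "h22": Q(5)}
    sigmas = {"x1": 1, "y1": 3, "x2": 2, "y2": 4}
    return assemble_full(3, free, aes=(1, 5, 15), sigmas=sigmas, eta=1, t0=5)


@pytest.fixture(scope="session")
def example1_free() -> dict:
    return {"A11": Q(4, 5), "A12": Q(2, 5),
            "h12": Q(139919, 7619), "h22": Q(39493, 15238)}


@pytest.fixture(scope="session")
def example1_sigmas() -> dict:
    return {"x1": Q(3, 5), "y1": Q(7834855, 274284),
            "x2": Q(7, 15), "y2": Q(685710, 223853)}


@pytest.fixture(scope="session")
def example1_triple_eta4(example1_free, example1_sigmas):
    """Example-1 triple at the stated rate eta = 4 (exponents 4t - 5)."""
    return assemble_full(3, example1_free, aes=(8, 14, 7), sigmas=example1_sigmas,
                         eta=4, t0=Q(5, 4))


@pytest.fixture(scope="session")
def example1_triple_eta1(example1_free, example1_sigmas):
    """Example-1 triple at eta = 1; its system matches the reference one."""
    return assemble_full(3, example1_free, aes=(8, 14, 7), sigmas=example1_sigmas,
                         eta=1, t0=5)


@pytest.fixture(scope="session")
def example1_reference_system() -> MetaModelSystem:
    """The system as reference alongside example 1 (eta = 1 scale)."""
    return MetaModelSystem(
        a0=(1, 1),
        a1=(Q(-4049, 4410), Q(-8249, 4410)),
        a2=(Q(-40, 3), Q(-30, 7)),
        lam=(Q(15238, 60025), Q(31979, 56700)),
        b0=(Q(219139741, 4937112), Q(56093641, 10968797)),
        b1=(Q(-5755739, 11199930), Q(-238135267, 141027390)),
        b2=(Q(15238, 60025), Q(31979, 56700)),
        mu=(Q(-40, 3), Q(-30, 7)),
        gam=(Q(223853, 685710), Q(274284, 7834855)),
    )


def scale_system(system: MetaModelSystem, factor) -> MetaModelSystem:
    """Multiply every coefficient of the system by an exact factor."""
    factor = sp.sympify(factor)
    return MetaModelSystem(**{
        name: tuple(factor * c for c in getattr(system, name))
        for name in ("a0", "a1", "a2", "lam", "b0", "b1", "b2", "mu", "gam")
    })
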