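import numpy as np
import pytest

from pvdarbor.io import ArborNode, ArborSkeleton


class TreeBuilder:
    """Hand-build small skeletons node by node for oracle tests."""

    def __init__(self):
        self.nodes = []
        self._next = 1

    def add(self, x, y, parent=None, code=3, z=0.0, radius=0.5):
        nid = self._next
        self._next += 1
        self.nodes.append(ArborNode(nid, code, float(x), float(y), float(z), radius, parent if parent is not None else -1))
        return nid

    def chain(self, points, parent):
        last = parent
        ids = []
        for (x, y) in points:
            last = self.add(x, y, parent=last)
            ids.append(last)
        return ids

    def build(self, soma_id, metadata=None):
        return ArborSkeleton(nodes=list(self.nodes), soma_id=soma_id, metadata=metadata or {})


@pytest.fixture
def tree_builder():
    return TreeBuilder


def make_primary(builder, x_min=-10, x_max=20):
    """Straight primary along x at integer spacing; returns (builder, soma_id, id_of_x)."""
    ids = {}
    soma_id = builder.add(0, 0, code=1)
    ids[0] = soma_id
    prev = soma_id
    for x in range(1, x_max + 1):
        prev = builder.add(x, 0, parent=prev)
        ids[x] = prev
    prev = soma_id
    for x in range(-1, x_min - 1, -1):
        prev = builder.add(x, 0, parent=prev)
        ids[x] = prev
    return soma_id, ids


@pytest.fixture
def toy_menorah():
    """One complete menorah: a 2° stem at x=3 bifurcating into two A-P 3°
    arms, each bearing two orthogonal 4° twigs (n2=1, n2_with3=1, n3=2, n4=4)."""
    b = TreeBuilder()
    soma_id, ids = make_primary(b, -10, 20)
    stem = b.chain([(3, 2), (3, 4), (3, 6)], ids[3])
    top = stem[-1]
    right = b.chain([(5, 6), (7, 6), (9, 6)], top)
    left = b.chain([(1, 6), (-1, 6), (-3, 6)], top)
    for arm_node in (right[0], right[1]):
        x = {right[0]: 5, right[1]: 7}[arm_node]
        b.chain([(x, 8), (x, 10)], arm_node)
    for arm_node, x in ((left[0], 1), (left[1], -1)):
        b.chain([(x, 8), (x, 10)], arm_node)
    return b.build(soma_id)


@pytest.fixture
def bare_primary():
    b = TreeBuilder()
    soma_id, _ = make_primary(b, -10, 20)
    return b.build(soma_id)


@pytest.fixture(scope="session")
def wt_profile():
    from pvdarbor.simulate import get_profile

    return get_profile("wild_type")


@pytest.fixture(scope="session")
def rab10_profile():
    from pvdarbor.simulate import get_profile

    return get_profile("wy787")


@pytest.fixture(scope="session")
def small_wt_cohort(wt_profile):
    """A reusable 20-animal wild-type cohort (default noise)."""
    from pvdarbor.simulate import simulate_cohort

    return simulate_cohort(wt_profile, 20, seed=11)
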