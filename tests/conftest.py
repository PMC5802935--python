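import pytest

from metaecoflux.core import Compartment, Flow, Orientation, Role, build_network
from metaecoflux.nhld import nhld_network


def ring_network(n: int, magnitude: float = 1.0):
    """Unidirectional ring: c0 -> c1 -> ... -> c(n-1) -> c0, equal flows."""
    comps = [Compartment(id=f"c{i}", role=Role.INTERNAL) for i in range(n)]
    flows = [
        Flow(
            source=f"c{i}",
            target=f"c{(i + 1) % n}",
            process="other",
            orientation=Orientation.LATERAL,
            best=magnitude,
        )
        for i in range(n)
    ]
    return build_network(comps, flows)


def uniform_network_with_self_loops(n: int, magnitude: float = 1.0):
    """Complete directed network including self-loops, all flows equal.

    Every transfer is equally likely regardless of origin, so the flow
    structure carries no information (AMI = 0).  Self-loops use the
    accumulation process, the storage term the model permits.
    """
    comps = [Compartment(id=f"c{i}", role=Role.INTERNAL) for i in range(n)]
    flows = []
    for i in range(n):
        for j in range(n):
            flows.append(
                Flow(
                    source=f"c{i}",
                    target=f"c{j}",
                    process="accumulation" if i == j else "other",
                    orientation=Orientation.INTERNAL
                    if i == j
                    else Orientation.LATERAL,
                    best=magnitude,
                )
            )
    return build_network(comps, flows)


@pytest.fixture
def nhld():
    return nhld_network()


@pytest.fixture
def ring4():
    return ring_network(4)
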