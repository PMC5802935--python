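"""Flux-network data model and per-compartment throughput/balance primitives.

A landscape carbon (or nutrient) budget is represented as a weighted directed
multigraph: *compartments* are ecosystems, exterior pools or storage nodes,
and *flows* are directed mass-transfer records between them.  Every other
stage of the protocol — significance filtering, landscape-system
classification, meta-ecosystem adjustment, ecological network analysis —
consumes and produces this structure.

All flows are stored as whole-system totals in Gg C yr⁻¹ (1 Gg = 10⁹ g).
Readers are responsible for converting areal/lineal intensities to totals
before constructing a network (see :mod:`metaecoflux.spatial`).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from enum import Enum
from typing import Iterable, Sequence

__all__ = [
    "Role",
    "Orientation",
    "Significance",
    "Compartment",
    "Flow",
    "FluxNetwork",
    "ValidationError",
    "UnknownCompartmentError",
    "ConfigurationError",
    "PROCESSES",
    "SELF_FLOW_PROCESSES",
    "CANONICAL_UNITS",
    "build_network",
    "compartment_throughput",
    "net_balance",
]

CANONICAL_UNITS = "Gg C yr-1"

#: Controlled process vocabulary.  ``other`` is the catch-all for synthetic
#: or non-carbon applications.
PROCESSES = frozenset(
    {
        "GPP",
        "respiration",
        "precipitation",
        "DIC_runoff",
        "DOC_runoff",
        "litter",
        "CH4",
        "CO2_evasion",
        "sediment",
        "accumulation",
        "runoff_export",
        "other",
    }
)

#: Processes allowed to run from a compartment to itself (storage terms).
SELF_FLOW_PROCESSES = frozenset({"accumulation", "sediment"})


class ValidationError(ValueError):
    """A network or record violates a structural invariant."""


class UnknownCompartmentError(KeyError):
    """A compartment id was looked up that is not in the network."""


class ConfigurationError(ValueError):
    """A configuration object is incomplete or inconsistent."""


class Role(str, Enum):
    INTERNAL = "internal_ecosystem"
    EXTERIOR = "exterior"
    STORAGE = "storage"


class Orientation(str, Enum):
    LATERAL = "lateral"
    VERTICAL = "vertical"
    INTERNAL = "internal"


class Significance(str, Enum):
    UNSET = "unset"
    SIGNIFICANT = "significant"
    INSIGNIFICANT = "insignificant"


@dataclass(frozen=True)
class Compartment:
    """A named node: an internal ecosystem, an exterior pool, or a storage node.

    Parameters
    ----------
    id:
        Short unique token, e.g. ``"forest"``.
    name:
        Free-text label.
    role:
        Whether the node is an internal ecosystem, an exterior
        (inexhaustible) pool such as the atmosphere, or a storage aspect.
    area:
        Optional surface area in m²; must be positive when given.
    stock:
        Optional standing stock in Gg C.
    """

    id: str
    name: str = ""
    role: Role = Role.INTERNAL
    area: float | None = None
    stock: float | None = None

    def __post_init__(self) -> None:
        if not self.id:
            raise ValidationError("compartment id must be a non-empty token")
        if self.area is not None and not self.area > 0:
            raise ValidationError(
                f"compartment {self.id!r}: area must be > 0, got {self.area}"
            )


@dataclass(frozen=True)
class Flow:
    """A directed flux record between two compartments.

    ``best`` is the best-estimate magnitude in Gg C yr⁻¹; ``low``/``high``
    are optional range bounds (``low`` may be negative).  ``best`` may be
    negative only for ``accumulation`` — a pool drawing down its store.
    """

    source: str
    target: str
    process: str = "other"
    orientation: Orientation = Orientation.LATERAL
    best: float = 0.0
    low: float | None = None
    high: float | None = None
    significance: Significance = Significance.UNSET

    def __post_init__(self) -> None:
        if self.process not in PROCESSES:
            raise ValidationError(
                f"flow {self.source}->{self.target}: unknown process {self.process!r}"
            )
        if not math.isfinite(self.best):
            raise ValidationError(
                f"flow {self.source}->{self.target} ({self.process}): "
                f"best magnitude must be finite, got {self.best}"
            )
        if self.best < 0 and self.process != "accumulation":
            raise ValidationError(
                f"flow {self.source}->{self.target} ({self.process}): negative "
                "magnitude is only allowed for process 'accumulation'"
            )
        if self.low is not None and self.high is not None:
            if not (self.low <= self.best <= self.high):
                raise ValidationError(
                    f"flow {self.source}->{self.target} ({self.process}): "
                    f"range must bracket best, got low={self.low} "
                    f"best={self.best} high={self.high}"
                )
        if self.source == self.target and self.process not in SELF_FLOW_PROCESSES:
            raise ValidationError(
                f"flow {self.source}->{self.target}: self-flows are only "
                f"allowed for processes {sorted(SELF_FLOW_PROCESSES)}"
            )

    @property
    def key(self) -> tuple[str, str, str]:
        return (self.source, self.target, self.process)

    @property
    def is_self_flow(self) -> bool:
        return self.source == self.target


@dataclass(frozen=True)
class FluxNetwork:
    """The full weighted directed multigraph plus units metadata."""

    compartments: tuple[Compartment, ...]
    flows: tuple[Flow, ...]
    units: str = CANONICAL_UNITS
    provenance: str = ""

    def compartment(self, id: str) -> Compartment:
        for c in self.compartments:
            if c.id == id:
                return c
        raise UnknownCompartmentError(id)

    @property
    def compartment_ids(self) -> tuple[str, ...]:
        return tuple(c.id for c in self.compartments)

    def internal_ids(self) -> tuple[str, ...]:
        return tuple(c.id for c in self.compartments if c.role is Role.INTERNAL)

    def flows_touching(self, id: str) -> tuple[Flow, ...]:
        return tuple(f for f in self.flows if id in (f.source, f.target))

    def with_flows(self, flows: Iterable[Flow]) -> "FluxNetwork":
        return replace(self, flows=tuple(flows))

    def to_networkx(self):
        """Export as a :class:`networkx.MultiDiGraph` (weights on edges)."""
        import networkx as nx

        g = nx.MultiDiGraph(units=self.units)
        for c in self.compartments:
            g.add_node(c.id, role=c.role.value, area=c.area, stock=c.stock)
        for f in self.flows:
            g.add_edge(
                f.source,
                f.target,
                key=f.process,
                weight=f.best,
                orientation=f.orientation.value,
                significance=f.significance.value,
            )
        return g


def build_network(
    compartments: Sequence[Compartment],
    flows: Sequence[Flow],
    units: str = CANONICAL_UNITS,
    provenance: str = "",
) -> FluxNetwork:
    """Validate and assemble a :class:`FluxNetwork`.

    Rejects duplicate compartment ids, duplicate ``(source, target,
    process)`` triples, and flows whose endpoints name no declared
    compartment.
    """
    ids = [c.id for c in compartments]
    seen: set[str] = set()
    for cid in ids:
        if cid in seen:
            raise ValidationError(f"duplicate compartment id {cid!r}")
        seen.add(cid)

    keys: set[tuple[str, str, str]] = set()
    for f in flows:
        for endpoint in (f.source, f.target):
            if endpoint not in seen:
                raise ValidationError(
                    f"flow {f.source}->{f.target} ({f.process}) names "
                    f"undeclared compartment {endpoint!r}"
                )
        if f.key in keys:
            raise ValidationError(
                f"duplicate flow record for (source={f.source!r}, "
                f"target={f.target!r}, process={f.process!r})"
            )
        keys.add(f.key)

    return FluxNetwork(
        compartments=tuple(compartments),
        flows=tuple(flows),
        units=units,
        provenance=provenance,
    )


def compartment_throughput(
    network: FluxNetwork, id: str, include_self_flows: bool = False
) -> float:
    """Total flux through one compartment, in Gg C yr⁻¹.

    The sum of ``|best|`` over every flow entering or leaving the
    compartment.  Storage self-flows (accumulation, sediment) are excluded
    by default: they describe what the compartment retains, not what moves
    through its boundary.
    """
    network.compartment(id)  # raises UnknownCompartmentError
    total = 0.0
    for f in network.flows_touching(id):
        if f.is_self_flow and not include_self_flows:
            continue
        total += abs(f.best)
    return total


def net_balance(network: FluxNetwork, id: str) -> float:
    """Inflow minus outflow for one compartment (self-flows excluded).

    The empirical analogue of a compartment's local growth rate: what the
    boundary fluxes leave behind, in Gg C yr⁻¹.
    """
    network.compartment(id)
    total = 0.0
    for f in network.flows:
        if f.is_self_flow:
            continue
        if f.target == id:
            total += f.best
        if f.source == id:
            total -= f.best
    return total
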