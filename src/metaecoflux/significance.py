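"""Significance filtering and landscape-system classification.

A flux crossing an ecosystem boundary is treated as *insignificant* when it
is two orders of magnitude smaller than the activity of every internal
ecosystem it touches — operationally, smaller than ``ratio`` (default 1%)
of the compartment throughput of each internal endpoint.  A flow is
therefore **significant iff it reaches the threshold of at least one of its
internal endpoints**: a small ecosystem can depend on a flux that a large
neighbour would not notice.

Once flagged, the network is classified:

* **systemic** — internal ecosystems are significantly interconnected and
  no significant flux crosses the system boundary (closed circulation);
* **fragmental** — internal ecosystems are significantly interconnected but
  significant fluxes cross the boundary (the delineation misses part of the
  connected whole);
* **laterally discrete** — internal ecosystems share no significant lateral
  flows, but vertical connections exist;
* **omnidirectionally discrete** — a collection of relatively isolated
  ecosystems: no significant inter-ecosystem flows in any orientation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from enum import Enum

from .core import (
    FluxNetwork,
    Orientation,
    Role,
    Significance,
    ValidationError,
    compartment_throughput,
)

__all__ = [
    "SignificanceConfig",
    "LandscapeClass",
    "flag_significance",
    "classify_landscape_system",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class SignificanceConfig:
    """Threshold for the two-orders-of-magnitude rule.

    ``ratio`` is the fraction of an internal ecosystem's throughput below
    which a boundary-crossing flux is considered negligible.  The
    comparison basis is fixed: per-ecosystem throughput on the unfiltered
    network, self-flows excluded.
    """

    ratio: float = 0.01

    def __post_init__(self) -> None:
        if not (0.0 < self.ratio < 1.0):
            raise ValidationError(f"ratio must lie in (0, 1), got {self.ratio}")


class LandscapeClass(str, Enum):
    SYSTEMIC = "systemic"
    FRAGMENTAL = "fragmental"
    OMNIDIRECTIONALLY_DISCRETE = "omnidirectionally_discrete"
    LATERALLY_DISCRETE = "laterally_discrete"


def flag_significance(
    network: FluxNetwork, config: SignificanceConfig | None = None
) -> FluxNetwork:
    """Return a copy of the network with every flow flagged.

    A non-self flow is significant iff ``|best| >= ratio * throughput(e)``
    for at least one internal-ecosystem endpoint ``e``.  Thresholds are
    computed once, on the unfiltered network, so flagging is idempotent and
    order-independent.  Self-flows (storage terms) are always significant.
    """
    config = config or SignificanceConfig()
    internal = set(network.internal_ids())
    if not internal:
        raise ValidationError("network has no internal ecosystems to flag against")

    throughput = {
        cid: compartment_throughput(network, cid, include_self_flows=False)
        for cid in internal
    }
    if all(t == 0.0 for t in throughput.values()):
        logger.warning(
            "all internal throughputs are zero; flagging every non-self flow "
            "insignificant"
        )

    flagged = []
    for f in network.flows:
        if f.is_self_flow:
            flagged.append(replace(f, significance=Significance.SIGNIFICANT))
            continue
        endpoints = {f.source, f.target} & internal
        significant = any(
            throughput[e] > 0 and abs(f.best) >= config.ratio * throughput[e]
            for e in endpoints
        )
        flagged.append(
            replace(
                f,
                significance=Significance.SIGNIFICANT
                if significant
                else Significance.INSIGNIFICANT,
            )
        )
    return network.with_flows(flagged)


def classify_landscape_system(network: FluxNetwork) -> LandscapeClass:
    """Classify a flagged network into one of the four landscape classes."""
    if any(f.significance is Significance.UNSET for f in network.flows):
        raise ValidationError(
            "network carries unflagged flows; run flag_significance first"
        )
    internal = set(network.internal_ids())

    sig = [f for f in network.flows if f.significance is Significance.SIGNIFICANT]

    def crosses_boundary(f):
        # an endpoint outside the internal ecosystem set, self-flows aside
        if f.is_self_flow:
            return False
        return f.source not in internal or f.target not in internal

    def interconnects(f):
        return (
            f.source in internal and f.target in internal and f.source != f.target
        )

    interconnected = any(interconnects(f) for f in sig)
    boundary = any(crosses_boundary(f) for f in sig)

    if interconnected:
        return (
            LandscapeClass.FRAGMENTAL if boundary else LandscapeClass.SYSTEMIC
        )

    # no significant inter-ecosystem links: discrete.  Vertical connections
    # (through the shared atmosphere, or between stacked compartments) make
    # the isolation lateral-only.
    vertical = any(
        f.orientation is Orientation.VERTICAL
        and not f.is_self_flow
        and (f.source in internal or f.target in internal)
        for f in sig
    )
    if vertical:
        return LandscapeClass.LATERALLY_DISCRETE
    return LandscapeClass.OMNIDIRECTIONALLY_DISCRETE
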