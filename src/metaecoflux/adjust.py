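"""Adjusting a fragmental landscape system into a (quasi-)closed meta-ecosystem.

A fragmental system leaks: significant fluxes cross its boundary.  It can be
approximated as a closed meta-ecosystem by re-pointing every
boundary-crossing flux at a small set of *exterior inexhaustible
compartments* (typically the atmosphere for vertical exchange and a
downstream pool for lateral export), dropping fluxes flagged insignificant,
and normalising the storage terms.

Sign conventions for a **negative accumulation** (a pool drawing down its
store) are genuinely open and are kept configurable:

* ``release_inflow`` — the drawdown becomes a flow of ``+m`` into the
  compartment from a dedicated storage node (the store subsidises the
  network);
* ``signed_self_loop`` — kept as a signed self-loop (downstream analyses
  take magnitudes);
* ``exclude`` — the term is omitted from the flow network entirely.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

from .core import (
    CANONICAL_UNITS,
    Compartment,
    ConfigurationError,
    Flow,
    FluxNetwork,
    Orientation,
    Role,
    Significance,
    build_network,
    net_balance,
)

__all__ = ["ExteriorSpec", "to_meta_ecosystem", "source_sink_residual"]

NEGATIVE_ACCUMULATION_POLICIES = ("release_inflow", "signed_self_loop", "exclude")


@dataclass(frozen=True)
class ExteriorSpec:
    """How boundary-crossing flows map onto exterior compartments.

    ``orientation_map`` sends each flow orientation to an exterior
    compartment id; ``process_map`` overrides per process (checked first).
    Exterior compartments are inexhaustible: no stock is tracked and no
    balance is required of them.
    """

    orientation_map: dict[str, str] = field(
        default_factory=lambda: {"vertical": "atmosphere", "lateral": "downstream"}
    )
    process_map: dict[str, str] = field(default_factory=dict)
    drop_insignificant: bool = True
    negative_accumulation_policy: str = "release_inflow"
    self_loops_in_tst: bool = True

    def __post_init__(self) -> None:
        if self.negative_accumulation_policy not in NEGATIVE_ACCUMULATION_POLICIES:
            raise ConfigurationError(
                f"unknown negative_accumulation_policy "
                f"{self.negative_accumulation_policy!r}; expected one of "
                f"{NEGATIVE_ACCUMULATION_POLICIES}"
            )

    def exterior_for(self, flow: Flow) -> str | None:
        if flow.process in self.process_map:
            return self.process_map[flow.process]
        return self.orientation_map.get(flow.orientation.value)


def to_meta_ecosystem(network: FluxNetwork, spec: ExteriorSpec | None = None) -> FluxNetwork:
    """Close a flagged network into a meta-ecosystem.

    Every flow with an endpoint outside the internal-ecosystem set is
    re-pointed at the exterior compartment the spec maps its
    orientation/process to; insignificant flows are dropped when
    ``spec.drop_insignificant``; accumulation terms are normalised per the
    negative-accumulation policy.  The result has no dangling endpoints.
    Re-adjusting an adjusted network is a no-op.
    """
    spec = spec or ExteriorSpec()
    if any(f.significance is Significance.UNSET for f in network.flows):
        raise ConfigurationError(
            "network carries unflagged flows; run flag_significance before "
            "adjustment"
        )
    roles = {c.id: c.role for c in network.compartments}

    uncovered: list[Flow] = []
    out_flows: list[Flow] = []
    exterior_ids: set[str] = set()
    storage_ids: set[str] = set()

    for f in network.flows:
        if spec.drop_insignificant and f.significance is Significance.INSIGNIFICANT:
            continue

        if f.is_self_flow:
            if f.best >= 0:
                out_flows.append(f)
                continue
            policy = spec.negative_accumulation_policy
            if policy == "exclude":
                continue
            if policy == "signed_self_loop":
                out_flows.append(f)
                continue
            # release_inflow: the store feeds the compartment
            store = f"{f.source}_storage"
            storage_ids.add(store)
            out_flows.append(
                Flow(
                    source=store,
                    target=f.target,
                    process=f.process,
                    orientation=Orientation.INTERNAL,
                    best=abs(f.best),
                    significance=Significance.SIGNIFICANT,
                )
            )
            continue

        # storage nodes are members of the closed system; only exterior
        # (or exterior-bound) endpoints get re-pointed
        src_out = roles[f.source] is Role.EXTERIOR
        tgt_out = roles[f.target] is Role.EXTERIOR
        if not (src_out or tgt_out):
            out_flows.append(f)
            continue

        ext = spec.exterior_for(f)
        if ext is None:
            uncovered.append(f)
            continue
        exterior_ids.add(ext)
        new_src = ext if src_out else f.source
        new_tgt = ext if tgt_out else f.target
        out_flows.append(replace(f, source=new_src, target=new_tgt))

    if uncovered:
        listing = ", ".join(
            f"{f.source}->{f.target} ({f.process}, {f.orientation.value})"
            for f in uncovered
        )
        raise ConfigurationError(
            f"exterior spec covers no orientation/process for: {listing}"
        )

    comps: list[Compartment] = [
        c for c in network.compartments if c.role is Role.INTERNAL
    ]
    # keep pre-existing exterior/storage compartments that still carry flows
    used = {e for f in out_flows for e in (f.source, f.target)}
    comps += [
        c
        for c in network.compartments
        if c.role is not Role.INTERNAL and c.id in used
    ]
    have = {c.id for c in comps}
    comps += [
        Compartment(id=e, name=e, role=Role.EXTERIOR)
        for e in sorted(exterior_ids)
        if e not in have
    ]
    comps += [
        Compartment(id=s, name=s, role=Role.STORAGE)
        for s in sorted(storage_ids)
        if s not in have
    ]

    return build_network(
        comps,
        out_flows,
        units=network.units,
        provenance=(network.provenance + " | adjusted to meta-ecosystem").strip(" |"),
    )


def source_sink_residual(network: FluxNetwork) -> float:
    """How far the closed system is from mass conservation, in Gg C yr⁻¹.

    The sum of net boundary balances over internal compartments.  For a
    perfectly balanced network this is zero; for a system storing carbon it
    equals the total accumulation retained by the internal compartments.
    """
    return sum(net_balance(network, cid) for cid in network.internal_ids())
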