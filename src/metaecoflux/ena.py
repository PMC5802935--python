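"""Ecological network analysis: the whole-system information indices.

For a flow matrix ``T_ij`` (mass from compartment *i* to compartment *j*),
with ``T = ΣΣ T_ij`` the total system throughput, ``T_i. = Σ_j T_ij`` the
out-throughflow of *i* and ``T_.j = Σ_i T_ij`` the in-throughflow of *j*:

* ``TST = T`` — system size / overall activity;
* ``AMI = k Σ (T_ij/T) log(T_ij T / (T_i. T_.j))`` — average mutual
  information of the flow structure: how constrained (organised) transfers
  are, in bits for log base 2 and k = 1;
* ``A = TST × AMI`` — ascendency, activity and organisation jointly;
* ``C`` — development capacity, an upper bound on A.  Two forms are
  provided (see :func:`capacity`): the flow-diversity form
  ``−Σ T_ij log(T_ij/T)`` (the standard in the ENA literature) and the
  throughflow-diversity form ``−Σ_i T_i. log(T_i./T)``, the Shannon
  diversity of compartment out-throughflows scaled by TST.  Both bound A
  from above, since mutual information never exceeds either the joint or
  the marginal entropy;
* ``R = C − A`` — redundancy / resilience: parallel, unorganised pathway
  capacity.

Multiple flow records between the same ordered pair (e.g. DIC, DOC and
litter all moving forest → surface waters) are aggregated into a single
matrix cell before any index is computed.  The convention ``0·log 0 = 0``
applies throughout; magnitudes are used, so a signed self-loop contributes
its absolute value.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping

from .core import FluxNetwork, ValidationError

__all__ = [
    "ENAReport",
    "CAPACITY_FORMS",
    "pair_flows",
    "tst",
    "ami",
    "ascendency",
    "capacity",
    "redundancy",
    "report",
]

CAPACITY_FORMS = ("flow", "throughflow")


def pair_flows(
    network: FluxNetwork, include_self_loops: bool = True
) -> dict[tuple[str, str], float]:
    """Aggregate flow magnitudes into matrix cells keyed by (source, target)."""
    cells: dict[tuple[str, str], float] = {}
    for f in network.flows:
        if f.is_self_flow and not include_self_loops:
            continue
        key = (f.source, f.target)
        cells[key] = cells.get(key, 0.0) + abs(f.best)
    return {k: v for k, v in cells.items() if v > 0.0}


def _marginals(cells: Mapping[tuple[str, str], float]):
    total = sum(cells.values())
    out: dict[str, float] = {}
    inn: dict[str, float] = {}
    for (i, j), v in cells.items():
        out[i] = out.get(i, 0.0) + v
        inn[j] = inn.get(j, 0.0) + v
    return total, out, inn


def _require_flow(total: float) -> None:
    if total <= 0.0:
        raise ValidationError("network carries no flow; indices are undefined")


def tst(network: FluxNetwork, include_self_loops: bool = True) -> float:
    """Total system throughput: the sum of all flow magnitudes."""
    return sum(pair_flows(network, include_self_loops).values())


def ami(
    network: FluxNetwork,
    log_base: float = 2.0,
    k: float = 1.0,
    include_self_loops: bool = True,
) -> float:
    """Average mutual information of the flow structure (bits for base 2)."""
    cells = pair_flows(network, include_self_loops)
    total, out, inn = _marginals(cells)
    _require_flow(total)
    lb = math.log(log_base)
    acc = 0.0
    for (i, j), v in cells.items():
        acc += (v / total) * math.log(v * total / (out[i] * inn[j])) / lb
    return k * acc


def ascendency(
    network: FluxNetwork, log_base: float = 2.0, include_self_loops: bool = True
) -> float:
    """Ascendency ``A = TST × AMI`` in Gg C bits yr⁻¹ (for base 2)."""
    cells = pair_flows(network, include_self_loops)
    total, out, inn = _marginals(cells)
    _require_flow(total)
    lb = math.log(log_base)
    return sum(
        v * math.log(v * total / (out[i] * inn[j])) / lb
        for (i, j), v in cells.items()
    )


def capacity(
    network: FluxNetwork,
    log_base: float = 2.0,
    form: str = "flow",
    include_self_loops: bool = True,
) -> float:
    """Development capacity, the upper bound on ascendency.

    ``form="flow"`` (default) is the flow-diversity form
    ``−Σ T_ij log(T_ij/T)`` standard in the ENA literature.
    ``form="throughflow"`` is ``−Σ_i T_i. log(T_i./T)``, the entropy of the
    compartment out-throughflow distribution scaled by TST; it is the
    tighter bound ``A ≤ TST·H(source marginal)`` and is the form consistent
    with the published NHLD case-study values (see docs/methods.md).
    """
    if form not in CAPACITY_FORMS:
        raise ValidationError(
            f"unknown capacity form {form!r}; expected one of {CAPACITY_FORMS}"
        )
    cells = pair_flows(network, include_self_loops)
    total, out, _ = _marginals(cells)
    _require_flow(total)
    lb = math.log(log_base)
    if form == "flow":
        return -sum(v * math.log(v / total) / lb for v in cells.values())
    return -sum(v * math.log(v / total) / lb for v in out.values() if v > 0.0)


def redundancy(
    network: FluxNetwork,
    log_base: float = 2.0,
    form: str = "flow",
    include_self_loops: bool = True,
) -> float:
    """Redundancy / resilience ``R = C − A`` (≥ 0 for both capacity forms)."""
    return capacity(network, log_base, form, include_self_loops) - ascendency(
        network, log_base, include_self_loops
    )


@dataclass(frozen=True)
class ENAReport:
    """The five holistic indices plus derived ratios.

    ``ascendency_ratio = A/C`` and ``resilience_ratio = R/C`` sum to one;
    ``activity_ratio = TST / total_stock`` (dimensionless, yr⁻¹ in spirit)
    is present only when a stock was supplied.
    """

    tst: float
    ami: float
    ascendency: float
    capacity: float
    redundancy: float
    ascendency_ratio: float
    resilience_ratio: float
    n_compartments: int
    n_flows: int
    capacity_form: str = "flow"
    activity_ratio: float | None = None

    def as_dict(self) -> dict:
        d = {
            "tst": self.tst,
            "ami": self.ami,
            "ascendency": self.ascendency,
            "capacity": self.capacity,
            "redundancy": self.redundancy,
            "ascendency_ratio": self.ascendency_ratio,
            "resilience_ratio": self.resilience_ratio,
            "n_compartments": self.n_compartments,
            "n_flows": self.n_flows,
            "capacity_form": self.capacity_form,
        }
        if self.activity_ratio is not None:
            d["activity_ratio"] = self.activity_ratio
        return d

    def __str__(self) -> str:  # presentation: indices to 2 dp, AMI to 6 dp
        lines = [
            f"TST        {self.tst:12.2f} Gg C yr-1",
            f"AMI        {self.ami:12.6f} bits",
            f"A          {self.ascendency:12.2f} Gg C bits yr-1",
            f"C ({self.capacity_form}) {self.capacity:12.2f} Gg C bits yr-1",
            f"R          {self.redundancy:12.2f} Gg C bits yr-1",
            f"A/C        {100 * self.ascendency_ratio:11.2f} %",
            f"R/C        {100 * self.resilience_ratio:11.2f} %",
        ]
        if self.activity_ratio is not None:
            lines.append(f"TST/stock  {100 * self.activity_ratio:11.2f} %")
        lines.append(
            f"({self.n_compartments} compartments, {self.n_flows} flow records)"
        )
        return "\n".join(lines)


def report(
    network: FluxNetwork,
    total_stock: float | None = None,
    log_base: float = 2.0,
    capacity_form: str = "flow",
    include_self_loops: bool = True,
) -> ENAReport:
    """Compute all indices on an adjusted (closed) network."""
    t = tst(network, include_self_loops)
    a_mi = ami(network, log_base, 1.0, include_self_loops)
    a = ascendency(network, log_base, include_self_loops)
    c = capacity(network, log_base, capacity_form, include_self_loops)
    r = c - a
    return ENAReport(
        tst=t,
        ami=a_mi,
        ascendency=a,
        capacity=c,
        redundancy=r,
        ascendency_ratio=a / c if c > 0 else 0.0,
        resilience_ratio=r / c if c > 0 else 0.0,
        n_compartments=len(network.compartments),
        n_flows=len(network.flows),
        capacity_form=capacity_form,
        activity_ratio=(t / total_stock) if total_stock else None,
    )
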