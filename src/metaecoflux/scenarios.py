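"""Scenario substitution and cross-scenario comparison of ENA reports.

A scenario is an explicit map from ``(source, target, process)`` keys to
replacement best-estimate magnitudes — e.g. shifting a handful of fluxes to
their range endpoints, or a user-supplied "relatively active" flux set.
Application is pure: the base network is never mutated.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import pandas as pd

from .core import FluxNetwork, ValidationError
from .ena import report

__all__ = ["Scenario", "apply_scenario", "compare_scenarios", "read_scenario_file"]


@dataclass(frozen=True)
class Scenario:
    name: str
    substitutions: dict[tuple[str, str, str], float] = field(default_factory=dict)


def apply_scenario(network: FluxNetwork, scenario: Scenario) -> FluxNetwork:
    """Return a copy of the network with substituted magnitudes."""
    keys = {f.key for f in network.flows}
    unknown = sorted(set(scenario.substitutions) - keys)
    if unknown:
        raise ValidationError(
            f"scenario {scenario.name!r} substitutes flows absent from the "
            f"base network: {unknown}"
        )
    flows = [
        replace(f, best=scenario.substitutions[f.key], low=None, high=None)
        if f.key in scenario.substitutions
        else f
        for f in network.flows
    ]
    return network.with_flows(flows)


def compare_scenarios(
    base: FluxNetwork,
    scenarios: Sequence[Scenario],
    total_stock: float | None = None,
    log_base: float = 2.0,
    capacity_form: str = "flow",
    include_self_loops: bool = True,
) -> pd.DataFrame:
    """One ENA-report row per scenario plus the base, with per-index deltas.

    Rows are ordered base first, then scenarios as given; delta columns are
    each index minus the base value.
    """
    rows = []
    names = ["base"] + [s.name for s in scenarios]
    nets = [base] + [apply_scenario(base, s) for s in scenarios]
    for name, net in zip(names, nets):
        r = report(
            net,
            total_stock=total_stock,
            log_base=log_base,
            capacity_form=capacity_form,
            include_self_loops=include_self_loops,
        )
        rows.append(
            {
                "scenario": name,
                "tst": r.tst,
                "ami": r.ami,
                "ascendency": r.ascendency,
                "capacity": r.capacity,
                "redundancy": r.redundancy,
            }
        )
    df = pd.DataFrame(rows).set_index("scenario")
    for col in ("tst", "ami", "ascendency", "capacity", "redundancy"):
        df[f"d_{col}"] = df[col] - df[col].iloc[0]
    return df


def read_scenario_file(path, name: str | None = None) -> Scenario:
    """Parse the one-substitution-per-line format ``source,target,process,value``."""
    subs: dict[tuple[str, str, str], float] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = [p.strip() for p in line.split(",")]
            if len(parts) != 4:
                raise ValidationError(
                    f"{path}:{lineno}: expected 'source,target,process,value'"
                )
            try:
                value = float(parts[3])
            except ValueError:
                raise ValidationError(
                    f"{path}:{lineno}: non-numeric value {parts[3]!r}"
                ) from None
            subs[(parts[0], parts[1], parts[2])] = value
    return Scenario(name=name or str(path), substitutions=subs)
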