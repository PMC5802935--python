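"""Reading and writing flux tables and network documents.

The canonical exchange format is a flows CSV with columns ``source, target,
process, orientation, best, low, high, units`` (plus an optional
``significance`` column, preserved on round-trip).  A JSON document format
carries full fidelity — compartment roles, areas, stocks, units and
provenance.  A square flow-matrix layout (matrix plus import/export
vectors, the arrangement classic network-ecology software expects) is
provided as an export-only convenience.

Units: totals are stored in Gg C yr⁻¹; a table in g C yr⁻¹ is converted on
read (1 Gg = 10⁹ g).  Mixed units within one file are rejected.
"""

from __future__ import annotations

import csv
import json
from pathlib import Path

import pandas as pd

from .core import (
    CANONICAL_UNITS,
    Compartment,
    Flow,
    FluxNetwork,
    Orientation,
    Role,
    Significance,
    ValidationError,
    build_network,
)
from .spatial import IntensitySet

__all__ = [
    "DEFAULT_EXTERIOR_IDS",
    "read_flow_table",
    "write_network",
    "read_network_json",
    "write_ena_matrix",
    "read_intensity_table",
]

#: endpoint ids treated as exterior pools when inferring compartments
DEFAULT_EXTERIOR_IDS = frozenset(
    {"External", "external", "atmosphere", "downstream"}
)

_UNIT_SCALE = {CANONICAL_UNITS: 1.0, "Gg C yr⁻¹": 1.0, "g C yr-1": 1e-9}

_FLOW_COLUMNS = (
    "source",
    "target",
    "process",
    "orientation",
    "best",
    "low",
    "high",
    "units",
    "significance",
)


def _parse_optional(value: str) -> float | None:
    return None if value in ("", None) else float(value)


def read_flow_table(
    path,
    exterior_ids=DEFAULT_EXTERIOR_IDS,
    default_orientation: Orientation = Orientation.LATERAL,
    provenance: str = "",
) -> FluxNetwork:
    """Read a flows CSV into a validated network.

    Compartments are inferred from flow endpoints: ids in ``exterior_ids``
    become exterior pools, ids ending in ``_storage`` become storage nodes,
    everything else an internal ecosystem.
    """
    path = Path(path)
    flows: list[Flow] = []
    units_seen: set[str] = set()
    with path.open(newline="") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None or "source" not in reader.fieldnames:
            raise ValidationError(f"{path}: missing header with 'source' column")
        for lineno, row in enumerate(reader, start=2):
            try:
                unit = (row.get("units") or CANONICAL_UNITS).strip()
                units_seen.add(unit)
                orient = row.get("orientation") or default_orientation.value
                sig = row.get("significance") or Significance.UNSET.value
                flows.append(
                    Flow(
                        source=row["source"].strip(),
                        target=row["target"].strip(),
                        process=(row.get("process") or "other").strip(),
                        orientation=Orientation(orient.strip()),
                        best=float(row["best"]),
                        low=_parse_optional(row.get("low")),
                        high=_parse_optional(row.get("high")),
                        significance=Significance(sig.strip()),
                    )
                )
            except (KeyError, ValueError) as exc:
                if isinstance(exc, ValidationError):
                    raise ValidationError(f"{path}:{lineno}: {exc}") from None
                raise ValidationError(
                    f"{path}:{lineno}: malformed row ({exc})"
                ) from None
    if len(units_seen) > 1:
        raise ValidationError(
            f"{path}: mixed units {sorted(units_seen)}; one unit per file"
        )
    if units_seen:
        unit = units_seen.pop()
        if unit not in _UNIT_SCALE:
            raise ValidationError(f"{path}: unsupported units {unit!r}")
        scale = _UNIT_SCALE[unit]
        if scale != 1.0:
            flows = [
                Flow(
                    source=f.source,
                    target=f.target,
                    process=f.process,
                    orientation=f.orientation,
                    best=f.best * scale,
                    low=None if f.low is None else f.low * scale,
                    high=None if f.high is None else f.high * scale,
                    significance=f.significance,
                )
                for f in flows
            ]

    ids: list[str] = []
    for f in flows:
        for e in (f.source, f.target):
            if e not in ids:
                ids.append(e)
    comps = []
    for cid in ids:
        if cid in exterior_ids:
            role = Role.EXTERIOR
        elif cid.endswith("_storage"):
            role = Role.STORAGE
        else:
            role = Role.INTERNAL
        comps.append(Compartment(id=cid, name=cid, role=role))
    return build_network(comps, flows, provenance=provenance or str(path))


def _fmt_optional(value: float | None) -> str:
    return "" if value is None else repr(value)


def write_network(network: FluxNetwork, path, format: str = "csv") -> None:
    """Serialise a network; ``read(write(x))`` round-trips.

    CSV keeps the flow table only (compartments re-inferred on read); JSON
    keeps compartment roles, areas, stocks and provenance too.
    """
    path = Path(path)
    if format == "csv":
        with path.open("w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(_FLOW_COLUMNS)
            for f in network.flows:
                writer.writerow(
                    [
                        f.source,
                        f.target,
                        f.process,
                        f.orientation.value,
                        repr(f.best),
                        _fmt_optional(f.low),
                        _fmt_optional(f.high),
                        network.units,
                        f.significance.value,
                    ]
                )
    elif format == "json":
        doc = {
            "units": network.units,
            "provenance": network.provenance,
            "compartments": [
                {
                    "id": c.id,
                    "name": c.name,
                    "role": c.role.value,
                    "area": c.area,
                    "stock": c.stock,
                }
                for c in network.compartments
            ],
            "flows": [
                {
                    "source": f.source,
                    "target": f.target,
                    "process": f.process,
                    "orientation": f.orientation.value,
                    "best": f.best,
                    "low": f.low,
                    "high": f.high,
                    "significance": f.significance.value,
                }
                for f in network.flows
            ],
        }
        path.write_text(json.dumps(doc, indent=1))
    else:
        raise ValidationError(f"unknown format {format!r}; expected csv or json")


def read_network_json(path) -> FluxNetwork:
    doc = json.loads(Path(path).read_text())
    comps = [
        Compartment(
            id=c["id"],
            name=c.get("name", c["id"]),
            role=Role(c.get("role", Role.INTERNAL.value)),
            area=c.get("area"),
            stock=c.get("stock"),
        )
        for c in doc["compartments"]
    ]
    flows = [
        Flow(
            source=f["source"],
            target=f["target"],
            process=f.get("process", "other"),
            orientation=Orientation(f.get("orientation", "lateral")),
            best=f["best"],
            low=f.get("low"),
            high=f.get("high"),
            significance=Significance(f.get("significance", "unset")),
        )
        for f in doc["flows"]
    ]
    return build_network(
        comps, flows, units=doc.get("units", CANONICAL_UNITS),
        provenance=doc.get("provenance", ""),
    )


def write_ena_matrix(network: FluxNetwork, path) -> pd.DataFrame:
    """Export the aggregated square flow matrix (export-only convenience).

    Rows are sources, columns targets, cells the summed magnitudes —
    the layout classic flow-network software ingests.  Returns the frame
    written.
    """
    from .ena import pair_flows

    ids = list(network.compartment_ids)
    cells = pair_flows(network, include_self_loops=True)
    mat = pd.DataFrame(0.0, index=ids, columns=ids)
    for (i, j), v in cells.items():
        mat.loc[i, j] = v
    mat.to_csv(path)
    return mat


def read_intensity_table(path) -> IntensitySet:
    """Read intensities CSV: columns compartment, process, basis, value, units.

    ``basis`` is ``areal`` (g C m⁻² yr⁻¹), ``lineal`` (g C m⁻¹ yr⁻¹),
    ``area`` (m²) or ``length`` (m).
    """
    df = pd.read_csv(path, comment="#")
    required = {"compartment", "process", "basis", "value"}
    missing = required - set(df.columns)
    if missing:
        raise ValidationError(f"{path}: missing columns {sorted(missing)}")
    areal: dict[tuple[str, str], float] = {}
    lineal: dict[str, float] = {}
    areas: dict[str, float] = {}
    lengths: dict[str, float] = {}
    for _, row in df.iterrows():
        basis = row["basis"]
        comp = str(row["compartment"])
        value = float(row["value"])
        if basis == "areal":
            areal[(comp, str(row["process"]))] = value
        elif basis == "lineal":
            lineal[comp] = value
        elif basis == "area":
            areas[comp] = value
        elif basis == "length":
            lengths[comp] = value
        else:
            raise ValidationError(f"{path}: unknown basis {basis!r}")
    return IntensitySet(areal=areal, lineal=lineal, areas=areas, lengths=lengths)
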