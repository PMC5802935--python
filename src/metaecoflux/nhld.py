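"""The Northern Highlands Lake District (NHLD) carbon-budget case study.

The NHLD of Wisconsin and Michigan is a lake-rich mixed landscape — roughly
53% forest, 28% wetland, 13% lakes — whose regional carbon budget has been
compiled compartment by compartment.  This module ships that budget as a
packaged flow table (21 flux records among forests, wetlands and surface
waters plus the exterior) together with the areal/lineal intensity table,
and exposes the full case-study pipeline: flag significance at the 1%
rule, classify the landscape system, close it into a meta-ecosystem with
atmosphere and downstream exterior pools, and compute the ENA report.

Case-study conventions (see docs/methods.md for the reasoning):

* the negative surface-water accumulation (−15 Gg C yr⁻¹, a pool drawdown)
  is omitted from the closed flow network — the composition whose total
  system throughput matches the published account most closely;
* development capacity is reported in the throughflow-diversity form, the
  form consistent with the published capacity/redundancy values.
"""

from __future__ import annotations

from importlib import resources

from .adjust import ExteriorSpec, to_meta_ecosystem
from .core import FluxNetwork
from .ena import ENAReport, report
from .io import read_flow_table, read_intensity_table
from .significance import (
    LandscapeClass,
    SignificanceConfig,
    classify_landscape_system,
    flag_significance,
)
from .spatial import IntensitySet

__all__ = [
    "TOTAL_C_STOCK_GG",
    "CASE_STUDY_EXTERIOR",
    "CASE_STUDY_CAPACITY_FORM",
    "nhld_network",
    "nhld_intensities",
    "nhld_adjusted",
    "nhld_report",
]

#: regional carbon pool, Gg C (380.05 Tg C)
TOTAL_C_STOCK_GG = 380050.0

CASE_STUDY_EXTERIOR = ExteriorSpec(
    orientation_map={"vertical": "atmosphere", "lateral": "downstream"},
    drop_insignificant=True,
    negative_accumulation_policy="exclude",
)

CASE_STUDY_CAPACITY_FORM = "throughflow"


def _data(name: str):
    return resources.files("metaecoflux").joinpath("data", name)


def nhld_network() -> FluxNetwork:
    """The raw NHLD flux table as a three-ecosystem network (21 records)."""
    with resources.as_file(_data("nhld_fluxes.csv")) as path:
        return read_flow_table(path, provenance="NHLD regional carbon budget")


def nhld_intensities() -> IntensitySet:
    """Areal/lineal intensities plus back-derived areas and shoreline lengths."""
    with resources.as_file(_data("nhld_intensities.csv")) as path:
        return read_intensity_table(path)


def nhld_adjusted(
    ratio: float = 0.01, spec: ExteriorSpec | None = None
) -> tuple[FluxNetwork, LandscapeClass]:
    """Run significance filtering, classification and adjustment.

    Returns the closed meta-ecosystem network and the landscape class of
    the raw system (fragmental, for the defaults).
    """
    flagged = flag_significance(nhld_network(), SignificanceConfig(ratio=ratio))
    cls = classify_landscape_system(flagged)
    adjusted = to_meta_ecosystem(flagged, spec or CASE_STUDY_EXTERIOR)
    return adjusted, cls


def nhld_report(ratio: float = 0.01) -> ENAReport:
    """The case-study ENA report on the adjusted NHLD meta-ecosystem."""
    adjusted, _ = nhld_adjusted(ratio=ratio)
    return report(
        adjusted,
        total_stock=TOTAL_C_STOCK_GG,
        capacity_form=CASE_STUDY_CAPACITY_FORM,
    )
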