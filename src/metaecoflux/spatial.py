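"""Model selection and areal/lineal flux-budget equations.

Whether spatial heterogeneity matters is decided by three questions — are
there lateral fluxes, spatially variable drivers, nonlinearities?  The
answers select one of three treatments:

* **homogeneous** — a single mean intensity characterises the whole system
  (``F = ρ · A``);
* **mosaic** — compartments are modelled separately and summed
  (composition matters, configuration does not);
* **interactive** — inter-compartment exchanges enter the budget
  (composition and configuration both matter).

Intensities are *areal* (g C m⁻² yr⁻¹, scaled by compartment area) or
*lineal* (g C m⁻¹ yr⁻¹, scaled by interface length — e.g. leaf litter
falling across a shoreline).  Budgets are returned in Gg C yr⁻¹
(1 Gg = 10⁹ g).  Sign convention: vertical budgets are net fluxes into the
compartment; lateral budgets are negative for donors and positive for the
recipient, so donors + recipient + downstream export sum to zero exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .core import ConfigurationError

__all__ = [
    "G_PER_GG",
    "IntensitySet",
    "SpatialBudget",
    "select_spatial_model",
    "homogeneous_flux",
    "mosaic_vertical_budget",
    "interactive_lateral_budget",
]

G_PER_GG = 1e9

#: intensity symbols consumed by the vertical budgets, per compartment
_VERTICAL_TERMS = {
    "forest": (("GPP", +1), ("respiration", -1)),
    "wetland": (("GPP", +1), ("respiration", -1), ("CH4", -1)),
    "surface_waters": (("CO2_evasion", -1), ("CH4", -1)),
}
_LATERAL_DONOR_TERMS = ("DIC_runoff", "DOC_runoff")


@dataclass(frozen=True)
class IntensitySet:
    """Areal and lineal flux intensities plus the geometry they scale by.

    ``areal`` maps ``(compartment, process)`` to g C m⁻² yr⁻¹ (use
    compartment ``"all"`` for spatially invariable drivers such as carbon
    precipitation).  ``lineal`` maps a donor compartment to its litter
    intensity in g C m⁻¹ of shoreline yr⁻¹.  ``areas`` are in m²,
    ``lengths`` (donor's interface with the receiving waters) in m.
    """

    areal: dict[tuple[str, str], float] = field(default_factory=dict)
    lineal: dict[str, float] = field(default_factory=dict)
    areas: dict[str, float] = field(default_factory=dict)
    lengths: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, v in {**self.areas, **self.lengths}.items():
            if v < 0:
                raise ConfigurationError(
                    f"area/length for {name!r} must be >= 0, got {v}"
                )

    def area(self, compartment: str) -> float:
        try:
            return self.areas[compartment]
        except KeyError:
            raise ConfigurationError(f"missing area A_{compartment}") from None

    def rho(self, compartment: str, process: str) -> float:
        key = (compartment, process)
        if key in self.areal:
            return self.areal[key]
        if ("all", process) in self.areal:  # spatially invariable driver
            return self.areal[("all", process)]
        raise ConfigurationError(f"missing intensity rho_{compartment},{process}")


@dataclass(frozen=True)
class SpatialBudget:
    """Per-compartment vertical and lateral totals, Gg C yr⁻¹."""

    vertical: dict[str, float] = field(default_factory=dict)
    lateral: dict[str, float] = field(default_factory=dict)
    model: str = "interactive"


def select_spatial_model(
    has_lateral: bool, has_variable_drivers: bool, has_nonlinearity: bool
) -> str:
    """Pick the simplest treatment the system's heterogeneity permits."""
    if has_lateral:
        return "interactive"
    if has_variable_drivers or has_nonlinearity:
        return "mosaic"
    return "homogeneous"


def homogeneous_flux(rho: float, area: float) -> float:
    """``ρ × A`` converted g → Gg: one mean intensity over one area."""
    return rho * area / G_PER_GG


def mosaic_vertical_budget(intensities: IntensitySet) -> SpatialBudget:
    """Net vertical flux into each surface compartment, plus the atmosphere.

    Each compartment receives carbon precipitation and its own
    production/emission terms; the atmosphere balances the three surface
    compartments exactly, so the four vertical budgets sum to zero.
    """
    vertical: dict[str, float] = {}
    for comp, terms in _VERTICAL_TERMS.items():
        a = intensities.area(comp)
        net = intensities.rho(comp, "precipitation") * a
        for process, sign in terms:
            net += sign * intensities.rho(comp, process) * a
        vertical[comp] = net / G_PER_GG
    vertical["atmosphere"] = -sum(vertical.values())
    return SpatialBudget(vertical=vertical, model="mosaic")


def interactive_lateral_budget(
    intensities: IntensitySet, downstream_export: float = 0.0
) -> SpatialBudget:
    """Lateral budgets with inter-compartment exchange terms.

    Donors (forest, wetland) lose their areal runoff terms plus the lineal
    litter term across their shoreline; surface waters receive everything
    the donors lose, minus the downstream export.  ``downstream_export`` is
    in Gg C yr⁻¹.
    """
    lateral: dict[str, float] = {}
    received = 0.0
    for donor in ("forest", "wetland"):
        a = intensities.area(donor)
        loss = sum(
            intensities.rho(donor, p) * a for p in _LATERAL_DONOR_TERMS
        )
        if donor in intensities.lineal:
            try:
                length = intensities.lengths[donor]
            except KeyError:
                raise ConfigurationError(
                    f"missing interface length L_{donor}"
                ) from None
            loss += intensities.lineal[donor] * length
        loss /= G_PER_GG
        lateral[donor] = -loss
        received += loss
    lateral["surface_waters"] = received - downstream_export
    lateral["downstream"] = downstream_export
    return SpatialBudget(lateral=lateral, model="interactive")
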