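"""Reactor geometry model and algebraic hydrodynamic descriptors.

The cultivation chamber of a micro bubble column reactor is a cuboid; gas is
sparged at the bottom and the relevant hydrodynamic scale is the rectangular
cross section ``A = width × depth``.  External interfaces use the customary
bench units (mm, µL, mL min⁻¹); every computation converts to SI internally.

A published three-geometry design ("narrow", "medium", "wide", all holding
550 µL) ships as presets; custom geometries load from YAML or JSON.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from decimal import Decimal, ROUND_HALF_UP
from pathlib import Path

import yaml

from microbcr.errors import InvalidFluidError, InvalidGeometryError

__all__ = [
    "ReactorGeometry",
    "GasFlow",
    "FluidProperties",
    "GEOMETRY_PRESETS",
    "WATER_25C",
    "superficial_gas_velocity",
    "equivalent_circular_diameter",
    "height_diameter_ratio",
    "hydraulic_diameter",
    "local_reynolds",
    "load_geometry",
    "round_half_away",
]

#: mm → m
_MM = 1e-3
#: mm² → m²
_MM2 = 1e-6
#: mL min⁻¹ → m³ s⁻¹
_ML_PER_MIN = 1e-6 / 60.0


@dataclass(frozen=True)
class ReactorGeometry:
    """Cuboid cultivation chamber.

    Parameters
    ----------
    name
        Label for reports.
    width_mm, depth_mm, height_mm
        Inner chamber dimensions in millimetres.  ``width × depth`` is the
        sparged cross section; ``height`` the chamber (liquid column) height.
    liquid_volume_ul
        Working liquid volume in microlitres.
    """

    name: str
    width_mm: float
    depth_mm: float
    height_mm: float
    liquid_volume_ul: float

    def __post_init__(self) -> None:
        for field in ("width_mm", "depth_mm", "height_mm", "liquid_volume_ul"):
            if getattr(self, field) <= 0:
                raise InvalidGeometryError(f"{self.name!r}: {field} must be > 0")
        chamber_ul = self.width_mm * self.depth_mm * self.height_mm  # mm³ == µL
        if self.liquid_volume_ul > chamber_ul * (1 + 1e-9):
            raise InvalidGeometryError(
                f"{self.name!r}: liquid volume {self.liquid_volume_ul} µL exceeds "
                f"chamber volume {chamber_ul:.1f} µL"
            )

    @property
    def cross_section_mm2(self) -> float:
        """Rectangular cross-sectional area A in mm²."""
        return self.width_mm * self.depth_mm

    @property
    def cross_section_m2(self) -> float:
        return self.cross_section_mm2 * _MM2


@dataclass(frozen=True)
class GasFlow:
    """Volumetric gas flow rate, bench units (mL min⁻¹)."""

    ml_per_min: float

    def __post_init__(self) -> None:
        if self.ml_per_min < 0:
            raise ValueError("volumetric flow rate must be >= 0")

    @property
    def m3_per_s(self) -> float:
        return self.ml_per_min * _ML_PER_MIN


@dataclass(frozen=True)
class FluidProperties:
    """Continuous (liquid) phase properties for Reynolds-number evaluation."""

    density_kg_m3: float
    dynamic_viscosity_pa_s: float

    def __post_init__(self) -> None:
        if self.density_kg_m3 <= 0:
            raise InvalidFluidError("density must be > 0")
        if self.dynamic_viscosity_pa_s <= 0:
            raise InvalidFluidError("dynamic viscosity must be > 0")


#: Water near room temperature, the working fluid of the characterization runs.
WATER_25C = FluidProperties(density_kg_m3=997.0, dynamic_viscosity_pa_s=8.9e-4)

#: The three published chamber designs, all with a 550 µL working volume.
GEOMETRY_PRESETS: dict[str, ReactorGeometry] = {
    "narrow": ReactorGeometry("narrow", 3.5, 3.5, 45.0, 550.0),
    "medium": ReactorGeometry("medium", 4.0, 5.0, 27.5, 550.0),
    "wide": ReactorGeometry("wide", 6.0, 4.0, 23.0, 550.0),
}


def round_half_away(value: float, ndigits: int) -> float:
    """Round half away from zero (the convention behind reported ratios).

    Python's builtin ``round`` is banker's rounding; reported ratios such as
    height/diameter use commercial rounding of the unrounded quotient.
    """
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(value)).quantize(q, rounding=ROUND_HALF_UP))


def superficial_gas_velocity(flow: GasFlow, geom: ReactorGeometry) -> float:
    """Superficial gas velocity u_g = V̇_g / A in m s⁻¹.

    The volumetric gas flow rate divided by the reactor cross section; linear
    in the flow rate and inversely proportional to the cross-sectional area.
    """
    area = geom.cross_section_m2
    if area <= 0:
        raise InvalidGeometryError("cross-sectional area must be > 0")
    return flow.m3_per_s / area


def equivalent_circular_diameter(geom: ReactorGeometry) -> float:
    """Diameter (mm) of the circle with the same area as the rectangular cross
    section: d = sqrt(4A/π)."""
    return math.sqrt(4.0 * geom.cross_section_mm2 / math.pi)


def height_diameter_ratio(geom: ReactorGeometry, *, rounded: bool = False) -> float:
    """Chamber height over equivalent circular diameter (dimensionless).

    Computed from the unrounded diameter; ``rounded=True`` applies the
    1-decimal half-away-from-zero reporting convention (27.5 mm / 5.0463 mm
    = 5.4496 → 5.4).
    """
    ratio = geom.height_mm / equivalent_circular_diameter(geom)
    return round_half_away(ratio, 1) if rounded else ratio


def hydraulic_diameter(geom: ReactorGeometry) -> float:
    """Hydraulic diameter of the rectangular cross section in metres:
    d_h = 4A / perimeter = 2wd/(w+d)."""
    w, d = geom.width_mm, geom.depth_mm
    return (2.0 * w * d / (w + d)) * _MM


def local_reynolds(
    fluid: FluidProperties, hydraulic_diameter_m: float, velocity_magnitude: float
) -> float:
    """Local Reynolds number Re_L = ρ_c · d_h · |v_c| / µ_c.

    Scalar formula for a user-supplied local liquid velocity magnitude
    (m s⁻¹); no flow field is computed here.
    """
    if hydraulic_diameter_m < 0 or velocity_magnitude < 0:
        raise ValueError("hydraulic diameter and velocity must be >= 0")
    return (
        fluid.density_kg_m3
        * hydraulic_diameter_m
        * velocity_magnitude
        / fluid.dynamic_viscosity_pa_s
    )


def load_geometry(path: str | Path) -> ReactorGeometry:
    """Load a custom geometry from a YAML or JSON file.

    Expected keys: ``name``, ``width_mm``, ``depth_mm``, ``height_mm``,
    ``volume_uL``.
    """
    path = Path(path)
    text = path.read_text()
    data = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
    try:
        return ReactorGeometry(
            name=str(data["name"]),
            width_mm=float(data["width_mm"]),
            depth_mm=float(data["depth_mm"]),
            height_mm=float(data["height_mm"]),
            liquid_volume_ul=float(data["volume_uL"]),
        )
    except KeyError as exc:  # pragma: no cover - message path
        raise InvalidGeometryError(f"missing geometry key {exc} in {path}") from exc
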