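"""Beam-parameter model of an ion-therapy facility.

A synchrotron-based ion-therapy facility delivers beams whose properties are
selected from discrete, pre-validated libraries rather than tuned continuously.
Each validated beam setting is identified by a MEFI tuple — Machine (ion
species), Energy step, Focus step, Intensity step — and every beamline device
stores one parameter set per MEFI combination.  This module holds the physical
grids those indices address (step counts and physical ranges per species), the
MEFI key type, and the treatment-room topology.  All other modules index beam
settings through these types.

Default grid values describe a representative dual-species facility: protons and
carbon ions, two fixed horizontal treatment rooms plus one 360° gantry room.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping

__all__ = [
    "IonSpecies",
    "AxisSpec",
    "GantrySpec",
    "BeamParameterGrid",
    "MEFIKey",
    "TreatmentRoom",
    "PROTON",
    "CARBON",
    "DEFAULT_SPECIES",
    "DEFAULT_ROOMS",
    "default_grid",
    "default_grids",
    "grids_from_config",
    "step_value",
    "in_range",
    "RangeCheck",
]


@dataclass(frozen=True)
class IonSpecies:
    """An ion species available for treatment (e.g. proton, carbon)."""

    name: str

    def __post_init__(self) -> None:
        if not self.name:
            raise ValueError("species name must be non-empty")


PROTON = IonSpecies("proton")
CARBON = IonSpecies("carbon")

#: Species registry of the default facility model.  Extensible via
#: :func:`grids_from_config`, but never empty.
DEFAULT_SPECIES: tuple[IonSpecies, ...] = (PROTON, CARBON)


@dataclass(frozen=True)
class AxisSpec:
    """One quantized beam-parameter axis: step count plus physical range.

    ``step_count == 1`` denotes a single fixed setting at ``min``; the range
    then records the physically meaningful span (e.g. the proton focus axis
    has a single step but an 8–32 mm validity window).
    """

    step_count: int
    min: float
    max: float

    def __post_init__(self) -> None:
        if self.step_count < 1:
            raise ValueError(f"step_count must be >= 1, got {self.step_count}")
        if not self.min < self.max:
            raise ValueError(f"need min < max, got [{self.min}, {self.max}]")


@dataclass(frozen=True)
class GantrySpec:
    """Gantry-angle quantization: setting resolution and interpolation nodes."""

    resolution: float = 0.01  # degrees
    interpolation_step_count: int = 36

    def __post_init__(self) -> None:
        if self.resolution <= 0:
            raise ValueError("gantry resolution must be positive")
        if self.interpolation_step_count < 1:
            raise ValueError("interpolation_step_count must be >= 1")


@dataclass(frozen=True)
class BeamParameterGrid:
    """Per-species MEFI parameter grid: energy, focus, intensity axes + gantry.

    Immutable value object; equality is field-wise.  Units: energy in MeV/u,
    focus in mm FWHM, intensity in particles/s, gantry angle in degrees.
    """

    species: IonSpecies
    energy: AxisSpec
    focus: AxisSpec
    intensity: AxisSpec
    gantry: GantrySpec = field(default_factory=GantrySpec)

    def axis(self, quantity: str) -> AxisSpec:
        try:
            return {"energy": self.energy, "focus": self.focus,
                    "intensity": self.intensity}[quantity]
        except KeyError:
            raise KeyError(f"unknown grid quantity {quantity!r}") from None


# Treatment-validated beam parameter ranges of the default facility.
_DEFAULT_GRIDS: dict[str, BeamParameterGrid] = {
    "proton": BeamParameterGrid(
        species=PROTON,
        energy=AxisSpec(255, 48.0, 221.0),       # MeV/u
        focus=AxisSpec(1, 8.0, 32.0),            # mm FWHM
        intensity=AxisSpec(9, 1e8, 3e10),        # particles/s
    ),
    "carbon": BeamParameterGrid(
        species=CARBON,
        energy=AxisSpec(255, 88.0, 430.0),
        focus=AxisSpec(4, 6.0, 12.0),
        intensity=AxisSpec(8, 1e7, 1e8),
    ),
}


def default_grid(species: IonSpecies | str) -> BeamParameterGrid:
    """Return the default treatment grid for *species*.

    Raises ``KeyError`` for species outside the default registry.
    """
    name = species.name if isinstance(species, IonSpecies) else species
    try:
        return _DEFAULT_GRIDS[name]
    except KeyError:
        raise KeyError(f"unknown ion species {name!r}") from None


def default_grids() -> dict[str, BeamParameterGrid]:
    """All default grids, keyed by species name."""
    return dict(_DEFAULT_GRIDS)


def grids_from_config(config: Mapping) -> dict[str, BeamParameterGrid]:
    """Build a grid registry from a configuration mapping.

    The mapping mirrors :class:`BeamParameterGrid` fields::

        proton:
          energy:    {step_count: 255, min: 48, max: 221}
          focus:     {step_count: 1,   min: 8,  max: 32}
          intensity: {step_count: 9,   min: 1e8, max: 3e10}
          gantry:    {resolution: 0.01, interpolation_step_count: 36}

    The ``gantry`` block is optional and defaults to the facility standard.
    Real facilities use tabulated step libraries; a config override is the
    supported path to replace the default linear spacing assumptions.
    """
    if not config:
        raise ValueError("grid config must define at least one species")
    grids: dict[str, BeamParameterGrid] = {}
    for name, block in config.items():
        axes = {}
        for q in ("energy", "focus", "intensity"):
            if q not in block:
                raise ValueError(f"species {name!r}: missing axis {q!r}")
            a = block[q]
            axes[q] = AxisSpec(int(a["step_count"]), float(a["min"]), float(a["max"]))
        g = block.get("gantry")
        gantry = (GantrySpec(float(g["resolution"]), int(g["interpolation_step_count"]))
                  if g else GantrySpec())
        grids[name] = BeamParameterGrid(IonSpecies(name), axes["energy"],
                                        axes["focus"], axes["intensity"], gantry)
    return grids


@dataclass(frozen=True, order=True)
class MEFIKey:
    """Index tuple identifying one validated beam setting.

    Indices are 0-based.  ``validate_against`` checks each index against the
    step count of the species' grid axis.
    """

    species: str
    energy_index: int
    focus_index: int
    intensity_index: int

    def __post_init__(self) -> None:
        for v in (self.energy_index, self.focus_index, self.intensity_index):
            if v < 0:
                raise ValueError(f"MEFI indices must be >= 0: {self}")

    def validate_against(self, grid: BeamParameterGrid) -> None:
        for q, idx in (("energy", self.energy_index), ("focus", self.focus_index),
                       ("intensity", self.intensity_index)):
            n = grid.axis(q).step_count
            if idx >= n:
                raise IndexError(
                    f"{q} index {idx} out of range for {self.species} grid "
                    f"({n} steps)")


@dataclass(frozen=True)
class TreatmentRoom:
    """A treatment room served by the beamline."""

    room_id: str
    beamline_type: str  # "horizontal" | "gantry"

    def __post_init__(self) -> None:
        if self.beamline_type not in ("horizontal", "gantry"):
            raise ValueError(f"unknown beamline type {self.beamline_type!r}")


#: Default topology: two fixed horizontal rooms, one gantry room.
DEFAULT_ROOMS: tuple[TreatmentRoom, ...] = (
    TreatmentRoom("H1", "horizontal"),
    TreatmentRoom("H2", "horizontal"),
    TreatmentRoom("G1", "gantry"),
)


def step_value(grid: BeamParameterGrid, quantity: str, index: int) -> float:
    """Physical value of step *index* on a grid axis.

    Steps are linearly spaced from min to max inclusive; an axis with a single
    step returns its minimum.  Raises ``IndexError`` outside the step count.
    """
    axis = grid.axis(quantity)
    if not 0 <= index < axis.step_count:
        raise IndexError(
            f"{quantity} index {index} out of range [0, {axis.step_count})")
    if axis.step_count == 1:
        return axis.min
    return axis.min + index * (axis.max - axis.min) / (axis.step_count - 1)


@dataclass(frozen=True)
class RangeCheck:
    """Accept/reject outcome of a physical range check, with reason."""

    accepted: bool
    reason: str = ""

    def __bool__(self) -> bool:
        return self.accepted


def in_range(grid: BeamParameterGrid, quantity: str, value: float,
             *, rel_tol: float = 1e-9) -> RangeCheck:
    """Check a physical value against the treatment-valid range of an axis.

    Boundaries are inclusive on both ends (the grids tabulate treatment-valid
    ranges, so min and max themselves are valid settings).  The gantry angle
    is checked as ``0 <= angle < 360`` and an integer multiple of the setting
    resolution within numeric tolerance.
    """
    if quantity in ("gantry", "gantry_angle"):
        res = grid.gantry.resolution
        if not 0 <= value < 360:
            return RangeCheck(False, f"gantry angle {value} outside [0, 360)")
        steps = value / res
        if abs(steps - round(steps)) > rel_tol * max(1.0, abs(steps)):
            return RangeCheck(
                False, f"gantry angle {value} not a multiple of {res}°")
        return RangeCheck(True)
    axis = grid.axis(quantity)
    if value < axis.min:
        return RangeCheck(
            False, f"{grid.species.name} {quantity} {value} below minimum {axis.min}")
    if value > axis.max:
        return RangeCheck(
            False, f"{grid.species.name} {quantity} {value} above maximum {axis.max}")
    return RangeCheck(True)


def angle_nodes(grid: BeamParameterGrid) -> list[float]:
    """Gantry angle interpolation nodes, equally spaced over [0, 360).

    Node k of n sits at k*360/n degrees, snapped to the setting resolution.
    """
    n = grid.gantry.interpolation_step_count
    res = grid.gantry.resolution
    return [round(round(k * 360.0 / n / res) * res, 10) % 360.0 for k in range(n)]
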