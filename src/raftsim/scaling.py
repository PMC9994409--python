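"""Real-world to simulation-unit conversion for platelet GPVI simulations.

The simulation works in a dimensionless periodic box (side 30 units by
default).  This module maps measured platelet and receptor constants --
platelet volume, GPVI copy number, single-particle-tracking diffusivity,
crystal-structure dimensions, raft diameter and raft surface coverage --
onto the box: how large the box is in metres, how many receptor discs it
holds, how large a disc is relative to the box, and what one simulation
tick corresponds to in seconds.

The chain of arithmetic is:

    sphere radius/area from platelet volume
    -> total raft area and raft (= box) count per platelet
    -> box area and box length
    -> receptors per box, scaled receptor diameter
    -> expected Brownian step per tick and the tick duration

All intermediates are carried unrounded; rounding happens only for
display (``format_table``) or where an integer is physically required
(receptor count per box, box count).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import NamedTuple

__all__ = [
    "ScalingError",
    "RealWorldParams",
    "ScaledParams",
    "HUMAN",
    "MOUSE",
    "sphere_geometry",
    "raft_layout",
    "box_dimensions",
    "receptors_per_box",
    "scaled_diameter",
    "expected_step_and_timestep",
    "surface_density",
    "derive",
    "format_table",
]


class ScalingError(ValueError):
    """Invalid input to a scaling computation."""


@dataclass(frozen=True)
class RealWorldParams:
    """Measured constants describing one platelet phenotype.

    Attributes
    ----------
    platelet_volume : float
        Platelet volume in m^3 (human default 7.4 fl).
    gpvi_copies : float
        GPVI copies per platelet.
    gpvi_diffusivity : float
        Lateral diffusion coefficient of monomeric GPVI, m^2/s.
    gpvi_crystal_length : float
        Longest side of the GPVI ectodomain crystal structure, m.
    raft_diameter : float
        Assumed lipid-raft (confined-domain) diameter, m.
    raft_fraction : float
        Fraction of the membrane surface occupied by rafts, in (0, 1].
    scaled_box_units : float
        Side of the simulation box in dimensionless units (default 30).
    """

    platelet_volume: float = 7.4e-18
    gpvi_copies: float = 9600.0
    gpvi_diffusivity: float = 0.091e-12
    gpvi_crystal_length: float = 114e-10
    raft_diameter: float = 200e-9
    raft_fraction: float = 0.35
    scaled_box_units: float = 30.0

    def __post_init__(self) -> None:
        for name in (
            "platelet_volume",
            "gpvi_copies",
            "gpvi_diffusivity",
            "gpvi_crystal_length",
            "raft_diameter",
            "scaled_box_units",
        ):
            if not getattr(self, name) > 0:
                raise ScalingError(f"{name} must be strictly positive")
        if not 0 < self.raft_fraction <= 1:
            raise ScalingError("raft_fraction must lie in (0, 1]")


#: Human platelet: 7.4 fl volume, 9600 GPVI copies.
HUMAN = RealWorldParams()
#: Mouse platelet: 4.7 fl volume, 7800 GPVI copies.
MOUSE = RealWorldParams(platelet_volume=4.7e-18, gpvi_copies=7800.0)


@dataclass(frozen=True)
class ScaledParams:
    """Derived simulation-scale parameters (SI units unless noted)."""

    platelet_radius: float
    platelet_area: float
    raft_total_area: float
    boxes_per_platelet: int
    boxes_per_platelet_exact: float
    box_area: float
    box_length: float
    receptors_per_box: int
    scaled_receptor_diameter: float  # fraction of box length
    expected_step: float  # m per tick
    timestep: float  # s per tick
    surface_density: float  # molecules per um^2


class SphereGeometry(NamedTuple):
    radius: float
    area: float


class RaftLayout(NamedTuple):
    raft_total_area: float
    boxes_exact: float
    boxes: int


def sphere_geometry(volume: float) -> SphereGeometry:
    """Radius and surface area of a sphere of the given volume.

    Platelets are idealised as perfect spheres, so the membrane area
    follows from the volume alone.
    """
    if not volume > 0:
        raise ScalingError("volume must be strictly positive")
    radius = (3.0 * volume / (4.0 * math.pi)) ** (1.0 / 3.0)
    return SphereGeometry(radius, 4.0 * math.pi * radius**2)


def raft_layout(area: float, raft_fraction: float, raft_diameter: float) -> RaftLayout:
    """Total raft area and number of raft-sized boxes tiling one platelet.

    One simulation box contains one confined domain, so the number of
    boxes per platelet is total raft area divided by the area of a
    single circular raft.  Returned both unrounded and rounded.
    """
    if not 0 < raft_fraction <= 1:
        raise ScalingError("raft_fraction must lie in (0, 1]")
    if not raft_diameter > 0:
        raise ScalingError("raft_diameter must be strictly positive")
    raft_total = raft_fraction * area
    boxes_exact = raft_total / (math.pi * (raft_diameter / 2.0) ** 2)
    return RaftLayout(raft_total, boxes_exact, _round_half_up(boxes_exact))


def box_dimensions(area: float, boxes_per_platelet: float) -> tuple[float, float]:
    """Area and side length of one square simulation box."""
    if not boxes_per_platelet >= 1:
        raise ScalingError("boxes_per_platelet must be >= 1")
    box_area = area / boxes_per_platelet
    return box_area, math.sqrt(box_area)


def receptors_per_box(copies: float, boxes: float) -> int:
    """Nearest integer number of receptor monomers in one box."""
    if copies < 0:
        raise ScalingError("copies must be non-negative")
    if not boxes >= 1:
        raise ScalingError("boxes must be >= 1")
    return _round_half_up(copies / boxes)


def scaled_diameter(crystal_length: float, box_length: float) -> float:
    """Receptor diameter as a fraction of the box side."""
    if not (crystal_length > 0 and box_length > 0):
        raise ScalingError("lengths must be strictly positive")
    if crystal_length >= box_length:
        raise ScalingError("crystal_length must be smaller than box_length")
    return crystal_length / box_length


def expected_step_and_timestep(
    box_length: float, scaled_box_units: float, diffusivity: float
) -> tuple[float, float]:
    """Expected per-tick step in metres, and the tick duration in seconds.

    With D scaled to 1 and step length |N(0,1)|, the expected step in box
    units is (pi/2)^(1/2); multiplying by the physical length of one box
    unit gives the real-world step, and MSD = 4 D t then fixes the tick:
    dt = dS^2 / (4 D).
    """
    if not (box_length > 0 and scaled_box_units > 0):
        raise ScalingError("box_length and scaled_box_units must be positive")
    if not diffusivity > 0:
        raise ScalingError("diffusivity must be strictly positive")
    step = math.sqrt(math.pi / 2.0) * (box_length / scaled_box_units)
    return step, step**2 / (4.0 * diffusivity)


def surface_density(copies: float, area: float) -> float:
    """Receptor surface density in molecules per square micrometre."""
    if not area > 0:
        raise ScalingError("area must be strictly positive")
    if copies < 0:
        raise ScalingError("copies must be non-negative")
    return copies / area * 1e-12


def derive(params: RealWorldParams, round_intermediates: bool = False) -> ScaledParams:
    """Run the full conversion chain for one parameter set.

    ``round_intermediates=True`` rounds every intermediate to two
    significant figures before it feeds the next step, mimicking working
    from the printed values instead of the exact chain; final outputs
    move by well under 3% either way.
    """
    maybe = (lambda x: _round_sig(x, 2)) if round_intermediates else (lambda x: x)

    radius, area = sphere_geometry(params.platelet_volume)
    radius, area = maybe(radius), maybe(area)
    raft_total, boxes_exact, boxes = raft_layout(
        area, params.raft_fraction, params.raft_diameter
    )
    raft_total = maybe(raft_total)
    box_area, box_length = box_dimensions(area, maybe(boxes_exact))
    box_area, box_length = maybe(box_area), maybe(box_length)
    step, dt = expected_step_and_timestep(
        box_length, params.scaled_box_units, params.gpvi_diffusivity
    )
    return ScaledParams(
        platelet_radius=radius,
        platelet_area=area,
        raft_total_area=raft_total,
        boxes_per_platelet=boxes,
        boxes_per_platelet_exact=boxes_exact,
        box_area=box_area,
        box_length=box_length,
        receptors_per_box=receptors_per_box(params.gpvi_copies, boxes_exact),
        scaled_receptor_diameter=scaled_diameter(
            params.gpvi_crystal_length, box_length
        ),
        expected_step=step,
        timestep=dt,
        surface_density=surface_density(params.gpvi_copies, area),
    )


def format_table(params: RealWorldParams, sep: str | None = None) -> str:
    """Derived-parameter table as aligned text (or CSV with ``sep=','``)."""
    s = derive(params)
    rows = [
        ("platelet_volume", f"{params.platelet_volume:.3g}", "m^3"),
        ("platelet_radius", f"{s.platelet_radius:.3g}", "m"),
        ("platelet_area", f"{s.platelet_area:.3g}", "m^2"),
        ("raft_total_area", f"{s.raft_total_area:.3g}", "m^2"),
        ("boxes_per_platelet", f"{s.boxes_per_platelet}", "count"),
        ("box_area", f"{s.box_area:.3g}", "m^2"),
        ("box_length", f"{s.box_length:.3g}", "m"),
        ("receptors_per_box", f"{s.receptors_per_box}", "count"),
        (
            "scaled_receptor_diameter",
            f"{100 * s.scaled_receptor_diameter:.2g}",
            "% of box length",
        ),
        ("expected_step", f"{s.expected_step:.3g}", "m"),
        ("timestep", f"{s.timestep:.3g}", "s"),
        ("surface_density", f"{s.surface_density:.4g}", "molecules/um^2"),
    ]
    if sep is not None:
        lines = [sep.join(("parameter", "value", "units"))]
        lines += [sep.join(r) for r in rows]
        return "\n".join(lines)
    w0 = max(len(r[0]) for r in rows)
    w1 = max(len(r[1]) for r in rows)
    return "\n".join(f"{n:<{w0}}  {v:>{w1}}  {u}" for n, v, u in rows)


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


def _round_sig(x: float, sig: int) -> float:
    if x == 0:
        return 0.0
    return round(x, sig - 1 - int(math.floor(math.log10(abs(x)))))
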