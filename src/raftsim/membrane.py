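"""Geometry and Brownian motion on a periodic membrane patch.

The membrane is a square two-dimensional box with periodic boundary
conditions (a torus), so distances use the minimal-image convention.
Agents are hard circular discs that never overlap: receptor monomers,
receptor dimers (radius sqrt(2) times the monomer, conserving disc
area) and inert crowder proteins.  Circular confined domains model
lipid rafts: inside them an agent diffuses with ``d_in`` instead of
``d_out``.

Motion is a per-tick jump process: a uniformly random direction and a
random step length sqrt(D)*|N(0,1)| (half-normal law; a Rayleigh law
with scale sqrt(D) is available as an alternative).  Moves that would
create an overlap are rejected and the agent stays put for that tick.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import IntEnum
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "Species",
    "BoxSpec",
    "Circle",
    "DomainSet",
    "Agent",
    "MotionParams",
    "PackingError",
    "wrap",
    "minimal_image",
    "toroidal_distance",
    "local_diffusivity",
    "step_scale",
    "propose_step",
    "NeighborGrid",
    "overlaps",
    "place_uniform",
    "make_domains",
    "DIMER_STEP_FACTOR",
]

#: Step-length ratio dimer:monomer at equal D.  Stokes-Einstein gives
#: D ~ 1/R and dS ~ D^(1/2), so a disc sqrt(2) times larger steps
#: 2^(1/4) times shorter.
DIMER_STEP_FACTOR = 2.0 ** (-0.25)

_OVERLAP_REL_TOL = 1e-12  # tangency (distance == radius sum) is not an overlap


class Species(IntEnum):
    MONOMER = 0
    DIMER = 1
    INERT = 2


class PackingError(RuntimeError):
    """Requested disc packing could not be realised."""

    def __init__(self, requested: int, achieved: int, message: str | None = None):
        self.requested = requested
        self.achieved = achieved
        super().__init__(
            message
            or f"packing infeasible: placed {achieved} of {requested} discs"
        )


@dataclass(frozen=True)
class BoxSpec:
    """Square periodic simulation box."""

    length: float = 30.0
    periodic: bool = True

    def __post_init__(self) -> None:
        if not self.length > 0:
            raise ValueError("box length must be strictly positive")


@dataclass(frozen=True)
class Circle:
    center: tuple[float, float]
    radius: float

    def __post_init__(self) -> None:
        if not self.radius > 0:
            raise ValueError("circle radius must be strictly positive")

    @property
    def area(self) -> float:
        return math.pi * self.radius**2


@dataclass
class DomainSet:
    """Static circular confined domains (raft proxies) in a box."""

    circles: list[Circle] = field(default_factory=list)
    box: BoxSpec = field(default_factory=BoxSpec)

    @property
    def occupied_fraction(self) -> float:
        """Nominal area fraction sum(pi r^2) / L^2 (wrap overlap ignored)."""
        return sum(c.area for c in self.circles) / self.box.length**2

    def arrays(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        if not self.circles:
            z = np.empty(0)
            return z, z.copy(), z.copy()
        cx = np.array([c.center[0] for c in self.circles])
        cy = np.array([c.center[1] for c in self.circles])
        r = np.array([c.radius for c in self.circles])
        return cx, cy, r

    def contains(self, position: Sequence[float]) -> bool:
        """Closed-disc, minimal-image membership test."""
        x, y = position
        L = self.box.length
        for c in self.circles:
            dx = _min_component(x - c.center[0], L)
            dy = _min_component(y - c.center[1], L)
            if dx * dx + dy * dy <= c.radius**2:
                return True
        return False


@dataclass
class Agent:
    """One disc on the membrane."""

    id: int
    species: Species
    radius: float
    position: np.ndarray

    def __post_init__(self) -> None:
        if not self.radius > 0:
            raise ValueError("agent radius must be strictly positive")
        self.position = np.asarray(self.position, dtype=float)


@dataclass(frozen=True)
class MotionParams:
    """Diffusivities (box units^2 per tick) and the step-length law."""

    d_out: float = 1.0
    d_in: float = 1.0
    inert_speed_factor: float = 0.5
    step_length_law: str = "half_normal"

    def __post_init__(self) -> None:
        if not self.d_out > 0:
            raise ValueError("d_out must be strictly positive")
        if not self.d_in > 0:
            raise ValueError("d_in must be strictly positive")
        if not self.inert_speed_factor > 0:
            raise ValueError("inert_speed_factor must be strictly positive")
        if self.step_length_law not in ("half_normal", "rayleigh"):
            raise ValueError("step_length_law must be 'half_normal' or 'rayleigh'")


def wrap(position: np.ndarray, box: BoxSpec) -> np.ndarray:
    """Map coordinates into [0, L) by modular arithmetic."""
    p = np.asarray(position, dtype=float)
    if not np.all(np.isfinite(p)):
        raise ValueError("non-finite coordinate passed to wrap")
    out = np.mod(p, box.length)
    # guard against float wrap landing exactly on L
    out = np.where(out >= box.length, out - box.length, out)
    return out


def minimal_image(p: np.ndarray, q: np.ndarray, box: BoxSpec) -> np.ndarray:
    """Shortest displacement q - p on the torus, components in [-L/2, L/2]."""
    d = np.asarray(q, dtype=float) - np.asarray(p, dtype=float)
    L = box.length
    return d - L * np.round(d / L)


def toroidal_distance(p: np.ndarray, q: np.ndarray, box: BoxSpec) -> float:
    d = minimal_image(p, q, box)
    return float(np.hypot(d[..., 0], d[..., 1])) if d.ndim > 1 else float(
        math.hypot(d[0], d[1])
    )


def _min_component(d: float, L: float) -> float:
    return d - L * round(d / L)


def local_diffusivity(
    position: Sequence[float],
    domains: DomainSet | None,
    motion: MotionParams,
    species: Species = Species.MONOMER,
) -> float:
    """d_in if the agent centre lies in any confined domain, else d_out.

    The species argument is accepted for interface symmetry; the inert
    speed factor is applied to the step scale at proposal time, not to
    the diffusivity field itself.
    """
    if domains is not None and domains.contains(position):
        return motion.d_in
    return motion.d_out


def step_scale(species: Species, diffusivity: float, motion: MotionParams) -> float:
    """Step-length scale sqrt(D) with species multipliers."""
    s = math.sqrt(diffusivity)
    if species == Species.INERT:
        s *= motion.inert_speed_factor
    elif species == Species.DIMER:
        s *= DIMER_STEP_FACTOR
    return s


def propose_step(
    agent: Agent,
    diffusivity: float,
    rng: np.random.Generator,
    box: BoxSpec,
    motion: MotionParams | None = None,
) -> np.ndarray:
    """Candidate position after one Brownian jump (not yet overlap-checked)."""
    motion = motion or MotionParams()
    scale = step_scale(agent.species, diffusivity, motion)
    if motion.step_length_law == "rayleigh":
        r = rng.rayleigh(scale) if scale > 0 else 0.0
    else:
        r = scale * abs(rng.standard_normal())
    theta = rng.uniform(0.0, 2.0 * math.pi)
    return wrap(agent.position + r * np.array([math.cos(theta), math.sin(theta)]), box)


class NeighborGrid:
    """Uniform cell-list grid for neighbour lookups on the torus.

    The cell size must be at least the largest interaction distance so
    that a 3x3 cell neighbourhood is guaranteed to contain every
    relevant disc.  Falls back to a single cell (all-pairs) when the
    box is too small to hold a 3x3 grid.
    """

    def __init__(self, box: BoxSpec, cell_size: float):
        self.box = box
        n = int(box.length // cell_size)
        self.n = n if n >= 3 else 1
        self.width = box.length / self.n
        self.cells: dict[tuple[int, int], list[int]] = {}

    @classmethod
    def build(
        cls, positions: np.ndarray, radii: np.ndarray, box: BoxSpec,
        extra_range: float = 0.0,
    ) -> "NeighborGrid":
        reach = 2.0 * (float(np.max(radii)) if len(radii) else 1.0) + extra_range
        grid = cls(box, max(reach, 1e-9))
        for i, p in enumerate(np.atleast_2d(positions)):
            grid.insert(i, p)
        return grid

    def _cell(self, position: Sequence[float]) -> tuple[int, int]:
        ix = int(position[0] // self.width) % self.n
        iy = int(position[1] // self.width) % self.n
        return ix, iy

    def insert(self, idx: int, position: Sequence[float]) -> None:
        self.cells.setdefault(self._cell(position), []).append(idx)

    def remove(self, idx: int, position: Sequence[float]) -> None:
        self.cells[self._cell(position)].remove(idx)

    def move(self, idx: int, old: Sequence[float], new: Sequence[float]) -> None:
        a, b = self._cell(old), self._cell(new)
        if a != b:
            self.cells[a].remove(idx)
            self.cells.setdefault(b, []).append(idx)

    def neighbors(self, position: Sequence[float]) -> list[int]:
        ix, iy = self._cell(position)
        out: list[int] = []
        seen: set[tuple[int, int]] = set()
        for dx in (-1, 0, 1):
            for dy in (-1, 0, 1):
                cell = ((ix + dx) % self.n, (iy + dy) % self.n)
                if cell in seen:
                    continue
                seen.add(cell)
                out.extend(self.cells.get(cell, ()))
        return out


def overlaps(
    candidate: Sequence[float],
    radius: float,
    positions: np.ndarray,
    radii: np.ndarray,
    box: BoxSpec,
    exclude: Iterable[int] = (),
    grid: NeighborGrid | None = None,
) -> bool:
    """True iff a disc at ``candidate`` would overlap any listed disc.

    Overlap is a strict inequality on the minimal-image centre distance:
    tangency is allowed.  With a ``grid`` the test is restricted to the
    3x3 cell neighbourhood; the result is identical to the all-pairs
    check provided the grid cell size covers the interaction range.
    """
    positions = np.atleast_2d(positions)
    if positions.shape[0] == 0:
        return False
    candidate = np.asarray(candidate, dtype=float)
    idx = np.arange(positions.shape[0]) if grid is None else np.array(
        grid.neighbors(candidate), dtype=int
    )
    excl = set(exclude)
    if excl:
        idx = np.array([i for i in idx if i not in excl], dtype=int)
    if idx.size == 0:
        return False
    d = minimal_image(candidate, positions[idx], box)
    dist2 = d[:, 0] ** 2 + d[:, 1] ** 2
    limit = (radius + np.asarray(radii)[idx]) * (1.0 - _OVERLAP_REL_TOL)
    return bool(np.any(dist2 < limit**2))


def place_uniform(
    n: int,
    radius: float,
    box: BoxSpec,
    rng: np.random.Generator,
    existing_positions: np.ndarray | None = None,
    existing_radii: np.ndarray | None = None,
    max_attempts_per_disc: int = 100_000,
) -> np.ndarray:
    """Place ``n`` non-overlapping discs uniformly by rejection sampling.

    Raises :class:`PackingError` naming the achieved count if any disc
    cannot be placed within ``max_attempts_per_disc`` attempts.
    """
    if n == 0:
        return np.empty((0, 2))
    if existing_positions is None:
        pos = np.empty((0, 2))
        rad = np.empty(0)
    else:
        pos = np.atleast_2d(existing_positions).astype(float)
        rad = np.asarray(existing_radii, dtype=float)
    placed = []
    for k in range(n):
        for _ in range(max_attempts_per_disc):
            cand = rng.uniform(0.0, box.length, size=2)
            if not overlaps(cand, radius, pos, rad, box):
                placed.append(cand)
                pos = np.vstack([pos, cand])
                rad = np.append(rad, radius)
                break
        else:
            raise PackingError(n, k)
    return np.array(placed)


def make_domains(
    total_area_fraction: float,
    n_parts: int,
    box: BoxSpec,
    rng: np.random.Generator | None = None,
    max_attempts: int = 100_000,
) -> DomainSet:
    """``n_parts`` equal circles totalling the given area fraction.

    A single circle sits at the box centre; several are placed by
    uniform rejection sampling, pairwise non-overlapping under the
    minimal image.  Domains are static for the whole run.
    """
    if total_area_fraction < 0 or total_area_fraction > 1:
        raise ValueError("total_area_fraction must lie in [0, 1]")
    if n_parts < 1:
        raise ValueError("n_parts must be >= 1")
    if total_area_fraction == 0:
        return DomainSet([], box)
    r = box.length * math.sqrt(total_area_fraction / (n_parts * math.pi))
    if n_parts == 1:
        return DomainSet([Circle((box.length / 2.0, box.length / 2.0), r)], box)
    if rng is None:
        rng = np.random.default_rng(0)
    centers: list[np.ndarray] = []
    for k in range(n_parts):
        for _ in range(max_attempts):
            cand = rng.uniform(0.0, box.length, size=2)
            ok = True
            for c in centers:
                d = minimal_image(cand, c, box)
                if d[0] ** 2 + d[1] ** 2 < (2.0 * r) ** 2:
                    ok = False
                    break
            if ok:
                centers.append(cand)
                break
        else:
            raise PackingError(n_parts, k, "confined-domain layout infeasible")
    return DomainSet([Circle((c[0], c[1]), r) for c in centers], box)
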