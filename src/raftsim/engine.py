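"""Simulation configuration, state, tick scheduler and replicate runner.

A run advances an initial state of uniformly placed receptor monomers
(plus optional inert crowders) through ``n_steps`` ticks and records
monomer/dimer counts, the fraction of receptor molecules in dimeric
form, and the molecule-weighted fraction inside confined domains.
Equilibrium observables are window means over the final ``window``
ticks, and experiments repeat each configuration over independent
replicate seeds (mean +/- sample SD).

Two execution paths exist: a numba kernel (default backend, used for
every production run) and a pure-Python tick built from the
``membrane``/``reactions`` primitives, kept as the readable reference
and for cross-checking.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterator

import numpy as np
import pandas as pd

from . import _kernel
from .membrane import (
    BoxSpec,
    DomainSet,
    MotionParams,
    PackingError,
    Species,
    local_diffusivity,
    make_domains,
    minimal_image,
    overlaps,
    place_uniform,
    propose_step,
    Agent,
)
from .reactions import (
    ReactionParams,
    attempt_dimerise,
    attempt_dissociate,
    capture_candidates,
)

__all__ = [
    "ConfigError",
    "SimulationError",
    "DomainSpec",
    "SimConfig",
    "SimState",
    "TimeSeries",
    "SummaryStat",
    "init_state",
    "tick",
    "run",
    "window_mean",
    "run_replicates",
    "OBSERVABLES",
]

OBSERVABLES = ("fraction_dimeric", "fraction_inside", "n_monomers", "n_dimers")


class ConfigError(ValueError):
    """Invalid simulation configuration."""


class SimulationError(RuntimeError):
    """Internal consistency violation during a run (overlap or count leak)."""


@dataclass(frozen=True)
class DomainSpec:
    """Confined-domain layout: how many circles and how much area."""

    count: int = 1
    occupied_percent: float = 35.0
    layout: str = "central"  # "central" (single circle) or "uniform"

    def __post_init__(self) -> None:
        if self.count < 0:
            raise ConfigError("domains.count must be >= 0")
        if not 0.0 <= self.occupied_percent <= 100.0:
            raise ConfigError("domains.occupied_percent must lie in [0, 100]")
        if self.layout not in ("central", "uniform"):
            raise ConfigError("domains.layout must be 'central' or 'uniform'")


@dataclass(frozen=True)
class SimConfig:
    """Complete, seedable specification of one simulation."""

    box: BoxSpec = field(default_factory=BoxSpec)
    domains: DomainSpec = field(default_factory=DomainSpec)
    motion: MotionParams = field(default_factory=MotionParams)
    reactions: ReactionParams = field(default_factory=ReactionParams)
    n_receptor_monomers: int = 47
    n_inert: int = 0
    receptor_radius: float | None = None  # default: 3.8% of box length / 2
    inert_radius: float | None = None  # default: 5% of box length / 2
    n_steps: int = 200_000
    window: int = 50_000
    thin: int = 10
    replicates: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_receptor_monomers < 0:
            raise ConfigError("n_receptor_monomers must be >= 0")
        if self.n_inert < 0:
            raise ConfigError("n_inert must be >= 0")
        if self.n_steps < 0:
            raise ConfigError("n_steps must be >= 0")
        if self.window > self.n_steps and self.n_steps > 0:
            raise ConfigError("window must be <= n_steps")
        if self.thin < 1:
            raise ConfigError("thin must be >= 1")
        if self.replicates < 1:
            raise ConfigError("replicates must be >= 1")
        for name in ("receptor_radius", "inert_radius"):
            v = getattr(self, name)
            if v is not None and not v > 0:
                raise ConfigError(f"{name} must be strictly positive")

    @property
    def mono_radius(self) -> float:
        if self.receptor_radius is not None:
            return self.receptor_radius
        return 0.038 * self.box.length / 2.0

    @property
    def crowder_radius(self) -> float:
        if self.inert_radius is not None:
            return self.inert_radius
        return 0.05 * self.box.length / 2.0


@dataclass
class SimState:
    """Flat-array agent state with fixed slot capacity."""

    box: BoxSpec
    domains: DomainSet
    pos: np.ndarray  # (cap, 2)
    radius: np.ndarray  # (cap,)
    species: np.ndarray  # (cap,) int64, Species codes
    alive: np.ndarray  # (cap,) bool
    stamp: np.ndarray  # (cap,) int64, tick of creation (-1 initial)
    mono_radius: float

    def live_indices(self) -> list[int]:
        return list(np.flatnonzero(self.alive))

    def claim_slot(self) -> int:
        free = np.flatnonzero(~self.alive)
        if free.size == 0:
            raise SimulationError("no free agent slot (capacity leak)")
        return int(free[0])

    @property
    def n_monomers(self) -> int:
        return int(np.sum(self.alive & (self.species == Species.MONOMER)))

    @property
    def n_dimers(self) -> int:
        return int(np.sum(self.alive & (self.species == Species.DIMER)))

    @property
    def n_inert(self) -> int:
        return int(np.sum(self.alive & (self.species == Species.INERT)))

    @property
    def n_molecules(self) -> int:
        return self.n_monomers + 2 * self.n_dimers

    @property
    def total_receptor_area(self) -> float:
        mask = self.alive & (self.species != Species.INERT)
        return float(np.sum(math.pi * self.radius[mask] ** 2))

    def agents(self) -> Iterator[Agent]:
        for i in self.live_indices():
            yield Agent(i, Species(int(self.species[i])),
                        float(self.radius[i]), self.pos[i].copy())

    def fraction_inside(self) -> float:
        total = self.n_molecules
        if total == 0 or not self.domains.circles:
            return 0.0
        inside = 0
        for i in self.live_indices():
            if self.species[i] == Species.INERT:
                continue
            if self.domains.contains(self.pos[i]):
                inside += 1 if self.species[i] == Species.MONOMER else 2
        return inside / total

    def has_overlap(self, allow_encounter_pairs: bool = False) -> bool:
        """All-pairs overlap oracle (strict; tangency allowed).

        With ``allow_encounter_pairs`` monomer-monomer overlaps are
        tolerated: under the cocentric dissociation rule a freshly
        split dimer is a transient encounter pair of co-located
        monomers, and no other monomer-monomer overlap can arise.
        """
        idx = self.live_indices()
        for a in range(len(idx)):
            i = idx[a]
            for b in range(a + 1, len(idx)):
                j = idx[b]
                if (
                    allow_encounter_pairs
                    and self.species[i] == Species.MONOMER
                    and self.species[j] == Species.MONOMER
                ):
                    continue
                d = minimal_image(self.pos[i], self.pos[j], self.box)
                lim = (self.radius[i] + self.radius[j]) * (1 - 1e-12)
                if d[0] ** 2 + d[1] ** 2 < lim**2:
                    return True
        return False

    def check_invariants(self, expected_molecules: int,
                         allow_encounter_pairs: bool = False,
                         check_overlaps: bool = True) -> None:
        if self.n_molecules != expected_molecules:
            raise SimulationError(
                f"molecule count leak: {self.n_molecules} != {expected_molecules}"
            )
        if check_overlaps and self.has_overlap(allow_encounter_pairs):
            raise SimulationError("overlapping agents detected")

    def snapshot(self, step: int = 0) -> pd.DataFrame:
        """Tidy per-agent snapshot (columns match the CSV export)."""
        rows = []
        for i in self.live_indices():
            rows.append(
                {
                    "step": step,
                    "agent_id": i,
                    "species": Species(int(self.species[i])).name.lower(),
                    "x": self.pos[i, 0],
                    "y": self.pos[i, 1],
                    "radius": self.radius[i],
                    "inside_domain": int(self.domains.contains(self.pos[i])),
                }
            )
        return pd.DataFrame(
            rows,
            columns=["step", "agent_id", "species", "x", "y", "radius",
                     "inside_domain"],
        )


@dataclass
class TimeSeries:
    """Per-record observables of one run (records every ``thin`` ticks)."""

    step: np.ndarray
    n_monomers: np.ndarray
    n_dimers: np.ndarray
    fraction_dimeric: np.ndarray
    fraction_inside: np.ndarray
    n_total_molecules: int
    seed: int
    deferred_dissociations: int = 0
    abandoned_dimerisations: int = 0
    trajectory: np.ndarray | None = None  # unwrapped (n_rec, 2) of slot 0

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "step": self.step,
                "n_monomers": self.n_monomers,
                "n_dimers": self.n_dimers,
                "fraction_dimeric": self.fraction_dimeric,
                "fraction_inside": self.fraction_inside,
            }
        )


@dataclass(frozen=True)
class SummaryStat:
    """Mean and sample SD of a window-mean observable over replicates."""

    mean: float
    sd: float | None  # None when a single replicate (SD not applicable)
    n_replicates: int


def build_domains(config: SimConfig, rng: np.random.Generator) -> DomainSet:
    frac = config.domains.occupied_percent / 100.0
    if frac == 0.0 or config.domains.count == 0:
        return DomainSet([], config.box)
    return make_domains(frac, config.domains.count, config.box, rng)


def init_state(config: SimConfig, rng: np.random.Generator) -> SimState:
    """Domains laid out, inert discs then receptor monomers placed uniformly.

    All receptors start monomeric (no dimers at tick 0).
    """
    domains = build_domains(config, rng)
    cap = config.n_receptor_monomers + config.n_inert
    pos = np.zeros((max(cap, 1), 2))
    rad = np.zeros(max(cap, 1))
    spc = np.zeros(max(cap, 1), dtype=np.int64)
    alive = np.zeros(max(cap, 1), dtype=bool)
    stamp = np.full(max(cap, 1), -1, dtype=np.int64)

    inert_pos = place_uniform(config.n_inert, config.crowder_radius,
                              config.box, rng)
    mono_pos = place_uniform(
        config.n_receptor_monomers,
        config.mono_radius,
        config.box,
        rng,
        existing_positions=inert_pos if config.n_inert else None,
        existing_radii=np.full(config.n_inert, config.crowder_radius)
        if config.n_inert
        else None,
    )
    k = 0
    for p in inert_pos:
        pos[k] = p
        rad[k] = config.crowder_radius
        spc[k] = Species.INERT
        alive[k] = True
        k += 1
    for p in mono_pos:
        pos[k] = p
        rad[k] = config.mono_radius
        spc[k] = Species.MONOMER
        alive[k] = True
        k += 1
    return SimState(config.box, domains, pos, rad, spc, alive, stamp,
                    config.mono_radius)


def tick(state: SimState, config: SimConfig, rng: np.random.Generator,
         tick_index: int = 1) -> SimState:
    """One tick of the pure-Python scheduler (reference path).

    Visits live agents in a fresh uniform random order; per agent:
    Brownian jump with overlap rejection, then a dimerisation attempt
    (monomers) or a dissociation attempt (dimers).  Agents created
    mid-tick are stamped and skipped until the next tick.
    """
    n_mol = state.n_molecules
    order = rng.permutation(len(state.alive))
    for i in order:
        if not state.alive[i] or state.stamp[i] == tick_index:
            continue
        sp = Species(int(state.species[i]))
        agent = Agent(i, sp, float(state.radius[i]), state.pos[i].copy())
        D = local_diffusivity(state.pos[i], state.domains, config.motion, sp)
        cand = propose_step(agent, D, rng, state.box, config.motion)
        others = [j for j in state.live_indices() if j != i]
        if not others or not overlaps(cand, state.radius[i], state.pos[others],
                                      state.radius[others], state.box):
            state.pos[i] = cand
        if sp == Species.MONOMER and config.reactions.k_b > 0:
            cands = capture_candidates(state, i, config.reactions, rng)
            if cands:
                attempt_dimerise(state, i, cands, config.reactions, rng,
                                 tick_index)
        elif sp == Species.DIMER and config.reactions.k_d > 0:
            attempt_dissociate(state, i, config.reactions, rng, tick_index)
    state.check_invariants(
        n_mol,
        allow_encounter_pairs=(
            config.reactions.dissociation_placement == "cocentric"
        ),
        check_overlaps=config.reactions.reaction_overlap_veto,
    )
    return state


def run(config: SimConfig, seed: int | None = None,
        backend: str = "numba", track_first: bool = False) -> TimeSeries:
    """Run ``n_steps`` ticks from a fresh initial state.

    Records every ``config.thin`` ticks (plus the initial state).  The
    ``python`` backend uses the reference tick; results agree
    statistically but not bitwise (independent RNG streams).
    ``track_first=True`` additionally records the unwrapped trajectory
    of agent slot 0 (numba backend only), for diffusion diagnostics.
    """
    if seed is None:
        seed = config.seed
    rng = np.random.default_rng(seed)
    state = init_state(config, rng)
    n_mol0 = state.n_molecules

    if backend == "python":
        return _run_python(config, state, rng, seed)
    if backend != "numba":
        raise ConfigError("backend must be 'numba' or 'python'")

    dom_x, dom_y, dom_r = state.domains.arrays()
    n_rec = config.n_steps // config.thin + 1
    rec_step = np.zeros(n_rec, dtype=np.int64)
    rec_nm = np.zeros(n_rec, dtype=np.int64)
    rec_nd = np.zeros(n_rec, dtype=np.int64)
    rec_inside = np.zeros(n_rec, dtype=np.int64)
    track_slot = 0 if track_first else -1
    rec_tx = np.zeros(n_rec if track_first else 1)
    rec_ty = np.zeros(n_rec if track_first else 1)
    kernel_seed = int(np.random.default_rng(seed).integers(0, 2**31 - 1))
    written, deferred, abandoned, status = _kernel.run_kernel(
        kernel_seed,
        config.n_steps,
        config.thin,
        config.box.length,
        state.pos,
        state.radius,
        state.species,
        state.alive,
        dom_x,
        dom_y,
        dom_r,
        config.motion.d_out,
        config.motion.d_in,
        config.motion.inert_speed_factor,
        1 if config.motion.step_length_law == "rayleigh" else 0,
        config.reactions.k_b,
        config.reactions.k_d,
        config.reactions.capture_threshold_fraction,
        config.mono_radius,
        1 if config.reactions.dissociation_placement == "cocentric" else 0,
        1 if config.reactions.reaction_overlap_veto else 0,
        track_slot,
        rec_step,
        rec_nm,
        rec_nd,
        rec_inside,
        rec_tx,
        rec_ty,
    )
    if status != _kernel.STATUS_OK:
        raise SimulationError("molecule conservation violated during run")
    # Final-state count oracle, plus overlap oracle where the rules
    # guarantee a hard-disc state.  Without the reaction overlap veto,
    # reactions may leave transient overlaps that relax diffusively, so
    # only moves are guaranteed overlap-free and the static check is
    # limited to monomer pairs created by dissociation.
    state.check_invariants(
        n_mol0,
        allow_encounter_pairs=(
            config.reactions.dissociation_placement == "cocentric"
        ),
        check_overlaps=config.reactions.reaction_overlap_veto,
    )
    total = max(n_mol0, 1)
    frac_dim = 2.0 * rec_nd[:written] / total
    frac_in = rec_inside[:written] / total
    traj = None
    if track_first:
        traj = np.column_stack([rec_tx[:written], rec_ty[:written]])
    return TimeSeries(
        step=rec_step[:written],
        n_monomers=rec_nm[:written],
        n_dimers=rec_nd[:written],
        fraction_dimeric=frac_dim,
        fraction_inside=frac_in,
        n_total_molecules=n_mol0,
        seed=seed,
        deferred_dissociations=int(deferred),
        abandoned_dimerisations=int(abandoned),
        trajectory=traj,
    )


def _run_python(config: SimConfig, state: SimState,
                rng: np.random.Generator, seed: int) -> TimeSeries:
    n_mol0 = state.n_molecules
    total = max(n_mol0, 1)
    steps = [0]
    nm = [state.n_monomers]
    nd = [state.n_dimers]
    fin = [state.fraction_inside()]
    for t in range(1, config.n_steps + 1):
        tick(state, config, rng, t)
        if t % config.thin == 0:
            steps.append(t)
            nm.append(state.n_monomers)
            nd.append(state.n_dimers)
            fin.append(state.fraction_inside())
    nm_a = np.array(nm)
    nd_a = np.array(nd)
    return TimeSeries(
        step=np.array(steps),
        n_monomers=nm_a,
        n_dimers=nd_a,
        fraction_dimeric=2.0 * nd_a / total,
        fraction_inside=np.array(fin),
        n_total_molecules=n_mol0,
        seed=seed,
    )


def window_mean(series: TimeSeries, window: int) -> dict[str, float]:
    """Mean of each observable over the final ``window`` ticks."""
    last = int(series.step[-1])
    if window > last:
        raise ValueError(f"window ({window}) exceeds recorded span ({last})")
    mask = series.step > last - window
    if not np.any(mask):  # window == 0 or nothing retained: last record only
        mask = series.step == last
    return {
        "fraction_dimeric": float(np.mean(series.fraction_dimeric[mask])),
        "fraction_inside": float(np.mean(series.fraction_inside[mask])),
        "n_monomers": float(np.mean(series.n_monomers[mask])),
        "n_dimers": float(np.mean(series.n_dimers[mask])),
    }


def replicate_seeds(config: SimConfig) -> list[int]:
    """Deterministic per-replicate seeds: seed, seed+1, ..."""
    return [config.seed + k for k in range(config.replicates)]


def run_replicates(config: SimConfig, backend: str = "numba"
                   ) -> dict[str, SummaryStat]:
    """Window means over independent replicate seeds, as mean +/- SD.

    Returns one :class:`SummaryStat` per observable; the per-replicate
    window means are attached under ``"_replicates"`` -> dict of lists.
    """
    per_rep: dict[str, list[float]] = {k: [] for k in OBSERVABLES}
    for s in replicate_seeds(config):
        series = run(config, seed=s, backend=backend)
        wm = window_mean(series, config.window if config.n_steps else 0)
        for k in OBSERVABLES:
            per_rep[k].append(wm[k])
    out: dict[str, SummaryStat] = {}
    for k in OBSERVABLES:
        vals = np.array(per_rep[k])
        sd = float(np.std(vals, ddof=1)) if len(vals) > 1 else None
        out[k] = SummaryStat(float(np.mean(vals)), sd, len(vals))
    out["_replicates"] = per_rep  # type: ignore[assignment]
    return out
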