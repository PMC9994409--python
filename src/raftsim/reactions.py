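"""Stochastic monomer <-> dimer conversion rules.

Dimerisation converts two monomers within capture range into one dimer
of radius sqrt(2) R placed at the minimal-image midpoint; dissociation
converts a dimer back into two tangent monomers along a random axis.
Both conserve total receptor disc area exactly (pi (sqrt2 R)^2 =
2 pi R^2) and the molecule count n_monomers + 2 n_dimers.

Capture range is measured edge to edge: two monomers are candidates if
the gap between their rims is at most ``capture_threshold_fraction`` of
a monomer diameter (default 10%).  A centre-to-centre reading of the
threshold would be geometrically impossible for non-overlapping discs.

The functions here operate on a :class:`raftsim.engine.SimState` and
are the readable reference implementation; the numba kernel in
``_kernel`` applies identical rules inside the fast tick loop.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .membrane import Species, minimal_image, overlaps, wrap

__all__ = ["ReactionParams", "capture_candidates", "attempt_dimerise",
           "attempt_dissociate"]


@dataclass(frozen=True)
class ReactionParams:
    """Per-tick reaction probabilities.

    k_b : dimerisation probability per monomer per tick (applied when at
        least one capture-range partner exists).
    k_d : dissociation probability per dimer per tick.
    capture_threshold_fraction : capture gap as a fraction of the
        monomer diameter.
    """

    k_b: float = 0.05
    k_d: float = 0.01
    capture_threshold_fraction: float = 0.1
    dissociation_placement: str = "cocentric"
    reaction_overlap_veto: bool = False

    def __post_init__(self) -> None:
        if not 0.0 <= self.k_b <= 1.0:
            raise ValueError("k_b must lie in [0, 1]")
        if not 0.0 <= self.k_d <= 1.0:
            raise ValueError("k_d must lie in [0, 1]")
        if not self.capture_threshold_fraction > 0:
            raise ValueError("capture_threshold_fraction must be positive")
        if self.dissociation_placement not in ("cocentric", "tangent"):
            raise ValueError(
                "dissociation_placement must be 'cocentric' or 'tangent'"
            )


def capture_candidates(state, focal: int, params: ReactionParams,
                       rng: np.random.Generator | None = None) -> list[int]:
    """Other monomers within capture range of ``focal``, nearest first.

    Ties at identical gap are broken uniformly at random (requires
    ``rng``; without one ties keep index order).
    """
    if state.species[focal] != Species.MONOMER:
        raise ValueError("focal agent must be a monomer")
    R = state.mono_radius
    threshold = params.capture_threshold_fraction * 2.0 * R
    out: list[tuple[float, int]] = []
    p = state.pos[focal]
    for j in state.live_indices():
        if j == focal or state.species[j] != Species.MONOMER:
            continue
        d = minimal_image(p, state.pos[j], state.box)
        gap = math.hypot(d[0], d[1]) - 2.0 * R
        if gap <= threshold:
            out.append((gap, j))
    if rng is not None:
        tie = {j: rng.random() for _, j in out}
        out.sort(key=lambda t: (t[0], tie[t[1]]))
    else:
        out.sort(key=lambda t: t[0])
    return [j for _, j in out]


def attempt_dimerise(state, focal: int, candidates: list[int],
                     params: ReactionParams, rng: np.random.Generator,
                     tick: int = 0) -> dict | None:
    """One dimerisation draw for ``focal`` against its nearest candidate.

    Returns an event record on success, None otherwise.  The event is
    abandoned (state untouched) if the new dimer would overlap any other
    agent.
    """
    if not candidates:
        return None
    if not rng.random() < params.k_b:
        return None
    j = candidates[0]
    p = state.pos[focal]
    d = minimal_image(p, state.pos[j], state.box)
    mid = wrap(p + 0.5 * d, state.box)
    dimer_r = math.sqrt(2.0) * state.mono_radius
    if params.reaction_overlap_veto:
        live = [k for k in state.live_indices() if k not in (focal, j)]
        if live and overlaps(mid, dimer_r, state.pos[live],
                             state.radius[live], state.box):
            return {"event": "abandoned_dimerise", "ids": (focal, j)}
    state.alive[j] = False
    state.pos[focal] = mid
    state.radius[focal] = dimer_r
    state.species[focal] = Species.DIMER
    state.stamp[focal] = tick
    return {"event": "dimerise", "ids": (focal, j), "position": tuple(mid)}


def attempt_dissociate(state, dimer: int, params: ReactionParams,
                       rng: np.random.Generator, tick: int = 0,
                       max_axis_attempts: int = 20) -> dict | None:
    """One dissociation draw for ``dimer``.

    Placement follows ``params.dissociation_placement``.  Cocentric
    (default): both product monomers sit at the dimer centre, forming a
    transient encounter pair that separates (or rebinds) by diffusion;
    always succeeds, since each product fits inside the old dimer
    footprint.  Tangent: centres at dimer centre +/- R along a
    uniformly random axis, retried with fresh axes up to
    ``max_axis_attempts`` times; on total failure the event is deferred
    and the dimer kept.
    """
    if state.species[dimer] != Species.DIMER:
        raise ValueError("agent must be a dimer")
    if not rng.random() < params.k_d:
        return None
    R = state.mono_radius
    c = state.pos[dimer]
    if params.dissociation_placement == "cocentric":
        state.species[dimer] = Species.MONOMER
        state.radius[dimer] = R
        state.stamp[dimer] = tick
        s = state.claim_slot()
        state.alive[s] = True
        state.species[s] = Species.MONOMER
        state.radius[s] = R
        state.pos[s] = c.copy()
        state.stamp[s] = tick
        return {"event": "dissociate", "ids": (dimer, s),
                "position": tuple(c)}
    live = [k for k in state.live_indices() if k != dimer]
    for _ in range(max_axis_attempts):
        phi = rng.uniform(0.0, 2.0 * math.pi)
        u = R * np.array([math.cos(phi), math.sin(phi)])
        pa = wrap(c + u, state.box)
        pb = wrap(c - u, state.box)
        clash = live and (
            overlaps(pa, R, state.pos[live], state.radius[live], state.box)
            or overlaps(pb, R, state.pos[live], state.radius[live], state.box)
        )
        if not clash:
            state.species[dimer] = Species.MONOMER
            state.radius[dimer] = R
            state.pos[dimer] = pa
            state.stamp[dimer] = tick
            s = state.claim_slot()
            state.alive[s] = True
            state.species[s] = Species.MONOMER
            state.radius[s] = R
            state.pos[s] = pb
            state.stamp[s] = tick
            return {"event": "dissociate", "ids": (dimer, s),
                    "position": tuple(c)}
    return {"event": "deferred_dissociate", "ids": (dimer,)}
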