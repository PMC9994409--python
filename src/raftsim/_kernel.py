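"""Numba kernel for the per-tick agent scheduler.

This is the fast path behind :func:`raftsim.engine.run`.  It implements
exactly the same per-agent rules as the pure-Python reference path
(``membrane`` + ``reactions`` + ``engine.tick``): each tick visits the
agents in a fresh uniform random order; each agent first attempts a
Brownian jump (rejected on overlap), then a monomer may dimerise with
its nearest capture-range neighbour with probability k_b, and a dimer
may dissociate with probability k_d.  Agents created mid-tick are
stamped and skipped until the next tick.

State lives in flat arrays with a fixed slot capacity (initial monomer
count + inert count bounds the live agent count for the whole run).
Neighbour lookups use a cell-list grid with linked lists; when the box
is too small for a 3x3 grid the kernel degrades to all-pairs scans.

The kernel uses numba's own seeded RNG (``np.random.seed`` inside the
jitted function), so a run is bit-reproducible for a given seed.
"""

from __future__ import annotations

import math

import numpy as np
from numba import njit

MONOMER = 0
DIMER = 1
INERT = 2

STATUS_OK = 0
STATUS_CONSERVATION = 1

_DIMER_STEP_FACTOR = 2.0 ** (-0.25)
_OVERLAP_REL_TOL = 1e-12


@njit(cache=True, inline="always")
def _wrap1(x, L):
    x = x % L
    if x >= L:
        x -= L
    if x < 0.0:
        x += L
    return x


@njit(cache=True, inline="always")
def _mini(d, L):
    return d - L * round(d / L)


@njit(cache=True)
def _in_domain(x, y, dom_x, dom_y, dom_r, L):
    for k in range(dom_x.shape[0]):
        dx = _mini(x - dom_x[k], L)
        dy = _mini(y - dom_y[k], L)
        if dx * dx + dy * dy <= dom_r[k] * dom_r[k]:
            return True
    return False


@njit(cache=True, inline="always")
def _cell_of(x, y, ncell, cw):
    ix = int(x // cw) % ncell
    iy = int(y // cw) % ncell
    return ix * ncell + iy


@njit(cache=True)
def _grid_insert(i, x, y, head, nxt, cellof, ncell, cw):
    c = _cell_of(x, y, ncell, cw)
    nxt[i] = head[c]
    head[c] = i
    cellof[i] = c


@njit(cache=True)
def _grid_remove(i, head, nxt, cellof):
    c = cellof[i]
    j = head[c]
    if j == i:
        head[c] = nxt[i]
        return
    while nxt[j] != i:
        j = nxt[j]
    nxt[j] = nxt[i]


@njit(cache=True)
def _overlap_at(x, y, r, excl_a, excl_b, pos, rad, alive,
                head, nxt, ncell, cw, L):
    """Strict-overlap test for a disc at (x, y); tangency allowed."""
    if ncell == 1:
        for j in range(pos.shape[0]):
            if not alive[j] or j == excl_a or j == excl_b:
                continue
            dx = _mini(x - pos[j, 0], L)
            dy = _mini(y - pos[j, 1], L)
            lim = (r + rad[j]) * (1.0 - _OVERLAP_REL_TOL)
            if dx * dx + dy * dy < lim * lim:
                return True
        return False
    ix = int(x // cw) % ncell
    iy = int(y // cw) % ncell
    for ox in range(-1, 2):
        cx = (ix + ox) % ncell
        for oy in range(-1, 2):
            c = cx * ncell + (iy + oy) % ncell
            j = head[c]
            while j != -1:
                if alive[j] and j != excl_a and j != excl_b:
                    dx = _mini(x - pos[j, 0], L)
                    dy = _mini(y - pos[j, 1], L)
                    lim = (r + rad[j]) * (1.0 - _OVERLAP_REL_TOL)
                    if dx * dx + dy * dy < lim * lim:
                        return True
                j = nxt[j]
    return False


@njit(cache=True)
def _nearest_capture(i, capture_dist, pos, rad, species, alive,
                     head, nxt, ncell, cw, L):
    """Nearest other monomer within centre distance ``capture_dist``.

    Ties at identical distance are broken uniformly at random.
    """
    best = -1
    best_d2 = 1e300
    n_tied = 0
    x = pos[i, 0]
    y = pos[i, 1]
    if ncell == 1:
        for j in range(pos.shape[0]):
            if j == i or not alive[j] or species[j] != MONOMER:
                continue
            dx = _mini(x - pos[j, 0], L)
            dy = _mini(y - pos[j, 1], L)
            d2 = dx * dx + dy * dy
            if d2 <= capture_dist * capture_dist:
                if d2 < best_d2:
                    best = j
                    best_d2 = d2
                    n_tied = 1
                elif d2 == best_d2:
                    n_tied += 1
                    if np.random.random() < 1.0 / n_tied:
                        best = j
        return best
    ix = int(x // cw) % ncell
    iy = int(y // cw) % ncell
    for ox in range(-1, 2):
        cx = (ix + ox) % ncell
        for oy in range(-1, 2):
            c = cx * ncell + (iy + oy) % ncell
            j = head[c]
            while j != -1:
                if j != i and alive[j] and species[j] == MONOMER:
                    dx = _mini(x - pos[j, 0], L)
                    dy = _mini(y - pos[j, 1], L)
                    d2 = dx * dx + dy * dy
                    if d2 <= capture_dist * capture_dist:
                        if d2 < best_d2:
                            best = j
                            best_d2 = d2
                            n_tied = 1
                        elif d2 == best_d2:
                            n_tied += 1
                            if np.random.random() < 1.0 / n_tied:
                                best = j
                j = nxt[j]
    return best


@njit(cache=True)
def run_kernel(
    seed,
    n_ticks,
    record_every,
    L,
    pos,          # (cap, 2) float64, modified in place
    rad,          # (cap,)
    species,      # (cap,) int64
    alive,        # (cap,) bool
    dom_x, dom_y, dom_r,
    d_out, d_in, inert_factor, law_rayleigh,
    k_b, k_d, capture_frac, mono_r, cocentric_split, react_veto,
    track_slot,   # record unwrapped trajectory of this slot (-1: off)
    rec_step, rec_nm, rec_nd, rec_inside, rec_tx, rec_ty,
):
    """Advance the state ``n_ticks`` ticks, recording every ``record_every``.

    Returns (records_written, deferred_dissociations, abandoned_dimerisations,
    status).  Records land in the ``rec_*`` arrays: counts of monomers and
    dimers, molecule-weighted count inside domains, and (optionally) the
    unwrapped trajectory of ``track_slot``.
    """
    np.random.seed(seed)
    cap = pos.shape[0]
    dimer_r = math.sqrt(2.0) * mono_r
    capture_dist = 2.0 * mono_r + capture_frac * 2.0 * mono_r

    # target molecule count for the conservation check
    n_mol0 = 0
    r_max = 1e-9
    for i in range(cap):
        if alive[i]:
            if species[i] == MONOMER:
                n_mol0 += 1
            elif species[i] == DIMER:
                n_mol0 += 2
            if rad[i] > r_max:
                r_max = rad[i]
    if dimer_r > r_max:
        r_max = dimer_r  # dimers may form mid-run

    # cell grid sized for the largest interaction range
    cell_size = 2.0 * r_max
    if capture_dist > cell_size:
        cell_size = capture_dist
    ncell = int(L / cell_size)
    if ncell < 3:
        ncell = 1
    cw = L / ncell
    head = np.full(ncell * ncell, -1, dtype=np.int64)
    nxt = np.full(cap, -1, dtype=np.int64)
    cellof = np.zeros(cap, dtype=np.int64)
    for i in range(cap):
        if alive[i]:
            _grid_insert(i, pos[i, 0], pos[i, 1], head, nxt, cellof, ncell, cw)

    stamp = np.full(cap, -1, dtype=np.int64)
    order = np.empty(cap, dtype=np.int64)
    tx = 0.0
    ty = 0.0

    deferred_dissoc = 0
    abandoned_dim = 0
    n_rec = 0

    # initial record (tick 0)
    nm = 0
    nd = 0
    inside = 0
    for i in range(cap):
        if alive[i] and species[i] != INERT:
            w = 1 if species[i] == MONOMER else 2
            if species[i] == MONOMER:
                nm += 1
            else:
                nd += 1
            if _in_domain(pos[i, 0], pos[i, 1], dom_x, dom_y, dom_r, L):
                inside += w
    rec_step[n_rec] = 0
    rec_nm[n_rec] = nm
    rec_nd[n_rec] = nd
    rec_inside[n_rec] = inside
    if track_slot >= 0:
        rec_tx[n_rec] = tx
        rec_ty[n_rec] = ty
    n_rec += 1

    for t in range(1, n_ticks + 1):
        # fresh uniform random visiting order (Fisher-Yates over all slots)
        for i in range(cap):
            order[i] = i
        for i in range(cap - 1, 0, -1):
            j = np.random.randint(0, i + 1)
            tmpo = order[i]
            order[i] = order[j]
            order[j] = tmpo

        for oi in range(cap):
            i = order[oi]
            if not alive[i] or stamp[i] == t:
                continue
            sp = species[i]

            # --- 1. Brownian jump, rejected on overlap -----------------
            x = pos[i, 0]
            y = pos[i, 1]
            D = d_in if _in_domain(x, y, dom_x, dom_y, dom_r, L) else d_out
            scale = math.sqrt(D)
            if sp == INERT:
                scale *= inert_factor
            elif sp == DIMER:
                scale *= _DIMER_STEP_FACTOR
            if law_rayleigh == 1:
                u = np.random.random()
                r_step = scale * math.sqrt(-2.0 * math.log(1.0 - u))
            else:
                r_step = scale * abs(np.random.normal(0.0, 1.0))
            theta = np.random.random() * 2.0 * math.pi
            nx = _wrap1(x + r_step * math.cos(theta), L)
            ny = _wrap1(y + r_step * math.sin(theta), L)
            if not _overlap_at(nx, ny, rad[i], i, -1, pos, rad, alive,
                               head, nxt, ncell, cw, L):
                oldx = pos[i, 0]
                oldy = pos[i, 1]
                pos[i, 0] = nx
                pos[i, 1] = ny
                newc = _cell_of(nx, ny, ncell, cw)
                if newc != cellof[i]:
                    _grid_remove(i, head, nxt, cellof)
                    _grid_insert(i, nx, ny, head, nxt, cellof, ncell, cw)
                if i == track_slot:
                    tx += _mini(nx - oldx, L)
                    ty += _mini(ny - oldy, L)

            # --- 2. monomer: dimerisation attempt ----------------------
            if sp == MONOMER and k_b > 0.0:
                j = _nearest_capture(i, capture_dist, pos, rad, species,
                                     alive, head, nxt, ncell, cw, L)
                if j >= 0 and np.random.random() < k_b:
                    dx = _mini(pos[j, 0] - pos[i, 0], L)
                    dy = _mini(pos[j, 1] - pos[i, 1], L)
                    mx = _wrap1(pos[i, 0] + 0.5 * dx, L)
                    my = _wrap1(pos[i, 1] + 0.5 * dy, L)
                    if react_veto == 1 and _overlap_at(
                        mx, my, dimer_r, i, j, pos, rad, alive,
                        head, nxt, ncell, cw, L,
                    ):
                        abandoned_dim += 1
                    else:
                        _grid_remove(j, head, nxt, cellof)
                        alive[j] = False
                        _grid_remove(i, head, nxt, cellof)
                        pos[i, 0] = mx
                        pos[i, 1] = my
                        rad[i] = dimer_r
                        species[i] = DIMER
                        stamp[i] = t
                        _grid_insert(i, mx, my, head, nxt, cellof, ncell, cw)

            # --- 3. dimer: dissociation attempt ------------------------
            elif sp == DIMER and k_d > 0.0:
                if np.random.random() < k_d:
                    cx = pos[i, 0]
                    cy = pos[i, 1]
                    placed = False
                    ax = 0.0
                    ay = 0.0
                    bx = 0.0
                    by = 0.0
                    if cocentric_split == 1:
                        # both products at the dimer centre (encounter
                        # complex); always fits inside the old footprint
                        placed = True
                        ax = cx
                        ay = cy
                        bx = cx
                        by = cy
                    for _ in range(0 if placed else 20):
                        phi = np.random.random() * 2.0 * math.pi
                        ux = mono_r * math.cos(phi)
                        uy = mono_r * math.sin(phi)
                        ax = _wrap1(cx + ux, L)
                        ay = _wrap1(cy + uy, L)
                        bx = _wrap1(cx - ux, L)
                        by = _wrap1(cy - uy, L)
                        if not _overlap_at(ax, ay, mono_r, i, -1, pos, rad,
                                           alive, head, nxt, ncell, cw, L) \
                           and not _overlap_at(bx, by, mono_r, i, -1, pos, rad,
                                               alive, head, nxt, ncell, cw, L):
                            placed = True
                            break
                    if placed:
                        _grid_remove(i, head, nxt, cellof)
                        species[i] = MONOMER
                        rad[i] = mono_r
                        pos[i, 0] = ax
                        pos[i, 1] = ay
                        stamp[i] = t
                        _grid_insert(i, ax, ay, head, nxt, cellof, ncell, cw)
                        s = -1
                        for q in range(cap):
                            if not alive[q]:
                                s = q
                                break
                        alive[s] = True
                        species[s] = MONOMER
                        rad[s] = mono_r
                        pos[s, 0] = bx
                        pos[s, 1] = by
                        stamp[s] = t
                        _grid_insert(s, bx, by, head, nxt, cellof, ncell, cw)
                    else:
                        deferred_dissoc += 1

        if t % record_every == 0:
            nm = 0
            nd = 0
            inside = 0
            for i in range(cap):
                if alive[i] and species[i] != INERT:
                    if species[i] == MONOMER:
                        nm += 1
                        w = 1
                    else:
                        nd += 1
                        w = 2
                    if _in_domain(pos[i, 0], pos[i, 1], dom_x, dom_y, dom_r, L):
                        inside += w
            if nm + 2 * nd != n_mol0:
                return n_rec, deferred_dissoc, abandoned_dim, STATUS_CONSERVATION
            rec_step[n_rec] = t
            rec_nm[n_rec] = nm
            rec_nd[n_rec] = nd
            rec_inside[n_rec] = inside
            if track_slot >= 0:
                rec_tx[n_rec] = tx
                rec_ty[n_rec] = ty
            n_rec += 1

    return n_rec, deferred_dissoc, abandoned_dim, STATUS_OK
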