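"""Simulation loop: initialisation, adaptive time stepping, events.

Each step executes, in order: contact detection, force evaluation, the
parallel overdamped update of all positions and radii, stochastic growth,
divisions, removals (junction exit, anoikis, Paneth lifespan), and
finally the internal state-vector update (Wnt/Notch activities and fate
reclassification).  Removals precede fate updates so Notch sums never
include removed cells.

The time step adapts so no cell moves more than a fixed fraction of the
minimal radius per step, and any step that would push two cells closer
than 0.2 (R_i + R_j) is rejected and retried at dt/2.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import fate as fate_mod
from . import mechanics as mech
from .bm import triangulate_surface
from .geometry import arc_length_table, crypt_radius_derivatives, surface_frame
from .params import ModelParams
from .state import (
    Cells,
    LineageState,
    PROLIFERATIVE_STATES,
    TERMINAL_STATES,
    SimState,
)

log = logging.getLogger(__name__)

__all__ = ["initialize_crypt", "adaptive_dt", "step", "simulate", "Trajectory"]

_STATE_NAMES = {
    LineageState.UNDIFFERENTIATED: "undifferentiated",
    LineageState.PANETH_PRIMED: "paneth_primed",
    LineageState.ENTEROCYTE_PROGENITOR: "enterocyte_progenitor",
    LineageState.GOBLET_PROGENITOR: "goblet_progenitor",
    LineageState.PANETH: "paneth",
    LineageState.ENTEROCYTE: "enterocyte",
    LineageState.GOBLET: "goblet",
}


@dataclass
class Trajectory:
    """Time-indexed observables of a run."""

    rows: list = field(default_factory=list)

    def record(self, state: SimState, efflux: int, anoikis: int) -> None:
        counts = np.bincount(state.cells.state, minlength=len(LineageState))
        row = {"time": state.time, "n_total": len(state.cells),
               "efflux_events": efflux, "anoikis_events": anoikis}
        for s, name in _STATE_NAMES.items():
            row[f"n_{name}"] = int(counts[s])
        self.rows.append(row)

    def to_frame(self) -> pd.DataFrame:
        cols = ["time", "n_total"] + [f"n_{n}" for n in _STATE_NAMES.values()] + [
            "efflux_events", "anoikis_events"]
        return pd.DataFrame(self.rows, columns=cols)


# ---------------------------------------------------------------------------
# initialisation
# ---------------------------------------------------------------------------

def _monolayer_positions(params: ModelParams, rng) -> tuple[np.ndarray, np.ndarray]:
    """Seed cell centres one offset radius inside the BM, base to junction."""
    shape = params.shape
    r_min = params.r_min
    spacing = 1.9 * r_min
    z_tab, s_tab = arc_length_table(shape)
    s_total = s_tab[-1]
    n_rows = max(2, int(s_total / (spacing * math.sqrt(3.0) / 2.0)))
    s_rows = (np.arange(n_rows) + 0.5) * s_total / n_rows
    # slightly inside the knot-potential minimum so even on a coarse mesh
    # every seeded cell starts with at least one interacting knot
    offset = 0.95 * params.bm.omega * r_min
    candidates = [np.array([[0.0, 0.0, -shape.z0 + offset]])]  # pole cell
    zetas = [np.array([-shape.z0])]
    for s_row, phase in zip(s_rows, rng.random(n_rows)):
        z_row = float(np.interp(s_row, s_tab, z_tab))
        r_row, dr_row, _ = crypt_radius_derivatives(z_row, shape)
        # ring count from the circumference of the *offset* ring the cell
        # centres actually occupy, one offset radius inside the surface
        w = math.sqrt(1.0 + float(dr_row) ** 2)
        rho_off = max(float(r_row) - offset / w, 0.5 * spacing / math.pi)
        n_c = max(1, int(round(2.0 * math.pi * rho_off / spacing)))
        theta = 2.0 * math.pi * ((np.arange(n_c) / n_c + phase) % 1.0)
        inward, _ = surface_frame(np.full(n_c, z_row), theta, shape)
        foot = np.column_stack(
            [r_row * np.cos(theta), r_row * np.sin(theta), np.full(n_c, z_row)]
        )
        candidates.append(foot + inward * offset)
        zetas.append(np.full(n_c, z_row))
    cand = np.vstack(candidates)
    zetas = np.concatenate(zetas)
    # the inward offset makes rings near the cap converge; greedily drop any
    # candidate that lands too close to an already accepted one
    keep: list[int] = []
    for i in range(len(cand)):
        if all(np.linalg.norm(cand[i] - cand[j]) >= 0.45 * spacing for j in keep):
            keep.append(i)
    idx = np.asarray(keep, dtype=int)
    return cand[idx], zetas[idx]


def _seed_states(z: np.ndarray, params: ModelParams, rng) -> np.ndarray:
    """Positional heuristic for the initial lineage states.

    A secretory subset is seeded at random within each zone so the first
    Notch update sees ligand-presenting neighbours; the warm-up erases
    this initial condition.
    """
    fp = params.fate
    u = rng.random(len(z))
    states = np.empty(len(z), dtype=np.int8)
    below_p = z < fp.z_p
    mid = (z >= fp.z_p) & (z < fp.z_d)
    top = z >= fp.z_d
    states[below_p] = np.where(u[below_p] < 0.45, LineageState.PANETH,
                               LineageState.UNDIFFERENTIATED)
    states[mid] = np.where(u[mid] < 0.15, LineageState.GOBLET_PROGENITOR,
                           LineageState.ENTEROCYTE_PROGENITOR)
    states[top] = np.where(u[top] < 0.15, LineageState.GOBLET,
                           LineageState.ENTEROCYTE)
    return states


def initialize_crypt(params: ModelParams, seed: int = 0) -> SimState:
    """Build a relaxed crypt: BM mesh plus a monolayer of cells on it."""
    rng = np.random.default_rng(seed)
    net = triangulate_surface(params.shape, params.bm.lambda_max, seed=seed)
    pos, z_seed = _monolayer_positions(params, rng)
    n = len(pos)
    if n < 3:
        raise ValueError("infeasible packing: crypt too small for any cells")
    v0 = params.v0
    vt = np.full(n, v0)
    radius = np.full(n, params.r_min * 0.97)
    states = _seed_states(z_seed, params, rng)
    phase = rng.random(n)  # growth-cycle staggering, applied after relaxation

    cells = Cells(
        ids=np.arange(n, dtype=np.int64),
        pos=pos,
        radius=radius,
        v_target=vt,
        state=states,
        cycling=np.zeros(n, bool),
        clone=np.full(n, -1, np.int64),
        brdu=np.zeros(n, bool),
        birth_time=np.zeros(n),
        paneth_since=np.full(n, np.nan),
        growth_clock=np.zeros(n),
        next_wait=np.full(n, np.inf),
        growth_steps=np.zeros(n, np.int16),
        draw_count=np.zeros(n, np.int64),
    )
    # stagger terminal-Paneth ages so lifespans do not expire in a wave
    paneth = states == LineageState.PANETH
    cells.paneth_since[paneth] = -rng.random(int(paneth.sum())) * 0.5 * params.fate.t_p
    state = SimState(time=0.0, cells=cells, net=net, params=params, seed=seed,
                     next_id=n)

    _relax(state)
    # stagger growth phases so divisions do not come in waves; radii follow
    # the raised target volumes through the volume-friction dynamics
    n_steps = params.fate.n_growth_steps
    for i in range(len(state.cells)):
        if LineageState(int(state.cells.state[i])) in PROLIFERATIVE_STATES:
            fate_mod.start_cycle(state, i)
            done = int(phase[i] * 0.8 * n_steps)
            state.cells.growth_steps[i] = done
            state.cells.v_target[i] = v0 * (1.0 + done / n_steps)
    return state


def _relax(state: SimState) -> None:
    """Mechanical relaxation (no growth, no migration) of the initial packing."""
    p = state.params
    ep = p.engine
    dt = ep.dt_max
    for _ in range(ep.relax_max_steps):
        c = state.cells
        res = mech.evaluate_forces(
            c.pos, c.radius, c.v_target,
            fate_mod.eps_knot_per_cell(c.state, p),
            np.zeros(len(c)), state.net, p,
        )
        vel, drad = mech.solve_motion(res, c.radius, dt, p)
        disp = np.linalg.norm(vel, axis=1) * dt
        bound = ep.displacement_fraction * p.r_min
        if disp.size and disp.max() > bound:
            scale = bound / disp.max()
        else:
            scale = 1.0
        c.pos += vel * dt * scale
        c.radius = np.clip(c.radius + drad * dt * scale, 0.5 * p.r_min, 1.8 * p.r_min)
        if disp.size == 0 or disp.max() * scale < ep.relax_tol:
            break


# ---------------------------------------------------------------------------
# stepping
# ---------------------------------------------------------------------------

def adaptive_dt(state: SimState, res: mech.Forces | None = None) -> float:
    """Time step honouring the displacement bound (rejection happens in step)."""
    p = state.params
    ep = p.engine
    c = state.cells
    if res is None:
        res = mech.evaluate_forces(
            c.pos, c.radius, c.v_target,
            fate_mod.eps_knot_per_cell(c.state, p),
            fate_mod.migration_magnitudes(c.state, p), state.net, p,
        )
    vel, drad = mech.solve_motion(res, c.radius, ep.dt_max, p)
    speed = max(
        float(np.max(np.linalg.norm(vel, axis=1), initial=0.0)),
        float(np.max(np.abs(drad), initial=0.0)),
    )
    bound = ep.displacement_fraction * p.r_min
    if speed * ep.dt_max <= bound:
        return ep.dt_max
    return max(bound / speed, ep.dt_min)


def _move(state: SimState, res: mech.Forces, dt_try: float) -> float:
    """Parallel position/radius update with overlap rejection; returns dt used."""
    p = state.params
    ep = p.engine
    c = state.cells
    bound = ep.displacement_fraction * p.r_min
    dt = dt_try
    # a pre-existing close pair (e.g. freshly placed daughters) must be able
    # to relax: only reject steps that push the closest approach below both
    # the bound and its current value
    floor = min(ep.overlap_reject, _min_separation_ratio(c.pos, c.radius) * 0.999)
    while True:
        vel, drad = mech.solve_motion(res, c.radius, dt, p)
        disp = np.linalg.norm(vel, axis=1) * dt
        if disp.size and disp.max() > bound:
            dt = max(bound / (disp.max() / dt), ep.dt_min)
            vel, drad = mech.solve_motion(res, c.radius, dt, p)
        new_pos = c.pos + vel * dt
        new_rad = np.clip(c.radius + drad * dt, 0.5 * p.r_min, 1.8 * p.r_min)
        if _min_separation_ratio(new_pos, new_rad) >= floor:
            c.pos = new_pos
            c.radius = new_rad
            return dt
        if dt <= ep.dt_min * 2.0:
            raise FloatingPointError(
                "time step underflow while avoiding cell interpenetration"
            )
        dt *= 0.5


def _min_separation_ratio(pos, rad) -> float:
    """Smallest d_ij / (R_i + R_j) over all close pairs (1.0 if none)."""
    from scipy.spatial import cKDTree

    if len(pos) < 2:
        return 1.0
    tree = cKDTree(pos)
    pairs = tree.query_pairs(r=float(2.0 * rad.max()), output_type="ndarray")
    if pairs.size == 0:
        return 1.0
    d = np.linalg.norm(pos[pairs[:, 0]] - pos[pairs[:, 1]], axis=1)
    return float(np.min(d / (rad[pairs[:, 0]] + rad[pairs[:, 1]])))


def step(state: SimState) -> float:
    """Advance the simulation by one adaptive step; returns the dt taken."""
    p = state.params
    c = state.cells
    n = len(c)
    if n == 0:
        state.time += p.engine.dt_max
        return p.engine.dt_max

    # (1-2) contacts and forces
    res = mech.evaluate_forces(
        c.pos, c.radius, c.v_target,
        fate_mod.eps_knot_per_cell(c.state, p),
        fate_mod.migration_magnitudes(c.state, p), state.net, p,
    )
    # (3) parallel overdamped motion
    dt = _move(state, res, p.engine.dt_max)
    state.time += dt

    # (4) stochastic growth (clock runs only while uninhibited)
    inhibited = fate_mod.contact_inhibited(res.v_actual, c.v_target, p.fate, p.v0)
    active = c.cycling & ~inhibited
    c.growth_clock[active] += dt
    due = np.nonzero(active & (c.growth_clock >= c.next_wait))[0]
    dividers = []
    for i in due:
        fp = p.fate
        while c.growth_clock[i] >= c.next_wait[i]:
            c.growth_clock[i] -= c.next_wait[i]
            c.v_target[i] = min(c.v_target[i] + p.v0 / fp.n_growth_steps, 2.0 * p.v0)
            c.growth_steps[i] += 1
            c.next_wait[i] = fate_mod.draw_growth_wait(
                state.seed, int(c.ids[i]), int(c.draw_count[i]), fp
            )
            c.draw_count[i] += 1
            if c.growth_steps[i] >= fp.n_growth_steps:
                dividers.append(int(c.ids[i]))
                break

    # (5) divisions (by id: the arrays are rebuilt after each division)
    for cid in dividers:
        idx = int(np.nonzero(state.cells.ids == cid)[0][0])
        state.cells.cycling[idx] = False
        fate_mod.divide(state, idx)

    # (6) removals
    c = state.cells
    if len(c):
        from .mechanics import _knot_lists

        _, _, n_knots = _knot_lists(c.pos, c.radius, state.net)
        age = state.time - c.paneth_since
        expired = (
            (c.state == LineageState.PANETH)
            & np.isfinite(c.paneth_since)
            & (age > p.fate.t_p)
        )
        junction = c.pos[:, 2] > 0.0
        anoikis = (n_knots == 0) & ~junction
        remove = junction | anoikis | expired
        if np.any(remove):
            for i in np.nonzero(remove)[0]:
                cause = ("junction_exit" if junction[i]
                         else "anoikis" if anoikis[i] else "paneth_lifespan")
                state.log_event("removal", cell=int(c.ids[i]), cause=cause,
                                state=int(c.state[i]), z=float(c.pos[i, 2]))
            state.cells = c.keep(~remove)
            c = state.cells

    # (7) internal state vector and fate reclassification
    if len(c):
        _update_fates(state)
    state.step_count += 1
    return dt


def _update_fates(state: SimState) -> None:
    """Sequential state-vector update in a seeded random order.

    Each cell is reclassified against the *current* states of its contact
    neighbours, so a pair of mutually uninhibited cells resolves into a
    stable ligand-presenter/receiver arrangement instead of oscillating
    (the synchronous-update artefact of lateral-inhibition rules).
    """
    p = state.params
    c = state.cells
    n = len(c)
    pairs = mech._pair_lists(c.pos, c.radius)
    neighbours: list[list[int]] = [[] for _ in range(n)]
    for a, b in pairs:
        neighbours[a].append(b)
        neighbours[b].append(a)
    i_wnt = np.atleast_1d(
        fate_mod.effective_wnt(
            fate_mod.wnt_activity(c.pos[:, 2].clip(-p.shape.z0, 0.0), p.shape), p
        )
    )
    lp = fate_mod.lp_weights(p.fate)
    tp_wnt, td_wnt = fate_mod.wnt_thresholds(p)
    fp = p.fate
    terminal_codes = {int(s) for s in TERMINAL_STATES}

    for i in state.update_permutation(n):
        s_cur = int(c.state[i])
        if s_cur in terminal_codes:
            continue
        i_notch = float(
            fate_mod.effective_notch(
                float(sum(lp[c.state[j]] for j in neighbours[i])), p
            )
        )
        if i_wnt[i] >= tp_wnt:
            tgt = (LineageState.UNDIFFERENTIATED if i_notch >= fp.tp_notch
                   else LineageState.PANETH_PRIMED)
        elif i_wnt[i] >= td_wnt:
            tgt = (LineageState.ENTEROCYTE_PROGENITOR if i_notch >= fp.tp_notch
                   else LineageState.GOBLET_PROGENITOR)
        else:
            tgt = (LineageState.ENTEROCYTE if i_notch >= fp.td_notch
                   else LineageState.GOBLET)
        if int(tgt) == s_cur:
            continue
        # terminal transitions wait for the running cycle to finish
        if int(tgt) in terminal_codes and c.cycling[i]:
            continue
        state.log_event("transition", cell=int(c.ids[i]), src=s_cur, dst=int(tgt))
        c.state[i] = int(tgt)
        if tgt in (LineageState.GOBLET, LineageState.ENTEROCYTE):
            c.cycling[i] = False

    # Paneth-primed cells terminally differentiate once not cycling
    to_paneth = (c.state == LineageState.PANETH_PRIMED) & ~c.cycling
    for i in np.nonzero(to_paneth)[0]:
        state.log_event("transition", cell=int(c.ids[i]),
                        src=int(LineageState.PANETH_PRIMED), dst=int(LineageState.PANETH))
        c.state[i] = LineageState.PANETH
        c.paneth_since[i] = state.time

    # proliferative, idle cells start a new cycle
    prolif_codes = np.array(sorted(int(s) for s in PROLIFERATIVE_STATES))
    idle = np.isin(c.state, prolif_codes) & ~c.cycling
    for i in np.nonzero(idle)[0]:
        fate_mod.start_cycle(state, i)


def simulate(state: SimState, duration: float, observer_interval: float = 1.0,
             observers=()) -> pd.DataFrame:
    """Advance ``duration`` hours, sampling the trajectory at a fixed cadence.

    Returns the trajectory table (one row per sample: time, counts per
    lineage, total, cumulative efflux and anoikis event counts).
    """
    if duration < 0:
        raise ValueError("duration must be non-negative")
    traj = Trajectory()
    if duration == 0:
        return traj.to_frame()
    t_end = state.time + duration
    counters = _event_counters(state)
    traj.record(state, *counters)
    next_sample = state.time + observer_interval
    while state.time < t_end - 1e-9:
        step(state)
        if state.time >= next_sample - 1e-9 or state.time >= t_end - 1e-9:
            traj.record(state, *_event_counters(state))
            for obs in observers:
                obs(state)
            while next_sample <= state.time + 1e-9:
                next_sample += observer_interval
    return traj.to_frame()


def _event_counters(state: SimState) -> tuple[int, int]:
    efflux = sum(1 for e in state.event_log
                 if e["kind"] == "removal" and e["cause"] == "junction_exit")
    anoikis = sum(1 for e in state.event_log
                  if e["kind"] == "removal" and e["cause"] == "anoikis")
    return efflux, anoikis
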