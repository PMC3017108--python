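"""Wnt/Notch signalling, the reversible lineage state machine, and the
proliferation, division and removal rules.

Wnt activity I_wnt is a monotone function of the basal-membrane Gaussian
curvature expressed along the crypt axis; the priming and differentiation
thresholds TP_wnt and TD_wnt are the activity values at the axial
positions z_p and z_d, so fate changes occur when cells cross those
positions.  Notch activity I_notch is the sum of ligand weights LP over
all neighbours in direct contact; secretory cells and their progenitors
present ligands (Paneth weakly, Goblet maximally), all others none.

The state machine: high Wnt + high Notch = undifferentiated; high Wnt +
low Notch = Paneth-primed; intermediate Wnt splits into enterocyte
(high Notch) and Goblet (low Notch) progenitors; Wnt below TD_wnt makes
the corresponding terminal fate, which is irreversible.  All transitions
among non-terminal states are allowed.  Cells prime reversibly; a
Paneth-primed cell turns terminally Paneth once its running cell cycle
(if any) completes.

Growth is a chain of ``n_growth_steps`` stochastic volume increments with
exponential waiting times, giving Gamma-distributed doubling times with
mean ``tau_growth``; increments pause while the cell is contact-inhibited
(V_a < 0.88 V_t).  Reaching twice the minimal volume triggers a division
into two equal daughters placed along a random BM-tangent direction.
"""

from __future__ import annotations

import math

import numpy as np

from .geometry import WntLink, project_to_surface, surface_frame
from .params import CryptShape, FateParams, ModelParams
from .state import (
    Cells,
    LineageState,
    PROLIFERATIVE_STATES,
    TERMINAL_STATES,
    SimState,
    stream_uniform,
)

__all__ = [
    "wnt_activity",
    "wnt_thresholds",
    "notch_activity",
    "notch_activity_all",
    "classify_fate",
    "classify_fate_array",
    "lp_weights",
    "eps_knot_per_cell",
    "migration_magnitudes",
    "contact_inhibited",
    "attempt_growth",
    "divide",
    "check_removal",
    "draw_growth_wait",
]

_LINK_CACHE: dict[tuple, WntLink] = {}


def _link(shape: CryptShape) -> WntLink:
    key = (shape.z0, shape.r0, shape.lambda1, shape.lambda2)
    if key not in _LINK_CACHE:
        _LINK_CACHE[key] = WntLink(shape)
    return _LINK_CACHE[key]


def wnt_activity(z, shape: CryptShape):
    """Wnt pathway activity I_wnt = f(z): monotone, high at the crypt base."""
    return _link(shape)(z)


def wnt_thresholds(params: ModelParams) -> tuple[float, float]:
    """(TP_wnt, TD_wnt) = (f(z_p), f(z_d)) for the configured shape."""
    link = _link(params.shape)
    return float(link(params.fate.z_p)), float(link(params.fate.z_d))


def effective_wnt(i_wnt, params: ModelParams):
    """Wnt activity after any constitutive gain/loss-of-function override.

    ``high`` clamps activity above TP_wnt everywhere (constitutive
    activation); ``low`` clamps it below TP_wnt (but above TD_wnt where it
    was) so proliferative progenitors persist while the stem/Paneth niche
    is lost.
    """
    mode = params.fate.wnt_mode
    if mode == "normal":
        return i_wnt
    tp, td = wnt_thresholds(params)
    if mode == "high":
        return np.maximum(i_wnt, tp)
    return np.minimum(i_wnt, 0.5 * (tp + td))


def effective_notch(i_notch, params: ModelParams):
    """Notch activity after any constitutive gain/loss-of-function override."""
    mode = params.fate.notch_mode
    if mode == "normal":
        return i_notch
    if mode == "high":
        return np.maximum(i_notch, max(params.fate.tp_notch, params.fate.td_notch))
    return np.zeros_like(np.asarray(i_notch, dtype=float))


# --- Notch -----------------------------------------------------------------

def lp_weights(fp: FateParams) -> np.ndarray:
    """Ligand presentation weight LP per lineage-state code."""
    lp = np.zeros(len(LineageState))
    lp[LineageState.PANETH_PRIMED] = fp.lp_paneth
    lp[LineageState.PANETH] = fp.lp_paneth
    lp[LineageState.GOBLET_PROGENITOR] = fp.lp_goblet
    lp[LineageState.GOBLET] = fp.lp_goblet
    return lp


def notch_activity(neighbour_states, fp: FateParams) -> float:
    """I_notch of one cell: sum of LP over neighbours in direct contact."""
    lp = lp_weights(fp)
    return float(sum(lp[int(s)] for s in neighbour_states))


def notch_activity_all(states: np.ndarray, pairs: np.ndarray, fp: FateParams) -> np.ndarray:
    """Vectorised I_notch for all cells from the contact pair list."""
    lp = lp_weights(fp)
    n = len(states)
    out = np.zeros(n)
    if len(pairs):
        i_, j_ = pairs[:, 0], pairs[:, 1]
        np.add.at(out, i_, lp[states[j_]])
        np.add.at(out, j_, lp[states[i_]])
    return out


# --- classification --------------------------------------------------------

def classify_fate(i_wnt: float, i_notch: float, current: LineageState,
                  params: ModelParams) -> LineageState:
    """Target lineage state from the Wnt/Notch truth table.

    Activities exactly at a threshold count as high (>=), so a single
    Goblet contact (LP = 1.00) suffices for Notch activation.  Terminal
    current states are never re-classified.
    """
    if LineageState(current) in TERMINAL_STATES:
        raise ValueError("terminal states are never re-classified")
    tp_wnt, td_wnt = wnt_thresholds(params)
    fp = params.fate
    if i_wnt >= tp_wnt:
        return (LineageState.UNDIFFERENTIATED if i_notch >= fp.tp_notch
                else LineageState.PANETH_PRIMED)
    if i_wnt >= td_wnt:
        return (LineageState.ENTEROCYTE_PROGENITOR if i_notch >= fp.tp_notch
                else LineageState.GOBLET_PROGENITOR)
    return (LineageState.ENTEROCYTE if i_notch >= fp.td_notch
            else LineageState.GOBLET)


def classify_fate_array(i_wnt: np.ndarray, i_notch: np.ndarray,
                        params: ModelParams) -> np.ndarray:
    """Vectorised truth table (int8 codes); ignores current state."""
    tp_wnt, td_wnt = wnt_thresholds(params)
    fp = params.fate
    high_p = i_notch >= fp.tp_notch
    high_d = i_notch >= fp.td_notch
    out = np.where(
        i_wnt >= tp_wnt,
        np.where(high_p, LineageState.UNDIFFERENTIATED, LineageState.PANETH_PRIMED),
        np.where(
            i_wnt >= td_wnt,
            np.where(high_p, LineageState.ENTEROCYTE_PROGENITOR,
                     LineageState.GOBLET_PROGENITOR),
            np.where(high_d, LineageState.ENTEROCYTE, LineageState.GOBLET),
        ),
    )
    return out.astype(np.int8)


# --- per-lineage mechanics couplings ---------------------------------------

def eps_knot_per_cell(states: np.ndarray, params: ModelParams) -> np.ndarray:
    """Cell-knot interaction energy: Paneth(-primed) cells anchor strongly."""
    paneth = np.isin(states, (LineageState.PANETH_PRIMED, LineageState.PANETH))
    return np.where(paneth, params.bm.eps_knot_paneth, params.bm.eps_knot_other)


def migration_magnitudes(states: np.ndarray, params: ModelParams) -> np.ndarray:
    """Signed migration force per cell.

    Paneth-lineage cells are pulled down the crypt (-F_A_paneth); all
    other *primed* cells (progenitors and terminal enterocytes/Goblets
    still inside the crypt) actively move up (+F_A_other).
    Undifferentiated cells are not primed and are passive by default
    (f_a_undiff, normally zero).
    """
    paneth = np.isin(states, (LineageState.PANETH_PRIMED, LineageState.PANETH))
    undiff = states == LineageState.UNDIFFERENTIATED
    return np.where(
        paneth, -params.mech.f_a_paneth,
        np.where(undiff, params.mech.f_a_undiff, params.mech.f_a_other),
    )


# --- growth, division, removal ---------------------------------------------

def contact_inhibited(v_actual, v_target, fp: FateParams, v0: float):
    """True when compression pushes V_a below the threshold volume V_p.

    By default V_p = 0.88 V_0 (an absolute volume); the alternative
    ``relative`` mode compares against the cell's own target volume
    (V_a < 0.88 V_t) instead.
    """
    if fp.v_p_mode == "absolute":
        return np.asarray(v_actual) < fp.v_p_ratio * v0
    return np.asarray(v_actual) < fp.v_p_ratio * np.asarray(v_target)


def draw_growth_wait(seed: int, cell_id: int, counter: int, fp: FateParams) -> float:
    """Exponential waiting time (h of uninhibited growth) to the next increment."""
    u = stream_uniform(seed, cell_id, counter)
    scale = fp.tau_growth / fp.n_growth_steps
    return -scale * math.log(1.0 - u)


def attempt_growth(state: SimState, i: int, dt: float, inhibited: bool) -> bool:
    """Advance cell i's stochastic growth by dt; return True when division is due.

    The growth clock only accumulates while the cell is not contact
    inhibited; each elapsed waiting time adds one volume increment
    V0/n_steps to the target volume, and reaching V_t = 2 V0 triggers
    division.  Cells that are not cycling are untouched.
    """
    c = state.cells
    if not c.cycling[i] or inhibited:
        return False
    fp = state.params.fate
    v0 = state.params.v0
    c.growth_clock[i] += dt
    divide_now = False
    while c.growth_clock[i] >= c.next_wait[i]:
        c.growth_clock[i] -= c.next_wait[i]
        c.v_target[i] = min(c.v_target[i] + v0 / fp.n_growth_steps, 2.0 * v0)
        c.growth_steps[i] += 1
        c.next_wait[i] = draw_growth_wait(
            state.seed, int(c.ids[i]), int(c.draw_count[i]), fp
        )
        c.draw_count[i] += 1
        if c.growth_steps[i] >= fp.n_growth_steps:
            divide_now = True
            break
    return divide_now


def start_cycle(state: SimState, i: int) -> None:
    """Begin a new growth/division cycle for cell i."""
    c = state.cells
    c.cycling[i] = True
    c.growth_steps[i] = 0
    c.growth_clock[i] = 0.0
    c.next_wait[i] = draw_growth_wait(state.seed, int(c.ids[i]), int(c.draw_count[i]),
                                      state.params.fate)
    c.draw_count[i] += 1


def divide(state: SimState, i: int) -> tuple[int, int]:
    """Divide cell i into two equal daughters; returns their ids.

    Daughters each get target volume V0 (half the mother's 2 V0), inherit
    the mother's lineage state and clone/BrdU labels, and are placed
    symmetrically about the mother centre along a random direction in the
    local BM tangent plane, separated by one daughter radius.
    """
    c = state.cells
    v0 = state.params.v0
    if c.v_target[i] < 2.0 * v0 - 1e-9:
        raise ValueError("division of a cell that has not doubled its volume")
    shape = state.params.shape
    zeta, _, _ = project_to_surface(c.pos[i][None, :], shape)
    theta = math.atan2(c.pos[i, 1], c.pos[i, 0])
    normal, tangent = surface_frame(zeta[0], theta, shape)
    east = np.asarray(tangent, float).ravel()
    north = np.cross(np.asarray(normal, float).ravel(), east)

    u = state.draw_uniform(i)
    psi = 2.0 * math.pi * u
    direction = math.cos(psi) * east + math.sin(psi) * north

    r_child = (3.0 * v0 / (4.0 * math.pi)) ** (1.0 / 3.0)
    sep = 0.5 * r_child
    base = _daughter_arrays(state, i, direction, sep, r_child)
    ids = (state.next_id, state.next_id + 1)
    state.next_id += 2
    base.ids[:] = ids
    mother_state = int(c.state[i])
    state.cells = state.cells.keep(np.arange(len(c)) != i).concat(base)
    state.log_event("division", mother=int(c.ids[i]), daughters=list(map(int, ids)),
                    state=mother_state)
    # daughters born into a proliferative state enter their cycle at birth,
    # so a subsequent secretory priming leaves them a reversibility window
    # of one cell cycle before terminal Paneth differentiation; daughters
    # born above the differentiation threshold z_d do not start a cycle and
    # differentiate terminally at the next state update
    if LineageState(mother_state) in PROLIFERATIVE_STATES:
        _, td_wnt = wnt_thresholds(state.params)
        n_new = len(state.cells)
        for j in (n_new - 2, n_new - 1):
            zj = float(np.clip(state.cells.pos[j, 2], -shape.z0, 0.0))
            if effective_wnt(wnt_activity(zj, shape), state.params) >= td_wnt:
                start_cycle(state, j)
    return ids


def _daughter_arrays(state: SimState, i: int, direction, sep, r_child) -> Cells:
    c = state.cells
    v0 = state.params.v0
    shape = state.params.shape
    omega = state.params.bm.omega
    pos = np.vstack([c.pos[i] + sep * direction, c.pos[i] - sep * direction])
    # place each daughter at its own equilibrium height above the membrane so
    # both retain BM contact (the mother, being larger, sat further out)
    zeta, _, _ = project_to_surface(pos, shape)
    theta = np.arctan2(pos[:, 1], pos[:, 0])
    from .geometry import crypt_radius_derivatives

    r_foot, _, _ = crypt_radius_derivatives(zeta, shape)
    foot = np.column_stack([r_foot * np.cos(theta), r_foot * np.sin(theta), zeta])
    inward, _ = surface_frame(zeta, theta, shape)
    pos = foot + inward * (0.98 * omega * r_child)
    two = lambda x, dtype=None: np.array([x, x], dtype=dtype)  # noqa: E731
    return Cells(
        ids=two(0, np.int64),
        pos=pos,
        radius=two(r_child, float),
        v_target=two(v0, float),
        state=two(c.state[i], np.int8),
        cycling=two(False, bool),
        clone=two(c.clone[i], np.int64),
        brdu=two(c.brdu[i], bool),
        birth_time=two(state.time, float),
        paneth_since=two(np.nan, float),
        growth_clock=two(0.0, float),
        next_wait=two(np.inf, float),
        growth_steps=two(0, np.int16),
        draw_count=two(0, np.int64),
    )


def check_removal(state: SimState, i: int, n_knots: int) -> str:
    """Removal verdict for cell i.

    Returns one of ``keep``, ``junction_exit`` (crossed the crypt-villus
    junction z > 0), ``anoikis`` (no interacting BM knot), or
    ``paneth_lifespan`` (terminal Paneth older than t_P).
    """
    c = state.cells
    if c.pos[i, 2] > 0.0:
        return "junction_exit"
    if n_knots == 0:
        return "anoikis"
    if (
        c.state[i] == LineageState.PANETH
        and np.isfinite(c.paneth_since[i])
        and state.time - c.paneth_since[i] > state.params.fate.t_p
    ):
        return "paneth_lifespan"
    return "keep"
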