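"""Virtual experiments on simulated crypts and their statistics.

Implements the in-silico counterparts of the classic crypt assays:
positional scoring of half-crypt sections, the BrdU pulse-chase labelling
experiment, clonal labelling with conversion to monoclonality, constitutive
gain/loss of Wnt/Notch function, instantaneous ablation of cell
subpopulations with recovery analysis, steady-state turnover statistics,
and config-driven parameter sweeps.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from . import engine
from .geometry import arc_length_table, project_to_surface
from .params import ModelParams
from .state import LineageState, PROLIFERATIVE_STATES, SimState

__all__ = [
    "PositionalProfile",
    "CloneRecord",
    "virtual_section",
    "brdu_assay",
    "clonal_conversion_experiment",
    "double_exponential_fit",
    "apply_perturbation",
    "ablate",
    "ablation_experiment",
    "steady_state_metrics",
    "parameter_sweep",
]

PERTURBATION_KINDS = ("WNT_UP", "WNT_DOWN", "NOTCH_UP", "NOTCH_DOWN")


@dataclass
class PositionalProfile:
    """Fraction of cells positive for a marker at each cell position.

    Position 1 is the cell at the crypt base of a half-crypt column.
    """

    fractions: np.ndarray       # (n_positions,) in [0, 1]
    counts: np.ndarray          # (n_positions,) cells scored per position
    n_halfcrypts: int

    @property
    def centre_of_mass(self) -> float:
        w = self.fractions * self.counts
        if w.sum() == 0:
            return 0.0
        pos = np.arange(1, len(self.fractions) + 1)
        return float((pos * w).sum() / w.sum())


@dataclass
class CloneRecord:
    """History of one clone from labelling to extinction (or censoring)."""

    label: int
    founder_z: float
    founder_position: int
    founder_state: int
    extinction_time: float | None = None   # h after labelling; None = censored
    sizes: list = field(default_factory=list)  # (time, size) samples

    @property
    def survived(self) -> bool:
        return self.extinction_time is None


# ---------------------------------------------------------------------------
# sectioning
# ---------------------------------------------------------------------------

def virtual_section(state: SimState, thickness: float | None = None,
                    azimuth: float = 0.0):
    """Cells inside a planar slab through the crypt axis, as two half-crypts.

    Returns ``(half_a, half_b)``: index arrays into ``state.cells``, each
    ordered by meridian arc position from the crypt base (positional index
    = 1 + rank).  The slab has the configured section thickness and passes
    through the axis at the given azimuth.
    """
    if thickness is None:
        thickness = state.params.fate.t_section
    if thickness <= 0:
        raise ValueError("section thickness must be positive")
    c = state.cells
    if len(c) == 0:
        return np.empty(0, np.int64), np.empty(0, np.int64)
    normal = np.array([-math.sin(azimuth), math.cos(azimuth), 0.0])
    inplane = np.array([math.cos(azimuth), math.sin(azimuth), 0.0])
    off_axis = c.pos @ normal
    side = c.pos @ inplane
    in_slab = np.abs(off_axis) <= 0.5 * thickness
    z_tab, s_tab = arc_length_table(state.params.shape)
    zeta, _, _ = project_to_surface(c.pos, state.params.shape)
    s = np.interp(zeta, z_tab, s_tab)
    halves = []
    for sign in (1.0, -1.0):
        idx = np.nonzero(in_slab & (np.sign(side) == sign))[0]
        halves.append(idx[np.argsort(s[idx], kind="stable")])
    return halves[0], halves[1]


def _profiles_from_state(state: SimState, marker: np.ndarray, azimuths,
                         max_pos: int = 40) -> PositionalProfile:
    pos_count = np.zeros(max_pos)
    pos_hits = np.zeros(max_pos)
    n_half = 0
    for az in azimuths:
        for half in virtual_section(state, azimuth=az):
            if len(half) == 0:
                continue
            n_half += 1
            for rank, i in enumerate(half[:max_pos]):
                pos_count[rank] += 1
                pos_hits[rank] += bool(marker[i])
    with np.errstate(invalid="ignore"):
        frac = np.where(pos_count > 0, pos_hits / np.maximum(pos_count, 1), 0.0)
    used = int(np.max(np.nonzero(pos_count)[0])) + 1 if pos_count.any() else 0
    return PositionalProfile(frac[:used], pos_count[:used], n_half)


# ---------------------------------------------------------------------------
# BrdU pulse-chase
# ---------------------------------------------------------------------------

def brdu_assay(state: SimState, sample_times=(2.0, 24.0), n_halfcrypts: int = 50,
               label_fraction: float | None = None, seed: int = 0):
    """Virtual BrdU pulse-chase: label, chase, score positional profiles.

    At t = 0 every proliferating (cycling) cell is labelled independently
    with the configured probability; the label is inherited by the entire
    progeny.  The crypt is then simulated forward and positional label
    profiles are scored on half-crypt sections at each sample time.
    Returns ``{time: PositionalProfile}``.  The input state is not
    modified.
    """
    if label_fraction is None:
        label_fraction = state.params.fate.brdu_label_fraction
    work = state.copy()
    rng = np.random.default_rng(seed)
    prolif_codes = [int(s) for s in PROLIFERATIVE_STATES]
    eligible = work.cells.cycling & np.isin(work.cells.state, prolif_codes)
    work.cells.brdu = eligible & (rng.random(len(work.cells)) < label_fraction)
    azimuths = np.linspace(0.0, math.pi, max(1, n_halfcrypts // 2), endpoint=False)
    out = {}
    t0 = work.time
    for t_s in sorted(sample_times):
        engine.simulate(work, duration=t0 + t_s - work.time,
                        observer_interval=max(t_s, 1.0))
        out[t_s] = _profiles_from_state(work, work.cells.brdu, azimuths)
    return out


# ---------------------------------------------------------------------------
# clonal dynamics
# ---------------------------------------------------------------------------

def clonal_conversion_experiment(state: SimState, duration: float,
                                 sample_interval: float = 12.0):
    """Label every cell with a unique heritable clone marker and chase.

    Returns ``(records, counts, fit)`` where ``records`` is a list of
    :class:`CloneRecord`, ``counts`` a DataFrame (time, n_clones) and
    ``fit`` the double-exponential fit (tau1, tau2) of the clone-count
    decay, or None when the fit does not converge.
    """
    work = state.copy()
    c = work.cells
    labels = c.ids.copy()
    c.clone = labels.copy()
    z_tab, s_tab = arc_length_table(work.params.shape)
    zeta, _, _ = project_to_surface(c.pos, work.params.shape)
    s = np.interp(zeta, z_tab, s_tab)
    spacing = 2.0 * work.params.r_min * 0.9
    records = {
        int(lab): CloneRecord(
            label=int(lab),
            founder_z=float(c.pos[i, 2]),
            founder_position=int(s[i] // spacing) + 1,
            founder_state=int(c.state[i]),
        )
        for i, lab in enumerate(labels)
    }
    times, ncl = [0.0], [len(np.unique(labels))]
    t0 = work.time
    known_extinct: set[int] = set()
    while work.time - t0 < duration - 1e-9:
        engine.simulate(work, duration=min(sample_interval, duration - (work.time - t0)),
                        observer_interval=sample_interval)
        t_rel = work.time - t0
        alive = set(int(x) for x in np.unique(work.cells.clone))
        for lab, rec in records.items():
            if lab not in alive and lab not in known_extinct:
                rec.extinction_time = t_rel
                known_extinct.add(lab)
            elif lab in alive:
                rec.sizes.append((t_rel, int((work.cells.clone == lab).sum())))
        times.append(t_rel)
        ncl.append(len(alive))
    counts = pd.DataFrame({"time": times, "n_clones": ncl})
    fit = double_exponential_fit(counts.time.to_numpy(), counts.n_clones.to_numpy())
    return list(records.values()), counts, fit


def double_exponential_fit(t, n):
    """Least-squares fit of N(t) = A1 exp(-t/tau1) + A2 exp(-t/tau2).

    Returns ``(tau1, tau2, a1, a2)`` with tau1 <= tau2, or None when the
    fit fails to converge (e.g. on a too-short series).
    """
    t = np.asarray(t, dtype=float)
    n = np.asarray(n, dtype=float)

    def model(t, a1, tau1, a2, tau2):
        return a1 * np.exp(-t / tau1) + a2 * np.exp(-t / tau2)

    span = max(t.max() - t.min(), 1.0)
    p0 = (0.8 * n[0], span / 10.0, 0.2 * n[0], span / 2.0)
    try:
        popt, _ = curve_fit(
            model, t, n, p0=p0,
            bounds=(0.0, [10 * n[0], 100 * span, 10 * n[0], 100 * span]),
            maxfev=20000,
        )
    except (RuntimeError, ValueError):
        return None
    a1, tau1, a2, tau2 = popt
    if tau1 > tau2:
        a1, tau1, a2, tau2 = a2, tau2, a1, tau1
    return float(tau1), float(tau2), float(a1), float(a2)


# ---------------------------------------------------------------------------
# gain / loss of function and ablation
# ---------------------------------------------------------------------------

def apply_perturbation(state: SimState, kind: str) -> SimState:
    """Return a copy of the state with a constitutive signalling override.

    WNT_UP forces Wnt activity above TP_wnt in every cell; WNT_DOWN keeps
    it below TP_wnt everywhere (progenitor levels); NOTCH_UP fixes Notch
    activity at threshold in every cell; NOTCH_DOWN blocks Notch entirely.
    The fate rules themselves are unchanged.
    """
    if kind not in PERTURBATION_KINDS:
        raise ValueError(f"unknown perturbation {kind!r}")
    mods = {
        "WNT_UP": {"wnt_mode": "high"},
        "WNT_DOWN": {"wnt_mode": "low"},
        "NOTCH_UP": {"notch_mode": "high"},
        "NOTCH_DOWN": {"notch_mode": "zero"},
    }[kind]
    out = state.copy()
    out.params = replace(state.params, fate=replace(state.params.fate, **mods))
    return out


def _lineage_codes(lineages):
    return [int(LineageState[s]) if isinstance(s, str) else int(LineageState(s))
            for s in lineages]


def ablate(state: SimState, lineages) -> SimState:
    """Instantaneously remove every cell of the given lineage states."""
    codes = _lineage_codes(lineages)
    out = state.copy()
    doomed = np.isin(out.cells.state, codes)
    for i in np.nonzero(doomed)[0]:
        out.log_event("removal", cell=int(out.cells.ids[i]), cause="ablation",
                      state=int(out.cells.state[i]), z=float(out.cells.pos[i, 2]))
    out.cells = out.cells.keep(~doomed)
    return out


def ablation_experiment(state: SimState, lineages, duration: float,
                        band: float = 0.2, hold: float = 24.0,
                        observer_interval: float = 4.0):
    """Ablate a subpopulation and measure the recovery of its census.

    Recovery time = first time the ablated lineage-set count re-enters
    ±``band`` of its pre-ablation value and stays there for ``hold``
    hours.  Returns a dict with the recovery time (h, or None), the
    trajectory, and the number of de-differentiation events
    (enterocyte progenitor -> undifferentiated) during recovery.
    """
    codes = _lineage_codes(lineages)
    baseline = int(np.isin(state.cells.state, codes).sum())
    work = ablate(state, lineages)
    n_events_before = len(work.event_log)
    traj = engine.simulate(work, duration, observer_interval=observer_interval)
    cols = [f"n_{engine._STATE_NAMES[LineageState(c)]}" for c in codes]
    series = traj[cols].sum(axis=1).to_numpy()
    t = traj.time.to_numpy() - traj.time.iloc[0]
    in_band = np.abs(series - baseline) <= band * max(baseline, 1)
    recovery = None
    for k in range(len(t)):
        window = (t >= t[k]) & (t <= t[k] + hold)
        if t[k] + hold > t[-1] + 1e-9:
            break  # not enough trailing data to certify persistence
        if in_band[k] and np.all(in_band[window]):
            recovery = float(t[k])
            break
    dediff = sum(
        1 for e in work.event_log[n_events_before:]
        if e["kind"] == "transition"
        and e["src"] == int(LineageState.ENTEROCYTE_PROGENITOR)
        and e["dst"] == int(LineageState.UNDIFFERENTIATED)
    )
    return {
        "baseline": baseline,
        "recovery_time_h": recovery,
        "dedifferentiation_events": dediff,
        "trajectory": traj,
        "state": work,
    }


# ---------------------------------------------------------------------------
# steady-state statistics
# ---------------------------------------------------------------------------

def steady_state_metrics(traj: pd.DataFrame, event_log, window: tuple[float, float],
                         final_state: SimState | None = None) -> dict:
    """Summary statistics of a steady-state window of a trajectory.

    ``window`` is (t_start, t_end) in simulation hours.  Turnover time is
    the mean crypt cell number divided by the mean cell-removal rate
    (junction exits + anoikis); the apoptosis rate is anoikis events per
    day as a percentage of the mean cell number.  Division-interval
    statistics cover cells that divided while undifferentiated; the
    censored quiescent fraction uses cells still alive at the end of the
    window.
    """
    t0, t1 = window
    if t1 - t0 < 48.0:
        raise ValueError("steady-state window must span at least 2 days")
    w = traj[(traj.time >= t0) & (traj.time <= t1)]
    if len(w) < 2:
        raise ValueError("trajectory does not cover the requested window")
    days = (t1 - t0) / 24.0
    mean_counts = {
        col: float(w[col].mean()) for col in w.columns if col.startswith("n_")
    }
    removals = [e for e in event_log
                if e["kind"] == "removal" and t0 <= e["time"] <= t1
                and e["cause"] in ("junction_exit", "anoikis")]
    anoikis = [e for e in removals if e["cause"] == "anoikis"]
    removal_rate = len(removals) / days
    mean_n = mean_counts["n_total"]
    turnover_days = mean_n / removal_rate if removal_rate > 0 else math.inf
    anoikis_pct_per_day = 100.0 * (len(anoikis) / days) / mean_n if mean_n else 0.0

    # inter-division intervals of undifferentiated cells
    birth: dict[int, float] = {}
    intervals = []
    for e in event_log:
        if e["kind"] != "division":
            continue
        for d in e["daughters"]:
            birth[d] = e["time"]
        if e["state"] == int(LineageState.UNDIFFERENTIATED) and e["mother"] in birth:
            b = birth[e["mother"]]
            if b >= t0 and e["time"] <= t1:
                intervals.append(e["time"] - b)
    intervals = np.asarray(intervals)
    frac_48h = float((intervals < 48.0).mean()) if intervals.size else math.nan
    quiescent_frac = math.nan
    if final_state is not None:
        und = final_state.cells.state == int(LineageState.UNDIFFERENTIATED)
        ages = final_state.time - final_state.cells.birth_time[und]
        observed = np.concatenate([intervals, ages[ages >= 0]])
        if observed.size:
            quiescent_frac = float((observed > 168.0).mean())

    # de-differentiation rate per enterocyte-progenitor-day
    dediff = sum(
        1 for e in event_log
        if e["kind"] == "transition" and t0 <= e["time"] <= t1
        and e["src"] == int(LineageState.ENTEROCYTE_PROGENITOR)
        and e["dst"] == int(LineageState.UNDIFFERENTIATED)
    )
    prog_days = float(w["n_enterocyte_progenitor"].mean()) * days
    dediff_rate = dediff / prog_days if prog_days > 0 else math.nan

    return {
        **mean_counts,
        "paneth_compartment": (
            mean_counts["n_undifferentiated"] + mean_counts["n_paneth_primed"]
            + mean_counts["n_paneth"]
        ),
        "removal_rate_per_day": removal_rate,
        "turnover_days": turnover_days,
        "anoikis_pct_per_day": anoikis_pct_per_day,
        "division_intervals_h": intervals,
        "frac_divide_within_48h": frac_48h,
        "frac_quiescent_over_1wk": quiescent_frac,
        "dedifferentiation_per_progenitor_day": dediff_rate,
    }


# ---------------------------------------------------------------------------
# parameter sweeps
# ---------------------------------------------------------------------------

def _set_by_path(params: ModelParams, path: str, value) -> ModelParams:
    parts = path.split(".")
    if len(parts) == 1:
        return replace(params, **{parts[0]: value})
    if len(parts) == 2:
        group = getattr(params, parts[0])
        if not hasattr(group, parts[1]):
            raise ValueError(f"unknown parameter {path!r}")
        return replace(params, **{parts[0]: replace(group, **{parts[1]: value})})
    raise ValueError(f"unknown parameter {path!r}")


def parameter_sweep(base: ModelParams, param: str, values, replicates: int = 1,
                    seed: int = 0, warmup: float = 120.0, window: float = 120.0):
    """Run replicate simulations across a parameter range.

    ``param`` is a dotted path into :class:`ModelParams` (e.g.
    ``fate.lp_paneth``).  Each run initialises a crypt, discards the
    warm-up, measures the window, and reports lineage counts and turnover.
    Returns a tidy DataFrame with one row per (value, replicate).
    """
    rows = []
    for value in values:
        p = _set_by_path(base, param, value)
        for rep in range(replicates):
            run_seed = (seed * 1009 + rep) % (2**31)
            st = engine.initialize_crypt(p, seed=run_seed)
            traj = engine.simulate(st, warmup + window, observer_interval=6.0)
            m = steady_state_metrics(traj, st.event_log, (warmup, warmup + window),
                                     final_state=st)
            rows.append({
                "param": param, "value": value, "replicate": rep,
                "n_total": m["n_total"],
                "paneth_compartment": m["paneth_compartment"],
                "n_paneth": m["n_paneth"],
                "n_undifferentiated": m["n_undifferentiated"],
                "turnover_days": m["turnover_days"],
                "anoikis_pct_per_day": m["anoikis_pct_per_day"],
            })
    return pd.DataFrame(rows)
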