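"""Simulation state: cell arrays, the BM network, clock and event log.

Cells are stored as structure-of-arrays for vectorised mechanics; a
lightweight :class:`Cell` view exposes one cell's fields by name.  The
state serialises to a single ``.npz`` container and is bit-reproducible
under a fixed seed: per-cell stochastic draws use counter-based Philox
streams keyed by (master seed, cell id, draw counter), so results do not
depend on iteration order and replay exactly from a checkpoint.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from enum import IntEnum

import numpy as np

from .bm import BMNetwork, triangulate_surface
from .params import ModelParams, params_from_dict, params_to_dict


class LineageState(IntEnum):
    """Lineage states of the reversible specification model.

    Transitions among the first five (non-terminal) states are free;
    transitions into the terminal subset {PANETH, ENTEROCYTE, GOBLET}
    are irreversible.
    """

    UNDIFFERENTIATED = 0
    PANETH_PRIMED = 1
    ENTEROCYTE_PROGENITOR = 2
    GOBLET_PROGENITOR = 3
    PANETH = 4
    ENTEROCYTE = 5
    GOBLET = 6


TERMINAL_STATES = frozenset(
    {LineageState.PANETH, LineageState.ENTEROCYTE, LineageState.GOBLET}
)
#: states allowed to start a new growth/division cycle
PROLIFERATIVE_STATES = frozenset(
    {LineageState.UNDIFFERENTIATED, LineageState.ENTEROCYTE_PROGENITOR}
)
#: secretory lineage states (progenitors present Notch ligands too)
SECRETORY_STATES = frozenset(
    {
        LineageState.PANETH_PRIMED,
        LineageState.PANETH,
        LineageState.GOBLET_PROGENITOR,
        LineageState.GOBLET,
    }
)

_ARRAY_FIELDS = (
    "ids", "pos", "radius", "v_target", "state", "cycling", "clone", "brdu",
    "birth_time", "paneth_since", "growth_clock", "next_wait", "growth_steps",
    "draw_count",
)


@dataclass
class Cells:
    """Structure-of-arrays container for all living cells."""

    ids: np.ndarray           # int64, unique, never reused
    pos: np.ndarray           # (N, 3) µm
    radius: np.ndarray        # µm
    v_target: np.ndarray      # µm³, in [V0, 2 V0]
    state: np.ndarray         # int8 LineageState codes
    cycling: np.ndarray       # bool: a growth/division cycle is under way
    clone: np.ndarray         # int64 clonal label (-1 = unlabelled)
    brdu: np.ndarray          # bool BrdU label
    birth_time: np.ndarray    # h
    paneth_since: np.ndarray  # h at terminal Paneth differentiation (nan else)
    growth_clock: np.ndarray  # accumulated uninhibited growth time, h
    next_wait: np.ndarray     # growth-clock time of the next stochastic step, h
    growth_steps: np.ndarray  # int16 completed increments this cycle
    draw_count: np.ndarray    # int64 per-cell stochastic draw counter

    def __len__(self) -> int:
        return len(self.ids)

    @classmethod
    def empty(cls) -> "Cells":
        return cls(
            ids=np.empty(0, np.int64),
            pos=np.empty((0, 3), float),
            radius=np.empty(0, float),
            v_target=np.empty(0, float),
            state=np.empty(0, np.int8),
            cycling=np.empty(0, bool),
            clone=np.empty(0, np.int64),
            brdu=np.empty(0, bool),
            birth_time=np.empty(0, float),
            paneth_since=np.empty(0, float),
            growth_clock=np.empty(0, float),
            next_wait=np.empty(0, float),
            growth_steps=np.empty(0, np.int16),
            draw_count=np.empty(0, np.int64),
        )

    def keep(self, mask_or_index) -> "Cells":
        return Cells(**{f: getattr(self, f)[mask_or_index] for f in _ARRAY_FIELDS})

    def concat(self, other: "Cells") -> "Cells":
        return Cells(
            **{
                f: np.concatenate([getattr(self, f), getattr(other, f)])
                for f in _ARRAY_FIELDS
            }
        )


@dataclass
class Cell:
    """Read-only view of a single cell (testing/inspection convenience)."""

    id: int
    position: np.ndarray
    radius: float
    v_target: float
    lineage_state: LineageState
    cycling: bool
    clone_label: int
    brdu_label: bool
    birth_time: float

    @classmethod
    def from_arrays(cls, cells: Cells, i: int) -> "Cell":
        return cls(
            id=int(cells.ids[i]),
            position=cells.pos[i].copy(),
            radius=float(cells.radius[i]),
            v_target=float(cells.v_target[i]),
            lineage_state=LineageState(int(cells.state[i])),
            cycling=bool(cells.cycling[i]),
            clone_label=int(cells.clone[i]),
            brdu_label=bool(cells.brdu[i]),
            birth_time=float(cells.birth_time[i]),
        )


@dataclass
class SimState:
    """Complete simulation state: cells + network + clock + RNG bookkeeping."""

    time: float
    cells: Cells
    net: BMNetwork
    params: ModelParams
    seed: int
    next_id: int
    step_count: int = 0
    event_log: list = field(default_factory=list)

    def log_event(self, kind: str, **info) -> None:
        self.event_log.append({"time": self.time, "kind": kind, **info})

    # --- per-cell counter-based stochastic streams ---
    def draw_uniform(self, i: int) -> float:
        """One U(0,1) draw from cell i's Philox stream (order-independent)."""
        u = stream_uniform(self.seed, int(self.cells.ids[i]), int(self.cells.draw_count[i]))
        self.cells.draw_count[i] += 1
        return u

    def copy(self) -> "SimState":
        return SimState(
            time=self.time,
            cells=self.cells.keep(slice(None)),
            net=self.net,
            params=self.params,
            seed=self.seed,
            next_id=self.next_id,
            step_count=self.step_count,
            event_log=list(self.event_log),
        )

    def update_permutation(self, n: int) -> np.ndarray:
        """Seeded random order for the sequential fate pass of this step."""
        bg = np.random.Philox(
            key=np.array([self.seed & 0x7FFFFFFF, 0xFA7E], dtype=np.uint64),
            counter=np.array([self.step_count, 1, 0, 0], dtype=np.uint64),
        )
        return np.random.Generator(bg).permutation(n)


def stream_uniform(seed: int, cell_id: int, counter: int) -> float:
    """Deterministic U(0,1) from a Philox stream keyed by (seed, cell id)."""
    bg = np.random.Philox(
        key=np.array([seed & 0x7FFFFFFF, cell_id], dtype=np.uint64),
        counter=np.array([counter, 0, 0, 0], dtype=np.uint64),
    )
    return float(np.random.Generator(bg).random())


def save_state(state: SimState, path) -> None:
    """Write the state to a single-file binary (.npz) checkpoint."""
    meta = {
        "time": state.time,
        "seed": state.seed,
        "next_id": state.next_id,
        "step_count": state.step_count,
        "params": params_to_dict(state.params),
        "lambda_max": state.net.lambda_max,
        "mesh_seed": getattr(state.net, "mesh_seed", 0),
        "event_log": state.event_log,
    }
    arrays = {f: getattr(state.cells, f) for f in _ARRAY_FIELDS}
    np.savez_compressed(path, meta=json.dumps(meta), **arrays)


def load_state(path) -> SimState:
    """Reload a checkpoint written by :func:`save_state`.

    The BM network is rebuilt deterministically from its stored shape,
    mesh size and seed (it is static during a run).
    """
    data = np.load(path, allow_pickle=False)
    meta = json.loads(str(data["meta"]))
    params = params_from_dict(ModelParams, meta["params"])
    net = triangulate_surface(params.shape, meta["lambda_max"], seed=meta["mesh_seed"])
    net.mesh_seed = meta["mesh_seed"]
    cells = Cells(**{f: data[f] for f in _ARRAY_FIELDS})
    return SimState(
        time=float(meta["time"]),
        cells=cells,
        net=net,
        params=params,
        seed=int(meta["seed"]),
        next_id=int(meta["next_id"]),
        step_count=int(meta.get("step_count", 0)),
        event_log=list(meta["event_log"]),
    )
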