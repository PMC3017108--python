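"""Small deterministic fixtures for tests and examples.

``mini_crypt`` is a half-size crypt (z0 = 75 µm, r0 = 30 µm, coarse mesh
at lambda_max = 2.5 µm).  Its fate-threshold positions sit at the same
absolute Gaussian-curvature landmarks as in the reference crypt (~4e-4/µm²
for priming, ~0 for terminal differentiation), which for the half-size
shape is z_p = -50 µm and z_d = -35 µm.  ``two_cell`` and
``five_cell`` are BM-free mechanics fixtures (the network is present but
far out of interaction range).
"""

from __future__ import annotations

import numpy as np

from .bm import BMNetwork
from .engine import initialize_crypt
from .params import CryptShape, FateParams, ModelParams
from .state import Cells, LineageState, SimState

__all__ = ["make_fixture", "mini_crypt_params"]


def mini_crypt_params() -> ModelParams:
    """Parameters of the reduced test crypt (fast to simulate)."""
    p = ModelParams(
        shape=CryptShape(z0=75.0, r0=30.0),
        fate=FateParams(z_p=-50.0, z_d=-35.0),
    )
    p.bm.lambda_max = 2.5
    return p


def _free_cells(n: int, seed: int, params: ModelParams) -> SimState:
    """Cells floating mid-lumen, out of range of any BM knot."""
    rng = np.random.default_rng(seed)
    spacing = 1.85 * params.r_min
    pos = np.zeros((n, 3))
    pos[:, 0] = np.arange(n) * spacing
    pos += rng.normal(0.0, 0.05, pos.shape)
    pos[:, 2] -= 0.5 * params.shape.z0
    v0 = params.v0
    cells = Cells(
        ids=np.arange(n, dtype=np.int64),
        pos=pos,
        radius=np.full(n, params.r_min),
        v_target=np.full(n, v0),
        state=np.full(n, LineageState.ENTEROCYTE_PROGENITOR, np.int8),
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
    # a token far-away network: present, but no cell can interact with it
    far = 50.0 * params.shape.r0
    knots = np.array(
        [[far, 0.0, -1.0], [0.0, far, -1.0], [far, far, -1.0]]
    )
    net = BMNetwork(
        knots=knots,
        triangles=np.array([[0, 1, 2]]),
        lambda_max=params.bm.lambda_max,
        knot_z=knots[:, 2],
        knot_normals=np.tile([0.0, 0.0, 1.0], (3, 1)),
        shape=params.shape,
        mesh_seed=seed,
    )
    return SimState(time=0.0, cells=cells, net=net, params=params, seed=seed,
                    next_id=n)


def make_fixture(kind: str, seed: int = 0) -> SimState:
    """Build a deterministic test fixture: two_cell, five_cell or mini_crypt."""
    if kind == "two_cell":
        return _free_cells(2, seed, mini_crypt_params())
    if kind == "five_cell":
        st = _free_cells(5, seed, mini_crypt_params())
        # pull into a loose cluster so every pair has a realistic contact graph
        centre = st.cells.pos.mean(axis=0)
        st.cells.pos = centre + 0.55 * (st.cells.pos - centre)
        return st
    if kind == "mini_crypt":
        return initialize_crypt(mini_crypt_params(), seed=seed)
    raise ValueError(f"unknown fixture kind {kind!r}")
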