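"""Built-in invariant checks (exposed through the ``validate`` subcommand)."""

from __future__ import annotations

import numpy as np

from . import mechanics as mech
from .bm import triangle_inradii, triangulate_surface
from .fixtures import make_fixture, mini_crypt_params


def run_invariant_checks(seed: int = 0):
    """Run fast structural checks; returns [(name, passed, detail), ...]."""
    results = []
    p = mini_crypt_params()
    net = triangulate_surface(p.shape, p.bm.lambda_max, seed=seed)
    ir = triangle_inradii(net)
    results.append((
        "mesh inradius bound", bool(np.all(ir <= p.bm.lambda_max)),
        f"max inradius {ir.max():.3f} µm <= {p.bm.lambda_max} µm",
    ))

    st = make_fixture("mini_crypt", seed=seed)
    c = st.cells
    from . import fate as fate_mod

    eps = fate_mod.eps_knot_per_cell(c.state, p)
    res = mech.evaluate_forces(c.pos, c.radius, c.v_target, eps,
                               np.zeros(len(c)), st.net, p)
    h = 1e-6
    i = int(np.argmax(np.linalg.norm(res.force, axis=1)))
    errs = []
    for a in range(3):
        pp, pm = c.pos.copy(), c.pos.copy()
        pp[i, a] += h
        pm[i, a] -= h
        fd = -(mech.total_energy(pp, c.radius, c.v_target, eps, st.net, p)
               - mech.total_energy(pm, c.radius, c.v_target, eps, st.net, p)) / (2 * h)
        errs.append(abs(fd - res.force[i, a]) / max(abs(fd), 1e-9))
    results.append((
        "force = -grad(energy)", max(errs) < 1e-4,
        f"max relative deviation {max(errs):.2e}",
    ))

    st2 = make_fixture("mini_crypt", seed=seed)
    same = np.array_equal(st.cells.pos, st2.cells.pos)
    results.append(("deterministic initialisation", bool(same),
                    "same seed reproduces the same state"))
    return results
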