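"""Cell-cell and cell-BM biomechanics and the overdamped equations of motion.

Cells are adhesive elastic spheres.  For a pair in contact the potential
has three parts: an adhesion term -eps_c * A (A the sphere-sphere
intersection-disc area), a Hertz deformation energy
(8/15) E* sqrt(R_eff) delta^(5/2), and a volume-compression penalty
K (V_a - V_t)^2 / (2 V_t) where the actual volume V_a is the sphere
volume minus the spherical-cap overlap with every neighbour and with the
basal membrane (treated as the local tangent plane of the surface).
Cell-knot interactions add the short-ranged adhesive/repulsive kernel of
:mod:`cryptsim.bm`, scaled by the interacting-knot count.

Motion is overdamped (no inertia, no thermal noise): at every step the
linear system

    (eta_BM + sum_j eta_c A_ij) v_i - sum_j eta_c A_ij v_j = F_i

is solved for all cell velocities simultaneously, with a semi-implicit
diagonal term dt * J_i (the positive part of the knot-force Jacobian)
that renders the stiff BM-normal mode unconditionally stable without
affecting tangential (migratory) dynamics.  Radii evolve analogously
against the volume-change friction eta_VO.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp
from scipy.sparse.linalg import spsolve
from scipy.spatial import cKDTree

from . import bm as bm_mod
from .geometry import crypt_radius_derivatives, project_to_surface, surface_frame
from .params import MechanicsParams, ModelParams

log = logging.getLogger(__name__)

__all__ = [
    "contact_area",
    "adhesion_energy",
    "hertz_energy",
    "compression_energy",
    "sphere_cap_volume",
    "actual_volume",
    "Forces",
    "evaluate_forces",
    "total_energy",
    "solve_motion",
]

_FOUR_THIRDS_PI = 4.0 * math.pi / 3.0


# ---------------------------------------------------------------------------
# pairwise primitives
# ---------------------------------------------------------------------------

def contact_area(r_i: float, r_j: float, d_ij: float) -> float:
    """Sphere-sphere intersection-disc area, µm².

    Zero at and beyond tangency (d = R_i + R_j), positive and continuous
    for overlapping spheres, symmetric in the two cells.
    """
    if d_ij <= 0:
        raise ValueError("degenerate contact: cell centres coincide")
    if d_ij >= r_i + r_j:
        return 0.0
    x_i = 0.5 * d_ij + (r_i**2 - r_j**2) / (2.0 * d_ij)
    a2 = r_i**2 - x_i**2
    return math.pi * max(a2, 0.0)


def adhesion_energy(area: float, eps_c: float) -> float:
    """Adhesive interaction energy -eps_c * A (nN·µm); adhesion lowers energy."""
    if area < 0:
        raise ValueError("contact area must be non-negative")
    return -eps_c * area


def hertz_energy(r_i: float, r_j: float, d_ij: float, E: float, nu: float) -> float:
    """Hertz deformation energy of the contact, nN·µm.

    W = (8/15) E* sqrt(R_eff) delta^(5/2) with the standard effective
    modulus 1/E* = (1-nu_i²)/E_i + (1-nu_j²)/E_j (identical cells here)
    and 1/R_eff = 1/R_i + 1/R_j.  Zero for non-overlapping spheres.
    """
    delta = r_i + r_j - d_ij
    if delta <= 0:
        return 0.0
    e_star = E / (2.0 * (1.0 - nu**2))
    r_eff = r_i * r_j / (r_i + r_j)
    return (8.0 / 15.0) * e_star * math.sqrt(r_eff) * delta**2.5


def compression_energy(v_t: float, v_a: float, K: float) -> float:
    """Uniform compression/inflation energy K (V_a - V_t)² / (2 V_t), nN·µm."""
    if v_t <= 0:
        raise ValueError("target volume must be positive")
    if v_a <= 0:
        raise ValueError("actual volume must be positive")
    return K * (v_a - v_t) ** 2 / (2.0 * v_t)


def sphere_cap_volume(radius, height):
    """Volume of a spherical cap of the given height, µm³."""
    h = np.clip(height, 0.0, 2.0 * radius)
    return math.pi * np.asarray(radius) * h**2 - (math.pi / 3.0) * h**3


def actual_volume(radius: float, neighbours=(), bm_distance: float | None = None,
                  v_floor: float = 1e-3) -> float:
    """Actual cell volume: sphere minus overlap caps, µm³.

    ``neighbours`` is an iterable of (R_j, d_ij) pairs; ``bm_distance`` is
    the distance from the cell centre to the local BM tangent plane (the
    BM clips a cap when it is closer than one radius).  The result is
    clamped to a small positive floor if overlaps exceed the sphere.
    """
    v = _FOUR_THIRDS_PI * radius**3
    for r_j, d in neighbours:
        if d <= 0:
            raise ValueError("degenerate contact: cell centres coincide")
        if d < radius + r_j:
            x_i = 0.5 * d + (radius**2 - r_j**2) / (2.0 * d)
            v -= float(sphere_cap_volume(radius, radius - x_i))
    if bm_distance is not None and bm_distance < radius:
        v -= float(sphere_cap_volume(radius, radius - bm_distance))
    if v < v_floor:
        log.warning("cell overlaps exceed sphere volume; clamping V_a")
        v = v_floor
    return v


# ---------------------------------------------------------------------------
# vectorised force evaluation
# ---------------------------------------------------------------------------

@dataclass
class Forces:
    """Result of one force evaluation over all cells."""

    force: np.ndarray          # (N, 3) generalized position forces, nN
    radius_force: np.ndarray   # (N,) forces conjugate to the radii, nN
    v_actual: np.ndarray       # (N,) actual volumes, µm³
    pairs: np.ndarray          # (P, 2) contact pair indices (d < R_i + R_j)
    pair_area: np.ndarray      # (P,) contact areas, µm²
    n_knots: np.ndarray        # (N,) interacting-knot counts
    knot_jacobian: np.ndarray  # (N, 3, 3) SPD part of knot-force Jacobian
    radius_stiffness: np.ndarray  # (N,) positive radius-force stiffness bound
    bm_contact: np.ndarray     # (N,) bool, at least one interacting knot
    zeta: np.ndarray           # (N,) axial coordinate of surface foot point
    theta: np.ndarray          # (N,) azimuth of each cell
    energy: float              # total potential energy, nN·µm


def _pair_lists(positions, radii):
    tree = cKDTree(positions)
    pairs = tree.query_pairs(r=2.0 * float(np.max(radii)), output_type="ndarray")
    if pairs.size == 0:
        return np.empty((0, 2), dtype=np.int64)
    pairs = pairs[np.lexsort((pairs[:, 1], pairs[:, 0]))]
    d = np.linalg.norm(positions[pairs[:, 0]] - positions[pairs[:, 1]], axis=1)
    keep = d < radii[pairs[:, 0]] + radii[pairs[:, 1]]
    return pairs[keep]


_KNOT_QUERY_K = 64


def _knot_lists(positions, radii, net):
    """(cell idx, knot idx, per-cell count) for all pairs with d < R_i."""
    n = len(positions)
    if n == 0:
        return (np.empty(0, np.int64),) * 2 + (np.empty(0, np.int64),)
    k = min(_KNOT_QUERY_K, net.n_knots)
    rmax = float(np.max(radii))
    dist, idx = net.tree.query(positions, k=k, distance_upper_bound=rmax)
    hit = dist < radii[:, None]
    if k == _KNOT_QUERY_K and bool(hit[:, -1].any()):
        # a cell touches more knots than the fixed query width; fall back
        lists = net.tree.query_ball_point(positions, r=radii, return_sorted=True)
        counts = np.array([len(v) for v in lists], dtype=np.int64)
        ci = np.repeat(np.arange(n), counts)
        ki = np.concatenate([np.asarray(v, np.int64) for v in lists]) if counts.sum() else np.empty(0, np.int64)
        return ci, ki, counts
    counts = hit.sum(axis=1).astype(np.int64)
    ci = np.repeat(np.arange(n), counts)
    ki = idx[hit].astype(np.int64)
    return ci, ki, counts


def evaluate_forces(positions, radii, v_target, eps_knot, migration, net, params: ModelParams,
                    with_energy: bool = False) -> Forces:
    """Compute all generalized forces (the exact negative energy gradient).

    Parameters
    ----------
    positions, radii, v_target : per-cell state arrays.
    eps_knot : (N,) maximum cell-knot interaction energy per cell (lineage
        dependent), nN·µm.
    migration : (N,) signed migration-force magnitude, nN; positive values
        push up the crypt (toward z = 0), negative down.  Applied only to
        cells with BM contact, along the local meridian tangent.
    """
    mp: MechanicsParams = params.mech
    bmp = params.bm
    shape = params.shape
    n = len(positions)
    positions = np.asarray(positions, dtype=float)
    radii = np.asarray(radii, dtype=float)
    v_target = np.asarray(v_target, dtype=float)

    force = np.zeros((n, 3))
    radius_force = np.zeros(n)
    jac = np.zeros((n, 3, 3))
    k_rad = np.zeros(n)
    energy = 0.0

    # --- surface foot points (BM tangent-plane clip + migration frame) ---
    zeta, _, _ = project_to_surface(positions, shape)
    theta = np.arctan2(positions[:, 1], positions[:, 0])
    r_foot, _, _ = crypt_radius_derivatives(zeta, shape)
    foot = np.column_stack([r_foot * np.cos(theta), r_foot * np.sin(theta), zeta])
    inward, tangent = surface_frame(zeta, theta, shape)
    p_bm = np.einsum("ij,ij->i", positions - foot, inward)  # signed; >0 inside

    # --- actual volumes ---
    v_actual = _FOUR_THIRDS_PI * radii**3
    pairs = _pair_lists(positions, radii)
    i_, j_ = pairs[:, 0], pairs[:, 1]
    rij = positions[i_] - positions[j_]
    d = np.linalg.norm(rij, axis=1)
    if np.any(d <= 1e-9):
        raise FloatingPointError("degenerate contact: coincident cell centres")
    nhat = rij / d[:, None]
    ri, rj = radii[i_], radii[j_]

    x_i = 0.5 * d + (ri**2 - rj**2) / (2.0 * d)
    x_j = d - x_i
    h_i = np.clip(ri - x_i, 0.0, 2.0 * ri)
    h_j = np.clip(rj - x_j, 0.0, 2.0 * rj)
    np.add.at(v_actual, i_, -(math.pi * ri * h_i**2 - math.pi / 3.0 * h_i**3))
    np.add.at(v_actual, j_, -(math.pi * rj * h_j**2 - math.pi / 3.0 * h_j**3))

    h_bm = np.clip(radii - p_bm, 0.0, 2.0 * radii)
    ci, ki, n_knots = _knot_lists(positions, radii, net)
    bm_contact = n_knots > 0
    h_bm = np.where(bm_contact, h_bm, 0.0)  # volume clip only for BM-attached cells
    v_actual -= math.pi * radii * h_bm**2 - math.pi / 3.0 * h_bm**3
    low = v_actual < 1e-3
    if np.any(low):
        log.warning("%d cell(s) with overlaps exceeding sphere volume; clamping V_a",
                    int(low.sum()))
        v_actual = np.maximum(v_actual, 1e-3)

    # compression prefactor dU/dV_a per cell
    c_pref = mp.K * (v_actual - v_target) / v_target
    if with_energy:
        energy += float(np.sum(mp.K * (v_actual - v_target) ** 2 / (2.0 * v_target)))

    # --- pair terms ---
    if len(pairs):
        delta = ri + rj - d
        e_star = mp.E / (2.0 * (1.0 - mp.nu**2))
        r_eff = ri * rj / (ri + rj)
        c_h = (8.0 / 15.0) * e_star * np.sqrt(r_eff)
        dW_h = -2.5 * c_h * delta**1.5                       # dW_hertz/dd

        a2 = np.clip(ri**2 - x_i**2, 0.0, None)
        area = math.pi * a2
        dxi_dd = 0.5 - (ri**2 - rj**2) / (2.0 * d**2)
        dA_dd = -2.0 * math.pi * x_i * dxi_dd
        dW_a = -mp.eps_c * dA_dd                              # d(-eps_c A)/dd

        # compression coupling through both caps
        dcap_i = math.pi * h_i * (2.0 * ri - h_i)            # dVcap/dh
        dcap_j = math.pi * h_j * (2.0 * rj - h_j)
        dhi_dd = -dxi_dd
        dhj_dd = -(1.0 - dxi_dd)
        dW_k = -(c_pref[i_] * dcap_i * dhi_dd + c_pref[j_] * dcap_j * dhj_dd)

        f_pair = -(dW_h + dW_a + dW_k)                        # along nhat, on i
        force[:, 0] += np.bincount(i_, f_pair * nhat[:, 0], minlength=n)
        force[:, 1] += np.bincount(i_, f_pair * nhat[:, 1], minlength=n)
        force[:, 2] += np.bincount(i_, f_pair * nhat[:, 2], minlength=n)
        force[:, 0] -= np.bincount(j_, f_pair * nhat[:, 0], minlength=n)
        force[:, 1] -= np.bincount(j_, f_pair * nhat[:, 1], minlength=n)
        force[:, 2] -= np.bincount(j_, f_pair * nhat[:, 2], minlength=n)

        # radius-conjugate forces
        dCh_dRi = (8.0 / 15.0) * e_star * 0.5 / np.sqrt(r_eff) * (rj / (ri + rj)) ** 2
        dCh_dRj = (8.0 / 15.0) * e_star * 0.5 / np.sqrt(r_eff) * (ri / (ri + rj)) ** 2
        dWh_dRi = 2.5 * c_h * delta**1.5 + dCh_dRi * delta**2.5
        dWh_dRj = 2.5 * c_h * delta**1.5 + dCh_dRj * delta**2.5
        dA_dRi = 2.0 * math.pi * (ri - x_i * ri / d)
        dA_dRj = 2.0 * math.pi * x_i * rj / d
        dhi_dRi = 1.0 - ri / d
        dhj_dRj = 1.0 - rj / d
        dhi_dRj = rj / d
        dhj_dRi = ri / d
        dVai_dRi_pair = -(math.pi * h_i**2 + dcap_i * dhi_dRi)
        dVaj_dRj_pair = -(math.pi * h_j**2 + dcap_j * dhj_dRj)
        dVai_dRj = -dcap_i * dhi_dRj
        dVaj_dRi = -dcap_j * dhj_dRi
        fr_i = -(dWh_dRi - mp.eps_c * dA_dRi
                 + c_pref[i_] * dVai_dRi_pair + c_pref[j_] * dVaj_dRi)
        fr_j = -(dWh_dRj - mp.eps_c * dA_dRj
                 + c_pref[j_] * dVaj_dRj_pair + c_pref[i_] * dVai_dRj)
        radius_force += np.bincount(i_, fr_i, minlength=n)
        radius_force += np.bincount(j_, fr_j, minlength=n)

        k_rad += np.bincount(i_, 2.5 * 1.5 * c_h * np.sqrt(delta), minlength=n)
        k_rad += np.bincount(j_, 2.5 * 1.5 * c_h * np.sqrt(delta), minlength=n)

        if with_energy:
            energy += float(np.sum(c_h * delta**2.5 - mp.eps_c * area))
    else:
        area = np.zeros(0)

    # own-sphere part of the compression gradient (4 pi R^2 dR)
    radius_force -= c_pref * 4.0 * math.pi * radii**2
    k_rad += mp.K / v_target * (4.0 * math.pi * radii**2) ** 2

    # --- BM tangent-plane compression clip ---
    on_bm = h_bm > 0.0
    dcap_bm = math.pi * h_bm * (2.0 * radii - h_bm)
    # dVa/dp = +dcap/dh (h = R - p); force on position along inward normal
    f_bm = -(c_pref * dcap_bm)          # -dU/dp, applied along +inward
    force += np.where(on_bm, f_bm, 0.0)[:, None] * inward
    # dVa/dR from the BM cap is -(pi h^2 + dcap/dh), so -dU/dR = +c_pref*(...)
    radius_force += np.where(on_bm, c_pref * (math.pi * h_bm**2 + dcap_bm), 0.0)

    # --- knot interactions: E_i = eps_i * S_i / W_i with S = sum g*t and
    # the smooth effective knot count W = max(sum t, 1) ---
    if ci.size:
        dk_vec = positions[ci] - net.knots[ki]
        dk = np.linalg.norm(dk_vec, axis=1)
        uk = dk_vec / dk[:, None]
        rk = radii[ci]
        g, g_d, g_dd, g_R, t, t_d, t_R = bm_mod.knot_terms(dk, rk, bmp.omega)
        S = np.bincount(ci, g * t, minlength=n)
        W_raw = np.bincount(ci, t, minlength=n)
        W = np.maximum(W_raw, 1.0)
        grad_W = (W_raw > 1.0).astype(float)     # W gradient vanishes at the floor
        eps_W = eps_knot / W
        # dE/dd_k = eps [ (g t)'_k / W - (S/W²) t'_k ]
        dE_dd = eps_W[ci] * ((g_d * t + g * t_d)
                             - (S[ci] / W[ci]) * t_d * grad_W[ci])
        fk = -dE_dd
        force[:, 0] += np.bincount(ci, fk * uk[:, 0], minlength=n)
        force[:, 1] += np.bincount(ci, fk * uk[:, 1], minlength=n)
        force[:, 2] += np.bincount(ci, fk * uk[:, 2], minlength=n)
        dE_dR = eps_W[ci] * ((g_R * t + g * t_R)
                             - (S[ci] / W[ci]) * t_R * grad_W[ci])
        radius_force += np.bincount(ci, -dE_dR, minlength=n)
        wpos = np.clip(eps_W[ci] * g_dd * t, 0.0, None)
        contrib = wpos[:, None, None] * uk[:, :, None] * uk[:, None, :]
        np.add.at(jac, ci, contrib)
        # positive bound on the radius stiffness of the knot term
        # (d²g/dR² = sqrt(y)/(2R²) for the soft kernel)
        y = bmp.omega * rk / dk
        k_rad += np.bincount(
            ci, np.clip(eps_W[ci] * np.sqrt(y) / (2.0 * rk**2) * t, 0.0, None),
            minlength=n,
        )
        if with_energy:
            energy += float(np.sum(eps_knot * S / W))

    # --- migration force (non-conservative) ---
    mig = np.asarray(migration, dtype=float)
    force += np.where(bm_contact, mig, 0.0)[:, None] * tangent

    return Forces(
        force=force,
        radius_force=radius_force,
        v_actual=v_actual,
        pairs=pairs,
        pair_area=area,
        n_knots=n_knots,
        knot_jacobian=jac,
        radius_stiffness=k_rad,
        bm_contact=bm_contact,
        zeta=zeta,
        theta=theta,
        energy=energy,
    )


def total_energy(positions, radii, v_target, eps_knot, net, params: ModelParams) -> float:
    """Total potential energy (nN·µm); migration forces excluded."""
    res = evaluate_forces(
        positions, radii, v_target, eps_knot, np.zeros(len(positions)), net, params,
        with_energy=True,
    )
    return res.energy


def solve_motion(res: Forces, radii, dt: float, params: ModelParams):
    """Solve the coupled overdamped system for one step.

    Returns (velocities (N,3) µm/h, radius rates (N,) µm/h).  All cells
    feel at least the cell-BM friction eta_BM (cells momentarily without a
    friction path are regularized by the same floor, which is logged).
    """
    mp = params.mech
    n = len(res.force)
    if n == 0:
        return np.zeros((0, 3)), np.zeros(0)
    diag = np.full(n, mp.eta_bm)
    if not np.all(res.bm_contact):
        log.debug("%d cell(s) without BM contact; eta_BM floor applied",
                  int((~res.bm_contact).sum()))

    rows, cols, vals = [], [], []
    if len(res.pairs):
        i_, j_ = res.pairs[:, 0], res.pairs[:, 1]
        fric = mp.eta_c * res.pair_area
        diag += np.bincount(i_, fric, minlength=n)
        diag += np.bincount(j_, fric, minlength=n)
        for a in range(3):
            rows.append(3 * i_ + a)
            cols.append(3 * j_ + a)
            vals.append(-fric)
            rows.append(3 * j_ + a)
            cols.append(3 * i_ + a)
            vals.append(-fric)

    idx = np.arange(n)
    big_diag = np.repeat(diag, 3)
    rows.append(np.arange(3 * n))
    cols.append(np.arange(3 * n))
    vals.append(big_diag)
    # semi-implicit stabilisation of the stiff BM-normal mode
    jac = dt * res.knot_jacobian
    for a in range(3):
        for b in range(3):
            rows.append(3 * idx + a)
            cols.append(3 * idx + b)
            vals.append(jac[:, a, b])
    mat = sp.csr_matrix(
        (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))),
        shape=(3 * n, 3 * n),
    )
    b = res.force.ravel()
    # SPD and strongly diagonal: Jacobi-preconditioned CG from the
    # free-draining guess converges in a handful of iterations
    dinv = 1.0 / mat.diagonal()
    x0 = b * dinv
    precond = sp.linalg.LinearOperator((3 * n, 3 * n), matvec=lambda v: v * dinv)
    vel, info = sp.linalg.cg(mat, b, x0=x0, M=precond, rtol=1e-9, atol=0.0,
                             maxiter=400)
    if info != 0:  # pragma: no cover - fallback for pathological systems
        vel = spsolve(mat, b)
    vel = vel.reshape(n, 3)
    dradius = res.radius_force / (mp.eta_vo + dt * res.radius_stiffness)
    return vel, dradius
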