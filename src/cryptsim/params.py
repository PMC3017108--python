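"""Model parameters for the intestinal-crypt simulation.

All quantities are stored in a single consistent internal unit system:

====================  =========================
length                micrometre (µm)
force                 nanonewton (nN)
time                  hour (h)
energy                nN·µm  (= 1e-15 N·m)
pressure / modulus    nN/µm² (= 1 kPa)
====================  =========================

Conversion helpers from the units the literature quotes (N·m, N·s/m,
N·s/m³, µN/m, days) are applied once, in the default constructors below,
so the rest of the code never needs unit factors.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, fields, is_dataclass

# --- unit conversion constants (literature unit -> internal unit) ---
NM_TO_NN_UM = 1e15          # N·m        -> nN·µm
NSM_TO_NN_H_UM = 1e3 / 3600.0   # N·s/m  -> nN·h/µm
NSM3_TO_NN_H_UM3 = 1e-9 / 3600.0  # N·s/m³ -> nN·h/µm³
UN_PER_M_TO_NN_UM = 1e-3    # µN/m -> nN/µm  (1e-6 N/m = 1e3 nN / 1e6 µm)
KPA_TO_NN_UM2 = 1.0         # kPa = 1e3 N/m² = 1 nN/µm²
DAY = 24.0                  # hours per day

#: minimal (isolated, newborn) cell radius, µm
R_MIN = 5.0
#: minimal volume of an isolated cell, µm³
V0 = 4.0 / 3.0 * math.pi * R_MIN**3


@dataclass
class CryptShape:
    """Parametric crypt surface of revolution.

    The crypt axis is z, the crypt-villus junction sits at z = 0 and the
    closed base at z = -z0.  ``lambda1`` weights the square-root flare
    into the villus junction and ``lambda2`` the linear taper of the
    shaft; together they narrow the crypt from r0 at the mouth to about
    (1 - lambda1 - lambda2) r0 at the basal cap (see
    :mod:`cryptsim.geometry` for the exact profile).
    """

    z0: float = 150.0       # crypt length, µm
    r0: float = 60.0        # radius at the crypt-villus junction, µm
    lambda1: float = 0.25   # dimensionless shape parameter 1
    lambda2: float = 0.1    # dimensionless shape parameter 2

    def __post_init__(self) -> None:
        if self.z0 <= 0 or self.r0 <= 0:
            raise ValueError("z0 and r0 must be positive")
        if not 0.0 <= self.lambda1 < 1.0:
            raise ValueError("lambda1 must lie in [0, 1)")
        if self.lambda2 <= 0:
            raise ValueError("lambda2 must be positive")


@dataclass
class BMInteractionParams:
    """Cell-basal-membrane interaction constants."""

    lambda_max: float = 1.25          # maximum triangle inradius, µm
    eps_knot_paneth: float = 35e-12 * NM_TO_NN_UM   # nN·µm
    eps_knot_other: float = 5.5e-12 * NM_TO_NN_UM   # nN·µm
    omega: float = 0.95               # threshold ratio Ω (adhesive/repulsive split)

    def __post_init__(self) -> None:
        if self.eps_knot_paneth <= 0 or self.eps_knot_other <= 0:
            raise ValueError("knot interaction energies must be positive")
        if not 0.0 < self.omega < 1.0:
            raise ValueError("omega must lie in (0, 1)")


@dataclass
class MechanicsParams:
    """Cell-cell interaction and friction constants."""

    E: float = 1.0 * KPA_TO_NN_UM2        # Young modulus, nN/µm² (1 kPa)
    nu: float = 1.0 / 3.0                 # Poisson ratio
    eps_c: float = 200.0 * UN_PER_M_TO_NN_UM  # adhesion energy / area, nN/µm
    K: float = 5.0 * KPA_TO_NN_UM2        # bulk modulus, nN/µm²; cells resist
    # volume change far more stiffly than shape change (effective Poisson
    # ratio ~0.47 in K = E/(3(1-2nu)))
    eta_c: float = 5e10 * NSM3_TO_NN_H_UM3    # cell-cell friction, nN·h/µm³
    eta_bm: float = 3.2 * NSM_TO_NN_H_UM      # cell-BM friction, nN·h/µm
    eta_vo: float = 400.0 * NSM_TO_NN_H_UM    # volume-change friction, nN·h/µm
    f_a_paneth: float = 7.5               # Paneth migration force, nN (downward)
    f_a_other: float = 4.5                # migration force of primed cells, nN
    f_a_undiff: float = 0.0               # migration force of undifferentiated
    # cells (signed, + = up); they are not primed and rest passively in the
    # niche by default, but the value is sweepable

    def __post_init__(self) -> None:
        for name in ("E", "eps_c", "K", "eta_c", "eta_bm", "eta_vo",
                     "f_a_paneth", "f_a_other"):  # f_a_undiff may be zero/negative
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not 0.0 < self.nu < 0.5:
            raise ValueError("nu must lie in (0, 0.5)")


@dataclass
class FateParams:
    """Lineage specification, proliferation and removal parameters."""

    z_p: float = -125.0        # priming threshold position, µm (TP_wnt = f(z_p))
    z_d: float = -87.5         # differentiation threshold position, µm
    lp_paneth: float = 0.35    # Notch activation through Paneth(-primed) cells
    lp_goblet: float = 1.00    # Notch activation through Goblet(-progenitor) cells
    tp_notch: float = 1.0      # Notch threshold for priming
    td_notch: float = 1.0      # Notch threshold for differentiation
    t_p: float = 57.0 * DAY    # terminal Paneth lifetime, h
    tau_growth: float = 14.0   # mean volume-doubling time of a free cell, h
    n_growth_steps: int = 50   # stochastic growth increments per doubling
    v_p_ratio: float = 0.88    # contact-inhibition threshold volume factor
    v_p_mode: str = "absolute"  # "absolute": inhibited when V_a < 0.88 V_0
    #                             "relative": inhibited when V_a < 0.88 V_t
    brdu_label_fraction: float = 0.7
    t_section: float = 4.5     # virtual section thickness, µm
    wnt_mode: str = "normal"   # "normal" | "high" (constitutive) | "low" (blocked)
    notch_mode: str = "normal"  # "normal" | "high" (constitutive) | "zero" (blocked)

    def __post_init__(self) -> None:
        if not self.z_p < self.z_d <= 0:
            raise ValueError("need z_p < z_d <= 0")
        if not 0.0 < self.lp_paneth <= self.lp_goblet:
            raise ValueError("need 0 < lp_paneth <= lp_goblet")
        if self.t_p <= 0 or self.tau_growth <= 0:
            raise ValueError("t_p and tau_growth must be positive")
        if self.n_growth_steps < 1:
            raise ValueError("n_growth_steps must be >= 1")
        if not 0.0 < self.v_p_ratio < 1.0:
            raise ValueError("v_p_ratio must lie in (0, 1)")
        if self.v_p_mode not in ("absolute", "relative"):
            raise ValueError("v_p_mode must be 'absolute' or 'relative'")
        if self.wnt_mode not in ("normal", "high", "low"):
            raise ValueError("wnt_mode must be 'normal', 'high' or 'low'")
        if self.notch_mode not in ("normal", "high", "zero"):
            raise ValueError("notch_mode must be 'normal', 'high' or 'zero'")
        if not 0.0 <= self.brdu_label_fraction <= 1.0:
            raise ValueError("brdu_label_fraction must lie in [0, 1]")


@dataclass
class EngineParams:
    """Time stepping and initialisation controls (technical, not biological)."""

    dt_max: float = 0.05             # h
    dt_min: float = 1e-6             # h; underflow aborts the run
    displacement_fraction: float = 0.1   # max step = fraction * minimal radius
    overlap_reject: float = 0.2      # reject step if d < overlap_reject*(Ri+Rj)
    relax_tol: float = 0.01          # µm per step; initial relaxation target
    relax_max_steps: int = 400
    knot_query_pad: float = 0.5      # µm of slack on the knot search radius

    def __post_init__(self) -> None:
        if self.dt_max <= 0 or self.dt_min <= 0 or self.dt_min > self.dt_max:
            raise ValueError("need 0 < dt_min <= dt_max")


@dataclass
class ModelParams:
    """Complete parameter set of the model (reference defaults)."""

    shape: CryptShape = field(default_factory=CryptShape)
    bm: BMInteractionParams = field(default_factory=BMInteractionParams)
    mech: MechanicsParams = field(default_factory=MechanicsParams)
    fate: FateParams = field(default_factory=FateParams)
    engine: EngineParams = field(default_factory=EngineParams)
    v0: float = V0             # minimal volume of an isolated cell, µm³

    @property
    def r_min(self) -> float:
        """Radius of an isolated newborn cell, µm."""
        return (3.0 * self.v0 / (4.0 * math.pi)) ** (1.0 / 3.0)


def params_to_dict(p) -> dict:
    """Recursively convert a (nested) params dataclass to plain dicts."""
    if is_dataclass(p):
        return {f.name: params_to_dict(getattr(p, f.name)) for f in fields(p)}
    return p


def params_from_dict(cls, data: dict, _path: str = ""):
    """Build a params dataclass from nested dicts, rejecting unknown keys.

    Unspecified fields keep their defaults; unknown keys raise ``ValueError``
    naming the offending key and its location.
    """
    if not isinstance(data, dict):
        raise ValueError(f"expected a mapping at '{_path or '<root>'}'")
    known = {f.name: f for f in fields(cls)}
    unknown = set(data) - set(known)
    if unknown:
        where = _path or "<root>"
        raise ValueError(f"unknown key(s) {sorted(unknown)} at '{where}'")
    kwargs = {}
    for name, f in known.items():
        if name not in data:
            continue
        sub = f.type if isinstance(f.type, type) else None
        # resolve forward-declared dataclass field types by inspecting defaults
        default = getattr(cls(), name)
        if is_dataclass(default):
            kwargs[name] = params_from_dict(
                type(default), data[name], f"{_path}.{name}" if _path else name
            )
        else:
            kwargs[name] = data[name]
    return cls(**kwargs)
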