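"""Parametric crypt surface, analytic curvatures and the curvature-Wnt link.

The crypt is a surface of revolution about the z axis.  The junction with
the villus is at z = 0, the closed base at z = -z0.  The local radius is

    r(z) = r0 * (1 - lambda1*(sqrt(u + u0) - sqrt(u0)) - lambda2*u)
              * sqrt(1 - u^8)

with u = -z/z0 in [0, 1] and a small regulariser u0 = 0.01.  The taper
factor narrows the crypt from r0 at the mouth to ~0.65 r0 at the bottom
(the sqrt term is the flare into the villus junction, the linear term the
gradual taper); the last factor closes the base with a wide smooth cap.
For the reference shape the Gaussian curvature is maximal at the crypt
bottom (~6e-4 /µm²), ~4e-4 /µm² at the priming threshold position z_p,
essentially zero at the differentiation threshold z_d, and negative in
the flared upper crypt — the curvature landscape the Wnt link assumes.

Wnt activity is a monotone function f of this Gaussian curvature expressed
along z: high at the strongly curved base, low toward the junction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize_scalar

from .params import CryptShape

__all__ = [
    "crypt_radius",
    "crypt_radius_derivatives",
    "surface_curvatures",
    "curvatures_of_profile",
    "WntLink",
    "surface_area",
    "arc_length_table",
    "project_to_surface",
    "surface_frame",
]

_POLE_PAD = 1e-3  # µm kept clear of the degenerate pole in curvature evaluations
#: cap-fullness exponent of the profile; 8 keeps the crypt bottom wide (the
#: basal cap curvature ~6e-4/µm² matches the scale the Wnt thresholds assume)
#: while the Gaussian curvature still crosses zero between z_d and the junction
_CAP_EXPONENT = 8
#: regulariser of the flare term so the profile slope stays finite at z = 0
_FLARE_PAD = 0.01


def _check_domain(z, shape: CryptShape) -> np.ndarray:
    z = np.asarray(z, dtype=float)
    if np.any(z < -shape.z0 - 1e-9) or np.any(z > 1e-9):
        raise ValueError(f"axial coordinate outside [-{shape.z0}, 0]")
    return np.clip(z, -shape.z0, 0.0)


def crypt_radius(z, shape: CryptShape):
    """Local crypt radius r(z) in µm for z in [-z0, 0]."""
    z = _check_domain(z, shape)
    r, _, _ = crypt_radius_derivatives(z, shape)
    return r


def crypt_radius_derivatives(z, shape: CryptShape):
    """Return (r, dr/dz, d2r/dz2) of the profile; domain is not checked."""
    z = np.asarray(z, dtype=float)
    z0, r0, l1, l2 = shape.z0, shape.r0, shape.lambda1, shape.lambda2
    u = -z / z0
    u0 = _FLARE_PAD
    su = np.sqrt(u + u0)
    g = 1.0 - l1 * (su - math.sqrt(u0)) - l2 * u
    gp = -0.5 * l1 / su - l2
    gpp = 0.25 * l1 / su**3
    m = _CAP_EXPONENT
    um = u**m
    f = np.sqrt(np.clip(1.0 - um, 0.0, None))
    fsafe = np.where(f > 0, f, 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        # f' = -(m/2) u^(m-1) / f ;  f'' = -(m/2)(m-1) u^(m-2)/f - (m/2)^2 u^(2m-2)/f^3
        fp = np.where(f > 0, -(m / 2.0) * u ** (m - 1) / fsafe, -np.inf)
        fpp = np.where(
            f > 0,
            -(m / 2.0) * (m - 1) * u ** (m - 2) / fsafe
            - (m / 2.0) ** 2 * u ** (2 * m - 2) / fsafe**3,
            -np.inf,
        )
    r = r0 * g * f
    # chain rule: du/dz = -1/z0; dr/d2r are ±inf at the pole itself
    with np.errstate(all="ignore"):
        dr = -r0 * (gp * f + g * fp) / z0
        d2r = r0 * (gpp * f + 2.0 * gp * fp + g * fpp) / z0**2
    return r, dr, d2r


def curvatures_of_profile(r, dr, d2r):
    """Gaussian and mean curvature of a surface of revolution from its profile.

    ``r`` is the radius, ``dr``/``d2r`` its first/second derivative with
    respect to the axial coordinate.  Sign convention: a sphere has
    K = 1/R² and H = 1/R; a cylinder has K = 0 and H = 1/(2r).
    """
    r = np.asarray(r, dtype=float)
    if np.any(r <= 0):
        raise ValueError("degenerate surface: profile radius must be positive")
    w = 1.0 + np.asarray(dr) ** 2
    k_meridian = -np.asarray(d2r) / w**1.5
    k_circum = 1.0 / (r * np.sqrt(w))
    return k_meridian * k_circum, 0.5 * (k_meridian + k_circum)


def surface_curvatures(z, shape: CryptShape):
    """Analytic (Gaussian 1/µm², mean 1/µm) curvature of the crypt surface."""
    z = _check_domain(z, shape)
    r, dr, d2r = crypt_radius_derivatives(z, shape)
    return curvatures_of_profile(r, dr, d2r)


def _gauss(z, shape: CryptShape):
    zc = np.maximum(z, -shape.z0 + _POLE_PAD)
    r, dr, d2r = crypt_radius_derivatives(zc, shape)
    k, _ = curvatures_of_profile(r, dr, d2r)
    return k


@dataclass
class WntLink:
    """Monotone link between axial position and Wnt activity (I_wnt = f(z)).

    Wnt activity is identified with the analytic Gaussian curvature of the
    basal membrane, which decreases monotonically from the crypt base
    through the whole threshold region.  In the outermost flare the
    curvature magnitude turns back toward zero; there f is continued
    linearly (with a small negative slope) to keep the link strictly
    monotone, which is what the threshold logic requires.  No fate
    threshold lies in the continued region for any shape the model uses.
    """

    shape: CryptShape

    def __post_init__(self) -> None:
        z0 = self.shape.z0
        # curvature maximum sits on the basal cap; the link plateaus below it
        res = minimize_scalar(
            lambda z: -float(_gauss(z, self.shape)),
            bounds=(-z0 + _POLE_PAD, -0.5 * z0),
            method="bounded",
            options={"xatol": 1e-6 * z0},
        )
        self._z_peak = float(res.x)
        self._k_peak = float(_gauss(self._z_peak, self.shape))
        res = minimize_scalar(
            lambda z: float(_gauss(z, self.shape)),
            bounds=(self._z_peak, 0.0),
            method="bounded",
            options={"xatol": 1e-6 * z0},
        )
        self._z_star = float(res.x)
        self._k_star = float(_gauss(self._z_star, self.shape))
        k0 = float(_gauss(0.0, self.shape))
        if self._k_star >= k0 - 1e-15:       # curvature monotone up to the mouth
            self._z_star = 0.0
            self._k_star = k0
        self._slope = (abs(self._k_star) + 1e-6) / z0

    def __call__(self, z):
        z = _check_domain(z, self.shape)
        scalar = np.ndim(z) == 0
        z = np.atleast_1d(z)
        out = np.where(
            z <= self._z_peak,
            self._k_peak,
            np.where(
                z <= self._z_star,
                _gauss(np.maximum(z, self._z_peak), self.shape),
                self._k_star - self._slope * (z - self._z_star),
            ),
        )
        return float(out[0]) if scalar else out

    @property
    def zero_crossing(self) -> float | None:
        """z where the Gaussian curvature changes sign, if it does."""
        from scipy.optimize import brentq

        z0 = self.shape.z0
        zs = np.linspace(-z0 + _POLE_PAD, self._z_star, 512)
        ks = _gauss(zs, self.shape)
        sign = np.sign(ks)
        idx = np.nonzero(np.diff(sign) != 0)[0]
        if idx.size == 0:
            return None
        i = idx[0]
        return float(brentq(lambda z: float(_gauss(z, self.shape)), zs[i], zs[i + 1]))


def arc_length_table(shape: CryptShape, n: int = 2048):
    """Dense (z, s) table of meridian arc length measured from the base."""
    z = np.linspace(-shape.z0 + 1e-4 * shape.z0, 0.0, n)
    _, dr, _ = crypt_radius_derivatives(z, shape)
    ds = np.sqrt(1.0 + dr**2)
    s = np.concatenate([[0.0], np.cumsum(0.5 * (ds[1:] + ds[:-1]) * np.diff(z))])
    return z, s


def surface_area(shape: CryptShape, n: int = 4096) -> float:
    """Total area of the crypt surface, µm²."""
    # keep clear of the pole where dr diverges; the excluded cap is O(1e-6) µm²
    z = np.linspace(-shape.z0 + 1e-4 * shape.z0, 0.0, n)
    r, dr, _ = crypt_radius_derivatives(z, shape)
    integrand = 2.0 * math.pi * r * np.sqrt(1.0 + dr**2)
    return float(np.trapezoid(integrand, z))


def project_to_surface(points: np.ndarray, shape: CryptShape, iters: int = 8):
    """Project points onto the crypt surface.

    Returns ``(zeta, rho, dist)``: the axial coordinate of the foot point,
    the cylindrical radius of each input point and the Euclidean distance
    to the surface.  Newton iteration on the meridian coordinate; robust
    at the cap where the foot point clamps to the pole.
    """
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    rho = np.hypot(pts[:, 0], pts[:, 1])
    z = pts[:, 2]
    z0 = shape.z0
    zeta = np.clip(z, -z0 + _POLE_PAD, 0.0)
    for _ in range(iters):
        r, dr, d2r = crypt_radius_derivatives(zeta, shape)
        # minimise D = (rho - r)^2 + (z - zeta)^2
        dD = -2.0 * dr * (rho - r) - 2.0 * (z - zeta)
        d2D = 2.0 * dr**2 - 2.0 * d2r * (rho - r) + 2.0
        step = dD / np.where(np.abs(d2D) > 1e-12, d2D, 1e-12)
        zeta = np.clip(zeta - np.clip(step, -0.1 * z0, 0.1 * z0), -z0 + _POLE_PAD, 0.0)
    r, _, _ = crypt_radius_derivatives(zeta, shape)
    dist = np.sqrt((rho - r) ** 2 + (z - zeta) ** 2)
    return zeta, rho, dist


def surface_frame(zeta, theta, shape: CryptShape):
    """Inward normal and up-the-crypt tangent of the surface at (zeta, theta).

    The inward normal points from the surface toward the crypt lumen (the
    side the cells occupy); the tangent is the meridian direction of
    increasing z.  Both are unit 3-vectors.
    """
    zeta = np.asarray(zeta, dtype=float)
    theta = np.asarray(theta, dtype=float)
    _, dr, _ = crypt_radius_derivatives(zeta, shape)
    w = np.sqrt(1.0 + dr**2)
    ct, st = np.cos(theta), np.sin(theta)
    normal = np.stack([-ct / w, -st / w, dr / w], axis=-1)
    tangent = np.stack([dr * ct / w, dr * st / w, 1.0 / w], axis=-1)
    return normal, tangent
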