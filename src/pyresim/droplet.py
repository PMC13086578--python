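"""Sharp-interface theory of a single chemically active droplet.

A spherically symmetric condensate of sticky EPYC1 (volume fraction φ)
sits in a bath of solvent plus non-sticky EPYC1.  In the quasi-steady
limit the sticky fraction obeys the linear reaction–diffusion balance

    0 = ∇²φ − φ + k̃ (1 − φ),

with lengths in units of ℓ = sqrt(D / k_s→ns).

.. warning:: **k̃ convention.** This module uses the *droplet* ratio
   ``k_tilde_d = k_ns→s / k_s→ns`` (dephosphorylation over
   phosphorylation), the **inverse** of ``ModelParams.k_tilde``
   (``k_s→ns / k_ns→s``).  Use :func:`k_tilde_from_pde` /
   :func:`k_tilde_to_pde` to convert.

The interface at radius R̃ pins the concentrations to the binodal values
φ₊ (inside) and φ₋ (outside); matching the diffusive fluxes on the two
sides yields a kinematic equation dR̃/dt̃ whose stable fixed point — when
the switching ratio is below the critical value
k̃_c ≃ (φ₊+φ₋)/(2−φ₊−φ₋) — is the preferred condensate radius.  Above
k̃_c the droplet grows without bound (classical ripening).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy.optimize import brentq

__all__ = [
    "DropletParams",
    "k_tilde_from_pde",
    "k_tilde_to_pde",
    "profile_inside",
    "profile_outside",
    "radius_rate",
    "equilibrium_radius",
    "critical_k",
    "req_approx",
    "passive_growth",
]


def k_tilde_from_pde(k_tilde_pde: float) -> float:
    """Convert the PDE ratio k_s→ns/k_ns→s to the droplet ratio."""
    if k_tilde_pde <= 0:
        raise ValueError("PDE k_tilde must be positive to invert")
    return 1.0 / k_tilde_pde


def k_tilde_to_pde(k_tilde_d: float) -> float:
    """Convert the droplet ratio k_ns→s/k_s→ns to the PDE ratio."""
    if k_tilde_d <= 0:
        raise ValueError("droplet k_tilde must be positive to invert")
    return 1.0 / k_tilde_d


@dataclass
class DropletParams:
    """Parameters of the sharp-interface droplet problem.

    ``k_tilde_d = k_ns→s / k_s→ns`` (droplet convention — the inverse of
    the PDE module's ratio).  ``D`` (µm² s⁻¹) and ``k_s_to_ns`` (s⁻¹) are
    optional and only used to express results in physical units via
    ℓ = sqrt(D / k_s→ns).
    """

    phi_plus: float
    phi_minus: float
    k_tilde_d: float
    D: Optional[float] = None
    k_s_to_ns: Optional[float] = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.phi_minus < self.phi_plus <= 1.0:
            raise ValueError("require 0 <= phi_minus < phi_plus <= 1")
        if self.k_tilde_d < 0:
            raise ValueError("k_tilde_d must be non-negative")

    @property
    def phi_inf(self) -> float:
        """Far-field sticky fraction k̃/(1+k̃) set by reaction balance."""
        return self.k_tilde_d / (1.0 + self.k_tilde_d)

    @property
    def length_scale(self) -> float:
        """ℓ = sqrt(D / k_s→ns) in µm (1.0 if scales are not given)."""
        if self.D is None or self.k_s_to_ns is None:
            return 1.0
        return math.sqrt(self.D / self.k_s_to_ns)


def profile_inside(r, R: float, dp: DropletParams) -> np.ndarray:
    """Quasi-steady sticky profile inside the droplet, φ_in(r̃).

    ``φ_inf + R̃ [k̃(φ₊−1)+φ₊] csch(cR̃) sinh(c r̃) / ((1+k̃) r̃)`` with
    ``c = sqrt(1+k̃)``; the removable singularity at r̃=0 is evaluated by
    its limit ``sinh(c r̃)/r̃ → c``.  Exactly φ₊ at r̃ = R̃.
    """
    r = np.asarray(r, dtype=float)
    if (r < 0).any() or (r > R * (1 + 1e-12)).any():
        raise ValueError("require 0 <= r <= R inside the droplet")
    k = dp.k_tilde_d
    c = math.sqrt(1.0 + k)
    amp = R * (k * (dp.phi_plus - 1.0) + dp.phi_plus) / (
        (1.0 + k) * math.sinh(c * R)
    )
    with np.errstate(invalid="ignore", divide="ignore"):
        shape = np.where(r > 0, np.sinh(c * r) / np.where(r > 0, r, 1.0), c)
    return dp.phi_inf + amp * shape


def profile_outside(r, R: float, dp: DropletParams) -> np.ndarray:
    """Quasi-steady sticky profile outside the droplet, φ_out(r̃).

    ``φ_inf + R̃ [k̃(φ₋−1)+φ₋] exp(c(R̃−r̃)) / ((1+k̃) r̃)``; exactly φ₋
    at r̃ = R̃ and → φ_inf = k̃/(1+k̃) far away.
    """
    r = np.asarray(r, dtype=float)
    if (r < R * (1 - 1e-12)).any():
        raise ValueError("require r >= R outside the droplet")
    k = dp.k_tilde_d
    c = math.sqrt(1.0 + k)
    amp = R * (k * (dp.phi_minus - 1.0) + dp.phi_minus) / (1.0 + k)
    return dp.phi_inf + amp * np.exp(c * (R - r)) / r


def radius_rate(R: float, dp: DropletParams) -> float:
    """Interface velocity dR̃/dt̃ of the kinematic equation.

    ``1/R̃ − [k̃(φ₋−1)+φ₋ + (k̃(φ₊−1)+φ₊) coth(c R̃)] / (c (φ₊−φ₋))``
    with ``c = sqrt(1+k̃)``; time in units of ℓ²/D.
    """
    if R <= 0:
        raise ValueError("droplet radius must be positive")
    k = dp.k_tilde_d
    c = math.sqrt(1.0 + k)
    num = (
        k * (dp.phi_minus - 1.0) + dp.phi_minus
        + (k * (dp.phi_plus - 1.0) + dp.phi_plus) / math.tanh(c * R)
    )
    return 1.0 / R - num / (c * (dp.phi_plus - dp.phi_minus))


def equilibrium_radius(
    dp: DropletParams, r_min: float = 1e-3, r_max: float = 1e3,
    n_scan: int = 400,
) -> Optional[float]:
    """Stable fixed point R̃_eq of :func:`radius_rate`, or ``None``.

    A log-spaced pre-scan locates a sign change from positive (growth)
    to negative (shrinkage); bracketed bisection refines it.  Absence of
    such a crossing means the droplet either dissolves or grows without
    bound (k̃ above the critical ratio).
    """
    grid = np.geomspace(r_min, r_max, n_scan)
    rates = np.array([radius_rate(r, dp) for r in grid])
    for i in range(len(grid) - 1):
        if rates[i] > 0.0 and rates[i + 1] < 0.0:
            return float(brentq(lambda r: radius_rate(r, dp),
                                grid[i], grid[i + 1], xtol=1e-12))
    return None


def critical_k(
    phi_plus: float, phi_minus: float, mode: str = "analytic",
    tol: float = 1e-4,
) -> float:
    """Critical switching ratio k̃_c above which no stable radius exists.

    ``analytic`` evaluates the large-R̃ closed form
    ``(φ₊+φ₋)/(2−φ₊−φ₋)``; ``numeric`` bisects on the existence of a
    stable fixed point of the kinematic equation.
    """
    if not 0.0 <= phi_minus < phi_plus <= 1.0:
        raise ValueError("require 0 <= phi_minus < phi_plus <= 1")
    s = phi_plus + phi_minus
    if s >= 2.0:
        raise ValueError("phi_plus + phi_minus must be < 2")
    if mode == "analytic":
        return s / (2.0 - s)
    if mode != "numeric":
        raise ValueError("mode must be 'analytic' or 'numeric'")

    def has_stable(k: float) -> bool:
        dp = DropletParams(phi_plus, phi_minus, k)
        return equilibrium_radius(dp) is not None

    k_lo = s / (2.0 - s) * 0.25
    k_hi = s / (2.0 - s) * 4.0
    # widen the bracket if the analytic estimate is off
    for _ in range(30):
        if has_stable(k_lo):
            break
        k_lo *= 0.5
    for _ in range(30):
        if not has_stable(k_hi):
            break
        k_hi *= 2.0
    if not has_stable(k_lo) or has_stable(k_hi):
        raise RuntimeError("could not bracket the critical switching ratio")
    while k_hi - k_lo > tol * k_hi:
        k_mid = 0.5 * (k_lo + k_hi)
        if has_stable(k_mid):
            k_lo = k_mid
        else:
            k_hi = k_mid
    return 0.5 * (k_lo + k_hi)


def req_approx(dp: DropletParams) -> float:
    """Closed-form equilibrium radius in the φ₊ ≫ φ₋ limit.

    ``R_eq ≃ ℓ (3k̃ + sqrt(3k̃(4+3k̃))) / (2 sqrt(1+k̃))`` — dimensional
    if the physical scales are set on ``dp``, otherwise in units of ℓ.
    """
    k = dp.k_tilde_d
    return dp.length_scale * (
        (3.0 * k + math.sqrt(3.0 * k * (4.0 + 3.0 * k)))
        / (2.0 * math.sqrt(1.0 + k))
    )


def passive_growth(R_init: float, phi_inf: float, phi_minus: float,
                   phi_plus: float, t) -> np.ndarray:
    """Reaction-free diffusive growth law R̃(t̃).

    Without switching, a droplet in a supersaturated bath
    (φ_inf > φ₋) adsorbs material diffusively:
    ``R̃ = R̃_init + sqrt(2 (φ_inf−φ₋)/(φ₊−φ₋) · t̃)`` — the classic
    square-root-of-time growth.
    """
    if phi_inf <= phi_minus:
        raise ValueError("no growth: bath is not supersaturated "
                         "(phi_inf <= phi_minus)")
    t = np.asarray(t, dtype=float)
    if (t < 0).any():
        raise ValueError("time must be non-negative")
    return R_init + np.sqrt(2.0 * (phi_inf - phi_minus)
                            / (phi_plus - phi_minus) * t)
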