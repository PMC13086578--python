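"""Thermodynamic core of the two-state EPYC1 condensate model.

The pyrenoid linker protein EPYC1 is modelled as a ternary Flory–Huggins
mixture of sticky (unphosphorylated) EPYC1, non-sticky (phosphorylated)
EPYC1 and solvent, with volume fractions ``phi_s``, ``phi_ns`` and
``phi_sol = 1 - phi_s - phi_ns``.  Only the sticky species self-attracts;
``chi`` is stored as a *positive attraction magnitude*, i.e. the
interaction contribution to the free-energy density is ``-chi * phi_s**2``
(in units of k_B T per lattice site), so its exchange chemical potential
carries ``-2*chi*phi_s``.  This single convention is used consistently in
the dynamics, the linear stability analysis and the droplet theory.

Lengths are measured in units of ``l_kappa = sqrt(kappa_s_ns_prime)`` (the
cross-species interfacial parameter) and times in units of the inverse
dephosphorylation rate ``1/k_ns_to_s``.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np

__all__ = [
    "ModelParams",
    "DimensionalScales",
    "FieldState",
    "free_energy_density",
    "chemical_potential_pair",
    "switching_fluxes",
    "uniform_steady_state",
    "dimensionless_groups",
    "rates_from_dimensionless",
    "periodic_gradient",
    "periodic_laplacian",
    "load_params",
    "save_params",
]

#: clipping floor used inside logarithms only (the state itself is never clipped)
LOG_EPS = 1e-9


@dataclass
class ModelParams:
    """Dimensionless parameter set of the continuum model.

    Parameters
    ----------
    phi_tot
        Total EPYC1 volume fraction, ``0 < phi_tot < 1``.
    chi
        Sticky–sticky attraction magnitude (positive; larger = stickier).
    kappa_s, kappa_ns
        Interfacial-parameter ratios κ̃_s, κ̃_ns (units of the cross
        parameter κ'_s-ns).  The gradient-energy matrix
        ``[[kappa_s, 1], [1, kappa_ns]]`` must be positive definite,
        i.e. ``kappa_s * kappa_ns > 1``.
    D_tilde
        Ratio of EPYC1 diffusion rate to dephosphorylation rate,
        ``D / (kappa_s_ns_prime * k_ns_to_s)``.
    k_tilde
        Kinase/phosphatase activity ratio ``k_s_to_ns / k_ns_to_s``
        (PDE convention; the droplet module uses the inverse ratio).
    theta
        Contact angle of condensates at no-flux walls (radians); the
        default 5π/6 is strongly anti-wetting.
    """

    phi_tot: float = 0.1
    chi: float = 7.0
    kappa_s: float = 5.0
    kappa_ns: float = 1.0
    D_tilde: float = 10.0
    k_tilde: float = 0.14
    theta: float = 5.0 * math.pi / 6.0

    def __post_init__(self) -> None:
        if not 0.0 < self.phi_tot < 1.0:
            raise ValueError(f"phi_tot must be in (0, 1), got {self.phi_tot}")
        if self.kappa_s <= 0 or self.kappa_ns <= 0:
            raise ValueError("kappa_s and kappa_ns must be positive")
        if self.kappa_s * self.kappa_ns <= 1.0:
            raise ValueError(
                "gradient-energy matrix [[kappa_s,1],[1,kappa_ns]] must be "
                f"positive definite: kappa_s*kappa_ns = "
                f"{self.kappa_s * self.kappa_ns} <= 1"
            )
        if self.D_tilde <= 0:
            raise ValueError("D_tilde must be positive")
        if self.k_tilde < 0:
            raise ValueError("k_tilde must be non-negative")
        if not 0.0 < self.theta < math.pi:
            raise ValueError("theta must be in (0, pi)")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "ModelParams":
        return cls(**d)


@dataclass
class DimensionalScales:
    """Physical-unit counterparts of the dimensionless groups.

    ``c_max`` (maximum molar concentration) only converts volume fractions
    to concentrations; it never enters dimensionless computations.
    """

    D: float = 60.0  # µm² s⁻¹
    k_ns_to_s: float = 294.0  # s⁻¹
    kappa_s_ns_prime: float = (5.0 / 35.0) ** 2  # µm²
    c_max: float = 1.0  # arbitrary concentration unit

    def __post_init__(self) -> None:
        for name in ("D", "k_ns_to_s", "kappa_s_ns_prime", "c_max"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")

    @property
    def length_unit(self) -> float:
        """ℓ_κ = sqrt(κ'_s-ns) in µm (so length_unit² == kappa_s_ns_prime)."""
        return math.sqrt(self.kappa_s_ns_prime)

    @property
    def time_unit(self) -> float:
        """Characteristic time 1/k_ns_to_s in seconds."""
        return 1.0 / self.k_ns_to_s


@dataclass
class FieldState:
    """Volume-fraction fields on a grid at one dimensionless time."""

    phi_s: np.ndarray
    phi_ns: np.ndarray
    time: float = 0.0
    grid_spacing: float = 1.0

    def __post_init__(self) -> None:
        self.phi_s = np.asarray(self.phi_s, dtype=float)
        self.phi_ns = np.asarray(self.phi_ns, dtype=float)
        if self.phi_s.shape != self.phi_ns.shape:
            raise ValueError("phi_s and phi_ns must have the same shape")
        if self.grid_spacing <= 0:
            raise ValueError("grid_spacing must be positive")

    @property
    def phi_sol(self) -> np.ndarray:
        return 1.0 - self.phi_s - self.phi_ns

    def validate(self, tol: float = 1e-10) -> None:
        """Raise if any node violates 0 ≤ φ_i and φ_s + φ_ns ≤ 1."""
        if self.phi_s.min() < -tol or self.phi_ns.min() < -tol:
            raise ValueError("negative volume fraction")
        if (self.phi_s + self.phi_ns).max() > 1.0 + tol:
            raise ValueError("phi_s + phi_ns exceeds 1 (negative solvent)")

    def copy(self) -> "FieldState":
        return FieldState(
            self.phi_s.copy(), self.phi_ns.copy(), self.time, self.grid_spacing
        )


# ---------------------------------------------------------------------------
# periodic finite-difference operators (second-order central)
# ---------------------------------------------------------------------------

def periodic_gradient(f: np.ndarray, h: float) -> list[np.ndarray]:
    """Central-difference gradient with periodic wrapping, one array per axis."""
    return [
        (np.roll(f, -1, axis=a) - np.roll(f, 1, axis=a)) / (2.0 * h)
        for a in range(f.ndim)
    ]


def periodic_laplacian(f: np.ndarray, h: float) -> np.ndarray:
    """Standard 2·ndim+1-point Laplacian with periodic wrapping."""
    out = -2.0 * f.ndim * f
    for a in range(f.ndim):
        out = out + np.roll(f, -1, axis=a) + np.roll(f, 1, axis=a)
    return out / h**2


def _safe_log(x: np.ndarray) -> np.ndarray:
    return np.log(np.clip(x, LOG_EPS, None))


def _check_fractions(state: FieldState) -> None:
    tol = 1e-12
    if (
        state.phi_s.min() < -tol
        or state.phi_ns.min() < -tol
        or state.phi_s.max() > 1.0 + tol
        or state.phi_ns.max() > 1.0 + tol
        or (state.phi_s + state.phi_ns).max() > 1.0 + tol
    ):
        raise ValueError("volume fractions outside the physical domain")


# ---------------------------------------------------------------------------
# thermodynamics
# ---------------------------------------------------------------------------

def free_energy_density(state: FieldState, params: ModelParams) -> np.ndarray:
    """Flory–Huggins free-energy density f/(k_B T) per node.

    Entropy of mixing ``Σ_i φ_i ln φ_i`` over sticky, non-sticky and
    solvent, plus the sticky self-attraction ``-chi * φ_s²``, plus the
    gradient energy ``½ (κ̃_s |∇φ_s|² + 2 ∇φ_s·∇φ_ns + κ̃_ns |∇φ_ns|²)``
    evaluated with periodic central differences.  ``0·ln 0`` is 0.
    """
    _check_fractions(state)
    ps, pns = state.phi_s, state.phi_ns
    psol = state.phi_sol
    entropy = (
        np.where(ps > 0, ps * _safe_log(ps), 0.0)
        + np.where(pns > 0, pns * _safe_log(pns), 0.0)
        + np.where(psol > 0, psol * _safe_log(psol), 0.0)
    )
    interaction = -params.chi * ps**2
    h = state.grid_spacing
    gs = periodic_gradient(ps, h)
    gns = periodic_gradient(pns, h)
    grad = sum(
        0.5 * params.kappa_s * a**2 + a * b + 0.5 * params.kappa_ns * b**2
        for a, b in zip(gs, gns)
    )
    return entropy + interaction + grad


def chemical_potential_pair(
    state: FieldState, params: ModelParams
) -> tuple[np.ndarray, np.ndarray]:
    """Exchange chemical potentials (μ_s − μ_sol, μ_ns − μ_sol) in k_B T.

    Variational derivatives of :func:`free_energy_density` with respect to
    φ_s and φ_ns (solvent eliminated by incompressibility)::

        μ_s  − μ_sol = ln(φ_s /φ_sol) − 2 χ φ_s − κ̃_s ∇²φ_s − ∇²φ_ns
        μ_ns − μ_sol = ln(φ_ns/φ_sol)           − ∇²φ_s − κ̃_ns ∇²φ_ns

    using periodic central-difference Laplacians.
    """
    _check_fractions(state)
    psol = state.phi_sol
    if psol.min() <= 0:
        raise ValueError("phi_sol vanishes somewhere: log divergence")
    h = state.grid_spacing
    lap_s = periodic_laplacian(state.phi_s, h)
    lap_ns = periodic_laplacian(state.phi_ns, h)
    mu_s = (
        _safe_log(state.phi_s)
        - _safe_log(psol)
        - 2.0 * params.chi * state.phi_s
        - params.kappa_s * lap_s
        - lap_ns
    )
    mu_ns = (
        _safe_log(state.phi_ns)
        - _safe_log(psol)
        - lap_s
        - params.kappa_ns * lap_ns
    )
    return mu_s, mu_ns


def switching_fluxes(
    state: FieldState, k_s_to_ns: float, k_ns_to_s: float
) -> tuple[np.ndarray, np.ndarray]:
    """Pointwise phosphorylation/dephosphorylation fluxes.

    ``J_s→ns = k_s→ns φ_s`` and ``J_ns→s = k_ns→s φ_ns``; inserted with
    opposite signs into the two kinetic equations they conserve
    ``φ_s + φ_ns`` exactly.
    """
    if k_s_to_ns < 0 or k_ns_to_s < 0:
        raise ValueError("switching rates must be non-negative")
    return k_s_to_ns * state.phi_s, k_ns_to_s * state.phi_ns


def uniform_steady_state(phi_tot: float, k_tilde: float) -> tuple[float, float]:
    """Uniform fixed point of the reaction kinetics.

    Returns ``(φ_s,0, φ_ns,0) = (φ_tot/(1+k̃), φ_tot k̃/(1+k̃))``; the two
    sum to ``phi_tot`` exactly.  ``k_tilde = inf`` yields ``(0, phi_tot)``.
    """
    if not 0.0 < phi_tot < 1.0:
        raise ValueError("phi_tot must be in (0, 1)")
    if k_tilde < 0:
        raise ValueError("k_tilde must be non-negative")
    if math.isinf(k_tilde):
        return 0.0, phi_tot
    phi_s0 = phi_tot / (1.0 + k_tilde)
    return phi_s0, phi_tot - phi_s0


def dimensionless_groups(
    scales: DimensionalScales, k_s_to_ns: float
) -> tuple[float, float, float, float]:
    """Map physical scales to ``(D̃, k̃, length_unit, time_unit)``.

    ``D̃ = D/(κ'_s-ns k_ns→s)``, ``k̃ = k_s→ns/k_ns→s``; the length unit
    is ``sqrt(κ'_s-ns)`` and the time unit ``1/k_ns→s``.
    """
    if k_s_to_ns < 0:
        raise ValueError("k_s_to_ns must be non-negative")
    D_tilde = scales.D / (scales.kappa_s_ns_prime * scales.k_ns_to_s)
    k_tilde = k_s_to_ns / scales.k_ns_to_s
    return D_tilde, k_tilde, scales.length_unit, scales.time_unit


def rates_from_dimensionless(
    D_tilde: float, k_tilde: float, D: float, kappa_s_ns_prime: float
) -> tuple[float, float]:
    """Inverse of :func:`dimensionless_groups`: recover the physical rates.

    Returns ``(k_ns_to_s, k_s_to_ns)`` given the dimensionless groups and
    the physical diffusivity/interfacial parameter.
    """
    if D_tilde <= 0 or D <= 0 or kappa_s_ns_prime <= 0:
        raise ValueError("D_tilde, D and kappa_s_ns_prime must be positive")
    k_ns_to_s = D / (kappa_s_ns_prime * D_tilde)
    return k_ns_to_s, k_tilde * k_ns_to_s


# ---------------------------------------------------------------------------
# config serialization
# ---------------------------------------------------------------------------

def save_params(params: ModelParams, path: str | Path) -> None:
    """Write parameters to a flat YAML or JSON file (by extension)."""
    path = Path(path)
    d = params.to_dict()
    if path.suffix in {".yaml", ".yml"}:
        import yaml

        path.write_text(yaml.safe_dump(d))
    else:
        path.write_text(json.dumps(d, indent=2))


def load_params(path: str | Path) -> ModelParams:
    """Read parameters from a flat YAML or JSON file."""
    path = Path(path)
    text = path.read_text()
    if path.suffix in {".yaml", ".yml"}:
        import yaml

        d = yaml.safe_load(text)
    else:
        d = json.loads(text)
    return ModelParams.from_dict(d)
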