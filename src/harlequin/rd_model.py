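"""Kinetics of the PeMYB11–PeMYBx activator–inhibitor system.

The model is a two-species Gierer–Meinhardt-type reaction–diffusion system
in which the activator A (the PeMYB11 regulatory system, driving anthocyanin
biosynthesis) self-activates with saturating kinetics, and the diffusible
inhibitor H (the PeMYBx repressor system) is produced by the activator and
represses it::

    dA/dt = G_A * A**2 / (H + k) + rho_A + D_A * lap(A) - mu_A * A
    dH/dt = G_H * A**2            + D_H * lap(H) - mu_H * H

Concentrations are in uM; time and space are dimensionless.  This module
holds the reaction terms, the homogeneous (diffusion-free) fixed point, the
reaction Jacobian, and the linear-stability dispersion relation that
predicts whether spatial (Turing) patterns form and at what wavelength.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.optimize import brentq

__all__ = [
    "KineticParams",
    "HomogeneousState",
    "DispersionResult",
    "STANDARD_PARAMS",
    "reaction_terms",
    "homogeneous_steady_state",
    "jacobian_at",
    "dispersion_relation",
]


@dataclass(frozen=True)
class KineticParams:
    """The eight kinetic coefficients of the activator-inhibitor system.

    Parameters
    ----------
    G_A : float
        Self-activation potency of the activator (concentration/time).
    G_H : float
        Potency of inhibitor production driven by A**2 (1/(concentration*time)).
    D_A, D_H : float
        Diffusion rates (area/time).  Pattern formation requires ``D_H > D_A``.
    mu_A, mu_H : float
        First-order degradation rates (1/time).
    rho_A : float
        Basal (activator-independent) production of A (concentration/time).
    k : float
        Saturation constant in the activation term (uM); keeps the
        self-activation finite when the inhibitor is absent.
    """

    G_A: float
    G_H: float
    D_A: float
    D_H: float
    mu_A: float
    mu_H: float
    rho_A: float
    k: float

    def __post_init__(self) -> None:
        for name in ("G_A", "G_H", "D_A", "D_H", "mu_A", "mu_H", "k"):
            value = getattr(self, name)
            if not value > 0:
                raise ValueError(f"{name} must be strictly positive, got {value}")
        if self.rho_A < 0:
            raise ValueError(f"rho_A must be >= 0, got {self.rho_A}")
        # Pattern formation needs D_H > D_A; equality is allowed so that
        # the no-pattern control (equal diffusion) can be constructed.
        if self.D_H < self.D_A:
            raise ValueError(
                f"D_H ({self.D_H}) must not be smaller than D_A ({self.D_A}); "
                "lateral inhibition requires the inhibitor to diffuse faster"
            )

    def with_overrides(self, **overrides: float) -> "KineticParams":
        """Return a copy with the given coefficients replaced."""
        return replace(self, **overrides)


#: The standard parameter set of the spotted-patterning baseline
#: (Ding et al. 2020 values).
STANDARD_PARAMS = KineticParams(
    G_A=0.08, G_H=0.12, D_A=0.01, D_H=0.5,
    mu_A=0.03, mu_H=0.03, rho_A=0.01, k=0.001,
)


@dataclass(frozen=True)
class HomogeneousState:
    """A spatially uniform fixed point (A*, H*) of the reaction kinetics."""

    A_star: float
    H_star: float


@dataclass(frozen=True)
class DispersionResult:
    """Linear growth rates of spatial perturbations versus wavenumber.

    ``turing_unstable`` is True iff some wavenumber q > 0 grows
    (``lambda_max > 0``) while the uniform (q = 0) mode decays — the
    signature of a diffusion-driven instability.
    """

    wavenumbers: np.ndarray
    growth_rates: np.ndarray
    q_max: float
    lambda_max: float
    turing_unstable: bool


def reaction_terms(A, H, params: KineticParams, GA_map=None):
    """Evaluate the reaction (non-diffusive) part of both equations.

    Parameters
    ----------
    A, H : array_like or scalar
        Nonnegative concentrations of matching shape.
    params : KineticParams
    GA_map : array_like, optional
        Spatially varying self-activation potency overriding ``params.G_A``
        pointwise (used for piece-wise G_A scenarios).

    Returns
    -------
    (dA_dt, dH_dt) with the shape of the inputs.
    """
    A = np.asarray(A, dtype=float)
    H = np.asarray(H, dtype=float)
    if A.shape != H.shape:
        raise ValueError(f"shape mismatch: A {A.shape} vs H {H.shape}")
    if np.any(A < 0) or np.any(H < 0):
        raise ValueError("negative concentration passed to reaction_terms")
    G_A = params.G_A if GA_map is None else np.asarray(GA_map, dtype=float)
    dA_dt = G_A * A**2 / (H + params.k) + params.rho_A - params.mu_A * A
    dH_dt = params.G_H * A**2 - params.mu_H * H
    if A.ndim == 0:
        return float(dA_dt), float(dH_dt)
    return dA_dt, dH_dt


def _activator_balance(A: float, params: KineticParams) -> float:
    # Scalar residual of dA/dt = 0 after eliminating H via H = (G_H/mu_H) A^2.
    H = params.G_H / params.mu_H * A**2
    return params.G_A * A**2 / (H + params.k) + params.rho_A - params.mu_A * A


def homogeneous_steady_state(
    params: KineticParams, residual_tol: float = 1e-10
) -> HomogeneousState:
    """Find the positive homogeneous fixed point of the kinetics.

    Setting dH/dt = 0 gives H* = (G_H/mu_H) A*^2; substituting into
    dA/dt = 0 leaves one scalar equation in A*, solved by a bracketed
    root search.  When several positive roots exist the largest (the
    upper, patterning-relevant branch) is returned.

    Raises
    ------
    RuntimeError
        If no positive root exists in the search bracket, or the root
        does not satisfy both reaction residuals below ``residual_tol``.
    """
    # Upper bracket: generous bound above the saturated balance
    # A ~ (G_A mu_H / G_H + rho_A) / mu_A.
    A_hi = 10.0 * (
        params.G_A / (params.mu_A * params.G_H / params.mu_H)
        + params.rho_A / params.mu_A
    )
    A_lo = 1e-8
    # Scan a geometric grid and keep the last sign change so that the
    # largest root is selected deterministically.
    grid = np.geomspace(A_lo, A_hi, 512)
    vals = np.array([_activator_balance(a, params) for a in grid])
    sign_flips = np.nonzero(np.diff(np.sign(vals)) != 0)[0]
    if len(sign_flips) == 0:
        raise RuntimeError(
            "no positive fixed point found in bracket "
            f"[{A_lo:g}, {A_hi:g}] for params {params}"
        )
    i = sign_flips[-1]
    A_star = brentq(
        _activator_balance, grid[i], grid[i + 1], args=(params,),
        xtol=1e-14, rtol=1e-15,
    )
    H_star = params.G_H / params.mu_H * A_star**2
    dA, dH = reaction_terms(A_star, H_star, params)
    if abs(dA) > residual_tol or abs(dH) > residual_tol:
        raise RuntimeError(
            f"fixed point residuals too large: dA={dA:.3e}, dH={dH:.3e}"
        )
    return HomogeneousState(A_star=A_star, H_star=H_star)


def jacobian_at(params: KineticParams, state: HomogeneousState):
    """Partial derivatives of the reaction terms at a fixed point.

    Returns ``(f_A, f_H, g_A, g_H)`` where f is the activator equation and
    g the inhibitor equation.
    """
    A, H = state.A_star, state.H_star
    denom = H + params.k
    f_A = 2.0 * params.G_A * A / denom - params.mu_A
    f_H = -params.G_A * A**2 / denom**2
    g_A = 2.0 * params.G_H * A
    g_H = -params.mu_H
    return f_A, f_H, g_A, g_H


def dispersion_relation(
    params: KineticParams,
    state: HomogeneousState,
    q_max: float = float(np.pi),
    n_q: int = 200,
    fixed_point_tol: float = 1e-8,
) -> DispersionResult:
    """Growth rate of spatial perturbations ~exp(lambda t + i q.x).

    For each wavenumber q the growth rate is the largest real part of the
    eigenvalues of ``[[f_A - D_A q^2, f_H], [g_A, g_H - D_H q^2]]``.

    The default wavenumber grid spans [0, pi] (in grid units, unit
    spacing), which contains the unstable band of every scenario here.
    """
    if q_max <= 0 or n_q < 2:
        raise ValueError("q_max must be > 0 and n_q >= 2")
    dA, dH = reaction_terms(state.A_star, state.H_star, params)
    if abs(dA) > fixed_point_tol or abs(dH) > fixed_point_tol:
        raise ValueError(
            "dispersion_relation requires a fixed point; residuals "
            f"dA={dA:.3e}, dH={dH:.3e}"
        )
    f_A, f_H, g_A, g_H = jacobian_at(params, state)
    q = np.linspace(0.0, q_max, n_q)
    growth = np.empty_like(q)
    for idx, qi in enumerate(q):
        J = np.array([
            [f_A - params.D_A * qi**2, f_H],
            [g_A, g_H - params.D_H * qi**2],
        ])
        growth[idx] = np.max(np.linalg.eigvals(J).real)
    i_best = int(np.argmax(growth))
    lambda_max = float(growth[i_best])
    unstable = bool(lambda_max > 0 and q[i_best] > 0 and growth[0] < 0)
    return DispersionResult(
        wavenumbers=q,
        growth_rates=growth,
        q_max=float(q[i_best]),
        lambda_max=lambda_max,
        turing_unstable=unstable,
    )
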