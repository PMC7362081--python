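"""Closed-form multifractal hydrodynamic fields and the mass-release law.

The release dynamics of structural units (polymer--payload aggregates) are
modelled on continuous but non-differentiable (multifractal) trajectories.
At a fixed scale resolution the dynamics reduce to a Madelung-type
hydrodynamic pair -- a momentum equation with a quantum-like potential and a
continuity equation -- whose one-dimensional solution for a Gaussian initial
density and uniform initial velocity is available in closed form:

    V(x, t) = [V0 a^2 + (s/a)^2 x t] / [a^2 + (s/a)^2 t^2]
    rho(x, t) = pi^(-1/2) [a^2 + (s/a)^2 t^2]^(-1/2)
                * exp(-(x - V0 t)^2 / (a^2 + (s/a)^2 t^2))

with ``a`` the initial Gaussian width, ``V0`` the initial velocity and ``s``
(sigma) the diffusion-like scale coefficient.  Sigma encodes the fractality
degree f(alpha) of the motion curves through

    sigma = lam * dt^(2/f(alpha) - 1)

where ``lam`` is the fractal/non-fractal transition coefficient and ``dt``
the scale resolution.  In nondimensional variables xi = x/(V0 tau0),
eta = t/tau0 the solution collapses to two shape parameters

    mu = sigma tau0 / a^2   (fractality degree parameter)
    phi = a / (V0 tau0)     (width parameter)

and the released mass follows from the local depletion of the density at a
fixed observation coordinate:  dM/deta = -m0 * d rho(mu, xi, eta)/d eta.

All functions are pure, vectorized over coordinates, and deterministic.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = [
    "ScaleParams",
    "HydroParams",
    "NondimParams",
    "ReleaseModelParams",
    "sigma_from_scale",
    "fractality_from_sigma",
    "nondimensionalize",
    "to_nondim_coords",
    "from_nondim_coords",
    "velocity_field",
    "density_field",
    "dimensional_velocity",
    "dimensional_density",
    "pde_residual",
    "pde_residual_max",
    "mass_release_rate",
    "cumulative_release",
]

# Exponent saturation bound: arguments of exp() are clipped to +-700 so that
# extreme parameter combinations saturate instead of overflowing.
_EXP_CLIP = 700.0


def _safe_exp(z):
    return np.exp(np.clip(z, -_EXP_CLIP, _EXP_CLIP))


# ---------------------------------------------------------------------------
# Parameter containers
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ScaleParams:
    """Multifractal scale quantities.

    Parameters
    ----------
    lam : float
        Scale-transition coefficient (length^2/time), >= 0.  ``lam == 0`` is
        the non-fractal limit (sigma = 0).
    dt : float
        Scale resolution, > 0 (dimensionless in nondimensional use).
    f_alpha : float
        Singularity-spectrum value, i.e. the effective fractal dimension of
        the motion curves, > 0.
    """

    lam: float
    dt: float
    f_alpha: float

    def __post_init__(self):
        if self.lam < 0:
            raise ValueError(f"lam must be >= 0, got {self.lam}")
        if self.dt <= 0:
            raise ValueError(f"dt must be > 0, got {self.dt}")
        if self.f_alpha <= 0:
            raise ValueError(f"f_alpha must be > 0, got {self.f_alpha}")


@dataclass(frozen=True)
class HydroParams:
    """Dimensional hydrodynamic model parameters.

    Parameters
    ----------
    v0 : float
        Initial (and comoving boundary) velocity, length/time, > 0.
    alpha : float
        Width of the initial Gaussian position distribution, length, > 0.
    sigma : float
        Diffusion-like scale coefficient, length^2/time, >= 0.
    tau0 : float
        Specific time used for nondimensionalization, time, > 0.
    """

    v0: float
    alpha: float
    sigma: float
    tau0: float

    def __post_init__(self):
        if self.alpha <= 0:
            raise ValueError(f"alpha must be > 0, got {self.alpha}")
        if self.tau0 <= 0:
            raise ValueError(f"tau0 must be > 0, got {self.tau0}")
        if self.sigma < 0:
            raise ValueError(f"sigma must be >= 0, got {self.sigma}")


@dataclass(frozen=True)
class NondimParams:
    """Nondimensional shape parameters (mu, phi)."""

    mu: float
    phi: float

    def __post_init__(self):
        if self.mu < 0:
            raise ValueError(f"mu must be >= 0, got {self.mu}")
        if self.phi <= 0:
            raise ValueError(f"phi must be > 0, got {self.phi}")


@dataclass(frozen=True)
class ReleaseModelParams:
    """Parameters of the nondimensional mass-release law.

    ``m0_bar`` is the nondimensional releasable mass of the structural units
    (the asymptotic released fraction); ``xi_obs`` is the fixed observation
    coordinate at which the density depletion is read (default 0, the peak of
    the initial density, i.e. the matrix position).
    """

    mu: float
    phi: float
    m0_bar: float
    xi_obs: float = 0.0

    def __post_init__(self):
        if self.mu < 0:
            raise ValueError(f"mu must be >= 0, got {self.mu}")
        if self.phi <= 0:
            raise ValueError(f"phi must be > 0, got {self.phi}")
        if self.m0_bar <= 0:
            raise ValueError(f"m0_bar must be > 0, got {self.m0_bar}")


# ---------------------------------------------------------------------------
# Scale relation
# ---------------------------------------------------------------------------


def sigma_from_scale(scale: ScaleParams) -> float:
    """Diffusion-like coefficient from the scale quantities.

    sigma = lam * dt**(2/f_alpha - 1).  At f_alpha = 2 the exponent vanishes
    and sigma = lam regardless of dt; lam = 0 gives the non-fractal limit.
    """
    exponent = 2.0 / scale.f_alpha - 1.0
    return scale.lam * scale.dt**exponent


def fractality_from_sigma(sigma: float, lam: float, dt: float) -> float:
    """Invert the scale relation for the fractality degree f(alpha).

    Solves sigma = lam * dt**(2/f - 1) for f, i.e.
    f = 2 / (1 + ln(sigma/lam)/ln(dt)).

    Raises
    ------
    ValueError
        If sigma <= 0, lam <= 0, dt <= 0, dt == 1 (exponent unidentifiable)
        or the implied f(alpha) is not positive.
    """
    if sigma <= 0:
        raise ValueError(f"sigma must be > 0 to invert, got {sigma}")
    if lam <= 0:
        raise ValueError(f"lam must be > 0, got {lam}")
    if dt <= 0:
        raise ValueError(f"dt must be > 0, got {dt}")
    if dt == 1.0:
        raise ValueError("dt == 1 makes the exponent unidentifiable")
    e = math.log(sigma / lam) / math.log(dt)
    denom = 1.0 + e
    if denom <= 0:
        raise ValueError(
            f"sigma={sigma}, lam={lam}, dt={dt} imply a nonpositive "
            "fractality degree"
        )
    return 2.0 / denom


# ---------------------------------------------------------------------------
# Nondimensionalization
# ---------------------------------------------------------------------------


def nondimensionalize(h: HydroParams) -> NondimParams:
    """Map dimensional parameters to (mu, phi).

    mu = sigma * tau0 / alpha**2,  phi = alpha / (v0 * tau0).
    """
    if h.v0 == 0:
        raise ValueError("v0 must be nonzero: phi is undefined at v0 = 0")
    if h.v0 < 0:
        raise ValueError("v0 must be positive (phi > 0 required)")
    return NondimParams(
        mu=h.sigma * h.tau0 / h.alpha**2,
        phi=h.alpha / (h.v0 * h.tau0),
    )


def to_nondim_coords(x, t, h: HydroParams):
    """(x, t) -> (xi, eta) with xi = x/(v0 tau0), eta = t/tau0."""
    x = np.asarray(x, dtype=float)
    t = np.asarray(t, dtype=float)
    return x / (h.v0 * h.tau0), t / h.tau0


def from_nondim_coords(xi, eta, h: HydroParams):
    """(xi, eta) -> (x, t); exact inverse of :func:`to_nondim_coords`."""
    xi = np.asarray(xi, dtype=float)
    eta = np.asarray(eta, dtype=float)
    return xi * h.v0 * h.tau0, eta * h.tau0


# ---------------------------------------------------------------------------
# Nondimensional fields
# ---------------------------------------------------------------------------


def velocity_field(mu, xi, eta):
    """Nondimensional velocity V/V0 = (1 + mu^2 xi eta) / (1 + mu^2 eta^2).

    Equals 1 on the comoving boundary xi = eta and at eta = 0 (initial
    condition).
    """
    mu = np.asarray(mu, dtype=float)
    xi = np.asarray(xi, dtype=float)
    eta = np.asarray(eta, dtype=float)
    a = 1.0 + mu**2 * eta**2
    return (1.0 + mu**2 * xi * eta) / a


def density_field(mu, phi, xi, eta):
    """Nondimensional density.

    rho_bar = (1 + mu^2 eta^2)^(-1/2)
              * exp(-(xi - eta)^2 / (phi^2 (1 + mu^2 eta^2)))

    which is sqrt(pi)*alpha times the dimensional density; values in (0, 1].
    """
    if np.any(np.asarray(phi, dtype=float) <= 0):
        raise ValueError("phi must be > 0")
    mu = np.asarray(mu, dtype=float)
    phi = np.asarray(phi, dtype=float)
    xi = np.asarray(xi, dtype=float)
    eta = np.asarray(eta, dtype=float)
    a = 1.0 + mu**2 * eta**2
    return a**-0.5 * _safe_exp(-((xi - eta) ** 2) / (phi**2 * a))


# ---------------------------------------------------------------------------
# Dimensional fields
# ---------------------------------------------------------------------------


def _width_sq(t, h: HydroParams):
    """Time-dependent squared width alpha^2 + (sigma/alpha)^2 t^2."""
    return h.alpha**2 + (h.sigma / h.alpha) ** 2 * t**2


def dimensional_velocity(x, t, h: HydroParams):
    """Dimensional velocity field V(x, t).

    V = [v0 alpha^2 + (sigma/alpha)^2 x t] / [alpha^2 + (sigma/alpha)^2 t^2].
    Equals v0 at t = 0 (for every x) and on the comoving line x = v0 t.
    """
    x = np.asarray(x, dtype=float)
    t = np.asarray(t, dtype=float)
    d = _width_sq(t, h)
    return (h.v0 * h.alpha**2 + (h.sigma / h.alpha) ** 2 * x * t) / d


def dimensional_density(x, t, h: HydroParams):
    """Dimensional density rho(x, t); a spreading, translating Gaussian.

    rho = pi^(-1/2) D^(-1/2) exp(-(x - v0 t)^2 / D) with
    D = alpha^2 + (sigma/alpha)^2 t^2.  Normalized: integral over x is 1 at
    every t.  Sigma = 0 gives rigid translation without spreading.
    """
    x = np.asarray(x, dtype=float)
    t = np.asarray(t, dtype=float)
    d = _width_sq(t, h)
    return math.pi**-0.5 * d**-0.5 * _safe_exp(-((x - h.v0 * t) ** 2) / d)


# ---------------------------------------------------------------------------
# PDE residual oracle
# ---------------------------------------------------------------------------


def pde_residual(h: HydroParams, x_grid, t_grid):
    """Finite-difference residuals of the hydrodynamic pair on the
    analytic fields.

    Evaluates, with centered second-order differences on the closed-form
    (V, rho):

    * the momentum balance  dV/dt + V dV/dx - (sigma^2/2) d/dx[(d2 sqrt(rho)/
      dx2)/sqrt(rho)],
    * the continuity equation  d rho/dt + d(rho V)/dx.

    Returns the two residual matrices on the interior of the grid (three
    cells trimmed on every edge, where the nested one-sided gradient
    stencils degrade the order), together with the corresponding interior density values so
    callers can weight or mask by the amount of material present.

    Parameters
    ----------
    h : HydroParams
    x_grid, t_grid : array_like
        Strictly increasing, uniformly spaced, >= 5 points each.

    Returns
    -------
    dict with keys ``momentum``, ``continuity``, ``density`` (arrays of shape
    (len(t_grid)-6, len(x_grid)-6)), ``dx``, ``dt``.
    """
    x = np.asarray(x_grid, dtype=float)
    t = np.asarray(t_grid, dtype=float)
    for name, g in (("x_grid", x), ("t_grid", t)):
        if g.ndim != 1 or g.size < 5:
            raise ValueError(f"{name} must be 1-D with at least 5 points")
        d = np.diff(g)
        if np.any(d <= 0):
            raise ValueError(f"{name} must be strictly increasing")
        if not np.allclose(d, d[0], rtol=1e-10):
            raise ValueError(f"{name} must be uniformly spaced")
    dx = x[1] - x[0]
    dt = t[1] - t[0]

    tt, xx = np.meshgrid(t, x, indexing="ij")
    v = dimensional_velocity(xx, tt, h)
    rho = dimensional_density(xx, tt, h)
    s = np.sqrt(rho)

    d_dt = lambda f: np.gradient(f, dt, axis=0)
    d_dx = lambda f: np.gradient(f, dx, axis=1)

    # Quantum-like potential term: q = (d2 sqrt(rho)/dx2) / sqrt(rho).
    # Coefficient sigma^2/2: the unique multiple under which the closed-form
    # (V, rho) pair solves the momentum balance exactly (the free-packet
    # Madelung correspondence sigma = hbar/m gives hbar^2/2m^2 = sigma^2/2).
    sxx = d_dx(d_dx(s))
    q = sxx / s
    force = 0.5 * h.sigma**2 * d_dx(q)

    res_momentum = d_dt(v) + v * d_dx(v) - force
    res_continuity = d_dt(rho) + d_dx(rho * v)

    sl = (slice(3, -3), slice(3, -3))
    return {
        "momentum": res_momentum[sl],
        "continuity": res_continuity[sl],
        "density": rho[sl],
        "dx": dx,
        "dt": dt,
    }


def pde_residual_max(h: HydroParams, x_grid, t_grid, density_floor: float = 1e-3):
    """Max |residual| of both equations, restricted to where material exists.

    The momentum residual is weighted by the normalized density (momentum-
    density form): far from the packet both rho and the momentum it carries
    vanish, and the unweighted defect there is dominated by amplification of
    discretization error through the 1/sqrt(rho) factor of the quantum-like
    term.  The continuity residual is evaluated unweighted wherever
    rho/max(rho) >= ``density_floor``.

    Returns (max_momentum, max_continuity).
    """
    r = pde_residual(h, x_grid, t_grid)
    w = r["density"] / r["density"].max()
    mask = w >= density_floor
    mom = np.abs(r["momentum"] * w).max()
    cont = np.abs(r["continuity"][mask]).max()
    return float(mom), float(cont)


# ---------------------------------------------------------------------------
# Mass-release law
# ---------------------------------------------------------------------------


def _drho_deta(mu, phi, xi, eta):
    """Closed-form d rho_bar / d eta at fixed xi."""
    a = 1.0 + mu**2 * eta**2
    r = density_field(mu, phi, xi, eta)
    u = xi - eta
    return r * (
        -(mu**2) * eta / a
        + 2.0 * u / (phi**2 * a)
        + 2.0 * mu**2 * eta * u**2 / (phi**2 * a**2)
    )


def mass_release_rate(p: ReleaseModelParams, eta):
    """Nondimensional release rate dM/deta = -m0_bar * d rho_bar/d eta.

    Evaluated at the fixed observation coordinate ``p.xi_obs`` with the
    analytic derivative of the density field.  Nonnegative for all eta >= 0
    when xi_obs = 0 (the density at the matrix peak only ever depletes).
    """
    eta = np.asarray(eta, dtype=float)
    if np.any(eta < 0):
        raise ValueError("eta must be >= 0")
    return -p.m0_bar * _drho_deta(p.mu, p.phi, p.xi_obs, eta)


def cumulative_release(p: ReleaseModelParams, eta):
    """Cumulative nondimensional released mass M(eta).

    Antiderivative of the release rate, normalized by the initial density at
    the observation point so that m0_bar is directly the asymptotic released
    fraction:

        M(eta) = m0_bar * [rho(xi_obs, 0) - rho(xi_obs, eta)] / rho(xi_obs, 0)

    M(0) = 0, M is nondecreasing for xi_obs = 0, and M -> m0_bar as
    eta -> infinity.
    """
    eta = np.asarray(eta, dtype=float)
    if np.any(eta < 0):
        raise ValueError("eta must be >= 0")
    rho0 = density_field(p.mu, p.phi, p.xi_obs, 0.0)
    rho = density_field(p.mu, p.phi, p.xi_obs, eta)
    return p.m0_bar * (rho0 - rho) / rho0
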