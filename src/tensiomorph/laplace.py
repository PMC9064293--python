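"""Axisymmetric Young–Laplace forward model for sessile tissue aggregates.

A liquid-like tissue aggregate resting on a plate under gravity takes an
equilibrium shape in which the pressure jump across its surface balances
surface tension times total curvature:

    ``dP0 + drho * g * z = gamma * (1/R1 + 1/R2)``

with ``dP0 = 2*gamma/R0`` the apex pressure jump, ``z`` the depth below the
apex, and ``R1``, ``R2`` the meridional and azimuthal radii of curvature.
In the Bashforth–Adams arc-length parametrization this becomes the ODE
system

    dx/ds = cos(theta),  dz/ds = sin(theta),
    dtheta/ds = 2/R0 + c*z - sin(theta)/x,      c = drho*g/gamma,

integrated from the (umbilic) apex where ``x = z = theta = 0`` and
``sin(theta)/x -> 1/R0``.  The dimensionless group controlling gravity
flattening is the Bond number ``Bo = drho*g*R0**2/gamma``; at ``Bo = 0``
the shape is a sphere and carries no tension information.

Internally the system is integrated in units of the apex radius (so only
``Bo`` enters), which makes the solution exactly scale-equivariant.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import solve_ivp

__all__ = [
    "FluidContext",
    "TheoreticalProfile",
    "integrate_profile",
    "integrate_profile_fixed_rk4",
    "profile_curvatures",
]

#: default gravitational acceleration, m/s^2 (standard gravity)
G_STANDARD = 9.80665

#: apex series is used for s < APEX_EPS * R0 before handing to the integrator
APEX_EPS = 1e-4


class LaplaceIntegrationError(RuntimeError):
    """Raised when profile integration fails or reaches a non-physical state."""


@dataclass(frozen=True)
class FluidContext:
    """Fluid parameters of a tissue/medium pairing.

    Parameters
    ----------
    gamma : float
        Surface (or interfacial) tension, N/m.  Tissue tensions are of
        order 0.1–5 mN/m.
    delta_rho : float
        Density difference tissue minus medium, kg/m^3.  Must be supplied
        from config; there is no biological default.
    g : float
        Gravitational acceleration, m/s^2.
    """

    gamma: float
    delta_rho: float
    g: float = G_STANDARD

    def __post_init__(self) -> None:
        if not (self.gamma > 0):
            raise ValueError(f"gamma must be > 0, got {self.gamma}")
        if self.delta_rho < 0:
            raise ValueError(f"delta_rho must be >= 0, got {self.delta_rho}")
        if not (self.g > 0):
            raise ValueError(f"g must be > 0, got {self.g}")

    @property
    def capillary_constant(self) -> float:
        """c = delta_rho * g / gamma, 1/m^2."""
        return self.delta_rho * self.g / self.gamma

    def bond_number(self, apex_radius: float) -> float:
        """Bo = delta_rho * g * R0^2 / gamma for a given apex radius (m)."""
        return self.capillary_constant * apex_radius**2


@dataclass
class TheoreticalProfile:
    """A forward-integrated axisymmetric drop profile.

    Coordinates are one meridional section: ``x(s) >= 0`` is the radial
    distance from the symmetry axis, ``z(s) >= 0`` the depth below the apex
    (increasing toward the supporting substrate for a sessile aggregate
    denser than its medium), ``theta(s)`` the tangent angle.  ``R1``/``R2``
    are filled in by :func:`profile_curvatures`.
    """

    s: np.ndarray
    x: np.ndarray
    z: np.ndarray
    theta: np.ndarray
    apex_radius: float
    gamma: float
    delta_rho: float
    g: float
    R1: np.ndarray | None = None
    R2: np.ndarray | None = None
    meta: dict = field(default_factory=dict)

    @property
    def bond_number(self) -> float:
        return self.delta_rho * self.g * self.apex_radius**2 / self.gamma

    @property
    def apex_pressure(self) -> float:
        """dP0 = 2*gamma/R0, Pa."""
        return 2.0 * self.gamma / self.apex_radius

    @property
    def capillary_constant(self) -> float:
        return self.delta_rho * self.g / self.gamma

    def equatorial_radius(self) -> float:
        """x at theta = pi/2, by local cubic interpolation of x(theta)."""
        th, xx = self.theta, self.x
        if th[-1] < np.pi / 2:
            raise ValueError("profile does not reach theta = pi/2")
        k = int(np.searchsorted(th, np.pi / 2))
        lo, hi = max(0, k - 4), min(len(th), k + 4)
        from scipy.interpolate import CubicSpline

        return float(CubicSpline(th[lo:hi], xx[lo:hi])(np.pi / 2))

    def outline(self) -> np.ndarray:
        """Full mirrored 2-D outline (n, 2) in (x, z), left side first."""
        left = np.column_stack([-self.x[::-1], self.z[::-1]])
        right = np.column_stack([self.x[1:], self.z[1:]])
        return np.vstack([left, right])

    def to_dataframe(self):
        import pandas as pd

        d = {"s": self.s, "x": self.x, "z": self.z, "theta": self.theta}
        if self.R1 is not None:
            d["R1"] = self.R1
            d["R2"] = self.R2
        return pd.DataFrame(d)


def _apex_series(u: float, bo: float) -> tuple[float, float, float]:
    """Dimensionless apex expansion at arc length u = s/R0.

    theta = u + Bo*u^3/8, x = u - u^3/6, z = u^2/2 + (Bo/8 - 1/6)*u^4/4,
    valid to O(u^5); used to step off the removable singularity at s = 0.
    """
    theta = u + bo * u**3 / 8.0
    x = u - u**3 / 6.0
    z = u**2 / 2.0 + (bo / 8.0 - 1.0 / 6.0) * u**4 / 4.0
    return x, z, theta


def _rhs(u, y, bo):
    x, z, theta = y
    return [np.cos(theta), np.sin(theta), 2.0 + bo * z - np.sin(theta) / x]


def integrate_profile(
    ctx: FluidContext,
    R0: float,
    s_max: float | None = None,
    tolerance: float = 1e-9,
    n_samples: int = 400,
) -> TheoreticalProfile:
    """Integrate the Young–Laplace profile for apex radius ``R0``.

    Integration runs from the apex out to arc length ``s_max`` (default
    ``30*R0``) or until the tangent angle reaches pi, whichever comes
    first.  The apex singularity is bridged with a series expansion for
    ``s < 1e-4 * R0``; the remainder uses an adaptive 8th-order
    Runge–Kutta (DOP853) at relative tolerance ``tolerance``.

    Returns a densely sampled :class:`TheoreticalProfile` (``n_samples``
    points uniform in arc length, plus the terminal point).
    """
    if not (R0 > 0):
        raise ValueError(f"R0 must be > 0, got {R0}")
    if s_max is None:
        s_max = 30.0 * R0
    if not (s_max > 0):
        raise ValueError(f"s_max must be > 0, got {s_max}")

    bo = ctx.bond_number(R0)
    u_max = s_max / R0
    u0 = APEX_EPS
    y0 = _apex_series(u0, bo)

    def theta_reaches_pi(u, y, bo):
        return y[2] - np.pi

    theta_reaches_pi.terminal = True
    theta_reaches_pi.direction = 1

    sol = solve_ivp(
        _rhs,
        (u0, u_max),
        y0,
        method="DOP853",
        rtol=tolerance,
        atol=tolerance * 1e-2,
        max_step=0.05,  # keep steps small enough not to jump the theta=pi closure
        dense_output=True,
        events=theta_reaches_pi,
        args=(bo,),
    )
    if not sol.success:
        raise LaplaceIntegrationError(
            f"Young-Laplace integration failed (Bo={bo:.4g}): {sol.message}"
        )
    u_end = sol.t[-1]
    u_grid = np.linspace(0.0, u_end, n_samples)
    # evaluate: series near apex, dense output beyond
    x = np.empty_like(u_grid)
    z = np.empty_like(u_grid)
    th = np.empty_like(u_grid)
    near = u_grid <= u0
    if near.any():
        xs, zs, ts = _apex_series(u_grid[near], bo)
        x[near], z[near], th[near] = xs, zs, ts
    far = ~near
    if far.any():
        y = sol.sol(u_grid[far])
        x[far], z[far], th[far] = y[0], y[1], y[2]
    x[0], z[0], th[0] = 0.0, 0.0, 0.0
    # the theta=pi closure point can land at x = -eps numerically (sphere limit)
    if np.any(x < -1e-6 * max(x.max(), 1e-30)):
        raise LaplaceIntegrationError(
            f"non-physical state: x < 0 encountered (Bo={bo:.4g})"
        )
    x = np.clip(x, 0.0, None)

    return TheoreticalProfile(
        s=u_grid * R0,
        x=x * R0,
        z=z * R0,
        theta=th,
        apex_radius=R0,
        gamma=ctx.gamma,
        delta_rho=ctx.delta_rho,
        g=ctx.g,
        meta={"bond_number": bo, "terminated_at_theta_pi": bool(sol.t_events[0].size)},
    )


def integrate_profile_fixed_rk4(
    ctx: FluidContext,
    R0: float,
    s_max: float | None = None,
    n_steps: int = 200_000,
) -> TheoreticalProfile:
    """Reference integrator: classical fixed-step 4th-order Runge–Kutta.

    Deliberately independent of :func:`integrate_profile` (no adaptive
    stepping, no dense output); used to cross-check the adaptive path.
    Stops at theta >= pi by linear interpolation of the final step.
    """
    if not (R0 > 0):
        raise ValueError(f"R0 must be > 0, got {R0}")
    if s_max is None:
        s_max = 30.0 * R0
    bo = ctx.bond_number(R0)
    u_max = s_max / R0
    h = (u_max - APEX_EPS) / n_steps
    x, z, th = _apex_series(APEX_EPS, bo)
    u = APEX_EPS

    def f(x, z, th):
        return np.cos(th), np.sin(th), 2.0 + bo * z - np.sin(th) / x

    us = [0.0, u]
    xs = [0.0, x]
    zs = [0.0, z]
    ths = [0.0, th]
    for _ in range(n_steps):
        k1 = f(x, z, th)
        k2 = f(x + 0.5 * h * k1[0], z + 0.5 * h * k1[1], th + 0.5 * h * k1[2])
        k3 = f(x + 0.5 * h * k2[0], z + 0.5 * h * k2[1], th + 0.5 * h * k2[2])
        k4 = f(x + h * k3[0], z + h * k3[1], th + h * k3[2])
        xn = x + h / 6.0 * (k1[0] + 2 * k2[0] + 2 * k3[0] + k4[0])
        zn = z + h / 6.0 * (k1[1] + 2 * k2[1] + 2 * k3[1] + k4[1])
        thn = th + h / 6.0 * (k1[2] + 2 * k2[2] + 2 * k3[2] + k4[2])
        u += h
        if thn >= np.pi:
            w = (np.pi - th) / (thn - th)
            us.append(u - h + w * h)
            xs.append(x + w * (xn - x))
            zs.append(z + w * (zn - z))
            ths.append(np.pi)
            break
        x, z, th = xn, zn, thn
        us.append(u)
        xs.append(x)
        zs.append(z)
        ths.append(th)

    return TheoreticalProfile(
        s=np.asarray(us) * R0,
        x=np.asarray(xs) * R0,
        z=np.asarray(zs) * R0,
        theta=np.asarray(ths),
        apex_radius=R0,
        gamma=ctx.gamma,
        delta_rho=ctx.delta_rho,
        g=ctx.g,
        meta={"bond_number": bo, "integrator": "fixed-step RK4", "n_steps": n_steps},
    )


def profile_curvatures(p: TheoreticalProfile) -> TheoreticalProfile:
    """Populate principal radii R1 (meridional) and R2 (azimuthal) in place.

    R1 = 1/(dtheta/ds) from the governing ODE; R2 = x/sin(theta).  At the
    apex both equal R0 (umbilic point); the sin(theta)/x limit is taken
    analytically rather than by division.
    """
    R0 = p.apex_radius
    c = p.capillary_constant
    with np.errstate(divide="ignore", invalid="ignore"):
        sin_over_x = np.where(p.x > 0, np.sin(p.theta) / np.where(p.x > 0, p.x, 1.0), 1.0 / R0)
        dtheta_ds = 2.0 / R0 + c * p.z - sin_over_x
        R1 = 1.0 / dtheta_ds
        R2 = np.where(p.x > 0, np.where(np.sin(p.theta) != 0, p.x / np.where(np.sin(p.theta) != 0, np.sin(p.theta), 1.0), np.inf), R0)
    R1[0] = R0
    R2[0] = R0
    p.R1 = R1
    p.R2 = R2
    return p


def laplace_residual(p: TheoreticalProfile) -> np.ndarray:
    """Pointwise residual of the housed equation, normalized by dP0.

    |dP0 + drho*g*z - gamma*(1/R1 + 1/R2)| / dP0 per sample; requires
    curvatures to be populated.
    """
    if p.R1 is None or p.R2 is None:
        profile_curvatures(p)
    dp0 = p.apex_pressure
    lhs = dp0 + p.delta_rho * p.g * p.z
    rhs = p.gamma * (1.0 / p.R1 + 1.0 / p.R2)
    return np.abs(lhs - rhs) / dp0
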