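"""Dimensional inputs, shape constants and dimensionless groups.

The modelled particle is an M13-bacteriophage-like rigid slender fibre,
treated as a prolate spheroid of length a* and width b* (aspect ratio
r = a*/b* ~ 133).  The constitutive constants of dilute-suspension stress
theory are used in their high-aspect-ratio (slender-fibre) closed forms,

    alpha_2 = r^2 / (2 (ln 2r - 3/2))        (fourth-moment stress)
    alpha_3 = (6 ln 2r - 11) / r^2           (second-moment stress)
    alpha_4 = 1                              (isotropic Newtonian correction)
    alpha_5 = 0                              (pressure-like; absent from the
                                              cross-sectional flow problem)
    alpha_r = 3 r^2 / (ln 2r - 1/2)          (rotary-diffusion stress)

which are the r -> infinity limits of the exact ellipsoidal-integral
expressions.  This is self-consistent with the orientation dynamics, which
already take the infinitely-slender Jeffery limit alpha_0 = 1.  The
underlying ellipsoidal integrals are available in
:func:`ellipsoidal_integrals` for validation of the asymptotics.

The slender-rod rotary diffusivity is

    D_r = 3 k_B T (ln 2r - 1/2) / (pi mu a*^3),

overridable by an explicitly supplied value.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import quad

__all__ = [
    "ParticleProperties",
    "FluidProperties",
    "ShapeConstants",
    "DimensionlessGroups",
    "rotational_diffusion",
    "shape_constants",
    "ellipsoidal_integrals",
    "dimensionless_groups",
    "BOLTZMANN",
    "AVOGADRO",
]

logger = logging.getLogger(__name__)

# Physical constants as tabulated with the standard parameter set.
BOLTZMANN = 1.38e-23  # kg m^2 K^-1 s^-2
AVOGADRO = 6e23  # particles mol^-1


class InvalidShapeError(ValueError):
    pass


@dataclass(frozen=True)
class ParticleProperties:
    """Geometric and optical properties of the suspended fibre."""

    a_star: float  # length (m)
    b_star: float  # width (m)
    m_w: float = 2e7  # molecular weight (g / mol)
    eps: float = 0.38  # extinction coefficient (m^2 / g)
    Vc: float | None = None  # particle volume override (m^3)

    def __post_init__(self):
        if self.a_star <= 0 or self.b_star <= 0:
            raise InvalidShapeError("particle dimensions must be positive")
        if self.aspect_ratio <= 1:
            raise InvalidShapeError("aspect ratio must exceed 1 for a slender rod")

    @property
    def aspect_ratio(self) -> float:
        return self.a_star / self.b_star

    @property
    def alpha0(self) -> float:
        """Jeffery shape parameter (r^2 - 1)/(r^2 + 1); metadata only, the
        orientation kernel takes the slender limit alpha0 = 1."""
        r2 = self.aspect_ratio ** 2
        return (r2 - 1.0) / (r2 + 1.0)

    @property
    def volume(self) -> float:
        """Particle volume; defaults to the prolate-spheroid value
        (pi/6) a* b*^2 unless explicitly overridden."""
        if self.Vc is not None:
            return self.Vc
        return np.pi / 6.0 * self.a_star * self.b_star ** 2


@dataclass(frozen=True)
class FluidProperties:
    mu: float = 9.5e-4  # viscosity (Pa s)
    rho: float = 1e3  # density (kg / m^3)
    T: float = 295.0  # temperature (K)
    k_B: float = BOLTZMANN


def rotational_diffusion(
    particle: ParticleProperties, fluid: FluidProperties, override: float | None = None
) -> float:
    """Slender-rod rotary diffusivity D_r (1/s).

    D_r = 3 k_B T (ln 2r - 1/2) / (pi mu a*^3); an explicit ``override``
    value (e.g. a measured diffusivity) takes precedence.
    """
    if override is not None:
        return float(override)
    r = particle.aspect_ratio
    return (
        3.0
        * fluid.k_B
        * fluid.T
        * (np.log(2.0 * r) - 0.5)
        / (np.pi * fluid.mu * particle.a_star ** 3)
    )


@dataclass(frozen=True)
class ShapeConstants:
    alpha2: float
    alpha3: float
    alpha4: float
    alpha5: float
    alpha_r: float


def shape_constants(r: float) -> ShapeConstants:
    """Slender-fibre constitutive constants for aspect ratio r > 1.

    alpha_2 grows like r^2/ln r (dominant fourth-moment stress of long
    fibres) while alpha_3 and alpha_4 stay bounded; alpha_5 multiplies an
    isotropic term that cannot enter the axial-flow PDE and is zero in the
    slender limit.
    """
    if r <= 1:
        raise InvalidShapeError("aspect ratio must exceed 1")
    l2r = np.log(2.0 * r)
    return ShapeConstants(
        alpha2=r * r / (2.0 * (l2r - 1.5)),
        alpha3=(6.0 * l2r - 11.0) / (r * r),
        alpha4=1.0,
        alpha5=0.0,
        alpha_r=3.0 * r * r / (l2r - 0.5),
    )


def ellipsoidal_integrals(r: float) -> dict:
    """Fundamental ellipsoidal integrals of a prolate spheroid, numerically.

    For semi-axes (r, 1, 1) in units of the minor semi-axis, with
    Delta(t) = sqrt(r^2 + t) (1 + t):

        I_a  = int_0^inf dt / ((r^2 + t) Delta)
        I_b  = int_0^inf dt / ((1 + t) Delta)
        J_aa = int_0^inf dt / ((r^2 + t)^2 Delta)
        J_bb = int_0^inf dt / ((1 + t)^2 Delta)
        J_ab = int_0^inf dt / ((r^2 + t)(1 + t) Delta)

    Evaluated by adaptive quadrature on a compactified variable; used to
    validate the high-aspect-ratio forms of the shape constants.
    """
    if r <= 1:
        raise InvalidShapeError("aspect ratio must exceed 1")
    r2 = r * r

    def delta(t):
        return np.sqrt(r2 + t) * (1.0 + t)

    # substitute t = s / (1 - s) to map [0, inf) -> [0, 1)
    def transformed(f):
        def g(s):
            t = s / (1.0 - s)
            return f(t) / (1.0 - s) ** 2

        val, err = quad(g, 0.0, 1.0, limit=500, epsabs=0.0, epsrel=1e-10)
        if not np.isfinite(val) or err > 1e-6 * abs(val) + 1e-15:
            raise RuntimeError("ellipsoidal integral quadrature did not converge")
        return val

    return {
        "I_a": transformed(lambda t: 1.0 / ((r2 + t) * delta(t))),
        "I_b": transformed(lambda t: 1.0 / ((1.0 + t) * delta(t))),
        "J_aa": transformed(lambda t: 1.0 / ((r2 + t) ** 2 * delta(t))),
        "J_bb": transformed(lambda t: 1.0 / ((1.0 + t) ** 2 * delta(t))),
        "J_ab": transformed(lambda t: 1.0 / ((r2 + t) * (1.0 + t) * delta(t))),
    }


@dataclass(frozen=True)
class DimensionlessGroups:
    Phi: float  # volume fraction V_c n_d
    P_G: float  # global Peclet number G* h* / (D_r mu)
    womersley: float  # alpha^2 = omega* h*^2 rho / mu (0 for steady flow)
    kappa: float  # local-time conversion d tau / d t = 6 D_r / omega*
    D_r: float  # rotary diffusivity (1/s)
    shape: ShapeConstants = field(repr=False, default=None)
    aspect_ratio: float = 0.0
    nd_a3: float = 0.0  # concentration measure n_d a*^3


def dimensionless_groups(
    particle: ParticleProperties,
    fluid: FluidProperties,
    n_d: float,
    G_star: float,
    h_star: float,
    omega_star: float = 0.0,
    D_r_override: float | None = None,
    published: dict | None = None,
) -> DimensionlessGroups:
    """Derive every dimensionless group from dimensional inputs.

    ``published`` may carry externally quoted values ({"P_G": ..., ...});
    any mismatch beyond 1% is logged, never silently overridden.
    """
    if n_d < 0 or G_star < 0 or h_star <= 0:
        raise ValueError("number density and pressure gradient must be >= 0, h* > 0")
    D_r = rotational_diffusion(particle, fluid, override=D_r_override)
    r = particle.aspect_ratio
    groups = DimensionlessGroups(
        Phi=particle.volume * n_d,
        P_G=G_star * h_star / (D_r * fluid.mu),
        womersley=omega_star * h_star ** 2 * fluid.rho / fluid.mu,
        kappa=(6.0 * D_r / omega_star) if omega_star > 0 else np.inf,
        D_r=D_r,
        shape=shape_constants(r),
        aspect_ratio=r,
        nd_a3=n_d * particle.a_star ** 3,
    )
    if groups.nd_a3 > 1.0:
        warnings.warn(
            f"n_d a*^3 = {groups.nd_a3:.3g} > 1: beyond the dilute regime, "
            "results are extrapolations of dilute theory",
            stacklevel=2,
        )
    if published:
        for key, val in published.items():
            got = getattr(groups, key, None)
            if got is not None and val and abs(got - val) > 0.01 * abs(val):
                logger.warning(
                    "derived %s = %.6g differs from published %.6g; using derived",
                    key,
                    got,
                    val,
                )
    return groups
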