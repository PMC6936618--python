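"""Material parameters: rotary diffusivity, shape constants, groups."""

import warnings

import numpy as np
import pytest
import sympy as sp

from ductld import (
    FluidProperties,
    ParticleProperties,
    dimensionless_groups,
    ellipsoidal_integrals,
    rotational_diffusion,
    shape_constants,
)
from ductld.materials import InvalidShapeError


@pytest.fixture(scope="module")
def std_particle():
    return ParticleProperties(a_star=8e-7, b_star=6e-9)


@pytest.fixture(scope="module")
def std_fluid():
    return FluidProperties()


def test_rotary_diffusivity_standard_value(std_particle, std_fluid):
    """Slender-rod formula at the standard M13 parameters: 40.65 1/s (2 dp)."""
    d_r = rotational_diffusion(std_particle, std_fluid)
    assert d_r == pytest.approx(40.65, abs=0.01)


def test_rotary_diffusivity_scaling(std_particle, std_fluid):
    d1 = rotational_diffusion(std_particle, std_fluid)
    thick = FluidProperties(mu=2 * std_fluid.mu)
    assert rotational_diffusion(std_particle, thick) == pytest.approx(d1 / 2)
    assert rotational_diffusion(std_particle, std_fluid, override=7.7) == 7.7


def test_rotary_diffusivity_extended_precision(std_particle, std_fluid):
    """Float evaluation agrees with the same expression in 50-digit arithmetic."""
    d_float = rotational_diffusion(std_particle, std_fluid)
    kB, T, r, mu, a = [
        sp.Float(v, 50)
        for v in (std_fluid.k_B, std_fluid.T, std_particle.aspect_ratio,
                  std_fluid.mu, std_particle.a_star)
    ]
    d_exact = 3 * kB * T * (sp.log(2 * r) - sp.Rational(1, 2)) / (sp.pi * mu * a ** 3)
    assert abs(d_float / float(d_exact) - 1.0) <= 1e-12


def test_invalid_aspect_ratio_rejected():
    with pytest.raises(InvalidShapeError):
        ParticleProperties(a_star=1e-9, b_star=6e-9)
    with pytest.raises(InvalidShapeError):
        shape_constants(0.5)


def test_shape_constants_positive_at_m13():
    sc = shape_constants(133.3)
    for v in (sc.alpha2, sc.alpha3, sc.alpha4, sc.alpha_r):
        assert np.isfinite(v) and v > 0
    assert sc.alpha5 == 0.0


def test_shape_constant_aspect_ratio_trends():
    """alpha_2 grows without bound as r increases; alpha_3, alpha_4 bounded."""
    rs = [10.0, 1e2, 1e3, 1e4]
    a2 = [shape_constants(r).alpha2 for r in rs]
    a3 = [shape_constants(r).alpha3 for r in rs]
    a4 = [shape_constants(r).alpha4 for r in rs]
    assert all(np.diff(a2) > 0) and a2[-1] > 1e6
    assert all(v < 1.0 for v in a3) and all(np.diff(a3) < 0)
    assert all(v == 1.0 for v in a4)


def test_ellipticity_over_random_admissible_moments(rng):
    """Coefficient fields stay elliptic for Phi up to 1e-2 for any moments."""
    from ductld.materials import DimensionlessGroups
    from ductld.steady import assemble_coefficients

    sc = shape_constants(133.3)
    for _ in range(200):
        # random admissible second/fourth moments from random directions
        p = rng.normal(size=(64, 3))
        p /= np.linalg.norm(p, axis=1, keepdims=True)
        w = rng.dirichlet(np.ones(64))
        m2 = np.einsum("k,ki,kj->ij", w, p, p)
        q22 = np.einsum("k,k->", w, p[:, 0] ** 2 * p[:, 1] ** 2)
        q33 = np.einsum("k,k->", w, p[:, 0] ** 2 * p[:, 2] ** 2)
        q23 = np.einsum("k,k->", w, p[:, 0] ** 2 * p[:, 1] * p[:, 2])
        lab = {
            "m11": m2[0, 0], "m22": m2[1, 1], "m33": m2[2, 2],
            "m12": m2[0, 1], "m13": m2[0, 2], "m23": m2[1, 2],
            "q22": q22, "q33": q33, "q23": q23,
        }
        groups = DimensionlessGroups(
            Phi=1e-2, P_G=10.0, womersley=0.0, kappa=np.inf, D_r=40.0,
            shape=sc, aspect_ratio=133.3,
        )
        coeffs = assemble_coefficients({k: np.atleast_1d(v) for k, v in lab.items()}, groups)
        assert np.all(coeffs.c_yy * coeffs.c_zz - coeffs.c_yz ** 2 > 0)


def test_ellipsoidal_integrals_closed_forms():
    """Quadrature integrals match the exact prolate closed forms/identities."""
    for r in (5.0, 133.3333):
        I = ellipsoidal_integrals(r)
        d = np.sqrt(r * r - 1.0)
        ia_exact = (2.0 / d ** 2) * (np.log(r + d) / d - 1.0 / r)
        assert I["I_a"] == pytest.approx(ia_exact, rel=1e-8)
        # sum rule: I_a + 2 I_b = 2 / (product of semi-axes ratios) = 2/r
        assert I["I_a"] + 2 * I["I_b"] == pytest.approx(2.0 / r, rel=1e-7)
        # mixed integral identity J_ab = (I_b - I_a)/(r^2 - 1)
        assert I["J_ab"] == pytest.approx((I["I_b"] - I["I_a"]) / (r * r - 1), rel=1e-8)


def test_dimensionless_groups_standard(std_particle, std_fluid):
    g = dimensionless_groups(
        std_particle, std_fluid, n_d=7.33e17, G_star=4.4e3, h_star=3e-4,
        omega_star=10.0,
    )
    # self-consistency with the defining formulas to 4 significant figures
    assert g.P_G == pytest.approx(4.4e3 * 3e-4 / (g.D_r * std_fluid.mu), rel=1e-4)
    assert g.nd_a3 == pytest.approx(0.3753, abs=1e-4)
    assert g.Phi == pytest.approx(std_particle.volume * 7.33e17, rel=1e-12)
    assert g.womersley == pytest.approx(10.0 * (3e-4) ** 2 * 1e3 / std_fluid.mu, rel=1e-12)
    assert g.kappa == pytest.approx(6 * g.D_r / 10.0, rel=1e-12)


def test_particle_volume_default_and_override(std_particle):
    assert std_particle.volume == pytest.approx(np.pi / 6 * 8e-7 * (6e-9) ** 2, rel=1e-12)
    overridden = ParticleProperties(a_star=8e-7, b_star=6e-9, Vc=1.21e-21)
    assert overridden.volume == 1.21e-21


def test_dilute_warning(std_particle, std_fluid):
    with pytest.warns(UserWarning, match="dilute"):
        dimensionless_groups(std_particle, std_fluid, n_d=1e19, G_star=4.4e3, h_star=3e-4)
    with warnings.catch_warnings():
        warnings.simplefilter("error")
        dimensionless_groups(std_particle, std_fluid, n_d=7.33e17, G_star=4.4e3, h_star=3e-4)


def test_zero_pressure_gradient_groups(std_particle, std_fluid):
    g = dimensionless_groups(std_particle, std_fluid, n_d=7.33e17, G_star=0.0, h_star=3e-4)
    assert g.P_G == 0.0


def test_groups_round_trip(std_particle, std_fluid):
    """Serializing the config and re-deriving reproduces identical groups."""
    from ductld import RunConfig, standard_config

    cfg = standard_config()
    g1 = cfg.groups(oscillatory=True)
    cfg2 = RunConfig.model_validate(cfg.resolved_dict())
    g2 = cfg2.groups(oscillatory=True)
    for attr in ("Phi", "P_G", "womersley", "kappa", "D_r", "nd_a3"):
        assert getattr(g1, attr) == getattr(g2, attr)
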