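"""Steady anisotropic duct flow and the Picard-coupled solution."""

import numpy as np
import pytest

from ductld import (
    ChannelConfig,
    FluidProperties,
    Numerics,
    ParticleProperties,
    dimensionless_groups,
    newtonian_duct_solution,
    picard_couple,
    solve_anisotropic_poisson,
)
from ductld.materials import DimensionlessGroups, shape_constants
from ductld.steady import (
    CoefficientField,
    EllipticityError,
    assemble_coefficients,
    grid_arrays,
    identity_coefficients,
    orientation_moment_fields,
    shear_fields,
)

WBAR = 10.0 / 3.0


def _std_groups(n_d=7.33e17, G=4.4e3, h=3e-4):
    return dimensionless_groups(
        ParticleProperties(a_star=8e-7, b_star=6e-9),
        FluidProperties(),
        n_d=n_d,
        G_star=G,
        h_star=h,
    )


def test_newtonian_series_limits():
    u = newtonian_duct_solution(np.array([0.0]), np.array([0.0]), 50.0)
    assert u[0, 0] == pytest.approx(0.5, abs=1e-6)  # plane Poiseuille
    y = np.linspace(-WBAR, WBAR, 7)
    z = np.linspace(-1, 1, 5)
    u = newtonian_duct_solution(y, z, WBAR)
    assert np.allclose(u[:, [0, -1]], 0.0, atol=1e-10)
    assert np.allclose(u[[0, -1], :], 0.0, atol=1e-10)


def test_fd_matches_series_with_second_order():
    errs = []
    for (Y, Z) in [(30, 24), (60, 48), (120, 96)]:
        u = solve_anisotropic_poisson(identity_coefficients(Y, Z), WBAR, Y, Z)
        y, z = grid_arrays(WBAR, Y, Z)
        errs.append(np.abs(u - newtonian_duct_solution(y, z, WBAR)).max())
    orders = [np.log2(errs[i] / errs[i + 1]) for i in range(2)]
    assert min(orders) >= 1.9
    assert errs[-1] < 1e-4


def test_constant_anisotropy_change_of_variables():
    """c_yy = 2 equals the Newtonian solution on a sqrt(2)-stretched domain."""
    Y, Z = 80, 64
    coeffs = identity_coefficients(Y, Z)
    coeffs = CoefficientField(
        c_yy=2.0 * coeffs.c_yy, c_zz=coeffs.c_zz, c_yz=coeffs.c_yz,
        f_y=coeffs.f_y, f_z=coeffs.f_z, source_prefactor=0.0,
    )
    u = solve_anisotropic_poisson(coeffs, WBAR, Y, Z)
    y, z = grid_arrays(WBAR, Y, Z)
    u_exact = newtonian_duct_solution(y / np.sqrt(2.0), z, WBAR / np.sqrt(2.0))
    assert np.abs(u - u_exact).max() < 5e-4


def test_symmetric_coefficients_give_symmetric_velocity():
    """Reflection symmetry of the solution (to direct-solver rounding)."""
    Y, Z = 40, 32
    u = solve_anisotropic_poisson(identity_coefficients(Y, Z), WBAR, Y, Z)
    assert np.abs(u - u[::-1, :]).max() <= 1e-13
    assert np.abs(u - u[:, ::-1]).max() <= 1e-13


def test_assemble_identity_when_phi_zero():
    lab = {k: np.full((5, 5), 0.1) for k in
           ("m11", "m22", "m33", "m12", "m13", "m23", "q22", "q33", "q23")}
    g = DimensionlessGroups(Phi=0.0, P_G=10.0, womersley=0.0, kappa=np.inf,
                            D_r=40.0, shape=shape_constants(133.3), aspect_ratio=133.3)
    coeffs = assemble_coefficients(lab, g)
    assert np.all(coeffs.c_yy == 1.0) and np.all(coeffs.c_zz == 1.0)
    assert np.all(coeffs.c_yz == 0.0) and coeffs.source_prefactor == 0.0


def test_assemble_isotropic_moments():
    """Isotropic suspension: c = 1 + 4 Phi (alpha2/15 + alpha3/3 + alpha4/2)."""
    iso = {"m11": 1 / 3, "m22": 1 / 3, "m33": 1 / 3, "m12": 0.0, "m13": 0.0,
           "m23": 0.0, "q22": 1 / 15, "q33": 1 / 15, "q23": 0.0}
    iso = {k: np.atleast_1d(v) for k, v in iso.items()}
    sc = shape_constants(133.3)
    g = DimensionlessGroups(Phi=1e-4, P_G=10.0, womersley=0.0, kappa=np.inf,
                            D_r=40.0, shape=sc, aspect_ratio=133.3)
    coeffs = assemble_coefficients(iso, g)
    expected = 1.0 + 4e-4 * (sc.alpha2 / 15 + sc.alpha3 / 3 + sc.alpha4 / 2)
    assert coeffs.c_yy[0] == pytest.approx(expected, rel=1e-12)
    assert coeffs.c_zz[0] == pytest.approx(expected, rel=1e-12)
    assert coeffs.c_yz[0] == pytest.approx(0.0, abs=1e-15)


def test_ellipticity_violation_raises():
    lab = {"m11": 0.4, "m22": 0.3, "m33": 0.3, "m12": 0.0, "m13": 0.0,
           "m23": 0.9, "q22": 0.0, "q33": 0.0, "q23": 0.9}
    lab = {k: np.atleast_1d(v) for k, v in lab.items()}
    sc = shape_constants(133.3)
    g = DimensionlessGroups(Phi=0.1, P_G=10.0, womersley=0.0, kappa=np.inf,
                            D_r=40.0, shape=sc, aspect_ratio=133.3)
    with pytest.raises(EllipticityError):
        assemble_coefficients(lab, g)


def test_phi_zero_picard_converges_first_iteration():
    groups = _std_groups(n_d=0.0)
    res = picard_couple(ChannelConfig(3e-4, 1e-3, 4.4e3), groups,
                        Numerics(N=6, Y=24, Z=16))
    assert len(res.residuals) == 1
    assert res.residuals[0] == 0.0


def test_standard_run_structure(coarse_steady):
    """Velocity max at centre; S minimum at centre, maxima near walls."""
    cfg, res, summary, groups = coarse_steady
    iy, iz = res.u.shape[0] // 2, res.u.shape[1] // 2
    assert res.u[iy, iz] == res.u.max()
    # Pe symmetric and zero at the centre
    assert res.Pe[iy, iz] == pytest.approx(0.0, abs=1e-12)
    assert np.allclose(res.Pe, res.Pe[::-1, :], atol=1e-9)
    assert np.allclose(res.Pe, res.Pe[:, ::-1], atol=1e-9)
    # S minimum at the centre node (ties with the zero-shear corners at
    # floating precision, where local minima also occur)
    assert res.S[iy, iz] <= res.S.min() + 1e-12
    assert res.S[iy, iz] == pytest.approx(0.0, abs=1e-12)
    interior = res.S[1:-1, 1:-1]
    imin_int = np.unravel_index(np.argmin(interior), interior.shape)
    assert imin_int == (iy - 1, iz - 1)
    imax = np.unravel_index(np.argmax(res.S), res.S.shape)
    dist_wall = min(
        imax[0], res.S.shape[0] - 1 - imax[0], imax[1], res.S.shape[1] - 1 - imax[1]
    )
    assert dist_wall <= 2


def test_standard_run_monotone_residuals(coarse_steady):
    _, res, _, _ = coarse_steady
    r = res.residuals
    assert all(r[i + 1] < r[i] for i in range(len(r) - 1))


def test_suspension_slows_flow_slightly(coarse_steady):
    """Relative velocity reduction is small (order 1e-3 to 1e-2)."""
    cfg, res, _, groups = coarse_steady
    Y, Z = res.u.shape[0] - 1, res.u.shape[1] - 1
    uN = solve_anisotropic_poisson(identity_coefficients(Y, Z), cfg.channel_config().Wbar, Y, Z)
    rel = np.max(np.abs(uN - res.u)) / uN.max()
    assert 1e-4 < rel < 2e-2
    assert np.all(uN - res.u >= -1e-12)  # particles only ever slow the flow


def test_node_order_invariance(coarse_steady, basis8, table8, rng):
    """Permuting the per-node evaluation order changes nothing (<= 1e-14)."""
    _, res, _, _ = coarse_steady
    order = rng.permutation(res.Pe.size)
    lab_natural = orientation_moment_fields(res.Pe, res.beta, basis8, table8)
    lab_shuffled = orientation_moment_fields(res.Pe, res.beta, basis8, table8,
                                             node_order=order)
    for k in lab_natural:
        assert np.max(np.abs(lab_natural[k] - lab_shuffled[k])) <= 1e-14


def test_number_density_monotonically_slows_flow():
    """Mean velocity decreases as number density rises over 1e16..1e19."""
    means = []
    for nd in (1e16, 1e17, 1e18, 1e19):
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            groups = _std_groups(n_d=nd)
        res = picard_couple(ChannelConfig(3e-4, 1e-3, 4.4e3), groups,
                            Numerics(N=6, Y=24, Z=16))
        means.append(res.u.mean())
    assert all(means[i + 1] < means[i] for i in range(len(means) - 1))


def test_zero_pressure_gradient_gives_isotropy():
    groups = _std_groups(G=0.0)
    res = picard_couple(ChannelConfig(3e-4, 1e-3, 0.0), groups,
                        Numerics(N=6, Y=24, Z=16))
    assert np.allclose(res.S, 0.0, atol=1e-12)
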