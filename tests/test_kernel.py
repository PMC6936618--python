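"""Local Fokker-Planck solves: steady states, transients and invariants."""

import numpy as np
import pytest
import sympy as sp
from hypothesis import given, settings
from hypothesis import strategies as st

from ductld import (
    HarmonicBasis,
    LocalShearContext,
    build_coupling_table,
    compute_moments,
    isotropic_state,
    orientation_parameter_biaxial,
    reconstruct_psi,
    solve_steady_local,
    step_transient_local,
)
from ductld.kernel import A00, heun_step_many


def test_zero_shear_is_isotropic(basis10, table10):
    st_ = solve_steady_local(LocalShearContext(Pe=0.0), basis10, table10)
    assert st_.A0[basis10.cos_index(0, 0)] == pytest.approx(A00)
    assert np.allclose(np.delete(st_.A0, basis10.cos_index(0, 0)), 0.0)
    assert np.allclose(st_.A1, 0.0)
    assert orientation_parameter_biaxial(compute_moments(st_)) == pytest.approx(0.0)


def test_n2_truncation_matches_hand_reduced_system(table10):
    """At N=2 the steady system has three unknowns; an independent exact
    solve of the hand-assembled 3x3 rational system must match to machine
    precision."""
    basis = HarmonicBasis(2)
    table = build_coupling_table(basis)
    pe = 0.3
    a0022 = table.entries[(0, 0, 2, 2)]
    a2022 = table.entries[(2, 0, 2, 2)]
    a2222 = table.entries[(2, 2, 2, 2)]
    a2220 = table.entries[(2, 2, 2, 0)]
    x20, x22, y22, Pe = sp.symbols("x20 x22 y22 Pe")
    sol = sp.solve(
        [
            sp.Eq(1 * x20, -Pe * a2220 * y22),
            sp.Eq(1 * x22, -Pe * a2222 * y22),
            sp.Eq(1 * y22, Pe * (a0022 / (4 * sp.pi) + a2022 * x20 + a2222 * x22)),
        ],
        [x20, x22, y22],
    )
    state = solve_steady_local(LocalShearContext(Pe=pe), basis, table)
    assert state.A0[basis.cos_index(2, 0)] == pytest.approx(
        float(sol[x20].subs(Pe, pe)), abs=1e-15
    )
    assert state.A0[basis.cos_index(2, 2)] == pytest.approx(
        float(sol[x22].subs(Pe, pe)), abs=1e-15
    )
    assert state.A1[basis.sin_index(2, 2)] == pytest.approx(
        float(sol[y22].subs(Pe, pe)), abs=1e-15
    )


def test_pure_diffusion_decay_closed_form(basis8, table8, rng):
    """With Pe = 0 every mode decays as exp(-q(q+1) tau / 6)."""
    a0 = rng.normal(size=basis8.n_cos) * 0.01
    a0[basis8.cos_index(0, 0)] = A00
    a1 = rng.normal(size=basis8.n_sin) * 0.01
    from ductld.kernel import OrientationState

    state = OrientationState(basis=basis8, A0=a0.copy(), A1=a1.copy())
    dtau, nsteps = 0.002, 200
    for _ in range(nsteps):
        state = step_transient_local(state, lambda tau: 0.0, dtau, basis8, table8)
    tau = dtau * nsteps
    d_cos, d_sin = basis8.decay_rates()
    # continuous closed form (to scheme accuracy) ...
    assert np.allclose(state.A0, a0 * np.exp(-d_cos * tau), atol=5e-6)
    assert np.allclose(state.A1, a1 * np.exp(-d_sin * tau), atol=5e-6)
    # ... and the exact per-mode Heun amplification factor (mode independence)
    g_cos = (1.0 - d_cos * dtau + 0.5 * (d_cos * dtau) ** 2) ** nsteps
    g_sin = (1.0 - d_sin * dtau + 0.5 * (d_sin * dtau) ** 2) ** nsteps
    assert np.allclose(state.A0, a0 * g_cos, atol=1e-13)
    assert np.allclose(state.A1, a1 * g_sin, atol=1e-13)


def test_transient_converges_to_steady(basis10, table10):
    """Constant Pe, long time: the transient reaches the steady solution."""
    pe = 2.0
    state = isotropic_state(basis10)
    for _ in range(4000):
        state = step_transient_local(state, lambda tau: pe, 0.01, basis10, table10)
    s_tr = orientation_parameter_biaxial(compute_moments(state))
    s_st = orientation_parameter_biaxial(
        compute_moments(solve_steady_local(LocalShearContext(pe), basis10, table10))
    )
    assert abs(s_tr - s_st) <= 1e-6


def test_heun_second_order(basis8, table8):
    """Richardson check: observed convergence order >= 1.9 for smooth Pe(tau)."""

    def pe_of(tau):
        return 2.0 * np.sin(tau)

    def advance(dtau, nsteps):
        state = isotropic_state(basis8)
        for _ in range(nsteps):
            state = step_transient_local(state, pe_of, dtau, basis8, table8)
        return np.concatenate([state.A0, state.A1])

    ref = advance(0.4 / 256, 256)
    e1 = np.max(np.abs(advance(0.4 / 16, 16) - ref))
    e2 = np.max(np.abs(advance(0.4 / 32, 32) - ref))
    order = np.log2(e1 / e2)
    assert order >= 1.9


def test_normalization_conserved_many_steps(basis8, table8):
    """A0_00 is algebraically decoupled: drift <= 1e-12 over 1e4 steps."""
    X0 = np.zeros((1, basis8.n_cos))
    X0[0, basis8.cos_index(0, 0)] = A00
    X1 = np.zeros((1, basis8.n_sin))
    pe = np.array([3.0])
    for _ in range(10_000):
        X0, X1 = heun_step_many(X0, X1, pe, pe, 0.02, basis8, table8)
    assert abs(X0[0, basis8.cos_index(0, 0)] - A00) <= 1e-12
    assert np.all(np.isfinite(X0)) and np.all(np.isfinite(X1))


def test_instability_raises(basis8, table8):
    from ductld.kernel import KernelNumericalError

    state = isotropic_state(basis8)
    with pytest.raises(KernelNumericalError):
        for _ in range(200):
            state = step_transient_local(state, lambda tau: 50.0, 5.0, basis8, table8)


@settings(max_examples=15, deadline=None, derandomize=True)
@given(pe=st.floats(min_value=0.0, max_value=50.0))
def test_steady_state_invariants(pe):
    """For any Pe: S in [-1, 1], trace(M2) = 1, psi antipodally symmetric."""
    basis = HarmonicBasis(8)
    table = build_coupling_table(basis)
    state = solve_steady_local(LocalShearContext(Pe=pe), basis, table)
    ms = compute_moments(state)
    assert abs(np.trace(ms.M2) - 1.0) <= 1e-10
    s = orientation_parameter_biaxial(ms)
    assert -1.0 <= s <= 1.0
    theta = np.array([0.4, 1.1, 2.0])
    phi = np.array([0.3, 2.2, 4.0])
    psi = reconstruct_psi(state, theta, phi)
    psi_anti = reconstruct_psi(state, np.pi - theta, np.mod(phi + np.pi, 2 * np.pi))
    assert np.allclose(psi, psi_anti, atol=1e-12)


def test_convergence_in_truncation_order():
    """|S(N) - S(N+2)| shrinks monotonically at moderate Pe."""
    pe = 10.0
    svals = []
    for N in (4, 6, 8, 10, 12):
        b = HarmonicBasis(N)
        t = build_coupling_table(b)
        svals.append(
            orientation_parameter_biaxial(
                compute_moments(solve_steady_local(LocalShearContext(pe), b, t))
            )
        )
    diffs = [abs(svals[i + 1] - svals[i]) for i in range(len(svals) - 1)]
    assert all(diffs[i + 1] < diffs[i] for i in range(len(diffs) - 1))
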