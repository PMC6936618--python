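"""Pointwise Fokker-Planck solves for the orientation distribution.

At each spatial location the rod orientation distribution psi(phi', theta')
obeys, in the local shear frame and on the rotary-diffusion time scale tau,

    d A0_qp / dtau = - q(q+1)/6 A0_qp - Pe(tau) sum a^{m,p}_{n,q} A1_nm
    d A1_qp / dtau = - q(q+1)/6 A1_qp + Pe(tau) sum a^{m,p}_{n,q} A0_nm

with A0_00 = 1/(4 pi) pinned by normalization.  Pe = gamma_dot / (6 D_r) is
the local Peclet number; a negative Pe represents the same shear with
reversed sign (psi(phi') -> psi(-phi')), which arises in oscillatory flow.

The steady state satisfies the linear system obtained by zeroing the time
derivatives; it is solved densely over all retained modes (~40 unknowns at
N = 10).  Transient states are advanced with Heun's second-order
predictor-corrector (improved Euler) scheme, vectorized over many spatial
nodes at once.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .basis import CouplingTable, HarmonicBasis

__all__ = [
    "OrientationState",
    "LocalShearContext",
    "isotropic_state",
    "solve_steady_local",
    "step_transient_local",
    "heun_step_many",
]

A00 = 1.0 / (4.0 * np.pi)


class KernelNumericalError(RuntimeError):
    pass


@dataclass(frozen=True)
class LocalShearContext:
    """Local shear environment: Peclet number and frame angle beta.

    ``beta`` is the signed rotation about the flow (x) axis carrying the
    laboratory frame into the local frame in which the velocity gradient is
    purely along y'; beta = atan2(du/dz, du/dy).
    """

    Pe: float
    beta: float = 0.0

    def __post_init__(self):
        if not np.isfinite(self.Pe):
            raise ValueError("Pe must be finite")


@dataclass(frozen=True)
class OrientationState:
    """Spherical-harmonic coefficients of psi at one spatial point."""

    basis: HarmonicBasis
    A0: np.ndarray  # cosine family, ordered per basis.cos_modes
    A1: np.ndarray  # sine family, ordered per basis.sin_modes
    tau: float = 0.0

    def __post_init__(self):
        if len(self.A0) != self.basis.n_cos or len(self.A1) != self.basis.n_sin:
            raise ValueError("coefficient arrays do not match basis layout")


def isotropic_state(basis: HarmonicBasis, tau: float = 0.0) -> OrientationState:
    a0 = np.zeros(basis.n_cos)
    a0[basis.cos_index(0, 0)] = A00
    return OrientationState(basis=basis, A0=a0, A1=np.zeros(basis.n_sin), tau=tau)


@dataclass(frozen=True)
class _SteadyOperator:
    """Cached dense blocks for the steady solve at arbitrary Pe.

    Unknown vector x = [A0 (without the pinned (0,0) mode), A1].
    The system is  (D + Pe * K) x = Pe * b,  where D holds the q(q+1)/6
    decay rates, K the shear couplings and b the forcing from the pinned
    normalization mode.
    """

    basis: HarmonicBasis
    D: np.ndarray
    K: np.ndarray
    b: np.ndarray
    G: np.ndarray  # cos rows x sin cols
    H: np.ndarray  # sin rows x cos cols


_steady_cache: dict = {}


def _steady_operator(basis: HarmonicBasis, table: CouplingTable) -> _SteadyOperator:
    key = (basis.N, id(table))
    op = _steady_cache.get(key)
    if op is not None:
        return op
    G = table.matrix_cos_from_sin()
    H = table.matrix_sin_from_cos()
    d_cos, d_sin = basis.decay_rates()
    i00 = basis.cos_index(0, 0)
    keep = [i for i in range(basis.n_cos) if i != i00]
    nc, ns = len(keep), basis.n_sin
    D = np.diag(np.concatenate([d_cos[keep], d_sin]))
    K = np.zeros((nc + ns, nc + ns))
    # cos equations: q(q+1)/6 A0 + Pe * G A1 = 0
    K[:nc, nc:] = G[keep, :]
    # sin equations: q(q+1)/6 A1 - Pe * H A0 = Pe * H[:, i00] * A00
    K[nc:, :nc] = -H[:, keep]
    b = np.zeros(nc + ns)
    b[nc:] = H[:, i00] * A00
    op = _SteadyOperator(basis=basis, D=D, K=K, b=b, G=G, H=H)
    _steady_cache[key] = op
    return op


def solve_steady_local(
    ctx: LocalShearContext, basis: HarmonicBasis, table: CouplingTable
) -> OrientationState:
    """Steady orientation distribution at local Peclet number ctx.Pe.

    Solves the dense linear system over all retained modes with the
    normalization mode pinned.  Pe = 0 returns the isotropic state exactly.
    """
    op = _steady_operator(basis, table)
    pe = float(ctx.Pe)
    if pe == 0.0:
        return isotropic_state(basis)
    try:
        x = np.linalg.solve(op.D + pe * op.K, pe * op.b)
    except np.linalg.LinAlgError as exc:  # pragma: no cover - not expected
        raise KernelNumericalError(f"steady orientation solve failed at Pe={pe}") from exc
    if not np.all(np.isfinite(x)):
        raise KernelNumericalError(f"non-finite steady solution at Pe={pe}")
    i00 = basis.cos_index(0, 0)
    nc = basis.n_cos - 1
    a0 = np.empty(basis.n_cos)
    keep = [i for i in range(basis.n_cos) if i != i00]
    a0[keep] = x[:nc]
    a0[i00] = A00
    return OrientationState(basis=basis, A0=a0, A1=x[nc:].copy())


def solve_steady_many(
    pe_values: np.ndarray, basis: HarmonicBasis, table: CouplingTable
) -> tuple[np.ndarray, np.ndarray]:
    """Steady coefficients for an array of Peclet numbers.

    Returns (X0, X1) with shapes (npts, n_cos) and (npts, n_sin).  Each
    point's solve is independent; the result does not depend on evaluation
    order.
    """
    pe_values = np.asarray(pe_values, dtype=float).ravel()
    op = _steady_operator(basis, table)
    i00 = basis.cos_index(0, 0)
    keep = [i for i in range(basis.n_cos) if i != i00]
    nc = len(keep)
    X0 = np.zeros((pe_values.size, basis.n_cos))
    X1 = np.zeros((pe_values.size, basis.n_sin))
    X0[:, i00] = A00
    # identical Pe values share a solve
    uniq, inv = np.unique(pe_values, return_inverse=True)
    for k, pe in enumerate(uniq):
        if pe == 0.0:
            continue
        x = np.linalg.solve(op.D + pe * op.K, pe * op.b)
        rows = np.nonzero(inv == k)[0]
        X0[np.ix_(rows, keep)] = x[:nc]
        X1[rows, :] = x[nc:]
    return X0, X1


_specnorm_cache: dict = {}


def coupling_spectral_norm(basis: HarmonicBasis, table: CouplingTable) -> float:
    """Spectral radius of the shear-coupling block per unit Peclet number.

    The transient generator is L(Pe) = -D + Pe * J with J the
    skew-structured block [[0, -G], [H, 0]]; its eigenvalues are close to
    the imaginary axis, so explicit time stepping must resolve
    |Pe| * rho(J).  Cached per basis.
    """
    key = (basis.N, id(table))
    val = _specnorm_cache.get(key)
    if val is None:
        G = table.matrix_cos_from_sin()
        H = table.matrix_sin_from_cos()
        nc, ns = G.shape
        J = np.zeros((nc + ns, nc + ns))
        J[:nc, nc:] = -G
        J[nc:, :nc] = H
        val = float(np.abs(np.linalg.eigvals(J)).max())
        _specnorm_cache[key] = val
    return val


def stable_substep(dtau: float, pe_max: float, basis, table, safety: float = 1.0) -> int:
    """Number of Heun sub-steps keeping the update inside its stability region.

    The dominant eigenvalues are lightly damped (real part ~ -1 to -3) with
    imaginary part up to rho = d_max + |Pe| rho(J); for Heun the weak
    imaginary-axis growth (1 + (omega h)^4/4 per step) is absorbed by the
    physical damping when h <~ 2 / rho^{4/3}.
    """
    d_max = basis.N * (basis.N + 1) / 6.0
    rho = d_max + abs(pe_max) * coupling_spectral_norm(basis, table)
    h_max = safety * 2.0 / rho ** (4.0 / 3.0)
    return max(1, int(np.ceil(dtau / h_max)))


def _rhs_many(X0, X1, pe, op, d_cos, d_sin):
    """Time derivatives for many nodes at once; pe has shape (npts,)."""
    dX0 = -X0 * d_cos[None, :] - pe[:, None] * (X1 @ op.G.T)
    dX1 = -X1 * d_sin[None, :] + pe[:, None] * (X0 @ op.H.T)
    return dX0, dX1


def heun_step_many(X0, X1, pe_start, pe_end, dtau, basis, table):
    """One Heun (trapezoidal predictor-corrector) step for many nodes.

    ``pe_start`` and ``pe_end`` are the per-node Peclet numbers at the start
    and end of the step (the shear evaluator supplies both).  The
    normalization mode has no coupling into it (Upsilon is a divergence on
    the sphere), so A0_00 is conserved exactly.
    """
    op = _steady_operator(basis, table)
    d_cos, d_sin = basis.decay_rates()
    with np.errstate(over="ignore", invalid="ignore"):
        k1_0, k1_1 = _rhs_many(X0, X1, pe_start, op, d_cos, d_sin)
        P0 = X0 + dtau * k1_0
        P1 = X1 + dtau * k1_1
        k2_0, k2_1 = _rhs_many(P0, P1, pe_end, op, d_cos, d_sin)
        Y0 = X0 + 0.5 * dtau * (k1_0 + k2_0)
        Y1 = X1 + 0.5 * dtau * (k1_1 + k2_1)
    if not (np.all(np.isfinite(Y0)) and np.all(np.isfinite(Y1))):
        raise KernelNumericalError(
            "non-finite coefficients after transient step; reduce dtau"
        )
    return Y0, Y1


def step_transient_local(
    state: OrientationState,
    pe_of_tau,
    dtau: float,
    basis: HarmonicBasis,
    table: CouplingTable,
) -> OrientationState:
    """Advance one orientation state by a single Heun step of size dtau.

    ``pe_of_tau`` is a callable returning the (possibly signed) local Peclet
    number at a given tau.
    """
    if dtau <= 0:
        raise ValueError("dtau must be positive")
    pe0 = np.array([float(pe_of_tau(state.tau))])
    pe1 = np.array([float(pe_of_tau(state.tau + dtau))])
    Y0, Y1 = heun_step_many(
        state.A0[None, :], state.A1[None, :], pe0, pe1, dtau, basis, table
    )
    return replace(state, A0=Y0[0], A1=Y1[0], tau=state.tau + dtau)
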