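"""Steady pressure-driven duct flow coupled to rod orientation.

The lubrication-limit axial momentum balance on the cross-section
[-Wbar, Wbar] x [-1, 1] reads

    -1 = d/dy( c_yy u_y + c_yz u_z ) + d/dz( c_zz u_z + c_yz u_y )
         + (2 Phi alpha_r / P_G) ( d f_y / dy + d f_z / dz ),

where the anisotropic viscosity coefficients and the rotary-stress fluxes
f_y = <p1 p2>, f_z = <p1 p3> are laboratory-frame moments of the local
orientation distribution.  The orientation at each node depends on the flow
only through the local Peclet number Pe = (P_G / 6) |grad u| and frame
angle beta = atan2(u_z, u_y), so flow and orientation are converged by
Picard (fixed-point) iteration starting from the Newtonian field.

Finite differences are conservative (flux form) and second order: viscosity
coefficients are arithmetically averaged at half-nodes and the mixed
c_yz fluxes are centrally differenced.  The discrete operator is solved by
sparse direct factorization.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .basis import CouplingTable, HarmonicBasis, build_coupling_table
from .kernel import solve_steady_many
from .materials import DimensionlessGroups
from .moments import moments_from_coeffs, rotate_moments_to_lab

__all__ = [
    "ChannelConfig",
    "Numerics",
    "CoefficientField",
    "SteadyResult",
    "grid_arrays",
    "shear_fields",
    "orientation_moment_fields",
    "assemble_coefficients",
    "identity_coefficients",
    "solve_anisotropic_poisson",
    "picard_couple",
]


class EllipticityError(ValueError):
    """Coefficient field lost ellipticity (non-physical shape constants)."""


class PicardNonConvergence(RuntimeError):
    def __init__(self, residuals):
        self.residuals = list(residuals)
        super().__init__(
            f"Picard iteration did not converge in {len(residuals)} iterations; "
            f"last residual {residuals[-1]:.3e}"
        )


@dataclass(frozen=True)
class ChannelConfig:
    """Channel cross-section geometry and forcing (dimensional)."""

    h_star: float  # half-depth (m)
    W_star: float  # half-width (m)
    G_star: float  # pressure-gradient amplitude (Pa / m)

    def __post_init__(self):
        if min(self.h_star, self.W_star) <= 0 or self.G_star < 0:
            raise ValueError("channel dimensions must be positive, G* >= 0")

    @property
    def Wbar(self) -> float:
        return self.W_star / self.h_star


@dataclass(frozen=True)
class Numerics:
    """Numerical controls for the coupled solvers.

    Defaults follow the convergence study of the full model (N = 10,
    Y = 150, Z = 120); coarse presets (e.g. Y = 60, Z = 48) trade accuracy
    for speed in tests and sweeps.
    """

    N: int = 10
    Y: int = 150
    Z: int = 120
    picard_tol: float = 1e-6
    picard_maxiter: int = 50
    relaxation: float = 1.0

    def __post_init__(self):
        if self.Y < 8 or self.Z < 8:
            raise ValueError("grid sizes Y, Z must be at least 8")


def grid_arrays(Wbar: float, Y: int, Z: int):
    """Vertex-centred grid including boundary nodes."""
    y = np.linspace(-Wbar, Wbar, Y + 1)
    z = np.linspace(-1.0, 1.0, Z + 1)
    return y, z


def shear_fields(u: np.ndarray, y: np.ndarray, z: np.ndarray, P_G: float):
    """Velocity gradients, shear rate, local Peclet number and frame angle.

    Second-order central differences in the interior, one-sided second-order
    at the walls.  Nodes with zero shear (the channel centre) take beta = 0
    by convention; the orientation there is isotropic so the choice is
    immaterial.
    """
    u_y = np.gradient(u, y, axis=0, edge_order=2)
    u_z = np.gradient(u, z, axis=1, edge_order=2)
    gamma = np.hypot(u_y, u_z)
    pe = (P_G / 6.0) * gamma
    beta = np.where(gamma > 0, np.arctan2(u_z, u_y), 0.0)
    return u_y, u_z, gamma, pe, beta


def orientation_moment_fields(
    pe: np.ndarray,
    beta: np.ndarray,
    basis: HarmonicBasis,
    table: CouplingTable,
    node_order: np.ndarray | None = None,
):
    """Steady orientation moments at every grid node (laboratory frame).

    Each node's Fokker-Planck solve is independent; ``node_order`` permutes
    the evaluation order without changing any result (the parallelization
    contract), and is exercised by the order-invariance tests.
    """
    shape = pe.shape
    pe_flat = pe.ravel()
    if node_order is not None:
        inv = np.empty_like(node_order)
        inv[node_order] = np.arange(node_order.size)
        X0p, X1p = solve_steady_many(pe_flat[node_order], basis, table)
        X0, X1 = X0p[inv], X1p[inv]
    else:
        X0, X1 = solve_steady_many(pe_flat, basis, table)
    local9 = moments_from_coeffs(X0, X1, basis)
    lab = rotate_moments_to_lab(local9, beta.ravel())
    return {k: v.reshape(shape) for k, v in lab.items()}


@dataclass(frozen=True)
class CoefficientField:
    """Anisotropic viscosity coefficients and rotary-stress fluxes per node."""

    c_yy: np.ndarray
    c_zz: np.ndarray
    c_yz: np.ndarray
    f_y: np.ndarray
    f_z: np.ndarray
    source_prefactor: float  # 2 Phi alpha_r / P_G


def assemble_coefficients(lab_moments: dict, groups: DimensionlessGroups) -> CoefficientField:
    """PDE coefficients from laboratory-frame orientation moments."""
    Phi = groups.Phi
    al = groups.shape
    m11, m22, m33 = lab_moments["m11"], lab_moments["m22"], lab_moments["m33"]
    c_yy = 1.0 + 4.0 * Phi * (
        al.alpha2 * lab_moments["q22"] + 0.5 * al.alpha3 * (m11 + m22) + 0.5 * al.alpha4
    )
    c_zz = 1.0 + 4.0 * Phi * (
        al.alpha2 * lab_moments["q33"] + 0.5 * al.alpha3 * (m11 + m33) + 0.5 * al.alpha4
    )
    c_yz = 4.0 * Phi * (
        al.alpha2 * lab_moments["q23"] + 0.5 * al.alpha3 * lab_moments["m23"]
    )
    if np.any(c_yy * c_zz - c_yz ** 2 <= 0):
        raise EllipticityError("coefficient field is not elliptic")
    prefactor = 2.0 * Phi * al.alpha_r / groups.P_G if groups.P_G > 0 else 0.0
    return CoefficientField(
        c_yy=np.asarray(c_yy, dtype=float),
        c_zz=np.asarray(c_zz, dtype=float),
        c_yz=np.asarray(c_yz, dtype=float),
        f_y=np.asarray(lab_moments["m12"], dtype=float),
        f_z=np.asarray(lab_moments["m13"], dtype=float),
        source_prefactor=prefactor,
    )


def identity_coefficients(Y: int, Z: int) -> CoefficientField:
    one = np.ones((Y + 1, Z + 1))
    zero = np.zeros((Y + 1, Z + 1))
    return CoefficientField(one, one.copy(), zero, zero.copy(), zero.copy(), 0.0)


def _source_divergence(coeffs: CoefficientField, y: np.ndarray, z: np.ndarray) -> np.ndarray:
    if coeffs.source_prefactor == 0.0:
        return np.zeros_like(coeffs.f_y)
    div = np.gradient(coeffs.f_y, y, axis=0, edge_order=2) + np.gradient(
        coeffs.f_z, z, axis=1, edge_order=2
    )
    return coeffs.source_prefactor * div


def solve_anisotropic_poisson(
    coeffs: CoefficientField, Wbar: float, Y: int, Z: int
) -> np.ndarray:
    """Direct sparse solve of the anisotropic cross-sectional flow PDE."""
    y, z = grid_arrays(Wbar, Y, Z)
    dy = y[1] - y[0]
    dz = z[1] - z[0]
    ny, nz = Y + 1, Z + 1

    def idx(i, j):
        return i * nz + j

    ii, jj = np.meshgrid(np.arange(1, Y), np.arange(1, Z), indexing="ij")
    ii = ii.ravel()
    jj = jj.ravel()
    rows, cols, vals = [], [], []

    def add(di, dj, w):
        rows.append(idx(ii, jj))
        cols.append(idx(ii + di, jj + dj))
        vals.append(np.broadcast_to(w, ii.shape).astype(float).ravel())

    cyy, czz, cyz = coeffs.c_yy, coeffs.c_zz, coeffs.c_yz
    cE = 0.5 * (cyy[ii, jj] + cyy[ii + 1, jj]) / dy ** 2
    cW = 0.5 * (cyy[ii, jj] + cyy[ii - 1, jj]) / dy ** 2
    cN = 0.5 * (czz[ii, jj] + czz[ii, jj + 1]) / dz ** 2
    cS = 0.5 * (czz[ii, jj] + czz[ii, jj - 1]) / dz ** 2
    add(1, 0, cE)
    add(-1, 0, cW)
    add(0, 1, cN)
    add(0, -1, cS)
    add(0, 0, -(cE + cW + cN + cS))
    # mixed fluxes d/dy(c_yz u_z) + d/dz(c_yz u_y), centred
    q = 1.0 / (4.0 * dy * dz)
    add(1, 1, q * (cyz[ii + 1, jj] + cyz[ii, jj + 1]))
    add(1, -1, -q * (cyz[ii + 1, jj] + cyz[ii, jj - 1]))
    add(-1, 1, -q * (cyz[ii - 1, jj] + cyz[ii, jj + 1]))
    add(-1, -1, q * (cyz[ii - 1, jj] + cyz[ii, jj - 1]))

    # Dirichlet walls
    bi = []
    for i in (0, Y):
        for j in range(nz):
            bi.append(idx(i, j))
    for j in (0, Z):
        for i in range(1, Y):
            bi.append(idx(i, j))
    bi = np.array(bi)
    rows.append(bi)
    cols.append(bi)
    vals.append(np.ones(bi.size))

    A = sp.csr_matrix(
        (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))),
        shape=(ny * nz, ny * nz),
    )
    rhs = np.zeros(ny * nz)
    src = _source_divergence(coeffs, y, z)
    rhs[idx(ii, jj)] = -1.0 - src[ii, jj]
    u = spla.spsolve(A, rhs)
    if not np.all(np.isfinite(u)):
        raise RuntimeError("anisotropic flow solve produced non-finite values")
    return u.reshape(ny, nz)


@dataclass
class SteadyResult:
    """Converged coupled fields on the cross-section grid."""

    y: np.ndarray
    z: np.ndarray
    u: np.ndarray
    S: np.ndarray
    Pe: np.ndarray
    beta: np.ndarray
    lab_moments: dict
    coeffs: CoefficientField
    residuals: list = field(default_factory=list)


def picard_couple(
    channel: ChannelConfig,
    groups: DimensionlessGroups,
    numerics: Numerics = Numerics(),
    table: CouplingTable | None = None,
    node_order: np.ndarray | None = None,
) -> SteadyResult:
    """Fixed-point coupling of the flow PDE and pointwise orientation solves.

    Starts from the Newtonian field; at each sweep the local Peclet and
    frame-angle fields are formed from the current velocity, the steady
    Fokker-Planck problem is solved at every node, the anisotropic
    coefficients are reassembled and the PDE re-solved, with optional
    under-relaxation.  Convergence is measured in the relative max norm of
    the velocity update.
    """
    basis = HarmonicBasis(numerics.N)
    if table is None:
        table = build_coupling_table(basis)
    Wbar = channel.Wbar
    y, z = grid_arrays(Wbar, numerics.Y, numerics.Z)
    u = solve_anisotropic_poisson(
        identity_coefficients(numerics.Y, numerics.Z), Wbar, numerics.Y, numerics.Z
    )
    residuals = []
    omega = numerics.relaxation
    lab = None
    coeffs = identity_coefficients(numerics.Y, numerics.Z)
    pe = np.zeros_like(u)
    beta = np.zeros_like(u)
    for _ in range(numerics.picard_maxiter):
        _, _, _, pe, beta = shear_fields(u, y, z, groups.P_G)
        lab = orientation_moment_fields(pe, beta, basis, table, node_order=node_order)
        coeffs = assemble_coefficients(lab, groups)
        u_new = solve_anisotropic_poisson(coeffs, Wbar, numerics.Y, numerics.Z)
        u_next = omega * u_new + (1.0 - omega) * u
        res = np.max(np.abs(u_next - u)) / max(np.max(np.abs(u_next)), 1e-300)
        residuals.append(res)
        u = u_next
        if res < numerics.picard_tol:
            break
    else:
        raise PicardNonConvergence(residuals)
    _, _, _, pe, beta = shear_fields(u, y, z, groups.P_G)
    lab = orientation_moment_fields(pe, beta, basis, table, node_order=node_order)
    coeffs = assemble_coefficients(lab, groups)
    S = lab["m11"] - lab["m22"]
    return SteadyResult(
        y=y, z=z, u=u, S=S, Pe=pe, beta=beta, lab_moments=lab, coeffs=coeffs,
        residuals=residuals,
    )
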