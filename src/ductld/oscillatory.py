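"""Oscillatory pressure-driven duct flow coupled to rod orientation.

The dimensionless axial momentum balance with an oscillating pressure
gradient is

    alpha^2 du/dt = -P'(t) + d/dy( c_yy u_y + c_yz u_z )
                    + d/dz( c_zz u_z + c_yz u_y )
                    + (2 Phi alpha_r / P_G) ( d f_y / dy + d f_z / dz ),

with alpha^2 the Womersley number and time scaled on the oscillation
frequency (t = omega* t*).  The real pressure-gradient forcing is
P'(t) = cos(t + pi/2) = -sin t, so the system starts from rest with zero
initial forcing.

The flow is advanced by a Peaceman-Rachford alternating-direction-implicit
(ADI) split: implicit tridiagonal solves in y then z, with the mixed c_yz
fluxes and the particle-stress divergence treated explicitly in both half
steps.  Every node's orientation state is advanced on the rotary-diffusion
time scale tau = kappa t (kappa = 6 D_r / omega*) with Heun's method,
sub-stepped as needed for explicit stability, using the velocity field
lagged by one flow step (first-order operator splitting).

Each node's local shear frame is fixed over the run at the reference angle
beta_ref given by the steady Newtonian gradient direction at that node; the
instantaneous shear is projected onto that axis, giving a signed Peclet
number that reverses with the flow.  For the lubrication-limit flows
considered here the gradient direction is very nearly time-invariant (the
velocity profile oscillates almost self-similarly), so the discarded
perpendicular component is small.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .basis import CouplingTable, HarmonicBasis, build_coupling_table
from .kernel import A00, heun_step_many, stable_substep
from .materials import DimensionlessGroups
from .moments import moments_from_coeffs, rotate_moments_to_lab
from .steady import (
    ChannelConfig,
    Numerics,
    assemble_coefficients,
    grid_arrays,
    identity_coefficients,
    solve_anisotropic_poisson,
)

__all__ = [
    "OscillationConfig",
    "TransientRecord",
    "Checkpoint",
    "pressure_forcing",
    "adi_step",
    "run_oscillatory",
]


class ADIInstabilityError(RuntimeError):
    pass


@dataclass(frozen=True)
class OscillationConfig:
    """Oscillation frequency and temporal resolution."""

    omega_star: float  # rad / s
    n_periods: int = 3
    steps_per_period: int = 1200
    snapshot_stride: int = 0  # 0 disables field snapshots

    def __post_init__(self):
        if self.omega_star <= 0:
            raise ValueError("oscillation frequency must be positive")
        if self.n_periods < 1 or self.steps_per_period < 8:
            raise ValueError("need at least one period and 8 steps per period")


def pressure_forcing(t) -> np.ndarray:
    """Dimensionless pressure gradient P'(t) = cos(t + pi/2) = -sin t.

    The momentum equation is driven by -P'(t) = sin t; the quarter-period
    phase shift makes the forcing vanish at t = 0 so the run starts from
    rest.
    """
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("time must be non-negative")
    out = -np.sin(t)
    return out if out.shape else float(out)


def _tridiag_solve_many(lower, diag, upper, rhs):
    """Thomas algorithm vectorized over the leading axis.

    All arguments have shape (n_lines, n); returns solutions of the same
    shape.  Each line's tridiagonal system is independent.
    """
    n = diag.shape[1]
    cp = np.empty_like(diag)
    dp = np.empty_like(diag)
    cp[:, 0] = upper[:, 0] / diag[:, 0]
    dp[:, 0] = rhs[:, 0] / diag[:, 0]
    for k in range(1, n):
        denom = diag[:, k] - lower[:, k] * cp[:, k - 1]
        cp[:, k] = upper[:, k] / denom
        dp[:, k] = (rhs[:, k] - lower[:, k] * dp[:, k - 1]) / denom
    x = np.empty_like(diag)
    x[:, -1] = dp[:, -1]
    for k in range(n - 2, -1, -1):
        x[:, k] = dp[:, k] - cp[:, k] * x[:, k + 1]
    return x


def _mixed_and_source(coeffs, u, y, z):
    """Explicit terms: mixed c_yz fluxes plus particle-stress divergence."""
    u_y = np.gradient(u, y, axis=0, edge_order=2)
    u_z = np.gradient(u, z, axis=1, edge_order=2)
    mixed = np.gradient(coeffs.c_yz * u_z, y, axis=0, edge_order=2) + np.gradient(
        coeffs.c_yz * u_y, z, axis=1, edge_order=2
    )
    if coeffs.source_prefactor != 0.0:
        mixed = mixed + coeffs.source_prefactor * (
            np.gradient(coeffs.f_y, y, axis=0, edge_order=2)
            + np.gradient(coeffs.f_z, z, axis=1, edge_order=2)
        )
    return mixed


def adi_step(u, coeffs, forcing_pair, dt, alpha2, y, z):
    """One Peaceman-Rachford step of the oscillatory flow equation.

    ``forcing_pair`` holds the driving term -P'(t) evaluated at the two
    half-step midpoints.  Implicit tridiagonal solve in y with explicit z
    terms first, then implicit in z; mixed-derivative and particle-stress
    terms are explicit in both half steps.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    r = dt / (2.0 * alpha2)
    dy = y[1] - y[0]
    dz = z[1] - z[0]
    cyy, czz = coeffs.c_yy, coeffs.c_zz
    ny, nz = u.shape

    def Ly(v):
        out = np.zeros_like(v)
        cE = 0.5 * (cyy[1:-1, :] + cyy[2:, :])
        cW = 0.5 * (cyy[1:-1, :] + cyy[:-2, :])
        out[1:-1, :] = (cE * (v[2:, :] - v[1:-1, :]) - cW * (v[1:-1, :] - v[:-2, :])) / dy ** 2
        return out

    def Lz(v):
        out = np.zeros_like(v)
        cN = 0.5 * (czz[:, 1:-1] + czz[:, 2:])
        cS = 0.5 * (czz[:, 1:-1] + czz[:, :-2])
        out[:, 1:-1] = (cN * (v[:, 2:] - v[:, 1:-1]) - cS * (v[:, 1:-1] - v[:, :-2])) / dz ** 2
        return out

    explicit = _mixed_and_source(coeffs, u, y, z)

    # half step 1: implicit in y (lines of constant z, interior j)
    rhs_full = u + r * (Lz(u) + explicit + forcing_pair[0])
    cE = 0.5 * (cyy[1:-1, 1:-1] + cyy[2:, 1:-1]) / dy ** 2  # (Y-1, Z-1)
    cW = 0.5 * (cyy[1:-1, 1:-1] + cyy[:-2, 1:-1]) / dy ** 2
    lower = -r * cW.T
    upper = -r * cE.T
    diag = 1.0 + r * (cE + cW).T
    ustar = np.zeros_like(u)
    ustar[1:-1, 1:-1] = _tridiag_solve_many(lower, diag, upper, rhs_full[1:-1, 1:-1].T).T

    # half step 2: implicit in z (lines of constant y, interior i)
    explicit2 = _mixed_and_source(coeffs, ustar, y, z)
    rhs2 = ustar + r * (Ly(ustar) + explicit2 + forcing_pair[1])
    cN = 0.5 * (czz[1:-1, 1:-1] + czz[1:-1, 2:]) / dz ** 2
    cS = 0.5 * (czz[1:-1, 1:-1] + czz[1:-1, :-2]) / dz ** 2
    unew = np.zeros_like(u)
    unew[1:-1, 1:-1] = _tridiag_solve_many(-r * cS, 1.0 + r * (cN + cS), -r * cN, rhs2[1:-1, 1:-1])
    if not np.all(np.isfinite(unew)):
        raise ADIInstabilityError("non-finite velocity after ADI step; reduce dt")
    return unew


@dataclass
class TransientRecord:
    """Per-step scalar series and optional field snapshots."""

    t: np.ndarray
    S_mean: np.ndarray
    S_max: np.ndarray
    u_mean: np.ndarray
    snapshots: list = field(default_factory=list)  # (step, S field, u field)

    def final_period_max_S_mean(self, steps_per_period: int) -> float:
        """Maximum of the spatially averaged S over the final period."""
        return float(np.max(self.S_mean[-steps_per_period:]))

    def period_series(self, steps_per_period: int):
        """Spatially-averaged-S series split per period."""
        nfull = len(self.S_mean) // steps_per_period
        return [
            self.S_mean[k * steps_per_period:(k + 1) * steps_per_period]
            for k in range(nfull)
        ]


@dataclass
class Checkpoint:
    """Full solver state allowing bit-identical resumption."""

    step: int
    u: np.ndarray
    X0: np.ndarray  # (nodes, n_cos)
    X1: np.ndarray  # (nodes, n_sin)


def _trapz_weights(y, z):
    wy = np.gradient(y)
    wy[0] *= 0.5
    wy[-1] *= 0.5
    wz = np.gradient(z)
    wz[0] *= 0.5
    wz[-1] *= 0.5
    w = np.outer(wy, wz)
    return w / w.sum()


def run_oscillatory(
    channel: ChannelConfig,
    osc: OscillationConfig,
    groups: DimensionlessGroups,
    numerics: Numerics = Numerics(),
    table: CouplingTable | None = None,
    checkpoint: Checkpoint | None = None,
    checkpoint_at: int | None = None,
):
    """Time-march the coupled oscillatory problem from rest.

    Starting from zero velocity and isotropic orientation everywhere (or
    from ``checkpoint``), each step (i) evaluates the signed local Peclet
    field from the current velocity, (ii) advances every node's orientation
    state over d tau = kappa dt, (iii) assembles the anisotropic
    coefficients from the new moments, and (iv) ADI-advances the velocity.
    Per-node updates are independent and order-invariant.

    Returns (TransientRecord, final_fields dict); if ``checkpoint_at`` is
    given, stops after that many steps and returns (record, Checkpoint).
    """
    basis = HarmonicBasis(numerics.N)
    if table is None:
        table = build_coupling_table(basis)
    alpha2 = groups.womersley
    if not np.isfinite(groups.kappa) or alpha2 <= 0:
        raise ValueError("oscillatory run requires omega* > 0 (finite kappa, alpha^2 > 0)")
    y, z = grid_arrays(channel.Wbar, numerics.Y, numerics.Z)
    ny, nz = numerics.Y + 1, numerics.Z + 1
    nnodes = ny * nz

    # fixed per-node shear axis from the steady Newtonian gradient direction
    u_ref = solve_anisotropic_poisson(
        identity_coefficients(numerics.Y, numerics.Z), channel.Wbar, numerics.Y, numerics.Z
    )
    ry = np.gradient(u_ref, y, axis=0, edge_order=2)
    rz = np.gradient(u_ref, z, axis=1, edge_order=2)
    gref = np.hypot(ry, rz)
    beta_ref = np.where(gref > 0, np.arctan2(rz, ry), 0.0)
    e_ref = (np.cos(beta_ref), np.sin(beta_ref))

    dt = 2.0 * np.pi / osc.steps_per_period
    dtau_step = groups.kappa * dt
    total_steps = osc.n_periods * osc.steps_per_period

    if checkpoint is not None:
        start = checkpoint.step
        u = checkpoint.u.copy()
        X0 = checkpoint.X0.copy()
        X1 = checkpoint.X1.copy()
    else:
        start = 0
        u = np.zeros((ny, nz))
        X0 = np.zeros((nnodes, basis.n_cos))
        X0[:, basis.cos_index(0, 0)] = A00
        X1 = np.zeros((nnodes, basis.n_sin))

    w = _trapz_weights(y, z)
    rec_t, rec_smean, rec_smax, rec_umean = [], [], [], []
    snapshots = []
    stop = checkpoint_at if checkpoint_at is not None else total_steps
    # time averages of the fields over the final half period
    half_start = total_steps - osc.steps_per_period // 2
    S_half_sum = np.zeros((ny, nz))
    u_half_sum = np.zeros((ny, nz))
    n_half = 0

    for step in range(start, stop):
        t_n = step * dt
        u_y = np.gradient(u, y, axis=0, edge_order=2)
        u_z = np.gradient(u, z, axis=1, edge_order=2)
        pe_signed = (groups.P_G / 6.0) * (u_y * e_ref[0] + u_z * e_ref[1])
        pe_flat = pe_signed.ravel()

        n_sub = stable_substep(dtau_step, np.abs(pe_flat).max(), basis, table)
        sub = dtau_step / n_sub
        for _ in range(n_sub):
            X0, X1 = heun_step_many(X0, X1, pe_flat, pe_flat, sub, basis, table)

        local9 = moments_from_coeffs(X0, X1, basis)
        lab = rotate_moments_to_lab(local9, beta_ref.ravel())
        lab = {k: v.reshape(ny, nz) for k, v in lab.items()}
        coeffs = assemble_coefficients(lab, groups)
        forcing_pair = (
            -pressure_forcing(t_n + 0.25 * dt),
            -pressure_forcing(t_n + 0.75 * dt),
        )
        try:
            u = adi_step(u, coeffs, forcing_pair, dt, alpha2, y, z)
        except ADIInstabilityError as exc:
            raise ADIInstabilityError(f"instability at step {step}: {exc}") from exc

        S = lab["m11"] - lab["m22"]
        if step >= half_start:
            S_half_sum += S
            u_half_sum += u
            n_half += 1
        rec_t.append(t_n + dt)
        rec_smean.append(float(np.sum(S * w)))
        rec_smax.append(float(S.max()))
        rec_umean.append(float(np.sum(u * w)))
        if osc.snapshot_stride and (step + 1) % osc.snapshot_stride == 0:
            snapshots.append((step + 1, S.copy(), u.copy()))

    record = TransientRecord(
        t=np.array(rec_t),
        S_mean=np.array(rec_smean),
        S_max=np.array(rec_smax),
        u_mean=np.array(rec_umean),
        snapshots=snapshots,
    )
    if checkpoint_at is not None:
        return record, Checkpoint(step=stop, u=u, X0=X0, X1=X1)

    local9 = moments_from_coeffs(X0, X1, basis)
    lab = rotate_moments_to_lab(local9, beta_ref.ravel())
    lab = {k: v.reshape(ny, nz) for k, v in lab.items()}
    final = {
        "y": y,
        "z": z,
        "u": u,
        "S": lab["m11"] - lab["m22"],
        "S_half_avg": S_half_sum / max(n_half, 1),
        "u_half_avg": u_half_sum / max(n_half, 1),
        "lab_moments": lab,
        "beta_ref": beta_ref,
        "X0": X0,
        "X1": X1,
    }
    return record, final
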