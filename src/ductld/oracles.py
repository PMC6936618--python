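"""Independent validation oracles for the spectral orientation kernel.

These deliberately avoid the spherical-harmonic machinery: the steady
Fokker-Planck equation is discretized directly on an angular grid, and
moments are integrated by Monte-Carlo sampling of the reconstructed
distribution.  They exist for cross-validation in the test suite and the
``validate`` command, never as the production path.
"""

from __future__ import annotations

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

__all__ = ["fd_steady_orientation", "fd_orientation_parameter", "mc_moments"]


def fd_steady_orientation(Pe: float, n_theta: int = 180, n_phi: int = 360):
    """Finite-difference solution of (1/6) Lambda(psi) = Pe Upsilon(psi).

    Conservative second-order discretization on a pole-staggered
    (theta, phi) grid with periodic phi; the singular neutral direction
    (any multiple of a solution) is removed by replacing one row with the
    normalization condition int psi dOmega = 1.

    Returns (theta, phi, psi) with psi of shape (n_theta, n_phi).
    """
    ht = np.pi / n_theta
    hp = 2.0 * np.pi / n_phi
    theta = (np.arange(n_theta) + 0.5) * ht
    phi = np.arange(n_phi) * hp
    st = np.sin(theta)
    st_half = np.sin((np.arange(n_theta + 1)) * ht)  # theta = i*ht edges
    g_half = (np.sin(np.arange(n_theta + 1) * ht) ** 2) * np.cos(np.arange(n_theta + 1) * ht)
    ssq = np.sin(phi) ** 2
    ssq_half = np.sin(phi + 0.5 * hp) ** 2
    sc = np.sin(phi) * np.cos(phi)

    N = n_theta * n_phi

    def idx(i, j):
        return i * n_phi + (j % n_phi)

    rows, cols, vals = [], [], []

    def add(r, c, v):
        rows.append(r)
        cols.append(c)
        vals.append(v)

    for i in range(n_theta):
        for j in range(n_phi):
            r = idx(i, j)
            # (1/6) * (1/sin) d/dtheta( sin d psi/dtheta )
            cN = st_half[i + 1] / (ht * ht * st[i]) / 6.0  # towards i+1
            cS = st_half[i] / (ht * ht * st[i]) / 6.0
            if i + 1 < n_theta:
                add(r, idx(i + 1, j), cN)
                add(r, r, -cN)
            else:
                # psi(pi + d, phi) = psi(pi - d, phi + pi): flux across the
                # pole cancels at the staggered edge (sin = 0), nothing to add
                pass
            if i - 1 >= 0:
                add(r, idx(i - 1, j), cS)
                add(r, r, -cS)
            # (1/6) * (1/sin^2) d2 psi/dphi2
            cP = 1.0 / (hp * hp * st[i] ** 2) / 6.0
            add(r, idx(i, j + 1), cP)
            add(r, idx(i, j - 1), cP)
            add(r, r, -2.0 * cP)
            # -Pe * (sin phi cos phi / sin) d/dtheta( sin^2 cos . psi ) , centred flux
            a = -Pe * sc[j] / (st[i] * ht)
            if i + 1 < n_theta:
                add(r, idx(i + 1, j), a * 0.5 * g_half[i + 1])
                add(r, r, a * 0.5 * g_half[i + 1])
            if i - 1 >= 0:
                add(r, r, -a * 0.5 * g_half[i])
                add(r, idx(i - 1, j), -a * 0.5 * g_half[i])
            # +Pe * d/dphi( sin^2 phi . psi ), centred flux
            b = Pe / hp
            add(r, idx(i, j + 1), b * 0.5 * ssq_half[j])
            add(r, r, b * 0.5 * ssq_half[j])
            add(r, r, -b * 0.5 * ssq_half[j - 1])
            add(r, idx(i, j - 1), -b * 0.5 * ssq_half[j - 1])

    A = sp.csr_matrix((vals, (rows, cols)), shape=(N, N)).tolil()
    # replace one interior equation by the normalization condition
    w = (st[:, None] * np.ones(n_phi)[None, :] * ht * hp).ravel()
    r0 = idx(n_theta // 2, 0)
    A.rows[r0] = list(range(N))
    A.data[r0] = list(w)
    rhs = np.zeros(N)
    rhs[r0] = 1.0
    psi = spla.spsolve(A.tocsr(), rhs)
    return theta, phi, psi.reshape(n_theta, n_phi)


def fd_orientation_parameter(Pe: float, n_theta: int = 180, n_phi: int = 360) -> float:
    """S = <p1^2> - <p2^2> from the angular-grid solution (local frame)."""
    theta, phi, psi = fd_steady_orientation(Pe, n_theta, n_phi)
    ht = np.pi / n_theta
    hp = 2.0 * np.pi / n_phi
    st = np.sin(theta)[:, None]
    p1sq = (st * np.cos(phi)[None, :]) ** 2
    p2sq = (st * np.sin(phi)[None, :]) ** 2
    w = st * ht * hp
    return float(np.sum((p1sq - p2sq) * psi * w))


def mc_moments(state, n_samples: int = 10_000_000, seed: int = 0) -> dict:
    """Monte-Carlo moment integrals of a reconstructed distribution.

    Samples directions uniformly on the sphere and averages f(p) psi(p) 4 pi,
    for the second moments and the fourth-moment contractions tracked by the
    solver.  Returns a dict keyed like the local moment fields.
    """
    rng = np.random.default_rng(seed)
    # chunked evaluation keeps memory bounded
    acc = np.zeros(9)
    done = 0
    chunk = 1_000_000
    while done < n_samples:
        n = min(chunk, n_samples - done)
        u = rng.normal(size=(n, 3))
        u /= np.linalg.norm(u, axis=1, keepdims=True)
        theta = np.arccos(np.clip(u[:, 2], -1, 1))
        phi = np.mod(np.arctan2(u[:, 1], u[:, 0]), 2 * np.pi)
        # pointwise psi via the basis expansion
        psi = _psi_at(state, np.cos(theta), phi)
        p1, p2, p3 = u[:, 0], u[:, 1], u[:, 2]
        f = np.stack(
            [p1 * p1, p2 * p2, p3 * p3, p1 * p2, p1 * p3, p2 * p3,
             p1 * p1 * p2 * p2, p1 * p1 * p3 * p3, p1 * p1 * p2 * p3]
        )
        acc += (f * psi[None, :]).sum(axis=1) * 4.0 * np.pi
        done += n
    vals = acc / n_samples
    keys = ("m11", "m22", "m33", "m12", "m13", "m23", "q22", "q33", "q23")
    return dict(zip(keys, vals))


def _psi_at(state, x, phi):
    from .basis import _legendre_and_xderiv

    out = np.zeros_like(x)
    for j, (n, m) in enumerate(state.basis.cos_modes):
        pv, _ = _legendre_and_xderiv(n, m, x)
        out += state.A0[j] * pv * np.cos(m * phi)
    for j, (n, m) in enumerate(state.basis.sin_modes):
        pv, _ = _legendre_and_xderiv(n, m, x)
        out += state.A1[j] * pv * np.sin(m * phi)
    return out
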