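"""Closed-form Newtonian duct flows used as limits and validation oracles.

All quantities are dimensionless: the cross-section is [-Wbar, Wbar] x
[-1, 1], the steady problem is laplacian(u) = -1 with u = 0 on the walls,
and the oscillatory problem is alpha^2 du/dt = sin(t) + laplacian(u)
(pressure forcing -P'(t) = sin t, so the flow starts from rest at t = 0).
"""

from __future__ import annotations

import numpy as np

__all__ = ["newtonian_duct_solution", "womersley_plane", "womersley_duct"]


def newtonian_duct_solution(y, z, Wbar: float, tol: float = 1e-12) -> np.ndarray:
    """Steady Poiseuille flow in a rectangular duct, double-series solution.

        u(y, z) = (1 - z^2)/2
                  - (16/pi^3) sum_{k odd} (-1)^((k-1)/2) cosh(k pi y / 2)
                    cos(k pi z / 2) / (k^3 cosh(k pi Wbar / 2))

    summed until the term bound drops below ``tol``.  ``y`` and ``z`` are
    broadcast against each other.
    """
    y = np.asarray(y, dtype=float)
    z = np.asarray(z, dtype=float)
    yy, zz = np.meshgrid(y, z, indexing="ij") if y.ndim == 1 and z.ndim == 1 else (y, z)
    u = 0.5 * (1.0 - zz * zz)
    k = 1
    while True:
        arg = 0.5 * k * np.pi
        coef = 16.0 / np.pi ** 3 * (-1.0) ** ((k - 1) // 2) / k ** 3
        # cosh(k pi y/2)/cosh(k pi W/2), computed stably via exponentials
        ratio = np.exp(arg * (np.abs(yy) - Wbar)) * (
            (1.0 + np.exp(-2.0 * arg * np.abs(yy))) / (1.0 + np.exp(-2.0 * arg * Wbar))
        )
        u -= coef * ratio * np.cos(arg * zz)
        if 16.0 / np.pi ** 3 / k ** 3 * np.exp(-arg * (Wbar - np.abs(yy).max())) < tol or k > 4001:
            break
        k += 2
    return u


def womersley_plane(z, t, alpha2: float) -> np.ndarray:
    """Long-time periodic plane-channel solution of the oscillatory problem.

    Solves alpha^2 du/dt = sin t + u_zz with u(+-1, t) = 0; returns
    Im[ uhat(z) e^{it} ] with uhat = (1/(i alpha^2)) (1 - cosh(lam z)/cosh(lam)),
    lam = sqrt(i alpha^2).
    """
    z = np.asarray(z, dtype=float)
    lam = np.sqrt(1j * alpha2)
    uhat = (1.0 - np.cosh(lam * z) / np.cosh(lam)) / (1j * alpha2)
    return np.imag(uhat * np.exp(1j * np.asarray(t)))


def womersley_duct(y, z, t, alpha2: float, Wbar: float, nterms: int = 101) -> np.ndarray:
    """Long-time periodic oscillatory flow in the rectangular duct.

    Series over depth modes cos(k pi z / 2), k odd, each with a
    finite-width correction in y:

        uhat = sum_k (c_k / mu_k^2) [1 - cosh(mu_k y)/cosh(mu_k Wbar)]
               cos(k pi z/2),
        mu_k^2 = i alpha^2 + k^2 pi^2 / 4,  c_k = (4/(k pi)) (-1)^((k-1)/2).

    Returns Im[ uhat e^{it} ].
    """
    y = np.asarray(y, dtype=float)
    z = np.asarray(z, dtype=float)
    yy, zz = np.meshgrid(y, z, indexing="ij") if y.ndim == 1 and z.ndim == 1 else (y, z)
    uhat = np.zeros(yy.shape, dtype=complex)
    for k in range(1, 2 * nterms, 2):
        ck = 4.0 / (k * np.pi) * (-1.0) ** ((k - 1) // 2)
        mu = np.sqrt(1j * alpha2 + (k * np.pi / 2.0) ** 2)  # Re(mu) > 0
        # cosh ratio via exponentials to avoid overflow at large k Wbar
        ay = np.abs(yy)
        ratio = np.exp(mu * (ay - Wbar)) * (
            (1.0 + np.exp(-2.0 * mu * ay)) / (1.0 + np.exp(-2.0 * mu * Wbar))
        )
        uhat += ck / mu ** 2 * (1.0 - ratio) * np.cos(0.5 * k * np.pi * zz)
    return np.imag(uhat * np.exp(1j * np.asarray(t)))
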