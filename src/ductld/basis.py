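"""Spherical-harmonic basis for the orientation distribution of Brownian rods.

The orientation distribution psi(phi', theta') of a fore-aft symmetric rod is
expanded in unnormalized associated Legendre polynomials,

    psi = sum_{n,m} [ A0_nm P_n^m(cos theta') cos(m phi')
                    + A1_nm P_n^m(cos theta') sin(m phi') ],

with only even n and even m retained (antipodal particle symmetry) and the
(n, m) = (0, 0) cosine coefficient pinned to 1/(4 pi) by normalization.

The rotary-diffusion operator Lambda is diagonal in this basis with eigenvalue
-n(n+1).  The simple-shear advection operator

    Upsilon(psi) = (sin phi' cos phi' / sin theta')
                     d/dtheta'( sin^2 theta' cos theta' psi )
                   - d/dphi'( sin^2 phi' psi )

is banded: it couples mode (n, m) only to modes (q, p) with |q - n| <= 2 and
|p - m| <= 2, swapping the cosine and sine families.  The coupling
coefficients a^{m,p}_{n,q} are generated here by exact Gauss-Legendre /
trigonometric quadrature projection (the integrands are polynomials in
cos theta' times trigonometric polynomials, so the projection is exact to
round-off), rather than transcribed from printed tables.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numpy.polynomial.legendre import leggauss
from scipy.special import lpmv

__all__ = ["HarmonicBasis", "CouplingTable", "build_coupling_table"]


class InvalidBasisError(ValueError):
    """Raised for a truncation order that is not an even non-negative integer."""


@dataclass(frozen=True)
class HarmonicBasis:
    """Index bookkeeping for the retained spherical-harmonic modes.

    Parameters
    ----------
    N : int
        Maximum harmonic degree (even, >= 0).  Modes with odd degree or odd
        azimuthal order are excluded by particle fore-aft symmetry.
    """

    N: int
    cos_modes: tuple = field(init=False)
    sin_modes: tuple = field(init=False)

    def __post_init__(self):
        if self.N < 0 or self.N % 2 != 0:
            raise InvalidBasisError(f"harmonic order must be even and >= 0, got {self.N}")
        cos_modes = tuple(
            (n, m) for n in range(0, self.N + 1, 2) for m in range(0, n + 1, 2)
        )
        sin_modes = tuple((n, m) for (n, m) in cos_modes if m > 0)
        object.__setattr__(self, "cos_modes", cos_modes)
        object.__setattr__(self, "sin_modes", sin_modes)

    @property
    def n_cos(self) -> int:
        return len(self.cos_modes)

    @property
    def n_sin(self) -> int:
        return len(self.sin_modes)

    def cos_index(self, n: int, m: int) -> int:
        return self.cos_modes.index((n, m))

    def sin_index(self, n: int, m: int) -> int:
        return self.sin_modes.index((n, m))

    def decay_rates(self):
        """Diagonal of -Lambda/6: q(q+1)/6 per mode, (cos family, sin family)."""
        d_cos = np.array([n * (n + 1) / 6.0 for (n, m) in self.cos_modes])
        d_sin = np.array([n * (n + 1) / 6.0 for (n, m) in self.sin_modes])
        return d_cos, d_sin


def _legendre_and_xderiv(n, m, x):
    """P_n^m(x) and (1 - x^2) dP_n^m/dx, via the standard recurrence.

    Only even m is ever requested here, so the Condon-Shortley phase of
    scipy's ``lpmv`` is unity and the values coincide with the unnormalized
    P_n^m of the expansion.
    """
    p = lpmv(m, n, x)
    if n == 0:
        return p, np.zeros_like(x)
    pm1 = lpmv(m, n - 1, x) if m <= n - 1 else np.zeros_like(x)
    b = (n + m) * pm1 - n * x * p  # (1 - x^2) dP/dx
    return p, b


def _apply_upsilon(n, m, family, x, phi):
    """Evaluate Upsilon applied to one basis function on the (x, phi) grid.

    ``family`` is "cos" or "sin".  Returns an array of shape (len(x), len(phi)).
    """
    p, b = _legendre_and_xderiv(n, m, x)
    radial = ((3.0 * x * x - 1.0) * p - x * b)[:, None]  # (1/sin) d/dtheta(sin^2 cos . P)
    sc = (np.sin(phi) * np.cos(phi))[None, :]
    s2 = np.sin(2.0 * phi)[None, :]
    ssq = (np.sin(phi) ** 2)[None, :]
    if family == "cos":
        t = np.cos(m * phi)[None, :]
        dt = -m * np.sin(m * phi)[None, :]
    else:
        t = np.sin(m * phi)[None, :]
        dt = m * np.cos(m * phi)[None, :]
    term1 = sc * t * radial
    term2 = -p[:, None] * (s2 * t + ssq * dt)
    return term1 + term2


@dataclass(frozen=True)
class CouplingTable:
    """Shear-coupling coefficients a^{m,p}_{n,q} on a :class:`HarmonicBasis`.

    ``entries`` maps (n, m, q, p) -> coefficient, where (n, m) is the source
    mode and (q, p) the target mode.  The same coefficients serve both
    directions of the cosine/sine swap:

        Upsilon(C_nm) = - sum a^{m,p}_{n,q} S_qp
        Upsilon(S_nm) = + sum a^{m,p}_{n,q} C_qp
    """

    basis: HarmonicBasis
    entries: dict

    def matrix_cos_from_sin(self) -> np.ndarray:
        """G with G[(q,p), (n,m)] = a^{m,p}_{n,q}: sine coeffs -> cosine eqs."""
        g = np.zeros((self.basis.n_cos, self.basis.n_sin))
        for (n, m, q, p), a in self.entries.items():
            if m > 0 and (q, p) in self.basis.cos_modes:
                g[self.basis.cos_index(q, p), self.basis.sin_index(n, m)] = a
        return g

    def matrix_sin_from_cos(self) -> np.ndarray:
        """H with H[(q,p), (n,m)] = a^{m,p}_{n,q}: cosine coeffs -> sine eqs."""
        h = np.zeros((self.basis.n_sin, self.basis.n_cos))
        for (n, m, q, p), a in self.entries.items():
            if p > 0 and (q, p) in self.basis.sin_modes:
                h[self.basis.sin_index(q, p), self.basis.cos_index(n, m)] = a
        return h


def build_coupling_table(basis: HarmonicBasis, drop_tol: float = 1e-12) -> CouplingTable:
    """Construct the a^{m,p}_{n,q} by quadrature projection.

    Upsilon is applied analytically to each retained basis function,
    evaluated on a Gauss-Legendre (cos theta') x uniform (phi') product grid,
    and projected onto the basis using the orthogonality of associated
    Legendre polynomials and trigonometric functions.  Entries below
    ``drop_tol`` are dropped as structural zeros.  The cosine-source and
    sine-source constructions overlap for m >= 2, p >= 2; both are computed
    and cross-checked before merging.
    """
    if not isinstance(basis, HarmonicBasis):
        basis = HarmonicBasis(basis)
    N = basis.N
    nx = 2 * N + 10
    nphi = 4 * N + 16
    x, wx = leggauss(nx)
    phi = np.arange(nphi) * (2.0 * np.pi / nphi)
    wphi = 2.0 * np.pi / nphi

    # Precompute target-mode values and norms.
    pvals = {}
    for (q, p) in basis.cos_modes:
        pv, _ = _legendre_and_xderiv(q, p, x)
        pvals[(q, p)] = pv

    def theta_norm(q, p):
        from math import factorial

        return 2.0 / (2 * q + 1) * factorial(q + p) / factorial(q - p)

    from collections import defaultdict

    found = defaultdict(list)

    for family in ("cos", "sin"):
        sources = basis.cos_modes if family == "cos" else basis.sin_modes
        for (n, m) in sources:
            ups = _apply_upsilon(n, m, family, x, phi)
            for q in range(max(0, n - 2), min(N, n + 2) + 1, 2):
                for p in range(max(0, m - 2), min(q, m + 2) + 1, 2):
                    if family == "cos":
                        if p == 0:
                            continue  # no sine target with p = 0
                        trig = np.sin(p * phi)
                        sign = -1.0
                        phi_norm = np.pi
                    else:
                        trig = np.cos(p * phi)
                        sign = 1.0
                        phi_norm = 2.0 * np.pi if p == 0 else np.pi
                    proj = (wx * pvals[(q, p)]) @ ups @ (trig * wphi)
                    a = sign * proj / (theta_norm(q, p) * phi_norm)
                    if abs(a) > drop_tol:
                        found[(n, m, q, p)].append(a)

    entries = {}
    for key, vals in found.items():
        if len(vals) == 2 and abs(vals[0] - vals[1]) > 1e-10:
            raise AssertionError(
                f"inconsistent coupling projection for {key}: {vals}"
            )
        entries[key] = float(np.mean(vals))
    return CouplingTable(basis=basis, entries=entries)
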