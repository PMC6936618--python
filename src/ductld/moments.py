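"""Orientation moments and scalar orientation parameters.

The flow coupling needs low-order moments of psi: the second moments
<p_i p_j>, the fourth-moment contractions <p1^2 p2^2>, <p1^2 p3^2>,
<p1^2 p2 p3>, and the mixed moments <p1 p2>, <p1 p3> feeding the
rotary-stress divergence.  Each is a linear functional of the harmonic
coefficients; the functionals are evaluated once per basis on a
Gauss-Legendre (cos theta') x uniform (phi') quadrature grid (order
>= 2N+4 and >= 4N+8 respectively, which integrates the polynomial
integrands exactly) and cached as small matrices.  Per-state moments are
then matrix-vector products.

The local frame at a spatial point is rotated away from the laboratory
frame about the flow (x) axis by the signed angle beta = atan2(u_z, u_y);
second-moment tensors transport with two rotations and the <p1^2 p_i p_j>
block with the same 2x2 rotation in the (y, z) plane (p1 is invariant).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numpy.polynomial.legendre import leggauss

from .basis import HarmonicBasis, _legendre_and_xderiv
from .kernel import OrientationState

__all__ = [
    "MomentSet",
    "compute_moments",
    "local_moment_operator",
    "moments_from_coeffs",
    "rotate_moments_to_lab",
    "orientation_parameter_biaxial",
    "orientation_parameter_uniaxial",
    "reconstruct_psi",
]


@dataclass(frozen=True)
class MomentSet:
    """Second moments and selected fourth moments of psi in one frame.

    M2 is the full symmetric second-moment tensor <p_i p_j>; the fourth-
    moment contractions are those entering the anisotropic flow PDE.
    """

    M2: np.ndarray  # (3, 3)
    p11p22: float  # <p1^2 p2^2>
    p11p33: float  # <p1^2 p3^2>
    p11p23: float  # <p1^2 p2 p3>
    frame: str = "lab"


# ---------------------------------------------------------------------------
# quadrature functionals

# order of the nine tracked local moments
_MOMENT_NAMES = ("m11", "m22", "m33", "m12", "m13", "m23", "q22", "q33", "q23")

_moment_cache: dict = {}


def local_moment_operator(basis: HarmonicBasis):
    """(W0, W1): matrices mapping (A0, A1) to the nine local moments."""
    op = _moment_cache.get(basis.N)
    if op is not None:
        return op
    N = basis.N
    nx = 2 * N + 6
    nphi = 4 * N + 10
    x, wx = leggauss(nx)
    phi = np.arange(nphi) * (2.0 * np.pi / nphi)
    wphi = 2.0 * np.pi / nphi
    st = np.sqrt(1.0 - x * x)
    p1 = st[:, None] * np.cos(phi)[None, :]
    p2 = st[:, None] * np.sin(phi)[None, :]
    p3 = np.broadcast_to(x[:, None], p1.shape)
    integrands = np.stack(
        [
            p1 * p1,
            p2 * p2,
            p3 * p3,
            p1 * p2,
            p1 * p3,
            p2 * p3,
            p1 * p1 * p2 * p2,
            p1 * p1 * p3 * p3,
            p1 * p1 * p2 * p3,
        ]
    )  # (9, nx, nphi)
    W0 = np.zeros((9, basis.n_cos))
    W1 = np.zeros((9, basis.n_sin))
    for j, (n, m) in enumerate(basis.cos_modes):
        pv, _ = _legendre_and_xderiv(n, m, x)
        f = pv[:, None] * np.cos(m * phi)[None, :]
        W0[:, j] = np.einsum("kij,i,j->k", integrands * f[None], wx, np.full(nphi, wphi))
    for j, (n, m) in enumerate(basis.sin_modes):
        pv, _ = _legendre_and_xderiv(n, m, x)
        f = pv[:, None] * np.sin(m * phi)[None, :]
        W1[:, j] = np.einsum("kij,i,j->k", integrands * f[None], wx, np.full(nphi, wphi))
    _moment_cache[basis.N] = (W0, W1)
    return W0, W1


def moments_from_coeffs(X0: np.ndarray, X1: np.ndarray, basis: HarmonicBasis) -> np.ndarray:
    """Nine local-frame moments for stacked coefficient arrays.

    X0: (npts, n_cos), X1: (npts, n_sin) -> (npts, 9), columns ordered as
    (m11, m22, m33, m12, m13, m23, q22, q33, q23) with qij = <p1^2 p_i p_j>.
    """
    W0, W1 = local_moment_operator(basis)
    return X0 @ W0.T + X1 @ W1.T


def rotate_moments_to_lab(local9: np.ndarray, beta: np.ndarray) -> dict:
    """Rotate the nine local moments to the laboratory frame.

    ``local9`` has shape (..., 9); ``beta`` broadcasts over the leading
    dimensions.  Returns a dict of lab-frame fields.  With p_lab = R(beta)
    p_loc and R a rotation about x: p_y = c p2' - s p3', p_z = s p2' + c p3'.
    """
    m11, m22, m33, m12, m13, m23, q22, q33, q23 = (local9[..., k] for k in range(9))
    c, s = np.cos(beta), np.sin(beta)
    lab = {
        "m11": m11,
        "m22": c * c * m22 + s * s * m33 - 2 * c * s * m23,
        "m33": s * s * m22 + c * c * m33 + 2 * c * s * m23,
        "m12": c * m12 - s * m13,
        "m13": s * m12 + c * m13,
        "m23": c * s * (m22 - m33) + (c * c - s * s) * m23,
        "q22": c * c * q22 + s * s * q33 - 2 * c * s * q23,
        "q33": s * s * q22 + c * c * q33 + 2 * c * s * q23,
        "q23": c * s * (q22 - q33) + (c * c - s * s) * q23,
    }
    return lab


def compute_moments(state: OrientationState, beta: float = 0.0) -> MomentSet:
    """Laboratory-frame moment set for one orientation state."""
    loc = moments_from_coeffs(state.A0[None, :], state.A1[None, :], state.basis)[0]
    lab = rotate_moments_to_lab(loc, np.asarray(beta))
    M2 = np.array(
        [
            [lab["m11"], lab["m12"], lab["m13"]],
            [lab["m12"], lab["m22"], lab["m23"]],
            [lab["m13"], lab["m23"], lab["m33"]],
        ],
        dtype=float,
    )
    return MomentSet(
        M2=M2,
        p11p22=float(lab["q22"]),
        p11p33=float(lab["q33"]),
        p11p23=float(lab["q23"]),
        frame="lab",
    )


def orientation_parameter_biaxial(moments: MomentSet) -> float:
    """S = <p_x^2> - <p_y^2>, the biaxial flow-alignment parameter."""
    return float(moments.M2[0, 0] - moments.M2[1, 1])


def orientation_parameter_uniaxial(state: OrientationState) -> float:
    """Uniaxial membrane-style parameter (1/2)(3 <cos^2 theta_S> - 1).

    theta_S = arccos |p . x|, so <cos^2 theta_S> = <p_x^2>; the formula is
    exact for uniaxial samples and over-predicts alignment in shear, where
    the distribution is biaxial.  <p_x^2> is frame-independent under the
    rotation about x, so no beta is needed.
    """
    loc = moments_from_coeffs(state.A0[None, :], state.A1[None, :], state.basis)[0]
    return 0.5 * (3.0 * float(loc[0]) - 1.0)


def reconstruct_psi(state: OrientationState, theta: np.ndarray, phi: np.ndarray) -> np.ndarray:
    """Evaluate psi on a (theta, phi) product grid in the local frame."""
    x = np.cos(np.asarray(theta, dtype=float))
    phi = np.asarray(phi, dtype=float)
    out = np.zeros((x.size, phi.size))
    for j, (n, m) in enumerate(state.basis.cos_modes):
        pv, _ = _legendre_and_xderiv(n, m, x)
        out += state.A0[j] * pv[:, None] * np.cos(m * phi)[None, :]
    for j, (n, m) in enumerate(state.basis.sin_modes):
        pv, _ = _legendre_and_xderiv(n, m, x)
        out += state.A1[j] * pv[:, None] * np.sin(m * phi)[None, :]
    return out
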