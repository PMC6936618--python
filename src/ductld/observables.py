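"""Reported scalars: spatial/width averages, S_rms and the LD signal.

The linear dichroism signal of a suspension of aligned chromophoric fibres
is proportional to concentration and to the degree of alignment,

    LD = (eps* m_w n_d / N_A) * S_rms     [1/m],

with S_rms the root-mean-square of the orientation parameter across the
channel depth, S_rms(y) = sqrt( (1/2h*) int S^2 dz* ).  Both the S_rms
profile across the width and its width average are exposed; all integrals
use the trapezoidal rule on the solver grid, consistent with the
second-order discretizations feeding them.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .materials import AVOGADRO

__all__ = [
    "ObservableSummary",
    "spatial_average",
    "width_average",
    "s_rms_profile",
    "ld_signal",
    "summarize_steady",
]


def spatial_average(field: np.ndarray, y: np.ndarray, z: np.ndarray) -> float:
    """Cross-section average (1 / 4 Wbar) int int field dy dz (trapezoid)."""
    inner = np.trapezoid(field, z, axis=1)
    return float(np.trapezoid(inner, y) / ((y[-1] - y[0]) * (z[-1] - z[0])))


def width_average(field: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Average over the width coordinate: profile versus depth z."""
    return np.trapezoid(field, y, axis=0) / (y[-1] - y[0])


def s_rms_profile(S: np.ndarray, z: np.ndarray) -> np.ndarray:
    """RMS of S across the depth at each width position."""
    return np.sqrt(np.trapezoid(S ** 2, z, axis=1) / (z[-1] - z[0]))


def ld_signal(S_rms, n_d: float, eps: float, m_w: float, N_A: float = AVOGADRO):
    """Linear dichroism signal (1/m) from S_rms (scalar or profile)."""
    if n_d < 0 or eps < 0:
        raise ValueError("number density and extinction coefficient must be >= 0")
    return eps * m_w * n_d / N_A * np.asarray(S_rms, dtype=float)


@dataclass(frozen=True)
class ObservableSummary:
    """Scalar summary row for one steady or oscillatory run."""

    S_mean: float
    S_max: float
    S_rms_width_avg: float
    LD_mean: float
    u_mean: float


def summarize_steady(result, n_d: float, eps: float, m_w: float) -> ObservableSummary:
    """Summary scalars for a converged steady result."""
    srms = s_rms_profile(result.S, result.z)
    srms_avg = float(np.trapezoid(srms, result.y) / (result.y[-1] - result.y[0]))
    return ObservableSummary(
        S_mean=spatial_average(result.S, result.y, result.z),
        S_max=float(result.S.max()),
        S_rms_width_avg=srms_avg,
        LD_mean=float(ld_signal(srms_avg, n_d, eps, m_w)),
        u_mean=spatial_average(result.u, result.y, result.z),
    )
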