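"""High-level run drivers shared by the CLI, sweeps and scripts."""

from __future__ import annotations

import numpy as np

from .config import RunConfig
from .observables import ObservableSummary, ld_signal, s_rms_profile, summarize_steady
from .oscillatory import run_oscillatory
from .steady import picard_couple

__all__ = ["run_steady", "run_transient", "summary_row"]


def run_steady(cfg: RunConfig, table=None):
    """Steady Picard-coupled solve from a run configuration.

    Returns (SteadyResult, ObservableSummary, DimensionlessGroups).
    """
    groups = cfg.groups(oscillatory=False)
    result = picard_couple(cfg.channel_config(), groups, cfg.numerics_config(), table=table)
    summary = summarize_steady(result, cfg.particle.n_d, cfg.particle.eps, cfg.particle.m_w)
    return result, summary, groups


def run_transient(cfg: RunConfig, table=None, checkpoint=None, checkpoint_at=None):
    """Oscillatory coupled run from a run configuration.

    Returns (TransientRecord, final fields or Checkpoint, summary, groups);
    the summary uses the final-period maximum of the spatially averaged S as
    the reported orientation parameter.
    """
    groups = cfg.groups(oscillatory=True)
    osc = cfg.oscillation_config()
    out = run_oscillatory(
        cfg.channel_config(),
        osc,
        groups,
        cfg.numerics_config(),
        table=table,
        checkpoint=checkpoint,
        checkpoint_at=checkpoint_at,
    )
    record, final = out
    if checkpoint_at is not None:
        return record, final, None, groups
    spp = osc.steps_per_period
    s_metric = record.final_period_max_S_mean(spp)
    # LD from the half-period time-averaged S field (what a detector
    # integrating over the cycle sees), not an arbitrary-phase snapshot
    srms = s_rms_profile(final["S_half_avg"], final["z"])
    srms_avg = float(np.trapezoid(srms, final["y"]) / (final["y"][-1] - final["y"][0]))
    summary = ObservableSummary(
        S_mean=s_metric,
        S_max=float(np.max(record.S_max[-spp:])),
        S_rms_width_avg=srms_avg,
        LD_mean=float(ld_signal(srms_avg, cfg.particle.n_d, cfg.particle.eps, cfg.particle.m_w)),
        u_mean=float(np.max(np.abs(record.u_mean[-spp:]))),
    )
    return record, final, summary, groups


def summary_row(cfg: RunConfig, summary: ObservableSummary, groups, extra: dict | None = None) -> dict:
    """Flat summary row: dimensional inputs, groups, observables."""
    row = {
        "h_star": cfg.channel.h_star,
        "W_star": cfg.channel.W_star,
        "G_star": cfg.channel.G_star,
        "n_d": cfg.particle.n_d,
        "omega_star": cfg.oscillation.omega_star,
        "Phi": groups.Phi,
        "P_G": groups.P_G,
        "womersley": groups.womersley,
        "D_r": groups.D_r,
        "S_mean": summary.S_mean,
        "S_max": summary.S_max,
        "S_rms": summary.S_rms_width_avg,
        "LD": summary.LD_mean,
        "u_mean": summary.u_mean,
    }
    if extra:
        row.update(extra)
    return row
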