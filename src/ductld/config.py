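"""Structured run configuration mirroring the standard parameter table.

A run is described by one YAML file with nested sections (channel, particle,
fluid, oscillation, numerics, outputs); keys carry the same symbols and SI
units as the standard parameter set.  Unknown keys are rejected.  Dotted
``section.key=value`` override strings are accepted from the command line.
"""

from __future__ import annotations

from pathlib import Path

import yaml
from pydantic import BaseModel, ConfigDict, Field

from .materials import BOLTZMANN, FluidProperties, ParticleProperties, dimensionless_groups
from .oscillatory import OscillationConfig
from .steady import ChannelConfig, Numerics

__all__ = ["RunConfig", "load_config", "standard_config", "apply_overrides"]


class _Section(BaseModel):
    model_config = ConfigDict(extra="forbid")


class ChannelSection(_Section):
    h_star: float = 3e-4  # half-depth (m)
    W_star: float = 1e-3  # half-width (m)
    G_star: float = 4.4e3  # pressure-gradient amplitude (Pa/m)


class ParticleSection(_Section):
    a_star: float = 8e-7  # length (m)
    b_star: float = 6e-9  # width (m)
    n_d: float = 7.33e17  # number density (1/m^3)
    m_w: float = 2e7  # molecular weight (g/mol)
    eps: float = 0.38  # extinction coefficient (m^2/g)
    V_c: float | None = None  # particle-volume override (m^3)
    D_r: float | None = None  # rotary-diffusivity override (1/s)


class FluidSection(_Section):
    mu: float = 9.5e-4  # viscosity (Pa s)
    rho: float = 1e3  # density (kg/m^3)
    T: float = 295.0  # temperature (K)
    k_B: float = BOLTZMANN


class OscillationSection(_Section):
    omega_star: float = 10.0  # rad/s
    n_periods: int = 3
    steps_per_period: int = 1200


class NumericsSection(_Section):
    N: int = 10
    Y: int = 150
    Z: int = 120
    picard_tol: float = 1e-6
    picard_maxiter: int = 50
    relaxation: float = 1.0
    seed: int = 0  # only the Monte-Carlo test oracles are stochastic


class OutputsSection(_Section):
    directory: str = "runs"
    snapshot_stride: int = 0


class RunConfig(_Section):
    channel: ChannelSection = Field(default_factory=ChannelSection)
    particle: ParticleSection = Field(default_factory=ParticleSection)
    fluid: FluidSection = Field(default_factory=FluidSection)
    oscillation: OscillationSection = Field(default_factory=OscillationSection)
    numerics: NumericsSection = Field(default_factory=NumericsSection)
    outputs: OutputsSection = Field(default_factory=OutputsSection)

    # --- adapters to the solver-layer objects -----------------------------
    def channel_config(self) -> ChannelConfig:
        c = self.channel
        return ChannelConfig(h_star=c.h_star, W_star=c.W_star, G_star=c.G_star)

    def particle_properties(self) -> ParticleProperties:
        p = self.particle
        return ParticleProperties(
            a_star=p.a_star, b_star=p.b_star, m_w=p.m_w, eps=p.eps, Vc=p.V_c
        )

    def fluid_properties(self) -> FluidProperties:
        f = self.fluid
        return FluidProperties(mu=f.mu, rho=f.rho, T=f.T, k_B=f.k_B)

    def groups(self, oscillatory: bool = False):
        return dimensionless_groups(
            self.particle_properties(),
            self.fluid_properties(),
            n_d=self.particle.n_d,
            G_star=self.channel.G_star,
            h_star=self.channel.h_star,
            omega_star=self.oscillation.omega_star if oscillatory else 0.0,
            D_r_override=self.particle.D_r,
        )

    def numerics_config(self) -> Numerics:
        n = self.numerics
        return Numerics(
            N=n.N,
            Y=n.Y,
            Z=n.Z,
            picard_tol=n.picard_tol,
            picard_maxiter=n.picard_maxiter,
            relaxation=n.relaxation,
        )

    def oscillation_config(self) -> OscillationConfig:
        o = self.oscillation
        return OscillationConfig(
            omega_star=o.omega_star,
            n_periods=o.n_periods,
            steps_per_period=o.steps_per_period,
            snapshot_stride=self.outputs.snapshot_stride,
        )

    def resolved_dict(self) -> dict:
        return self.model_dump()


def standard_config(**numerics_overrides) -> RunConfig:
    """The standard parameter set, optionally with numerics overrides."""
    cfg = RunConfig()
    if numerics_overrides:
        cfg = cfg.model_copy(
            update={"numerics": cfg.numerics.model_copy(update=numerics_overrides)}
        )
    return cfg


def load_config(path: str | Path) -> RunConfig:
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    return RunConfig.model_validate(data)


def apply_overrides(cfg: RunConfig, overrides: list[str]) -> RunConfig:
    """Apply dotted ``section.key=value`` overrides to a config."""
    data = cfg.model_dump()
    for item in overrides:
        if "=" not in item:
            raise ValueError(f"override must look like section.key=value, got {item!r}")
        key, _, raw = item.partition("=")
        parts = key.strip().split(".")
        node = data
        for part in parts[:-1]:
            if part not in node:
                raise KeyError(f"unknown config section {part!r} in {key!r}")
            node = node[part]
        if parts[-1] not in node:
            raise KeyError(f"unknown config key {key!r}")
        node[parts[-1]] = yaml.safe_load(raw)
    return RunConfig.model_validate(data)
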