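"""Linear dichroism signal versus particle number density.

Sweeps the number density over three decades with the steady solver.  LD is
nominally linear in n_d, but above ~1e18 phage/m^3 the suspension thickens
the fluid and attenuates both the flow and the alignment, so the signal
grows slightly sub-linearly.
"""

from ductld import run_steady, standard_config

print("   n_d (1/m^3)    S_mean     LD (1/m)   LD / n_d (x1e-18)")
for n_d in (1e16, 1e17, 1e18, 1e19):
    cfg = standard_config(Y=40, Z=32, N=8)
    cfg = cfg.model_copy(
        update={"particle": cfg.particle.model_copy(update={"n_d": n_d})}
    )
    result, summary, groups = run_steady(cfg)
    print(
        f"  {n_d:11.1e}   {summary.S_mean:.4f}   {summary.LD_mean:10.4f}"
        f"   {summary.LD_mean / n_d * 1e18:10.4f}"
    )
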