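"""Derive the dimensionless groups for the standard M13 suspension.

Builds the standard particle/fluid description (800 nm x 6 nm fibre in
water at 295 K) and prints the derived rotary diffusivity, volume fraction,
global Peclet number and Womersley number.  These set the regime: P_G ~ 34
means shear wins over rotary diffusion near the walls (strong alignment),
while Phi ~ 1e-5 means the suspension feedback on the flow is weak.
"""

from ductld import FluidProperties, ParticleProperties, dimensionless_groups

particle = ParticleProperties(a_star=8e-7, b_star=6e-9)
fluid = FluidProperties()
groups = dimensionless_groups(
    particle, fluid, n_d=7.33e17, G_star=4.4e3, h_star=3e-4, omega_star=10.0
)

print(f"aspect ratio r        = {groups.aspect_ratio:.1f}")
print(f"rotary diffusivity    = {groups.D_r:.2f} 1/s")
print(f"volume fraction Phi   = {groups.Phi:.3e}")
print(f"global Peclet P_G     = {groups.P_G:.2f}")
print(f"Womersley alpha^2     = {groups.womersley:.3f}")
print(f"concentration n_d a^3 = {groups.nd_a3:.4f} (< 1: dilute regime)")
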