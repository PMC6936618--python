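"""Orientation of Brownian rods in homogeneous shear: S versus Peclet number.

Solves the pointwise steady Fokker-Planck problem in the spherical-harmonic
basis for a range of local Peclet numbers and prints the biaxial orientation
parameter S = <px^2> - <py^2>.  S rises from 0 (isotropy) toward a plateau
below 1: even at strong shear, Brownian rotation and tumbling keep the rods
from perfect alignment.
"""

from ductld import (
    HarmonicBasis,
    LocalShearContext,
    build_coupling_table,
    compute_moments,
    orientation_parameter_biaxial,
    solve_steady_local,
)

basis = HarmonicBasis(10)
table = build_coupling_table(basis)

print(" Pe      S")
for pe in (0.0, 0.5, 1.0, 2.0, 5.0, 10.0, 20.0, 50.0):
    state = solve_steady_local(LocalShearContext(Pe=pe), basis, table)
    s = orientation_parameter_biaxial(compute_moments(state))
    print(f"{pe:5.1f}  {s:.4f}")
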