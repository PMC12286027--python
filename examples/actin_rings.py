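"""Periodic actin rings along a branch.

The ring field h = (x^2 + y^2)/sin(k z) - 4 has circular cross-sections
wherever sin(k z) > 0; the physical wavenumber comes from the measured
~190 nm ring periodicity.
"""

import numpy as np

from neuroactin import actin_ring_field, actin_wavenumber

print("k(190 nm) =", actin_wavenumber(190.0), "rad/um  (2*pi / periodicity)")
print("k(100 nm) =", actin_wavenumber(100.0), "rad/um")

ring = actin_ring_field()  # display wavenumber 4 for visual ring spacing
print("h =", ring.h)
print("H = integral of h dz =", ring.H)
print("d/dz H - h simplifies to:", ring.exactness_residual())

z = np.pi / 8  # sin(4z) = 1: the widest ring
print(f"ring radius at z = pi/8: {2 * np.sqrt(np.sin(4 * z)):.3f} um "
      "(cross-section of the zero set of h)")
# The stack of such circles along z is the periodic membrane skeleton.
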