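"""Symbolic vector-field calculus: Jacobians, Lie brackets, iterates.

Builds the planar van der Pol and concentric actin fields, couples them
through the Lie bracket, and verifies the bracket's antisymmetry.
"""

import sympy as sp

from neuroactin import VdpParams, actin_field_2d, lie_bracket, vdp_field_2d
from neuroactin.fields import iterated_lie_bracket, jacobian

f = actin_field_2d()                  # concentric actin geometry (y^2/r, x^2/r)
g = vdp_field_2d(VdpParams(m=1.0))    # excitability field (y/r, -(x + m y (x^2-1))/r)

bracket = lie_bracket(f, g)
print("[f, g] components (the interaction field):")
for c in bracket.components:
    print("   ", sp.sstr(c))

# antisymmetry: [g, f] = -[f, g]
flipped = lie_bracket(g, f)
residual = [sp.simplify(a + b) for a, b in zip(bracket.components, flipped.components)]
print("antisymmetry residual [f,g] + [g,f]:", residual)

# a deeper iterate captures a deeper level of interaction
ad2 = iterated_lie_bracket(f, g, 2)
print("ad_f^(2) g at (1, 1, 0):", [complex(v) for v in ad2.with_params(m=1.0)(1.0, 1.0)])
print("Jacobian of f is the sensitivity of the actin flow to position:")
sp.pprint(jacobian(f))
# The bracket (and its iterates) measure how the excitability flow
# deforms the actin flow; it is the raw material of the potential model.
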