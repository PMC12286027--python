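"""Primary-cilium Shh signaling via complex incomplete gamma fields.

U = P(x+iy, z) is the accumulated signal fraction, L = Q(x+iy, z) the
remainder; they sum to one everywhere.
"""

import numpy as np

from neuroactin import incomplete_gamma_P, incomplete_gamma_Q, shh_field

print("P(1, 1) =", incomplete_gamma_P(1.0, 1.0), " (= 1 - e^-1)")
print("Q(1, 1) =", incomplete_gamma_Q(1.0, 1.0))

s = 1.5 + 0.8j
z = -2.0  # the display range runs z = -5..0
print(f"P({s}, {z}) = {incomplete_gamma_P(s, z):.6f}  (complex: principal branch of z^s)")

sig = shh_field(nz=4)
print(f"sampled {sig.U.size} grid points; max |U + L - 1| = "
      f"{sig.complementarity_residual():.2e}")
print("signal magnitude range |U|:",
      f"{np.abs(sig.U[~sig.mask]).min():.3g} .. {np.abs(sig.U[~sig.mask]).max():.3g}")
# The two magnitude surfaces (|U|, |L|) are the model's two display
# shapes of ciliary signal reception.
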