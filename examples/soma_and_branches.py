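"""Soma and branch geometry from characteristic polynomials.

The soma boundary is the zero set of det(zI - A0) at z = 1; the branch
curves come from the A1-A3 matrices the same way.
"""

import numpy as np

from neuroactin import branch_locus, characteristic_poly
from neuroactin.morphology import matrix_A0, matrix_A1

C0 = characteristic_poly(matrix_A0())
print("soma polynomial  C0 =", C0.poly)

contours = branch_locus(C0)  # z = 1 slice
pts = np.vstack(contours)
radius = np.hypot(pts[:, 0] - 1.0, pts[:, 1])
print(f"soma contour: {len(pts)} points, radius about (1,0) = "
      f"{radius.mean():.4f} +- {radius.std():.4f}  (unit circle)")

C1 = characteristic_poly(matrix_A1())
branches = branch_locus(C1)
print(f"branch polynomial C1 yields {len(branches)} curve segments")
# The single closed soma contour vs the open branch curves is the
# geometric distinction between cell body and growing neurites.
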