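"""Primary-cilium Shh signal fields via complex incomplete gamma functions.

Sonic Hedgehog (Shh) aggregates on the cell surface follow a
right-skewed, gamma-shaped distribution; the partial accumulation of the
signal over space is represented by the regularized incomplete gamma
pair evaluated at a *complex* first argument built from the in-plane
position:

    U(x, y, z) = P(x + iy, z) = gamma_lower(x + iy, z) / Gamma(x + iy)
    L(x, y, z) = Q(x + iy, z) = 1 - P(x + iy, z)

with z doubling as the third spatial coordinate and the gamma function's
second argument (the formula makes them the same variable, and so do
we).  The display range z in [-5, 0] puts the second argument on the
negative real axis, where z**s is multivalued: the principal branch of
the complex power is used throughout.

The lower incomplete gamma is evaluated by the Kummer series

    gamma(s, z) = z**s * exp(-z) * sum_{n>=0} z**n / (s (s+1) ... (s+n)),

which converges for every finite complex z and every s away from the
poles of Gamma; on the moderate |z| of the display domain it converges
in a few dozen terms.  Gamma(s) itself comes from scipy's complex gamma.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field

import numpy as np
import scipy.special

from .fields import ContractViolation, GridSpec
from .morphology import PoleError

__all__ = [
    "CiliaSignalField",
    "incomplete_gamma_P",
    "incomplete_gamma_Q",
    "lower_incomplete_gamma",
    "magnitude_surface",
    "shh_field",
]

#: Series iteration cap; reached only far outside the model's domain.
_MAX_TERMS = 2000


def _is_gamma_pole(s: complex) -> bool:
    sr = complex(s)
    return sr.imag == 0 and sr.real <= 0 and float(sr.real).is_integer()


def lower_incomplete_gamma(s: complex, z: complex) -> complex:
    """Unregularized lower incomplete gamma  gamma(s, z), complex args.

    Principal branch of z**s; gamma(s, 0) = 0.  Raises
    :class:`ArithmeticError` with the iteration count on the (practically
    unreachable for the model's domain) failure to converge.
    """
    if _is_gamma_pole(s):
        raise PoleError(f"Gamma pole at s={s}")
    s = complex(s)
    z = complex(z)
    if z == 0:
        return 0j
    # sum_{n>=0} z**n / (s (s+1) ... (s+n)), term ratio z/(s+n) -> 0
    term = 1.0 / s
    total = term
    for n in range(1, _MAX_TERMS):
        term *= z / (s + n)
        total += term
        if abs(term) < 1e-17 * max(abs(total), 1e-300):
            break
    else:
        raise ArithmeticError(
            f"incomplete gamma series did not converge in {_MAX_TERMS} terms "
            f"at s={s}, z={z}"
        )
    prefactor = np.exp(s * np.log(z) - z)  # principal log
    return complex(prefactor * total)


def incomplete_gamma_P(s: complex, z: complex) -> complex:
    """Regularized lower incomplete gamma  P(s, z) = gamma(s, z)/Gamma(s)."""
    if _is_gamma_pole(s):
        raise PoleError(f"Gamma pole at s={s}")
    return lower_incomplete_gamma(s, z) / complex(scipy.special.gamma(complex(s)))


def incomplete_gamma_Q(s: complex, z: complex) -> complex:
    """Regularized upper incomplete gamma  Q(s, z) = 1 - P(s, z)."""
    return 1.0 - incomplete_gamma_P(s, z)


@dataclass
class CiliaSignalField:
    """Sampled U (= P) and L (= Q) signal fields over an (x, y, z) lattice.

    ``U + L = 1`` holds at every unmasked point to numerical precision;
    values are complex and the magnitude is what the display surfaces
    show.  ``mask`` is True at gamma poles (x a non-positive integer on
    the real axis).
    """

    x: np.ndarray
    y: np.ndarray
    z: np.ndarray
    U: np.ndarray
    L: np.ndarray
    mask: np.ndarray
    meta: dict = dc_field(default_factory=dict)

    def complementarity_residual(self) -> float:
        res = np.abs(self.U + self.L - 1.0)
        return float(np.max(res[~self.mask])) if (~self.mask).any() else 0.0


def magnitude_surface(sig: CiliaSignalField, which: str = "U", z_index: int = 0):
    """Triangulated height surface |signal|(x, y) at one z slice.

    Returns ``(vertices, faces)`` suitable for OBJ export: vertices are
    (x, y, |U|) (or |L|), faces triangulate the lattice; cells touching a
    masked (gamma-pole) vertex are dropped.
    """
    if which not in ("U", "L"):
        raise ContractViolation(f"which must be 'U' or 'L', got {which!r}")
    arr = sig.U if which == "U" else sig.L
    mag = np.abs(arr[:, :, z_index])
    msk = sig.mask[:, :, z_index]
    nx, ny = mag.shape
    verts = np.column_stack([
        sig.x[:, :, z_index].ravel(),
        sig.y[:, :, z_index].ravel(),
        np.where(msk, 0.0, mag).ravel(),
    ])
    faces = []
    for i in range(nx - 1):
        for j in range(ny - 1):
            q = (msk[i, j], msk[i + 1, j], msk[i, j + 1], msk[i + 1, j + 1])
            if any(q):
                continue
            a = i * ny + j
            b = (i + 1) * ny + j
            c = i * ny + (j + 1)
            d = (i + 1) * ny + (j + 1)
            faces.append((a, b, d))
            faces.append((a, d, c))
    return verts, np.asarray(faces, dtype=int)


def shh_field(
    grid: GridSpec = None,
    z_range: tuple = (-5.0, 0.0),
    nz: int = 6,
) -> CiliaSignalField:
    """Sample the Shh signal pair over an in-plane grid and a z range.

    ``grid`` gives the (x, y) lattice (default x in [0.2, 3], y in
    [-1.5, 1.5], 25 points per axis, clear of the gamma poles at
    non-positive integer x on the real axis); ``z_range`` defaults to the
    display range [-5, 0].
    """
    if grid is None:
        grid = GridSpec(((0.2, 3.0, 25), (-1.5, 1.5, 25)))
    if grid.ndim != 2:
        raise ContractViolation("shh_field expects a 2D (x, y) grid")
    xs, ys = grid.points()
    zs = np.linspace(z_range[0], z_range[1], nz)
    Xg, Yg, Zg = np.meshgrid(xs, ys, zs, indexing="ij")
    U = np.empty(Xg.shape, dtype=complex)
    L = np.empty(Xg.shape, dtype=complex)
    mask = np.zeros(Xg.shape, dtype=bool)
    it = np.nditer(Xg, flags=["multi_index"])
    for _ in it:
        idx = it.multi_index
        s = complex(Xg[idx], Yg[idx])
        if _is_gamma_pole(s):
            mask[idx] = True
            U[idx] = L[idx] = np.nan
            continue
        U[idx] = incomplete_gamma_P(s, complex(Zg[idx]))
        L[idx] = 1.0 - U[idx]
    return CiliaSignalField(
        x=Xg, y=Yg, z=Zg, U=U, L=L, mask=mask,
        meta={"grid": grid.to_dict(), "z_range": list(z_range), "nz": nz},
    )
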