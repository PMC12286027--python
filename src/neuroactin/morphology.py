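"""Geometric constructions of soma, branches and actin rings.

The soma boundary and neurite branches are modelled as level sets of
characteristic polynomials det(zI - A) of symbolic 2x2 complex matrices;
ramification (the branching of curves from a common origin) is rendered
through four closed-form scalar fields; and the periodic actin rings
along axons are the level sets of a sinusoidally modulated field whose
physical wavenumber comes from the measured ~190 nm ring periodicity.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field

import numpy as np
import sympy as sp
from skimage import measure

from .fields import (
    COORDS,
    X,
    Y,
    Z,
    ContractViolation,
    GridSpec,
    SymbolicScalarField,
    evaluate_on_grid,
)

__all__ = [
    "MatrixFamily2x2",
    "CharPoly",
    "RamificationField",
    "ActinRingField",
    "mobius_apply",
    "characteristic_poly",
    "branch_locus",
    "ramification_field",
    "soma_sphere",
    "soma_sphere_field",
    "actin_wavenumber",
    "actin_ring_field",
    "matrix_A0",
    "matrix_A1",
    "matrix_A2",
    "matrix_A3",
    "PoleError",
]

I = sp.I


class PoleError(ZeroDivisionError):
    """A Moebius map was evaluated at its pole."""


@dataclass(frozen=True)
class MatrixFamily2x2:
    """A symbolic 2x2 complex matrix in the plane coordinates (x, y)."""

    entries: sp.Matrix
    label: str = ""

    def __post_init__(self):
        m = sp.Matrix(self.entries)
        if m.shape != (2, 2):
            raise ContractViolation(f"need a 2x2 matrix, got shape {m.shape}")
        object.__setattr__(self, "entries", m)

    def trace(self) -> sp.Expr:
        return self.entries.trace()

    def det(self) -> sp.Expr:
        return self.entries.det()


@dataclass(frozen=True)
class CharPoly:
    """Monic quadratic in z with coefficients that are expressions in (x, y)."""

    poly: sp.Expr
    label: str = ""

    def at(self, x, y, z) -> complex:
        return complex(self.poly.subs({X: x, Y: y, Z: z}))

    def slice_z(self, z_value) -> sp.Expr:
        return self.poly.subs(Z, z_value)


def _reciprocal_pair(diag_term: sp.Expr):
    """Diagonal entries of the branch matrices: d +- 1/(i y^2).

    The printed diagonals read as two separate reciprocals (1/x**2 plus
    1/(i*y**2)), not one combined reciprocal; this helper is the single
    place where that parse lives, so flipping it changes every matrix.
    """
    off = 1 / (I * Y**2)
    return diag_term + off, diag_term - off


def matrix_A0() -> MatrixFamily2x2:
    """Soma matrix: [[x+iy, 1], [1, x-iy]]."""
    return MatrixFamily2x2(sp.Matrix([[X + Y * I, 1], [1, X - Y * I]]), "A0")


def matrix_A1() -> MatrixFamily2x2:
    a, d = _reciprocal_pair(1 / X**2)
    return MatrixFamily2x2(sp.Matrix([[a, 1], [1, d]]), "A1")


def matrix_A2() -> MatrixFamily2x2:
    a, d = _reciprocal_pair(sp.exp(sp.sin(1 / X**2)))
    return MatrixFamily2x2(sp.Matrix([[a, 1], [1, d]]), "A2")


def matrix_A3() -> MatrixFamily2x2:
    a, d = _reciprocal_pair(sp.exp(sp.sin(1 / X**2)))
    return MatrixFamily2x2(sp.Matrix([[a, X + Y], [X + Y, d]]), "A3")


def mobius_apply(coeffs, z: complex) -> complex:
    """Apply the Moebius map (a z + b) / (c z + d).

    ``coeffs`` is a :class:`MatrixFamily2x2` with numeric entries or any
    2x2 array-like (a, b; c, d).  Raises :class:`PoleError` at c z + d = 0.
    """
    if isinstance(coeffs, MatrixFamily2x2):
        m = coeffs.entries
        a, b, c, d = (complex(m[0, 0]), complex(m[0, 1]), complex(m[1, 0]), complex(m[1, 1]))
    else:
        (a, b), (c, d) = coeffs
    den = c * z + d
    if abs(den) == 0:
        raise PoleError(f"Moebius map has a pole at z={z}")
    return (a * z + b) / den


def characteristic_poly(A: MatrixFamily2x2) -> CharPoly:
    """det(zI - A) = z**2 - tr(A) z + det(A), expanded and monic."""
    poly = sp.expand(Z**2 - A.trace() * Z + A.det())
    return CharPoly(poly, A.label)


def branch_locus(
    C: CharPoly,
    level: float = 0.0,
    grid: GridSpec = None,
    z_value: float = 1.0,
    imag_tol: float = 1e-9,
) -> list:
    """Level-set curves of Re(C) in the (x, y) plane at fixed z.

    The soma circle comes from the A0 polynomial and the branch curves
    from A1-A3, all viewed on the slice z = 1 by default.  Returns a list
    of (n, 2) arrays of (x, y) contour points; an empty list when the
    level is never crossed.  Contours are taken on the real part of the
    complex field; points whose imaginary residue exceeds ``imag_tol``
    times the real scale are not asserted real and simply participate via
    their real part.
    """
    if grid is None:
        grid = GridSpec(((-3.0, 3.0, 241), (-3.0, 3.0, 241)))
    s = SymbolicScalarField(C.slice_z(sp.nsimplify(z_value)))
    sg = evaluate_on_grid(s, grid)
    vals = np.real(sg.values).astype(float)
    vals[sg.mask] = np.nan
    xs, ys = grid.points()
    contours = measure.find_contours(vals, level)
    out = []
    for c in contours:
        px = np.interp(c[:, 0], np.arange(len(xs)), xs)
        py = np.interp(c[:, 1], np.arange(len(ys)), ys)
        out.append(np.column_stack([px, py]))
    return out


@dataclass(frozen=True)
class RamificationField:
    """A scalar branching field f(x, y) with an offset parameter c."""

    expression: sp.Expr
    which: str
    c: float
    singular_locus: str = ""

    def as_scalar_field(self) -> SymbolicScalarField:
        return SymbolicScalarField(self.expression)

    def contours(self, level: float = 0.0, grid: GridSpec = None) -> list:
        cp = CharPoly(self.expression + 0 * Z, self.which)
        return branch_locus(cp, level=level, grid=grid, z_value=0.0)


_RAMIFICATION_BUILDERS = {
    # four printed branching fields; c is the contour offset
    "f1": lambda c: (
        c - Y**3 / X**3 + X * (X + 1) * (X - 2) * (X + 2) * (X - 3),
        "x = 0",
    ),
    "f2": lambda c: (
        c - Y**3 / X**2 + X * (X - 1) ** 3 * (X + 1) ** 3 * (X + 2) ** 3 * (X + 3) ** 3,
        "x = 0",
    ),
    "f3": lambda c: (
        c + sp.exp(X) * (X - 1) ** 3 * (X + 1) ** 3 * (X + 2) ** 3 * (X + 3) ** 3
        - sp.exp(Y**3),
        "",
    ),
    "f4": lambda c: ((X - Y) / sp.Float(c) ** sp.Rational(2, 3), ""),
}


def ramification_field(which: str, c: float = 1.0) -> RamificationField:
    """One of the four closed-form branching fields f1-f4.

    ``c`` shifts the contour level family; for f4 it appears as c**(2/3)
    in the denominator, so c = 0 is rejected as a singular parameter.
    """
    if which not in _RAMIFICATION_BUILDERS:
        raise ContractViolation(f"unknown ramification field {which!r}; use f1..f4")
    if which == "f4" and c == 0:
        raise ContractViolation("f4 degenerates at c = 0 (division by c**(2/3))")
    expr, locus = _RAMIFICATION_BUILDERS[which](c)
    return RamificationField(sp.sympify(expr), which, float(c), locus)


#: Implicit soma surface (x**2 + y**2)**2 + z**2 - 1; the printed product
#: of the four complex boundary points (x +- iy)(-x +- iy) collapses to
#: (x**2 + y**2)**2.
_SOMA_EXPR = (X**2 + Y**2) ** 2 + Z**2 - 1


def soma_sphere_field() -> SymbolicScalarField:
    return SymbolicScalarField(_SOMA_EXPR)


def soma_sphere(grid: GridSpec = None):
    """Sample the implicit soma surface and extract its zero isosurface.

    Returns ``(scalar_grid, vertices, faces)``; vertices/faces triangulate
    the zero set via marching cubes and can be written out as OBJ.
    """
    if grid is None:
        grid = GridSpec(((-1.3, 1.3, 49), (-1.3, 1.3, 49), (-1.3, 1.3, 49)))
    sg = evaluate_on_grid(soma_sphere_field(), grid)
    vals = np.real(sg.values).astype(float)
    xs, ys, zs = grid.points()
    verts, faces, _, _ = measure.marching_cubes(vals, level=0.0)
    # index space -> physical coordinates
    verts = np.column_stack(
        [
            np.interp(verts[:, 0], np.arange(len(xs)), xs),
            np.interp(verts[:, 1], np.arange(len(ys)), ys),
            np.interp(verts[:, 2], np.arange(len(zs)), zs),
        ]
    )
    return sg, verts, faces


def actin_wavenumber(lambda_nm: float) -> float:
    """Wavenumber k = 2 pi / lambda in rad/um, to 3 significant figures.

    ``lambda_nm`` is the actin-ring periodicity in nanometres (about
    190 nm along axons); the conversion nm -> um happens here.
    """
    if lambda_nm <= 0:
        raise ContractViolation(f"periodicity must be positive, got {lambda_nm}")
    k = 2.0 * np.pi / (lambda_nm * 1e-3)
    return float(f"{k:.3g}")


@dataclass(frozen=True)
class ActinRingField:
    """The ring field h(x,y,z) and its z-antiderivative H(x,y,z).

    ``h = (x**2 + y**2)/sin(k z) - 4``: its zero set at fixed z is a
    circle of radius 2*sqrt(sin(k z)) wherever sin(k z) > 0, which is the
    ring cross-section.  ``H`` is recomputed symbolically (not transcribed)
    and satisfies dH/dz = h on the common domain.
    """

    h: sp.Expr
    H: sp.Expr
    k_display: float
    wavenumber_rad_per_um: float = dc_field(default=float("nan"))
    periodicity_nm: float = dc_field(default=float("nan"))

    def exactness_residual(self) -> sp.Expr:
        return sp.simplify(sp.diff(self.H, Z) - self.h)


def actin_ring_field(k_display: float = 4, lambda_nm: float = 190.0) -> ActinRingField:
    """Build the actin-ring field with display wavenumber ``k_display``.

    The default display value 4 in sin(4 z) keeps the rings visually
    separated on unit-scale plots; the physically scaled wavenumber
    (2 pi / 190 nm ~= 33.1 rad/um) is carried alongside and can be passed
    as ``k_display`` instead.
    """
    k = sp.nsimplify(k_display)
    if sp.simplify(sp.sin(k * Z)) == 0:
        raise ContractViolation("sin(k z) is identically zero for this k")
    h = X**2 / sp.sin(k * Z) + Y**2 / sp.sin(k * Z) - 4
    H = sp.integrate(h, Z)
    return ActinRingField(
        h=h,
        H=H,
        k_display=float(k_display),
        wavenumber_rad_per_um=actin_wavenumber(lambda_nm),
        periodicity_nm=float(lambda_nm),
    )
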