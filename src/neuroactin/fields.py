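"""Exact symbolic calculus on scalar and vector fields.

This module is the computational substrate for the whole package: vector
fields are stored as closed-form :mod:`sympy` expressions in the spatial
coordinates ``x, y, z`` (micrometres), and every differential operator
(Jacobian, Lie bracket and its iterates, gradient, divergence, curl,
vector Laplacian) is carried out exactly before anything is sampled on a
grid.  Numeric evaluation happens only at the very end, through
:func:`evaluate_on_grid`, which masks points near expression
singularities instead of letting NaNs propagate.

All arithmetic is complex-capable: several of the geometric constructions
downstream contain the imaginary unit, and real traces are obtained by an
explicit real-part extraction at documented call sites only.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Union

import numpy as np
import sympy as sp

__all__ = [
    "COORDS",
    "X",
    "Y",
    "Z",
    "ContractViolation",
    "UnboundParameterError",
    "SymbolicScalarField",
    "SymbolicVectorField",
    "GridSpec",
    "ScalarGrid",
    "jacobian",
    "lie_bracket",
    "iterated_lie_bracket",
    "gradient",
    "divergence",
    "curl",
    "vector_laplacian",
    "evaluate_on_grid",
    "field_to_json",
    "field_from_json",
]

#: Spatial coordinates, in micrometres.
X, Y, Z = COORDS = sp.symbols("x y z")

#: Default tolerance on a denominator's magnitude below which a lattice
#: point is treated as singular and masked.
SINGULAR_TOL = 1e-9

#: Default cap on Lie-bracket iteration depth; expression size grows
#: quickly with depth and nothing in the model needs more.
MAX_BRACKET_DEPTH = 4


class ContractViolation(ValueError):
    """An argument violates a documented precondition."""


class UnboundParameterError(ContractViolation):
    """A field still has free parameters at numeric-evaluation time."""


def _simplify(expr: sp.Expr) -> sp.Expr:
    """Canonical rational simplification used after each bracket step.

    ``together`` + ``cancel`` keeps rational structure compact without the
    cost (and instability) of full ``simplify``; it is what bounds
    expression growth across bracket iterations.
    """
    return sp.cancel(sp.together(expr))


def _check_symbols(exprs: Iterable[sp.Expr], params: Mapping[str, object]) -> None:
    allowed = set(COORDS) | {sp.Symbol(name) for name in params}
    for expr in exprs:
        stray = expr.free_symbols - allowed
        if stray:
            raise ContractViolation(
                f"free symbols {sorted(map(str, stray))} are neither coordinates "
                f"nor declared parameters {sorted(params)}"
            )


@dataclass(frozen=True)
class SymbolicScalarField:
    """A scalar field given in closed form.

    Parameters
    ----------
    expression
        A sympy expression (or string) in ``x, y, z`` plus declared params.
    params
        Name -> value map for non-coordinate symbols.  Values may be left
        symbolic until evaluation, but must be bound before sampling.
    """

    expression: sp.Expr
    params: Mapping[str, object] = field(default_factory=dict)

    def __post_init__(self):
        object.__setattr__(self, "expression", sp.sympify(self.expression))
        object.__setattr__(self, "params", dict(self.params))
        _check_symbols([self.expression], self.params)

    def bound_expression(self) -> sp.Expr:
        """Expression with every numeric parameter substituted in."""
        subs = {sp.Symbol(k): v for k, v in self.params.items() if v is not None}
        return self.expression.subs(subs)

    def __call__(self, x, y=0, z=0):
        expr = self.bound_expression()
        if expr.free_symbols - set(COORDS):
            raise UnboundParameterError(f"unbound parameters in {expr}")
        return complex(expr.subs({X: x, Y: y, Z: z}))


@dataclass(frozen=True)
class SymbolicVectorField:
    """A 2- or 3-component vector field with closed-form components.

    Two-component fields live in the ``(x, y)`` plane; before any 3D
    operator is applied they are lifted to three components with an
    identically zero third component (see :meth:`lift`), which makes the
    3D gradient/curl machinery well defined for planar fields.
    """

    components: tuple
    params: Mapping[str, object] = field(default_factory=dict)

    def __post_init__(self):
        comps = tuple(sp.sympify(c) for c in self.components)
        if len(comps) not in (2, 3):
            raise ContractViolation(f"need 2 or 3 components, got {len(comps)}")
        object.__setattr__(self, "components", comps)
        object.__setattr__(self, "params", dict(self.params))
        _check_symbols(comps, self.params)

    @property
    def ncomp(self) -> int:
        return len(self.components)

    def lift(self) -> "SymbolicVectorField":
        """Return the 3-component version (zero third component if 2D)."""
        if self.ncomp == 3:
            return self
        return SymbolicVectorField(self.components + (sp.Integer(0),), self.params)

    def bound_components(self) -> tuple:
        subs = {sp.Symbol(k): v for k, v in self.params.items() if v is not None}
        return tuple(c.subs(subs) for c in self.components)

    def with_params(self, **updates) -> "SymbolicVectorField":
        params = {**self.params, **updates}
        return SymbolicVectorField(self.components, params)

    def simplify(self) -> "SymbolicVectorField":
        return SymbolicVectorField(
            tuple(_simplify(c) for c in self.components), self.params
        )

    def __call__(self, x, y=0, z=0):
        comps = self.bound_components()
        for c in comps:
            if c.free_symbols - set(COORDS):
                raise UnboundParameterError(f"unbound parameters in {c}")
        return tuple(complex(c.subs({X: x, Y: y, Z: z})) for c in comps)


def _merged_params(*fields) -> dict:
    params: dict = {}
    for f in fields:
        for k, v in f.params.items():
            if k in params and params[k] is not None and v is not None and params[k] != v:
                raise ContractViolation(f"conflicting values for parameter {k!r}")
            params.setdefault(k, v)
            if params[k] is None:
                params[k] = v
    return params


def jacobian(field: SymbolicVectorField) -> sp.Matrix:
    """Jacobian matrix, entry (i, j) = d component_i / d coordinate_j.

    Two-component fields are lifted to three components first, so the
    result is always 3x3 over ``(x, y, z)``.
    """
    lifted = field.lift()
    return sp.Matrix(3, 3, lambda i, j: sp.diff(lifted.components[i], COORDS[j]))


def lie_bracket(f: SymbolicVectorField, g: SymbolicVectorField) -> SymbolicVectorField:
    """Commutator [f, g] = Jg.f - Jf.g of two vector fields.

    The bracket measures how the flow of one field deforms the other; it
    is the interaction operator coupling the excitability field and the
    actin-geometry field in the membrane-potential pipeline.
    """
    fl, gl = f.lift(), g.lift()
    fv = sp.Matrix(fl.components)
    gv = sp.Matrix(gl.components)
    out = jacobian(gl) * fv - jacobian(fl) * gv
    params = _merged_params(f, g)
    return SymbolicVectorField(tuple(_simplify(e) for e in out), params)


def iterated_lie_bracket(
    f: SymbolicVectorField,
    g: SymbolicVectorField,
    k: int,
    max_depth: int = MAX_BRACKET_DEPTH,
) -> SymbolicVectorField:
    """ad_f^(k) g, i.e. [f, [f, ... [f, g]]] nested k deep.

    ``k`` must be >= 1; the base case ad_f^(1) g is the plain bracket.
    Depth is capped (default 4) because expression size grows rapidly and
    the model never uses deep iterates.
    """
    if not isinstance(k, (int, np.integer)) or k < 1:
        raise ContractViolation(f"iteration depth k must be a positive integer, got {k}")
    if k > max_depth:
        raise ContractViolation(f"k={k} exceeds the depth cap {max_depth}")
    result = lie_bracket(f, g)
    for _ in range(k - 1):
        result = lie_bracket(f, result)
    return result


def gradient(s: SymbolicScalarField) -> SymbolicVectorField:
    """Gradient of a scalar field (components ds/dx, ds/dy, ds/dz).

    Note the electric field used downstream is the *negated* gradient;
    negation happens at the call site so this stays the plain operator.
    """
    comps = tuple(sp.diff(s.expression, c) for c in COORDS)
    return SymbolicVectorField(comps, s.params)


def divergence(F: SymbolicVectorField) -> SymbolicScalarField:
    lifted = F.lift()
    expr = sum(sp.diff(lifted.components[i], COORDS[i]) for i in range(3))
    return SymbolicScalarField(expr, F.params)


def curl(F: SymbolicVectorField) -> SymbolicVectorField:
    c = F.lift().components
    comps = (
        sp.diff(c[2], Y) - sp.diff(c[1], Z),
        sp.diff(c[0], Z) - sp.diff(c[2], X),
        sp.diff(c[1], X) - sp.diff(c[0], Y),
    )
    return SymbolicVectorField(comps, F.params)


def vector_laplacian(F: SymbolicVectorField) -> SymbolicVectorField:
    """grad(div F) - curl(curl F); requires an explicitly 3-component field.

    For smooth fields this equals the componentwise Laplacian, which the
    tests exploit as an independent check.
    """
    if F.ncomp != 3:
        raise ContractViolation(
            "vector_laplacian needs a 3-component field; lift() 2D fields first"
        )
    g = gradient(divergence(F))
    cc = curl(curl(F))
    comps = tuple(
        _simplify(g.components[i] - cc.components[i]) for i in range(3)
    )
    return SymbolicVectorField(comps, F.params)


# ---------------------------------------------------------------------------
# grids

@dataclass(frozen=True)
class GridSpec:
    """Rectilinear evaluation lattice; per-axis (min, max, count), in um."""

    axes: tuple

    def __post_init__(self):
        axes = tuple(tuple(a) for a in self.axes)
        for lo, hi, n in axes:
            if n < 2:
                raise ContractViolation(f"axis count must be >= 2, got {n}")
            if not lo < hi:
                raise ContractViolation(f"axis must have min < max, got ({lo}, {hi})")
        object.__setattr__(self, "axes", axes)

    @property
    def ndim(self) -> int:
        return len(self.axes)

    def points(self) -> tuple:
        return tuple(np.linspace(lo, hi, int(n)) for lo, hi, n in self.axes)

    def mesh(self) -> tuple:
        return tuple(np.meshgrid(*self.points(), indexing="ij"))

    def to_dict(self) -> dict:
        return {"axes": [list(a) for a in self.axes]}


@dataclass
class ScalarGrid:
    """Samples of one scalar quantity on a :class:`GridSpec`.

    ``mask`` is True at lattice points excluded as singular (denominator
    within tolerance of zero, or a non-finite sample); unmasked values are
    guaranteed finite.
    """

    spec: GridSpec
    values: np.ndarray
    mask: np.ndarray

    def finite_values(self) -> np.ndarray:
        return self.values[~self.mask]


def _denominators(expr: sp.Expr) -> list:
    """Denominators whose zeros make ``expr`` singular."""
    dens = []
    num, den = sp.fraction(sp.together(expr))
    if not den.is_number:
        dens.append(den)
    # catch inner denominators that together() may fold away (e.g. tan/log args)
    for pw in expr.atoms(sp.Pow):
        if pw.exp.is_number and pw.exp.is_negative and not pw.base.is_number:
            dens.append(pw.base)
    return dens


def evaluate_on_grid(
    obj: Union[SymbolicScalarField, SymbolicVectorField],
    grid: GridSpec,
    singular_tol: float = SINGULAR_TOL,
):
    """Sample a field on a lattice with singularity masking.

    Points where any denominator magnitude falls below ``singular_tol``
    are masked rather than evaluated, and any residual non-finite sample
    is masked too.  Returns a :class:`ScalarGrid` for scalar input or a
    tuple of them (one per component) for vector input.
    """
    if isinstance(obj, SymbolicVectorField):
        comps = obj.bound_components()
        return tuple(
            _eval_expr_on_grid(c, grid, singular_tol) for c in comps
        )
    expr = obj.bound_expression()
    return _eval_expr_on_grid(expr, grid, singular_tol)


def _eval_expr_on_grid(expr: sp.Expr, grid: GridSpec, tol: float) -> ScalarGrid:
    if expr.free_symbols - set(COORDS):
        raise UnboundParameterError(
            f"cannot evaluate {expr}: unbound parameters "
            f"{sorted(map(str, expr.free_symbols - set(COORDS)))}"
        )
    mesh = grid.mesh()
    coords = COORDS[: grid.ndim]
    pad = [np.zeros_like(mesh[0]) for _ in range(3 - grid.ndim)]
    args = list(mesh) + pad

    mask = np.zeros(mesh[0].shape, dtype=bool)
    for den in _denominators(expr):
        fn = sp.lambdify(COORDS, den, modules="numpy")
        with np.errstate(all="ignore"):
            dval = np.asarray(fn(*args), dtype=complex)
        mask |= ~np.isfinite(dval) | (np.abs(dval) < tol)

    fn = sp.lambdify(COORDS, expr, modules="numpy")
    with np.errstate(all="ignore"):
        raw = fn(*args)
    values = np.broadcast_to(np.asarray(raw, dtype=complex), mesh[0].shape).copy()
    values[mask] = np.nan
    mask = mask | ~np.isfinite(values)
    values[mask] = np.nan
    return ScalarGrid(grid, values, mask)


# ---------------------------------------------------------------------------
# serialization

def _parse_expr(text: str) -> sp.Expr:
    return sp.sympify(text.replace("^", "**"))


def field_to_json(obj: Union[SymbolicScalarField, SymbolicVectorField]) -> str:
    """Serialize a field to the package's JSON document form.

    Expressions are written in plain infix with ``**`` for powers; reads
    accept ``^`` as well.
    """
    params = {k: (str(v) if isinstance(v, sp.Expr) else v) for k, v in obj.params.items()}
    if isinstance(obj, SymbolicVectorField):
        doc = {"components": [sp.sstr(c) for c in obj.components], "params": params}
    else:
        doc = {"expression": sp.sstr(obj.expression), "params": params}
    return json.dumps(doc, indent=2, sort_keys=True)


def field_from_json(text: str):
    doc = json.loads(text)
    params = doc.get("params", {})
    if "components" in doc:
        return SymbolicVectorField(
            tuple(_parse_expr(c) for c in doc["components"]), params
        )
    return SymbolicScalarField(_parse_expr(doc["expression"]), params)
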