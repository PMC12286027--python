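"""Growth of an organoid-like N-neuron network from guidance fields.

A single model neuron is promoted to a deterministic cluster: an
interaction scalar V (actin filaments coupled to the van der Pol
oscillator), an elliptic-curve-style guidance polynomial P(x, y, z)
introducing curvature, directional fields F = grad-component(P) + V,
their coordinate antiderivatives G (accumulated path information), and a
Lagrange/Vandermonde placement step that turns the index nodes i = 1..N
into 3D neuron positions.  There is no randomness anywhere: identical
parameters give bitwise-identical layouts and traces.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field
from functools import lru_cache

import numpy as np
import sympy as sp

from .electrophysiology import PotentialTrace, VdpParams, trace_along_points
from .fields import COORDS, X, Y, Z, ContractViolation, SymbolicScalarField

__all__ = [
    "GuidanceParams",
    "NetworkLayout",
    "interaction_scalar_V",
    "guidance_polynomial",
    "guidance_fields",
    "place_nodes",
    "network_potential",
    "placement_sum",
]

_A, _B, _MBAR = sp.symbols("a b mbar")


@dataclass(frozen=True)
class GuidanceParams:
    """Elliptic-map coefficients a, b, interaction weight mbar, neuron count N."""

    a: float = 1.0
    b: float = 1.0
    mbar: float = 1.0
    N: int = 4

    def __post_init__(self):
        if not (isinstance(self.N, (int, np.integer)) and self.N >= 1):
            raise ContractViolation(f"neuron count N must be an integer >= 1, got {self.N}")


@dataclass
class NetworkLayout:
    """N node positions (um) plus the guidance metadata that produced them.

    ``interpolants`` holds, per axis, the Lagrange polynomial
    coefficients (ascending powers) obtained through the Vandermonde
    inverse; ``path_samples`` are the interpolant values on a dense
    sample of the index interval.
    """

    positions: np.ndarray
    params: GuidanceParams
    interpolants: dict
    path_samples: dict
    meta: dict = dc_field(default_factory=dict)

    @property
    def n_nodes(self) -> int:
        return len(self.positions)


def interaction_scalar_V(params: GuidanceParams = GuidanceParams()) -> SymbolicScalarField:
    """Interaction scalar V coupling actin filaments and the oscillator.

    Adopted parse (strategy isolated here):

        V = y/(z r) - x/(z r) + y*mbar/(z r) - x**2 y mbar/(z**3 r),
        r = sqrt(x**2 + y**2 + z**2),

    singular on z = 0 and at the origin, both masked on evaluation.
    """
    r = sp.sqrt(X**2 + Y**2 + Z**2)
    expr = (
        Y / (Z * r)
        - X / (Z * r)
        + Y * _MBAR / (Z * r)
        - X**2 * Y * _MBAR / (Z**3 * r)
    )
    return SymbolicScalarField(expr, {"mbar": params.mbar})


def guidance_polynomial(params: GuidanceParams = GuidanceParams()) -> SymbolicScalarField:
    """Guidance map P(x,y,z) = -x**3 z**3 - a x**2 z + x + y**2 z**2 - b.

    On the slice z = 1, P = 0 rearranges to the elliptic-curve-like form
    y**2 = x**3 + a x**2 - x + b, which is what lends the growth its
    curvature.
    """
    expr = -X**3 * Z**3 - _A * X**2 * Z + X + Y**2 * Z**2 - _B
    return SymbolicScalarField(expr, {"a": params.a, "b": params.b})


def guidance_fields(P: SymbolicScalarField = None, V: SymbolicScalarField = None):
    """Directional fields F and their accumulated antiderivatives G.

    F_c = dP/dc + V for c in (x, y, z); G_c is the symbolic
    antiderivative of F_c in its own coordinate, so dG_c/dc = F_c
    exactly.  Returns ``(F, G)`` as coordinate-keyed dicts of
    :class:`SymbolicScalarField`.  If sympy cannot find a closed form
    the unevaluated integral is kept and flagged in the field's params
    (numeric path integration then happens at evaluation time).
    """
    P = P or guidance_polynomial()
    V = V or interaction_scalar_V()
    params = {**P.params, **V.params}
    # integrate on positive-assumption symbols: sympy then avoids the
    # polar_lift/Abs branch bookkeeping that breaks exactness off the
    # positive octant (where the placement nodes q_i = (i,i,i) live)
    pos = sp.symbols("x_ y_ z_", positive=True)
    fwd = dict(zip(COORDS, pos))
    back = dict(zip(pos, COORDS))
    F, G = {}, {}
    for c, cpos in zip(COORDS, pos):
        f_expr = sp.diff(P.expression, c) + V.expression
        g_expr = sp.integrate(f_expr.subs(fwd), cpos).subs(back)
        flags = dict(params)
        if g_expr.has(sp.Integral):
            flags["numeric_fallback"] = True
        F[str(c)] = SymbolicScalarField(f_expr, params)
        G[str(c)] = SymbolicScalarField(g_expr, flags)
    return F, G


def antiderivative_exactness_residuals(F: dict, G: dict) -> dict:
    """Symbolic residuals dG_c/dc - F_c, simplified on the positive octant.

    All three residuals reduce to zero for the model's guidance fields;
    ``radsimp`` is needed to fold the radical products sympy leaves
    behind.
    """
    pos = sp.symbols("x_ y_ z_", positive=True)
    fwd = dict(zip(COORDS, pos))
    out = {}
    for c, name in zip(COORDS, "xyz"):
        resid = (sp.diff(G[name].expression, c) - F[name].expression).subs(fwd)
        out[name] = sp.simplify(sp.radsimp(resid))
    return out


@lru_cache(maxsize=8)
def _guidance_for(a: float, b: float, mbar: float):
    """Cached guidance fields: the symbolic integration is the slow step."""
    p = GuidanceParams(a=a, b=b, mbar=mbar)
    return guidance_fields(guidance_polynomial(p), interaction_scalar_V(p))


def placement_sum(axis: str, F: dict, G: dict, nodes: np.ndarray) -> sp.Expr:
    """The printed per-axis placement sum L_axis(x, y, z).

    The printed argument of the logarithm, ``ln(-e^(i-x)(i-y)(i-z)(i-x))``
    for the x axis (raw string kept verbatim here because the typography
    is corrupt), is read as the principal log of the negated product of
    the exponential decay term exp((i-x)+(i-y)+(i-z)) and the
    axis-specific linear factor (i - axis coordinate):

        L_ax = sum_i [ G_ax(q_i) * i + ax + F_ax(q_i) * Log(-exp((i-x)+(i-y)+(i-z)) * (i - ax)) ]

    where q_i is the i-th interpolation node.  At a point where the
    axis factor vanishes exactly (the node's own abscissa) the log term
    is omitted — the removable-node convention, mirroring how a Lagrange
    basis excludes its own node.  The real part is taken only at the very
    end, by the caller.
    """
    ax_sym = {"x": X, "y": Y, "z": Z}[axis]
    total = sp.Integer(0)
    for i, q in enumerate(nodes, start=1):
        Fi = F[axis].bound_expression().subs({X: q[0], Y: q[1], Z: q[2]})
        Gi = G[axis].bound_expression().subs({X: q[0], Y: q[1], Z: q[2]})
        decay = sp.exp((i - X) + (i - Y) + (i - Z))
        total += Gi * i + ax_sym + Fi * sp.log(-decay * (i - ax_sym))
    return total


def _axis_values(L_expr: sp.Expr, point) -> complex:
    """Evaluate a placement sum at a point, dropping vanishing-log terms."""
    subs = {X: point[0], Y: point[1], Z: point[2]}
    total = 0j
    for term in sp.Add.make_args(sp.expand(L_expr, deep=False)):
        val = term.subs(subs)
        if val.has(sp.zoo) or val.has(sp.nan) or val.has(sp.log(0)):
            continue  # removable node term: its axis factor vanished
        v = complex(sp.N(val))
        if not (np.isfinite(v.real) and np.isfinite(v.imag)):
            continue
        total += v
    return total


def place_nodes(params: GuidanceParams = GuidanceParams(), sample_points=None) -> NetworkLayout:
    """Deterministic node placement for an N-neuron network.

    ``sample_points`` are the N interpolation nodes (default q_i =
    (i, i, i), i = 1..N — the node index doubles as the interpolation
    abscissa).  Per axis, a Vandermonde system over the abscissae is
    inverted to obtain the Lagrange interpolant of the accumulated
    guidance values G, and the printed placement sums L_x, L_y, L_z are
    evaluated at each node (real part) to give the 3D positions.
    """
    N = params.N
    if sample_points is None:
        sample_points = np.array([[float(i)] * 3 for i in range(1, N + 1)])
    else:
        sample_points = np.asarray(sample_points, dtype=float)
        if len(sample_points) != N:
            raise ContractViolation(
                f"expected {N} sample points, got {len(sample_points)}"
            )
    F, G = _guidance_for(params.a, params.b, params.mbar)

    interpolants, path_samples = {}, {}
    dense = np.linspace(1.0, max(float(N), 1.0 + 1e-9), 64)
    for k, axis in enumerate("xyz"):
        t = sample_points[:, k]
        for i in range(N):
            for j in range(i + 1, N):
                if t[i] == t[j]:
                    raise np.linalg.LinAlgError(
                        f"Vandermonde matrix singular on axis {axis}: sample points "
                        f"{i + 1} and {j + 1} share abscissa {t[i]}"
                    )
        W = np.vander(t, increasing=True)
        vals = np.array(
            [
                complex(sp.N(G[axis].bound_expression().subs({X: q[0], Y: q[1], Z: q[2]})))
                for q in sample_points
            ]
        )
        coeff = np.linalg.solve(W, vals)
        interpolants[axis] = coeff
        path_samples[axis] = np.polyval(coeff[::-1], dense).real

    positions = np.empty((N, 3))
    for k, axis in enumerate("xyz"):
        L = placement_sum(axis, F, G, sample_points)
        for j, q in enumerate(sample_points):
            positions[j, k] = _axis_values(L, q).real
    return NetworkLayout(
        positions=positions,
        params=params,
        interpolants=interpolants,
        path_samples={"t": dense, **path_samples},
        meta={"sample_points": sample_points.tolist()},
    )


def network_potential(
    layout: NetworkLayout,
    p: VdpParams = VdpParams(1.0),
    variant: str = "gradient",
    t: int = 1,
    samples_per_edge: int = 120,
) -> PotentialTrace:
    """Membrane-potential trace along the network's node path.

    The Lie-bracket pipeline is evaluated along the piecewise-linear path
    visiting the node positions in index order (a single node gets a
    short segment around itself).  Local potential maxima along the path
    are the network's spatially localized activity peaks.
    """
    if layout.n_nodes == 0:
        raise ContractViolation("layout has no nodes")
    pos = np.asarray(layout.positions, dtype=float)
    if len(pos) == 1:
        a = pos[0] - np.array([0.5, 0.0, 0.0])
        b = pos[0] + np.array([0.5, 0.0, 0.0])
        pos = np.vstack([a, b])
    pts = []
    for a, b in zip(pos[:-1], pos[1:]):
        seg = np.linspace(a, b, samples_per_edge, endpoint=False)
        pts.append(seg)
    pts.append(pos[-1:])
    points = np.vstack(pts)
    trace = trace_along_points(points, p, t=t, variant=variant)
    trace.meta.update({"N": layout.n_nodes, "network": True})
    return trace
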