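"""Membrane potential from interacting excitability and actin vector fields.

The core pipeline couples two static vector fields — a van der Pol
phase-plane field standing in for neuronal excitability and a concentric
field encoding the circular actin geometry beneath the membrane — through
the (iterated) Lie bracket.  The bracket result Z yields a scalar
potential V = Z1 + Z2, an electric field EF = -grad V (or, as a
comparative variant, the vector Laplacian of Z), the field magnitude
EFT = |EF|, an activation-like quantity Dirac = -EFT*m (the exact
simplification of log(exp(-EFT*m))), and finally a membrane potential in
millivolts via the Nernst decade prefactor:

    MB = 61.5 * Re(Log(Dirac)) = 61.5 * ln(EFT * m)   for EFT*m > 0.

Log of the negative Dirac is taken as the principal complex logarithm
with the real part extracted — the only reading that yields a real
mV-scale trace — and that branch choice is isolated here.

Units follow the model's ledger: coordinates in um, potentials in mV, the
damping parameter m dimensionless and swept over [0.1, 4].
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field
from functools import lru_cache

import numpy as np
import scipy.integrate
import sympy as sp

from .fields import (
    COORDS,
    X,
    Y,
    Z,
    ContractViolation,
    GridSpec,
    SymbolicScalarField,
    SymbolicVectorField,
    gradient,
    iterated_lie_bracket,
    vector_laplacian,
)

__all__ = [
    "NERNST_SLOPE_MV",
    "RT_OVER_F_MV",
    "VdpParams",
    "PathSpec",
    "PotentialTrace",
    "vdp_field_2d",
    "actin_field_2d",
    "vdp_field_3d",
    "actin_field_3d",
    "membrane_potential_pipeline",
    "sweep_membrane_potential",
    "trace_along_points",
    "default_grid",
    "default_path",
    "default_m_sweep",
    "nernst",
    "goldman_factor",
]

#: RT/F at body temperature, in mV.
RT_OVER_F_MV = 26.7
#: Nernst decade slope ln(10) * RT/F = 2.3026 * 26.7 ~= 61.5 mV.
NERNST_SLOPE_MV = 2.3026 * RT_OVER_F_MV

_M = sp.Symbol("m")
_S = sp.Symbol("s")


@dataclass(frozen=True)
class VdpParams:
    """Dimensionless van der Pol damping parameter; swept over [0.1, 4]."""

    m: float = 1.0

    def __post_init__(self):
        if self.m <= 0:
            raise ContractViolation(f"damping m must be positive, got {self.m}")


@dataclass(frozen=True)
class PathSpec:
    """A parametric evaluation path (x(s), y(s), z(s)), s in [lo, hi].

    The default is the diagonal line (s, s, 1) with s in [0.1, 2] and 400
    samples; it stays clear of the z = 0 and r = 0 singular loci of the
    3D fields.
    """

    x: sp.Expr = _S
    y: sp.Expr = _S
    z: sp.Expr = sp.Integer(1)
    s_range: tuple = (0.1, 2.0)
    n: int = 400

    def parameter_values(self) -> np.ndarray:
        return np.linspace(self.s_range[0], self.s_range[1], self.n)

    def points(self) -> np.ndarray:
        ss = self.parameter_values()
        fns = [sp.lambdify(_S, sp.sympify(c), "numpy") for c in (self.x, self.y, self.z)]
        cols = [np.broadcast_to(np.asarray(f(ss), dtype=float), ss.shape) for f in fns]
        return np.column_stack(cols)

    def to_dict(self) -> dict:
        return {
            "x": str(self.x),
            "y": str(self.y),
            "z": str(self.z),
            "s_range": list(self.s_range),
            "n": self.n,
        }


@dataclass
class PotentialTrace:
    """An ordered (path parameter, membrane potential mV) trace.

    ``mask`` is True where the potential is undefined (EFT*m <= 0, field
    singularities, or log of zero); unmasked samples are finite mV.
    """

    s: np.ndarray
    mb_mV: np.ndarray
    mask: np.ndarray
    m: float
    variant: str
    meta: dict = dc_field(default_factory=dict)

    def finite(self) -> np.ndarray:
        return self.mb_mV[~self.mask]

    @property
    def max_mV(self) -> float:
        return float(np.max(self.finite()))

    @property
    def min_mV(self) -> float:
        return float(np.min(self.finite()))

    def local_maxima(self) -> np.ndarray:
        """Indices of local maxima of the trace.

        Endpoints count (a monotone trace has one maximum at its high
        end) and plateaus are counted once; masked samples never qualify.
        """
        mb = np.where(self.mask, -np.inf, self.mb_mV)
        n = len(mb)
        idx = []
        for i in range(n):
            if not np.isfinite(mb[i]):
                continue
            left = mb[i - 1] if i > 0 else -np.inf
            right = mb[i + 1] if i < n - 1 else -np.inf
            if (mb[i] >= left and mb[i] > right) or (mb[i] > left and mb[i] >= right):
                idx.append(i)
        return np.array(idx, dtype=int)


def default_grid() -> GridSpec:
    """Default export lattice: x, y in [-2, 2], z in [0.5, 2], 41 per axis."""
    return GridSpec(((-2.0, 2.0, 41), (-2.0, 2.0, 41), (0.5, 2.0, 41)))


def default_path() -> PathSpec:
    return PathSpec()


def default_m_sweep() -> np.ndarray:
    """The damping sweep m = 0.1 .. 4, realized as 40 uniform values."""
    return np.linspace(0.1, 4.0, 40)


# ---------------------------------------------------------------------------
# the coupled vector fields

def vdp_field_2d(p: VdpParams = None) -> SymbolicVectorField:
    """Planar van der Pol field (y/r, -(x + m y (x**2 - 1))/r), r = |(x,y)|.

    The radial normalization keeps the phase-plane flow bounded away from
    the origin, which is masked on evaluation.  The parameter m stays
    symbolic when ``p`` is None.
    """
    r = sp.sqrt(X**2 + Y**2)
    comps = (Y / r, -(X + _M * Y * (X**2 - 1)) / r)
    return SymbolicVectorField(comps, {"m": None if p is None else p.m})


def actin_field_2d() -> SymbolicVectorField:
    """Concentric actin-geometry field (y**2/r, x**2/r) in the plane."""
    r = sp.sqrt(X**2 + Y**2)
    return SymbolicVectorField((Y**2 / r, X**2 / r))


def _r3() -> sp.Expr:
    return sp.sqrt(X**2 + Y**2 + Z**2)


def actin_field_3d(parse: str = "reciprocal") -> SymbolicVectorField:
    """3D actin field f = (y**2/(r z**2), x**2/(r z**2), 0).

    The printed form is typographically ambiguous; ``parse`` selects the
    adopted reading ("reciprocal", z**2 in the denominator) or the
    alternative ("product", y**2 z**2 / r).  The planar components are
    lifted with a zero third component.
    """
    r = _r3()
    if parse == "reciprocal":
        comps = (Y**2 / (r * Z**2), X**2 / (r * Z**2), sp.Integer(0))
    elif parse == "product":
        comps = (Y**2 * Z**2 / r, X**2 * Z**2 / r, sp.Integer(0))
    else:
        raise ContractViolation(f"unknown parse strategy {parse!r}")
    return SymbolicVectorField(comps)


def vdp_field_3d(p: VdpParams = None, parse: str = "reciprocal") -> SymbolicVectorField:
    """3D van der Pol field g = (y/(r z), -(x z + m y (x**2 z**2 - 1) z)/r, 0)."""
    r = _r3()
    if parse == "reciprocal":
        x_comp = Y / (r * Z)
    elif parse == "product":
        x_comp = Y * Z / r
    else:
        raise ContractViolation(f"unknown parse strategy {parse!r}")
    y_comp = -(X * Z + _M * Y * (X**2 * Z**2 - 1) * Z) / r
    comps = (x_comp, y_comp, sp.Integer(0))
    return SymbolicVectorField(comps, {"m": None if p is None else p.m})


# ---------------------------------------------------------------------------
# the pipeline

@lru_cache(maxsize=16)
def _eft_expression(t: int, variant: str, parse: str) -> sp.Expr:
    """Symbolic EFT(x, y, z; m) for the standard coupled fields.

    Cached because the bracket algebra is the expensive step and is
    shared across the whole m sweep.
    """
    f = actin_field_3d(parse=parse)
    g = vdp_field_3d(parse=parse)
    Zf = iterated_lie_bracket(f, g, t)
    if variant == "gradient":
        V = SymbolicScalarField(
            sp.cancel(Zf.components[0] + Zf.components[1]), Zf.params
        )
        ef = tuple(-c for c in gradient(V).components)
    elif variant == "vector_laplacian":
        ef = vector_laplacian(Zf).components
    else:
        raise ContractViolation(f"unknown variant {variant!r}")
    return sp.sqrt(sum(c**2 for c in ef))


def _mb_from_eft(eft: np.ndarray, m: float, dirac_m: float = None) -> tuple:
    """Dirac and Nernst stages: MB = 61.5 * Re(Log(-EFT*m)) = 61.5*ln(EFT*m).

    Returns (mb, mask); masked where EFT*m <= 0 or non-finite (Log(0) and
    the imaginary branch are excluded rather than clipped).
    """
    mult = m if dirac_m is None else dirac_m
    arg = np.real(eft) * mult
    with np.errstate(all="ignore"):
        mb = NERNST_SLOPE_MV * np.log(arg)
    mask = ~np.isfinite(mb) | (arg <= 0)
    mb = np.where(mask, np.nan, mb)
    return mb, mask


def trace_along_points(
    points: np.ndarray,
    p: VdpParams,
    t: int = 1,
    variant: str = "gradient",
    parse: str = "reciprocal",
    dirac_m: float = None,
    s_values: np.ndarray = None,
) -> PotentialTrace:
    """Run the membrane-potential pipeline along explicit 3D points."""
    points = np.asarray(points, dtype=float)
    eft_expr = _eft_expression(int(t), variant, parse)
    fn = sp.lambdify((X, Y, Z, _M), eft_expr, "numpy")
    with np.errstate(all="ignore"):
        eft = np.asarray(
            fn(points[:, 0], points[:, 1], points[:, 2], p.m), dtype=complex
        )
    eft = np.abs(np.where(np.isfinite(eft), eft, np.nan))
    mb, mask = _mb_from_eft(eft, p.m, dirac_m)
    mask |= ~np.isfinite(eft)
    if s_values is None:
        seg = np.linalg.norm(np.diff(points, axis=0), axis=1)
        s_values = np.concatenate([[0.0], np.cumsum(seg)])
    return PotentialTrace(
        s=np.asarray(s_values, dtype=float),
        mb_mV=mb,
        mask=mask,
        m=p.m,
        variant=variant,
        meta={"t": int(t), "parse": parse, "dirac_m": dirac_m},
    )


def membrane_potential_pipeline(
    f: SymbolicVectorField = None,
    g: SymbolicVectorField = None,
    p: VdpParams = VdpParams(1.0),
    t: int = 1,
    grid: GridSpec = None,
    path: PathSpec = None,
    variant: str = "gradient",
    parse: str = "reciprocal",
    dirac_m: float = None,
) -> PotentialTrace:
    """Full pipeline: bracket -> V -> EF -> EFT -> Dirac -> Nernst scaling.

    ``f`` and ``g`` default to the standard 3D actin and van der Pol
    fields; passing custom fields bypasses the cached symbolic route.
    The trace is sampled along ``path`` (default: the diagonal line
    (s, s, 1), s in [0.1, 2], 400 samples); ``grid`` is recorded in the
    trace metadata for export reproducibility.  ``dirac_m`` lets the
    Dirac multiplier differ from the field damping; by default they are
    the same parameter.
    """
    if t < 1:
        raise ContractViolation(f"iteration depth t must be >= 1, got {t}")
    grid = grid or default_grid()
    path = path or default_path()
    if f is None and g is None:
        trace = trace_along_points(
            path.points(), p, t=t, variant=variant, parse=parse,
            dirac_m=dirac_m, s_values=path.parameter_values(),
        )
    else:
        f = (f or actin_field_3d(parse=parse)).lift()
        g = (g or vdp_field_3d(parse=parse)).lift()
        g = g.with_params(m=p.m) if "m" in g.params else g
        Zf = iterated_lie_bracket(f, g, t)
        if variant == "gradient":
            V = SymbolicScalarField(
                sp.cancel(Zf.components[0] + Zf.components[1]), Zf.params
            )
            ef_comps = tuple(-c for c in gradient(V).components)
        elif variant == "vector_laplacian":
            ef_comps = vector_laplacian(Zf).components
        else:
            raise ContractViolation(f"unknown variant {variant!r}")
        eft_expr = sp.sqrt(sum(c**2 for c in ef_comps))
        subs = {sp.Symbol(k): v for k, v in Zf.params.items() if v is not None}
        fn = sp.lambdify(COORDS, eft_expr.subs(subs), "numpy")
        pts = path.points()
        with np.errstate(all="ignore"):
            eft = np.asarray(fn(pts[:, 0], pts[:, 1], pts[:, 2]), dtype=complex)
        eft = np.abs(np.where(np.isfinite(eft), eft, np.nan))
        mb, mask = _mb_from_eft(eft, p.m, dirac_m)
        trace = PotentialTrace(
            s=path.parameter_values(), mb_mV=mb, mask=mask | ~np.isfinite(eft),
            m=p.m, variant=variant,
            meta={"t": int(t), "parse": parse, "dirac_m": dirac_m},
        )
    trace.meta.update({"grid": grid.to_dict(), "path": path.to_dict()})
    return trace


def sweep_membrane_potential(
    m_values: np.ndarray = None,
    t: int = 1,
    path: PathSpec = None,
    variant: str = "gradient",
    parse: str = "reciprocal",
) -> list:
    """One :class:`PotentialTrace` per damping value; shares the symbolic work."""
    if m_values is None:
        m_values = default_m_sweep()
    path = path or default_path()
    pts = path.points()
    ss = path.parameter_values()
    return [
        trace_along_points(
            pts, VdpParams(float(m)), t=t, variant=variant, parse=parse, s_values=ss
        )
        for m in np.asarray(m_values, dtype=float)
    ]


# ---------------------------------------------------------------------------
# classical membrane-potential utilities

def nernst(ratio: float) -> float:
    """Nernst potential 61.5 mV * log10(out/in) at body temperature."""
    if ratio <= 0:
        raise ContractViolation(f"concentration ratio must be positive, got {ratio}")
    return NERNST_SLOPE_MV * np.log10(ratio)


def goldman_factor(V, x_upper: float, RT_over_F: float = RT_OVER_F_MV) -> float:
    """Goldman exponential integral  integral_0^x exp(V(s)/(RT/F)) ds.

    ``V`` is a scalar function of position returning mV; the integrand
    exponent is F V / (R T) with RT/F in mV.  Uses adaptive quadrature
    and raises if it fails to converge.
    """
    result, err = scipy.integrate.quad(
        lambda s: np.exp(V(s) / RT_over_F), 0.0, x_upper, limit=200
    )
    if not np.isfinite(result) or err > max(1e-8, 1e-8 * abs(result)):
        raise RuntimeError(
            f"Goldman quadrature failed (value={result}, err estimate={err})"
        )
    return result
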