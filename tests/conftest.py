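import numpy as np
import pytest
import sympy as sp

from neuroactin.fields import COORDS, SymbolicVectorField

X, Y, Z = COORDS


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20250707)


def random_poly_field(rng, degree=2, ncomp=3) -> SymbolicVectorField:
    """Random small-integer polynomial vector field (always smooth)."""
    monos = [X**i * Y**j * Z**k
             for i in range(degree + 1) for j in range(degree + 1)
             for k in range(degree + 1) if i + j + k <= degree]
    comps = []
    for _ in range(ncomp):
        coeffs = rng.integers(-3, 4, size=len(monos))
        comps.append(sum(int(c) * m for c, m in zip(coeffs, monos)))
    return SymbolicVectorField(tuple(sp.sympify(c) for c in comps))


def fd_gradient(fn, p, h=1e-5):
    """Central finite-difference gradient of scalar fn at 3-point p."""
    p = np.asarray(p, dtype=float)
    out = np.empty(3)
    for i in range(3):
        e = np.zeros(3)
        e[i] = h
        out[i] = (fn(*(p + e)) - fn(*(p - e))) / (2 * h)
    return out


def fd_jacobian(vfn, p, h=1e-5):
    """Central finite-difference Jacobian of vector fn at 3-point p."""
    p = np.asarray(p, dtype=float)
    cols = []
    for i in range(3):
        e = np.zeros(3)
        e[i] = h
        cols.append((np.asarray(vfn(*(p + e))) - np.asarray(vfn(*(p - e)))) / (2 * h))
    return np.column_stack(cols)
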