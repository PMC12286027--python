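"""Symbolic field calculus: brackets, differential operators, grids."""

import numpy as np
import pytest
import sympy as sp
from hypothesis import given, settings, strategies as st

from neuroactin.fields import (
    COORDS,
    ContractViolation,
    GridSpec,
    SymbolicScalarField,
    SymbolicVectorField,
    UnboundParameterError,
    curl,
    evaluate_on_grid,
    field_from_json,
    field_to_json,
    gradient,
    iterated_lie_bracket,
    jacobian,
    lie_bracket,
    vector_laplacian,
)
from conftest import fd_gradient, fd_jacobian, random_poly_field

X, Y, Z = COORDS


def vf(*comps, **params):
    return SymbolicVectorField(tuple(sp.sympify(c) for c in comps), params)


def is_zero_field(f: SymbolicVectorField) -> bool:
    return all(sp.simplify(c) == 0 for c in f.components)


class TestJacobian:
    @pytest.mark.parametrize(
        "comps,expected",
        [
            ((X, Y, Z), sp.eye(3)),
            ((1, 2, 3), sp.zeros(3, 3)),
        ],
    )
    def test_identity_and_constant(self, comps, expected):
        assert jacobian(vf(*comps)) == expected

    def test_against_finite_differences(self):
        f = vf(X**2, X * Y, 0)
        J = jacobian(f)
        p = (1.0, 2.0, 0.0)
        num = np.array(J.subs(dict(zip(COORDS, p)))).astype(float)
        fd = fd_jacobian(lambda *q: [complex(c).real for c in f(*q)], p)
        assert np.allclose(num, fd, atol=1e-6)

    def test_two_component_field_lifted(self):
        J = jacobian(vf(Y, -X))
        assert J.shape == (3, 3)
        assert J[2, :] == sp.zeros(1, 3)


class TestLieBracket:
    def test_self_bracket_vanishes(self):
        f = vf(X * Y, Y**2 + Z, sp.sin(X))
        assert is_zero_field(lie_bracket(f, f))

    def test_rotation_and_dilation_commute(self):
        # [ (y,-x), (x,y) ] = 0: the rotation and scaling flows commute
        f = vf(Y, -X)
        g = vf(X, Y)
        assert is_zero_field(lie_bracket(f, g))

    @settings(max_examples=15, deadline=None, derandomize=True)
    @given(st.integers(0, 2**30))
    def test_antisymmetry_random_polynomials(self, seed):
        rng = np.random.default_rng(seed)
        f = random_poly_field(rng)
        g = random_poly_field(rng)
        fg = lie_bracket(f, g)
        gf = lie_bracket(g, f)
        for a, b in zip(fg.components, gf.components):
            assert sp.simplify(a + b) == 0

    @settings(max_examples=10, deadline=None, derandomize=True)
    @given(st.integers(0, 2**30))
    def test_bilinearity(self, seed):
        rng = np.random.default_rng(seed)
        f, g, h = (random_poly_field(rng, degree=1) for _ in range(3))
        lhs = lie_bracket(vf(*(2 * a + 3 * b for a, b in zip(f.components, g.components))), h)
        rhs_f = lie_bracket(f, h)
        rhs_g = lie_bracket(g, h)
        for l, a, b in zip(lhs.components, rhs_f.components, rhs_g.components):
            assert sp.simplify(l - 2 * a - 3 * b) == 0

    @settings(max_examples=8, deadline=None, derandomize=True)
    @given(st.integers(0, 2**30))
    def test_jacobi_identity(self, seed):
        rng = np.random.default_rng(seed)
        f, g, h = (random_poly_field(rng, degree=1) for _ in range(3))
        total = [
            sp.simplify(a + b + c)
            for a, b, c in zip(
                lie_bracket(f, lie_bracket(g, h)).components,
                lie_bracket(g, lie_bracket(h, f)).components,
                lie_bracket(h, lie_bracket(f, g)).components,
            )
        ]
        assert all(t == 0 for t in total)


class TestIteratedBracket:
    def test_base_case_is_plain_bracket(self, rng):
        f = random_poly_field(rng)
        g = random_poly_field(rng)
        k1 = iterated_lie_bracket(f, g, 1)
        br = lie_bracket(f, g)
        for a, b in zip(k1.components, br.components):
            assert sp.simplify(a - b) == 0

    def test_depth_two_equals_naive_nesting(self, rng):
        f = random_poly_field(rng, degree=1)
        g = random_poly_field(rng, degree=1)
        k2 = iterated_lie_bracket(f, g, 2)
        naive = lie_bracket(f, lie_bracket(f, g))
        for a, b in zip(k2.components, naive.components):
            assert sp.simplify(a - b) == 0

    def test_depth_two_against_numeric_nested_oracle(self):
        """ad_f^(2) g for the 3D coupled fields vs a finite-difference oracle."""
        from neuroactin.electrophysiology import actin_field_3d, vdp_field_3d

        f = actin_field_3d()
        g = vdp_field_3d().with_params(m=1.0)
        k2 = iterated_lie_bracket(f, g, 2)
        p = (1.0, 1.0, 1.0)
        sym = np.array([complex(c).real for c in k2.with_params(m=1.0)(*p)])

        def fnum(*q):
            return np.array([complex(c).real for c in f(*q)])

        def gnum(*q):
            return np.array([complex(c).real for c in g(*q)])

        def bracket_num(q, h=1e-5):
            return fd_jacobian(gnum, q, h) @ fnum(*q) - fd_jacobian(fnum, q, h) @ gnum(*q)

        def nested_num(q, h=1e-4):
            return fd_jacobian(lambda *u: bracket_num(u), q, h) @ fnum(*q) - fd_jacobian(
                fnum, q, h
            ) @ bracket_num(q)

        oracle = nested_num(p)
        assert np.allclose(sym, oracle, rtol=1e-4, atol=1e-4)

    @pytest.mark.parametrize("k", [0, -1])
    def test_invalid_depth_rejected(self, k, rng):
        f = random_poly_field(rng)
        with pytest.raises(ContractViolation):
            iterated_lie_bracket(f, f, k)

    def test_depth_cap(self, rng):
        f = random_poly_field(rng, degree=1)
        with pytest.raises(ContractViolation):
            iterated_lie_bracket(f, f, 5)


class TestScalarOperators:
    def test_gradient_of_quadratic(self):
        s = SymbolicScalarField(X**2 + Y**2 + Z**2)
        assert gradient(s).components == (2 * X, 2 * Y, 2 * Z)

    def test_gradient_of_constant(self):
        s = SymbolicScalarField(sp.Integer(7))
        assert all(c == 0 for c in gradient(s).components)

    def test_gradient_against_finite_differences(self):
        s = SymbolicScalarField(sp.sin(X) * sp.cos(Y))
        p = (0.3, 0.7, 0.0)
        num = np.array([complex(c.subs(dict(zip(COORDS, p)))).real
                        for c in gradient(s).components])
        fd = fd_gradient(lambda *q: complex(s.expression.subs(dict(zip(COORDS, q)))).real, p)
        assert np.allclose(num, fd, atol=1e-6)

    def test_curl_of_gradient_vanishes(self):
        s = SymbolicScalarField(sp.exp(X) * sp.sin(Y * Z) + X * Y**2)
        c = curl(gradient(s))
        assert all(sp.simplify(e) == 0 for e in c.components)


class TestVectorLaplacian:
    def test_quadratic_field(self):
        F = vf(X**2, Y**2, Z**2)
        assert tuple(sp.simplify(c) for c in vector_laplacian(F).components) == (2, 2, 2)

    def test_zero_field(self):
        F = vf(0, 0, 0)
        assert all(c == 0 for c in vector_laplacian(F).components)

    def test_unlifted_2d_field_rejected(self):
        with pytest.raises(ContractViolation):
            vector_laplacian(vf(Y, -X))

    @settings(max_examples=8, deadline=None, derandomize=True)
    @given(st.integers(0, 2**30))
    def test_equals_componentwise_laplacian(self, seed):
        rng = np.random.default_rng(seed)
        F = random_poly_field(rng)
        vl = vector_laplacian(F)
        for i, c in enumerate(F.components):
            comp_lap = sum(sp.diff(c, q, 2) for q in COORDS)
            assert sp.simplify(vl.components[i] - comp_lap) == 0


class TestFiniteDifferenceAgreement:
    """gradient/jacobian/vector_laplacian vs central differences at random points."""

    def test_three_operators_at_random_points(self, rng):
        s_expr = sp.sin(X) * Y + sp.exp(Z / 3) * X
        s = SymbolicScalarField(s_expr)
        F = vf(X**2 * Y, Y * Z, sp.cos(X) + Z**2)
        grad_s = gradient(s)
        J = jacobian(F)
        lap = vector_laplacian(F)
        s_num = sp.lambdify(COORDS, s_expr)
        F_num = sp.lambdify(COORDS, list(F.components))
        pts = rng.uniform(-2, 2, size=(100, 3))
        for p in pts:
            sub = dict(zip(COORDS, p))
            g_sym = np.array([float(c.subs(sub)) for c in grad_s.components])
            g_fd = fd_gradient(s_num, p)
            assert np.allclose(g_sym, g_fd, rtol=1e-5, atol=1e-7)
            J_sym = np.array(J.subs(sub)).astype(float)
            J_fd = fd_jacobian(F_num, p)
            assert np.allclose(J_sym, J_fd, rtol=1e-5, atol=1e-6)
        # Laplacian FD uses second differences; check a handful of points
        for p in pts[:10]:
            sub = dict(zip(COORDS, p))
            l_sym = np.array([float(sp.simplify(c).subs(sub)) for c in lap.components])
            h = 1e-4
            l_fd = np.zeros(3)
            base = np.array(F_num(*p))
            for i in range(3):
                e = np.zeros(3)
                e[i] = h
                l_fd += (np.array(F_num(*(p + e))) - 2 * base + np.array(F_num(*(p - e)))) / h**2
            assert np.allclose(l_sym, l_fd, rtol=1e-5, atol=1e-3)


class TestGridEvaluation:
    def test_singularity_masked_at_origin(self):
        s = SymbolicScalarField(1 / sp.sqrt(X**2 + Y**2 + Z**2))
        grid = GridSpec(((-1, 1, 3), (-1, 1, 3), (-1, 1, 3)))
        sg = evaluate_on_grid(s, grid)
        assert sg.mask[1, 1, 1]
        assert sg.mask.sum() == 1
        assert np.isfinite(sg.finite_values()).all()

    def test_constant_field_uniform_no_mask(self):
        s = SymbolicScalarField(sp.Integer(5))
        sg = evaluate_on_grid(s, GridSpec(((-1, 1, 4), (-1, 1, 4))))
        assert not sg.mask.any()
        assert np.allclose(sg.values, 5)

    def test_linear_axis_samples(self):
        s = SymbolicScalarField(X)
        sg = evaluate_on_grid(s, GridSpec(((-1, 1, 3), (0, 1, 2))))
        assert np.allclose(np.real(sg.values[:, 0]), [-1, 0, 1])

    def test_unbound_parameter_rejected(self):
        s = SymbolicScalarField(sp.Symbol("m") * X, {"m": None})
        with pytest.raises(UnboundParameterError):
            evaluate_on_grid(s, GridSpec(((-1, 1, 3),)))

    def test_gridspec_contract(self):
        with pytest.raises(ContractViolation):
            GridSpec(((0, 1, 1),))
        with pytest.raises(ContractViolation):
            GridSpec(((1, 0, 5),))


class TestSerialization:
    def test_round_trip(self):
        f = vf(X**2 / (Y + 1), sp.sin(Z), sp.Symbol("m") * X, m=2.0)
        back = field_from_json(field_to_json(f))
        for a, b in zip(f.components, back.components):
            assert sp.simplify(a - b) == 0
        assert back.params == {"m": 2.0}

    def test_caret_accepted_on_read(self):
        back = field_from_json('{"components": ["x^2", "y^3", "0"], "params": {}}')
        assert back.components == (X**2, Y**3, sp.Integer(0))

    def test_undeclared_symbol_rejected(self):
        with pytest.raises(ContractViolation):
            vf(sp.Symbol("q") * X, 0, 0)
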