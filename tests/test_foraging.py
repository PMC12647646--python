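"""Foraging operators: coefficient formulas against hand values, fixed
points, clamping, and the stagnation boost."""

import numpy as np
import pytest

from clamrfo import foraging as fo
from clamrfo.initialization import Bounds


@pytest.mark.parametrize(
    "cr0,r_t,expected",
    [(0.9, 0.0, 0.9), (0.9, 1.0, 0.63), (0.9, 0.5, 0.765)],
)
def test_crossover_rate(cr0, r_t, expected):
    assert fo.crossover_rate(cr0, r_t) == pytest.approx(expected)


def test_alpha_hand_values():
    assert fo.alpha_coeff(0.5) == pytest.approx(2 * 0.5 * np.sqrt(np.log(2)), rel=1e-6)
    assert fo.alpha_coeff(0.5) == pytest.approx(0.8326, abs=2e-4)
    assert fo.alpha_coeff(0.1) == pytest.approx(0.2 * np.sqrt(np.abs(np.log(0.1))), rel=1e-6)
    assert fo.alpha_coeff(0.1) == pytest.approx(0.3035, abs=2e-4)
    # log(1) = 0 limit
    assert fo.alpha_coeff(1.0 - 1e-10) == pytest.approx(0.0, abs=1e-4)


def test_beta_hand_values():
    assert fo.beta_coeff(0.5, 0.3) == pytest.approx(0.0, abs=1e-12)  # sin(pi) = 0
    assert fo.beta_coeff(0.25, 1.0) == pytest.approx(2.0)
    assert fo.beta_coeff(0.25, 0.0) == pytest.approx(2 * np.exp(0.25), rel=1e-9)


@pytest.mark.parametrize(
    "base,i,n,r_t,expected",
    [
        (1.0, 0, 200, 0.0, 1.0),
        (1.0, 100, 200, 0.0, 0.75),
        (0.85, 0, 200, 1.0, 1.0),  # 0.85 * 1.3 clipped
    ],
)
def test_cyclone_probability(base, i, n, r_t, expected):
    assert fo.cyclone_probability(base, i, n, r_t) == pytest.approx(expected)


def test_somersault_factor_schedule_and_boost():
    assert fo.somersault_factor(2.5, 0.0) == pytest.approx(2.5)
    assert fo.somersault_factor(2.5, 1.0) == pytest.approx(1.75)
    assert fo.somersault_factor(2.0, 0.4, stagnating=True) > fo.somersault_factor(2.0, 0.4)


def test_chain_fixed_point_and_no_update(rng):
    b = Bounds.cube(-100, 100, 3)
    x_best = np.array([1.0, 2.0, 3.0])
    out = fo.chain_forage(x_best[None, :], x_best, np.array([0.5]), 0.9, b, rng)
    np.testing.assert_allclose(out[0], x_best)
    x = np.array([[5.0, -4.0, 0.0]])
    out = fo.chain_forage(x, x_best, np.array([0.5]), 0.0, b, rng)  # CR = 0
    np.testing.assert_array_equal(out, x)


def test_chain_direct_1d_value(rng):
    """D=1: x=0, X_best=10, C=0.5, r < CR always -> 10 (0.5 + alpha)."""
    b = Bounds.cube(-100, 100, 1)
    out = fo.chain_forage(np.array([[0.0]]), np.array([10.0]), np.array([0.5]), 1.0, b, rng)
    expected = 10.0 * (0.5 + fo.alpha_coeff(0.5))
    assert out[0, 0] == pytest.approx(min(expected, 100.0))
    assert expected == pytest.approx(13.326, abs=2e-3)


def test_cyclone_fixed_point_and_direct_value():
    b = Bounds.cube(-100, 100, 1)
    ref = np.array([1.0])
    same = fo.cyclone_forage(ref[None, :], ref, np.array([0.25]), 1.0, b)
    np.testing.assert_allclose(same[0], ref)
    out = fo.cyclone_forage(np.array([[0.0]]), ref, np.array([0.25]), 1.0, b)
    assert out[0, 0] == pytest.approx(1 + (0.25 + 2.0) * 1.0)  # beta = 2 exactly
    contract = fo.cyclone_forage(np.array([[0.0]]), ref, np.array([0.5]), 0.7, b)
    assert contract[0, 0] == pytest.approx(1 + 0.5 * 1.0)  # beta = 0 at C = 0.5


def test_somersault_moves(rng):
    b = Bounds.cube(-100, 100, 1)

    class HalfRng:
        def random(self, shape):
            return np.full(shape, 0.5)

    x = np.array([[3.0]])
    out = fo.somersault_forage(x, np.array([3.0]), 2.0, b, HalfRng())
    np.testing.assert_allclose(out, x)  # symmetric cancellation at r = 0.5

    class ZeroRng:
        def random(self, shape):
            return np.zeros(shape)

    out = fo.somersault_forage(np.array([[2.0]]), np.array([0.0]), 1.0, b, ZeroRng())
    assert out[0, 0] == pytest.approx(0.0)
    out = fo.somersault_forage(np.array([[2.0]]), np.array([0.0]), 0.0, b, rng)
    assert out[0, 0] == pytest.approx(2.0)  # S = 0 is a null move


def test_operators_respect_bounds(rng):
    b = Bounds.cube(-1, 1, 4)
    x = rng.uniform(-1, 1, size=(50, 4))
    best = np.array([0.9, -0.9, 0.0, 0.5])
    for out in (
        fo.chain_forage(x, best, rng.uniform(0.1, 0.9, 50), 0.9, b, rng),
        fo.cyclone_forage(x, best, rng.uniform(0.1, 0.9, 50), 0.2, b),
        fo.somersault_forage(x, best, 2.5, b, rng),
    ):
        assert np.all(out >= -1) and np.all(out <= 1)


def test_coefficients_match_high_precision_grid():
    """alpha and beta agree with 50-digit evaluation to 1e-12 over a grid."""
    import sympy as sp

    c_sym, r_sym = sp.symbols("c r")
    alpha_expr = 2 * c_sym * sp.sqrt(sp.Abs(sp.log(c_sym + sp.Float("1e-10", 30))))
    beta_expr = 2 * sp.exp(c_sym * (1 - r_sym)) * sp.sin(2 * sp.pi * c_sym)
    rng = np.random.default_rng(77)
    cs = rng.uniform(0.1, 0.9, 40)
    rs = rng.uniform(0.0, 1.0, 25)
    for c in cs:
        ref_a = float(alpha_expr.evalf(30, subs={c_sym: sp.Float(float(c), 30)}))
        assert abs(fo.alpha_coeff(float(c)) - ref_a) < 1e-12
        for r in rs:
            ref_b = float(
                beta_expr.evalf(
                    30, subs={c_sym: sp.Float(float(c), 30), r_sym: sp.Float(float(r), 30)}
                )
            )
            assert abs(fo.beta_coeff(float(c), float(r)) - ref_b) < 1e-12
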