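import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from polholo.polarization import (
    CIRCULAR_STOKES,
    StokesVector,
    amplitudes_to_polarization,
    apply_mueller,
    interference_polarization,
    jones_to_mueller,
    lb_jones,
    lb_mueller,
    stokes_from_amplitudes,
    stokes_to_polarization,
)


def rot4(theta):
    """Poincare rotation about the circular axis by the double angle."""
    c, s = np.cos(2 * theta), np.sin(2 * theta)
    r = np.eye(4)
    r[1, 1], r[1, 2], r[2, 1], r[2, 2] = c, s, -s, c
    return r


def retarder4(delta):
    """Axis-aligned retarder block on the (s3, s4) plane."""
    m = np.eye(4)
    cd, sd = np.cos(delta), np.sin(delta)
    m[2, 2], m[2, 3], m[3, 2], m[3, 3] = cd, sd, -sd, cd
    return m


class TestLBMueller:
    def test_zero_retardance_is_identity(self):
        for rho in (0.0, 0.4, np.pi / 2, 2.9):
            np.testing.assert_allclose(lb_mueller(rho, 0.0).elements, np.eye(4), atol=1e-14)

    def test_quarter_axis_elements(self):
        delta = 0.77
        m = lb_mueller(np.pi / 4, delta).elements
        assert m[1, 1] == pytest.approx(np.cos(delta))
        assert m[1, 2] == pytest.approx(0, abs=1e-12)
        assert m[1, 3] == pytest.approx(np.sin(delta))
        assert m[2, 2] == pytest.approx(1)
        assert m[3, 3] == pytest.approx(np.cos(delta))

    def test_rotation_retarder_composition_oracle(self, rng):
        # brute-force composition on the Poincare rotation block
        for _ in range(50):
            rho = rng.uniform(0, np.pi)
            delta = rng.uniform(0, 2 * np.pi)
            oracle = rot4(rho) @ retarder4(delta) @ rot4(-rho)
            np.testing.assert_allclose(lb_mueller(rho, delta).elements, oracle, atol=1e-12)

    def test_structure_invariants(self, rng):
        for _ in range(50):
            m = lb_mueller(rng.uniform(0, np.pi), rng.uniform(0, 2 * np.pi)).elements
            np.testing.assert_allclose(m[0], [1, 0, 0, 0], atol=1e-14)
            np.testing.assert_allclose(m[:, 0], [1, 0, 0, 0], atol=1e-14)
            assert np.linalg.det(m) == pytest.approx(1.0, abs=1e-10)
            block = m[1:, 1:]
            np.testing.assert_allclose(block @ block.T, np.eye(3), atol=1e-12)

    def test_retardance_additivity(self, rng):
        for _ in range(20):
            rho = rng.uniform(0, np.pi)
            d1, d2 = rng.uniform(0, np.pi, 2)
            prod = lb_mueller(rho, d1).elements @ lb_mueller(rho, d2).elements
            np.testing.assert_allclose(prod, lb_mueller(rho, d1 + d2).elements, atol=1e-12)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            lb_mueller(np.nan, 0.3)
        with pytest.raises(ValueError):
            lb_mueller(0.3, -0.1)


class TestJones:
    def test_unitarity(self, rng):
        for _ in range(20):
            j = lb_jones(rng.uniform(0, np.pi), rng.uniform(0, 2 * np.pi)).elements
            np.testing.assert_allclose(j @ j.conj().T, np.eye(2), atol=1e-12)

    def test_jones_to_mueller_equivalence(self, rng):
        worst = 0.0
        for _ in range(1000):
            rho = rng.uniform(0, np.pi)
            delta = rng.uniform(0, 2 * np.pi)
            m = lb_mueller(rho, delta).elements
            mj = jones_to_mueller(lb_jones(rho, delta))
            worst = max(worst, np.abs(m - mj).max())
        assert worst < 1e-10


class TestApplyMueller:
    def test_identity(self):
        s = StokesVector(1, 0.2, -0.3, 0.5)
        out = apply_mueller(np.eye(4), s)
        np.testing.assert_allclose(out.as_array(), s.as_array())

    def test_circular_input_closed_form(self, rng):
        # expanded form of the single-interaction product on circular light
        for _ in range(50):
            rho = rng.uniform(0, np.pi)
            delta = rng.uniform(0, 2 * np.pi)
            out = apply_mueller(lb_mueller(rho, delta), CIRCULAR_STOKES)
            expect = [1, np.sin(2 * rho) * np.sin(delta), np.cos(2 * rho) * np.sin(delta), np.cos(delta)]
            np.testing.assert_allclose(out.as_array(), expect, atol=1e-12)

    def test_pi6_pi2_example(self):
        out = apply_mueller(lb_mueller(np.pi / 6, np.pi / 2), CIRCULAR_STOKES)
        np.testing.assert_allclose(out.as_array(), [1, np.sqrt(3) / 2, 0.5, 0], atol=1e-12)

    def test_s1_preserved(self, rng):
        s = StokesVector(1, 0.1, 0.2, 0.3)
        out = apply_mueller(lb_mueller(1.0, 0.7), s)
        assert out.s1 == pytest.approx(1.0)

    def test_shape_mismatch(self):
        with pytest.raises(ValueError):
            apply_mueller(np.eye(3), CIRCULAR_STOKES)


class TestStokesToPolarization:
    def test_horizontal_linear(self):
        p = stokes_to_polarization(StokesVector(1, 1, 0, 0))
        assert p.alpha == pytest.approx(0)
        assert p.beta == pytest.approx(0)
        assert p.alpha_defined

    def test_pi6_pi2_closed_form(self):
        s = apply_mueller(lb_mueller(np.pi / 6, np.pi / 2), CIRCULAR_STOKES)
        p = stokes_to_polarization(s)
        # 0.5*arctan(cot(pi/3)) = pi/12
        assert p.alpha == pytest.approx(0.5 * np.arctan(1 / np.tan(np.pi / 3)))
        assert p.alpha == pytest.approx(np.pi / 12)
        assert p.beta == pytest.approx(0, abs=1e-12)

    def test_right_circular_flagged(self):
        p = stokes_to_polarization(StokesVector(1, 0, 0, 1))
        assert not p.alpha_defined
        assert p.alpha == 0.0
        assert p.beta == pytest.approx(np.pi / 4)

    def test_circular_chain_invariant(self, rng):
        # alpha = 0.5*arctan(cot 2rho), beta = 0.5*arcsin(cos delta)
        for _ in range(200):
            rho = rng.uniform(0.05, np.pi / 2 - 0.05)
            delta = rng.uniform(0.05, np.pi - 0.05)
            p = stokes_to_polarization(apply_mueller(lb_mueller(rho, delta), CIRCULAR_STOKES))
            assert p.alpha == pytest.approx(0.5 * np.arctan(1 / np.tan(2 * rho)), abs=1e-10)
            assert p.beta == pytest.approx(0.5 * np.arcsin(np.cos(delta)), abs=1e-10)


def _ellipse_fit_oracle(ux, uy, n=4096):
    """Brute-force ellipse fit of the time-domain field trace."""
    t = np.linspace(0, 2 * np.pi, n, endpoint=False)
    x = np.real(ux * np.exp(-1j * t))
    y = np.real(uy * np.exp(-1j * t))
    sxx, syy, sxy = np.mean(x * x), np.mean(y * y), np.mean(x * y)
    alpha = 0.5 * np.arctan2(2 * sxy, sxx - syy)
    cov = np.array([[sxx, sxy], [sxy, syy]])
    lam = np.sort(np.linalg.eigvalsh(cov))[::-1]
    ratio = np.sqrt(max(lam[1], 0) / lam[0])
    # handedness from the rotation direction of the trace
    xdot = np.gradient(x, t)
    ydot = np.gradient(y, t)
    sign = np.sign(np.mean(x * ydot - y * xdot))
    return alpha, sign * np.arctan(ratio)


class TestAmplitudesToPolarization:
    def test_horizontal(self):
        p = amplitudes_to_polarization(1, 0)
        assert (p.alpha, p.beta) == (0, 0)

    def test_right_circular(self):
        p = amplitudes_to_polarization(1, 1j)
        assert not p.alpha_defined
        assert p.beta == pytest.approx(np.pi / 4)

    def test_ellipse_fit_oracle(self):
        ux, uy = 1.0, 0.5 * np.exp(1j * np.pi / 3)
        p = amplitudes_to_polarization(ux, uy)
        a_o, b_o = _ellipse_fit_oracle(ux, uy)
        assert p.alpha == pytest.approx(a_o, abs=1e-6)
        assert p.beta == pytest.approx(b_o, abs=1e-6)

    def test_agrees_with_stokes_path(self, rng):
        for _ in range(300):
            ux = rng.normal() + 1j * rng.normal()
            uy = rng.normal() + 1j * rng.normal()
            p1 = amplitudes_to_polarization(ux, uy)
            p2 = stokes_to_polarization(stokes_from_amplitudes(ux, uy))
            assert p1.alpha == pytest.approx(p2.alpha, abs=1e-10)
            assert p1.beta == pytest.approx(p2.beta, abs=1e-10)

    def test_zero_field_raises(self):
        with pytest.raises(ValueError):
            amplitudes_to_polarization(0, 0)

    @given(
        st.floats(-3, 3), st.floats(-3, 3), st.floats(-3, 3), st.floats(-3, 3)
    )
    @settings(max_examples=200, deadline=None)
    def test_ranges(self, a, b, c, d):
        ux, uy = complex(a, b), complex(c, d)
        if abs(ux) ** 2 + abs(uy) ** 2 == 0:  # incl. subnormal underflow
            return
        p = amplitudes_to_polarization(ux, uy)
        assert -np.pi / 2 <= p.alpha < np.pi / 2
        assert -np.pi / 4 <= p.beta <= np.pi / 4 + 1e-12


class TestInterferencePolarization:
    def test_in_phase_equal(self):
        p = interference_polarization(1, 1, 0)
        assert p.alpha == pytest.approx(np.pi / 4)
        assert p.beta == pytest.approx(0, abs=1e-12)

    def test_quadrature_equal_is_circular(self):
        p = interference_polarization(1, 1, np.pi / 2)
        assert p.beta == pytest.approx(np.pi / 4)

    def test_equivalence_to_amplitude_path(self):
        p1 = interference_polarization(2, 1, np.pi / 3)
        p2 = amplitudes_to_polarization(2, np.exp(1j * np.pi / 3))
        assert p1.alpha == pytest.approx(p2.alpha)
        assert p1.beta == pytest.approx(p2.beta)

    def test_negative_magnitude_raises(self):
        with pytest.raises(ValueError):
            interference_polarization(-1, 1, 0)
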