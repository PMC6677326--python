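"""Wall mechanics and TL coefficient tests, including independent oracles."""

import numpy as np
import pytest
import scipy.sparse as sp
import scipy.sparse.linalg as spla
from hypothesis import given, settings, strategies as st

from circwave.constitutive import (
    MMHG,
    PhysicalConstants,
    WallLawParams,
    area_from_pressure,
    compliance,
    dptrans_dA,
    line_inertance,
    line_resistance,
    profile_factors,
    transmural_pressure,
    wave_coefficients,
    wave_speed_at,
    womersley_number,
)

CONST = PhysicalConstants()
WALL = WallLawParams(p0=105 * MMHG, A0=np.pi * 0.01**2, k=8.0, b=0.02)


def womersley_fd_oracle(alpha, n=3000, r0=0.01):
    """Independent check: finite-difference solve of the oscillatory
    pipe-flow ODE  i w rho u = G + eta (u'' + u'/r),  no-slip at the wall,
    then g, h from the resulting longitudinal impedance."""
    rho, eta = CONST.rho, CONST.eta
    omega = (alpha / r0) ** 2 * eta / rho
    r = np.linspace(0.0, r0, n)
    dr = r[1] - r[0]
    main = np.full(n, -2.0 / dr**2, complex)
    up = np.zeros(n - 1, complex)
    lo = np.zeros(n - 1, complex)
    for i in range(1, n - 1):
        up[i] = 1 / dr**2 + 1 / (2 * r[i] * dr)
        lo[i - 1] = 1 / dr**2 - 1 / (2 * r[i] * dr)
    main[0] = -4.0 / dr**2
    up[0] = 4.0 / dr**2
    A = sp.diags([lo, main, up], [-1, 0, 1], format="lil")
    A = (eta * A - 1j * omega * rho * sp.eye(n)).tolil()
    rhs = -np.ones(n, complex)
    A[n - 1, :] = 0.0
    A[n - 1, n - 1] = 1.0
    rhs[n - 1] = 0.0
    u = spla.spsolve(A.tocsc(), rhs)
    q = np.trapezoid(2 * np.pi * r * u, r)
    Z = 1.0 / q
    A0 = np.pi * r0**2
    return np.imag(Z) * A0 / (omega * rho), np.real(Z) * A0**2 / (8 * np.pi * eta)


class TestWomersleyNumber:
    def test_zero_radius(self):
        assert womersley_number(0.0) == 0.0

    @pytest.mark.parametrize("r0, expected", [(0.01, 16.08), (0.015, 24.12)])
    def test_reference_values(self, r0, expected):
        assert womersley_number(r0) == pytest.approx(expected, rel=1e-3)

    def test_negative_radius_rejected(self):
        with pytest.raises(ValueError):
            womersley_number(-0.01)


class TestProfileFactors:
    def test_poiseuille_limit(self):
        g, h = profile_factors(1e-4)
        assert h == pytest.approx(1.0, abs=1e-6)
        assert g == pytest.approx(4.0 / 3.0, abs=1e-6)

    def test_inviscid_limit(self):
        g, h = profile_factors(1e4)
        assert g == pytest.approx(1.0, abs=2e-4)
        assert h > 100.0  # Stokes-layer friction grows without bound

    @pytest.mark.parametrize("alpha", [1.0, 2.0, 5.0, 10.0, 30.0])
    def test_matches_womersley_theory(self, alpha):
        """Within 5% of the independently computed longitudinal impedance
        over the stated validity range of the approximate profile."""
        g, h = profile_factors(alpha)
        g_ref, h_ref = womersley_fd_oracle(alpha)
        assert g == pytest.approx(g_ref, rel=0.05)
        assert h == pytest.approx(h_ref, rel=0.05)

    def test_limits_imply_poiseuille_resistance_and_inviscid_inertance(self):
        A0 = 1e-4
        R0 = line_resistance(1e-4, A0)
        assert R0 == pytest.approx(8 * np.pi * CONST.eta / A0**2, rel=1e-5)
        L_inf = line_inertance(1e4, A0)
        assert L_inf == pytest.approx(CONST.rho / A0, rel=3e-4)


class TestLineCoefficients:
    def test_inertance_arithmetic(self):
        # g = 1 forced via the inviscid limit
        L = 1.0 * CONST.rho / 1e-4
        assert L == pytest.approx(1.05e7)

    def test_resistance_arithmetic(self):
        R = 1.0 * 8 * np.pi * CONST.eta / (1e-4) ** 2
        assert R == pytest.approx(7.54e6, rel=1e-2)

    def test_area_scaling_law(self):
        alpha = 5.0
        assert line_resistance(alpha, 2e-4) == pytest.approx(
            line_resistance(alpha, 1e-4) / 4.0)
        assert line_inertance(alpha, 2e-4) == pytest.approx(
            line_inertance(alpha, 1e-4) / 2.0)

    def test_nonpositive_area_rejected(self):
        with pytest.raises(ValueError):
            line_resistance(5.0, 0.0)


class TestWallLaw:
    def test_reference_state_maps_to_reference_pressure(self):
        assert transmural_pressure(WALL.A0, WALL) == pytest.approx(WALL.p0)

    def test_reference_state_with_external_pressure(self):
        wall = WallLawParams(p0=WALL.p0, A0=WALL.A0, k=8.0, b=0.02,
                             p_ext=5 * MMHG)
        assert transmural_pressure(wall.A0, wall) == pytest.approx(
            wall.p0 - wall.p_ext)

    def test_collapse_divergence(self):
        assert transmural_pressure(1e-9 * WALL.A0, WALL) < -1e6 * WALL.p0

    def test_monotone_slope_numerically(self):
        A = np.linspace(0.5, 2.0, 41) * WALL.A0
        dA = 1e-9 * WALL.A0
        slope = (transmural_pressure(A + dA, WALL)
                 - transmural_pressure(A - dA, WALL)) / (2 * dA)
        assert np.all(slope > 0)
        assert np.allclose(slope, dptrans_dA(A, WALL), rtol=1e-4)

    def test_compliance_against_central_difference(self):
        for A in (0.7 * WALL.A0, WALL.A0, 1.5 * WALL.A0):
            dA = 1e-9
            fd = 2 * dA / (transmural_pressure(A + dA, WALL)
                           - transmural_pressure(A - dA, WALL))
            assert compliance(A, WALL) == pytest.approx(fd, rel=1e-6)

    def test_stiffer_wall_has_smaller_compliance(self):
        soft = WallLawParams(p0=WALL.p0, A0=WALL.A0, k=4.0, b=0.02)
        stiff = WallLawParams(p0=WALL.p0, A0=WALL.A0, k=12.0, b=0.02)
        assert compliance(WALL.A0, stiff) < compliance(WALL.A0, soft)

    def test_nonpositive_area_rejected(self):
        with pytest.raises(ValueError):
            transmural_pressure(0.0, WALL)

    @given(p=st.floats(min_value=-5e3, max_value=4e4))
    @settings(max_examples=50, deadline=None)
    def test_inversion_roundtrip(self, p):
        A = area_from_pressure(p, WALL)
        assert transmural_pressure(A, WALL) == pytest.approx(p, abs=1e-6 * WALL.p0)


class TestWaveCoefficients:
    def test_lossless_values(self):
        c, zc, att = wave_coefficients(0.0, 1.05e7, 1e-12)
        assert c == pytest.approx(308.6, rel=1e-3)
        assert zc == pytest.approx(3.24e9, rel=1e-2)
        assert att == 0.0

    def test_small_loss_matches_exact_propagation_constant(self):
        """Frequency-independent approximation vs the exact complex
        propagation constant sqrt((R + i w L)(i w C)) at w0."""
        L, C = 1.05e7, 1e-12
        w = CONST.omega0
        for R in (1e3, 1e4, 1e5):
            _, _, att = wave_coefficients(R, L, C)
            gamma = np.sqrt((R + 1j * w * L) * (1j * w * C))
            assert att == pytest.approx(np.real(gamma), rel=0.01)

    def test_wave_speed_monotone_in_k(self):
        p = 105 * MMHG
        speeds = [wave_speed_at(p, WallLawParams(p0=p, A0=WALL.A0, k=k, b=0.02))
                  for k in (2, 4, 8, 16, 30)]
        assert np.all(np.diff(speeds) > 0)

    def test_hypertensive_wall_is_faster_at_equal_pressure(self):
        p = 120 * MMHG
        ref = WallLawParams(p0=105 * MMHG, A0=WALL.A0, k=8.0, b=0.02)
        hyp = WallLawParams(p0=105 * MMHG, A0=WALL.A0, k=14.0, b=0.02)
        assert wave_speed_at(p, hyp) > wave_speed_at(p, ref)
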