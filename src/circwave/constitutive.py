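"""Vessel wall mechanics and transmission-line coefficients.

A vessel element behaves, electrically speaking, as a ladder section with a
series resistance ``R`` (viscous loss), series inertance ``L`` (blood
inertia) and shunt compliance ``C`` (wall distensibility), all per unit
length.  ``R`` and ``L`` depend on the velocity profile through the
characteristic Womersley number

    alpha0 = r0 * sqrt(rho * omega0 / eta),

the ratio of unsteady inertial to viscous forces at the characteristic
heart frequency ``omega0``.  The profile correction factors ``g`` and ``h``
are taken from exact Womersley oscillatory-flow theory (the longitudinal
impedance of a rigid tube, evaluated at ``omega0``), so that

    L(alpha0) = g(alpha0) * rho / A0,
    R(alpha0) = h(alpha0) * 8 * pi * eta / A0**2,

with the Poiseuille limit h -> 1, g -> 4/3 as alpha0 -> 0 and the inviscid
flat-profile limit g -> 1 (h ~ sqrt(2)*alpha0/8) as alpha0 -> infinity.

The wall is a thick-walled, longitudinally constrained nonlinear elastic
tube.  Transmural pressure follows a power law in the area ratio A/A0 with
a collapse term that drives the pressure to -infinity as the lumen closes:

    p_trans(A) = -p_ext + p0 * ((1 + b) * (A/A0)**(1 + k/3) - b * A0/A),

where ``k`` is the dimensionless stiffness coefficient and ``b`` a small
collapsible-tube fraction.  At the reference state A = A0 this gives
p_trans = p0 - p_ext exactly.  Compliance per unit length is the analytic
derivative C = dA/dp_trans.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import jve

__all__ = [
    "PhysicalConstants",
    "WallLawParams",
    "TLSegmentCoefficients",
    "womersley_number",
    "profile_factors",
    "line_inertance",
    "line_resistance",
    "transmural_pressure",
    "dptrans_dA",
    "area_from_pressure",
    "compliance",
    "wave_coefficients",
    "wave_speed_at",
    "MMHG",
]

#: Pa per mmHg (SI is used internally everywhere; mmHg only at I/O).
MMHG = 133.322


@dataclass(frozen=True)
class PhysicalConstants:
    """Blood and timing constants.

    rho    -- blood density [kg m^-3]
    eta    -- blood dynamic viscosity [Pa s]
    omega0 -- characteristic angular frequency [rad s^-1]
    T      -- cardiac cycle duration [s]
    """

    rho: float = 1050.0
    eta: float = 0.003
    omega0: float = 7.39
    T: float = 0.85

    def __post_init__(self) -> None:
        for name in ("rho", "eta", "omega0", "T"):
            if getattr(self, name) <= 0.0:
                raise ValueError(f"{name} must be strictly positive")
        # omega0 and T are listed independently; they must agree to ~1%.
        if abs(self.omega0 * self.T / (2.0 * np.pi) - 1.0) > 0.011:
            raise ValueError("omega0 and 2*pi/T disagree by more than 1%")


@dataclass(frozen=True)
class WallLawParams:
    """Parameters of the nonlinear pressure-area law (SI units)."""

    p0: float
    A0: float
    k: float
    b: float = 0.02
    p_ext: float = 0.0

    def __post_init__(self) -> None:
        if self.A0 <= 0.0:
            raise ValueError("A0 must be positive")
        if self.p0 <= 0.0:
            raise ValueError("p0 must be positive")
        if self.k <= 0.0:
            raise ValueError("k must be positive")
        if not 0.0 < self.b < 0.1:
            raise ValueError("b must lie in (0, 0.1)")


@dataclass(frozen=True)
class TLSegmentCoefficients:
    """Per-unit-length TL coefficients and derived wave quantities."""

    alpha0: float
    g: float
    h: float
    R: float  # Pa s m^-4
    L: float  # kg m^-5
    C: float  # m^3 Pa^-1 m^-1
    c: float  # m s^-1
    Zc: float  # Pa s m^-3
    attenuation: float  # m^-1


def womersley_number(r0, const: PhysicalConstants = PhysicalConstants()):
    """Characteristic Womersley number alpha0 = r0*sqrt(rho*omega0/eta)."""
    r0 = np.asarray(r0, dtype=float)
    if np.any(r0 < 0.0):
        raise ValueError("radius must be non-negative")
    out = r0 * np.sqrt(const.rho * const.omega0 / const.eta)
    return out.item() if out.ndim == 0 else out


def _womersley_admittance(alpha):
    """w = 1/(1 - F10(alpha)) with F10 = 2 J1(s)/(s J0(s)), s = i^(3/2) alpha.

    Exponentially scaled Bessel functions keep the ratio finite for large
    alpha; a series branch avoids catastrophic cancellation for small alpha.
    """
    alpha = np.asarray(alpha, dtype=float)
    w = np.empty(alpha.shape, dtype=complex)
    small = alpha < 0.1
    if np.any(small):
        a2 = alpha[small] ** 2
        # 1 - F10 = i a2/8 + a2^2/48 + O(a2^3)
        w[small] = 1.0 / (1j * a2 / 8.0 + a2 * a2 / 48.0 + 1e-300)
    if np.any(~small):
        a = alpha[~small]
        s = a * np.exp(1j * 3.0 * np.pi / 4.0)
        f10 = 2.0 * jve(1, s) / (s * jve(0, s))
        w[~small] = 1.0 / (1.0 - f10)
    return w


def profile_factors(alpha0):
    """Velocity-profile correction factors (g, h) at Womersley number alpha0.

    g scales the inertance, h the Poiseuille resistance.  Both derive from
    the exact oscillatory-flow longitudinal impedance
    Z = (i omega rho / A0) / (1 - F10): g = Re(w), h = -(alpha0^2/8) Im(w),
    with w = 1/(1 - F10).
    """
    alpha0_arr = np.asarray(alpha0, dtype=float)
    if np.any(alpha0_arr < 0.0):
        raise ValueError("alpha0 must be non-negative")
    scalar = alpha0_arr.ndim == 0
    a = np.atleast_1d(alpha0_arr)
    g = np.full(a.shape, 4.0 / 3.0)
    h = np.ones(a.shape)
    pos = a > 1e-6
    if np.any(pos):
        w = _womersley_admittance(a[pos])
        g[pos] = np.real(w)
        h[pos] = -(a[pos] ** 2 / 8.0) * np.imag(w)
    if scalar:
        return float(g[0]), float(h[0])
    return g, h


def line_inertance(alpha0, A0, const: PhysicalConstants = PhysicalConstants()):
    """Inertance per unit length L = g(alpha0) * rho / A0 [kg m^-5]."""
    if np.any(np.asarray(A0) <= 0.0):
        raise ValueError("A0 must be positive")
    g, _ = profile_factors(alpha0)
    return g * const.rho / np.asarray(A0, dtype=float)


def line_resistance(alpha0, A0, const: PhysicalConstants = PhysicalConstants()):
    """Resistance per unit length R = h(alpha0) * 8*pi*eta / A0^2 [Pa s m^-4]."""
    if np.any(np.asarray(A0) <= 0.0):
        raise ValueError("A0 must be positive")
    _, h = profile_factors(alpha0)
    return h * 8.0 * np.pi * const.eta / np.asarray(A0, dtype=float) ** 2


def transmural_pressure(A, params: WallLawParams):
    """Transmural pressure of the nonlinear wall law [Pa]."""
    A = np.asarray(A, dtype=float)
    if np.any(A <= 0.0):
        raise ValueError("lumen area must be positive")
    x = A / params.A0
    out = -params.p_ext + params.p0 * (
        (1.0 + params.b) * x ** (1.0 + params.k / 3.0) - params.b / x
    )
    return out.item() if out.ndim == 0 else out


def dptrans_dA(A, params: WallLawParams):
    """Analytic slope dp_trans/dA [Pa m^-2]; strictly positive for A > 0."""
    A = np.asarray(A, dtype=float)
    if np.any(A <= 0.0):
        raise ValueError("lumen area must be positive")
    x = A / params.A0
    out = (params.p0 / params.A0) * (
        (1.0 + params.b) * (1.0 + params.k / 3.0) * x ** (params.k / 3.0)
        + params.b / x**2
    )
    return out.item() if out.ndim == 0 else out


def compliance(A, params: WallLawParams):
    """Compliance per unit length C = dA/dp_trans [m^3 Pa^-1 m^-1]."""
    return 1.0 / dptrans_dA(A, params)


def area_from_pressure(p, params: WallLawParams, rtol: float = 1e-12):
    """Invert the wall law: lumen area at transmural pressure ``p`` [m^2].

    Newton iteration on log-area; the law is strictly monotone so the
    solution is unique.  Accepts scalars or arrays.
    """
    p = np.atleast_1d(np.asarray(p, dtype=float))
    # initial guess from the power-law branch (ignore the collapse term)
    y = (np.maximum(p + params.p_ext, 0.05 * params.p0) / params.p0) ** (
        1.0 / (1.0 + params.k / 3.0)
    )
    A = y * params.A0
    for _ in range(100):
        f = transmural_pressure(A, params) - p
        df = dptrans_dA(A, params)
        step = f / (df * A)  # Newton in log A
        step = np.clip(step, -0.5, 0.5)
        A = A * np.exp(-step)
        if np.all(np.abs(f) <= rtol * params.p0 + 1e-9):
            break
    else:
        raise RuntimeError("wall-law inversion did not converge")
    return A.item() if np.asarray(p).ndim == 0 or A.size == 1 else A


def wave_coefficients(R, L, C, const: PhysicalConstants = PhysicalConstants()):
    """Wave speed, characteristic impedance and attenuation of a TL section.

    Uses the weak-loss, frequency-independent approximation of the complex
    propagation constant: c = 1/sqrt(LC), Zc = sqrt(L/C), a = R/(2 Zc).
    In the lossless limit R -> 0 the attenuation vanishes.
    """
    R = np.asarray(R, dtype=float)
    L = np.asarray(L, dtype=float)
    C = np.asarray(C, dtype=float)
    if np.any(L <= 0.0) or np.any(C <= 0.0) or np.any(R < 0.0):
        raise ValueError("require L, C > 0 and R >= 0")
    c = 1.0 / np.sqrt(L * C)
    Zc = np.sqrt(L / C)
    attenuation = R / (2.0 * Zc)
    if np.ndim(c) == 0:
        return float(c), float(Zc), float(attenuation)
    return c, Zc, attenuation


def wave_speed_at(p, params: WallLawParams, const: PhysicalConstants = PhysicalConstants()):
    """Local (inviscid) wave speed c = sqrt(A dp/dA / rho) at pressure ``p``."""
    A = area_from_pressure(p, params)
    return np.sqrt(np.asarray(A) * dptrans_dA(A, params) / const.rho)


def segment_coefficients(
    r0, params: WallLawParams, const: PhysicalConstants = PhysicalConstants(),
    operating_pressure: float | None = None,
) -> TLSegmentCoefficients:
    """Bundle all per-unit-length coefficients for a tube of radius ``r0``.

    R and L are evaluated at the reference geometry and characteristic
    frequency (quasi-linear treatment); C at ``operating_pressure``
    (defaults to the reference pressure p0).
    """
    A0 = np.pi * float(r0) ** 2
    alpha0 = womersley_number(r0, const)
    g, h = profile_factors(alpha0)
    L = g * const.rho / A0
    R = h * 8.0 * np.pi * const.eta / A0**2
    p_op = params.p0 - params.p_ext if operating_pressure is None else operating_pressure
    A_op = area_from_pressure(p_op, params)
    C = compliance(A_op, params)
    c, Zc, att = wave_coefficients(R, L, C, const)
    return TLSegmentCoefficients(alpha0=alpha0, g=g, h=h, R=R, L=L, C=C,
                                 c=c, Zc=Zc, attenuation=att)
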