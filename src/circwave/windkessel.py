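"""Nonlinear, pressure-dependent three-element windkessel terminations.

Each terminal artery drains through a three-element windkessel (3WK) into
the matching terminal vein: a wave impedance ``Z_wave`` in series with the
tube, a compliance ``C`` to ground, and the peripheral resistance ``R_p``
bridging the arterial and venous bed nodes (which mirror each other).
Compliance and wave impedance are *not* constants: both are re-evaluated
every step from the vessel wall law at the instantaneous bed pressure,

    C_AV     = l_AV * dA/dp,
    Z_wave   = rho * c / A = sqrt(rho * (dp/dA) / A),

with ``l_AV = 6 * q_AV**(1/3)`` a characteristic bed length estimated from
the mean bed flow (SI units; 85 ml/s for the whole systemic circulation
gives ~0.26 m).  This makes the termination track large changes in
haemodynamic load (hypertension, exercise) without manual re-tuning of
windkessel parameters: raising the reference pressure raises ``R_p``
through the calibration R_p = (p0_art - p0_ven)/q_AV and stiffens the bed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .constitutive import (
    PhysicalConstants,
    WallLawParams,
    area_from_pressure,
    dptrans_dA,
)

__all__ = [
    "bed_length",
    "terminal_coefficients",
    "peripheral_resistance",
    "WindkesselTerminal",
]


def bed_length(q_AV: float) -> float:
    """Characteristic peripheral bed length l_AV = 6*q_AV^(1/3) [m], q in SI."""
    if q_AV < 0:
        raise ValueError("mean bed flow must be non-negative")
    return 6.0 * q_AV ** (1.0 / 3.0)


def terminal_coefficients(A_node: float, wall: WallLawParams, l_AV: float,
                          const: PhysicalConstants = PhysicalConstants()):
    """(C_AV, Z_wave_AV) evaluated from the wall law at the node area.

    Monotonicity of the wall law guarantees dp/dA > 0, hence positive
    compliance and impedance at any physiological pressure.
    """
    dpdA = dptrans_dA(A_node, wall)
    if dpdA <= 0:
        raise ValueError("wall law non-monotonic at evaluation point")
    C_AV = l_AV / dpdA
    Z_wave = float(np.sqrt(const.rho * dpdA / A_node))
    return C_AV, Z_wave


def peripheral_resistance(p_art: float, p_ven: float, q_AV: float) -> float:
    """R_p = (p_art - p_ven)/q_AV [Pa s m^-3]; the scenario-mean calibration."""
    if q_AV <= 0:
        raise ValueError("q_AV must be positive")
    return (p_art - p_ven) / q_AV


@dataclass
class WindkesselTerminal:
    """State of one arterio-venous bed termination.

    The internal unknowns are the two bed pressures ``p_art`` and ``p_ven``
    (behind the arterial and venous wave impedances).  ``step`` advances
    them with the trapezoidal rule, coefficients frozen at the start-of-step
    state, given the attached tube-end pressures; it returns the flows drawn
    from the arterial tube and delivered to the venous tube, evaluated with
    the same trapezoidal averaging so that volume is conserved exactly.
    """

    q_AV: float                 # mean bed flow, m^3/s
    R_p: float                  # peripheral resistance, Pa s m^-3
    wall_art: WallLawParams
    wall_ven: WallLawParams
    const: PhysicalConstants = field(default_factory=PhysicalConstants)
    l_AV: float = field(init=False)
    p_art: float = field(init=False)
    p_ven: float = field(init=False)
    volume_error: float = 0.0   # running bookkeeping check, m^3

    def __post_init__(self) -> None:
        if self.q_AV <= 0:
            raise ValueError("q_AV must be positive")
        if self.R_p <= 0:
            raise ValueError("R_p must be positive")
        self.l_AV = bed_length(self.q_AV)
        self.p_art = self.wall_art.p0 - self.wall_art.p_ext
        self.p_ven = self.wall_ven.p0 - self.wall_ven.p_ext

    # -- coefficient evaluation at current state -------------------------
    def coefficients(self):
        A_a = area_from_pressure(self.p_art, self.wall_art)
        A_v = area_from_pressure(self.p_ven, self.wall_ven)
        C_a, Z_a = terminal_coefficients(A_a, self.wall_art, self.l_AV, self.const)
        C_v, Z_v = terminal_coefficients(A_v, self.wall_ven, self.l_AV, self.const)
        return C_a, Z_a, C_v, Z_v

    def step(self, p_tube_art: float, p_tube_ven: float, dt: float):
        """Advance one dt; returns (q_from_artery, q_into_vein) averages."""
        C_a, Z_a, C_v, Z_v = self.coefficients()
        ga, gv, gp = 1.0 / Z_a, 1.0 / Z_v, 1.0 / self.R_p
        pa0, pv0 = self.p_art, self.p_ven
        # trapezoidal: C (p1-p0)/dt = 0.5*(f(p1) + f(p0)) with frozen C, Z
        # f_a = ga*(p_tube_art - p_a) - gp*(p_a - p_v)
        # f_v = gp*(p_a - p_v) - gv*(p_v - p_tube_ven)
        a11 = C_a / dt + 0.5 * (ga + gp)
        a12 = -0.5 * gp
        a21 = -0.5 * gp
        a22 = C_v / dt + 0.5 * (gp + gv)
        f_a0 = ga * (p_tube_art - pa0) - gp * (pa0 - pv0)
        f_v0 = gp * (pa0 - pv0) - gv * (pv0 - p_tube_ven)
        b1 = C_a / dt * pa0 + 0.5 * (f_a0 + ga * p_tube_art)
        b2 = C_v / dt * pv0 + 0.5 * (f_v0 + gv * p_tube_ven)
        det = a11 * a22 - a12 * a21
        pa1 = (b1 * a22 - a12 * b2) / det
        pv1 = (a11 * b2 - a21 * b1) / det
        q_in = ga * (p_tube_art - 0.5 * (pa0 + pa1))
        q_out = gv * (0.5 * (pv0 + pv1) - p_tube_ven)
        # volume bookkeeping: stored change must equal net in - out
        dV_store = C_a * (pa1 - pa0) + C_v * (pv1 - pv0)
        self.volume_error += dV_store - (q_in - q_out) * dt
        self.p_art, self.p_ven = pa1, pv1
        return q_in, q_out
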