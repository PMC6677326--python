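"""Closed-loop cardiac driver: chambers, valves, pericardium, lungs.

The four cardiac chambers are contractile cavities described by the
one-fibre model: assuming homogeneously distributed myofibre stress in a
thick wall, the transmural pressure of a chamber with cavity volume ``V``
and wall volume ``Vw`` is

    p_trans = (sigma_f / 3) * ln(1 + Vw / V),

where ``sigma_f`` is total Cauchy myofibre stress — an active twitch
contribution scaled by a periodic activation waveform and a sarcomere
length-dependence, plus a nonlinear passive contribution from titin and
extracellular matrix acting in parallel.  Sarcomere length follows from
cavity-plus-one-third-wall volume, the natural one-fibre kinematic measure.
Cavity pressure adds the pericardial pressure: the pericardium is a
compliant bag with a stiffening nonlinear pressure-volume relation in the
total heart volume.

Valves obey the unsteady Bernoulli equation

    rho l_v / A_v  dq/dt = dp - rho/2 q|q| (1/A_v^2 - 1/A_p^2),

with a phenomenological orifice: the effective area opens instantaneously
to ``A_open`` on a positive pressure gradient and relaxes exponentially to
a quasi-closed leak area on a negative one (the leak avoids a division by
zero and permits the brief physiological backflow at closure).

The pulmonary circulation is one nonlinear three-element windkessel
(pressure-dependent compliances and venous wave impedance, identical
machinery to the systemic beds) connecting the pulmonary artery node to
the pulmonary venous node that fills the left atrium.

The driver advances with sub-steps inside each vascular time step
(semi-implicit in the stiff valve terms), exchanging boundary flows with
the TL network: the aortic valve flow is a source on the aortic root node
and the vena-cava return, computed by the network, is committed to the
right atrium afterwards so that total blood volume is conserved exactly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .constitutive import MMHG, PhysicalConstants, WallLawParams, area_from_pressure, dptrans_dA
from .windkessel import bed_length

__all__ = ["Valve", "CardiacChamber", "Pericardium", "PulmonaryBed", "Heart",
           "valve_rhs", "valve_area_update", "inflow_halfsine",
           "activation_waveform"]


# ---------------------------------------------------------------------------
# valves
# ---------------------------------------------------------------------------

@dataclass
class Valve:
    """Unsteady-Bernoulli valve with phenomenological opening dynamics."""

    name: str
    A_open: float            # m^2, fully open effective area
    A_p: float               # m^2, area proximal to the valve
    A_leak: float = 5e-7     # m^2, quasi-closed leak area
    l_valve: float = 0.016   # m, effective length
    tau_close: float = 0.003  # s, closing time constant
    A_valve: float = field(init=False)
    q: float = 0.0

    def __post_init__(self) -> None:
        if not 0 < self.A_leak <= self.A_open:
            raise ValueError("need 0 < A_leak <= A_open")
        self.A_valve = self.A_leak


def valve_rhs(valve: Valve, dp: float, const: PhysicalConstants = PhysicalConstants()) -> float:
    """dq/dt of the unsteady Bernoulli valve equation [m^3 s^-2]."""
    if valve.A_valve <= 0:
        raise ValueError("valve area must be positive")
    B = 0.5 * const.rho * (1.0 / valve.A_valve**2 - 1.0 / valve.A_p**2)
    return (dp - B * valve.q * abs(valve.q)) * valve.A_valve / (const.rho * valve.l_valve)


def valve_area_update(valve: Valve, dp: float, dt: float) -> float:
    """Advance the effective orifice area by dt and return it.

    Positive gradient: instantaneous opening.  Negative: exponential decay
    towards the quasi-closed leak area, never zero.
    """
    if dp > 0:
        valve.A_valve = valve.A_open
    else:
        f = math.exp(-dt / valve.tau_close)
        valve.A_valve = valve.A_leak + (valve.A_valve - valve.A_leak) * f
    return valve.A_valve


def _valve_step(valve: Valve, dp: float, dt: float, rho: float,
                z_src: float = 0.0, q_ref: float = 0.0) -> float:
    """Semi-implicit flow update (implicit in the quadratic loss).

    ``z_src`` is an optional source impedance of the receiving vessel:
    the downstream pressure is modelled as rising by z_src*(q - q_ref)
    around the step-start operating point, which represents the wave the
    valve flow launches into the attached transmission line and keeps the
    staggered valve/network coupling stable.
    """
    valve_area_update(valve, dp - z_src * (valve.q - q_ref), dt)
    M = rho * valve.l_valve / valve.A_valve
    B = 0.5 * rho * (1.0 / valve.A_valve**2 - 1.0 / valve.A_p**2)
    q0 = valve.q
    valve.q = ((q0 + dt * (dp + z_src * q_ref) / M)
               / (1.0 + dt * (z_src + B * abs(q0)) / M))
    return valve.q


# ---------------------------------------------------------------------------
# activation and chambers
# ---------------------------------------------------------------------------

def activation_waveform(tau: float, t_rise: float, t_plateau: float,
                        t_decay: float, T: float) -> float:
    """Raised-cosine twitch, periodic with the cycle; 0 outside the twitch."""
    tau = tau % T
    if tau < t_rise:
        return 0.5 * (1.0 - math.cos(math.pi * tau / t_rise))
    tau -= t_rise
    if tau < t_plateau:
        return 1.0
    tau -= t_plateau
    if tau < t_decay:
        return 0.5 * (1.0 + math.cos(math.pi * tau / t_decay))
    return 0.0


@dataclass
class CardiacChamber:
    """One-fibre contractile cavity."""

    name: str
    Vw: float                # wall volume, m^3
    V_ref: float             # cavity volume at sarcomere reference length, m^3
    sigma_act: float         # peak active myofibre stress, Pa
    sigma_pas: float         # passive stress scale, Pa
    k_pas: float = 10.0      # passive stiffness exponent
    Ls_ref: float = 2.0      # sarcomere reference length, um
    Ls_act0: float = 1.40    # zero-active-force sarcomere length, um
    Ls_pas0: float = 1.8     # passive slack sarcomere length, um
    t_onset: float = 0.0     # activation onset within the cycle, s
    t_rise: float = 0.13
    t_plateau: float = 0.10
    t_decay: float = 0.15
    eta_visc: float = 6e2    # myocardial viscosity, Pa s (force-velocity damping)
    V: float = field(init=False)
    dVdt: float = field(init=False, default=0.0)

    def __post_init__(self) -> None:
        if min(self.Vw, self.V_ref, self.sigma_act, self.sigma_pas) <= 0:
            raise ValueError(f"{self.name}: volumes and stresses must be positive")
        self.V = self.V_ref

    def sarcomere_length(self, V: float | None = None) -> float:
        V = self.V if V is None else V
        Vm = V + self.Vw / 3.0
        Vm_ref = self.V_ref + self.Vw / 3.0
        return self.Ls_ref * (Vm / Vm_ref) ** (1.0 / 3.0)

    def fibre_stress(self, activation: float, V: float | None = None) -> float:
        Ls = self.sarcomere_length(V)
        f_len = max(0.0, (Ls - self.Ls_act0) / (self.Ls_ref - self.Ls_act0))
        s_act = self.sigma_act * activation * f_len
        x = Ls / self.Ls_pas0
        s_pas = self.sigma_pas * (x ** self.k_pas - 1.0)
        return s_act + s_pas

    def transmural_pressure(self, activation: float, V: float | None = None,
                            dVdt: float | None = None) -> float:
        V = self.V if V is None else V
        V = max(V, 1e-6)  # numerical floor, 1 ml
        dVdt = self.dVdt if dVdt is None else dVdt
        # viscous myofibre stress resists rapid shortening/lengthening
        # (strain rate ~ volume rate over the one-fibre kinematic volume)
        sigma = (self.fibre_stress(activation, V)
                 + self.eta_visc * dVdt / (V + self.Vw / 3.0))
        return sigma / 3.0 * math.log1p(self.Vw / V)

    def activation(self, t: float, T: float) -> float:
        return activation_waveform(t - self.t_onset, self.t_rise,
                                   self.t_plateau, self.t_decay, T)

    def pressure(self, t: float, T: float, pericardial_p: float = 0.0) -> float:
        """Cavity pressure = one-fibre transmural + pericardial pressure."""
        return self.transmural_pressure(self.activation(t, T)) + pericardial_p


@dataclass
class Pericardium:
    """Compliant bag: p = p_ref * (V/V_ref)^n, near zero below V_ref."""

    V_ref: float = 650e-6
    p_ref: float = 0.4 * MMHG
    n: float = 10.0

    def pressure(self, total_heart_volume: float) -> float:
        if total_heart_volume <= 0:
            return 0.0
        return self.p_ref * (total_heart_volume / self.V_ref) ** self.n


# ---------------------------------------------------------------------------
# pulmonary windkessel
# ---------------------------------------------------------------------------

@dataclass
class PulmonaryBed:
    """Nonlinear 3WK between the pulmonary valve and the left atrium."""

    q_ref: float = 85e-6
    p0_art: float = 15.0 * MMHG
    p0_ven: float = 8.0 * MMHG
    r_art: float = 0.0135
    r_ven: float = 0.0140
    k_art: float = 4.0
    k_ven: float = 6.0
    p_art: float = field(init=False)
    p_ven: float = field(init=False)

    def __post_init__(self) -> None:
        self.R_p = (self.p0_art - self.p0_ven) / self.q_ref
        self.l_AV = bed_length(self.q_ref)
        self.wall_art = WallLawParams(p0=self.p0_art, A0=math.pi * self.r_art**2,
                                      k=self.k_art, b=0.02)
        self.wall_ven = WallLawParams(p0=self.p0_ven, A0=math.pi * self.r_ven**2,
                                      k=self.k_ven, b=0.02)
        self.p_art = self.p0_art
        self.p_ven = self.p0_ven
        # volume is the primary state; pressure follows from the wall law
        self.A_art = area_from_pressure(self.p_art, self.wall_art)
        self.A_ven = area_from_pressure(self.p_ven, self.wall_ven)

    def coefficients(self, rho: float):
        da = dptrans_dA(self.A_art, self.wall_art)
        dv = dptrans_dA(self.A_ven, self.wall_ven)
        C_a = self.l_AV / da
        C_v = self.l_AV / dv
        Z_v = math.sqrt(rho * dv / self.A_ven)
        return C_a, C_v, Z_v

    def add_volume(self, dV_art: float, dV_ven: float) -> None:
        from .constitutive import transmural_pressure
        self.A_art += dV_art / self.l_AV
        self.A_ven += dV_ven / self.l_AV
        self.p_art = float(transmural_pressure(self.A_art, self.wall_art))
        self.p_ven = float(transmural_pressure(self.A_ven, self.wall_ven))

    def volume(self) -> float:
        return self.l_AV * (self.A_art + self.A_ven)


# ---------------------------------------------------------------------------
# the complete heart
# ---------------------------------------------------------------------------

def default_chambers(T: float = 0.85, contractility: float = 1.0,
                     av_delay: float = 0.17) -> dict[str, CardiacChamber]:
    """Chamber parameter set calibrated for the normotensive closed loop."""
    return {
        "lv": CardiacChamber("lv", Vw=140e-6, V_ref=90e-6,
                             sigma_act=65e3 * contractility, sigma_pas=700.0,
                             t_onset=av_delay, t_rise=0.16, t_plateau=0.08,
                             t_decay=0.20),
        "rv": CardiacChamber("rv", Vw=45e-6, V_ref=95e-6,
                             sigma_act=40e3 * contractility, sigma_pas=500.0,
                             t_onset=av_delay, t_rise=0.16, t_plateau=0.08,
                             t_decay=0.20),
        "la": CardiacChamber("la", Vw=22e-6, V_ref=55e-6,
                             sigma_act=24e3, sigma_pas=3000.0, k_pas=8.0,
                             t_onset=0.0, t_rise=0.09, t_plateau=0.0,
                             t_decay=0.11),
        "ra": CardiacChamber("ra", Vw=15e-6, V_ref=60e-6,
                             sigma_act=9e3, sigma_pas=2000.0, k_pas=8.0,
                             t_onset=0.0, t_rise=0.09, t_plateau=0.0,
                             t_decay=0.11),
    }


def default_valves() -> dict[str, Valve]:
    return {
        "mv": Valve("mv", A_open=7.0e-4, A_p=9.0e-4),
        "av": Valve("av", A_open=5.0e-4, A_p=7.0e-4),
        "tv": Valve("tv", A_open=8.0e-4, A_p=9.0e-4),
        "pv": Valve("pv", A_open=5.5e-4, A_p=7.0e-4),
    }


class Heart:
    """Closed-loop driver coupling chambers, valves and the pulmonary bed.

    ``presolve`` integrates the cardiac state over one vascular step with
    ``n_substeps`` semi-implicit sub-steps (boundary pressures frozen) and
    returns the step-average aortic valve flow plus the frozen right-atrial
    pressure; ``commit`` books the vena-cava return computed by the network.
    """

    def __init__(self, const: PhysicalConstants = PhysicalConstants(),
                 chambers: dict | None = None, valves: dict | None = None,
                 pericardium: Pericardium | None = None,
                 pulmonary: PulmonaryBed | None = None,
                 n_substeps: int = 10, ramp_cycles: float = 3.0):
        self.const = const
        self.ch = chambers or default_chambers(const.T)
        self.valves = valves or default_valves()
        self.pericardium = pericardium or Pericardium()
        self.pulmonary = pulmonary or PulmonaryBed()
        self.n_substeps = n_substeps
        self.ramp_cycles = ramp_cycles
        self.p_ra_frozen = 2.0 * MMHG
        self.t = 0.0
        self._samples: dict[str, float] = {}
        # reasonable diastolic starting volumes
        self.ch["lv"].V = 120e-6
        self.ch["rv"].V = 120e-6
        self.ch["la"].V = 60e-6
        self.ch["ra"].V = 60e-6

    # -- helpers ---------------------------------------------------------
    def total_heart_volume(self) -> float:
        return (sum(c.V for c in self.ch.values())
                + sum(c.Vw for c in self.ch.values()))

    def total_volume(self) -> float:
        """Blood volume held by the heart + pulmonary bed."""
        return sum(c.V for c in self.ch.values()) + self.pulmonary.volume()

    def _act_scale(self, t: float) -> float:
        """Contractility ramp over the first cycles for a gentle start-up."""
        if self.ramp_cycles <= 0:
            return 1.0
        return min(1.0, 0.25 + 0.75 * t / (self.ramp_cycles * self.const.T))

    def chamber_pressures(self, t: float) -> dict[str, float]:
        T = self.const.T
        p_peri = self.pericardium.pressure(self.total_heart_volume())
        scale = self._act_scale(t)
        return {name: c.transmural_pressure(scale * c.activation(t % T, T)) + p_peri
                for name, c in self.ch.items()}

    # -- coupling protocol ----------------------------------------------
    def presolve(self, t: float, dt: float, p_ao: float, p_vc: float,
                 z_ao: float = 0.0) -> dict:
        rho = self.const.rho
        T = self.const.T
        h = dt / self.n_substeps
        lv, rv, la, ra = (self.ch[k] for k in ("lv", "rv", "la", "ra"))
        mv, av, tv, pv = (self.valves[k] for k in ("mv", "av", "tv", "pv"))
        pul = self.pulmonary
        self.p_ra_frozen = self.chamber_pressures(t)["ra"]
        q_av_ref = av.q
        q_av_int = 0.0
        for i in range(self.n_substeps):
            tl = t + i * h
            pr = self.chamber_pressures(tl)
            C_pa, C_pv, Z_pv = pul.coefficients(rho)
            # valve flows (chamber/bed pressures frozen within substep);
            # the aortic valve sees the root's wave impedance as load line
            q_mv = _valve_step(mv, pr["la"] - pr["lv"], h, rho)
            q_av = _valve_step(av, pr["lv"] - p_ao, h, rho,
                               z_src=z_ao, q_ref=q_av_ref)
            q_tv = _valve_step(tv, pr["ra"] - pr["rv"], h, rho)
            q_pv = _valve_step(pv, pr["rv"] - pul.p_art, h, rho)
            # pulmonary bed (volume-conservative explicit substep)
            g_pp = 1.0 / pul.R_p
            g_zv = 1.0 / Z_pv
            q_pp = g_pp * (pul.p_art - pul.p_ven)
            q_la_in = g_zv * (pul.p_ven - pr["la"])
            pul.add_volume(h * (q_pv - q_pp), h * (q_pp - q_la_in))
            # chamber volumes (store rates for the viscous stress term)
            lv.dVdt = q_mv - q_av
            la.dVdt = q_la_in - q_mv
            rv.dVdt = q_tv - q_pv
            ra.dVdt = -q_tv
            lv.V += h * lv.dVdt
            la.V += h * la.dVdt
            rv.V += h * rv.dVdt
            ra.V += h * ra.dVdt
            q_av_int += q_av * h
        self.t = t + dt
        pr = self.chamber_pressures(self.t)
        self._samples = {
            "p_lv": pr["lv"], "p_rv": pr["rv"], "p_la": pr["la"], "p_ra": pr["ra"],
            "v_lv": lv.V, "v_rv": rv.V, "v_la": la.V, "v_ra": ra.V,
            "p_pa": pul.p_art, "p_pv": pul.p_ven,
            "q_mv": mv.q, "q_av": av.q, "q_tv": tv.q, "q_pv": pv.q,
        }
        return {"q_av": q_av_int / dt, "p_ra": self.p_ra_frozen}

    def commit(self, q_vc: float, dt: float) -> None:
        """Book the vena-cava return (network-consistent) into the RA."""
        self.ch["ra"].V += q_vc * dt

    def sample(self) -> dict[str, float]:
        return dict(self._samples)

    def valve_areas(self) -> dict[str, float]:
        return {name: v.A_valve for name, v in self.valves.items()}


# ---------------------------------------------------------------------------
# benchmark inflow (heart bypassed)
# ---------------------------------------------------------------------------

def inflow_halfsine(t: float, q_p: float, t_c: float, T: float) -> float:
    """Half-sinusoid root inflow: q_p*sin(pi t/t_c) for t in [0, t_c], else 0."""
    if t_c >= T:
        raise ValueError("half-sine duration must be below the period")
    if t < 0:
        raise ValueError("time must be non-negative")
    tau = t % T
    return q_p * math.sin(math.pi * tau / t_c) if tau <= t_c else 0.0
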