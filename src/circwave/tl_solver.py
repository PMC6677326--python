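"""Time-domain transmission-line solver for vascular networks.

The discretized tree is a ladder system: every element carries one flow
unknown governed by

    L_e dq/dt + R_e q = p_prox - p_dist,

and every node one pressure unknown governed by

    C_node dp/dt = sum(inflows) - sum(outflows),

where ``C_node`` is the sum of the adjacent half-element compliances
evaluated from the nonlinear wall law at the node's current pressure.
Junctions are ideal: a single nodal pressure and exact flow conservation,
no loss coefficients.

Time integration is implicit trapezoidal (Crank-Nicolson), A-stable and
second order, with the pressure-dependent compliances and windkessel
coefficients frozen at the start-of-step state (semi-implicit treatment of
the nonlinearity).  Terminal windkessels and, in closed-loop mode, the
coupling conductances to the heart are part of the same linear solve, so
nodal mass conservation holds to solver precision at every step.

Two modes:

* open (benchmark) mode -- a prescribed inflow waveform drives the root
  node and every terminal windkessel drains to a fixed venous pressure;
* closed-loop mode -- an arterial and a venous tree are bridged by the
  windkessel beds, and a heart model supplies the aortic inflow and
  receives the vena-cava return (see :mod:`circwave.heart`).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .analysis import SignalTrace
from .constitutive import MMHG, PhysicalConstants, WallLawParams, area_from_pressure, dptrans_dA
from .network import DiscretizedNetwork
from .windkessel import bed_length

__all__ = ["TerminalBridge", "TLSystem", "SimulationResult", "SolverDivergence"]


class SolverDivergence(RuntimeError):
    pass


@dataclass
class TerminalBridge:
    """One 3WK bed bridging an arterial leaf to a venous leaf (or fixed p).

    ``ven_node`` is a global node index of the venous tree in closed-loop
    mode, or ``None`` in open mode, in which case the bed drains to the
    fixed pressure ``p_ven_fixed``.
    """

    art_node: int
    q_AV: float
    R_p: float
    wall_art: WallLawParams
    wall_ven: WallLawParams
    ven_node: int | None = None
    p_ven_fixed: float = 1.1 * MMHG
    label: str = ""
    l_AV: float = field(init=False)

    def __post_init__(self) -> None:
        self.l_AV = bed_length(self.q_AV)


@dataclass
class SimulationResult:
    """Uniformly sampled traces of the last recorded cycles plus diagnostics."""

    dt: float
    T: float
    traces: dict[str, SignalTrace]
    cycles_run: int
    converged: bool
    periodicity_residual_mmhg: float
    valve_states: dict[str, np.ndarray] = field(default_factory=dict)
    heart_traces: dict[str, np.ndarray] = field(default_factory=dict)
    volume_drift_ml: float = 0.0
    mean_systemic_flow_ml_s: float = float("nan")


def _wk_coeffs(p, wall, l_AV, rho):
    A = area_from_pressure(p, wall)
    dpdA = dptrans_dA(A, wall)
    C = l_AV / dpdA
    Z = float(np.sqrt(rho * dpdA / A))
    return C, Z


class TLSystem:
    """Assembled TL ladder over one or two trees plus terminal beds.

    Parameters
    ----------
    networks : list of DiscretizedNetwork
        One (open mode) or two (arterial, venous) discretized trees.
    bridges : list of TerminalBridge
        Terminal windkessels; ``art_node``/``ven_node`` are *global* node
        indices (venous tree nodes offset by the arterial node count).
    inflow : callable t -> m^3/s, optional
        Prescribed source at the arterial root (open mode).
    heart : object, optional
        Closed-loop driver implementing ``presolve``/``commit`` (see
        :class:`circwave.heart.Heart`).
    """

    def __init__(self, networks, bridges, inflow=None, heart=None,
                 const: PhysicalConstants = PhysicalConstants(),
                 ven_root_impedance: float | None = None,
                 loads=(), theta: float = 0.5):
        #: implicit weight of the one-step scheme (0.5 = trapezoidal;
        #: slightly larger adds high-frequency damping, still ~2nd order)
        self.theta = theta
        #: static resistive loads: (global node, conductance, fixed pressure)
        self.loads = list(loads)
        self.networks = list(networks)
        self.bridges = list(bridges)
        self.inflow = inflow
        self.heart = heart
        self.const = const

        self.node_offset = []
        off = 0
        for net in self.networks:
            self.node_offset.append(off)
            off += net.n_nodes
        self.n_nodes = off
        self.elem_offset = []
        off = 0
        for net in self.networks:
            self.elem_offset.append(off)
            off += net.n_elements
        self.n_elem = off

        self.e_prox = np.concatenate([net.e_prox + no for net, no in
                                      zip(self.networks, self.node_offset)])
        self.e_dist = np.concatenate([net.e_dist + no for net, no in
                                      zip(self.networks, self.node_offset)])
        self.e_R = np.concatenate([net.e_R for net in self.networks])
        self.e_L = np.concatenate([net.e_L for net in self.networks])

        self.art_root = self.node_offset[0] + self.networks[0].root
        # characteristic impedance of the root element (valve load line)
        net0 = self.networks[0]
        wall0 = WallLawParams(p0=net0.e_p0[0], A0=net0.e_A0[0],
                              k=net0.e_k[0], b=net0.e_b[0], p_ext=net0.e_pext[0])
        C_len0 = 1.0 / dptrans_dA(net0.e_A0[0], wall0)
        self.z_art_root = float(np.sqrt((net0.e_L[0] / net0.e_dz[0]) / C_len0))
        self.ven_root = (self.node_offset[1] + self.networks[1].root
                         if len(self.networks) > 1 else None)
        # vena-cava -> atrium coupling conductance (closed loop)
        self.g_ven_root = (1.0 / ven_root_impedance
                           if ven_root_impedance else 0.0)

        self.n_wk = len(self.bridges)
        # unknown layout: [p (n_nodes) | q (n_elem) | p_a, p_v per bed]
        self.iq0 = self.n_nodes
        self.iwk0 = self.n_nodes + self.n_elem
        self.dim = self.iwk0 + 2 * self.n_wk

        # initial state
        self.p = np.zeros(self.n_nodes)
        for net, no in zip(self.networks, self.node_offset):
            self.p[no:no + net.n_nodes] = net.e_p0.mean() - net.e_pext.mean()
        self.q = np.zeros(self.n_elem)
        self.wk_pa = np.array([b.wall_art.p0 - b.wall_art.p_ext for b in self.bridges])
        self.wk_pv = np.array([b.wall_ven.p0 - b.wall_ven.p_ext for b in self.bridges])
        # vectorized wall-law parameter arrays + warm-started area caches
        def _wk_param(attr, side):
            return np.array([getattr(getattr(b, side), attr) for b in self.bridges])
        self._wkp = {side: {attr: _wk_param(attr, side)
                            for attr in ("p0", "A0", "k", "b", "p_ext")}
                     for side in ("wall_art", "wall_ven")}
        self._wk_lav = np.array([b.l_AV for b in self.bridges])
        self.wk_Aa = np.array([area_from_pressure(p, b.wall_art)
                               for p, b in zip(self.wk_pa, self.bridges)])
        self.wk_Av = np.array([area_from_pressure(p, b.wall_ven)
                               for p, b in zip(self.wk_pv, self.bridges)])
        self.A_caches = [net.initial_area_cache(self.p[no:no + net.n_nodes])
                         for net, no in zip(self.networks, self.node_offset)]
        self.node_V = np.concatenate([net.node_volumes(cache) for net, cache in
                                      zip(self.networks, self.A_caches)])
        self.wk_Va = self._wk_lav * self.wk_Aa
        self.wk_Vv = self._wk_lav * self.wk_Av
        self.t = 0.0
        # volume-control source at the venous root (closed loop), m^3/s
        self.volume_control_flow = 0.0
        self._last_residual = 0.0
        self._struct = None

    # -- contract-level counts -------------------------------------------
    @property
    def n_flow_unknowns(self) -> int:
        return self.n_elem

    @property
    def n_pressure_unknowns(self) -> int:
        return self.n_nodes

    # ------------------------------------------------------------------
    def nodal_compliance(self) -> np.ndarray:
        Cn = np.zeros(self.n_nodes)
        for net, no, cache in zip(self.networks, self.node_offset, self.A_caches):
            Cn[no:no + net.n_nodes] += net.nodal_compliance(
                self.p[no:no + net.n_nodes], cache)
        return Cn

    def _wk_side(self, side, p, A):
        """(C, Z) arrays evaluated at the current (volume-consistent) areas."""
        prm = self._wkp[side]
        p0, A0, k, b = prm["p0"], prm["A0"], prm["k"], prm["b"]
        x = A / A0
        dpdA = (p0 / A0) * ((1.0 + b) * (1.0 + k / 3.0) * x ** (k / 3.0) + b / x**2)
        C = self._wk_lav / dpdA
        Z = np.sqrt(self.const.rho * dpdA / A)
        return C, Z

    def _wk_pressure(self, side, A):
        """Transmural pressure of the bed wall law at area A (vectorized)."""
        prm = self._wkp[side]
        x = A / prm["A0"]
        return (-prm["p_ext"] + prm["p0"]
                * ((1.0 + prm["b"]) * x ** (1.0 + prm["k"] / 3.0) - prm["b"] / x))

    def _wk_arrays(self):
        """Per-bed coefficients at the current state (vectorized)."""
        if self.n_wk == 0:
            z = np.empty(0)
            return z, z, z, z
        C_a, Z_a = self._wk_side("wall_art", self.wk_pa, self.wk_Aa)
        C_v, Z_v = self._wk_side("wall_ven", self.wk_pv, self.wk_Av)
        return C_a, Z_a, C_v, Z_v

    def _structure(self):
        """Fixed (row, col) pattern of the step matrix, built once."""
        if self._struct is not None:
            return self._struct
        iq0, iwk0 = self.iq0, self.iwk0
        nn, ne, nw = self.n_nodes, self.n_elem, self.n_wk
        qi = iq0 + np.arange(ne)
        wa = np.array([br.art_node for br in self.bridges], dtype=int)
        has_ven = np.array([br.ven_node is not None for br in self.bridges])
        wv = np.array([br.ven_node if br.ven_node is not None else 0
                       for br in self.bridges], dtype=int)
        ia = iwk0 + 2 * np.arange(nw)
        iv = ia + 1
        rows = [np.arange(nn), self.e_prox, self.e_dist,
                qi, qi, qi,
                wa, wa, ia, ia, ia, iv, iv]
        cols = [np.arange(nn), qi, qi,
                qi, self.e_prox, self.e_dist,
                wa, ia, ia, wa, iv, iv, ia]
        if np.any(has_ven):
            hv = np.flatnonzero(has_ven)
            rows += [iv[hv], wv[hv], wv[hv]]
            cols += [wv[hv], wv[hv], iv[hv]]
        self._struct = (np.concatenate(rows), np.concatenate(cols),
                        qi, wa, wv, has_ven, ia, iv)
        return self._struct

    def _assemble(self, dt, sources, g_extra, gp_extra):
        """Build the trapezoidal system  M x1 = b  for one step (vectorized).

        sources : array (n_nodes) of step-average external inflows.
        g_extra : array (n_nodes) of total conductances to fixed external
                  pressures; gp_extra their conductance-weighted pressures
                  (e.g. atria, matched loads).  The nodal pressure enters
                  implicitly, the external pressure explicitly.
        """
        rows, cols, qi, wa, wv, has_ven, ia_idx, iv_idx = self._structure()
        Cn = self.nodal_compliance()
        inv = 1.0 / dt
        th = self.theta
        om = 1.0 - th
        nn, ne, nw = self.n_nodes, self.n_elem, self.n_wk
        C_a, Z_a, C_v, Z_v = self._wk_arrays()
        self._step_C = (Cn, C_a, C_v)
        ga, gv = 1.0 / Z_a, 1.0 / Z_v
        gp = np.array([1.0 / br.R_p for br in self.bridges])
        pa0, pv0 = self.wk_pa, self.wk_pv
        pn0 = self.p[wa] if nw else np.empty(0)
        pt0 = np.where(has_ven, self.p[wv] if nw else 0.0,
                       np.array([br.p_ven_fixed for br in self.bridges])) if nw \
            else np.empty(0)

        vals = [Cn * inv + th * g_extra,             # node diagonal
                np.full(ne, th), np.full(ne, -th),    # incidence (prox, dist)
                self.e_L * inv + th * self.e_R,       # momentum diag
                np.full(ne, -th), np.full(ne, th),    # momentum p couplings
                th * ga, -th * ga,                    # tube node <- bed
                C_a * inv + th * (ga + gp),           # bed art diag
                -th * ga, -th * gp,                   # bed art couplings
                C_v * inv + th * (gp + gv),           # bed ven diag
                -th * gp]                             # bed ven <- bed art
        if np.any(has_ven):
            hv = np.flatnonzero(has_ven)
            vals += [-th * gv[hv], th * gv[hv], -th * gv[hv]]
        M = sp.coo_matrix((np.concatenate(vals), (rows, cols)),
                          shape=(self.dim, self.dim)).tocsc()

        rhs = np.zeros(self.dim)
        rhs[:nn] = (Cn * inv * self.p
                    + gp_extra - om * g_extra * self.p + sources)
        np.add.at(rhs, self.e_prox, -om * self.q)
        np.add.at(rhs, self.e_dist, om * self.q)
        rhs[qi] = (self.e_L * inv * self.q - om * self.e_R * self.q
                   + om * (self.p[self.e_prox] - self.p[self.e_dist]))
        if nw:
            np.add.at(rhs, wa, -om * ga * (pn0 - pa0))
            rhs[ia_idx] = (C_a * inv * pa0
                           + om * (ga * (pn0 - pa0) - gp * (pa0 - pv0)))
            rhs[iv_idx] = (C_v * inv * pv0
                           + om * (gp * (pa0 - pv0) - gv * (pv0 - pt0)))
            fixed = ~has_ven
            if np.any(fixed):
                rhs[iv_idx[fixed]] += th * gv[fixed] * pt0[fixed]
            if np.any(has_ven):
                hv = np.flatnonzero(has_ven)
                np.add.at(rhs, wv[hv], om * gv[hv] * (pv0[hv] - self.p[wv[hv]]))
        return M, rhs

    # ------------------------------------------------------------------
    def step(self, dt: float):
        """Advance the full system by one time step."""
        if dt <= 0:
            raise ValueError("dt must be positive")
        sources = np.zeros(self.n_nodes)
        g_extra = np.zeros(self.n_nodes)
        gp_extra = np.zeros(self.n_nodes)
        for node, g, pref in self.loads:
            g_extra[node] += g
            gp_extra[node] += g * pref

        q_av_step = 0.0
        if self.inflow is not None:
            q_av_step = 0.5 * (self.inflow(self.t) + self.inflow(self.t + dt))
            sources[self.art_root] += q_av_step
        if self.heart is not None:
            hb = self.heart.presolve(self.t, dt,
                                     p_ao=self.p[self.art_root],
                                     p_vc=self.p[self.ven_root],
                                     z_ao=self.z_art_root)
            sources[self.art_root] += hb["q_av"]
            g_extra[self.ven_root] += self.g_ven_root
            gp_extra[self.ven_root] += self.g_ven_root * hb["p_ra"]
        if self.volume_control_flow and self.ven_root is not None:
            sources[self.ven_root] += self.volume_control_flow

        M, rhs = self._assemble(dt, sources, g_extra, gp_extra)
        x = spla.splu(M).solve(rhs)
        if not np.all(np.isfinite(x)):
            bad = np.flatnonzero(~np.isfinite(x))[0]
            raise SolverDivergence(f"non-finite state at unknown {bad} (t={self.t:.4f})")

        p1 = x[:self.n_nodes]
        q1 = x[self.iq0:self.iq0 + self.n_elem]
        # mass-conservation residual of the solved step (diagnostic)
        full_res = M @ x - rhs
        self._last_residual = float(np.max(np.abs(full_res[:self.n_nodes])))

        p_vc_lin = p1[self.ven_root] if self.ven_root is not None else 0.0
        # conservative update: the node equation guarantees C*(p1-p0) equals
        # the net discrete inflow, so advance stored volumes exactly and
        # re-derive pressures from the wall law (kills quadrature bias that
        # would otherwise bleed volume from the closed loop)
        Cn, C_a, C_v = self._step_C
        self.node_V += Cn * (p1 - self.p)
        for net, no, cache in zip(self.networks, self.node_offset, self.A_caches):
            sl = slice(no, no + net.n_nodes)
            p1[sl] = net.pressure_from_volume(p1[sl], self.node_V[sl], cache)
        if self.n_wk:
            pa1 = x[self.iwk0::2][:self.n_wk]
            pv1 = x[self.iwk0 + 1::2][:self.n_wk]
            self.wk_Va += C_a * (pa1 - self.wk_pa)
            self.wk_Vv += C_v * (pv1 - self.wk_pv)
            self.wk_Aa = self.wk_Va / self._wk_lav
            self.wk_Av = self.wk_Vv / self._wk_lav
            pa1 = self._wk_pressure("wall_art", self.wk_Aa)
            pv1 = self._wk_pressure("wall_ven", self.wk_Av)

        if self.heart is not None:
            # use the pre-correction pressure: exactly the flow the network
            # booked for the vena-cava -> atrium exchange this step
            p_vc_avg = ((1.0 - self.theta) * self.p[self.ven_root]
                        + self.theta * p_vc_lin)
            q_vc = self.g_ven_root * (p_vc_avg - self.heart.p_ra_frozen)
            self.heart.commit(q_vc, dt)

        self.p = p1
        self.q = q1
        if self.n_wk:
            self.wk_pa = pa1
            self.wk_pv = pv1
        self.t += dt
        return self

    def mass_residual(self) -> float:
        """Max nodal mass-conservation residual of the last step [m^3/s]."""
        return self._last_residual

    # ------------------------------------------------------------------
    def simulate(self, n_cycles: int, dt: float | None = None,
                 convergence_tol_mmhg: float = 0.1,
                 probes: dict | None = None,
                 control=None, min_cycles: int = 3) -> SimulationResult:
        """Run whole cardiac cycles until periodic convergence.

        ``probes`` maps labels to ("p", global_node) or ("q", global_elem)
        or ("wk", bed_index, "pa"|"pv").  ``control`` is an optional
        per-cycle callback (system, cycle_index, mean_root_flow,
        periodicity_residual_mmhg) used by the closed-loop volume
        regulation; convergence is only declared on cycles where the
        control reports itself inactive (returns False).
        """
        if n_cycles < 1:
            raise ValueError("n_cycles must be >= 1")
        T = self.const.T
        dt = T / round(T / (dt or 1e-3))
        n_per = round(T / dt)
        probes = probes or {}
        prev_cycle_p = None
        residual = np.inf
        converged = False
        cycles_run = 0
        rec = {k: np.empty(n_per) for k in probes}
        heart_rec: dict[str, np.ndarray] = {}
        valve_rec: dict[str, np.ndarray] = {}
        q_av_int = 0.0
        for cyc in range(n_cycles):
            cyc_p = np.empty((n_per, self.n_nodes))
            q_root_int = 0.0
            vol0 = self.total_volume()
            for j in range(n_per):
                self.step(dt)
                cyc_p[j] = self.p
                for k, spec in probes.items():
                    if spec[0] == "p":
                        rec[k][j] = self.p[spec[1]]
                    elif spec[0] == "q":
                        rec[k][j] = self.q[spec[1]]
                    else:
                        _, w, side = spec
                        rec[k][j] = self.wk_pa[w] if side == "pa" else self.wk_pv[w]
                if self.heart is not None:
                    for k, v in self.heart.sample().items():
                        heart_rec.setdefault(k, np.empty(n_per))[j] = v
                    for k, v in self.heart.valve_areas().items():
                        valve_rec.setdefault(k, np.empty(n_per))[j] = v
                # mean systemic flow: aortic-root element flow
                q_root_int += self.q[self.elem_offset[0]] * dt
            cycles_run = cyc + 1
            if prev_cycle_p is not None:
                residual = float(np.max(np.abs(cyc_p - prev_cycle_p))) / MMHG
            prev_cycle_p = cyc_p
            q_av_int = q_root_int
            active = False
            if control is not None:
                active = bool(control(self, cyc, q_root_int / T, residual))
            if (cyc + 1 >= min_cycles and not active
                    and residual < convergence_tol_mmhg):
                converged = True
                break
        traces = {}
        for k, arr in rec.items():
            unit = "Pa" if probes[k][0] in ("p", "wk") else "m^3/s"
            traces[k] = SignalTrace(samples=arr.copy(), dt=dt, units=unit, label=k)
        return SimulationResult(
            dt=dt, T=T, traces=traces, cycles_run=cycles_run,
            converged=converged, periodicity_residual_mmhg=residual,
            valve_states=valve_rec, heart_traces=heart_rec,
            mean_systemic_flow_ml_s=q_av_int / T * 1e6,
        )

    # ------------------------------------------------------------------
    def set_initial_pressure(self, network_index: int, p: float) -> None:
        """Re-initialize one tree (and beds on its side) to a uniform pressure."""
        no = self.node_offset[network_index]
        net = self.networks[network_index]
        self.p[no:no + net.n_nodes] = p
        self.A_caches[network_index] = net.initial_area_cache(
            self.p[no:no + net.n_nodes])
        if network_index == 1:
            for w, br in enumerate(self.bridges):
                self.wk_pv[w] = p
                self.wk_Av[w] = area_from_pressure(p, br.wall_ven)
            self.wk_Vv = self._wk_lav * self.wk_Av
        self.node_V = np.concatenate([net.node_volumes(cache) for net, cache in
                                      zip(self.networks, self.A_caches)])

    def total_volume(self) -> float:
        """Stored blood volume in tubes + beds (+ heart if present) [m^3].

        Tube volume integrates the wall law at current nodal pressures
        (half-element areas); bed volumes use l_AV * A(p).  Used for the
        closed-loop conservation diagnostic.
        """
        vol = float(np.sum(self.node_V))
        if self.n_wk:
            vol += float(np.sum(self.wk_Va) + np.sum(self.wk_Vv))
        if self.heart is not None:
            vol += self.heart.total_volume()
        return vol
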