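"""Reference 1D pulse-wave-propagation (PWP) solver.

Solves the same telegrapher's equations and wall law as the TL solver but
with a deliberately different discretization, so that agreement between the
two is a genuine numerical cross-check:

* both pressure *and* flow live on grid nodes (flow unknowns are duplicated
  per branch at junctions);
* the weak form is integrated with two-point trapezoidal element integrals,

      mass:      dz/2 (C_i dp_i/dt + C_j dp_j/dt) + (q_j - q_i) = 0,
      momentum:  dz/2  L (dq_i/dt + dq_j/dt)
                 + dz/2 R (q_i + q_j) + (p_j - p_i) = 0;

* time stepping is BDF2 (second-order backward differences) with one
  backward-Euler startup step.

Friction and inertance use the same Womersley profile factors and the same
nonlinear three-element windkessel terminations as the TL model, evaluated
semi-implicitly.  The solver runs open domains only: a prescribed inflow at
the root, windkessel beds draining to a fixed venous pressure.
"""

from __future__ import annotations

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .analysis import SignalTrace
from .constitutive import MMHG, PhysicalConstants, area_from_pressure
from .network import DiscretizedNetwork
from .tl_solver import SimulationResult, SolverDivergence, TerminalBridge

__all__ = ["PWPSystem", "simulate_pwp"]


class PWPSystem:
    """Assembled PWP grid over one discretized tree (open domain)."""

    def __init__(self, disc: DiscretizedNetwork, bridges, inflow,
                 const: PhysicalConstants = PhysicalConstants()):
        self.disc = disc
        self.bridges = list(bridges)
        self.inflow = inflow
        self.const = const
        ne = disc.n_elements
        nn = disc.n_nodes

        # q-unknown numbering: one per segment-node (shared along a segment,
        # duplicated across segments at junctions)
        seg_ids = disc.e_seg
        self.q_left = np.empty(ne, dtype=int)
        self.q_right = np.empty(ne, dtype=int)
        qn = 0
        prev_seg = None
        for e in range(ne):
            if seg_ids[e] != prev_seg:
                self.q_left[e] = qn
                qn += 1
            else:
                self.q_left[e] = self.q_right[e - 1]
            self.q_right[e] = qn
            qn += 1
            prev_seg = seg_ids[e]
        self.n_q = qn

        # junction bookkeeping: per global node, signed q-end incidences
        self.node_q: list[list[tuple[int, float]]] = [[] for _ in range(nn)]
        for e in range(ne):
            if e == 0 or seg_ids[e] != seg_ids[e - 1]:
                self.node_q[disc.e_prox[e]].append((self.q_left[e], -1.0))
            if e == ne - 1 or seg_ids[e] != seg_ids[e + 1]:
                self.node_q[disc.e_dist[e]].append((self.q_right[e], +1.0))

        self.root = disc.root
        leaf_nodes = {br.art_node for br in self.bridges}
        self.junction_nodes = [n for n in range(nn)
                               if self.node_q[n] and n != self.root
                               and n not in leaf_nodes]
        self.leaf_q = {}
        for br in self.bridges:
            (qid, sign), = self.node_q[br.art_node]
            self.leaf_q[br.art_node] = qid
        (self.root_q, _), = self.node_q[self.root]

        self.n_wk = len(self.bridges)
        self.ip0 = 0
        self.iq0 = nn
        self.iwk0 = nn + self.n_q
        self.dim = self.iwk0 + 2 * self.n_wk

        # state
        p0 = disc.e_p0.mean() - disc.e_pext.mean()
        self.x = np.zeros(self.dim)
        self.x[:nn] = p0
        self.x[self.iwk0::2][:self.n_wk] = [b.wall_art.p0 - b.wall_art.p_ext
                                            for b in self.bridges]
        self.x[self.iwk0 + 1::2][:self.n_wk] = [b.wall_ven.p0 - b.wall_ven.p_ext
                                                for b in self.bridges]
        self.x_prev = self.x.copy()
        self.t = 0.0
        self.n_steps = 0
        self.A_cache = disc.initial_area_cache(self.x[:nn])
        self.wk_Aa = np.array([area_from_pressure(p, b.wall_art) for p, b in
                               zip(self.x[self.iwk0::2][:self.n_wk], self.bridges)])
        self.wk_Av = np.array([area_from_pressure(p, b.wall_ven) for p, b in
                               zip(self.x[self.iwk0 + 1::2][:self.n_wk], self.bridges)])
        self._wk_lav = np.array([b.l_AV for b in self.bridges])
        self._wkp = {side: {attr: np.array([getattr(getattr(b, side), attr)
                                            for b in self.bridges])
                            for attr in ("p0", "A0", "k", "b", "p_ext")}
                     for side in ("wall_art", "wall_ven")}
        self._last_residual = 0.0

    # ------------------------------------------------------------------
    def _end_compliance(self):
        """C per unit length at both element ends, warm-started Newton."""
        disc = self.disc
        nodes = np.concatenate([disc.e_prox, disc.e_dist])
        p = self.x[:disc.n_nodes][nodes]
        p0 = np.concatenate([disc.e_p0] * 2)
        k = np.concatenate([disc.e_k] * 2)
        b = np.concatenate([disc.e_b] * 2)
        pext = np.concatenate([disc.e_pext] * 2)
        A0 = np.concatenate([disc.e_A0] * 2)
        A = self.A_cache
        for _ in range(2):
            xr = A / A0
            f = -pext + p0 * ((1.0 + b) * xr ** (1.0 + k / 3.0) - b / xr) - p
            df = (p0 / A0) * ((1.0 + b) * (1.0 + k / 3.0) * xr ** (k / 3.0) + b / xr**2)
            A *= np.exp(-np.clip(f / (df * A), -0.5, 0.5))
        xr = A / A0
        dpdA = (p0 / A0) * ((1.0 + b) * (1.0 + k / 3.0) * xr ** (k / 3.0) + b / xr**2)
        C = 1.0 / dpdA
        ne = disc.n_elements
        return C[:ne], C[ne:]

    def _wk_side(self, side, p, A):
        prm = self._wkp[side]
        p0, A0, k, b, pext = (prm["p0"], prm["A0"], prm["k"], prm["b"], prm["p_ext"])
        for _ in range(2):
            xr = A / A0
            f = -pext + p0 * ((1.0 + b) * xr ** (1.0 + k / 3.0) - b / xr) - p
            df = (p0 / A0) * ((1.0 + b) * (1.0 + k / 3.0) * xr ** (k / 3.0) + b / xr**2)
            A *= np.exp(-np.clip(f / (df * A), -0.5, 0.5))
        xr = A / A0
        dpdA = (p0 / A0) * ((1.0 + b) * (1.0 + k / 3.0) * xr ** (k / 3.0) + b / xr**2)
        return self._wk_lav / dpdA, np.sqrt(self.const.rho * dpdA / A)

    # ------------------------------------------------------------------
    def step(self, dt: float):
        if dt <= 0:
            raise ValueError("dt must be positive")
        disc = self.disc
        nn, ne = disc.n_nodes, disc.n_elements
        # BDF2 weights: D x = (a1 x1 + a0 x0 + am xm)/dt
        if self.n_steps == 0:
            a1, a0, am = 1.0, -1.0, 0.0
        else:
            a1, a0, am = 1.5, -2.0, 0.5
        Ci, Cj = self._end_compliance()
        dz2 = 0.5 * disc.e_dz
        Lpl = disc.e_L / disc.e_dz   # per-unit-length inertance
        Rpl = disc.e_R / disc.e_dz
        x0 = self.x
        xm = self.x_prev

        rows, cols, vals = [], [], []
        rhs = np.zeros(self.dim)

        def addv(r, c, v):
            rows.append(np.asarray(r, dtype=int))
            cols.append(np.asarray(c, dtype=int))
            vals.append(np.asarray(v, dtype=float))

        erow = np.arange(ne)
        ni, nj = disc.e_prox, disc.e_dist
        qi, qj = self.iq0 + self.q_left, self.iq0 + self.q_right
        # mass rows (0..ne-1)
        addv(erow, ni, dz2 * Ci * a1 / dt)
        addv(erow, nj, dz2 * Cj * a1 / dt)
        addv(erow, qj, np.ones(ne))
        addv(erow, qi, -np.ones(ne))
        rhs[:ne] -= dz2 * (Ci * (a0 * x0[ni] + am * xm[ni])
                           + Cj * (a0 * x0[nj] + am * xm[nj])) / dt
        # momentum rows (ne..2ne-1)
        mrow = ne + erow
        addv(mrow, qi, dz2 * (Lpl * a1 / dt + Rpl))
        addv(mrow, qj, dz2 * (Lpl * a1 / dt + Rpl))
        addv(mrow, nj, np.ones(ne))
        addv(mrow, ni, -np.ones(ne))
        np.add.at(rhs, mrow, -dz2 * Lpl * (a0 * x0[qi] + am * xm[qi]) / dt)
        np.add.at(rhs, mrow, -dz2 * Lpl * (a0 * x0[qj] + am * xm[qj]) / dt)
        # junction conservation rows
        r = 2 * ne
        for n in self.junction_nodes:
            for qid, sign in self.node_q[n]:
                addv([r], [self.iq0 + qid], [sign])
            r += 1
        # root inflow
        addv([r], [self.iq0 + self.root_q], [1.0])
        rhs[r] = self.inflow(self.t + dt)
        r += 1
        # leaf + windkessel rows
        pa = x0[self.iwk0::2][:self.n_wk]
        pv = x0[self.iwk0 + 1::2][:self.n_wk]
        C_a, Z_a = self._wk_side("wall_art", pa, self.wk_Aa)
        C_v, Z_v = self._wk_side("wall_ven", pv, self.wk_Av)
        for w, br in enumerate(self.bridges):
            ga, gv, gp = 1.0 / Z_a[w], 1.0 / Z_v[w], 1.0 / br.R_p
            ia = self.iwk0 + 2 * w
            iv = ia + 1
            n = br.art_node
            qid = self.iq0 + self.leaf_q[n]
            # q_leaf = ga (p_n - p_a)
            addv([r, r, r], [qid, n, ia], [1.0, -ga, ga])
            r += 1
            # C_a D p_a = ga (p_n - p_a) - gp (p_a - p_v)
            addv([ia, ia, ia], [ia, n, iv],
                 [C_a[w] * a1 / dt + ga + gp, -ga, -gp])
            rhs[ia] = -C_a[w] * (a0 * x0[ia] + am * xm[ia]) / dt
            # C_v D p_v = gp (p_a - p_v) - gv (p_v - p_fixed)
            addv([iv, iv], [iv, ia], [C_v[w] * a1 / dt + gp + gv, -gp])
            rhs[iv] = (-C_v[w] * (a0 * x0[iv] + am * xm[iv]) / dt
                       + gv * br.p_ven_fixed)
        M = sp.coo_matrix((np.concatenate(vals),
                           (np.concatenate(rows), np.concatenate(cols))),
                          shape=(self.dim, self.dim)).tocsc()
        x1 = spla.splu(M).solve(rhs)
        if not np.all(np.isfinite(x1)):
            bad = np.flatnonzero(~np.isfinite(x1))[0]
            raise SolverDivergence(f"PWP: non-finite unknown {bad} at t={self.t:.4f}")
        self._last_residual = float(np.max(np.abs((M @ x1 - rhs)[:ne])))
        self.x_prev = self.x
        self.x = x1
        self.t += dt
        self.n_steps += 1
        return self

    def mass_residual(self) -> float:
        return self._last_residual

    @property
    def p(self) -> np.ndarray:
        return self.x[:self.disc.n_nodes]

    def element_flow(self, e: int) -> float:
        """Mid-element flow: mean of the two end flows."""
        return 0.5 * (self.x[self.iq0 + self.q_left[e]]
                      + self.x[self.iq0 + self.q_right[e]])

    # ------------------------------------------------------------------
    def simulate(self, n_cycles: int, dt: float | None = None,
                 convergence_tol_mmhg: float = 0.1,
                 probes: dict | None = None, min_cycles: int = 3) -> SimulationResult:
        """Run whole cycles to periodicity; same contract as the TL solver."""
        if n_cycles < 1:
            raise ValueError("n_cycles must be >= 1")
        T = self.const.T
        dt = T / round(T / (dt or 1e-3))
        n_per = round(T / dt)
        probes = probes or {}
        rec = {k: np.empty(n_per) for k in probes}
        prev = None
        residual = np.inf
        converged = False
        cycles_run = 0
        for cyc in range(n_cycles):
            cyc_p = np.empty((n_per, self.disc.n_nodes))
            for j in range(n_per):
                self.step(dt)
                cyc_p[j] = self.p
                for k, spec in probes.items():
                    if spec[0] == "p":
                        rec[k][j] = self.p[spec[1]]
                    else:
                        rec[k][j] = self.element_flow(spec[1])
            cycles_run = cyc + 1
            if prev is not None:
                residual = float(np.max(np.abs(cyc_p - prev))) / MMHG
            prev = cyc_p
            if cyc + 1 >= min_cycles and residual < convergence_tol_mmhg:
                converged = True
                break
        traces = {k: SignalTrace(rec[k].copy(), dt,
                                 "Pa" if probes[k][0] == "p" else "m^3/s", k)
                  for k in rec}
        return SimulationResult(dt=dt, T=T, traces=traces, cycles_run=cycles_run,
                                converged=converged,
                                periodicity_residual_mmhg=residual)


def simulate_pwp(disc: DiscretizedNetwork, bridges, inflow, n_cycles: int,
                 dt: float = 1e-3, const: PhysicalConstants = PhysicalConstants(),
                 probes: dict | None = None,
                 convergence_tol_mmhg: float = 0.1) -> SimulationResult:
    """Convenience wrapper: assemble and run a PWP benchmark simulation."""
    sys_ = PWPSystem(disc, bridges, inflow, const)
    return sys_.simulate(n_cycles, dt=dt, probes=probes,
                         convergence_tol_mmhg=convergence_tol_mmhg)
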