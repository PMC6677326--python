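"""Scenario definitions and run orchestration.

Three scenarios mirror the study conditions:

* ``REF``   -- closed-loop normotension: arterial reference pressure
  p0,a = 105 mmHg, stiffness coefficients as tabulated.
* ``HYP``   -- closed-loop systemic hypertension: p0,a = 135 mmHg and every
  systemic *arterial* stiffness coefficient incremented by +6 (venous
  parameters untouched).  The p0 rise doubles as a peripheral-resistance
  rise through the windkessel calibration.
* ``BENCH`` -- open benchmark domain (aorta + left arm): a prescribed
  periodic half-sinusoid inflow (peak 350 ml/s, duration 0.3 s) drives the
  aortic root and both the TL and reference PWP solver are run on identical
  boundary conditions.

All scenario parameters are plain dataclass fields so configurations can be
loaded from a YAML/JSON-like mapping with :func:`ScenarioConfig.from_dict`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path

import numpy as np

from .analysis import SignalTrace
from .constitutive import (MMHG, PhysicalConstants, WallLawParams,
                           area_from_pressure, dptrans_dA)
from .network import VascularTree, discretize, load_network
from .tl_solver import TerminalBridge, TLSystem
from .windkessel import peripheral_resistance, terminal_coefficients
from .windkessel import bed_length

__all__ = ["ScenarioConfig", "data_path", "build_open_system",
           "build_closed_system", "inflow_halfsine_factory",
           "make_volume_controller", "run_closed", "run_benchmark",
           "run_scenario"]


def data_path(name: str) -> Path:
    """Path of a packaged fixture table."""
    return Path(resources.files("circwave.data") / name)


@dataclass
class ScenarioConfig:
    """All tunables of one simulation scenario (I/O units: mmHg, ml/s)."""

    name: str = "REF"
    p0_a_mmhg: float = 105.0
    p0_v_mmhg: float = 1.1
    delta_k: float = 0.0           # additive increment to arterial k
    T: float = 0.85
    q0_ml_s: float = 85.0
    dt: float = 1e-3
    dz: float = 0.02
    n_cycles: int = 40
    convergence_tol_mmhg: float = 0.1
    #: operating mean arterial pressure, as a fraction of the wall-law
    #: reference p0,a; calibrates the peripheral resistances
    map_factor: float = 0.925
    # BENCH only
    q_peak_ml_s: float = 350.0
    t_c: float = 0.3
    network_file: str | None = None
    terminal_file: str | None = None
    venous_file: str | None = None
    venous_terminal_file: str | None = None

    @classmethod
    def ref(cls, **kw) -> "ScenarioConfig":
        kw.setdefault("map_factor", 0.875)
        return cls(name="REF", **kw)

    @classmethod
    def hyp(cls, **kw) -> "ScenarioConfig":
        kw.setdefault("map_factor", 0.95)
        return cls(name="HYP", p0_a_mmhg=135.0, delta_k=6.0, **kw)

    @classmethod
    def bench(cls, **kw) -> "ScenarioConfig":
        return cls(name="BENCH", **kw)

    @classmethod
    def from_dict(cls, d: dict) -> "ScenarioConfig":
        base = {"REF": cls.ref, "HYP": cls.hyp, "BENCH": cls.bench}[
            d.get("name", "REF").upper()]()
        return replace(base, **{k: v for k, v in d.items() if k != "name"})

    def __post_init__(self) -> None:
        for name in ("p0_a_mmhg", "p0_v_mmhg", "T", "q0_ml_s", "dt", "dz",
                     "q_peak_ml_s", "t_c"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.t_c >= self.T:
            raise ValueError("inflow half-sine duration must be below the period")

    @property
    def const(self) -> PhysicalConstants:
        return PhysicalConstants(T=self.T, omega0=2.0 * math.pi / self.T)

    @property
    def q0(self) -> float:
        return self.q0_ml_s * 1e-6


def inflow_halfsine_factory(q_p: float, t_c: float, T: float):
    """Periodic half-sinusoid inflow q(t) (SI units)."""
    if t_c >= T:
        raise ValueError("half-sine duration must be below the period")

    def q(t):
        tau = np.mod(t, T)
        return np.where(tau <= t_c, q_p * np.sin(np.pi * tau / t_c), 0.0)

    return lambda t: float(q(t)) if np.ndim(t) == 0 else q(t)


def _apply_delta_k(tree: VascularTree, delta_k: float) -> None:
    if delta_k:
        for seg in tree.segments.values():
            if seg.vessel_class == "artery":
                seg.k += delta_k


def _terminal_walls(tree: VascularTree, seg_id: int) -> WallLawParams:
    """Wall-law parameters at the free end of a terminal segment."""
    seg = tree.resolve_id(seg_id)
    end = tree.leaf_end(seg.id)
    s = 1.0 if end == seg.dist_node else 0.0
    return seg.wall_params(s)


def load_scenario_trees(config: ScenarioConfig, closed: bool):
    art_file = config.network_file or data_path(
        "benchmark_arteries_synthetic.csv" if config.name == "BENCH"
        else "arteries_synthetic.csv")
    term_file = config.terminal_file or data_path(
        "benchmark_terminals_synthetic.csv" if config.name == "BENCH"
        else "terminals_synthetic.csv")
    art = load_network(art_file, term_file, p0_override_mmHg=config.p0_a_mmhg)
    _apply_delta_k(art, config.delta_k)
    if not closed:
        return art, None
    ven_file = config.venous_file or data_path("veins_synthetic.csv")
    ven_term = config.venous_terminal_file or data_path("veins_synthetic_terminals.csv")
    # venous root: heartward (distal) end of the lowest-id vein
    import pandas as pd
    vdf = pd.read_csv(ven_file, dtype=str, skipinitialspace=True)
    vids = vdf["id"].map(lambda s: int(str(s).split("+")[0]))
    ven_root = str(vdf.loc[vids.idxmin(), "dist_node"]).strip()
    ven = load_network(ven_file, ven_term, p0_override_mmHg=config.p0_v_mmhg,
                       root_node=ven_root)
    return art, ven




def _calibrated_rp(q_av: float, map_a: float, p0v: float,
                   wall_a: WallLawParams, wall_v: WallLawParams,
                   const: PhysicalConstants) -> float:
    """Peripheral resistance calibrated at the scenario operating point.

    The arterio-venous pressure difference of the calibration is taken
    between the *operating* mean arterial pressure and the venous reference,
    net of the series wave impedances, so that at the design flow the
    attached tube ends sit at the intended mean pressures."""
    l_av = bed_length(q_av)
    A_a = area_from_pressure(map_a - wall_a.p_ext, wall_a)
    A_v = area_from_pressure(p0v - wall_v.p_ext, wall_v)
    _, Z_a = terminal_coefficients(A_a, wall_a, l_av, const)
    _, Z_v = terminal_coefficients(A_v, wall_v, l_av, const)
    r_total = peripheral_resistance(map_a, p0v, q_av)
    return max(r_total - Z_a - Z_v, 0.25 * r_total)


def build_open_system(config: ScenarioConfig, tree: VascularTree | None = None,
                      mean_inflow: float | None = None) -> TLSystem:
    """Open-domain system: prescribed root inflow, 3WKs to fixed venous p."""
    const = config.const
    if tree is None:
        tree, _ = load_scenario_trees(config, closed=False)
    disc = discretize(tree, config.dz, const=const)
    if mean_inflow is None:
        mean_inflow = config.q_peak_ml_s * 1e-6 * (2.0 / math.pi) * config.t_c / config.T
    p0a = config.p0_a_mmhg * MMHG
    p0v = config.p0_v_mmhg * MMHG
    bridges = []
    for term in tree.terminals:
        q_av = term.flow_fraction * mean_inflow
        wall_a = _terminal_walls(tree, term.segment_id)
        r_ven = min(1.4 * math.sqrt(wall_a.A0 / math.pi), 0.012)
        wall_v = WallLawParams(p0=p0v, A0=math.pi * r_ven**2, k=10.0, b=wall_a.b)
        bridges.append(TerminalBridge(
            art_node=disc.leaf_node(term.segment_id),
            q_AV=q_av,
            R_p=_calibrated_rp(q_av, config.map_factor * p0a, p0v,
                               wall_a, wall_v, const),
            wall_art=wall_a, wall_ven=wall_v,
            p_ven_fixed=p0v,
            label=tree.resolve_id(term.segment_id).label,
        ))
    inflow = inflow_halfsine_factory(config.q_peak_ml_s * 1e-6, config.t_c, config.T)
    sys_ = TLSystem([disc], bridges, inflow=inflow, const=const)
    sys_.disc = disc
    return sys_


def build_closed_system(config: ScenarioConfig, heart=None) -> TLSystem:
    """Closed-loop system: arterial + venous trees, 3WK bridges, heart."""
    const = config.const
    art, ven = load_scenario_trees(config, closed=True)
    disc_a = discretize(art, config.dz, const=const)
    disc_v = discretize(ven, config.dz, const=const)
    p0a = config.p0_a_mmhg * MMHG
    p0v = config.p0_v_mmhg * MMHG
    bridges = []
    for term in art.terminals:
        if term.venous_segment_id is None:
            raise ValueError(f"terminal {term.segment_id} lacks a venous pair")
        q_av = term.flow_fraction * config.q0
        wall_a = _terminal_walls(art, term.segment_id)
        wall_v = _terminal_walls(ven, term.venous_segment_id)
        bridges.append(TerminalBridge(
            art_node=disc_a.leaf_node(term.segment_id),
            ven_node=disc_a.n_nodes + disc_v.leaf_node(term.venous_segment_id),
            q_AV=q_av,
            R_p=_calibrated_rp(q_av, config.map_factor * p0a, p0v,
                               wall_a, wall_v, const),
            wall_art=wall_a, wall_ven=wall_v,
            label=art.resolve_id(term.segment_id).label,
        ))
    # vena-cava -> right atrium series impedance: wave impedance of the
    # venous trunk at its reference state
    trunk = ven.segments[min(ven.segments)]
    from .constitutive import dptrans_dA, area_from_pressure
    wall_t = trunk.wall_params(1.0)
    A_t = area_from_pressure(p0v, wall_t)
    z_root = float(np.sqrt(const.rho * dptrans_dA(A_t, wall_t) / A_t))
    sys_ = TLSystem([disc_a, disc_v], bridges, heart=heart, const=const,
                    ven_root_impedance=z_root)
    sys_.disc = disc_a
    sys_.disc_ven = disc_v
    sys_.tree = art
    sys_.tree_ven = ven
    return sys_


# ---------------------------------------------------------------------------
# closed-loop orchestration
# ---------------------------------------------------------------------------

def make_volume_controller(q_target: float, gain: float = 1.3,
                           tol_ml_s: float = 0.3, settle: int = 2,
                           residual_tol_mmhg: float = 1.0,
                           max_cycles: int = 40):
    """Per-cycle circulating-volume regulation.

    Adds/removes volume at the venous root in proportion to the mean-flow
    error until the systemic flow matches ``q_target`` (SI) *and* the
    beat-to-beat pressure residual is small, then freezes so that the final
    cycles conserve volume exactly.  Returns a callback for
    :meth:`TLSystem.simulate`.
    """
    state = {"ok": 0, "frozen": False, "q_prev": None}

    def control(system, cyc, q_mean, residual):
        if state["frozen"]:
            system.volume_control_flow = 0.0
            return False
        err = q_target - q_mean
        slope = (abs(q_mean - state["q_prev"]) if state["q_prev"] is not None
                 else float("inf"))
        state["q_prev"] = q_mean
        # freeze only when the flow is on target AND stationary, so the
        # uncontrolled system stays put afterwards
        settled = (abs(err) < tol_ml_s * 1e-6
                   and slope < 0.5 * tol_ml_s * 1e-6
                   and residual < residual_tol_mmhg)
        state["ok"] = state["ok"] + 1 if settled else 0
        if state["ok"] >= settle or cyc >= max_cycles:
            state["frozen"] = True
            system.volume_control_flow = 0.0
            return False
        system.volume_control_flow = gain * err
        return True

    return control




def _element_ending_at(disc, seg_id, rel_pos):
    node = disc.probe_node(seg_id, rel_pos)
    idx = disc.segment_elements(seg_id)
    hits = idx[disc.e_dist[idx] == node]
    return int(hits[0]) if hits.size else int(idx[0])


def _element_starting_at(disc, seg_id, rel_pos):
    node = disc.probe_node(seg_id, rel_pos)
    idx = disc.segment_elements(seg_id)
    hits = idx[disc.e_prox[idx] == node]
    return int(hits[0]) if hits.size else int(idx[-1])


def _closed_probes(system) -> dict:
    disc, disc_v = system.disc, system.disc_ven
    nn0 = system.node_offset[1]
    return {
        "aorta_p": ("p", disc.probe_node(1, 0.5)),
        "aorta_root_p": ("p", system.art_root),
        "aorta_q": ("q", disc.probe_element(1, 0.5)),
        "carotid_p": ("p", disc.probe_node(15, 0.5)),
        "carotid_q_prox": ("q", _element_ending_at(disc, 15, 0.5)),
        "carotid_q_dist": ("q", _element_starting_at(disc, 15, 0.5)),
        "carotid_term_p": ("p", disc.leaf_node(15)),
        "femoral_term_p": ("p", disc.probe_node(48, 1.0)),
        "vena_cava_p": ("p", nn0 + disc_v.probe_node(101, 0.5)),
        "arm_vein_p": ("p", nn0 + disc_v.probe_node(121, 0.5)),
        "leg_vein_p": ("p", nn0 + disc_v.probe_node(148, 0.5)),
    }


def run_closed(config: ScenarioConfig, heart=None, theta: float = 0.55,
               probes: dict | None = None):
    """Run a closed-loop scenario to periodic convergence and analyse it.

    Returns a dict with the converged :class:`SimulationResult`, the
    haemodynamic indices (mmHg, m/s), the carotid wave-intensity analysis
    and bookkeeping diagnostics.
    """
    from .analysis import (haemodynamic_indices, pulse_wave_velocity,
                           wave_intensity, wia_features, SignalTrace)
    from .constitutive import area_from_pressure, wave_speed_at
    from .heart import Heart

    heart = heart or Heart(config.const)
    system = build_closed_system(config, heart=heart)
    system.theta = theta
    # start the venous side near its working pressure to shorten the slow
    # venous-pool charging transient (time constant ~ R_p * C_venous)
    system.set_initial_pressure(1, config.p0_v_mmhg * MMHG + 2.5 * MMHG)
    pr = _closed_probes(system)
    if probes:
        pr.update(probes)
    control = make_volume_controller(config.q0)
    main = system.simulate(config.n_cycles, dt=config.dt, probes=pr,
                           convergence_tol_mmhg=config.convergence_tol_mmhg,
                           control=control)
    # one extra recorded cycle for the volume-conservation diagnostic
    vol_before = system.total_volume()
    res = system.simulate(1, dt=config.dt, probes=pr, min_cycles=1,
                          convergence_tol_mmhg=float("inf"))
    res.volume_drift_ml = (system.total_volume() - vol_before) * 1e6
    res.converged = main.converged
    res.cycles_run = main.cycles_run + 1
    res.periodicity_residual_mmhg = main.periodicity_residual_mmhg

    # ---- derived quantities ------------------------------------------
    disc = system.disc
    path = float(disc.node_path_length[pr["femoral_term_p"][1]]
                 - disc.node_path_length[pr["carotid_term_p"][1]])
    pwv = pulse_wave_velocity(res.traces["carotid_term_p"],
                              res.traces["femoral_term_p"], path)
    indices = haemodynamic_indices(res.traces["aorta_p"], pwv=pwv)

    # carotid WIA: U = q/A(p) co-located with the pressure node (mean of
    # the two adjacent element flows; a half-element offset would act like
    # a deliberate p/U misalignment and corrupt the decomposition)
    seg15 = system.tree.resolve_id(15)
    wall = seg15.wall_params(0.5)
    p_tr = res.traces["carotid_p"]
    q_tr = SignalTrace(0.5 * (res.traces["carotid_q_prox"].samples
                              + res.traces["carotid_q_dist"].samples),
                       res.dt, "m^3/s", "carotid q")
    A = np.array([area_from_pressure(pi, wall) for pi in p_tr.samples])
    U = SignalTrace(q_tr.samples / A, q_tr.dt, "m/s", "carotid U")
    c_loc = float(wave_speed_at(float(p_tr.samples.mean()), wall, config.const))
    wia = wave_intensity(p_tr, U, config.const.rho, c_loc)
    # ejection onset: aortic valve opening from the orifice-area channel
    av = res.valve_states["av"]
    open_thresh = 0.5 * heart.valves["av"].A_open
    rising = np.flatnonzero((av[1:] >= open_thresh) & (av[:-1] < open_thresh))
    t_eject = float((rising[0] + 1) * res.dt) if rising.size else float("nan")
    features = wia_features(wia, t_eject)

    venous_pulsatility = {
        "central_mmhg": float(np.ptp(res.traces["vena_cava_p"].in_mmhg())),
        "arm_mmhg": float(np.ptp(res.traces["arm_vein_p"].in_mmhg())),
    }
    return {
        "system": system, "heart": heart, "result": res, "indices": indices,
        "pwv": pwv, "path_length_m": path, "wia": wia, "wia_features": features,
        "ejection_onset_s": t_eject, "venous_pulsatility": venous_pulsatility,
        "wave_speed_carotid": c_loc,
    }


def run_benchmark(config: ScenarioConfig | None = None, n_cycles: int = 16,
                  tube_labels=("1+2", "4", "15", "19+27", "3", "16", "20",
                               "21", "22", "23", "24", "26", "25")):
    """Run the TL and PWP solvers on the benchmark domain and compare.

    Agreement is evaluated at the element located at the centre of each
    tube, over the last (converged) cycle, as RMS and relative errors.
    """
    from .analysis import BenchmarkReport, error_metrics
    from .pwp_solver import PWPSystem

    config = config or ScenarioConfig.bench()
    tl = build_open_system(config)
    disc = tl.disc
    probes = {}
    for lab in tube_labels:
        sid = int(lab.split("+")[0])
        probes[f"p:{lab}"] = ("p", disc.probe_node(sid, 0.5))
        probes[f"q:{lab}"] = ("q", disc.probe_element(sid, 0.5))
    res_tl = tl.simulate(n_cycles, dt=config.dt, probes=probes,
                         convergence_tol_mmhg=config.convergence_tol_mmhg)
    ref = build_open_system(config)
    pwp = PWPSystem(ref.disc, ref.bridges, ref.inflow, config.const)
    res_pwp = pwp.simulate(n_cycles, dt=config.dt, probes=probes,
                           convergence_tol_mmhg=config.convergence_tol_mmhg)
    eps_p, eps_q, del_p, del_q = {}, {}, {}, {}
    for lab in tube_labels:
        ep, dp = error_metrics(res_tl.traces[f"p:{lab}"],
                               res_pwp.traces[f"p:{lab}"], "pressure")
        eq, dq = error_metrics(res_tl.traces[f"q:{lab}"],
                               res_pwp.traces[f"q:{lab}"], "flow")
        eps_p[lab] = ep / MMHG
        eps_q[lab] = eq * 1e6
        del_p[lab] = dp
        del_q[lab] = dq
    n_t = res_tl.traces[f"p:{tube_labels[0]}"].samples.size
    report = BenchmarkReport(tubes=list(tube_labels), eps_p_mmhg=eps_p,
                             eps_q_ml_s=eps_q, delta_p_pct=del_p,
                             delta_q_pct=del_q, n_samples=n_t, T=config.T)
    return {"report": report, "tl": res_tl, "pwp": res_pwp,
            "tl_system": tl, "pwp_system": pwp}


# ---------------------------------------------------------------------------
# lumped single-windkessel afterload mode and scenario dispatch
# ---------------------------------------------------------------------------

class Lumped3WKAfterload:
    """The whole systemic circulation as one nonlinear 3WK.

    Used as the comparison afterload: the heart ejects straight into a
    single wave impedance / compliance / peripheral-resistance termination
    (no distributed tree, hence no wave transmission or reflection).  The
    bed walls reuse the aortic-root and vena-cava wall laws so compliance
    and impedance remain pressure-dependent.
    """

    def __init__(self, config: ScenarioConfig, heart):
        from .heart import Heart
        self.config = config
        self.const = config.const
        self.heart = heart or Heart(self.const)
        art, ven = load_scenario_trees(config, closed=True)
        root_seg = art.segments[min(art.segments)]
        trunk = ven.segments[min(ven.segments)]
        self.wall_a = root_seg.wall_params(0.0)
        self.wall_v = trunk.wall_params(1.0)
        q0 = config.q0
        self.l_AV = bed_length(q0)
        p0a = config.p0_a_mmhg * MMHG
        p0v = config.p0_v_mmhg * MMHG
        self.R_p = _calibrated_rp(q0, config.map_factor * p0a, p0v,
                                  self.wall_a, self.wall_v, self.const)
        self.A_a = area_from_pressure(config.map_factor * p0a, self.wall_a)
        self.A_v = area_from_pressure(p0v + 2.5 * MMHG, self.wall_v)
        self.q_av_prev = 0.0

    def _pz(self):
        from .constitutive import transmural_pressure
        p_a = float(transmural_pressure(self.A_a, self.wall_a))
        p_v = float(transmural_pressure(self.A_v, self.wall_v))
        _, Z_a = terminal_coefficients(self.A_a, self.wall_a, self.l_AV, self.const)
        _, Z_v = terminal_coefficients(self.A_v, self.wall_v, self.l_AV, self.const)
        return p_a, p_v, Z_a, Z_v

    def step(self, t, dt):
        p_a, p_v, Z_a, Z_v = self._pz()
        hb = self.heart.presolve(t, dt, p_ao=p_a + Z_a * self.q_av_prev,
                                 p_vc=p_v, z_ao=Z_a)
        q_av = hb["q_av"]
        self.q_av_prev = q_av
        q_rp = (p_a - p_v) / self.R_p
        q_ra = (p_v - hb["p_ra"]) / Z_v
        self.A_a += dt * (q_av - q_rp) / self.l_AV
        self.A_v += dt * (q_rp - q_ra) / self.l_AV
        self.heart.commit(q_ra, dt)
        return p_a

    def simulate(self, n_cycles: int, control=None):
        """Run cycles; returns traces of aortic (bed) and LV pressure."""
        dt = self.config.dt
        T = self.const.T
        n = round(T / dt)
        p_sa = np.empty(n)
        p_lv = np.empty(n)
        av_area = np.empty(n)
        q_mean = 0.0
        for cyc in range(n_cycles):
            q_int = 0.0
            for j in range(n):
                t = cyc * T + j * dt
                p_sa[j] = self.step(t, dt)
                p_lv[j] = self.heart._samples["p_lv"]
                av_area[j] = self.heart.valves["av"].A_valve
                q_int += self.q_av_prev * dt
            q_mean = q_int / T
            if control is not None:
                # volume control: inject into the venous bed node
                err = self.config.q0 - q_mean
                self.A_v += err * T / self.l_AV
        return {
            "aortic_p": SignalTrace(p_sa.copy(), dt, "Pa", "aortic (3WK)"),
            "lv_p": SignalTrace(p_lv.copy(), dt, "Pa", "LV"),
            "av_area": av_area.copy(),
            "q_mean": q_mean,
        }


def detect_dicrotic_notch(p: "SignalTrace", t_avc: float,
                          window_s: float = 0.1):
    """Local pressure minimum shortly after aortic valve closure.

    Returns the notch time, or None when the trace decays monotonically
    through the window (no incisura).
    """
    n = p.samples.size
    i0 = int(round(t_avc / p.dt))
    m = int(round(window_s / p.dt))
    idx = (np.arange(i0, i0 + m) % n)
    seg = p.samples[idx]
    # interior local minimum with a genuine rebound afterwards
    for j in range(1, m - 1):
        if seg[j] < seg[j - 1] and seg[j + 1] > seg[j]:
            rebound = seg[j + 1:].max() - seg[j]
            if rebound > 0.5 * MMHG:
                return float(idx[j] * p.dt)
    return None


def aortic_valve_closure_time(av_area: np.ndarray, A_open: float,
                              dt: float) -> float:
    """Instant the orifice starts collapsing from fully open (AVC event)."""
    open_mask = av_area > 0.5 * A_open
    edges = np.flatnonzero(open_mask[:-1] & ~open_mask[1:])
    if edges.size == 0:
        raise ValueError("aortic valve never closes in this trace")
    return float((edges[0] + 1) * dt)


def compare_afterload_modes(config: ScenarioConfig, tl_run=None,
                            n_cycles_3wk: int = 25):
    """Paired LV/aortic traces: distributed TL vs lumped single-3WK afterload.

    Returns both trace pairs and the dicrotic-notch classification: the TL
    aortic trace carries an incisura after valve closure, the lumped
    afterload does not (no wave transmission).
    """
    from .heart import Heart
    if tl_run is None:
        tl_run = run_closed(config)
    res = tl_run["result"]
    heart3 = Heart(config.const)
    lump = Lumped3WKAfterload(config, heart3)
    out3 = lump.simulate(n_cycles_3wk, control=True)
    av_open = tl_run["heart"].valves["av"].A_open
    t_avc_tl = aortic_valve_closure_time(res.valve_states["av"], av_open, res.dt)
    t_avc_3wk = aortic_valve_closure_time(out3["av_area"], av_open, config.dt)
    tl_aortic = res.traces["aorta_root_p"]
    return {
        "tl_aortic": tl_aortic,
        "tl_lv": SignalTrace(res.heart_traces["p_lv"], res.dt, "Pa", "LV (TL)"),
        "wk_aortic": out3["aortic_p"],
        "wk_lv": out3["lv_p"],
        "tl_notch": detect_dicrotic_notch(tl_aortic, t_avc_tl),
        "wk_notch": detect_dicrotic_notch(out3["aortic_p"], t_avc_3wk),
    }


def run_scenario(config: ScenarioConfig, out_dir=None):
    """Dispatch a scenario run; optionally write the artifact bundle.

    BENCH runs both solvers and produces the error report; REF/HYP run the
    closed loop to convergence and produce indices + wave-intensity output.
    The CLI is a thin wrapper around this function.
    """
    if config.name == "BENCH":
        return run_benchmark(config)
    out = run_closed(config)
    if out_dir is not None:
        import json
        from pathlib import Path
        out_path = Path(out_dir)
        out_path.mkdir(parents=True, exist_ok=True)
        ind = out["indices"]
        (out_path / "indices.json").write_text(json.dumps({
            "p_sys_mmhg": ind.p_sys, "p_dia_mmhg": ind.p_dia,
            "p_pulse_mmhg": ind.p_pulse, "pwv_m_s": ind.pwv}, indent=2))
    return out
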