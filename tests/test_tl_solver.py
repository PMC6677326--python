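"""TL solver tests: assembly bookkeeping, quiescence, d'Alembert transport,
conservation and determinism."""

import numpy as np
import pytest

from circwave.constitutive import (MMHG, PhysicalConstants, WallLawParams,
                                   compliance, wave_coefficients)
from circwave.network import discretize, load_network
from circwave.scenarios import ScenarioConfig, build_open_system
from circwave.tl_solver import TerminalBridge, TLSystem

from conftest import make_network_csv, make_terminal_csv

CONST = PhysicalConstants()


def matched_tube_system(q_peak=2e-6, lossless=True, n_len=0.4):
    """Uniform tube, R forced to zero, terminated by its characteristic
    impedance (a matched resistive load): d'Alembert transport."""
    tree = load_network(
        make_network_csv([f"1,tube,artery,{n_len},0.01,0.01,8,0.02,105,0,ROOT,END"]),
        make_terminal_csv(["1,1.0"]))
    disc = discretize(tree, 0.02)
    if lossless:
        disc.e_R[:] = 0.0
    wall = tree.segments[1].wall_params(0.5)
    C_len = compliance(wall.A0, wall)
    L_len = disc.e_L[0] / disc.e_dz[0]
    c, zc, _ = wave_coefficients(0.0, L_len, C_len)
    p0 = wall.p0

    def inflow(t):
        # single narrow half-sine pulse, small amplitude (linear regime)
        return q_peak * np.sin(np.pi * t / 0.05) if 0 <= t <= 0.05 else 0.0

    sys_ = TLSystem([disc], [], inflow=inflow, const=CONST,
                    loads=[(disc.leaf_node(1), 1.0 / zc, p0)])
    return sys_, disc, c, zc, p0


class TestAssemblyBookkeeping:
    def test_series_ladder_counts(self):
        tree = load_network(
            make_network_csv(["1,t,artery,0.04,0.01,0.01,8,0.02,105,0,A,B"]),
            make_terminal_csv(["1,1.0"]))
        disc = discretize(tree, 0.02)
        sys_ = TLSystem([disc], [], inflow=lambda t: 0.0, const=CONST)
        assert sys_.n_flow_unknowns == 2       # two elements in series
        assert sys_.n_pressure_unknowns == 3   # root + 1 internal + leaf

    def test_bifurcation_flow_conservation(self, y_tree):
        disc = discretize(y_tree, 0.05)
        sys_ = TLSystem([disc], [], inflow=lambda t: 1e-5, const=CONST,
                        loads=[(disc.leaf_node(2), 1e-8, 0.0),
                               (disc.leaf_node(3), 1e-8, 0.0)])
        for _ in range(50):
            sys_.step(1e-3)
        # junction node: incident element flows balance the nodal storage
        assert sys_.mass_residual() < 1e-10

    def test_system_dimension_is_elements_plus_nodes(self):
        cfg = ScenarioConfig.bench()
        sys_ = build_open_system(cfg)
        assert sys_.dim == (sys_.n_elem + sys_.n_nodes + 2 * sys_.n_wk)


class TestQuiescence:
    def test_uniform_state_is_stationary(self):
        """All pressures at the terminal reference with zero inflow: the
        system must not move (discrete steady state)."""
        cfg = ScenarioConfig.bench()
        sys_ = build_open_system(cfg)
        p_ven = sys_.bridges[0].p_ven_fixed
        sys_.inflow = lambda t: 0.0
        for net, no in zip(sys_.networks, sys_.node_offset):
            sys_.set_initial_pressure(0, p_ven)
        sys_.wk_pa[:] = p_ven
        sys_.wk_pv[:] = p_ven
        from circwave.constitutive import area_from_pressure
        sys_.wk_Aa = np.array([area_from_pressure(p_ven, b.wall_art)
                               for b in sys_.bridges])
        sys_.wk_Av = np.array([area_from_pressure(p_ven, b.wall_ven)
                               for b in sys_.bridges])
        sys_.wk_Va = sys_._wk_lav * sys_.wk_Aa
        sys_.wk_Vv = sys_._wk_lav * sys_.wk_Av
        # bed resistors see equal pressures on both sides -> zero flow
        p_before = sys_.p.copy()
        for _ in range(20):
            sys_.step(1e-3)
        assert np.allclose(sys_.p, p_before, atol=1e-6)
        assert np.allclose(sys_.q, 0.0, atol=1e-12)


class TestDalembert:
    def test_matched_tube_transports_without_reflection(self):
        sys_, disc, c, zc, p0 = matched_tube_system()
        probe_in = disc.probe_node(1, 0.1)
        probe_out = disc.probe_node(1, 0.9)
        n = 1800
        rec_in = np.empty(n)
        rec_out = np.empty(n)
        for j in range(n):
            sys_.step(1e-4)
            rec_in[j] = sys_.p[probe_in]
            rec_out[j] = sys_.p[probe_out]
        rec_in -= p0
        rec_out -= p0
        # delay between probes matches the wave speed
        lag = (np.argmax(rec_out) - np.argmax(rec_in)) * 1e-4
        assert lag == pytest.approx(0.32 / c, rel=0.08)
        # shape preserved: peak amplitudes agree
        assert rec_out.max() == pytest.approx(rec_in.max(), rel=0.02)
        # after the pulse has fully passed the inlet probe, anything seen
        # there is a reflection from the termination: must stay below 2%
        passed = int(0.09 / 1e-4)
        assert np.max(np.abs(rec_in[passed:])) < 0.02 * rec_in.max()

    def test_incident_amplitude_is_zc_times_flow(self):
        sys_, disc, c, zc, p0 = matched_tube_system()
        probe = disc.probe_node(1, 0.5)
        peak = 0.0
        for j in range(900):
            sys_.step(1e-4)
            peak = max(peak, sys_.p[probe] - p0)
        assert peak == pytest.approx(zc * 2e-6, rel=0.05)


class TestConservation:
    def test_mass_residual_below_threshold(self):
        sys_ = build_open_system(ScenarioConfig.bench())
        for _ in range(100):
            sys_.step(1e-3)
        assert sys_.mass_residual() <= 1e-10

    def test_injected_volume_is_stored_exactly(self):
        """A constant source into a sealed single tube raises the stored
        volume by exactly the injected amount."""
        tree = load_network(
            make_network_csv(["1,t,artery,0.2,0.01,0.01,8,0.02,105,0,A,B"]),
            make_terminal_csv(["1,1.0"]))
        disc = discretize(tree, 0.02)
        s = 1e-6  # 1 ml/s
        sys_ = TLSystem([disc], [], inflow=lambda t: s, const=CONST)
        v0 = sys_.total_volume()
        n = 500
        for _ in range(n):
            sys_.step(1e-3)
        assert (sys_.total_volume() - v0) == pytest.approx(s * n * 1e-3,
                                                           rel=1e-9)


class TestDeterminism:
    def test_bit_identical_reruns(self):
        res = []
        for _ in range(2):
            sys_ = build_open_system(ScenarioConfig.bench())
            for _ in range(120):
                sys_.step(1e-3)
            res.append((sys_.p.copy(), sys_.q.copy()))
        assert np.array_equal(res[0][0], res[1][0])
        assert np.array_equal(res[0][1], res[1][1])


class TestSimulateProtocol:
    def test_infinite_tolerance_converges_after_two_cycles(self):
        sys_ = build_open_system(ScenarioConfig.bench())
        res = sys_.simulate(5, dt=1e-3, convergence_tol_mmhg=float("inf"),
                            min_cycles=2)
        assert res.converged
        assert res.cycles_run == 2

    def test_benchmark_converges_within_sixteen_cycles(self):
        sys_ = build_open_system(ScenarioConfig.bench())
        res = sys_.simulate(16, dt=1e-3, convergence_tol_mmhg=0.1)
        assert res.converged

    def test_invalid_arguments(self):
        sys_ = build_open_system(ScenarioConfig.bench())
        with pytest.raises(ValueError):
            sys_.simulate(0)
        with pytest.raises(ValueError):
            sys_.step(0.0)
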