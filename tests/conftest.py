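"""Shared fixtures: tiny in-memory networks and (session-scoped) scenario runs."""

from __future__ import annotations

import io
import textwrap

import numpy as np
import pytest

from circwave.constitutive import MMHG
from circwave.network import load_network


NETWORK_HEADER = ("id,name,class,length_m,r0_prox_m,r0_dist_m,k,b,"
                  "p0_mmHg,pext_mmHg,prox_node,dist_node")


def make_network_csv(rows: list[str]) -> io.StringIO:
    return io.StringIO(NETWORK_HEADER + "\n" + "\n".join(rows) + "\n")


def make_terminal_csv(rows: list[str]) -> io.StringIO:
    return io.StringIO("segment_id,flow_fraction\n" + "\n".join(rows) + "\n")


@pytest.fixture
def single_tube_tree():
    """One 0.4 m uniform artery with a single terminal bed."""
    net = make_network_csv(
        ["1,test_tube,artery,0.4,0.01,0.01,8,0.02,105,0,ROOT,END"])
    term = make_terminal_csv(["1,1.0"])
    return load_network(net, term)


@pytest.fixture
def y_tree():
    """Aorta-like parent bifurcating into two daughters."""
    net = make_network_csv([
        "1,parent,artery,0.2,0.01,0.009,4,0.02,105,0,ROOT,J",
        "2,child_a,artery,0.2,0.006,0.005,6,0.02,105,0,J,EA",
        "3,child_b,artery,0.3,0.005,0.004,6,0.02,105,0,J,EB",
    ])
    term = make_terminal_csv(["2,0.6", "3,0.4"])
    return load_network(net, term)


# ---------------------------------------------------------------------------
# expensive scenario runs, shared across the whole session
# ---------------------------------------------------------------------------

@pytest.fixture(scope="session")
def bench_run():
    from circwave.scenarios import run_benchmark
    return run_benchmark()


@pytest.fixture(scope="session")
def ref_run():
    from circwave.scenarios import ScenarioConfig, run_closed
    return run_closed(ScenarioConfig.ref(n_cycles=55, convergence_tol_mmhg=0.5))


@pytest.fixture(scope="session")
def hyp_run():
    from circwave.scenarios import ScenarioConfig, run_closed
    return run_closed(ScenarioConfig.hyp(n_cycles=55, convergence_tol_mmhg=0.5))
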