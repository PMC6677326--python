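"""Network I/O, validation and discretization tests."""

import io

import numpy as np
import pytest

from circwave.constitutive import MMHG
from circwave.network import (NetworkError, discretize, load_network,
                              save_network)
from circwave.scenarios import data_path

from conftest import make_network_csv, make_terminal_csv


@pytest.fixture
def arterial_tree():
    return load_network(data_path("arteries_synthetic.csv"),
                        data_path("terminals_synthetic.csv"))


class TestLoading:
    def test_single_segment_minimal_tree(self, single_tube_tree):
        assert len(single_tube_tree.segments) == 1
        assert len(single_tube_tree.terminals) == 1
        seg = single_tube_tree.segments[1]
        assert seg.p0 == pytest.approx(105 * MMHG)

    def test_arterial_fixture_fractions_sum_to_one(self, arterial_tree):
        total = sum(t.flow_fraction for t in arterial_tree.terminals)
        assert total == pytest.approx(1.0, abs=1e-9)

    def test_regional_flow_distribution(self, arterial_tree):
        """Resting flow split: 21% head, 47% abdomen, 18% pelvis+legs,
        14% upper extremities."""
        regions = {
            "head": ("carotid", "vertebral"),
            "abdomen": ("celiac", "mesenteric", "renal"),
            "legs": ("iliac", "tibial"),
            "arms": ("radial", "ulnar", "interosseous"),
        }
        sums = dict.fromkeys(regions, 0.0)
        for t in arterial_tree.terminals:
            name = arterial_tree.segments[t.segment_id].name
            for region, keys in regions.items():
                if any(k in name for k in keys):
                    sums[region] += t.flow_fraction
        assert sums["head"] == pytest.approx(0.21, abs=1e-9)
        assert sums["abdomen"] == pytest.approx(0.47, abs=1e-9)
        assert sums["legs"] == pytest.approx(0.18, abs=1e-9)
        assert sums["arms"] == pytest.approx(0.14, abs=1e-9)

    def test_no_cerebral_or_coronary_vessels(self, arterial_tree):
        names = " ".join(s.name for s in arterial_tree.segments.values())
        assert "cerebral" not in names and "coronary" not in names

    def test_undefined_node_rejected(self):
        net = make_network_csv([
            "1,a,artery,0.1,0.01,0.01,8,0.02,105,0,ROOT,J",
            "2,b,artery,0.1,0.01,0.01,8,0.02,105,0,X,END",
        ])
        with pytest.raises(NetworkError, match="dangling|reachable"):
            load_network(net, make_terminal_csv(["2,1.0"]))

    def test_duplicate_id_rejected(self):
        net = make_network_csv([
            "1,a,artery,0.1,0.01,0.01,8,0.02,105,0,ROOT,J",
            "1,b,artery,0.1,0.01,0.01,8,0.02,105,0,J,END",
        ])
        with pytest.raises(NetworkError, match="duplicate"):
            load_network(net, make_terminal_csv(["1,1.0"]))

    def test_missing_terminal_rejected(self, y_tree):
        net = make_network_csv([
            "1,a,artery,0.1,0.01,0.01,8,0.02,105,0,ROOT,END"])
        with pytest.raises(NetworkError, match="terminal"):
            load_network(net, make_terminal_csv(["1,0.5"]))

    def test_malformed_row_names_row(self):
        net = make_network_csv([
            "1,a,artery,not_a_number,0.01,0.01,8,0.02,105,0,ROOT,END"])
        with pytest.raises(NetworkError, match="row 1"):
            load_network(net, make_terminal_csv(["1,1.0"]))

    def test_cycle_rejected(self):
        net = make_network_csv([
            "1,a,artery,0.1,0.01,0.01,8,0.02,105,0,ROOT,J",
            "2,b,artery,0.1,0.01,0.01,8,0.02,105,0,J,ROOT",
        ])
        with pytest.raises(NetworkError, match="cycle"):
            load_network(net, make_terminal_csv(["2,1.0"]))

    def test_merged_tube_alias_resolution(self):
        bench = load_network(data_path("benchmark_arteries_synthetic.csv"),
                             data_path("benchmark_terminals_synthetic.csv"))
        seg = bench.resolve_id(2)  # alias of the merged "1+2" tube
        assert seg.label == "1+2"
        assert bench.resolve_id(27).label == "19+27"

    def test_roundtrip_serialization(self, arterial_tree, tmp_path):
        net_f = tmp_path / "net.csv"
        term_f = tmp_path / "term.csv"
        save_network(arterial_tree, net_f, term_f)
        again = load_network(net_f, term_f)
        assert set(again.segments) == set(arterial_tree.segments)
        for sid, seg in arterial_tree.segments.items():
            other = again.segments[sid]
            for attr in ("name", "length", "r0_prox", "r0_dist", "k", "b",
                         "p0", "p_ext", "prox_node", "dist_node", "aliases"):
                assert getattr(other, attr) == getattr(seg, attr), attr
        assert again.terminals == arterial_tree.terminals


class TestDiscretize:
    def test_exact_division(self, single_tube_tree):
        # 0.4 m at dz = 0.02 -> 20 equal elements; also 0.10/0.02 -> 5
        d = discretize(single_tube_tree, 0.02)
        assert d.n_elements == 20
        assert np.allclose(d.e_dz, 0.02)

    def test_ceiling_rule_with_remainder(self):
        tree = load_network(
            make_network_csv(["1,t,artery,0.05,0.01,0.01,8,0.02,105,0,A,B"]),
            make_terminal_csv(["1,1.0"]))
        d = discretize(tree, 0.02)
        assert d.n_elements == 3
        assert np.allclose(np.sort(d.e_dz), [0.01, 0.02, 0.02])
        assert d.e_dz.sum() == pytest.approx(0.05, abs=1e-12)

    def test_uniform_tube_has_identical_coefficients(self, single_tube_tree):
        d = discretize(single_tube_tree, 0.02)
        assert np.allclose(d.e_R, d.e_R[0])
        assert np.allclose(d.e_L, d.e_L[0])

    def test_tapered_coefficients_bracketed_by_end_values(self, y_tree):
        """Refining dz keeps each element's per-length R, L within the
        range spanned by the segment's end radii."""
        from circwave.constitutive import line_resistance, womersley_number
        for dz in (0.02, 0.01):
            d = discretize(y_tree, dz)
            for sid, seg in y_tree.segments.items():
                idx = d.segment_elements(sid)
                assert d.e_dz[idx].sum() == pytest.approx(seg.length, abs=1e-12)
                R_per_len = d.e_R[idx] / d.e_dz[idx]
                bounds = sorted(
                    line_resistance(womersley_number(r), np.pi * r**2)
                    for r in (seg.r0_prox, seg.r0_dist))
                assert np.all(R_per_len >= bounds[0] * (1 - 1e-9))
                assert np.all(R_per_len <= bounds[1] * (1 + 1e-9))

    def test_invalid_dz_rejected(self, single_tube_tree):
        with pytest.raises(ValueError):
            discretize(single_tube_tree, 0.0)

    def test_path_lengths(self, y_tree):
        d = discretize(y_tree, 0.02)
        assert d.node_path_length[d.leaf_node(2)] == pytest.approx(0.4)
        assert d.node_path_length[d.leaf_node(3)] == pytest.approx(0.5)

    def test_venous_orientation_leaf_detection(self):
        """Veins run periphery -> heart; the free end is proximal."""
        net = make_network_csv([
            "101,vein_trunk,vein,0.2,0.012,0.012,10,0.02,1.1,0,VJ,VROOT",
            "102,vein_branch,vein,0.2,0.008,0.008,10,0.02,1.1,0,VEND,VJ",
        ])
        tree = load_network(net, make_terminal_csv(["102,1.0"]),
                            root_node="VROOT")
        assert tree.leaf_end(102) == "VEND"
        d = discretize(tree, 0.05)
        assert d.node_labels[d.leaf_node(102)] == "VEND"
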