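"""Vascular tree representation, CSV I/O, validation and discretization.

A circulation side (arterial or venous) is a tree of tapered elastic tubes.
Each :class:`VesselSegment` is oriented proximal->distal in the direction of
mean blood flow; every leaf either is the root attachment (aortic root /
vena-cava--atrium junction) or carries a :class:`TerminalSpec` assigning it a
fraction of the mean systemic flow.  Merged tubes (e.g. an ascending aorta +
arch modelled as one line) keep an alias list so reports can use compound
labels like ``"1+2"``.

Discretization chops every segment into elements of nominal length ``dz``
(ceiling rule; the last element of a segment may be shorter), interpolates
the reference radius linearly along the taper, and evaluates the
transmission-line coefficients of :mod:`circwave.constitutive` at the
mid-element geometry.

File formats (UTF-8, header row, '.' decimal):

``network.csv``
    id,name,class,length_m,r0_prox_m,r0_dist_m,k,b,p0_mmHg,pext_mmHg,
    prox_node,dist_node  -- ``id`` may be a merged label such as ``1+2``.

``terminals.csv``
    segment_id,flow_fraction[,venous_segment_id] -- the optional third
    column pairs an arterial terminal with the venous leaf its bed drains
    into (closed-loop use).
"""

from __future__ import annotations

import io
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .constitutive import (
    MMHG,
    PhysicalConstants,
    WallLawParams,
    area_from_pressure,
    compliance,
    line_inertance,
    line_resistance,
    womersley_number,
)

__all__ = [
    "VesselSegment",
    "TerminalSpec",
    "VascularTree",
    "DiscretizedNetwork",
    "load_network",
    "save_network",
    "load_terminals",
    "discretize",
    "NetworkError",
]


class NetworkError(ValueError):
    """Malformed network file or inconsistent topology."""


@dataclass
class VesselSegment:
    """One named tapered tube (SI units)."""

    id: int
    name: str
    vessel_class: str  # "artery" | "vein"
    length: float
    r0_prox: float
    r0_dist: float
    k: float
    b: float
    p0: float
    p_ext: float
    prox_node: str
    dist_node: str
    aliases: tuple[int, ...] = ()

    def __post_init__(self) -> None:
        if self.length <= 0:
            raise NetworkError(f"segment {self.label}: length must be > 0")
        if self.r0_prox <= 0 or self.r0_dist <= 0:
            raise NetworkError(f"segment {self.label}: radii must be > 0")
        if self.k <= 0:
            raise NetworkError(f"segment {self.label}: k must be > 0")
        if not 0.0 < self.b < 0.1:
            raise NetworkError(f"segment {self.label}: b must be in (0, 0.1)")
        if self.p0 <= 0:
            raise NetworkError(f"segment {self.label}: p0 must be > 0")
        if self.vessel_class not in ("artery", "vein"):
            raise NetworkError(f"segment {self.label}: bad class {self.vessel_class}")

    @property
    def label(self) -> str:
        ids = self.aliases if self.aliases else (self.id,)
        return "+".join(str(i) for i in ids)

    def radius_at(self, s: float) -> float:
        """Reference radius at relative position s in [0, 1] (linear taper)."""
        return self.r0_prox + (self.r0_dist - self.r0_prox) * s

    def wall_params(self, s: float = 0.5) -> WallLawParams:
        r = self.radius_at(s)
        return WallLawParams(p0=self.p0, A0=math.pi * r * r, k=self.k,
                             b=self.b, p_ext=self.p_ext)


@dataclass(frozen=True)
class TerminalSpec:
    """Terminal bed attachment: which tube, what fraction of mean flow."""

    segment_id: int
    flow_fraction: float
    venous_segment_id: int | None = None


@dataclass
class VascularTree:
    """Validated tree of one circulation side plus its terminal beds."""

    segments: dict[int, VesselSegment]
    terminals: list[TerminalSpec]
    root_node: str
    junctions: dict[str, list[tuple[int, str]]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.junctions = {}
        for seg in self.segments.values():
            self.junctions.setdefault(seg.prox_node, []).append((seg.id, "prox"))
            self.junctions.setdefault(seg.dist_node, []).append((seg.id, "dist"))
        self.validate()

    # -- queries ---------------------------------------------------------
    def segment_by_name(self, name: str) -> VesselSegment:
        for seg in self.segments.values():
            if seg.name == name:
                return seg
        raise KeyError(name)

    def resolve_id(self, ident: int) -> VesselSegment:
        if ident in self.segments:
            return self.segments[ident]
        for seg in self.segments.values():
            if ident in seg.aliases:
                return seg
        raise KeyError(ident)

    @property
    def terminal_ids(self) -> set[int]:
        return {t.segment_id for t in self.terminals}

    def leaf_segments(self) -> list[VesselSegment]:
        """Segments with a free (degree-1, non-root) end.

        Arteries hang their free end distally; veins, being oriented
        periphery->heart, hang it proximally.
        """
        out = []
        for seg in self.segments.values():
            for node in (seg.prox_node, seg.dist_node):
                if node != self.root_node and len(self.junctions[node]) == 1:
                    out.append(seg)
                    break
        return out

    def leaf_end(self, seg_id: int) -> str:
        """Node label of the free end of a leaf segment."""
        seg = self.resolve_id(seg_id)
        for node in (seg.dist_node, seg.prox_node):
            if node != self.root_node and len(self.junctions[node]) == 1:
                return node
        raise NetworkError(f"segment {seg.label} is not a leaf")

    def total_length(self) -> float:
        return sum(s.length for s in self.segments.values())

    def path_length(self, node: str) -> float:
        """Along-tree distance from the root node to ``node``."""
        dist = {self.root_node: 0.0}
        stack = [self.root_node]
        while stack:
            n = stack.pop()
            for sid, end in self.junctions[n]:
                seg = self.segments[sid]
                other = seg.dist_node if end == "prox" else seg.prox_node
                if other not in dist:
                    dist[other] = dist[n] + seg.length
                    stack.append(other)
        if node not in dist:
            raise NetworkError(f"node {node!r} not reachable from root")
        return dist[node]

    # -- validation ------------------------------------------------------
    def validate(self) -> None:
        if self.root_node not in self.junctions:
            raise NetworkError(f"root node {self.root_node!r} not present in network")
        seen: set[int] = set()
        for seg in self.segments.values():
            for i in (seg.id, *seg.aliases):
                if i in seen and i != seg.id:
                    raise NetworkError(f"duplicate segment id {i}")
                seen.add(i)
        # connectivity: every node reachable from root; no cycles
        visited: set[str] = set()
        edges_used = 0
        stack = [self.root_node]
        visited.add(self.root_node)
        while stack:
            n = stack.pop()
            for sid, end in self.junctions[n]:
                seg = self.segments[sid]
                other = seg.dist_node if end == "prox" else seg.prox_node
                if other not in visited:
                    visited.add(other)
                    edges_used += 1
                    stack.append(other)
        if visited != set(self.junctions):
            dangling = sorted(set(self.junctions) - visited)
            raise NetworkError(f"dangling node(s) not reachable from root: {dangling}")
        if edges_used != len(self.segments):
            raise NetworkError("network contains a cycle; each side must be a tree")
        # every leaf except the root needs a terminal spec
        term_ids = self.terminal_ids
        for seg in self.leaf_segments():
            if seg.dist_node == self.root_node:
                continue
            if seg.id not in term_ids:
                raise NetworkError(
                    f"leaf segment {seg.label} ({seg.name}) has no terminal spec")
        for t in self.terminals:
            if t.segment_id not in self.segments:
                raise NetworkError(f"terminal references unknown segment {t.segment_id}")
        if self.terminals:
            total = sum(t.flow_fraction for t in self.terminals)
            if abs(total - 1.0) > 1e-9:
                raise NetworkError(f"terminal flow fractions sum to {total}, not 1")


def _parse_id(label: str) -> tuple[int, tuple[int, ...]]:
    parts = str(label).strip().split("+")
    try:
        ids = tuple(int(p) for p in parts)
    except ValueError as exc:
        raise NetworkError(f"malformed segment id {label!r}") from exc
    return ids[0], (ids if len(ids) > 1 else ())


_NETWORK_COLS = ["id", "name", "class", "length_m", "r0_prox_m", "r0_dist_m",
                 "k", "b", "p0_mmHg", "pext_mmHg", "prox_node", "dist_node"]


def load_network(network_file, terminal_file=None, root_node: str | None = None,
                 p0_override_mmHg: float | None = None) -> VascularTree:
    """Read a vessel-network CSV (+ optional terminal CSV) into a tree.

    ``root_node`` defaults to the prox node of the segment with the lowest id.
    ``p0_override_mmHg`` replaces every per-segment reference pressure, which
    is how scenario configurations impose a global p0.
    """
    df = pd.read_csv(network_file, dtype=str, skipinitialspace=True)
    missing = [c for c in _NETWORK_COLS if c not in df.columns]
    if missing:
        raise NetworkError(f"network file missing column(s): {missing}")
    segments: dict[int, VesselSegment] = {}
    for row_no, row in df.iterrows():
        try:
            sid, aliases = _parse_id(row["id"])
            p0 = (p0_override_mmHg if p0_override_mmHg is not None
                  else float(row["p0_mmHg"]))
            seg = VesselSegment(
                id=sid, name=str(row["name"]).strip(),
                vessel_class=str(row["class"]).strip(),
                length=float(row["length_m"]),
                r0_prox=float(row["r0_prox_m"]), r0_dist=float(row["r0_dist_m"]),
                k=float(row["k"]), b=float(row["b"]),
                p0=p0 * MMHG, p_ext=float(row["pext_mmHg"]) * MMHG,
                prox_node=str(row["prox_node"]).strip(),
                dist_node=str(row["dist_node"]).strip(),
                aliases=aliases,
            )
        except (ValueError, KeyError) as exc:
            raise NetworkError(f"malformed row {row_no + 1} of {network_file}: {exc}") from exc
        if seg.id in segments:
            raise NetworkError(f"duplicate segment id {seg.id} in {network_file}")
        segments[seg.id] = seg
    terminals = load_terminals(terminal_file) if terminal_file is not None else []
    if root_node is None:
        root_node = segments[min(segments)].prox_node
    return VascularTree(segments=segments, terminals=terminals, root_node=root_node)


def load_terminals(terminal_file) -> list[TerminalSpec]:
    df = pd.read_csv(terminal_file, skipinitialspace=True)
    if not {"segment_id", "flow_fraction"} <= set(df.columns):
        raise NetworkError("terminal file needs columns segment_id,flow_fraction")
    out = []
    for _, row in df.iterrows():
        ven = row.get("venous_segment_id")
        ven_id = None if ven is None or (isinstance(ven, float) and math.isnan(ven)) else int(ven)
        out.append(TerminalSpec(segment_id=int(row["segment_id"]),
                                flow_fraction=float(row["flow_fraction"]),
                                venous_segment_id=ven_id))
    return out


def save_network(tree: VascularTree, network_file, terminal_file=None) -> None:
    """Serialize back to the CSV dialect of :func:`load_network` (round-trips)."""
    rows = []
    for seg in sorted(tree.segments.values(), key=lambda s: s.id):
        rows.append({
            "id": seg.label, "name": seg.name, "class": seg.vessel_class,
            "length_m": repr(seg.length),
            "r0_prox_m": repr(seg.r0_prox), "r0_dist_m": repr(seg.r0_dist),
            "k": repr(seg.k), "b": repr(seg.b),
            "p0_mmHg": repr(seg.p0 / MMHG), "pext_mmHg": repr(seg.p_ext / MMHG),
            "prox_node": seg.prox_node, "dist_node": seg.dist_node,
        })
    pd.DataFrame(rows, columns=_NETWORK_COLS).to_csv(network_file, index=False)
    if terminal_file is not None:
        trows = [{"segment_id": t.segment_id, "flow_fraction": repr(t.flow_fraction),
                  "venous_segment_id": t.venous_segment_id} for t in tree.terminals]
        pd.DataFrame(trows).to_csv(terminal_file, index=False)


# ---------------------------------------------------------------------------
# discretization
# ---------------------------------------------------------------------------

@dataclass
class DiscretizedNetwork:
    """Per-element TL coefficients and global node numbering (0-based).

    Element arrays are ordered segment by segment, proximal to distal.
    ``e_R``/``e_L`` are lumped over the element (per-unit-length coefficient
    times element length); the compliance is pressure-dependent and is
    therefore represented by per-element wall-law parameter arrays, from
    which the solver re-evaluates nodal compliance at the current pressure.
    """

    tree: VascularTree
    dz: float
    const: PhysicalConstants
    # nodes
    n_nodes: int
    node_labels: list[str]
    label_to_node: dict[str, int]
    root: int
    node_path_length: np.ndarray
    # elements
    e_prox: np.ndarray
    e_dist: np.ndarray
    e_dz: np.ndarray
    e_A0: np.ndarray          # mid-element reference area
    e_R: np.ndarray           # lumped resistance, Pa s m^-3
    e_L: np.ndarray           # lumped inertance, Pa s^2 m^-3
    e_seg: np.ndarray         # parent segment id
    e_mid_pos: np.ndarray     # segment-relative position of element centre
    # wall-law parameter arrays (per element)
    e_p0: np.ndarray
    e_k: np.ndarray
    e_b: np.ndarray
    e_pext: np.ndarray

    @property
    def n_elements(self) -> int:
        return self.e_prox.size

    def segment_elements(self, seg_id: int) -> np.ndarray:
        seg = self.tree.resolve_id(seg_id)
        return np.flatnonzero(self.e_seg == seg.id)

    def probe_element(self, seg_id: int, rel_pos: float = 0.5) -> int:
        """Element of a segment closest to relative position ``rel_pos``."""
        idx = self.segment_elements(seg_id)
        if idx.size == 0:
            raise KeyError(f"segment {seg_id} not in network")
        return int(idx[np.argmin(np.abs(self.e_mid_pos[idx] - rel_pos))])

    def probe_node(self, seg_id: int, rel_pos: float = 0.5) -> int:
        """Node of a segment closest to relative position ``rel_pos``."""
        idx = self.segment_elements(seg_id)
        seg = self.tree.resolve_id(seg_id)
        # candidate nodes with their relative positions
        ln = np.cumsum(self.e_dz[idx])
        nodes = np.concatenate(([self.e_prox[idx[0]]], self.e_dist[idx]))
        pos = np.concatenate(([0.0], ln / seg.length))
        return int(nodes[np.argmin(np.abs(pos - rel_pos))])

    def leaf_node(self, seg_id: int) -> int:
        seg = self.tree.resolve_id(seg_id)
        return self.label_to_node[self.tree.leaf_end(seg.id)]

    def _end_arrays(self):
        """Per element-end arrays (prox ends then dist ends), cached."""
        if not hasattr(self, "_ends"):
            self._ends = {
                "nodes": np.concatenate([self.e_prox, self.e_dist]),
                "p0": np.concatenate([self.e_p0, self.e_p0]),
                "k": np.concatenate([self.e_k, self.e_k]),
                "b": np.concatenate([self.e_b, self.e_b]),
                "pext": np.concatenate([self.e_pext, self.e_pext]),
                "A0": np.concatenate([self.e_A0, self.e_A0]),
                "dz2": 0.5 * np.concatenate([self.e_dz, self.e_dz]),
            }
        return self._ends

    def nodal_compliance(self, p_nodes: np.ndarray, A_cache: np.ndarray) -> np.ndarray:
        """Sum of adjacent half-element compliances at the current areas.

        ``A_cache`` (shape: 2*n_elements, prox ends then dist ends) holds the
        lumen area per element end, kept consistent with the nodal state by
        :meth:`pressure_from_volume`.
        """
        e = self._end_arrays()
        x = A_cache / e["A0"]
        dpdA = (e["p0"] / e["A0"]) * ((1.0 + e["b"]) * (1.0 + e["k"] / 3.0)
                                      * x ** (e["k"] / 3.0) + e["b"] / x**2)
        Cn = np.zeros(self.n_nodes)
        np.add.at(Cn, e["nodes"], e["dz2"] / dpdA)
        return Cn

    def node_volumes(self, A_cache: np.ndarray) -> np.ndarray:
        """Blood volume attributed to each node (adjacent half-elements)."""
        e = self._end_arrays()
        V = np.zeros(self.n_nodes)
        np.add.at(V, e["nodes"], e["dz2"] * A_cache)
        return V

    def pressure_from_volume(self, p_guess: np.ndarray, V_target: np.ndarray,
                             A_cache: np.ndarray, n_iter: int = 2) -> np.ndarray:
        """Nodal pressures consistent with exactly the target node volumes.

        Newton iteration on the common nodal pressure with the half-element
        areas as the volume carriers; afterwards the areas are rescaled so
        the stored volume matches ``V_target`` to machine precision (the
        conservative step of the solver).  ``A_cache`` is updated in place.
        """
        e = self._end_arrays()
        nodes = e["nodes"]
        p = p_guess.copy()
        for _ in range(n_iter):
            pn = p[nodes]
            x = A_cache / e["A0"]
            f = (-e["pext"] + e["p0"] * ((1.0 + e["b"]) * x ** (1.0 + e["k"] / 3.0)
                                         - e["b"] / x) - pn)
            dpdA = (e["p0"] / e["A0"]) * ((1.0 + e["b"]) * (1.0 + e["k"] / 3.0)
                                          * x ** (e["k"] / 3.0) + e["b"] / x**2)
            A_cache *= np.exp(-np.clip(f / (dpdA * A_cache), -0.5, 0.5))
            V = np.zeros(self.n_nodes)
            np.add.at(V, nodes, e["dz2"] * A_cache)
            Cn = np.zeros(self.n_nodes)
            np.add.at(Cn, nodes, e["dz2"] / dpdA)
            p = p - (V - V_target) / Cn
        # pin the stored volume exactly (scale factor is ~1 +- 1e-8)
        V = np.zeros(self.n_nodes)
        np.add.at(V, nodes, e["dz2"] * A_cache)
        scale = np.where(V > 0, V_target / V, 1.0)
        A_cache *= scale[nodes]
        return p

    def initial_area_cache(self, p_nodes: np.ndarray) -> np.ndarray:
        nodes = np.concatenate([self.e_prox, self.e_dist])
        A = np.empty(2 * self.n_elements)
        for i, (n, A0, p0, k, b, pext) in enumerate(zip(
                nodes, np.concatenate([self.e_A0] * 2),
                np.concatenate([self.e_p0] * 2), np.concatenate([self.e_k] * 2),
                np.concatenate([self.e_b] * 2), np.concatenate([self.e_pext] * 2))):
            wall = WallLawParams(p0=p0, A0=A0, k=k, b=b, p_ext=pext)
            A[i] = area_from_pressure(float(p_nodes[n]), wall)
        return A


def discretize(tree: VascularTree, dz: float = 0.02,
               operating_pressure: float | None = None,
               const: PhysicalConstants = PhysicalConstants()) -> DiscretizedNetwork:
    """Chop the tree into TL elements of nominal length ``dz``.

    ``operating_pressure`` (Pa, transmural) sets the area at which the
    element R, L are evaluated; default is each segment's reference pressure,
    i.e. the reference geometry.
    """
    if dz <= 0:
        raise ValueError("dz must be positive")
    node_labels: list[str] = []
    label_to_node: dict[str, int] = {}

    def node_index(label: str) -> int:
        if label not in label_to_node:
            label_to_node[label] = len(node_labels)
            node_labels.append(label)
        return label_to_node[label]

    node_index(tree.root_node)
    e_prox, e_dist, e_dz, e_A0 = [], [], [], []
    e_R, e_L, e_seg, e_mid = [], [], [], []
    e_p0, e_k, e_b, e_pext = [], [], [], []
    for seg in sorted(tree.segments.values(), key=lambda s: s.id):
        n_el = max(1, math.ceil(round(seg.length / dz, 9)))
        bounds = np.minimum(np.arange(n_el + 1) * dz, seg.length)
        prox_idx = node_index(seg.prox_node)
        for j in range(n_el):
            z0, z1 = bounds[j], bounds[j + 1]
            dzj = z1 - z0
            mid = 0.5 * (z0 + z1) / seg.length
            r_mid = seg.radius_at(mid)
            A0 = math.pi * r_mid**2
            if operating_pressure is not None:
                wall = WallLawParams(p0=seg.p0, A0=A0, k=seg.k, b=seg.b,
                                     p_ext=seg.p_ext)
                A_op = area_from_pressure(operating_pressure, wall)
                r_op = math.sqrt(A_op / math.pi)
            else:
                A_op, r_op = A0, r_mid
            alpha0 = womersley_number(r_op, const)
            R = line_resistance(alpha0, A_op, const)
            L = line_inertance(alpha0, A_op, const)
            dist_label = (seg.dist_node if j == n_el - 1
                          else f"__{seg.id}_{j}")
            dist_idx = node_index(dist_label)
            e_prox.append(prox_idx)
            e_dist.append(dist_idx)
            e_dz.append(dzj)
            e_A0.append(A0)
            e_R.append(R * dzj)
            e_L.append(L * dzj)
            e_seg.append(seg.id)
            e_mid.append(mid)
            e_p0.append(seg.p0)
            e_k.append(seg.k)
            e_b.append(seg.b)
            e_pext.append(seg.p_ext)
            prox_idx = dist_idx

    n_nodes = len(node_labels)
    e_prox = np.asarray(e_prox)
    e_dist = np.asarray(e_dist)
    e_dz_arr = np.asarray(e_dz)
    # along-tree path length per node (for pulse-transit distances)
    path = np.full(n_nodes, np.nan)
    path[label_to_node[tree.root_node]] = 0.0
    pending = True
    while pending:
        pending = False
        for i in range(e_prox.size):
            a, bnode = e_prox[i], e_dist[i]
            if np.isnan(path[bnode]) and not np.isnan(path[a]):
                path[bnode] = path[a] + e_dz_arr[i]
                pending = True
            elif np.isnan(path[a]) and not np.isnan(path[bnode]):
                path[a] = path[bnode] + e_dz_arr[i]
                pending = True
    return DiscretizedNetwork(
        tree=tree, dz=dz, const=const,
        n_nodes=n_nodes, node_labels=node_labels, label_to_node=label_to_node,
        root=label_to_node[tree.root_node], node_path_length=path,
        e_prox=e_prox, e_dist=e_dist, e_dz=e_dz_arr,
        e_A0=np.asarray(e_A0), e_R=np.asarray(e_R), e_L=np.asarray(e_L),
        e_seg=np.asarray(e_seg), e_mid_pos=np.asarray(e_mid),
        e_p0=np.asarray(e_p0), e_k=np.asarray(e_k), e_b=np.asarray(e_b),
        e_pext=np.asarray(e_pext),
    )
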