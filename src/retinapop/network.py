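"""Spatial-graph data model of a retinal vascular network.

A :class:`VascularNetwork` is a columnar graph: node coordinates (mm, fovea at
the origin, z the plexus depth) plus per-segment radius (µm), kind and plexus
labels. Storage is NumPy-columnar because capillary beds reach ~10^5 segments;
:meth:`VascularNetwork.node` / :meth:`VascularNetwork.segment` provide record
views for inspection and tests.

Serialization is a diffable JSON header (metadata) plus CSV node and segment
tables, and :func:`export_artifacts` writes legacy-ASCII VTK polydata for 3-D
viewers together with a per-segment CSV table.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field
from typing import NamedTuple, Optional

import numpy as np
import pandas as pd

__all__ = [
    "NODE_KINDS", "SEG_KINDS", "PLEXI",
    "Node", "Segment", "VascularNetwork",
    "save_network", "load_network", "export_artifacts",
]

NODE_KINDS = ("arterial", "venous", "capillary", "compartment", "root")
SEG_KINDS = ("artery", "vein", "capillary", "artificial")
PLEXI = ("SVP", "ICP", "DCP", "none")

_NODE_KIND_CODE = {k: i for i, k in enumerate(NODE_KINDS)}
_SEG_KIND_CODE = {k: i for i, k in enumerate(SEG_KINDS)}
_PLEXUS_CODE = {k: i for i, k in enumerate(PLEXI)}


class Node(NamedTuple):
    id: int
    x: float          # mm
    y: float          # mm
    z: float          # µm (plexus depth)
    kind: str
    plexus: str


class Segment(NamedTuple):
    id: int
    nodes: tuple[int, int]
    radius: float     # µm
    length: float     # mm
    kind: str
    plexus: str
    is_terminal: bool
    fixed_resistance: bool


@dataclass
class VascularNetwork:
    """Columnar spatial graph CRA -> arteries -> capillaries -> veins -> CRV."""

    xyz: np.ndarray = field(default_factory=lambda: np.empty((0, 3)))   # mm
    node_kind: np.ndarray = field(default_factory=lambda: np.empty(0, np.int8))
    node_plexus: np.ndarray = field(default_factory=lambda: np.empty(0, np.int8))
    conn: np.ndarray = field(default_factory=lambda: np.empty((0, 2), np.int64))
    radius_um: np.ndarray = field(default_factory=lambda: np.empty(0))
    seg_kind: np.ndarray = field(default_factory=lambda: np.empty(0, np.int8))
    seg_plexus: np.ndarray = field(default_factory=lambda: np.empty(0, np.int8))
    is_terminal: np.ndarray = field(default_factory=lambda: np.empty(0, bool))
    fixed_resistance: np.ndarray = field(default_factory=lambda: np.empty(0, bool))
    metadata: dict = field(default_factory=dict)

    # ------------------------------------------------------------------
    @property
    def n_nodes(self) -> int:
        return len(self.xyz)

    @property
    def n_segments(self) -> int:
        return len(self.conn)

    @property
    def length_mm(self) -> np.ndarray:
        """Euclidean 3-D segment lengths in mm (artificial segments included,
        but their length plays no role in the flow model)."""
        if self.n_segments == 0:
            return np.empty(0)
        d = self.xyz[self.conn[:, 0]] - self.xyz[self.conn[:, 1]]
        return np.sqrt((d * d).sum(axis=1))

    def node(self, i: int) -> Node:
        return Node(i, float(self.xyz[i, 0]), float(self.xyz[i, 1]),
                    float(self.xyz[i, 2] * 1e3), NODE_KINDS[self.node_kind[i]],
                    PLEXI[self.node_plexus[i]])

    def segment(self, j: int) -> Segment:
        return Segment(j, (int(self.conn[j, 0]), int(self.conn[j, 1])),
                       float(self.radius_um[j]), float(self.length_mm[j]),
                       SEG_KINDS[self.seg_kind[j]], PLEXI[self.seg_plexus[j]],
                       bool(self.is_terminal[j]), bool(self.fixed_resistance[j]))

    # ------------------------------------------------------------------
    def add_nodes(self, xyz: np.ndarray, kind: str, plexus: str = "none") -> np.ndarray:
        """Append nodes; returns their new ids."""
        xyz = np.atleast_2d(np.asarray(xyz, float))
        if xyz.shape[1] == 2:  # planar input at depth 0
            xyz = np.column_stack([xyz, np.zeros(len(xyz))])
        start = self.n_nodes
        self.xyz = np.vstack([self.xyz, xyz])
        self.node_kind = np.concatenate(
            [self.node_kind, np.full(len(xyz), _NODE_KIND_CODE[kind], np.int8)])
        self.node_plexus = np.concatenate(
            [self.node_plexus, np.full(len(xyz), _PLEXUS_CODE[plexus], np.int8)])
        return np.arange(start, start + len(xyz))

    def add_segments(self, conn, radius_um, kind: str, plexus: str = "none",
                     is_terminal=False, fixed_resistance=False) -> np.ndarray:
        conn = np.atleast_2d(np.asarray(conn, np.int64))
        m = len(conn)
        radius_um = np.broadcast_to(np.asarray(radius_um, float), (m,)).copy()
        if np.any(radius_um <= 0):
            raise ValueError("segment radius must be > 0")
        start = self.n_segments
        self.conn = np.vstack([self.conn, conn])
        self.radius_um = np.concatenate([self.radius_um, radius_um])
        self.seg_kind = np.concatenate(
            [self.seg_kind, np.full(m, _SEG_KIND_CODE[kind], np.int8)])
        self.seg_plexus = np.concatenate(
            [self.seg_plexus, np.full(m, _PLEXUS_CODE[plexus], np.int8)])
        self.is_terminal = np.concatenate(
            [self.is_terminal, np.broadcast_to(np.asarray(is_terminal, bool), (m,)).copy()])
        self.fixed_resistance = np.concatenate(
            [self.fixed_resistance,
             np.broadcast_to(np.asarray(fixed_resistance, bool), (m,)).copy()])
        return np.arange(start, start + m)

    # -- convenience masks ---------------------------------------------
    def seg_kind_mask(self, kind: str) -> np.ndarray:
        return self.seg_kind == _SEG_KIND_CODE[kind]

    def seg_plexus_mask(self, plexus: str) -> np.ndarray:
        return self.seg_plexus == _PLEXUS_CODE[plexus]

    def node_kind_mask(self, kind: str) -> np.ndarray:
        return self.node_kind == _NODE_KIND_CODE[kind]

    def midpoints(self) -> np.ndarray:
        return 0.5 * (self.xyz[self.conn[:, 0]] + self.xyz[self.conn[:, 1]])

    def degrees(self) -> np.ndarray:
        deg = np.zeros(self.n_nodes, np.int64)
        np.add.at(deg, self.conn.ravel(), 1)
        return deg

    def validate(self) -> None:
        if self.n_segments and self.conn.max(initial=-1) >= self.n_nodes:
            raise ValueError("segment endpoint references missing node")
        if np.any(self.radius_um <= 0):
            raise ValueError("non-positive segment radius")

    def __eq__(self, other: object) -> bool:  # field-for-field identity
        if not isinstance(other, VascularNetwork):
            return NotImplemented
        return (np.array_equal(self.xyz, other.xyz)
                and np.array_equal(self.node_kind, other.node_kind)
                and np.array_equal(self.node_plexus, other.node_plexus)
                and np.array_equal(self.conn, other.conn)
                and np.array_equal(self.radius_um, other.radius_um)
                and np.array_equal(self.seg_kind, other.seg_kind)
                and np.array_equal(self.seg_plexus, other.seg_plexus)
                and np.array_equal(self.is_terminal, other.is_terminal)
                and np.array_equal(self.fixed_resistance, other.fixed_resistance)
                and self.metadata == other.metadata)


# ----------------------------------------------------------------------
# Serialization: JSON header + CSV tables (diffable, language-agnostic).
# ----------------------------------------------------------------------

def save_network(network: VascularNetwork, path: str) -> None:
    """Write ``network.json``, ``nodes.csv`` and ``segments.csv`` under ``path``."""
    os.makedirs(path, exist_ok=True)
    header = {
        "format": "retinapop-network",
        "version": 1,
        "n_nodes": network.n_nodes,
        "n_segments": network.n_segments,
        "metadata": network.metadata,
    }
    with open(os.path.join(path, "network.json"), "w") as fh:
        json.dump(header, fh, indent=1)
    nodes = pd.DataFrame({
        "id": np.arange(network.n_nodes),
        "x_mm": network.xyz[:, 0], "y_mm": network.xyz[:, 1], "z_mm": network.xyz[:, 2],
        "kind": [NODE_KINDS[k] for k in network.node_kind],
        "plexus": [PLEXI[k] for k in network.node_plexus],
    })
    nodes.to_csv(os.path.join(path, "nodes.csv"), index=False,
                 float_format="%.17g")
    segs = pd.DataFrame({
        "id": np.arange(network.n_segments),
        "node_a": network.conn[:, 0], "node_b": network.conn[:, 1],
        "radius_um": network.radius_um,
        "kind": [SEG_KINDS[k] for k in network.seg_kind],
        "plexus": [PLEXI[k] for k in network.seg_plexus],
        "is_terminal": network.is_terminal.astype(int),
        "fixed_resistance": network.fixed_resistance.astype(int),
    })
    segs.to_csv(os.path.join(path, "segments.csv"), index=False,
                float_format="%.17g")


def load_network(path: str) -> VascularNetwork:
    with open(os.path.join(path, "network.json")) as fh:
        header = json.load(fh)
    if header.get("format") != "retinapop-network":
        raise ValueError(f"{path}: not a retinapop network (record 'format')")
    nodes = pd.read_csv(os.path.join(path, "nodes.csv"),
                        float_precision="round_trip")
    segs = pd.read_csv(os.path.join(path, "segments.csv"),
                       float_precision="round_trip")
    net = VascularNetwork(metadata=header.get("metadata", {}))
    if len(nodes):
        for col in ("x_mm", "y_mm", "z_mm", "kind", "plexus"):
            if col not in nodes:
                raise ValueError(f"nodes.csv: missing column '{col}'")
        net.xyz = nodes[["x_mm", "y_mm", "z_mm"]].to_numpy(float)
        try:
            net.node_kind = np.array([_NODE_KIND_CODE[k] for k in nodes["kind"]], np.int8)
            net.node_plexus = np.array([_PLEXUS_CODE[k] for k in nodes["plexus"]], np.int8)
        except KeyError as exc:  # pragma: no cover - malformed input
            raise ValueError(f"nodes.csv: unknown label {exc}") from None
    if len(segs):
        net.conn = segs[["node_a", "node_b"]].to_numpy(np.int64)
        net.radius_um = segs["radius_um"].to_numpy(float)
        try:
            net.seg_kind = np.array([_SEG_KIND_CODE[k] for k in segs["kind"]], np.int8)
            net.seg_plexus = np.array([_PLEXUS_CODE[k] for k in segs["plexus"]], np.int8)
        except KeyError as exc:  # pragma: no cover
            raise ValueError(f"segments.csv: unknown label {exc}") from None
        net.is_terminal = segs["is_terminal"].to_numpy(bool)
        net.fixed_resistance = segs["fixed_resistance"].to_numpy(bool)
    net.validate()
    return net


def export_artifacts(network: VascularNetwork, solution: Optional[object],
                     path: str, stem: str = "vasculature") -> list[str]:
    """Write a VTK legacy polydata file (points + lines with per-segment
    radius, and flow attributes when a solution is given) and a CSV segment
    table. Returns the written file paths."""
    os.makedirs(path, exist_ok=True)
    written = []
    vtk_path = os.path.join(path, f"{stem}.vtk")
    with open(vtk_path, "w") as fh:
        fh.write("# vtk DataFile Version 3.0\n")
        fh.write(f"retinapop network seed={network.metadata.get('seed', 'n/a')}\n")
        fh.write("ASCII\nDATASET POLYDATA\n")
        fh.write(f"POINTS {network.n_nodes} float\n")
        for p in network.xyz:
            fh.write(f"{p[0]:.6f} {p[1]:.6f} {p[2]:.6f}\n")
        m = network.n_segments
        fh.write(f"LINES {m} {3 * m}\n")
        for a, b in network.conn:
            fh.write(f"2 {a} {b}\n")
        fh.write(f"CELL_DATA {m}\nSCALARS radius_um float 1\nLOOKUP_TABLE default\n")
        for r in network.radius_um:
            fh.write(f"{r:.4f}\n")
        if solution is not None:
            fh.write("SCALARS flow_uL_min float 1\nLOOKUP_TABLE default\n")
            for q in solution.flow_uL_min:
                fh.write(f"{q:.6e}\n")
    written.append(vtk_path)

    table = pd.DataFrame({
        "id": np.arange(network.n_segments),
        "node_a": network.conn[:, 0], "node_b": network.conn[:, 1],
        "radius_um": network.radius_um, "length_mm": network.length_mm,
        "kind": [SEG_KINDS[k] for k in network.seg_kind],
        "plexus": [PLEXI[k] for k in network.seg_plexus],
    })
    if solution is not None:
        table["flow_uL_min"] = solution.flow_uL_min
        table["velocity_cm_s"] = solution.velocity_cm_s
        table["pressure_drop_mmHg"] = solution.pressure_drop_mmHg
    csv_path = os.path.join(path, f"{stem}_segments.csv")
    table.to_csv(csv_path, index=False)
    written.append(csv_path)
    return written
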