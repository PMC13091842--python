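"""Parametric stent-graft models and the metal-to-artery (MTA) ratio.

Devices are built from sinusoidal nitinol rings (nodes on a cylinder of the
labelled diameter, axial coordinate following a pure sine in the unrolled
circumferential coordinate) sutured or bonded to a cylindrical graft
membrane.  A continuous-wire frame (single helical sinusoid over the whole
covered length) and an optional straight lateral bar are available for
design-comparison studies.

The MTA ratio of a device window is::

    MTA = 100 * (A_lateral_stent / 2) / A_lateral_cylinder

with ``A_lateral_stent = pi * wire_diameter * wire_length`` (cylinder-surface
area of the struts) and ``A_lateral_cylinder = pi * D * window_height``.

Packaged presets approximate four commercial thoracic devices from their
published diameters, lengths, working ranges and thicknesses; crown counts
and amplitudes are NOT published and are package assumptions (see
docs/methods.md).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from importlib import resources

import numpy as np

from .errors import ParameterError
from .mesh_core import TriMesh

__all__ = [
    "RingSpec",
    "BeamFrame",
    "DeviceModel",
    "build_ring",
    "build_continuous_wire",
    "build_graft",
    "add_lateral_bar",
    "assemble_device",
    "mta_ratio",
    "wire_length",
    "build_device_preset",
    "DEVICE_PRESETS",
]


@dataclass(frozen=True)
class RingSpec:
    """One sinusoidal stent ring.

    ``amplitude`` is half the peak-to-peak crown height; ``axial_position``
    the z of the sinusoid mean line; ``stress_free_diameter_increase`` the
    fractional relaxed-diameter oversize carried as metadata (rings are
    built at the labelled diameter).
    """

    diameter: float
    n_crowns: int
    amplitude: float
    wire_diameter: float
    axial_position: float = 0.0
    stress_free_diameter_increase: float = 0.0

    def __post_init__(self) -> None:
        if self.diameter <= 0:
            raise ParameterError("diameter must be positive")
        if self.n_crowns < 2:
            raise ParameterError("need at least 2 crowns")
        if self.amplitude < 0:
            raise ParameterError("amplitude must be non-negative")
        if self.wire_diameter <= 0:
            raise ParameterError("wire diameter must be positive")
        if self.stress_free_diameter_increase < 0:
            raise ParameterError("stress-free increase must be >= 0")


@dataclass
class BeamFrame:
    """Stent wireframe: nodes + 2-node beam elements with ring/cell labels."""

    nodes: np.ndarray
    elements: np.ndarray
    wire_diameter: float
    ring_ids: np.ndarray = None  # per-element ring label
    cell_ids: np.ndarray = None  # per-element crown-cell label
    element_wire_diameter: np.ndarray | None = None  # optional override

    def __post_init__(self) -> None:
        self.nodes = np.asarray(self.nodes, dtype=float).reshape(-1, 3)
        self.elements = np.asarray(self.elements, dtype=np.int64).reshape(-1, 2)
        if self.elements.size and (
            self.elements.min() < 0 or self.elements.max() >= len(self.nodes)
        ):
            raise ParameterError("beam elements reference invalid nodes")
        if self.wire_diameter <= 0:
            raise ParameterError("wire diameter must be positive")
        n = len(self.elements)
        if self.ring_ids is None:
            self.ring_ids = np.zeros(n, dtype=np.int64)
        else:
            self.ring_ids = np.asarray(self.ring_ids, dtype=np.int64)
        if self.cell_ids is None:
            self.cell_ids = np.zeros(n, dtype=np.int64)
        else:
            self.cell_ids = np.asarray(self.cell_ids, dtype=np.int64)
        if len(self.ring_ids) != n or len(self.cell_ids) != n:
            raise ParameterError("element labels must match element count")

    def element_lengths(self) -> np.ndarray:
        a = self.nodes[self.elements[:, 0]]
        b = self.nodes[self.elements[:, 1]]
        return np.linalg.norm(b - a, axis=1)

    def element_diameters(self) -> np.ndarray:
        if self.element_wire_diameter is not None:
            return np.asarray(self.element_wire_diameter, dtype=float)
        return np.full(len(self.elements), self.wire_diameter)

    def transformed(self, R: np.ndarray = None, t: np.ndarray = None
                    ) -> "BeamFrame":
        """Rigidly transformed copy (rotation R then translation t)."""
        nodes = self.nodes
        if R is not None:
            nodes = nodes @ np.asarray(R, dtype=float).T
        if t is not None:
            nodes = nodes + np.asarray(t, dtype=float)
        return BeamFrame(nodes, self.elements.copy(), self.wire_diameter,
                         self.ring_ids.copy(), self.cell_ids.copy(),
                         None if self.element_wire_diameter is None
                         else self.element_wire_diameter.copy())

    @staticmethod
    def concatenate(frames: list["BeamFrame"]) -> "BeamFrame":
        if not frames:
            raise ParameterError("no frames to concatenate")
        nodes, elems, rids, cids, dias = [], [], [], [], []
        off = 0
        for f in frames:
            nodes.append(f.nodes)
            elems.append(f.elements + off)
            rids.append(f.ring_ids)
            cids.append(f.cell_ids)
            dias.append(f.element_diameters())
            off += len(f.nodes)
        return BeamFrame(np.vstack(nodes), np.vstack(elems),
                         frames[0].wire_diameter, np.concatenate(rids),
                         np.concatenate(cids),
                         element_wire_diameter=np.concatenate(dias))


@dataclass
class DeviceModel:
    """Assembled stent-graft: wireframe, membrane and their connections."""

    stent: BeamFrame
    graft: TriMesh
    connections: list  # (stent node, graft node) pairs
    covered_length: float
    total_length: float
    working_range: tuple
    rings: list = field(default_factory=list)  # RingSpec per ring id
    name: str = "custom"

    def __post_init__(self) -> None:
        if self.covered_length > self.total_length + 1e-9:
            raise ParameterError("covered length cannot exceed total length")
        lo, hi = self.working_range
        if not lo < hi:
            raise ParameterError("working range must satisfy low < high")
        for sn, gn in self.connections:
            d = np.linalg.norm(self.stent.nodes[sn] - self.graft.nodes[gn])
            if d > 1e-3:
                raise ParameterError(
                    f"connection ({sn},{gn}) nodes {d:.2e} mm apart (> 1e-3)")


# ---------------------------------------------------------------------------
# builders
# ---------------------------------------------------------------------------

def _ring_point(theta, spec: RingSpec):
    r = spec.diameter / 2.0
    return np.column_stack([
        r * np.cos(theta), r * np.sin(theta),
        spec.axial_position + spec.amplitude * np.sin(spec.n_crowns * theta),
    ])


def _default_segments_per_crown(spec: RingSpec,
                                target_element_size: float = 1.0) -> int:
    # estimate the per-crown arc length with a fine polyline
    th = np.linspace(0, 2 * np.pi, 4096)
    L = np.linalg.norm(np.diff(_ring_point(th, spec), axis=0), axis=1).sum()
    return max(8, int(np.ceil(L / spec.n_crowns / target_element_size)))


def build_ring(spec: RingSpec, segments_per_crown: int | None = None,
               ring_id: int = 0) -> BeamFrame:
    """Closed sinusoidal ring as a chain of 2-node beam elements.

    Crown cells are labelled peak-to-peak: element ``cell_id`` k covers the
    sinusoid between peak k and peak k+1 (one cell per crown).
    """
    if segments_per_crown is None:
        segments_per_crown = _default_segments_per_crown(spec)
    n = spec.n_crowns * segments_per_crown
    # start the discretisation at the first peak so cells begin/end on peaks
    theta0 = (np.pi / 2.0) / spec.n_crowns
    theta = theta0 + np.arange(n) * (2 * np.pi / n)
    nodes = _ring_point(theta, spec)
    elements = np.column_stack([np.arange(n), (np.arange(n) + 1) % n])
    cell = np.arange(n) // segments_per_crown
    return BeamFrame(nodes, elements, spec.wire_diameter,
                     ring_ids=np.full(n, ring_id), cell_ids=cell)


def build_continuous_wire(diameter: float, length: float, n_crowns: int,
                          amplitude: float, n_turns: int,
                          wire_diameter: float,
                          segments_per_crown: int = 24) -> BeamFrame:
    """Single-wire helical sinusoid frame covering ``length`` in ``n_turns``.

    The wire advances axially by ``length / n_turns`` per revolution while
    oscillating with the given crown count and amplitude (a continuous-mesh
    design; cells are extracted with cut planes, not ring labels).
    """
    if n_turns < 1:
        raise ParameterError("need at least one turn")
    n = n_turns * n_crowns * segments_per_crown
    theta = np.linspace(0.0, 2 * np.pi * n_turns, n + 1)
    r = diameter / 2.0
    z = (length * theta / (2 * np.pi * n_turns)
         + amplitude * np.sin(n_crowns * theta))
    nodes = np.column_stack([r * np.cos(theta), r * np.sin(theta), z])
    elements = np.column_stack([np.arange(n), np.arange(1, n + 1)])
    return BeamFrame(nodes, elements, wire_diameter,
                     ring_ids=np.zeros(n, dtype=np.int64),
                     cell_ids=(np.arange(n) // segments_per_crown))


def build_graft(diameter: float, length: float,
                target_element_size: float) -> TriMesh:
    """Open cylindrical tube surface (no end caps) along +z from z = 0."""
    if diameter <= 0 or length <= 0 or target_element_size <= 0:
        raise ParameterError("all arguments must be positive")
    if length < target_element_size:
        raise ParameterError("length must be at least the element size")
    n_circ = max(8, int(round(np.pi * diameter / target_element_size)))
    n_rows = max(1, int(round(length / target_element_size)))
    theta = np.arange(n_circ) * (2 * np.pi / n_circ)
    z = np.linspace(0.0, length, n_rows + 1)
    r = diameter / 2.0
    ring = np.column_stack([r * np.cos(theta), r * np.sin(theta),
                            np.zeros(n_circ)])
    nodes = np.vstack([ring + [0, 0, zz] for zz in z])
    tris = []
    for j in range(n_rows):
        a = j * n_circ + np.arange(n_circ)
        b = j * n_circ + (np.arange(n_circ) + 1) % n_circ
        c = a + n_circ
        d = b + n_circ
        tris.append(np.column_stack([a, b, d]))
        tris.append(np.column_stack([a, d, c]))
    return TriMesh(nodes, np.vstack(tris))


def add_lateral_bar(frame: BeamFrame, diameter: float, z_lo: float,
                    z_hi: float, theta: float = 0.0,
                    element_size: float = 1.0,
                    wire_diameter: float | None = None) -> BeamFrame:
    """Append a straight longitudinal bar along one generator (ring id -1)."""
    if z_hi <= z_lo:
        raise ParameterError("z_hi must exceed z_lo")
    n = max(1, int(round((z_hi - z_lo) / element_size)))
    z = np.linspace(z_lo, z_hi, n + 1)
    r = diameter / 2.0
    bar_nodes = np.column_stack([np.full(n + 1, r * np.cos(theta)),
                                 np.full(n + 1, r * np.sin(theta)), z])
    d = wire_diameter if wire_diameter is not None else frame.wire_diameter
    bar = BeamFrame(bar_nodes, np.column_stack([np.arange(n),
                                                np.arange(1, n + 1)]),
                    d, ring_ids=np.full(n, -1), cell_ids=np.zeros(n))
    return BeamFrame.concatenate([frame, bar])


def _sample_ring_by_arclength(frame: BeamFrame, spacing: float
                              ) -> np.ndarray:
    """Node indices sampled along a single-ring chain at arc-length spacing.

    Starts at the chain origin and proceeds by arc length; the sample count
    is floor(total/spacing) + 1, leaving the final gap short when the total
    is not a multiple of the spacing.
    """
    lengths = frame.element_lengths()
    cum = np.concatenate([[0.0], np.cumsum(lengths)])
    total = cum[-1]
    n_samples = int(np.floor(total / spacing)) + 1
    targets = np.arange(n_samples) * spacing
    # snap each target arc length to the nearest chain node
    node_idx = []
    for s in targets:
        k = int(np.searchsorted(cum, s, side="right") - 1)
        k = min(k, len(lengths) - 1)
        frac = (s - cum[k]) / lengths[k]
        e = frame.elements[k]
        node_idx.append(int(e[0] if frac < 0.5 else e[1]))
    # drop duplicates introduced by snapping while preserving order
    seen, out = set(), []
    for i in node_idx:
        if i not in seen:
            seen.add(i)
            out.append(i)
    return np.array(out, dtype=np.int64)


def assemble_device(rings: list[RingSpec], graft: TriMesh,
                    suture_spacing: float = 1.0, bonded: bool = False,
                    working_range: tuple = (27.0, 32.0),
                    total_length: float | None = None,
                    covered_length: float | None = None,
                    stent: BeamFrame | None = None,
                    segments_per_crown: int | None = None,
                    name: str = "custom") -> DeviceModel:
    """Assemble rings (or a prebuilt frame) and a graft into a device.

    Connections are sampled along each ring at ``suture_spacing`` and the
    chosen graft node is welded onto the stent node position (node-to-node
    connection).  ``bonded=True`` connects every stent node lying over the
    covered graft instead (continuous tape bond).
    """
    if stent is None:
        frames = [build_ring(s, segments_per_crown, ring_id=i)
                  for i, s in enumerate(rings)]
        stent = BeamFrame.concatenate(frames)
    zmin, zmax = graft.nodes[:, 2].min(), graft.nodes[:, 2].max()
    if covered_length is None:
        covered_length = float(zmax - zmin)
    if total_length is None:
        total_length = float(
            max(zmax, stent.nodes[:, 2].max())
            - min(zmin, stent.nodes[:, 2].min()))

    mean_edge = float(np.mean(graft.element_areas()) ** 0.5)
    if not bonded and suture_spacing < mean_edge:
        warnings.warn("suture spacing below graft element size; "
                      "connections saturate at node resolution", stacklevel=2)

    graft_nodes = graft.nodes.copy()
    from scipy.spatial import cKDTree
    tree = cKDTree(graft_nodes)

    def covered(z: np.ndarray) -> np.ndarray:
        return (z >= zmin - 1e-9) & (z <= zmax + 1e-9)

    connections: list[tuple[int, int]] = []
    taken: set[int] = set()
    if bonded:
        stent_nodes = np.nonzero(covered(stent.nodes[:, 2]))[0]
        cand = stent_nodes
    else:
        cand = []
        for rid in np.unique(stent.ring_ids):
            if rid < 0:
                continue  # lateral bar is not sutured
            mask = stent.ring_ids == rid
            sub_elems = stent.elements[mask]
            sub_nodes = np.unique(sub_elems)
            remap = {n: i for i, n in enumerate(sub_nodes)}
            sub = BeamFrame(stent.nodes[sub_nodes],
                            np.vectorize(remap.get)(sub_elems),
                            stent.wire_diameter)
            local = _sample_ring_by_arclength(sub, suture_spacing)
            chosen = sub_nodes[local]
            cand.extend(int(c) for c in chosen
                        if covered(np.atleast_1d(stent.nodes[c, 2]))[0])
        cand = np.array(sorted(set(cand)), dtype=np.int64)
    k_query = min(8, len(graft_nodes))
    for sn in np.atleast_1d(cand):
        _, gns = tree.query(stent.nodes[sn], k=k_query)
        for gn in np.atleast_1d(gns):
            if int(gn) not in taken:
                taken.add(int(gn))
                # weld to exact node-to-node coincidence
                graft_nodes[gn] = stent.nodes[sn]
                connections.append((int(sn), int(gn)))
                break

    graft_out = TriMesh(graft_nodes, graft.triangles.copy(),
                        thickness=graft.thickness)
    return DeviceModel(stent, graft_out, connections,
                       covered_length=covered_length,
                       total_length=total_length,
                       working_range=tuple(working_range),
                       rings=list(rings), name=name)


# ---------------------------------------------------------------------------
# MTA ratio
# ---------------------------------------------------------------------------

def wire_length(frame: BeamFrame, axial_window: tuple | None = None
                ) -> float:
    """Total wire length, proportionally clipping elements at window edges."""
    a = frame.nodes[frame.elements[:, 0], 2]
    b = frame.nodes[frame.elements[:, 1], 2]
    lengths = frame.element_lengths()
    if axial_window is None:
        return float(lengths.sum())
    lo, hi = axial_window
    z0, z1 = np.minimum(a, b), np.maximum(a, b)
    span = z1 - z0
    overlap = np.clip(np.minimum(z1, hi) - np.maximum(z0, lo), 0.0, None)
    frac = np.where(span > 1e-12, overlap / np.where(span > 1e-12, span, 1.0),
                    ((z0 >= lo) & (z0 <= hi)).astype(float))
    return float((lengths * frac).sum())


def _windowed_strut_area(frame: BeamFrame, axial_window: tuple | None
                         ) -> float:
    a = frame.nodes[frame.elements[:, 0], 2]
    b = frame.nodes[frame.elements[:, 1], 2]
    lengths = frame.element_lengths()
    dias = frame.element_diameters()
    if axial_window is None:
        return float((np.pi * dias * lengths).sum())
    lo, hi = axial_window
    z0, z1 = np.minimum(a, b), np.maximum(a, b)
    span = z1 - z0
    overlap = np.clip(np.minimum(z1, hi) - np.maximum(z0, lo), 0.0, None)
    frac = np.where(span > 1e-12, overlap / np.where(span > 1e-12, span, 1.0),
                    ((z0 >= lo) & (z0 <= hi)).astype(float))
    return float((np.pi * dias * lengths * frac).sum())


def mta_ratio(frame: BeamFrame, cylinder_diameter: float,
              axial_window: tuple | None = None) -> float:
    """Metal-to-artery ratio in percent over the given axial window.

    Strut lateral area uses the wire cylinder-surface formula
    ``pi * d_wire * length`` (no crown-curvature correction).
    """
    if cylinder_diameter <= 0:
        raise ParameterError("cylinder diameter must be positive")
    if axial_window is None:
        z = frame.nodes[frame.elements.ravel(), 2]
        lo, hi = float(z.min()), float(z.max())
    else:
        lo, hi = map(float, axial_window)
    if not hi > lo:
        raise ParameterError("empty axial window")
    a_stent = _windowed_strut_area(frame, (lo, hi))
    a_cyl = np.pi * cylinder_diameter * (hi - lo)
    return 100.0 * (a_stent / 2.0) / a_cyl


# ---------------------------------------------------------------------------
# packaged presets
# ---------------------------------------------------------------------------

DEVICE_PRESETS = ("VC", "TBS", "CZA", "CTAG")


def load_device_spec(name: str) -> dict:
    if name not in DEVICE_PRESETS:
        raise ParameterError(f"unknown device preset {name!r}")
    text = resources.files("sgmech.data").joinpath("devices.json").read_text()
    return json.loads(text)[name]


def build_device_preset(name: str, graft_element_size: float | None = None,
                        segments_per_crown: int | None = None) -> DeviceModel:
    """Build a packaged device preset by short name (VC/TBS/CZA/CTAG).

    Ring layout parameters (crown count, amplitude, pitch) are package
    assumptions; diameters, lengths, working ranges, wire and graft
    thicknesses follow the published device tables.
    """
    spec = load_device_spec(name)
    d = spec["diameter"]
    covered = spec["covered_length"]
    esize = graft_element_size or spec["graft_element_size"]
    graft = build_graft(d, covered, esize)
    graft.thickness = spec["graft_thickness"]
    ring = spec["ring"]
    rings: list[RingSpec] = []
    stent = None
    if spec.get("continuous_wire"):
        n_turns = int(round(covered / ring["pitch"]))
        stent = build_continuous_wire(
            d, covered, ring["n_crowns"], ring["amplitude"], n_turns,
            spec["wire_diameter"],
            segments_per_crown=segments_per_crown or 24)
    else:
        z = ring["amplitude"]  # keep the first ring inside the graft
        while z + ring["amplitude"] <= covered + 1e-9:
            rings.append(RingSpec(
                diameter=d, n_crowns=ring["n_crowns"],
                amplitude=ring["amplitude"],
                wire_diameter=spec["wire_diameter"], axial_position=z,
                stress_free_diameter_increase=spec["stress_free_increase"]))
            z += ring["pitch"]
        if spec.get("proximal_ring"):
            pr = spec["proximal_ring"]
            rings.append(RingSpec(
                diameter=d, n_crowns=pr["n_crowns"],
                amplitude=pr["amplitude"],
                wire_diameter=pr["wire_diameter"],
                axial_position=pr["axial_position"],
                stress_free_diameter_increase=spec["stress_free_increase"]))
    device = assemble_device(
        rings, graft, suture_spacing=spec["suture_spacing"],
        bonded=spec["bonded"], working_range=tuple(spec["working_range"]),
        total_length=spec["total_length"], covered_length=covered,
        stent=stent, segments_per_crown=segments_per_crown, name=name)
    if spec.get("lateral_bar"):
        device.stent = add_lateral_bar(device.stent, d, 0.0, covered)
    return device
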