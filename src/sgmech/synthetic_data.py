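"""Synthetic fixtures with exact ground truth for every downstream metric.

This module stands in for the data a deployment study would measure:
idealised vessels (straight, torus-arc and tapered tubes), kinematically
deployed devices with controlled gap and fold structure, nodal contact
force fields with planted per-region sums, analytic pressurised-wall
stress fields, and perturbed "segmented" stent copies with planted
opening-area errors.  Every generator is deterministic given its seed and
returns a ground-truth record sufficient to predict the downstream metric
without running the metric code.

The deployment surrogate is purely kinematic: the graft is swept along the
centerline; at each axial station its radius is the smaller of the device
nominal radius and the local wall inner radius minus the prescribed gap,
and where the device is oversized the excess circumference folds into
inward sinusoidal lobes whose within-threshold arc fraction has a closed
form.  Wall meshes represent the inner lumen surface, and graft-to-wall
distances are measured to that surface.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable

import numpy as np

from .device_geometry import BeamFrame, DeviceModel
from .errors import ParameterError
from .mesh_core import Centerline, FieldTable, TriMesh
from .open_area import extract_cells

__all__ = [
    "VesselSpec",
    "DeploySpec",
    "make_vessel",
    "kinematic_deploy",
    "make_contact_field",
    "laplace_stress_field",
    "perturb_stent",
    "MMHG_TO_MPA",
]

#: 1 mmHg = 133.322 Pa
MMHG_TO_MPA = 133.322e-6


@dataclass(frozen=True)
class VesselSpec:
    """Idealised vessel description (dimensions mm, modulus MPa, mmHg)."""

    kind: str = "cylinder"          # cylinder | torus_segment | tapered
    diameter: float = 30.0          # inner diameter (proximal, for tapered)
    diameter_distal: float | None = None
    length: float = 100.0           # axial length (cylinder/tapered)
    bend_radius: float = 50.0       # centerline radius (torus)
    arc_deg: float = 90.0           # swept angle (torus)
    wall_thickness: float = 1.8
    E_wall: float = 2.0
    pressure: float = 80.0

    def __post_init__(self) -> None:
        if self.kind not in ("cylinder", "torus_segment", "tapered"):
            raise ParameterError(f"unknown vessel kind {self.kind!r}")
        if self.diameter <= 0 or self.length <= 0 or self.wall_thickness <= 0:
            raise ParameterError("dimensions must be positive")
        if self.kind == "tapered" and (self.diameter_distal is None
                                       or self.diameter_distal <= 0):
            raise ParameterError("tapered vessel needs diameter_distal > 0")
        if self.kind == "torus_segment" and (
                self.bend_radius <= self.diameter / 2 or self.arc_deg <= 0):
            raise ParameterError("torus needs bend_radius > tube radius "
                                 "and a positive arc")

    def inner_radius(self, s: np.ndarray | float) -> np.ndarray:
        """Wall inner radius at centerline arc length s."""
        s = np.asarray(s, dtype=float)
        if self.kind == "tapered":
            f = np.clip(s / self.length, 0.0, 1.0)
            return (self.diameter + f * (self.diameter_distal
                                         - self.diameter)) / 2.0
        return np.full_like(s, self.diameter / 2.0, dtype=float)

    def metadata(self) -> dict:
        return {
            "kind": self.kind, "diameter_mm": self.diameter,
            "wall_thickness_mm": self.wall_thickness,
            "E_wall_MPa": self.E_wall, "pressure_mmHg": self.pressure,
        }


@dataclass
class DeploySpec:
    """Kinematic deployment description with controlled apposition."""

    device: DeviceModel
    vessel: VesselSpec
    landing_arc_length: float = 0.0
    fold_count: int = 4
    fold_depth: float = 0.0
    gap_kind: str = "constant"      # constant | step | taper
    gap_params: dict = field(default_factory=lambda: {"value": 0.0})
    seed: int = 0

    def __post_init__(self) -> None:
        if self.fold_count < 0 or self.fold_depth < 0:
            raise ParameterError("fold count/depth must be non-negative")
        if self.gap_kind not in ("constant", "step", "taper"):
            raise ParameterError(f"unknown gap kind {self.gap_kind!r}")

    def gap(self, z: np.ndarray) -> np.ndarray:
        """Wall clearance prescribed at graft coordinate z (mm)."""
        z = np.asarray(z, dtype=float)
        p = self.gap_params
        if self.gap_kind == "constant":
            return np.full_like(z, float(p["value"]))
        if self.gap_kind == "step":
            return np.where(z < p["z_switch"], float(p["value_proximal"]),
                            float(p["value_distal"]))
        cov = self.device.covered_length
        return (float(p["value_proximal"])
                + np.clip(z / cov, 0.0, 1.0)
                * (float(p["value_distal"]) - float(p["value_proximal"])))


# ---------------------------------------------------------------------------
# vessels
# ---------------------------------------------------------------------------

def _tube_mesh(radius_fn: Callable, frame_fn: Callable, s_vals: np.ndarray,
               element_size: float) -> TriMesh:
    r_typ = float(np.mean(radius_fn(s_vals)))
    n_circ = max(8, int(round(2 * np.pi * r_typ / element_size)))
    theta = np.arange(n_circ) * (2 * np.pi / n_circ)
    rows = []
    for s in s_vals:
        c, n1, n2 = frame_fn(float(s))
        r = float(radius_fn(s))
        rows.append(c + r * (np.outer(np.cos(theta), n1)
                             + np.outer(np.sin(theta), n2)))
    nodes = np.vstack(rows)
    tris = []
    for j in range(len(s_vals) - 1):
        a = j * n_circ + np.arange(n_circ)
        b = j * n_circ + (np.arange(n_circ) + 1) % n_circ
        tris.append(np.column_stack([a, b, b + n_circ]))
        tris.append(np.column_stack([a, b + n_circ, a + n_circ]))
    return TriMesh(nodes, np.vstack(tris))


def make_vessel(spec: VesselSpec,
                element_size: float = 1.0) -> tuple[TriMesh, Centerline]:
    """Surface mesh of the inner lumen plus the exact centerline."""
    if element_size >= spec.diameter / 4:
        raise ParameterError("element size must be below diameter/4")
    if spec.kind in ("cylinder", "tapered"):
        n_rows = max(2, int(round(spec.length / element_size)) + 1)
        s_vals = np.linspace(0.0, spec.length, n_rows)

        def frame(s: float):
            return (np.array([0.0, 0.0, s]), np.array([1.0, 0.0, 0.0]),
                    np.array([0.0, 1.0, 0.0]))

        mesh = _tube_mesh(spec.inner_radius, frame, s_vals, element_size)
        cl = Centerline(np.column_stack([np.zeros(n_rows), np.zeros(n_rows),
                                         s_vals]), s_vals.copy())
    else:
        R = spec.bend_radius
        arc = np.deg2rad(spec.arc_deg)
        total = R * arc
        n_rows = max(2, int(round(total / element_size)) + 1)
        s_vals = np.linspace(0.0, total, n_rows)

        def frame(s: float):
            phi = s / R
            c = np.array([R * np.cos(phi) - R, 0.0, R * np.sin(phi)])
            n1 = np.array([np.cos(phi), 0.0, np.sin(phi)])  # radial, in-plane
            n2 = np.array([0.0, 1.0, 0.0])
            return c, n1, n2

        mesh = _tube_mesh(spec.inner_radius, frame, s_vals, element_size)
        pts = np.array([frame(float(s))[0] for s in s_vals])
        cl = Centerline(pts, s_vals.copy())
    mesh.thickness = spec.wall_thickness
    return mesh, cl


# ---------------------------------------------------------------------------
# kinematic deployment surrogate
# ---------------------------------------------------------------------------

def lobe_within_fraction(gap: float, depth: float, threshold: float) -> float:
    """Closed-form angular fraction of a folded section within the threshold.

    The folded radius profile is r(phi) = r_base - (depth/2)(1 - cos(k phi)),
    so the wall distance is gap + (depth/2)(1 - cos(k phi)); the angular
    fraction with distance < threshold is arccos-based and does not depend
    on the lobe count k.
    """
    if threshold <= gap:
        return 0.0
    if depth <= 0.0 or threshold >= gap + depth:
        return 1.0
    c = 1.0 - 2.0 * (threshold - gap) / depth
    return float(np.arccos(c) / np.pi)


def lobe_area_fraction(gap: float, depth: float, threshold: float,
                       r_base: float, n_lobes: int,
                       n_quad: int = 4097) -> float:
    """Exact surface-area fraction of a folded section within the threshold.

    Apposition is an area statement, so the angular fraction must be
    weighted by the circumferential arc-length element of the lobe profile,
    ``w(u) = sqrt(r(u)^2 + (depth * k / 2)^2 sin(u)^2)`` with ``u = k phi``;
    both the within part and the full circumference are integrated with a
    dense Simpson rule over one lobe period (exact lobe geometry, no mesh
    involved).
    """
    if threshold <= gap:
        return 0.0
    if depth <= 0.0 or threshold >= gap + depth:
        return 1.0
    u_star = float(np.arccos(1.0 - 2.0 * (threshold - gap) / depth))

    def weight(u: np.ndarray) -> np.ndarray:
        r = r_base - (depth / 2.0) * (1.0 - np.cos(u))
        return np.sqrt(r * r + (depth * n_lobes / 2.0 * np.sin(u)) ** 2)

    from scipy.integrate import simpson

    u_in = np.linspace(0.0, u_star, n_quad)
    u_all = np.linspace(0.0, np.pi, n_quad)
    return float(simpson(weight(u_in), x=u_in)
                 / simpson(weight(u_all), x=u_all))


def lobe_circumference(depth: float, r_base: float, n_lobes: int,
                       n_quad: int = 4097) -> float:
    """Arc length of the folded cross-section profile."""
    from scipy.integrate import simpson

    u = np.linspace(0.0, np.pi, n_quad)
    r = r_base - (depth / 2.0) * (1.0 - np.cos(u))
    w = np.sqrt(r * r + (depth * n_lobes / 2.0 * np.sin(u)) ** 2)
    return float(2.0 * simpson(w, x=u))


def _centerline_frames(cl: Centerline, s: np.ndarray
                       ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Parallel-transported orthonormal frames at the given arc lengths."""
    s_grid = cl.arc_length
    t = np.gradient(cl.points, s_grid, axis=0)
    t /= np.linalg.norm(t, axis=1, keepdims=True)
    n1 = np.zeros_like(t)
    ref = np.array([1.0, 0.0, 0.0])
    if abs(np.dot(ref, t[0])) > 0.9:
        ref = np.array([0.0, 1.0, 0.0])
    n1[0] = ref - np.dot(ref, t[0]) * t[0]
    n1[0] /= np.linalg.norm(n1[0])
    for i in range(1, len(t)):  # transport, removing the tangential part
        v = n1[i - 1] - np.dot(n1[i - 1], t[i]) * t[i]
        n1[i] = v / np.linalg.norm(v)
    n2 = np.cross(t, n1)
    c = cl.point_at(s).reshape(-1, 3)
    n1_i = np.column_stack([np.interp(s, s_grid, n1[:, k]) for k in range(3)])
    n1_i /= np.linalg.norm(n1_i, axis=1, keepdims=True)
    n2_i = np.column_stack([np.interp(s, s_grid, n2[:, k]) for k in range(3)])
    n2_i /= np.linalg.norm(n2_i, axis=1, keepdims=True)
    return c, n1_i, n2_i


def kinematic_deploy(spec: DeploySpec, vessel: TriMesh,
                     centerline: Centerline
                     ) -> tuple[DeviceModel, dict]:
    """Sweep the device along the centerline with prescribed gaps/folds.

    Returns the deployed device and a ground-truth record holding the gap,
    fold state and exact within-threshold area fraction per 1 mm section
    (and their area-weighted overall value) for the default 1 mm threshold.
    """
    dev = spec.device
    cov = dev.covered_length
    if spec.landing_arc_length + cov > centerline.length + 1e-9:
        raise ParameterError("device does not fit distal of the landing point")

    def deform(nodes: np.ndarray) -> np.ndarray:
        z = nodes[:, 2]
        theta = np.arctan2(nodes[:, 1], nodes[:, 0])
        r_nom = np.hypot(nodes[:, 0], nodes[:, 1])
        s = spec.landing_arc_length + z
        r_wall = spec.vessel.inner_radius(s)
        g = spec.gap(z)
        r_base = np.minimum(r_nom, r_wall - g)
        oversize = r_nom > r_wall - g + 1e-12
        r_new = r_base.copy()
        if spec.fold_depth > 0 and spec.fold_count > 0:
            lobe = (spec.fold_depth / 2.0) * (
                1.0 - np.cos(spec.fold_count * theta))
            r_new = np.where(oversize, r_base - lobe, r_base)
        if np.any(r_new <= 0):
            raise ParameterError("fold depth drives the graft through the "
                                 "axis (self-intersection)")
        c, n1, n2 = _centerline_frames(centerline, s)
        return (c + r_new[:, None] * (np.cos(theta)[:, None] * n1
                                      + np.sin(theta)[:, None] * n2))

    graft_nodes = deform(dev.graft.nodes)
    stent_nodes = deform(dev.stent.nodes)
    graft = TriMesh(graft_nodes, dev.graft.triangles.copy(),
                    thickness=dev.graft.thickness)
    stent = BeamFrame(stent_nodes, dev.stent.elements.copy(),
                      dev.stent.wire_diameter, dev.stent.ring_ids.copy(),
                      dev.stent.cell_ids.copy())
    deployed = DeviceModel(stent, graft, list(dev.connections), cov,
                           dev.total_length, dev.working_range,
                           rings=list(dev.rings), name=dev.name)

    # exact ground truth on 1 mm sections, threshold 1 mm
    threshold = 1.0
    edges = np.arange(0.0, cov + 1e-9, 1.0)
    if edges[-1] < cov - 1e-9:
        edges = np.append(edges, cov)
    mid = 0.5 * (edges[:-1] + edges[1:])
    r_nom = float(np.hypot(dev.graft.nodes[:, 0],
                           dev.graft.nodes[:, 1]).mean())
    r_wall = spec.vessel.inner_radius(spec.landing_arc_length + mid)
    g = spec.gap(mid)
    oversize = r_nom > r_wall - g + 1e-12
    frac = np.empty(len(mid))
    circ = np.empty(len(mid))
    for i in range(len(mid)):
        if oversize[i]:
            depth = spec.fold_depth if spec.fold_count > 0 else 0.0
            r_base = float(r_wall[i] - g[i])
            frac[i] = lobe_area_fraction(float(g[i]), depth, threshold,
                                         r_base, spec.fold_count)
            circ[i] = lobe_circumference(depth, r_base, spec.fold_count)
        else:
            d = float(r_wall[i] - r_nom)
            frac[i] = 1.0 if d < threshold else 0.0
            circ[i] = 2.0 * np.pi * r_nom
    widths = np.diff(edges)
    sec_area = circ * widths
    ground_truth = {
        "seed": spec.seed,
        "threshold_mm": threshold,
        "section_positions_mm": mid.tolist(),
        "section_within_fraction": frac.tolist(),
        "section_gap_mm": g.tolist(),
        "section_oversized": oversize.tolist(),
        "overall_within_fraction": float(np.sum(frac * sec_area)
                                         / np.sum(sec_area)),
    }
    return deployed, ground_truth


# ---------------------------------------------------------------------------
# contact-force fields
# ---------------------------------------------------------------------------

def make_contact_field(regions: np.ndarray, per_region_sum: list,
                       contact_fraction: list, seed: int = 0
                       ) -> tuple[FieldTable, dict]:
    """Random nodal force field with exact planted per-region |CF| sums.

    A seeded subset of each region's nodes receives positive magnitudes
    renormalised so the region's summed magnitude equals the planted value;
    directions are random unit vectors.  The bookkeeping dict records the
    exact sums, contact counts and fractions per region.
    """
    regions = np.asarray(regions, dtype=np.int64)
    n_regions = int(regions.max()) + 1
    if len(per_region_sum) != n_regions or len(contact_fraction) != n_regions:
        raise ParameterError("need one sum and fraction per region")
    rng = np.random.default_rng(seed)
    idx_all, vec_all = [], []
    book = {"seed": seed, "regions": []}
    for rid in range(n_regions):
        nodes = np.nonzero(regions == rid)[0]
        total = float(per_region_sum[rid])
        fr = float(contact_fraction[rid])
        if total < 0 or not 0 <= fr <= 1:
            raise ParameterError("sums must be >= 0 and fractions in [0,1]")
        n_contact = int(round(fr * len(nodes)))
        if total > 0 and n_contact < 1:
            raise ParameterError(
                f"region {rid}: positive sum needs contact_fraction * "
                "node count >= 1")
        chosen = rng.choice(nodes, size=n_contact, replace=False) \
            if n_contact else np.array([], dtype=np.int64)
        if n_contact and total > 0:
            mags = rng.uniform(0.5, 1.5, n_contact)
            mags *= total / mags.sum()
        else:
            mags = np.zeros(n_contact)
        dirs = rng.normal(size=(n_contact, 3))
        dirs /= np.linalg.norm(dirs, axis=1, keepdims=True) \
            if n_contact else 1.0
        idx_all.append(np.sort(chosen))
        order = np.argsort(chosen)
        vec_all.append(mags[order, None] * dirs[order])
        book["regions"].append({
            "region_id": rid, "node_count": int(len(nodes)),
            "contact_nodes": int(n_contact),
            "sum_cf_N": total if n_contact else 0.0,
            "contact_fraction": (n_contact / len(nodes)) if len(nodes)
            else 0.0,
        })
    idx = np.concatenate(idx_all) if idx_all else np.array([], dtype=int)
    vec = np.vstack(vec_all) if idx_all else np.zeros((0, 3))
    return FieldTable(idx, vec), book


def laplace_stress_field(spec: VesselSpec, mesh: TriMesh) -> FieldTable:
    """Uniform thin-wall pressure-vessel stress components per node.

    Plane-stress components (sxx, syy, txy) = (hoop, axial, 0) with
    hoop = p r / t and axial = p r / (2 t); p converted from mmHg.
    """
    if spec.kind != "cylinder":
        raise ParameterError("Laplace field is defined for cylinders only")
    p = spec.pressure * MMHG_TO_MPA
    r = spec.diameter / 2.0
    t = spec.wall_thickness
    hoop = p * r / t
    axial = p * r / (2.0 * t)
    n = mesh.n_nodes
    comps = np.column_stack([np.full(n, hoop), np.full(n, axial),
                             np.zeros(n)])
    return FieldTable(np.arange(n), comps)


# ---------------------------------------------------------------------------
# perturbed "segmented" stent copies
# ---------------------------------------------------------------------------

def perturb_stent(frame: BeamFrame, per_cell_scale=None,
                  noise_sd: float = 0.0, seed: int = 0
                  ) -> tuple[BeamFrame, list]:
    """Synthetic segmented-stent stand-in with planted opening-area errors.

    Each crown cell's loop is scaled uniformly about its centroid by its
    own factor (shared peak nodes are duplicated so the scalings stay
    independent), planting an exact OA error of ``|s^2 - 1| * 100`` per
    cell against the unperturbed frame taken as reference — compare with
    ``oa_error(sim=perturbed, ref=original)``.  ``per_cell_scale`` is a
    list of factors in cell-label order, or a dict
    ``{"low": a, "high": b}`` drawn uniformly with the given seed.
    Optional Gaussian coordinate noise (``noise_sd`` mm) breaks exactness
    and is off by default.
    """
    cells = extract_cells(frame, "ring_cells")
    if not cells:
        raise ParameterError("frame yields no closed cells")
    rng = np.random.default_rng(seed)
    if per_cell_scale is None:
        per_cell_scale = [1.0] * len(cells)
    if isinstance(per_cell_scale, dict):
        per_cell_scale = rng.uniform(per_cell_scale["low"],
                                     per_cell_scale["high"],
                                     len(cells)).tolist()
    if len(per_cell_scale) != len(cells):
        raise ParameterError("need one scale per cell")
    if any(s <= 0 for s in per_cell_scale):
        raise ParameterError("scales must be positive")

    nodes, elements, rids, cids = [], [], [], []
    planted = []
    off = 0
    for cell, s in zip(cells, per_cell_scale):
        pts = frame.nodes[cell.loop]
        centroid = pts.mean(axis=0)
        new_pts = centroid + float(s) * (pts - centroid)
        if noise_sd > 0:
            new_pts = new_pts + rng.normal(0.0, noise_sd, new_pts.shape)
        k = len(new_pts)
        nodes.append(new_pts)
        elements.append(np.column_stack([off + np.arange(k - 1),
                                         off + np.arange(1, k)]))
        rids.append(np.full(k - 1, cell.label[0]))
        cids.append(np.full(k - 1, cell.label[1]))
        planted.append(abs(float(s) ** 2 - 1.0) * 100.0)
        off += k
    out = BeamFrame(np.vstack(nodes), np.vstack(elements),
                    frame.wire_diameter, np.concatenate(rids),
                    np.concatenate(cids))
    return out, planted
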