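"""Per-strut opening areas (OA) and the OA% error between two frames.

A strut cell is the closed circuit spanned by one crown of a ring (cells
are labelled peak-to-peak at build time); continuous-wire frames have no
closed metal circuits, so their sections are taken with cut planes normal
to the device axis instead.  The opening area of a (generally non-planar)
loop is the shoelace area of its projection onto its least-squares
best-fit plane, which makes the measure rigid-motion invariant and scale
itself quadratically under uniform scaling.

The OA% error between a simulated and a reference (segmented) frame is the
absolute per-cell difference relative to the reference area, paired by
construction label order; the reference is treated as ground truth.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .device_geometry import BeamFrame
from .errors import ParameterError

__all__ = [
    "StrutCell",
    "OAComparison",
    "extract_cells",
    "opening_area",
    "oa_error",
]


@dataclass
class StrutCell:
    """Closed loop of a strut cell: node indices or explicit points."""

    label: tuple
    loop: np.ndarray | None = None     # ordered node indices into the frame
    points: np.ndarray | None = None   # explicit ordered loop points

    def coords(self, frame: BeamFrame | None = None) -> np.ndarray:
        if self.points is not None:
            return np.asarray(self.points, dtype=float)
        if frame is None:
            raise ParameterError("node-indexed cell needs its frame")
        return frame.nodes[np.asarray(self.loop, dtype=np.int64)]


@dataclass
class OAComparison:
    per_cell: list            # (label, OA_sim, OA_ref, error_pct)
    mean_error: float
    sd_error: float
    max_error: float

    def as_dict(self) -> dict:
        return {
            "mean_error_pct": self.mean_error,
            "sd_error_pct": self.sd_error,
            "max_error_pct": self.max_error,
            "n_cells": len(self.per_cell),
        }


# ---------------------------------------------------------------------------
# cell extraction
# ---------------------------------------------------------------------------

def _order_chain(elements: np.ndarray) -> list[int] | None:
    """Order a set of 2-node elements into a node path (or cycle).

    Returns the ordered node list, or None when the elements do not form a
    single simple path/cycle.
    """
    adj: dict[int, list[int]] = {}
    for a, b in elements:
        adj.setdefault(int(a), []).append(int(b))
        adj.setdefault(int(b), []).append(int(a))
    if any(len(v) > 2 for v in adj.values()):
        return None
    ends = [n for n, v in adj.items() if len(v) == 1]
    if len(ends) not in (0, 2):
        return None
    start = ends[0] if ends else min(adj)
    path = [start]
    prev = None
    while True:
        nxt = [n for n in adj[path[-1]] if n != prev]
        if not nxt:
            break
        prev = path[-1]
        path.append(nxt[0])
        if path[-1] == start:
            path.pop()
            break
        if len(path) > len(elements) + 1:
            return None
    if len(path) < 3 or len(set(path)) != len(path):
        return None
    return path


def extract_cells(frame: BeamFrame, mode: str = "ring_cells",
                  n_planes: int | None = None) -> list[StrutCell]:
    """Extract closed strut cells from a labelled frame.

    ``ring_cells`` groups elements by their (ring id, cell id) labels and
    chains each group into an ordered loop (closed by the chord between its
    end nodes).  ``cut_planes`` slices a continuous-wire frame with planes
    normal to the z axis and returns the azimuth-ordered crossing polygons;
    the default plane count is the number of crown-cell labels per axial
    extent (one plane per crown period).
    """
    if mode == "ring_cells":
        cells = []
        skipped = []
        keys = sorted(set(zip(frame.ring_ids.tolist(),
                              frame.cell_ids.tolist())))
        for key in keys:
            m = (frame.ring_ids == key[0]) & (frame.cell_ids == key[1])
            path = _order_chain(frame.elements[m])
            if path is None:
                skipped.append(key)
                continue
            cells.append(StrutCell(label=key,
                                   loop=np.array(path, dtype=np.int64)))
        if skipped:
            warnings.warn(f"skipped open/branched circuits: {skipped}",
                          stacklevel=2)
        return cells
    if mode == "cut_planes":
        z = frame.nodes[:, 2]
        zmin, zmax = float(z.min()), float(z.max())
        if n_planes is None:
            n_planes = max(1, len(np.unique(frame.cell_ids)))
        levels = zmin + (np.arange(n_planes) + 0.5) * (zmax - zmin) / n_planes
        cells = []
        for k, zp in enumerate(levels):
            z0 = frame.nodes[frame.elements[:, 0], 2]
            z1 = frame.nodes[frame.elements[:, 1], 2]
            crossing = ((z0 - zp) * (z1 - zp)) < 0
            if crossing.sum() < 3:
                warnings.warn(f"cut plane {k} crosses fewer than 3 struts; "
                              "skipped", stacklevel=2)
                continue
            a = frame.nodes[frame.elements[crossing, 0]]
            b = frame.nodes[frame.elements[crossing, 1]]
            t = (zp - a[:, 2]) / (b[:, 2] - a[:, 2])
            pts = a + t[:, None] * (b - a)
            center = pts.mean(axis=0)
            order = np.argsort(np.arctan2(pts[:, 1] - center[1],
                                          pts[:, 0] - center[0]))
            cells.append(StrutCell(label=("plane", k), points=pts[order]))
        return cells
    raise ParameterError(f"unknown extraction mode {mode!r}")


# ---------------------------------------------------------------------------
# areas and errors
# ---------------------------------------------------------------------------

def opening_area(cell: StrutCell, frame: BeamFrame | None = None) -> float:
    """Best-fit-plane shoelace area of the cell loop (mm^2)."""
    pts = cell.coords(frame)
    if len(pts) < 3:
        raise ParameterError("loop needs at least 3 points")
    centered = pts - pts.mean(axis=0)
    _, svals, vt = np.linalg.svd(centered, full_matrices=False)
    if svals[1] <= 1e-12 * max(svals[0], 1.0):
        warnings.warn("degenerate (collinear) loop; area set to 0",
                      stacklevel=2)
        return 0.0
    uv = centered @ vt[:2].T  # coordinates in the best-fit plane
    x, y = uv[:, 0], uv[:, 1]
    return float(0.5 * abs(np.dot(x, np.roll(y, -1))
                           - np.dot(y, np.roll(x, -1))))


def oa_error(sim: BeamFrame, ref: BeamFrame, mode: str = "ring_cells",
             n_planes: int | None = None) -> OAComparison:
    """Per-cell OA% error between a simulated and a reference frame.

    Cells are paired by label order; the error denominator is the reference
    area.  Frames must yield equal cell counts under the chosen mode.
    """
    cs = extract_cells(sim, mode, n_planes)
    cr = extract_cells(ref, mode, n_planes)
    ls = [c.label for c in cs]
    lr = [c.label for c in cr]
    if len(cs) != len(cr):
        raise ParameterError(
            "cell-count mismatch between frames; unmatched labels: "
            f"{sorted(set(ls) ^ set(lr))}")
    rows = []
    for a, b in zip(cs, cr):
        oa_s = opening_area(a, sim)
        oa_r = opening_area(b, ref)
        if oa_r <= 0:
            raise ParameterError(f"reference cell {b.label} has zero area")
        rows.append((a.label, oa_s, oa_r, 100.0 * abs(oa_s - oa_r) / oa_r))
    errs = np.array([r[3] for r in rows])
    sd = float(errs.std(ddof=1)) if len(errs) > 1 else 0.0
    return OAComparison(rows, float(errs.mean()), sd, float(errs.max()))
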