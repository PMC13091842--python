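"""Region-wise contact-force statistics and wall-stress summaries.

The aortic wall is segmented into fixed-length regions (default 20 mm) by
centerline arc length.  Per region the module reports the nodal contact
force (CF) distribution, the net friction force

    NFF = mu * sum |CF|        (isotropic Coulomb bound, mu = 0.1),

and the stent apposition density SAD, the fraction of region nodes carrying
a non-zero friction force.  Von Mises wall-stress summaries accept either a
precomputed scalar stress per node or plane-stress components
(sxx, syy, txy) and report the area-weighted mean (nodal areas lumped as a
third of incident triangle areas) and the maximum.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .errors import ParameterError
from .mesh_core import Centerline, FieldTable, TriMesh

__all__ = [
    "ForceAnalysisConfig",
    "RegionForceSummary",
    "partition_regions",
    "region_summary",
    "vm_summary",
    "von_mises_plane_stress",
]


@dataclass(frozen=True)
class ForceAnalysisConfig:
    region_length: float = 20.0   # mm
    mu: float = 0.1               # friction coefficient
    nonzero_tol: float = 1e-6     # N, friction force considered non-zero

    def __post_init__(self) -> None:
        if self.region_length <= 0:
            raise ParameterError("region length must be positive")
        if not 0.0 <= self.mu <= 1.0:
            raise ParameterError("mu must lie in [0, 1]")
        if self.nonzero_tol < 0:
            raise ParameterError("tolerance must be non-negative")


@dataclass
class RegionForceSummary:
    """Per-region force statistics (Nones where the region is empty)."""

    region_id: int
    node_count: int
    contact_nodes: int
    cf_values: np.ndarray          # nodal |CF| over region nodes, N
    median_cf: float | None        # over contact nodes (|CF|*mu > tol)
    median_cf_all: float | None    # over all region nodes
    max_cf: float | None
    nff: float                     # N
    sad: float                     # fraction of region nodes in contact

    def as_dict(self) -> dict:
        return {
            "region_id": self.region_id,
            "node_count": self.node_count,
            "contact_nodes": self.contact_nodes,
            "median_CF_N": self.median_cf,
            "median_CF_all_N": self.median_cf_all,
            "max_CF_N": self.max_cf,
            "NFF_N": self.nff,
            "SAD": self.sad,
        }


def partition_regions(wall: TriMesh, centerline: Centerline,
                      cfg: ForceAnalysisConfig = ForceAnalysisConfig()
                      ) -> np.ndarray:
    """Region id per wall node: floor(s / region_length) of projected arc.

    Bins are half-open [kL, (k+1)L); nodes projecting exactly onto the
    centerline end are clamped into the last region.
    """
    s = centerline.project(wall.nodes)
    ids = np.floor(s / cfg.region_length).astype(np.int64)
    n_regions = max(1, int(np.ceil(centerline.length / cfg.region_length
                                   - 1e-12)))
    # detect nodes lying axially beyond the polyline ends (their nearest
    # point is the endpoint itself); they are clamped into terminal regions
    t0 = centerline.points[1] - centerline.points[0]
    t1 = centerline.points[-1] - centerline.points[-2]
    before = (wall.nodes - centerline.points[0]) @ t0 < -1e-9 * np.linalg.norm(t0)
    after = (wall.nodes - centerline.points[-1]) @ t1 > 1e-9 * np.linalg.norm(t1)
    if np.any(before) or np.any(after):
        warnings.warn("nodes project beyond centerline ends; clamped to "
                      "terminal regions", stacklevel=2)
    ids[ids > n_regions - 1] = n_regions - 1
    ids[ids < 0] = 0
    return ids


def region_summary(cf_field: FieldTable, regions: np.ndarray,
                   cfg: ForceAnalysisConfig = ForceAnalysisConfig()
                   ) -> list[RegionForceSummary]:
    """Per-region CF statistics, NFF and SAD from a nodal force field."""
    regions = np.asarray(regions, dtype=np.int64)
    cf_field.check_bounds(len(regions))
    mags = np.zeros(len(regions))
    mags[cf_field.node_index] = cf_field.magnitudes()

    out = []
    for rid in range(int(regions.max()) + 1):
        m = regions == rid
        n = int(m.sum())
        if n == 0:
            out.append(RegionForceSummary(rid, 0, 0, np.array([]), None,
                                          None, None, 0.0, 0.0))
            continue
        cf = mags[m]
        contact = cf * cfg.mu > cfg.nonzero_tol
        nc = int(contact.sum())
        out.append(RegionForceSummary(
            region_id=rid, node_count=n, contact_nodes=nc, cf_values=cf,
            median_cf=float(np.median(cf[contact])) if nc else None,
            median_cf_all=float(np.median(cf)),
            max_cf=float(cf.max()),
            nff=float(cfg.mu * cf.sum()),
            sad=float(nc / n),
        ))
    return out


def von_mises_plane_stress(sxx: np.ndarray, syy: np.ndarray,
                           txy: np.ndarray) -> np.ndarray:
    return np.sqrt(sxx**2 - sxx * syy + syy**2 + 3.0 * txy**2)


def vm_summary(stress_field: FieldTable, wall: TriMesh,
               mask: np.ndarray | None = None) -> tuple[float, float]:
    """Area-weighted mean and max von Mises stress over (masked) wall nodes.

    ``stress_field`` holds either a scalar von Mises value per node or the
    three plane-stress components (sxx, syy, txy) per node.
    """
    stress_field.check_bounds(wall.n_nodes)
    if stress_field.is_vector:
        if stress_field.values.shape[1] != 3:
            raise ParameterError("component fields need exactly "
                                 "(sxx, syy, txy) columns")
        vm_vals = von_mises_plane_stress(*stress_field.values.T)
    else:
        vm_vals = stress_field.values
    vm = np.zeros(wall.n_nodes)
    vm[stress_field.node_index] = vm_vals

    weights = wall.nodal_areas()
    sel = np.ones(wall.n_nodes, dtype=bool) if mask is None \
        else np.asarray(mask, dtype=bool)
    w = weights[sel]
    if w.sum() <= 0:
        raise ParameterError("selected nodes carry zero area")
    v = vm[sel]
    return float(np.sum(w * v) / np.sum(w)), float(v.max())


def region_histograms(summaries: list[RegionForceSummary],
                      n_bins: int = 30) -> dict:
    """Violin-ready histograms of |CF| per region."""
    out = {}
    for s in summaries:
        if s.node_count == 0 or s.cf_values.size == 0:
            out[s.region_id] = {"edges": [], "counts": []}
            continue
        counts, edges = np.histogram(s.cf_values, bins=n_bins)
        out[s.region_id] = {"edges": edges.tolist(),
                            "counts": counts.tolist()}
    return out
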