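"""End-to-end orchestration: build -> crimp -> deploy surrogate -> metrics.

``run_pipeline`` produces a machine-readable report bundle in an output
directory: the apposition summary (overall + proximal/distal window stats),
the sectional G-APP profile CSV, region force summaries (CF/NFF/SAD), MTA
ratios (whole device and proximal 1 cm window), the crimp curve with its
working-range force drop, an optional opening-area comparison, and a
manifest recording the configuration hash and seed so any stage can be
re-run reproducibly.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import __version__
from .apposition import AppositionConfig, gapp_profile
from .contact_forces import (ForceAnalysisConfig, partition_regions,
                             region_summary, vm_summary)
from .crimp_sim import CrimpProtocol, crimp_device, working_range_metrics
from .device_geometry import build_device_preset, mta_ratio
from .errors import ParameterError, StageError
from .materials import load_material_preset
from .open_area import oa_error
from .synthetic_data import (DeploySpec, VesselSpec, kinematic_deploy,
                             laplace_stress_field, make_contact_field,
                             make_vessel, perturb_stent)

__all__ = ["RunConfig", "run_pipeline"]


@dataclass
class RunConfig:
    """Configuration of one end-to-end idealised-vessel run."""

    device: str = "VC"
    vessel: VesselSpec = field(default_factory=lambda: VesselSpec(
        kind="cylinder", diameter=30.0, length=200.0))
    out_dir: str = "sgmech_run"
    seed: int = 0
    landing_arc_length: float = 10.0
    fold_count: int = 4
    fold_depth: float = 2.0
    gap_value: float = 0.0
    crimp_target: float = 16.0
    apposition: AppositionConfig = field(default_factory=AppositionConfig)
    forces: ForceAnalysisConfig = field(default_factory=ForceAnalysisConfig)
    with_oa_check: bool = True
    graft_element_size: float | None = None
    segments_per_crown: int | None = None

    def config_hash(self) -> str:
        blob = json.dumps({
            "device": self.device, "vessel": self.vessel.metadata(),
            "seed": self.seed, "landing": self.landing_arc_length,
            "folds": [self.fold_count, self.fold_depth],
            "gap": self.gap_value, "crimp_target": self.crimp_target,
        }, sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def _json_default(o):
    if isinstance(o, (np.floating, np.integer)):
        return o.item()
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(type(o))


def run_pipeline(cfg: RunConfig) -> dict:
    """Run every stage and write the report bundle; returns the report."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {"stages": {}, "errors": {}}

    def stage(name, fn):
        try:
            report["stages"][name] = fn()
        except (ParameterError, StageError) as exc:
            report["errors"][name] = str(exc)
        return report["stages"].get(name)

    # ---- build ---------------------------------------------------------
    def _build():
        device = build_device_preset(
            cfg.device, graft_element_size=cfg.graft_element_size,
            segments_per_crown=cfg.segments_per_crown)
        stent, graft_mat = load_material_preset(cfg.device)
        return {"device": device, "stent_material": stent,
                "graft_material": graft_mat}

    built = stage("build", _build)
    if built is None:
        _finalise(report, cfg, out, exit_code=2)
        return report
    device = built["device"]

    # ---- MTA -----------------------------------------------------------
    def _mta():
        z = device.stent.nodes[:, 2]
        lo = float(z.min())
        return {
            "mta_pct": mta_ratio(device.stent, device.rings[0].diameter
                                 if device.rings else 34.0),
            "mta_proximal_1cm_pct": mta_ratio(
                device.stent, device.rings[0].diameter
                if device.rings else 34.0, (lo, lo + 10.0)),
        }

    stage("mta", _mta)

    # ---- crimp ---------------------------------------------------------
    def _crimp():
        d0 = float(2 * np.hypot(device.stent.nodes[:, 0],
                                device.stent.nodes[:, 1]).max())
        protocol = CrimpProtocol(d0, cfg.crimp_target)
        curve = crimp_device(device, built["stent_material"], protocol)
        curve.to_csv(out / "crimp_curve.csv")
        lo, hi = 28.0, min(32.0, d0 - 1e-6)
        f_lo, f_hi, df = working_range_metrics(curve, lo, hi)
        return {"F_at_target_N": float(curve.branch("loading")[1][-1]),
                "working_range_mm": [lo, hi],
                "F_lo_N": f_lo, "F_hi_N": f_hi, "deltaF_N": df,
                "loop_area_Nmm": curve.loop_area()}

    stage("crimp", _crimp)

    # ---- deploy surrogate + apposition --------------------------------
    def _deploy():
        wall, cl = make_vessel(cfg.vessel)
        dspec = DeploySpec(device, cfg.vessel,
                           landing_arc_length=cfg.landing_arc_length,
                           fold_count=cfg.fold_count,
                           fold_depth=cfg.fold_depth,
                           gap_kind="constant",
                           gap_params={"value": cfg.gap_value},
                           seed=cfg.seed)
        deployed, truth = kinematic_deploy(dspec, wall, cl)
        prof = gapp_profile(deployed.graft, wall, cl, cfg.apposition)
        prof.to_csv(out / "gapp_profile.csv")
        summary = prof.summary()
        summary["ground_truth_overall_pct"] = \
            100.0 * truth["overall_within_fraction"]
        return {"gapp": summary, "deployed": deployed, "wall": wall,
                "centerline": cl, "ground_truth": truth}

    dep = stage("deploy", _deploy)

    # ---- forces + wall stress -----------------------------------------
    def _forces():
        wall, cl = dep["wall"], dep["centerline"]
        regions = partition_regions(wall, cl, cfg.forces)
        n_regions = int(regions.max()) + 1
        rng = np.random.default_rng(cfg.seed)
        sums = rng.uniform(5.0, 30.0, n_regions)
        fracs = rng.uniform(0.05, 0.2, n_regions)
        cf, book = make_contact_field(regions, sums.tolist(),
                                      fracs.tolist(), seed=cfg.seed)
        summaries = region_summary(cf, regions, cfg.forces)
        stress = laplace_stress_field(cfg.vessel, wall)
        vm_mean, vm_max = vm_summary(stress, wall)
        return {"regions": [s.as_dict() for s in summaries],
                "contact_bookkeeping": book,
                "vm_pre_mean_MPa": vm_mean, "vm_pre_max_MPa": vm_max}

    if dep is not None:
        stage("forces", _forces)

    # ---- opening-area self check --------------------------------------
    def _oa():
        frame = dep["deployed"].stent if dep else device.stent
        ref, planted = perturb_stent(frame,
                                     {"low": 0.97, "high": 1.03},
                                     seed=cfg.seed)
        cmp_ = oa_error(ref, frame, mode="ring_cells")
        d = cmp_.as_dict()
        d["planted_mean_pct"] = float(np.mean(planted))
        return d

    if cfg.with_oa_check and device.rings:
        stage("openarea", _oa)

    _finalise(report, cfg, out,
              exit_code=3 if report["errors"] else 0)
    return report


def _finalise(report: dict, cfg: RunConfig, out: Path,
              exit_code: int) -> None:
    report["exit_code"] = exit_code
    report["manifest"] = {
        "package_version": __version__,
        "config_hash": cfg.config_hash(),
        "seed": cfg.seed,
        "device": cfg.device,
        "vessel": cfg.vessel.metadata(),
    }
    serialisable = {
        "manifest": report["manifest"],
        "errors": report["errors"],
        "exit_code": exit_code,
        "results": {},
    }
    for name, val in report["stages"].items():
        if isinstance(val, dict):
            serialisable["results"][name] = {
                k: v for k, v in val.items()
                if isinstance(v, (int, float, str, list, dict, type(None)))
            }
    with open(out / "report.json", "w") as fh:
        json.dump(serialisable, fh, indent=2, default=_json_default)
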