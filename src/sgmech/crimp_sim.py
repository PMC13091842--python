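"""Reduced-order quasi-static crimping/release simulator.

The crimped ring is modelled kinematically: the ring radius is prescribed
step by step, and each crown apex is treated as a semicircular bend whose
radius scales affinely with the current ring diameter,

    rho(D) = rho0 * D / D0,      kappa(D) = 1 / rho(D),

with ``rho0 = pi * D0 / (4 * n_crowns)`` (a quarter of the unrolled crown
wavelength) as the default apex radius at the labelled diameter ``D0``.
Fibre strains across the wire section follow beam kinematics,
``eps = -y * (kappa(D) - kappa(D0))``, and are integrated through the
superelastic law fibre by fibre, so the radial force-diameter curve inherits
the full loading/unloading hysteresis of the material.  The apex bending
moment converts to an equivalent total outward radial force by virtual work
over the prescribed radial mode, which for this geometry reduces to

    F(D) = 2 * n_crowns * pi * M(D) / D .

Whole-device curves are sums of per-ring curves at common diameter samples
(no inter-ring coupling); an optional linear graft hoop term can be added.

This is a deliberate desk-scale surrogate for plane-contact crimping FEA:
it reproduces the phenomenology (hysteresis, working-range force plateau,
loop-area trends) rather than the absolute force magnitudes of any
particular commercial device.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
from scipy.optimize import least_squares

from .device_geometry import DeviceModel, RingSpec
from .errors import ParameterError, StageError
from .materials import GPA_TO_MPA, MaterialState, SuperelasticParams, nitinol_update

__all__ = [
    "CrimpProtocol",
    "CrossSection",
    "RadialForceCurve",
    "crimp_ring",
    "crimp_device",
    "working_range_metrics",
    "calibrate",
]

#: fibre strains beyond this are rejected up front (material model bound)
MAX_FIBER_STRAIN = 0.15


@dataclass(frozen=True)
class CrimpProtocol:
    """Crimp sweep description: start/target diameters and step counts."""

    start_diameter: float
    target_diameter: float
    n_steps_per_branch: int = 60
    n_planes: int = 12  # crimper head plane count, carried as metadata

    def __post_init__(self) -> None:
        if not 0 < self.target_diameter < self.start_diameter:
            raise ParameterError("require 0 < target < start diameter")
        if self.n_steps_per_branch < 10:
            raise ParameterError("need at least 10 steps per branch")

    def diameters(self) -> tuple[np.ndarray, np.ndarray]:
        load = np.linspace(self.start_diameter, self.target_diameter,
                           self.n_steps_per_branch + 1)
        # both branches carry the turning point so interpolation never
        # extrapolates at the target diameter
        unload = load[::-1]
        return load, unload


class CrossSection:
    """Fibre quadrature over a circular wire section.

    Gauss-Chebyshev (second kind) nodes in the bending direction with
    chord-length weights: weights sum to the section area pi d^2/4 exactly.
    """

    def __init__(self, wire_diameter: float, n_fibers: int = 9):
        if n_fibers < 5:
            raise ParameterError("need at least 5 fibres")
        if wire_diameter <= 0:
            raise ParameterError("wire diameter must be positive")
        self.wire_diameter = float(wire_diameter)
        self.n_fibers = int(n_fibers)
        r = wire_diameter / 2.0
        i = np.arange(1, n_fibers + 1)
        u = np.cos(i * np.pi / (n_fibers + 1))
        w = (np.pi / (n_fibers + 1)) * np.sin(i * np.pi / (n_fibers + 1)) ** 2
        self.offsets = r * u                    # y_i, mm
        self.weights = 2.0 * r * r * w          # area weights, mm^2

    @property
    def area(self) -> float:
        return float(self.weights.sum())

    def inertia(self) -> float:
        """Quadrature second moment of area (== pi d^4/64 up to quadrature)."""
        return float((self.weights * self.offsets**2).sum())


@dataclass
class RadialForceCurve:
    """Paired (diameter, total radial force) samples with branch labels."""

    diameters: np.ndarray
    forces: np.ndarray
    branches: np.ndarray  # "loading" / "unloading"

    def __post_init__(self) -> None:
        self.diameters = np.asarray(self.diameters, dtype=float)
        self.forces = np.asarray(self.forces, dtype=float)
        self.branches = np.asarray(self.branches)
        if not (len(self.diameters) == len(self.forces) == len(self.branches)):
            raise ParameterError("curve arrays must share length")
        if np.any(self.forces < -1e-9):
            raise ParameterError("radial forces must be non-negative")

    def branch(self, name: str) -> tuple[np.ndarray, np.ndarray]:
        m = self.branches == name
        return self.diameters[m], self.forces[m]

    def loop_area(self) -> float:
        """Dissipated energy proxy: integral of (F_load - F_unload) dD."""
        dl, fl = self.branch("loading")
        du, fu = self.branch("unloading")
        grid = np.unique(np.concatenate([dl, du]))
        fl_i = np.interp(grid, dl[np.argsort(dl)], fl[np.argsort(dl)])
        fu_i = np.interp(grid, du[np.argsort(du)], fu[np.argsort(du)])
        return float(np.trapezoid(fl_i - fu_i, grid))

    def to_csv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("diameter_mm,force_N,branch\n")
            for d, f, b in zip(self.diameters, self.forces, self.branches):
                fh.write(f"{d:.9e},{f:.9e},{b}\n")


def _ring_force_sweep(ring: RingSpec, p: SuperelasticParams,
                      section: CrossSection, protocol: CrimpProtocol
                      ) -> RadialForceCurve:
    D0 = ring.diameter
    rho0 = np.pi * D0 / (4.0 * ring.n_crowns)
    kappa0 = 1.0 / rho0

    def kappa(D: float) -> float:
        return kappa0 * D0 / D

    load, unload = protocol.diameters()
    # feasibility: peak fibre strain at the target must stay in model range
    peak = abs(section.offsets).max() * (kappa(protocol.target_diameter)
                                         - kappa(max(D0, load[0])))
    if peak >= MAX_FIBER_STRAIN:
        raise ParameterError(
            f"target diameter drives fibre strain {peak:.3f} beyond "
            f"{MAX_FIBER_STRAIN}; crimp less deeply or use thinner wire")
    if protocol.target_diameter <= 2.0 * ring.amplitude:
        raise ParameterError("target diameter below the 2*amplitude "
                             "kinematic feasibility bound")
    if load[0] > D0 + 1e-9:
        raise ParameterError("protocol starts above the ring diameter")

    states = [MaterialState() for _ in range(section.n_fibers)]
    diam, force, branch = [], [], []
    for name, sweep in (("loading", load), ("unloading", unload)):
        for D in sweep:
            dk = kappa(float(D)) - kappa0
            moment = 0.0
            for i in range(section.n_fibers):
                eps = -section.offsets[i] * dk
                try:
                    states[i] = nitinol_update(float(eps), states[i], p)
                except ParameterError as exc:
                    raise StageError(
                        f"fibre update failed at D={D:.2f} mm: {exc}"
                    ) from exc
                moment += -section.weights[i] * states[i].stress \
                    * section.offsets[i]
            f = 2.0 * ring.n_crowns * np.pi * moment / float(D)
            diam.append(float(D))
            force.append(max(f, 0.0))
            branch.append(name)
    return RadialForceCurve(np.array(diam), np.array(force), np.array(branch))


def crimp_ring(ring: RingSpec, p: SuperelasticParams,
               section: CrossSection | None = None,
               protocol: CrimpProtocol | None = None) -> RadialForceCurve:
    """Radial force-diameter hysteresis of one ring under crimp/release."""
    if section is None:
        section = CrossSection(ring.wire_diameter)
    if protocol is None:
        protocol = CrimpProtocol(ring.diameter, 10.0)
    return _ring_force_sweep(ring, p, section, protocol)


def crimp_device(device: DeviceModel, p: SuperelasticParams,
                 protocol: CrimpProtocol,
                 section: CrossSection | None = None,
                 graft_term: bool = False,
                 graft_modulus: float | None = None) -> RadialForceCurve:
    """Whole-device curve: sum of per-ring curves at common samples.

    With ``graft_term=True`` an additive linear membrane hoop-strain force
    is included on the loading branch below the graft's natural diameter.
    """
    rings = device.rings
    load, unload = protocol.diameters()
    diam = np.concatenate([load, unload])
    branch = np.array(["loading"] * len(load) + ["unloading"] * len(unload))
    total = np.zeros(len(diam))
    for ring in rings:
        if protocol.target_diameter >= ring.diameter:
            raise ParameterError(
                f"ring diameter {ring.diameter} incompatible with target "
                f"{protocol.target_diameter}")
        sec = section or CrossSection(ring.wire_diameter)
        c = _ring_force_sweep(ring, p, sec, protocol)
        total += c.forces
    if graft_term:
        if graft_modulus is None or device.graft.thickness is None:
            raise ParameterError("graft term needs modulus and thickness")
        d_nat = 2.0 * np.abs(
            np.linalg.norm(device.graft.nodes[:, :2], axis=1)).max()
        hoop = np.clip((d_nat - diam) / d_nat, 0.0, None)
        # membrane tension per unit length -> total radial line force
        total += (graft_modulus * hoop * device.graft.thickness
                  * np.pi * device.covered_length / d_nat) * 2.0 * np.pi / 1e3
    return RadialForceCurve(diam, total, branch)


def working_range_metrics(curve: RadialForceCurve, d_lo: float,
                          d_hi: float) -> tuple[float, float, float]:
    """Unloading-branch forces at the window edges and their difference.

    Returns ``(F(d_lo), F(d_hi), dF)`` with ``dF = F(d_lo) - F(d_hi)``,
    interpolated linearly on the unloading branch.
    """
    if not d_lo < d_hi:
        raise ParameterError("require d_lo < d_hi")
    du, fu = curve.branch("unloading")
    if du.size < 2:
        raise ParameterError("curve has no unloading branch")
    order = np.argsort(du)
    du, fu = du[order], fu[order]
    if d_lo < du[0] - 1e-9 or d_hi > du[-1] + 1e-9:
        raise ParameterError("window outside the unloading diameter range")
    f_lo = float(np.interp(d_lo, du, fu))
    f_hi = float(np.interp(d_hi, du, fu))
    return f_lo, f_hi, f_lo - f_hi


# ---------------------------------------------------------------------------
# calibration
# ---------------------------------------------------------------------------

_CALIBRATABLE = ("E_A", "E_M", "eps_L", "sigma_SL", "sigma_EL",
                 "sigma_SU", "sigma_EU", "alpha")


def _r_squared(model: np.ndarray, data: np.ndarray) -> float:
    ss_res = float(np.sum((data - model) ** 2))
    ss_tot = float(np.sum((data - data.mean()) ** 2))
    return 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0


def _model_on_experimental(params: SuperelasticParams, ring: RingSpec,
                           section: CrossSection, protocol: CrimpProtocol,
                           experimental: RadialForceCurve) -> np.ndarray:
    sim = _ring_force_sweep(ring, params, section, protocol)
    out = np.empty(len(experimental.diameters))
    for name in ("loading", "unloading"):
        em = experimental.branches == name
        ds, fs = sim.branch(name)
        order = np.argsort(ds)
        out[em] = np.interp(experimental.diameters[em], ds[order], fs[order])
    return out


def calibrate(experimental: RadialForceCurve, base: SuperelasticParams,
              free_params: Sequence[str], bounds: dict,
              ring: RingSpec, protocol: CrimpProtocol,
              section: CrossSection | None = None, seed: int = 0,
              unloading_weight: float = 1.0) -> tuple[SuperelasticParams,
                                                      float, dict]:
    """Bounded least-squares fit of selected superelastic parameters.

    The model curve is re-simulated per iterate and compared with the
    experimental curve branch by branch; ``unloading_weight`` > 1 biases the
    fit towards the release path (the branch that sets the chronic outward
    force).  Returns (params, R^2 over both branches, info dict); on
    optimizer failure the best-so-far parameters are returned with
    ``info["converged"] = False``.
    """
    for name in free_params:
        if name not in _CALIBRATABLE:
            raise ParameterError(f"cannot calibrate parameter {name!r}")
        if name not in bounds:
            raise ParameterError(f"missing bounds for {name!r}")
    if section is None:
        section = CrossSection(ring.wire_diameter)

    dmin = float(experimental.diameters.min())
    dmax = float(experimental.diameters.max())
    if dmin > protocol.target_diameter + 1e-9 or \
            dmax < protocol.start_diameter - 1e-9:
        raise ParameterError("experimental curve does not span the "
                             "simulated diameter range")

    data = experimental.forces
    w = np.where(experimental.branches == "unloading",
                 float(unloading_weight), 1.0)

    if not free_params:
        model = _model_on_experimental(base, ring, section, protocol,
                                       experimental)
        return base, _r_squared(model, data), {"n_iter": 0, "converged": True}

    lo = np.array([bounds[n][0] for n in free_params], dtype=float)
    hi = np.array([bounds[n][1] for n in free_params], dtype=float)
    rng = np.random.default_rng(seed)
    x0 = lo + (hi - lo) * (0.4 + 0.2 * rng.random(len(free_params)))

    def make(x: np.ndarray) -> SuperelasticParams | None:
        try:
            return replace(base, **dict(zip(free_params, map(float, x))))
        except ParameterError:
            return None

    def resid(x: np.ndarray) -> np.ndarray:
        p = make(x)
        if p is None:
            return np.full(len(data), 1e6)
        try:
            model = _model_on_experimental(p, ring, section, protocol,
                                           experimental)
        except (ParameterError, StageError):
            return np.full(len(data), 1e6)
        return w * (model - data)

    try:
        res = least_squares(resid, x0, bounds=(lo, hi), xtol=1e-12,
                            ftol=1e-12, gtol=1e-12)
        x_best, converged = res.x, bool(res.success)
        n_iter = int(res.nfev)
    except Exception:  # noqa: BLE001 - keep best-so-far semantics
        x_best, converged, n_iter = x0, False, 0
    fitted = make(x_best) or base
    model = _model_on_experimental(fitted, ring, section, protocol,
                                   experimental)
    return fitted, _r_squared(model, data), {"n_iter": n_iter,
                                             "converged": converged}
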