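"""One-dimensional superelastic nitinol and linear-elastic graft laws.

The nitinol law is an isothermal 1D flag model of the Auricchio family.
Total strain decomposes into an elastic part and a transformation part,

    eps = sigma / E(xi) + xi * eps_L * sign(sigma),

where ``xi`` in [0, 1] is the martensite volume fraction, ``eps_L`` the
maximum transformation strain, and the mixture modulus follows the Reuss
(compliance-average) rule

    E(xi) = [ xi / E_M + (1 - xi) / E_A ]^-1 .

Forward (austenite -> martensite) transformation carries the stress linearly
from ``sigma_SL`` to ``sigma_EL`` as xi goes 0 -> 1; reverse transformation
runs from ``sigma_SU`` down to ``sigma_EU`` as xi goes 1 -> 0.  Outside the
transformation branches the response is elastic with modulus E(xi).  The
state update is strain-driven and solved exactly on each branch (scalar root
find), which keeps the response path-dependent and continuous across branch
switches without explicit sub-stepping.

Compression: the plateau stresses are scaled by a Drucker-Prager-like factor
``(1 + alpha) / (1 - alpha)`` for negative strains; with ``alpha = 0`` the
response is tension-compression symmetric.  This functional form is an
interpretation of the single asymmetry parameter the calibration reports
(see docs/methods.md).

Moduli are stored in GPa as calibrations report them; stresses internally
are MPa (1 GPa = 1000 MPa).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace
from importlib import resources
from typing import Sequence

import numpy as np
from scipy.optimize import brentq

from .errors import ParameterError

__all__ = [
    "SuperelasticParams",
    "MaterialState",
    "GraftMaterial",
    "nitinol_update",
    "uniaxial_curve",
    "fit_graft_modulus",
    "load_material_preset",
    "MATERIAL_PRESETS",
]

GPA_TO_MPA = 1000.0


@dataclass(frozen=True)
class SuperelasticParams:
    """Calibrated superelastic parameter set (moduli GPa, stresses MPa)."""

    E_A: float          # austenite Young's modulus [GPa]
    nu_A: float         # austenite Poisson ratio [-]
    E_M: float          # martensite Young's modulus [GPa]
    nu_M: float         # martensite Poisson ratio [-]
    eps_L: float        # maximum transformation strain [-]
    sigma_SL: float     # start transformation, loading [MPa]
    sigma_EL: float     # end transformation, loading [MPa]
    sigma_SU: float     # start transformation, unloading [MPa]
    sigma_EU: float     # end transformation, unloading [MPa]
    alpha: float = 0.0  # tension-compression asymmetry [-]

    def __post_init__(self) -> None:
        if not (self.sigma_SL < self.sigma_EL):
            raise ParameterError("require sigma_SL < sigma_EL")
        if not (self.sigma_SU > self.sigma_EU >= 0):
            raise ParameterError("require sigma_SU > sigma_EU >= 0")
        if not (0 < self.eps_L < 1):
            raise ParameterError("require 0 < eps_L < 1")
        if self.E_M > self.E_A:
            raise ParameterError("require E_M <= E_A")
        if self.alpha < 0 or self.alpha >= 1:
            raise ParameterError("require 0 <= alpha < 1")

    def mixture_modulus(self, xi: float) -> float:
        """Reuss mixture modulus in MPa."""
        ea = self.E_A * GPA_TO_MPA
        em = self.E_M * GPA_TO_MPA
        return 1.0 / (xi / em + (1.0 - xi) / ea)

    def compression_scale(self) -> float:
        return (1.0 + self.alpha) / (1.0 - self.alpha)


@dataclass(frozen=True)
class MaterialState:
    """Point state: martensite fraction, total strain, stress (MPa).

    ``overdriven`` flags strains carried past the martensite finish on the
    continued martensite elastic branch (no failure model).
    """

    xi: float = 0.0
    strain: float = 0.0
    stress: float = 0.0
    overdriven: bool = False

    def __post_init__(self) -> None:
        if not (0.0 <= self.xi <= 1.0):
            raise ParameterError("xi must lie in [0, 1]")
        if not (np.isfinite(self.strain) and np.isfinite(self.stress)):
            raise ParameterError("state must be finite")


@dataclass(frozen=True)
class GraftMaterial:
    """Linear-elastic graft membrane (longitudinal modulus MPa, thickness mm)."""

    E: float
    thickness: float

    def __post_init__(self) -> None:
        if self.E <= 0 or self.thickness <= 0:
            raise ParameterError("graft E and thickness must be positive")


# ---------------------------------------------------------------------------
# state update
# ---------------------------------------------------------------------------

def _branch_stress_loading(xi: float, p: SuperelasticParams) -> float:
    return p.sigma_SL + xi * (p.sigma_EL - p.sigma_SL)


def _branch_stress_unloading(xi: float, p: SuperelasticParams) -> float:
    return p.sigma_EU + xi * (p.sigma_SU - p.sigma_EU)


def _solve_xi_on_branch(abs_strain: float, p: SuperelasticParams,
                        branch_stress, scale: float,
                        lo: float, hi: float) -> float:
    """Solve |eps| = scale*sig(xi)/E(xi) + xi*eps_L for xi in [lo, hi].

    The residual is strictly decreasing in the strain mismatch sense
    (RHS strictly increasing in xi for admissible parameters), so a
    bracketed root is unique when it exists.
    """

    def resid(xi: float) -> float:
        return (scale * branch_stress(xi, p) / p.mixture_modulus(xi)
                + xi * p.eps_L) - abs_strain

    rlo, rhi = resid(lo), resid(hi)
    if rlo >= 0.0:
        return lo
    if rhi <= 0.0:
        return hi
    return brentq(resid, lo, hi, xtol=1e-14)


def nitinol_update(strain_new: float, state: MaterialState,
                   p: SuperelasticParams) -> MaterialState:
    """Advance the flag model to a new total strain.

    Path dependence is honoured across calls through the martensite fraction
    carried in ``state``.  Strains beyond the martensite finish continue on
    the martensite elastic branch and set the ``overdriven`` flag.
    """
    if not np.isfinite(strain_new):
        raise ParameterError("strain must be finite")
    if abs(strain_new) >= 0.15:
        raise ParameterError("strain magnitude must be below 0.15")

    sign = 1.0 if strain_new >= 0.0 else -1.0
    scale = 1.0 if sign > 0 else p.compression_scale()
    eps = abs(strain_new)
    xi = state.xi

    # trial elastic step at frozen xi
    sig_trial = p.mixture_modulus(xi) * (eps - xi * p.eps_L)

    fwd = scale * _branch_stress_loading(xi, p)
    rev = scale * _branch_stress_unloading(xi, p)

    if sig_trial > fwd and xi < 1.0:
        # forward transformation along the loading plateau
        xi_new = _solve_xi_on_branch(eps, p, _branch_stress_loading, scale,
                                     xi, 1.0)
        if xi_new >= 1.0:
            xi_new = 1.0
            stress = p.mixture_modulus(1.0) * (eps - p.eps_L)
            over = stress > scale * p.sigma_EL
            return MaterialState(xi_new, strain_new, sign * stress, over)
        stress = scale * _branch_stress_loading(xi_new, p)
        return MaterialState(xi_new, strain_new, sign * stress, False)

    if sig_trial < rev and xi > 0.0:
        # reverse transformation along the unloading plateau
        xi_new = _solve_xi_on_branch(eps, p, _branch_stress_unloading, scale,
                                     0.0, xi)
        if xi_new <= 0.0:
            stress = p.mixture_modulus(0.0) * eps
            return MaterialState(0.0, strain_new, sign * stress, False)
        stress = scale * _branch_stress_unloading(xi_new, p)
        return MaterialState(xi_new, strain_new, sign * stress, False)

    # elastic at frozen martensite fraction
    over = bool(xi >= 1.0 and sig_trial > scale * p.sigma_EL)
    return MaterialState(xi, strain_new, sign * sig_trial, over)


def uniaxial_curve(p: SuperelasticParams, strain_max: float,
                   n_steps: int) -> dict:
    """Strain-controlled sweep 0 -> strain_max -> 0.

    Returns a dict with ``strain``, ``stress``, ``xi`` arrays over the full
    sweep, plateau onset/end markers located by xi crossing 0/1, and a
    ``transformed`` flag (False when strain_max stays below the onset).
    """
    if n_steps < 10:
        raise ParameterError("n_steps must be at least 10")
    load = np.linspace(0.0, strain_max, n_steps + 1)
    unload = np.linspace(strain_max, 0.0, n_steps + 1)[1:]
    path = np.concatenate([load, unload])

    state = MaterialState()
    strain = np.empty(len(path))
    stress = np.empty(len(path))
    xi = np.empty(len(path))
    for k, e in enumerate(path):
        state = nitinol_update(float(e), state, p)
        strain[k], stress[k], xi[k] = state.strain, state.stress, state.xi

    n_load = len(load)
    out = {
        "strain": strain, "stress": stress, "xi": xi,
        "branch": np.array(["loading"] * n_load
                           + ["unloading"] * (len(path) - n_load)),
        "transformed": bool(xi.max() > 0.0),
    }
    # plateau markers on the loading branch
    lx = xi[:n_load]
    ls = stress[:n_load]
    onset = np.argmax(lx > 0.0) if lx.max() > 0 else None
    out["onset_loading_stress"] = None if onset is None else float(
        _branch_stress_loading(0.0, p))
    out["end_loading_stress"] = (float(_branch_stress_loading(1.0, p))
                                 if lx.max() >= 1.0 else None)
    ux = xi[n_load:]
    out["onset_unloading_stress"] = (float(_branch_stress_unloading(
        float(lx[-1]), p)) if ux.size and ux[0] > ux[-1] else None)
    out["end_unloading_stress"] = (float(_branch_stress_unloading(0.0, p))
                                   if ux.size and ux[-1] <= 0.0
                                   and ux[0] > 0.0 else None)
    # inelastic strain at full transformation: total minus martensite elastic
    if lx.max() >= 1.0:
        k1 = int(np.argmax(lx >= 1.0))
        out["transformation_strain"] = float(
            strain[k1] - stress[k1] / (p.E_M * GPA_TO_MPA))
    else:
        out["transformation_strain"] = None
    return out


def fit_graft_modulus(curve: Sequence[tuple[float, float]] | np.ndarray,
                      eps_cut: float = 0.015) -> float:
    """Least-squares slope through the origin over strains <= ``eps_cut``.

    This is the standard linearisation of the initial portion of a graft
    uniaxial tensile curve; returns Young's modulus in MPa.
    """
    arr = np.asarray(curve, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2:
        raise ParameterError("curve must be (strain, stress) pairs")
    mask = arr[:, 0] <= eps_cut
    if mask.sum() < 3:
        raise ParameterError("need at least 3 samples below the strain cut")
    e, s = arr[mask, 0], arr[mask, 1]
    denom = float(np.dot(e, e))
    if denom == 0.0:
        raise ParameterError("all strains are zero below the cut")
    return float(np.dot(e, s) / denom)


# ---------------------------------------------------------------------------
# packaged presets (calibrated commercial thoracic devices)
# ---------------------------------------------------------------------------

MATERIAL_PRESETS = ("VC", "TBS", "CZA", "CTAG")


def load_material_preset(name: str) -> tuple[SuperelasticParams, GraftMaterial]:
    """Load a packaged calibrated material set by device short name."""
    if name not in MATERIAL_PRESETS:
        raise ParameterError(f"unknown material preset {name!r}; "
                             f"choose from {MATERIAL_PRESETS}")
    text = resources.files("sgmech.data").joinpath("materials.json").read_text()
    entry = json.loads(text)[name]
    stent = SuperelasticParams(**entry["stent"])
    graft = GraftMaterial(**entry["graft"])
    return stent, graft
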