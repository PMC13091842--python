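# sgmech — stent-graft mechanical performance toolkit for TEVAR

Thoracic endovascular aortic repair (TEVAR) excludes a diseased aortic
segment with a stent-graft: a fabric tube (PET or ePTFE) supported by
superelastic nitinol rings or a continuous wireframe.  Whether the
procedure seals and stays anchored depends on quantities that are hard to
observe directly — how much radial force the device keeps exerting inside
its working range, how closely the graft fabric lies against the wall, and
how the contact forces distribute along the vessel.  `sgmech` is a desk-scale
Python library for engineers studying these questions: it builds parametric
device models, embodies calibrated superelastic nitinol behaviour, simulates
crimp/release hysteresis with a reduced-order model, and computes the
post-deployment metric suite used to compare device designs.

## What it computes

**Constitutive layer.** A 1D isothermal flag model of superelastic nitinol:
strain decomposes as `eps = sigma/E(xi) + xi*eps_L*sign(sigma)` with
martensite fraction `xi` and Reuss mixture modulus
`E(xi) = [xi/E_M + (1-xi)/E_A]^-1`.  Forward transformation carries the
stress from `sigma_SL` to `sigma_EL`, reverse from `sigma_SU` to
`sigma_EU`.  Calibrated parameter sets for four commercial thoracic devices
(VC, TBS, CZA, CTAG) are packaged, along with their linear-elastic graft
moduli (1060 / 520 / 520 / 90 MPa, linearised up to eps = 0.015).

**Device geometry.** Sinusoidal rings on a cylinder, continuous-wire
frames, cylindrical graft membranes, suture / bonded connection maps, and
the metal-to-artery ratio

```
MTA = 100 * (A_lateral_stent / 2) / A_lateral_cylinder
```

with `A_lateral_stent = pi * d_wire * L_wire` over any axial window.

**Crimp/release.** A reduced-order kinematic crimp: crown apexes bend as
semicircles whose radius scales with the ring diameter; fibre strains are
integrated through the nitinol law over a Gauss–Chebyshev wire section and
converted to total radial force by virtual work, `F = 2 n pi M / D`.  The
release branch yields the chronic outward force and the working-range force
drop; a bounded least-squares routine recovers material parameters from
force–diameter curves.

**Post-deployment metrics.**
- *G-APP*: percentage of graft surface within 1 mm of the wall, overall,
  per 1 mm section along the centerline, and as proximal/distal 1 cm
  window statistics (area-weighted, exact point-to-triangle distances).
- *CF / NFF / SAD*: per 2 cm vessel region, the contact-force
  distribution, net friction force `NFF = 0.1 * sum |CF|`, and stent
  apposition density (fraction of wall nodes with non-zero friction).
- *Wall stress*: area-weighted von Mises summaries from scalar or
  plane-stress component fields.
- *Opening areas*: per-cell strut opening areas (best-fit-plane shoelace)
  and the OA% error between a simulated and a segmented frame.

**Synthetic data.** Every fixture the pipeline needs is generated with
exact ground truth: idealised vessels (straight / torus-arc / tapered,
1.8 mm wall, E = 2 MPa, 80 mmHg), kinematically deployed devices with
controlled gaps and sinusoidal fold lobes (closed-form within-threshold
area fractions), contact fields with planted per-region sums, Laplace
pressure-vessel stress fields, and perturbed stent copies with planted
OA errors.

## Worked example

Crimping a 34 mm, 5-crown VC-like ring to 16 mm and releasing it
(`examples/03_crimp_release.py`):

```
release force at 28 mm: 5.51 N, at 32 mm: 2.03 N (dF = 3.48 N)
hysteresis loop area: 78.9 N*mm (energy dissipated per cycle)
recovered plateau onsets: loading 550.0 MPa, unloading 450.0 MPa (R^2 = 1.000)
```

The 28–32 mm window is the intended vessel-diameter range: the ring keeps
pushing outward with 2–5.5 N there, and the force drop `dF` measures how
sensitive anchoring is to vessel size.  The calibration step re-fits the
transformation plateau onsets from the simulated curve alone and recovers
the generating 550 / 450 MPa exactly.

Deploying an oversized (34 mm) device into a 30 mm tube with four fold
lobes (`examples/04_graft_apposition.py`):

```
overall G-APP: 42.1 % (ground truth 41.8 %)
proximal 1 cm: avg 42.0 % max 43.0 %
```

Only the lobe crests stay within 1 mm of the wall, so apposition sits near
the closed-form lobe-area fraction instead of 100 %.

Each script in `examples/` exercises one capability end to end; the
`sgmech` CLI (`sgmech crimp`, `sgmech synth`, `sgmech gapp`,
`sgmech forces`, `sgmech report`, ...) wraps the same functions for shell
use.

## Layout

- `src/sgmech/` — the library (`materials`, `device_geometry`,
  `crimp_sim`, `mesh_core`, `apposition`, `contact_forces`, `open_area`,
  `synthetic_data`, `pipeline`, `cli`)
- `docs/methods.md` — models, assumptions, numerical choices, limitations
- `examples/` — one narrative script per capability
- `tests/` — unit, property and acceptance suites
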