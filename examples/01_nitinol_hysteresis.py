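"""Uniaxial superelastic response of the calibrated stent materials.

Sweeps each calibrated nitinol parameter set through a strain-controlled
load/unload cycle and prints the plateau stresses and transformation strain
the model realises — the flag-shaped hysteresis that gives self-expanding
stents their chronic outward force.
"""

from sgmech.materials import MATERIAL_PRESETS, load_material_preset, uniaxial_curve

for name in MATERIAL_PRESETS:
    params, graft = load_material_preset(name)
    out = uniaxial_curve(params, strain_max=0.09, n_steps=2000)
    print(f"{name}:")
    print(f"  loading plateau   {out['onset_loading_stress']:.0f} -> "
          f"{out['end_loading_stress']:.0f} MPa")
    print(f"  unloading plateau {out['onset_unloading_stress']:.0f} -> "
          f"{out['end_unloading_stress']:.0f} MPa")
    print(f"  transformation strain {out['transformation_strain']:.3f}; "
          f"graft modulus {graft.E:.0f} MPa")

print("\nThe unloading plateau sets the force a deployed stent keeps "
      "exerting on the vessel; the gap between the two plateaus is the "
      "energy dissipated per crimp/release cycle.")
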