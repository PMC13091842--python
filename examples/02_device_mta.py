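"""Build the packaged device models and compare their metal-to-artery ratio.

The MTA ratio is half the lateral strut area over the enclosing cylinder
area, in percent.  Devices with an extra proximal ring or a continuous
wireframe carry more metal in the first centimetre — the sealing zone.
"""

from sgmech.device_geometry import DEVICE_PRESETS, build_device_preset, mta_ratio

for name in DEVICE_PRESETS:
    dev = build_device_preset(name, graft_element_size=1.5,
                              segments_per_crown=12)
    z = dev.stent.nodes[:, 2]
    lo = float(z.min())
    whole = mta_ratio(dev.stent, 34.0)
    prox = mta_ratio(dev.stent, 34.0, (lo, lo + 10.0))
    print(f"{name:4s}  MTA {whole:5.1f} %   proximal 1 cm {prox:5.1f} %  "
          f"({len(dev.stent.elements)} beam elements, "
          f"{len(dev.connections)} stent-graft connections)")

print("\nA higher proximal MTA means denser metal support where the graft "
      "must seal against the aortic wall.")
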