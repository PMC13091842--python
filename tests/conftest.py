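import numpy as np
import pytest

from sgmech.device_geometry import (RingSpec, assemble_device, build_graft,
                                    build_ring)
from sgmech.materials import load_material_preset
from sgmech.synthetic_data import DeploySpec, VesselSpec, make_vessel


@pytest.fixture(scope="session")
def vc_params():
    stent, graft = load_material_preset("VC")
    return stent


@pytest.fixture(scope="session")
def ring34():
    return RingSpec(diameter=34.0, n_crowns=5, amplitude=7.5,
                    wire_diameter=0.5)


@pytest.fixture(scope="session")
def straight_vessel():
    """30 mm straight tube, 1 mm elements, with its exact centerline."""
    spec = VesselSpec(kind="cylinder", diameter=30.0, length=100.0)
    wall, cl = make_vessel(spec, element_size=1.0)
    return spec, wall, cl


@pytest.fixture(scope="session")
def small_device():
    """Two-ring 34 mm device on a 40 mm graft (oversized for a 30 mm tube)."""
    graft = build_graft(34.0, 40.0, 1.0)
    rings = [RingSpec(34.0, 5, 7.5, 0.5, axial_position=z)
             for z in (10.0, 30.0)]
    return assemble_device(rings, graft, suture_spacing=1.0,
                           working_range=(29.0, 31.0))


@pytest.fixture(scope="session")
def fold_deployment(straight_vessel, small_device):
    """Oversized device folded into 4 lobes of 3 mm depth, zero gap."""
    spec, wall, cl = straight_vessel
    dspec = DeploySpec(small_device, spec, landing_arc_length=10.0,
                       fold_count=4, fold_depth=3.0, gap_kind="constant",
                       gap_params={"value": 0.0}, seed=0)
    return dspec, wall, cl


@pytest.fixture(scope="session")
def crown_ring():
    return build_ring(RingSpec(30.0, 5, 7.5, 0.5), segments_per_crown=24)
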