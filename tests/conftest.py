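import numpy as np
import pytest

from perfuseed import flow as fl
from perfuseed import geometry as geo
from perfuseed.scaffold import generate_scaffold
from perfuseed.study import TRUE_PORE_SCALE_MM, build_preset_domain


@pytest.fixture(scope="session")
def coarse_scaffold():
    """1 mm-voxel surrogate block used by the desk-scale flow studies."""
    return generate_scaffold(voxel_mm=1.0, pore_scale_mm=2.0, seed=1)


@pytest.fixture(scope="session")
def type2_domain():
    return build_preset_domain("type2", True, seed=1)


@pytest.fixture(scope="session")
def type2_flow(type2_domain):
    return fl.solve_flow(type2_domain, inlet_flow_ml_min=0.5,
                         mode=fl.HOMOGENIZED,
                         pore_scale_mm=TRUE_PORE_SCALE_MM)


@pytest.fixture(scope="session")
def default_scaffold():
    """The full-resolution default block (0.25 mm voxels, 69% porous)."""
    return generate_scaffold(seed=42)


def make_connector_domain(scaffold, shape, length_mm, diameter_mm=10.0,
                          base_mm=15.0, encasement=True, gap_mm=None):
    if shape == geo.CYLINDRICAL:
        conn = geo.ConnectorSpec(geo.CYLINDRICAL, diameter_mm, length_mm)
    else:
        conn = geo.ConnectorSpec(geo.CONICAL, 1.6, length_mm, width_mm=base_mm)
    gap = 0.0 if encasement else (gap_mm or max(1.0, scaffold.voxel_mm))
    sx, sy, _ = scaffold.dims_mm
    cfg = geo.ReactorConfig(
        chamber_mm=(sx + 2 * gap, sy + 2 * gap, scaffold.dims_mm[2]),
        inlet=conn, outlet=conn, encasement=encasement, gap_mm=gap)
    return geo.build_domain(scaffold, cfg)
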