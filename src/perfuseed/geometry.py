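"""Bioreactor geometry: connectors, chamber, encasement, orientation.

The simulated device is a perfusion chamber that form-fits a cuboid
scaffold block, with a nozzle ("connector") above and below it.  Nozzles
are either cylindrical channels of diameter D or conical diffusers that
expand from a narrow throat to the full scaffold face.  All nozzles are
fed through narrow flow tubing, so the prescribed inflow enters through a
small port disc at the connector mouth; how much the stream has spread by
the time it reaches the scaffold face is exactly what the connector
shape/length studies probe.

Without encasement (enc-) the chamber is loose-fit: an annular bypass gap
surrounds the scaffold's lateral faces and a thin plenum connects the
nozzle to both the scaffold face and the gap, letting flow go around the
block.  With press-fit encasement (enc+) the only fluid path crosses the
scaffold.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage

from .constants import DEFAULT_PORT_BORE_MM
from .scaffold import FLUID, SOLID, ScaffoldVolume, _FACE_STRUCT

# region labels
WALL = 0
INLET_PORT = 1
CONNECTOR = 2
SCAFFOLD_FLUID = 3
SCAFFOLD_SOLID = 4
BYPASS_GAP = 5
OUTLET_PORT = 6
CHAMBER_FLUID = 7

LABEL_LEGEND = {
    "WALL": WALL,
    "INLET_PORT": INLET_PORT,
    "CONNECTOR": CONNECTOR,
    "SCAFFOLD_FLUID": SCAFFOLD_FLUID,
    "SCAFFOLD_SOLID": SCAFFOLD_SOLID,
    "BYPASS_GAP": BYPASS_GAP,
    "OUTLET_PORT": OUTLET_PORT,
    "CHAMBER_FLUID": CHAMBER_FLUID,
}

#: labels that carry flow when the scaffold micro-structure is resolved
OPEN_FLUID_LABELS = (INLET_PORT, CONNECTOR, SCAFFOLD_FLUID, BYPASS_GAP,
                     OUTLET_PORT, CHAMBER_FLUID)

CYLINDRICAL = "cylindrical"
CONICAL = "conical"
LENGTHWISE = "lengthwise"
TRANSVERSE = "transverse"


@dataclass(frozen=True)
class ConnectorSpec:
    """Inflow/outflow nozzle.

    ``diameter_mm`` is the opening diameter at the port side: the channel
    diameter for a cylindrical connector, the throat diameter for a
    conical one (which then expands to ``width_mm`` at the scaffold face).
    """

    shape: str
    diameter_mm: float
    length_mm: float
    width_mm: float | None = None  # conical base width at the scaffold face

    def __post_init__(self):
        if self.shape not in (CYLINDRICAL, CONICAL):
            raise ValueError(f"unknown connector shape {self.shape!r}")
        if self.diameter_mm <= 0 or self.length_mm <= 0:
            raise ValueError("connector diameter and length must be positive")
        if self.shape == CONICAL:
            if self.width_mm is None or self.width_mm < self.diameter_mm:
                raise ValueError("conical base width must be >= throat diameter")


@dataclass(frozen=True)
class ReactorConfig:
    chamber_mm: tuple  # (width, depth, height) of the chamber cavity
    inlet: ConnectorSpec
    outlet: ConnectorSpec
    encasement: bool = True
    gap_mm: float = 0.0  # annular bypass width, enc- only
    orientation: str = LENGTHWISE
    type_label: str | None = None
    port_bore_mm: float = DEFAULT_PORT_BORE_MM

    def __post_init__(self):
        if self.orientation not in (LENGTHWISE, TRANSVERSE):
            raise ValueError(f"unknown orientation {self.orientation!r}")
        if self.encasement and self.gap_mm != 0.0:
            raise ValueError("enc+ is form-fit: gap_mm must be 0")
        if not self.encasement and self.gap_mm <= 0.0:
            raise ValueError("enc- (loose fit) requires a positive bypass gap")


# the three manufactured nozzle designs; conical heights/widths as built,
# cylindrical length chosen as a mid-range nozzle (the device drawing gives
# no length for the 1 mm cylindrical nozzle)
_PRESETS = {
    "type1": dict(shape=CYLINDRICAL, diameter_mm=1.0, length_mm=5.0, width_mm=None,
                  orientation=LENGTHWISE),
    "type2": dict(shape=CONICAL, diameter_mm=DEFAULT_PORT_BORE_MM, length_mm=15.0,
                  width_mm=15.0, orientation=LENGTHWISE),
    "type3": dict(shape=CONICAL, diameter_mm=DEFAULT_PORT_BORE_MM, length_mm=15.0,
                  width_mm=25.0, orientation=TRANSVERSE),
}

DEFAULT_GAP_MM = 0.5


def preset(type_label: str, encasement: bool = True,
           orientation: str | None = None,
           scaffold_dims_mm=(10.0, 10.0, 20.0),
           gap_mm: float | None = None) -> ReactorConfig:
    """Named reactor configuration (type1/2/3, enc+/enc-)."""
    if type_label not in _PRESETS:
        raise KeyError(f"unknown preset {type_label!r}; known: {sorted(_PRESETS)}")
    p = _PRESETS[type_label]
    orientation = orientation or p["orientation"]
    sx, sy, sz = scaffold_dims_mm
    if orientation == TRANSVERSE:
        cross = (sx, sz)  # flow crosses the short (10 mm) dimension
        height = sy
    else:
        cross = (sx, sy)
        height = sz
    gap = 0.0 if encasement else (DEFAULT_GAP_MM if gap_mm is None else gap_mm)
    conn = ConnectorSpec(p["shape"], p["diameter_mm"], p["length_mm"], p["width_mm"])
    return ReactorConfig(
        chamber_mm=(cross[0] + 2 * gap, cross[1] + 2 * gap, height),
        inlet=conn,
        outlet=conn,
        encasement=encasement,
        gap_mm=gap,
        orientation=orientation,
        type_label=type_label,
    )


@dataclass
class SimulationDomain:
    """Voxelized reactor with region labels; flow axis is the last axis."""

    labels: np.ndarray
    voxel_mm: float
    flow_axis: int = 2
    config: ReactorConfig | None = None
    scaffold_zrange: tuple = (0, 0)  # [z0, z1) voxel layers of the scaffold
    porosity: float = 1.0
    pore_scale_mm: float = 1.0
    provenance: dict = field(default_factory=dict)

    @property
    def shape(self):
        return self.labels.shape

    def fluid_mask(self, homogenized: bool = False) -> np.ndarray:
        m = np.isin(self.labels, OPEN_FLUID_LABELS)
        if homogenized:
            m |= self.labels == SCAFFOLD_SOLID
        return m

    def scaffold_mask(self, homogenized: bool = False) -> np.ndarray:
        if homogenized:
            return np.isin(self.labels, (SCAFFOLD_FLUID, SCAFFOLD_SOLID))
        return self.labels == SCAFFOLD_FLUID

    def port_mask(self, which: str) -> np.ndarray:
        lab = INLET_PORT if which == "inlet" else OUTLET_PORT
        return self.labels == lab


def _disc_mask(nx, ny, cx, cy, radius_vox, fallback_center=True):
    """Voxels of an (nx, ny) layer whose centers lie within radius of (cx, cy)."""
    x, y = np.meshgrid(np.arange(nx) + 0.5, np.arange(ny) + 0.5, indexing="ij")
    d2 = (x - cx) ** 2 + (y - cy) ** 2
    m = d2 <= radius_vox**2 + 1e-9
    if fallback_center and not m.any():
        m.flat[np.argmin(d2)] = True
    return m


def _oriented_occupancy(scaffold: ScaffoldVolume, orientation: str) -> np.ndarray:
    occ = scaffold.occupancy
    if orientation == TRANSVERSE:
        # rotate so flow (last axis) crosses the 10 mm dimension
        occ = np.ascontiguousarray(occ.transpose(0, 2, 1))
    return occ


def build_domain(scaffold: ScaffoldVolume, config: ReactorConfig) -> SimulationDomain:
    """Assemble the full labeled reactor domain around a scaffold block."""
    h = scaffold.voxel_mm
    occ = _oriented_occupancy(scaffold, config.orientation)
    sx, sy, sz = occ.shape

    cw, cd, chh = config.chamber_mm
    gap_vox = int(round(config.gap_mm / h)) if not config.encasement else 0
    if not config.encasement and gap_vox < 1:
        raise ValueError(
            f"bypass gap {config.gap_mm} mm under-resolved at voxel {h} mm"
        )
    cwv, cdv = sx + 2 * gap_vox, sy + 2 * gap_vox
    if abs(cwv * h - cw) > h or abs(cdv * h - cd) > h:
        raise ValueError(
            f"chamber cross-section {cw}x{cd} mm does not enclose the "
            f"scaffold footprint {sx * h}x{sy * h} mm (+gap) within one voxel"
        )
    if int(round(chh / h)) != sz:
        raise ValueError(
            f"chamber height {chh} mm does not match scaffold length {sz * h} mm"
        )

    for conn, name in ((config.inlet, "inlet"), (config.outlet, "outlet")):
        if conn.shape == CYLINDRICAL and conn.diameter_mm > max(cw, cd) + 1e-9:
            raise ValueError(
                f"{name} connector D={conn.diameter_mm} mm wider than the "
                f"chamber face {cw}x{cd} mm"
            )

    wall = 1  # wall thickness in voxels
    nx, ny = cwv + 2 * wall, cdv + 2 * wall
    li = max(1, int(round(config.inlet.length_mm / h)))
    lo = max(1, int(round(config.outlet.length_mm / h)))
    plenum = gap_vox if not config.encasement else 0
    stub = max(1, int(round(1.5 / h)))  # feed-tubing stub at each port
    nz = stub + li + plenum + sz + plenum + lo + stub

    lab = np.full((nx, ny, nz), WALL, dtype=np.uint8)
    cx, cy = nx / 2.0, ny / 2.0

    def connector_layers(conn: ConnectorSpec, z_layers, from_port: bool):
        """Carve a nozzle channel; z_layers ordered from the port inward."""
        n = len(z_layers)
        for j, z in enumerate(z_layers):
            if conn.shape == CYLINDRICAL:
                dia = conn.diameter_mm
            else:
                # sample the taper at each layer's scaffold-side edge so the
                # final layer always spans the full base width: the diffuser
                # feeds the entire scaffold face regardless of its length
                t = (j + 1.0) / n
                dia = conn.diameter_mm + (conn.width_mm - conn.diameter_mm) * t
            m = _disc_mask(nx, ny, cx, cy, dia / (2.0 * h))
            m &= _chamber_cross
            lab[:, :, z][m] = CONNECTOR

    _chamber_cross = np.zeros((nx, ny), dtype=bool)
    _chamber_cross[wall:wall + cwv, wall:wall + cdv] = True

    # feed-tube stubs (single connected boundary patches at z=0 and z=nz-1)
    for conn, zs, which in ((config.inlet, range(stub), INLET_PORT),
                            (config.outlet, range(nz - stub, nz), OUTLET_PORT)):
        bore = (min(conn.diameter_mm, config.port_bore_mm)
                if conn.shape == CYLINDRICAL else conn.diameter_mm)
        m = _disc_mask(nx, ny, cx, cy, bore / (2.0 * h)) & _chamber_cross
        for z in zs:
            lab[:, :, z][m] = which

    connector_layers(config.inlet, list(range(stub, stub + li)), True)
    connector_layers(config.outlet,
                     list(range(nz - stub - 1, nz - stub - 1 - lo, -1)), True)

    z0 = stub + li + plenum
    z1 = z0 + sz
    # scaffold block
    block = lab[wall + gap_vox:wall + gap_vox + sx,
                wall + gap_vox:wall + gap_vox + sy, z0:z1]
    block[...] = np.where(occ == FLUID, SCAFFOLD_FLUID, SCAFFOLD_SOLID)

    if not config.encasement:
        # annular bypass around the scaffold's lateral faces
        ring = _chamber_cross.copy()
        ring[wall + gap_vox:wall + gap_vox + sx,
             wall + gap_vox:wall + gap_vox + sy] = False
        lab[:, :, z0:z1][ring] = BYPASS_GAP
        # loose-fit plenum between nozzle and scaffold face / gap
        for zp in list(range(z0 - plenum, z0)) + list(range(z1, z1 + plenum)):
            lab[:, :, zp][_chamber_cross] = CHAMBER_FLUID

    dom = SimulationDomain(
        labels=lab,
        voxel_mm=h,
        flow_axis=2,
        config=config,
        scaffold_zrange=(z0, z1),
        porosity=scaffold.porosity,
        pore_scale_mm=scaffold.pore_scale_mm,
        provenance={"scaffold_seed": scaffold.seed,
                    "scaffold_provenance": scaffold.provenance,
                    "type_label": config.type_label},
    )
    _validate_domain(dom)
    return dom


def duct_domain(width_mm, depth_mm, length_mm, voxel_mm) -> SimulationDomain:
    """Empty rectangular duct with full-face inlet/outlet (solver test rig)."""
    h = voxel_mm
    nx = int(round(width_mm / h)) + 2
    ny = int(round(depth_mm / h)) + 2
    nz = int(round(length_mm / h)) + 2
    lab = np.full((nx, ny, nz), WALL, dtype=np.uint8)
    lab[1:-1, 1:-1, 1:-1] = CHAMBER_FLUID
    lab[1:-1, 1:-1, 0] = INLET_PORT
    lab[1:-1, 1:-1, -1] = OUTLET_PORT
    return SimulationDomain(labels=lab, voxel_mm=h, flow_axis=2,
                            scaffold_zrange=(1, nz - 1))


def _validate_domain(dom: SimulationDomain) -> None:
    lab = dom.labels
    for which in ("inlet", "outlet"):
        m = dom.port_mask(which)
        if not m.any():
            raise ValueError(f"{which} port patch is empty")
        _, ncomp = ndimage.label(m, structure=_FACE_STRUCT)
        if ncomp != 1:
            raise ValueError(f"{which} port patch is not a single connected patch")
    if dom.config is not None and dom.config.encasement:
        if (lab == BYPASS_GAP).any():
            raise ValueError("enc+ domain must not contain bypass-gap voxels")
    if not ports_connected(dom):
        raise ValueError("inlet and outlet ports are not connected by fluid")


def ports_connected(dom: SimulationDomain, through: np.ndarray | None = None) -> bool:
    """Graph check: do inlet and outlet connect through non-wall voxels?

    ``through`` optionally restricts the traversable voxel set (e.g. to
    assert that a path exists entirely through the bypass gap).
    """
    passable = dom.fluid_mask(homogenized=False) if through is None else through
    passable = passable | dom.port_mask("inlet") | dom.port_mask("outlet")
    labels, n = ndimage.label(passable, structure=_FACE_STRUCT)
    if n == 0:
        return False
    inlet_ids = np.unique(labels[dom.port_mask("inlet")])
    outlet_ids = np.unique(labels[dom.port_mask("outlet")])
    return bool(np.intersect1d(inlet_ids[inlet_ids > 0],
                               outlet_ids[outlet_ids > 0]).size)
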