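"""Day-0 tissue construction.

Builds the initial cross-section: frozen confinement walls at the lateral
extremes, a frozen stromal slab, a one-voxel basement membrane strip split
into a limbal zone (low-x) and a central/peripheral zone, limbal stem cells
tiling the limbal membrane, an optional pre-seeded basal population, a tear
film coating the apical surface, and a zeroed EGF field with the tear source
active.
"""

from __future__ import annotations

from dataclasses import dataclass

from . import _kernels as K
from .celltypes import (
    BASAL, LIMB, MEDIUM, MEMB, STEM, STROMA, TEAR, WALL,
)
from .potts import CellRegistry, LatticeState

__all__ = ["GeometrySpec", "build_initial_state"]


@dataclass
class GeometrySpec:
    """Domain geometry in lattice/physical units."""

    width: int = 200                  # voxels (400 μm at 2 μm/voxel)
    height: int = 90                  # voxels (180 μm)
    voxel_edge: float = 2.0           # μm
    limbal_width_um: float = 80.0     # limbal zone at the low-x end
    stroma_depth: int = 10            # voxels
    membrane_rows: int = 1
    tear_thickness: int = 4           # voxels (8 μm, within the 5-10 μm film)
    seed_stem: bool = True            # tile the limbal membrane with stems
    stem_size: int = 5                # stem cells seeded as 5x5 blocks
    #: seed a day-0 basal population on the central membrane alongside the
    #: limbal stem cells (set False for a stem-only start)
    seed_basal: bool = True
    basal_size: int = 5

    def __post_init__(self):
        lw = self.limbal_voxels
        if not (0 < lw < self.width):
            raise ValueError("limbal zone must fit inside the lattice")
        if self.stroma_depth + self.membrane_rows + self.stem_size + \
                self.tear_thickness + 2 > self.height:
            raise ValueError("geometry cannot fit the seeded cells")

    @property
    def limbal_voxels(self) -> int:
        return int(round(self.limbal_width_um / self.voxel_edge))

    @property
    def membrane_y(self) -> int:
        return self.stroma_depth


def build_initial_state(config) -> tuple[LatticeState, CellRegistry, dict]:
    """Construct the initial lattice, registry, and scalar fields.

    ``config`` is a RunConfig (or anything exposing ``geometry`` and
    ``fields``).  Fields are returned as a name -> ScalarField dict with the
    EGF field zero-initialized and clamped at the tear film.
    """
    from .fields import ScalarField, apply_source

    geo: GeometrySpec = config.geometry
    W, H = geo.width, geo.height
    state = LatticeState.empty(W, H, voxel_edge=geo.voxel_edge)
    cells = CellRegistry()
    spin, tmap = state.spin, state.tmap

    # frozen substrate
    spin[:, 0] = WALL
    spin[:, W - 1] = WALL
    spin[: geo.stroma_depth, 1: W - 1] = STROMA
    ym = geo.membrane_y
    lim = geo.limbal_voxels
    for r in range(geo.membrane_rows):
        spin[ym + r, 1: lim] = LIMB
        spin[ym + r, lim: W - 1] = MEMB
    y_cells = ym + geo.membrane_rows

    # stem cells tiling the limbal membrane
    if geo.seed_stem:
        s = geo.stem_size
        x = 1
        while x + s <= lim:
            cid = cells.new_cell(STEM, birth_mcs=0, target_volume=25.0)
            spin[y_cells: y_cells + s, x: x + s] = cid
            x += s
        if spin[y_cells, 1] == 0:
            raise ValueError("limbal zone too narrow for any stem cell")

    if geo.seed_basal:
        b = geo.basal_size
        x = lim
        while x + b <= W - 1:
            cid = cells.new_cell(BASAL, birth_mcs=0, target_volume=25.0)
            spin[y_cells: y_cells + b, x: x + b] = cid
            x += b

    # type map from spins, then tear film on the apical surface
    tmap[:] = 0
    tmap[spin == WALL] = WALL
    tmap[spin == STROMA] = STROMA
    tmap[spin == LIMB] = LIMB
    tmap[spin == MEMB] = MEMB
    for cid in cells.live_ids():
        tmap[spin == cid] = cells.ctype[cid]
    K.tear_repaint(spin, tmap, geo.tear_thickness, TEAR, TEAR, MEDIUM)

    cells.recompute_from(state)
    ids = cells.live_ids()
    cells.birth_y[ids] = cells.sumy[ids] / cells.vol[ids]

    fields = {}
    for name, fparams in config.field_params().items():
        f = ScalarField.zeros(name, (H, W), fparams)
        if name == "egf":
            apply_source(f, state)
        fields[name] = f
    return state, cells, fields
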