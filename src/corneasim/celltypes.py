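"""Cell-type codes and reserved lattice ids.

The lattice maps every voxel to a *spin* (a cell id, 0 = medium).  Static
tissue components — confining walls, the stromal slab, the two basement
membrane zones and the tear film — occupy reserved low ids equal to their
type code, so one integer identifies both the agent and its type.  Motile
epithelial cells get ids starting at :data:`FIRST_CELL_ID`, never reused,
which lets turnover statistics follow individual cells across a run.
"""

from __future__ import annotations

import numpy as np

# type codes (also reserved spins for the static agents)
MEDIUM = 0   # air above the tear film
WALL = 1     # frozen lateral confinement columns
STROMA = 2   # frozen stromal slab (spatial constraint only)
LIMB = 3     # limbal zone of the basement membrane (low stiffness)
MEMB = 4     # central/peripheral basement membrane + Bowman's layer
TEAR = 5     # tear film, constant growth-factor source
STEM = 6     # limbal epithelial stem cells
BASAL = 7
WING = 8
SUPER = 9

N_TYPES = 10
FIRST_CELL_ID = 10

#: types whose voxel sets never change through Potts dynamics
FROZEN_TYPES = (WALL, STROMA, LIMB, MEMB)

#: the four epithelial cell types, in differentiation order
EPITHELIAL_TYPES = (STEM, BASAL, WING, SUPER)

#: membrane entity: limbal + central zones (merged EpBM/Bowman's complex)
MEMBRANE_TYPES = (LIMB, MEMB)

TYPE_NAMES = {
    MEDIUM: "MEDIUM", WALL: "WALL", STROMA: "STROMA", LIMB: "LIMB",
    MEMB: "MEMB", TEAR: "TEAR", STEM: "STEM", BASAL: "BASAL",
    WING: "WING", SUPER: "SUPER",
}
NAME_TO_TYPE = {v: k for k, v in TYPE_NAMES.items()}

FROZEN_MASK = np.zeros(N_TYPES, dtype=np.uint8)
for _t in FROZEN_TYPES:
    FROZEN_MASK[_t] = 1

# Fig-3-style display palette (RGB)
PALETTE = {
    MEDIUM: (0, 0, 0),          # black (air)
    WALL: (90, 90, 90),         # grey
    STROMA: (190, 160, 220),    # lilac-purple
    LIMB: (255, 170, 200),      # pink
    MEMB: (230, 0, 126),        # magenta
    TEAR: (60, 220, 60),        # bright green
    STEM: (220, 60, 90),        # rose-red
    BASAL: (255, 190, 130),     # peach-orange
    WING: (70, 90, 230),        # blue
    SUPER: (90, 220, 230),      # cyan
}


def type_name(code: int) -> str:
    return TYPE_NAMES.get(int(code), f"?{code}")
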