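"""Injury scenarios: circular ablation and chemical (toxicant) exposure.

Ablation instantaneously removes all epithelial material inside a circle and
replaces it with tear film (reflecting reflex tearing over the wound bed).
Chemical exposure deposits a dose into the tear film — as a droplet-like
Gaussian along the surface or uniformly — whose spread is then handled by
the reaction-diffusion solver; cells die when their mean internal toxicant
concentration exceeds a threshold, and at moderate doses the basement
membrane itself is destroyed (permanently: the model has no membrane
regeneration, which is what produces recurrent-erosion-like dynamics).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .celltypes import (
    EPITHELIAL_TYPES, LIMB, MEMB, STROMA, TEAR,
)

__all__ = ["InjurySpec", "ablate", "apply_chemical", "destroy_membrane"]


@dataclass
class InjurySpec:
    """One injury event (exactly one mode active)."""

    mode: str = "chemical"            # "ablation" | "chemical"
    trigger_mcs: int = 0
    center: tuple = (120, 30)         # (x, y) voxels
    radius: float = 15.0              # ablation circle, voxels
    include_membrane: bool = False    # ablation reaches membrane depth
    dose: float = 750.0               # chemical, arb. units (integrated)
    spatial_profile: str = "gaussian"  # "gaussian" | "uniform"
    sigma: float = 25.0               # Gaussian droplet width, voxels
    cell_threshold: float = 0.6       # mean conc. triggering cell death
    membrane_threshold: float = 0.10  # conc. destroying membrane voxels
    death_rate: float = 1.0           # target-volume loss, voxels/MCS
    severity_label: str = ""

    def __post_init__(self):
        if self.mode not in ("ablation", "chemical"):
            raise ValueError(f"unknown injury mode {self.mode!r}")
        if self.mode == "chemical" and self.dose < 0:
            raise ValueError("chemical dose must be >= 0 (0 = inert exposure)")
        if self.spatial_profile not in ("gaussian", "uniform"):
            raise ValueError(f"unknown profile {self.spatial_profile!r}")


def ablate(state, cells, spec: InjurySpec):
    """Replace all epithelium inside the circle with tear film.

    Membrane voxels are removed only when ``include_membrane`` is set;
    stroma and walls are never touched.  Total voxel count is conserved
    (cell voxels become tear).
    """
    H, W = state.spin.shape
    cx, cy = spec.center
    yy, xx = np.mgrid[0:H, 0:W]
    circle = (xx - cx) ** 2 + (yy - cy) ** 2 <= spec.radius ** 2
    if not circle.any():
        raise ValueError("ablation circle lies entirely outside the lattice")
    target = circle & np.isin(state.tmap, EPITHELIAL_TYPES)
    if spec.include_membrane:
        target |= circle & np.isin(state.tmap, (LIMB, MEMB))
    if not target.any():
        return state
    state.spin[target] = TEAR
    state.tmap[target] = TEAR
    cells.recompute_from(state)
    dead = cells.live_ids()[cells.vol[cells.live_ids()] == 0]
    cells.alive[dead] = 0
    return state


def apply_chemical(state, fields: dict, spec: InjurySpec):
    """Deposit the toxicant dose into the tear film.

    The Gaussian profile distributes the integrated dose along the surface
    (amplitude scaled so the deposit sums to ``dose``); the uniform profile
    spreads it evenly.  Each column's share is split among its tear voxels.
    """
    chem = fields["chem"]
    H, W = state.spin.shape
    tear_cols = [x for x in range(W) if (state.tmap[:, x] == TEAR).any()]
    if not tear_cols:
        return chem
    cols = np.array(tear_cols)
    if spec.spatial_profile == "gaussian":
        w = np.exp(-0.5 * ((cols - spec.center[0]) / spec.sigma) ** 2)
    else:
        w = np.ones(len(cols), dtype=float)
    w = w / w.sum()
    for x, share in zip(cols, w):
        ys = np.nonzero(state.tmap[:, x] == TEAR)[0]
        chem.c[ys, x] += spec.dose * share / len(ys)
    return chem


def destroy_membrane(state, chem_field, membrane_threshold: float) -> int:
    """Permanently convert over-threshold membrane voxels to bare stroma.

    Returns the number of voxels destroyed.  There is no regeneration: once
    a membrane voxel is gone, basal cells above the gap can no longer
    maintain membrane contact.
    """
    sel = np.isin(state.tmap, (LIMB, MEMB)) & (chem_field.c > membrane_threshold)
    n = int(sel.sum())
    if n:
        state.spin[sel] = STROMA
        state.tmap[sel] = STROMA
    return n
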