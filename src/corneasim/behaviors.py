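"""Per-cell rule set: growth, mitosis, differentiation, sloughing, death.

Growth couples two Hill factors — an activating response to the local EGF
concentration and an inhibiting response to crowding pressure — and feeds
the product into the cell's target volume.  Mitosis is volume-triggered with
type-specific cleavage orientation.  Differentiation is a deterministic,
contact-triggered cascade (stem -> basal -> wing -> superficial), sloughing
is a constant-hazard removal of tear-exposed superficial cells, and chemical
injury kills cells by driving their target volume to zero.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import _kernels as K
from .celltypes import (
    BASAL, LIMB, MEMB, STEM, SUPER, TEAR, WING, NAME_TO_TYPE, N_TYPES,
)

__all__ = [
    "GrowthParams", "SloughParams", "egf_growth_factor",
    "density_growth_factor", "cell_pressure", "apply_growth", "maybe_divide",
    "differentiate", "maybe_slough", "injury_death",
]


@dataclass
class GrowthParams:
    """Proliferation parameters (concentrations in the EGF field's units)."""

    km_egf: dict = field(default_factory=lambda: {"STEM": 3.5, "BASAL": 7.0})
    km_density: float = 125.0
    hill_n: int = 4
    #: intrinsic maximal doubling rate, voxels/MCS; 25 voxels in 80 MCS (8 h)
    delta: dict = field(default_factory=lambda: {"STEM": 25.0 / 80.0,
                                                 "BASAL": 25.0 / 80.0})
    lambda_for_pressure: float = 30.0   # pressure per voxel of volume deficit

    def km_egf_array(self) -> np.ndarray:
        out = np.zeros(N_TYPES)
        for name, v in self.km_egf.items():
            out[NAME_TO_TYPE[name]] = float(v)
        return out

    def delta_array(self) -> np.ndarray:
        out = np.zeros(N_TYPES)
        for name, v in self.delta.items():
            out[NAME_TO_TYPE[name]] = float(v)
        return out


@dataclass
class SloughParams:
    """Constant-hazard desquamation of tear-exposed superficial cells."""

    day_to_mcs: int = 240
    lifetime_days: float = 3.0

    @property
    def p_per_mcs(self) -> float:
        p = 1.0 / (self.lifetime_days * self.day_to_mcs)
        if not (0.0 < p < 1.0):
            raise ValueError("sloughing probability must lie in (0, 1)")
        return p


def egf_growth_factor(egf: float, km: float, n: int = 4) -> float:
    """Activating Hill response: egf^n / (km^n + egf^n), in [0, 1]."""
    if egf < 0:
        raise ValueError("EGF concentration must be >= 0")
    if km <= 0:
        raise ValueError("half-max concentration must be > 0")
    r = (egf / km) ** n
    return r / (1.0 + r)


def density_growth_factor(pressure: float, km: float, n: int = 4) -> float:
    """Inhibiting Hill response: km^n / (km^n + P^n), in [0, 1]."""
    if km <= 0:
        raise ValueError("half-max pressure must be > 0")
    p = max(0.0, pressure)
    r = (p / km) ** n
    return 1.0 / (1.0 + r)


def cell_pressure(volume: float, target_volume: float,
                  lambda_for_pressure: float) -> float:
    """Crowding proxy: lam * (V_target - V), clamped at zero.

    A crowded cell cannot reach its target volume, so a positive deficit
    signals compression; overfilled cells report zero pressure.
    """
    return max(0.0, lambda_for_pressure * (target_volume - volume))


def apply_growth(cells, cid: int, egf_mean: float, params: GrowthParams) -> float:
    """Advance one proliferative cell's target volume by one MCS.

    Returns the applied increment (0 for non-proliferative types).
    """
    ct = int(cells.ctype[cid])
    name = {STEM: "STEM", BASAL: "BASAL"}.get(ct)
    if name is None:
        return 0.0
    g_egf = egf_growth_factor(egf_mean, params.km_egf[name], params.hill_n)
    p = cell_pressure(cells.vol[cid], cells.tvol[cid],
                      params.lambda_for_pressure)
    g_den = density_growth_factor(p, params.km_density, params.hill_n)
    inc = params.delta[name] * g_egf * g_den
    cells.tvol[cid] += inc
    return inc


DIVISION_VOLUME = 50   # voxels; double the 25-voxel initial volume


def maybe_divide(state, cells, cid: int, rng: np.random.Generator,
                 threshold: int = DIVISION_VOLUME) -> int | None:
    """Split a proliferative cell that has doubled its volume.

    The cleavage plane passes through the centroid: stem cells use a plane
    whose normal is the radial x-axis so one daughter lies centripetally
    (toward larger x); basal cells draw a uniformly random orientation.
    Voxels are partitioned by signed distance to the plane, sorted so the
    two daughters differ by at most one voxel.  Both daughters restart at a
    25-voxel target volume; the centripetal / upper half receives the new id.
    Returns the new cell id, or None below threshold.
    """
    ct = int(cells.ctype[cid])
    if ct not in (STEM, BASAL):
        return None
    if cells.vol[cid] < threshold:
        return None
    vox = np.argwhere(state.spin == cid)          # (n, 2) -> y, x
    ys, xs = vox[:, 0].astype(float), vox[:, 1].astype(float)
    cy, cx = ys.mean(), xs.mean()
    if ct == STEM:
        d = xs - cx                                # centripetal split
    else:
        theta = float(rng.uniform(0.0, np.pi))     # random cleavage plane
        d = np.cos(theta) * (xs - cx) + np.sin(theta) * (ys - cy)
    order = np.argsort(d, kind="stable")
    n = len(order)
    upper = order[n // 2:]                         # larger-d half -> new id
    new_id = cells.new_cell(ct, state.mcs, target_volume=25.0)
    for i in upper:
        state.spin[vox[i, 0], vox[i, 1]] = new_id
    state.tmap[state.spin == new_id] = ct
    # rebuild bookkeeping for both halves from their bounding box
    y0, x0 = int(vox[:, 0].min()) - 1, int(vox[:, 1].min()) - 1
    y1, x1 = int(vox[:, 0].max()) + 2, int(vox[:, 1].max()) + 2
    for c in (cid, new_id):
        v, sx, sy, sf = K.cell_stats_bbox(state.spin, c, y0, y1, x0, x1)
        cells.vol[c] = v
        cells.sumx[c] = sx
        cells.sumy[c] = sy
        cells.surf[c] = sf
    # division renews both halves: reset growth and trajectory bookkeeping
    for c in (cid, new_id):
        cells.tvol[c] = 25.0
        cells.tsurf[c] = 20.0
        cells.birth_mcs[c] = state.mcs
        cells.birth_y[c] = cells.sumy[c] / max(1, cells.vol[c])
        cells.birth_type[c] = ct
        cells.ntrans[c] = 0
    return new_id


def differentiate(cell_type: int, neighbor_types: set,
                  epbm_contact_area: int, omega_contact_basal: int = 5) -> int | None:
    """Contact-triggered differentiation cascade; returns the new type or None.

    - stem -> basal when limbal-membrane contact is lost;
    - basal -> wing when membrane contact area falls to <= omega (5 voxels);
    - wing -> superficial on tear contact with no remaining contact with the
      basal compartment (basal, stem, or central membrane).
    Transitions are deterministic, immediate, and strictly forward.
    """
    if cell_type == STEM:
        if LIMB not in neighbor_types:
            return BASAL
    elif cell_type == BASAL:
        if epbm_contact_area <= omega_contact_basal:
            return WING
    elif cell_type == WING:
        if TEAR in neighbor_types and not ({BASAL, MEMB, STEM} & neighbor_types):
            return SUPER
    return None


def maybe_slough(cell_type: int, neighbor_types: set, params: SloughParams,
                 rng: np.random.Generator) -> bool:
    """Probabilistic desquamation of one tear-exposed superficial cell."""
    if cell_type != SUPER or TEAR not in neighbor_types:
        return False
    return bool(rng.random() < params.p_per_mcs)


def injury_death(chem_mean: float, threshold: float) -> bool:
    """Toxicant trigger: a cell starts dying above the concentration threshold."""
    return chem_mean > threshold
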