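"""Glazier–Graner–Hogeweg lattice engine.

A cell is the set of lattice voxels sharing its id ("spin").  Configuration
changes are proposed as voxel copies between Moore neighbors and accepted by
the Metropolis rule on the effective-energy change

    dH = dH_contact + dH_links + dH_volume + dH_surface + dH_chemotaxis

with quadratic volume/surface penalties, per-type contact energies summed
over the 2nd-order neighborhood, Hookean center-to-center links between
superficial cells, and a linear chemotaxis coupling to scalar fields.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from . import _kernels as K
from .celltypes import (
    FIRST_CELL_ID, FROZEN_MASK, NAME_TO_TYPE, N_TYPES, SUPER, TYPE_NAMES,
)

__all__ = [
    "LatticeState", "CellRegistry", "ContactEnergyTable", "PottsParams",
    "LinkSet", "ChemotaxisSpec", "delta_hamiltonian", "attempt_copy",
    "metropolis_accept", "run_mcs",
]


@dataclass
class LatticeState:
    """Voxel grid (spin = cell id, 0 = medium) plus its physical scaling."""

    spin: np.ndarray                 # int32 (height, width)
    tmap: np.ndarray                 # uint8 cell-type of each voxel
    voxel_edge: float = 2.0          # μm per lattice unit
    mcs: int = 0
    mcs_minutes: float = 6.0         # biological minutes per MCS

    @property
    def height(self) -> int:
        return self.spin.shape[0]

    @property
    def width(self) -> int:
        return self.spin.shape[1]

    @property
    def mcs_per_day(self) -> int:
        return round(24 * 60 / self.mcs_minutes)

    @property
    def day(self) -> float:
        return self.mcs / self.mcs_per_day

    @classmethod
    def empty(cls, width: int, height: int, **kw) -> "LatticeState":
        return cls(
            spin=np.zeros((height, width), dtype=np.int32),
            tmap=np.zeros((height, width), dtype=np.uint8),
            **kw,
        )

    def copy(self) -> "LatticeState":
        return LatticeState(self.spin.copy(), self.tmap.copy(),
                            self.voxel_edge, self.mcs, self.mcs_minutes)


class CellRegistry:
    """Struct-of-arrays registry of agents, indexed by cell id.

    Ids below FIRST_CELL_ID are reserved for the static agents (wall, stroma,
    membrane zones, tear) and carry their type code as id.  Epithelial cell
    ids are allocated sequentially and never reused.
    """

    def __init__(self, capacity: int = 1024):
        capacity = max(capacity, FIRST_CELL_ID + 1)
        self._alloc(capacity)
        self.next_id = FIRST_CELL_ID
        for t in range(N_TYPES):
            self.ctype[t] = t

    def _alloc(self, cap: int):
        self.capacity = cap
        self.ctype = np.zeros(cap, dtype=np.uint8)
        self.alive = np.zeros(cap, dtype=np.uint8)
        self.vol = np.zeros(cap, dtype=np.int64)
        self.tvol = np.zeros(cap, dtype=np.float64)
        self.surf = np.zeros(cap, dtype=np.int64)
        self.tsurf = np.zeros(cap, dtype=np.float64)
        self.sumx = np.zeros(cap, dtype=np.float64)
        self.sumy = np.zeros(cap, dtype=np.float64)
        self.birth_mcs = np.zeros(cap, dtype=np.int64)
        self.birth_y = np.zeros(cap, dtype=np.float64)
        self.birth_type = np.zeros(cap, dtype=np.uint8)
        self.ntrans = np.zeros(cap, dtype=np.int64)
        self.dying = np.zeros(cap, dtype=np.uint8)

    def _grow(self):
        old = self.__dict__.copy()
        self._alloc(self.capacity * 2)
        for name in ("ctype", "alive", "vol", "tvol", "surf", "tsurf",
                     "sumx", "sumy", "birth_mcs", "birth_y", "birth_type",
                     "ntrans", "dying"):
            getattr(self, name)[: len(old[name])] = old[name]

    def new_cell(self, ctype: int, birth_mcs: int, target_volume: float = 25.0,
                 target_surface: float | None = None) -> int:
        if self.next_id >= self.capacity:
            self._grow()
        cid = self.next_id
        self.next_id += 1
        self.ctype[cid] = ctype
        self.alive[cid] = 1
        self.tvol[cid] = target_volume
        self.tsurf[cid] = (4.0 * math.sqrt(target_volume)
                           if target_surface is None else target_surface)
        self.birth_mcs[cid] = birth_mcs
        self.birth_type[cid] = ctype
        return cid

    def live_ids(self, types=None) -> np.ndarray:
        ids = np.nonzero(self.alive[: self.next_id])[0]
        ids = ids[ids >= FIRST_CELL_ID]
        if types is not None:
            keep = np.isin(self.ctype[ids], np.asarray(types, dtype=np.uint8))
            ids = ids[keep]
        return ids

    def centroid(self, cid: int) -> tuple[float, float]:
        v = float(self.vol[cid])
        return self.sumx[cid] / v, self.sumy[cid] / v

    def recompute_from(self, state: LatticeState):
        """Rebuild volume/centroid/surface bookkeeping from the grid."""
        vol, sumx, sumy, surf = K.lattice_stats(state.spin, self.capacity)
        self.vol[:] = vol
        self.sumx[:] = sumx
        self.sumy[:] = sumy
        self.surf[:] = surf

    def check_consistency(self, state: LatticeState):
        """Assert the registry invariants against the raw grid."""
        vol, sumx, sumy, surf = K.lattice_stats(state.spin, self.capacity)
        live = self.live_ids()
        assert np.array_equal(vol[live], self.vol[live]), "volume drift"
        assert np.array_equal(surf[live], self.surf[live]), "surface drift"
        assert np.allclose(sumx[live], self.sumx[live]), "centroid drift"
        assert (vol[live] >= 1).all(), "registered cell with no voxels"
        grid_ids = np.unique(state.spin)
        grid_ids = grid_ids[grid_ids >= FIRST_CELL_ID]
        assert np.isin(grid_ids, live).all(), "unregistered spin on grid"


class ContactEnergyTable:
    """Symmetric per-type-pair contact energies J(a, b), medium included."""

    def __init__(self, J: np.ndarray):
        J = np.asarray(J, dtype=np.float64)
        if J.shape != (N_TYPES, N_TYPES):
            raise ValueError(f"J must be {N_TYPES}x{N_TYPES}")
        if not np.allclose(J, J.T):
            raise ValueError("contact energy table must be symmetric")
        self.J = J

    @classmethod
    def from_dict(cls, pairs: dict, default: float = 0.0) -> "ContactEnergyTable":
        J = np.full((N_TYPES, N_TYPES), default, dtype=np.float64)
        for key, val in pairs.items():
            a, b = key if isinstance(key, tuple) else key.split("-")
            ia = NAME_TO_TYPE[a] if isinstance(a, str) else int(a)
            ib = NAME_TO_TYPE[b] if isinstance(b, str) else int(b)
            J[ia, ib] = J[ib, ia] = float(val)
        return cls(J)

    def __getitem__(self, key):
        a, b = key
        ia = NAME_TO_TYPE[a] if isinstance(a, str) else int(a)
        ib = NAME_TO_TYPE[b] if isinstance(b, str) else int(b)
        return self.J[ia, ib]

    def to_dict(self) -> dict:
        out = {}
        for a in range(N_TYPES):
            for b in range(a, N_TYPES):
                out[f"{TYPE_NAMES[a]}-{TYPE_NAMES[b]}"] = float(self.J[a, b])
        return out


@dataclass
class PottsParams:
    """Metropolis dynamics parameters (all calibrated model constants)."""

    temperature: float = 12.0
    neighbor_order: int = 2
    lambda_volume: float = 5.0
    lambda_surface: float = 0.0
    attempts_per_mcs: int | None = None   # defaults to width*height
    # Post-mitotic cells are softer: upwelling growth pressure can compress
    # terminally differentiated cells out of the tissue, a second removal
    # pathway alongside sloughing.
    lambda_volume_by_type: dict = field(
        default_factory=lambda: {"SUPER": 3.5, "WING": 4.5})
    lambda_surface_by_type: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.temperature <= 0:
            raise ValueError("temperature must be > 0")
        if self.lambda_volume <= 0:
            raise ValueError("lambda_volume must be > 0")
        if self.neighbor_order != 2:
            raise ValueError("only the 2nd-order (Moore) neighborhood is implemented")

    def lamv_array(self) -> np.ndarray:
        lam = np.zeros(N_TYPES)
        for t in (6, 7, 8, 9):  # epithelial types
            lam[t] = self.lambda_volume
        for name, v in self.lambda_volume_by_type.items():
            lam[NAME_TO_TYPE[name]] = float(v)
        return lam

    def lams_array(self) -> np.ndarray:
        lam = np.zeros(N_TYPES)
        for t in (6, 7, 8, 9):
            lam[t] = self.lambda_surface
        for name, v in self.lambda_surface_by_type.items():
            lam[NAME_TO_TYPE[name]] = float(v)
        return lam


class LinkSet:
    """Hookean center-to-center springs between superficial cells.

    Rebuilt every MCS from the current superficial population: each SUPER
    cell is linked to its ``max_partners`` nearest SUPER neighbors within
    ``max_distance`` (a surface chain, so the springs act as apical tension
    rather than bulk contraction).  Stored in CSR layout for the kernel.
    """

    def __init__(self, lam: float = 0.0, target_length: float = 6.0,
                 max_distance: float = 11.0, max_partners: int | None = None):
        self.lam = float(lam)
        self.target_length = float(target_length)
        self.max_distance = float(max_distance)
        self.max_partners = max_partners
        self.clear(FIRST_CELL_ID + 1)

    def clear(self, cap: int):
        self.ptr = np.zeros(cap + 1, dtype=np.int64)
        self.part = np.zeros(0, dtype=np.int64)
        self.lams = np.zeros(0, dtype=np.float64)
        self.l0 = np.zeros(0, dtype=np.float64)

    @property
    def n_links(self) -> int:
        return len(self.part) // 2

    def pairs(self) -> set:
        out = set()
        for cid in range(len(self.ptr) - 1):
            for k in range(self.ptr[cid], self.ptr[cid + 1]):
                out.add((min(cid, self.part[k]), max(cid, self.part[k])))
        return out

    def rebuild(self, cells: CellRegistry):
        cap = cells.capacity
        if self.lam <= 0.0:
            self.clear(cap)
            return
        ids = cells.live_ids(types=[SUPER])
        if len(ids) < 2:
            self.clear(cap)
            return
        cx = cells.sumx[ids] / cells.vol[ids]
        cy = cells.sumy[ids] / cells.vol[ids]
        d2 = (cx[:, None] - cx) ** 2 + (cy[:, None] - cy) ** 2
        np.fill_diagonal(d2, np.inf)
        close = d2 <= self.max_distance ** 2
        if self.max_partners is not None:
            k = min(self.max_partners, len(ids) - 1)
            nearest = np.argpartition(d2, k - 1, axis=1)[:, :k]
            keep = np.zeros_like(close)
            rows = np.repeat(np.arange(len(ids)), k)
            keep[rows, nearest.ravel()] = True
            close &= keep
        # symmetrize: each link is stored from both endpoints so the
        # incremental energy matches H_links = 1/2 sum over entries
        close |= close.T
        counts = np.zeros(cap, dtype=np.int64)
        counts[ids] = close.sum(axis=1)
        self.ptr = np.zeros(cap + 1, dtype=np.int64)
        np.cumsum(counts, out=self.ptr[1:])
        total = int(self.ptr[-1])
        self.part = np.zeros(total, dtype=np.int64)
        self.lams = np.full(total, self.lam)
        self.l0 = np.full(total, self.target_length)
        for i, cid in enumerate(ids):
            self.part[self.ptr[cid]: self.ptr[cid + 1]] = ids[close[i]]


@dataclass
class ChemotaxisSpec:
    """Per-cell-type chemotaxis strengths for up to two scalar fields."""

    lambda_by_type: dict = field(default_factory=dict)   # field -> {type: lam}
    field_names: tuple = ("egf", "bias")

    def lam_array(self, field_name: str) -> np.ndarray:
        lam = np.zeros(N_TYPES)
        for name, v in self.lambda_by_type.get(field_name, {}).items():
            lam[NAME_TO_TYPE[name]] = float(v)
        return lam


_Z = np.zeros((1, 1))
_Z10 = np.zeros(N_TYPES)


def _kernel_args(state, cells, params, contact, links, chemo, fields):
    c1 = c2 = _Z
    l1 = l2 = _Z10
    u1 = u2 = False
    if chemo is not None and fields:
        names = chemo.field_names
        if len(names) > 0 and names[0] in fields:
            c1 = fields[names[0]]
            l1 = chemo.lam_array(names[0])
            u1 = bool(np.any(l1))
        if len(names) > 1 and names[1] in fields:
            c2 = fields[names[1]]
            l2 = chemo.lam_array(names[1])
            u2 = bool(np.any(l2))
    if links is None:
        links = LinkSet()
        links.clear(cells.capacity)
    if len(links.ptr) != cells.capacity + 1:
        links.rebuild(cells)
        if len(links.ptr) != cells.capacity + 1:
            links.clear(cells.capacity)
    return (contact.J, params.lamv_array(), params.lams_array(), FROZEN_MASK,
            links.ptr, links.part, links.lams, links.l0,
            c1, l1, c2, l2, u1, u2)


def delta_hamiltonian(state: LatticeState, cells: CellRegistry,
                      params: PottsParams, contact: ContactEnergyTable,
                      links: LinkSet | None, chemo: ChemotaxisSpec | None,
                      source_voxel, target_voxel, fields=None) -> float:
    """dH for copying the source voxel's spin onto the target voxel.

    Pure query — no state is mutated.  Frozen targets (and frozen sources)
    return ``inf``; out-of-bounds voxels raise.
    """
    ys, xs = source_voxel
    yt, xt = target_voxel
    H, W = state.spin.shape
    for (y, x) in ((ys, xs), (yt, xt)):
        if not (0 <= y < H and 0 <= x < W):
            raise IndexError(f"voxel ({y}, {x}) outside {H}x{W} lattice")
    if max(abs(yt - ys), abs(xt - xs)) != 1:
        raise ValueError("source and target must be Moore neighbors")
    s_spin = int(state.spin[ys, xs])
    t_spin = int(state.spin[yt, xt])
    if s_spin == t_spin:
        return 0.0
    (J, lamv, lams, frozen, lp, lpa, lla, ll0,
     c1, l1, c2, l2, u1, u2) = _kernel_args(state, cells, params, contact,
                                            links, chemo, fields or {})
    dh = K._dh(state.spin, state.tmap, yt, xt, ys, xs, s_spin, t_spin,
               cells.ctype, cells.vol, cells.tvol, cells.surf, cells.tsurf,
               cells.sumx, cells.sumy, J, lamv, lams, frozen,
               lp, lpa, lla, ll0, c1, l1, c2, l2, u1, u2)
    return math.inf if dh >= K.BIG else float(dh)


def metropolis_accept(dh: float, temperature: float, u: float) -> bool:
    """Boltzmann acceptance: always if dH <= 0, else with p = exp(-dH/T)."""
    if not math.isfinite(dh):
        return False
    if dh <= 0.0:
        return True
    return u < math.exp(-dh / temperature)


def apply_copy(state: LatticeState, cells: CellRegistry, yt: int, xt: int,
               s_spin: int):
    """Flip the target voxel to ``s_spin`` with incremental bookkeeping."""
    t_spin = int(state.spin[yt, xt])
    if t_spin == s_spin:
        return
    H, W = state.spin.shape
    d_ss = d_st = 0
    for dy, dx in ((-1, 0), (1, 0), (0, -1), (0, 1)):
        ny, nx = yt + dy, xt + dx
        if not (0 <= ny < H and 0 <= nx < W):
            continue
        d_ss += 1 if state.spin[ny, nx] != s_spin else -1
        d_st += 1 if state.spin[ny, nx] == t_spin else -1
    state.spin[yt, xt] = s_spin
    state.tmap[yt, xt] = cells.ctype[s_spin]
    if s_spin > 0:
        cells.vol[s_spin] += 1
        cells.sumx[s_spin] += xt
        cells.sumy[s_spin] += yt
        cells.surf[s_spin] += d_ss
    if t_spin > 0:
        cells.vol[t_spin] -= 1
        cells.sumx[t_spin] -= xt
        cells.sumy[t_spin] -= yt
        cells.surf[t_spin] += d_st
        if cells.vol[t_spin] == 0:
            cells.alive[t_spin] = 0


def attempt_copy(state: LatticeState, cells: CellRegistry,
                 params: PottsParams, contact: ContactEnergyTable,
                 links: LinkSet | None, chemo: ChemotaxisSpec | None,
                 rng: np.random.Generator, fields=None) -> bool:
    """Draw one random copy attempt and apply the Metropolis rule."""
    H, W = state.spin.shape
    ys = int(rng.integers(H))
    xs = int(rng.integers(W))
    moves = ((-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1))
    dy, dx = moves[int(rng.integers(8))]
    yt, xt = ys + dy, xs + dx
    if not (0 <= yt < H and 0 <= xt < W):
        return False
    s_spin = int(state.spin[ys, xs])
    if s_spin == int(state.spin[yt, xt]):
        return False
    dh = delta_hamiltonian(state, cells, params, contact, links, chemo,
                           (ys, xs), (yt, xt), fields)
    if not metropolis_accept(dh, params.temperature, float(rng.random())):
        return False
    apply_copy(state, cells, yt, xt, s_spin)
    return True


def run_mcs(sim, n: int):
    """Advance a Simulation by n Monte Carlo steps (delegates to the engine)."""
    if n < 0:
        raise ValueError("n must be >= 0")
    sim.run(n)
    return sim.state
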