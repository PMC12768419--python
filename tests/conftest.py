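"""Shared fixtures: small hand-built lattices and helpers.

All fixtures are generated programmatically; none are read from disk.
"""

from __future__ import annotations

import numpy as np
import pytest

from corneasim.celltypes import BASAL, FIRST_CELL_ID, STEM, SUPER, WING
from corneasim.potts import (
    CellRegistry, ContactEnergyTable, LatticeState, PottsParams,
)


def make_state(type_rows, voxel_edge=2.0):
    """Build a LatticeState from a list of per-row type codes (y=0 first)."""
    tmap = np.array(type_rows, dtype=np.uint8)
    spin = tmap.astype(np.int32).copy()
    spin[tmap >= FIRST_CELL_ID] = 0
    return LatticeState(spin=spin, tmap=tmap, voxel_edge=voxel_edge)


def place_cell(state, cells, ctype, y0, y1, x0, x1, target_volume=25.0):
    """Stamp a rectangular cell onto the lattice and register it."""
    cid = cells.new_cell(ctype, birth_mcs=state.mcs,
                         target_volume=target_volume)
    state.spin[y0:y1, x0:x1] = cid
    state.tmap[y0:y1, x0:x1] = ctype
    return cid


def finalize(state, cells):
    cells.recompute_from(state)
    ids = cells.live_ids()
    if len(ids):
        cells.birth_y[ids] = cells.sumy[ids] / cells.vol[ids]
    return state, cells


@pytest.fixture
def small_rig():
    """8x8 lattice with three epithelial cells, ready for energy queries."""
    state = LatticeState.empty(8, 8)
    cells = CellRegistry()
    place_cell(state, cells, BASAL, 1, 4, 1, 4, target_volume=9)
    place_cell(state, cells, WING, 1, 4, 4, 7, target_volume=9)
    place_cell(state, cells, SUPER, 4, 7, 2, 6, target_volume=12)
    finalize(state, cells)
    return state, cells


def random_state(rng, size=8, n_cells=3):
    """Random small lattice: blobs of n_cells cells over medium."""
    state = LatticeState.empty(size, size)
    cells = CellRegistry()
    types = [BASAL, WING, SUPER, STEM]
    ids = [cells.new_cell(types[i % len(types)], 0,
                          target_volume=float(rng.integers(4, 12)))
           for i in range(n_cells)]
    # random seeded growth: assign each voxel to nearest of n random seeds
    seeds = rng.integers(0, size, size=(n_cells, 2))
    for y in range(size):
        for x in range(size):
            if rng.random() < 0.35:
                continue  # leave as medium
            d = ((seeds[:, 0] - y) ** 2 + (seeds[:, 1] - x) ** 2)
            state.spin[y, x] = ids[int(np.argmin(d))]
    for cid in ids:
        state.tmap[state.spin == cid] = cells.ctype[cid]
    cells.recompute_from(state)
    return state, cells


@pytest.fixture
def default_params():
    return PottsParams(temperature=10.0, lambda_volume=2.0,
                       lambda_surface=0.5,
                       lambda_volume_by_type={}, lambda_surface_by_type={})


@pytest.fixture
def uniform_contact():
    J = np.zeros((10, 10))
    J[1:, 1:] = 6.0
    J[0, :] = J[:, 0] = 12.0
    J[0, 0] = 0.0
    return ContactEnergyTable((J + J.T) / 2)


# ---------------------------------------------------------------- oracles

def full_hamiltonian(state, cells, params, contact, links=None):
    """Independent brute-force Hamiltonian: sums every term over the grid.

    Contact energy over all distinct-spin 2nd-order neighbor pairs (each
    unordered pair once), quadratic volume and surface penalties for every
    registered cell, and half the sum of the stored directed link energies.
    """
    H, W = state.spin.shape
    J = contact.J
    lamv = params.lamv_array()
    lams = params.lams_array()
    total = 0.0
    for y in range(H):
        for x in range(W):
            s = state.spin[y, x]
            for dy, dx in ((0, 1), (1, -1), (1, 0), (1, 1)):  # each pair once
                ny, nx = y + dy, x + dx
                if not (0 <= ny < H and 0 <= nx < W):
                    continue
                n = state.spin[ny, nx]
                if n != s:
                    total += J[state.tmap[y, x], state.tmap[ny, nx]]
    vols = np.zeros(cells.capacity)
    surfs = np.zeros(cells.capacity)
    for y in range(H):
        for x in range(W):
            s = state.spin[y, x]
            if s <= 0:
                continue
            vols[s] += 1
            for dy, dx in ((-1, 0), (1, 0), (0, -1), (0, 1)):
                ny, nx = y + dy, x + dx
                if not (0 <= ny < H and 0 <= nx < W):
                    continue
                if state.spin[ny, nx] != s:
                    surfs[s] += 1
    for cid in range(FIRST_CELL_ID, cells.next_id):
        if vols[cid] == 0:
            continue
        t = cells.ctype[cid]
        total += lamv[t] * (vols[cid] - cells.tvol[cid]) ** 2
        total += lams[t] * (surfs[cid] - cells.tsurf[cid]) ** 2
    if links is not None and len(links.part):
        for cid in range(len(links.ptr) - 1):
            for k in range(links.ptr[cid], links.ptr[cid + 1]):
                p = links.part[k]
                if vols[cid] == 0 or vols[p] == 0:
                    continue
                cx = np.nonzero(state.spin == cid)
                px = np.nonzero(state.spin == p)
                c = (np.mean(cx[1]), np.mean(cx[0]))
                q = (np.mean(px[1]), np.mean(px[0]))
                d = np.hypot(c[0] - q[0], c[1] - q[1])
                total += 0.5 * links.lams[k] * (d - links.l0[k]) ** 2
    return total
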