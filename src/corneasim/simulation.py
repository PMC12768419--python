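"""Simulation engine: the per-MCS update loop.

Order within one Monte Carlo step (the tested default):

1. lattice copy attempts (Metropolis sweep),
2. housekeeping: fragment culling, tear-film repaint,
3. injury trigger (ablation / chemical deposit) when scheduled,
4. scalar-field updates (EGF always; toxicant while an exposure is active),
5. adjacency snapshot (neighbor types, membrane contact, per-cell field means),
6. growth -> mitosis -> differentiation -> sloughing -> chemical death,
7. sampling of tissue metrics.

Cells created during a step are not re-evaluated until the next step.  All
randomness comes from three independent streams (lattice, behaviors, injury)
derived from the base seed, so trajectories are a pure function of
(configuration, seed).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import _kernels as K
from .behaviors import DIVISION_VOLUME, apply_growth, differentiate, maybe_divide
from .celltypes import (
    BASAL, FIRST_CELL_ID, FROZEN_MASK, MEDIUM, STEM, SUPER, TEAR, WING,
    TYPE_NAMES,
)
from .fields import step_field
from .injury import ablate, apply_chemical, destroy_membrane
from .metrics import TurnoverTracker, sample_metrics
from .tissue import build_initial_state

__all__ = ["Simulation"]

_NB_MASK = lambda t: np.uint16(1) << np.uint16(t)  # noqa: E731


def _mask_types(mask: int) -> set:
    return {t for t in range(16) if mask & (1 << t)}


class Simulation:
    """One trajectory of the virtual tissue."""

    def __init__(self, config, seed: int | None = None):
        self.config = config
        self.seed = int(config.run.seed if seed is None else seed)
        ss = np.random.SeedSequence(self.seed)
        s_potts, s_behave, s_injury = ss.spawn(3)
        self.rng_potts_state = K.seed_state(int(s_potts.generate_state(1)[0] >> 1))
        self.rng_behaviors = np.random.Generator(np.random.PCG64(s_behave))
        self.rng_injury = np.random.Generator(np.random.PCG64(s_injury))

        self.state, self.cells, self.fields = build_initial_state(config)
        self.contact = config.contact_table()
        self.chemo = config.chemotaxis_spec()
        self.links = config.links.build()
        self.potts = config.potts
        self.attempts = (config.potts.attempts_per_mcs
                         or self.state.width * self.state.height)
        self._lamv = config.potts.lamv_array()
        self._lams = config.potts.lams_array()
        self._clam1 = self.chemo.lam_array("egf")
        self._clam2 = self.chemo.lam_array("bias")
        from .celltypes import NAME_TO_TYPE
        self._type_tvol = {NAME_TO_TYPE[k]: float(v)
                           for k, v in config.target_volume_by_type.items()}

        self.metrics: list = []
        self._events: list = []
        self.turnover: TurnoverTracker | None = None
        self.chem_active = False
        self.injury_applied = False
        self.membrane_voxels_destroyed = 0
        self.accepted_last = 0
        self._sample()

    # ------------------------------------------------------------------ events
    def _log(self, event, cid, old=-1, new=-1, lifetime=-1, layers=-1):
        self._events.append((self.state.mcs, int(cid), event, int(old),
                             int(new), int(lifetime), int(layers)))

    @property
    def events(self) -> pd.DataFrame:
        return pd.DataFrame(
            self._events,
            columns=["mcs", "cell", "event", "old_type", "new_type",
                     "lifetime_mcs", "layers"],
        )

    # ------------------------------------------------------------------- loop
    def run(self, n_mcs: int):
        for _ in range(int(n_mcs)):
            self.step()
        return self

    def run_days(self, days: float):
        return self.run(round(days * self.state.mcs_per_day))

    def step(self):
        st, cells, cfg = self.state, self.cells, self.config
        pre_alive = cells.alive.copy()

        # 1. Metropolis sweep
        self.links.rebuild(cells)
        c1, c2, u1, u2 = self._chem_fields()
        self.accepted_last, _ = K.cpm_sweep(
            st.spin, st.tmap, cells.ctype, cells.alive, cells.vol, cells.tvol,
            cells.surf, cells.tsurf, cells.sumx, cells.sumy,
            self.contact.J, self._lamv, self._lams, FROZEN_MASK,
            self.potts.temperature, self.attempts,
            self.links.ptr, self.links.part, self.links.lams, self.links.l0,
            c1, self._clam1, c2, self._clam2, u1, u2, self.rng_potts_state)

        # 2. housekeeping
        for cid in np.nonzero((pre_alive == 1) & (cells.alive == 0))[0]:
            if cid >= FIRST_CELL_ID:
                self._log("crushed", cid, old=cells.ctype[cid])
        live = cells.live_ids()
        for cid in live[cells.vol[live] < cfg.fragment_cull_volume]:
            self._remove_cell(cid, MEDIUM, "culled")
        K.tear_repaint(st.spin, st.tmap, cfg.geometry.tear_thickness,
                       TEAR, TEAR, MEDIUM)

        # 3. injury trigger
        spec = cfg.injury
        if spec is not None and not self.injury_applied \
                and st.mcs >= spec.trigger_mcs:
            if spec.mode == "ablation":
                ablate(st, cells, spec)
            else:
                apply_chemical(st, self.fields, spec)
                self.chem_active = True
            self.injury_applied = True
            self._log("injury", -1)

        # 4. fields
        step_field(self.fields["egf"], st)
        if self.chem_active:
            chem = self.fields["chem"]
            step_field(chem, st)
            self.membrane_voxels_destroyed += destroy_membrane(
                st, chem, spec.membrane_threshold)
            if chem.c.max() < 1e-4:
                self.chem_active = False
        if "bias" in self.fields:
            step_field(self.fields["bias"], st)

        # 5. adjacency snapshot
        nmask, epbm, egf_sum, chem_sum = K.adjacency_pass(
            st.spin, st.tmap, cells.capacity, self.fields["egf"].c,
            self.fields["chem"].c)
        live = cells.live_ids()

        # 6a. growth
        grow = live[np.isin(cells.ctype[live], (STEM, BASAL))
                    & (cells.dying[live] == 0)]
        for cid in grow:
            apply_growth(cells, cid, egf_sum[cid] / cells.vol[cid], cfg.growth)

        # 6b. mitosis
        for cid in grow[cells.vol[grow] >= DIVISION_VOLUME]:
            new_id = maybe_divide(st, cells, cid, self.rng_behaviors)
            if new_id is not None:
                self._log("divide", new_id, old=cells.ctype[cid],
                          new=cells.ctype[cid])

        # 6c. differentiation (pre-snapshot neighborhoods; new cells wait)
        for cid in live:
            if cells.alive[cid] == 0 or cells.dying[cid]:
                continue
            nt = _mask_types(nmask[cid])
            new_type = differentiate(int(cells.ctype[cid]), nt, int(epbm[cid]))
            if new_type is not None:
                self._log("differentiate", cid, old=cells.ctype[cid],
                          new=new_type)
                cells.ctype[cid] = new_type
                st.tmap[st.spin == cid] = new_type
                cells.ntrans[cid] += 1
                tv = self._type_tvol.get(new_type)
                if tv is not None:
                    cells.tvol[cid] = tv
                    cells.tsurf[cid] = 4.0 * np.sqrt(tv)

        # 6d. sloughing
        p = cfg.slough.p_per_mcs
        supers = live[(cells.ctype[live] == SUPER) & (cells.alive[live] == 1)]
        exposed = supers[(nmask[supers] & _NB_MASK(TEAR)) != 0]
        if len(exposed):
            u = self.rng_behaviors.random(len(exposed))
            for cid in exposed[u < p]:
                self._remove_cell(cid, TEAR, "slough")

        # 6e. chemical death
        if self.chem_active:
            fresh = np.intersect1d(cells.live_ids(), live)
            means = chem_sum[fresh] / np.maximum(cells.vol[fresh], 1)
            for cid in fresh[(means > spec.cell_threshold)
                             & (cells.dying[fresh] == 0)]:
                cells.dying[cid] = 1
                self._log("dying", cid, old=cells.ctype[cid])
        dying = np.nonzero(cells.dying[: cells.next_id]
                           & cells.alive[: cells.next_id])[0]
        for cid in dying:
            cells.tvol[cid] = max(0.0, cells.tvol[cid]
                                  - (spec.death_rate if spec else 1.0))
            if cells.tvol[cid] <= 0.0:
                self._remove_cell(cid, TEAR, "chem_death")

        # 7. bookkeeping and sampling
        st.mcs += 1
        if self.turnover is not None:
            if st.mcs % st.mcs_per_day == 0:
                self.turnover.update(cells, st.mcs)
        if st.mcs % cfg.run.sample_every_mcs == 0:
            self._sample()

    # ---------------------------------------------------------------- helpers
    def _chem_fields(self):
        c1 = self.fields["egf"].c
        u1 = bool(np.any(self._clam1))
        if "bias" in self.fields:
            return c1, self.fields["bias"].c, u1, bool(np.any(self._clam2))
        return c1, np.zeros((1, 1)), u1, False

    #: one anatomical cell layer = one initial cell diameter (5 voxels, 10 μm)
    LAYER_HEIGHT_VOXELS = 5.0

    def _remove_cell(self, cid: int, fill_type: int, event: str):
        cells, st = self.cells, self.state
        sel = st.spin == cid
        st.spin[sel] = fill_type if fill_type != MEDIUM else 0
        st.tmap[sel] = fill_type
        lifetime = st.mcs - int(cells.birth_mcs[cid])
        # layers traversed: vertical climb from the birth position, in units
        # of one cell layer (floored at one layer)
        if cells.vol[cid] > 0:
            y_now = cells.sumy[cid] / cells.vol[cid]
        else:
            y_now = cells.birth_y[cid]
        layers = max(1, round((y_now - cells.birth_y[cid])
                              / self.LAYER_HEIGHT_VOXELS))
        self._log(event, cid, old=cells.ctype[cid], lifetime=lifetime,
                  layers=layers)
        cells.alive[cid] = 0
        cells.vol[cid] = 0
        cells.dying[cid] = 0

    def start_turnover_tracking(self):
        self.turnover = TurnoverTracker(self.state, self.cells)
        return self.turnover

    def _sample(self):
        self.metrics.append(sample_metrics(self.state, self.cells, self.fields))

    # ------------------------------------------------------------- dataframes
    @property
    def metrics_frame(self) -> pd.DataFrame:
        return pd.DataFrame([m.to_row() for m in self.metrics])

    def counts(self) -> dict:
        return {TYPE_NAMES[t]: len(self.cells.live_ids(types=[t]))
                for t in (STEM, BASAL, WING, SUPER)}
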