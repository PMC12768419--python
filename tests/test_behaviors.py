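"""Growth regulation, mitosis, differentiation, sloughing, injury death."""

import numpy as np
import pytest

from corneasim.behaviors import (
    GrowthParams, SloughParams, apply_growth, cell_pressure,
    density_growth_factor, differentiate, egf_growth_factor, injury_death,
    maybe_divide, maybe_slough,
)
from corneasim.celltypes import (
    BASAL, LIMB, MEMB, STEM, SUPER, TEAR, WING,
)
from corneasim.potts import CellRegistry, LatticeState

from conftest import finalize, place_cell


class TestHillFactors:
    def test_egf_midpoint(self):
        assert egf_growth_factor(3.5, 3.5) == pytest.approx(0.5)
        assert egf_growth_factor(7.0, 7.0) == pytest.approx(0.5)

    def test_egf_zero(self):
        assert egf_growth_factor(0.0, 3.5) == 0.0

    def test_egf_table_value(self):
        # km = 3.5, EGF = 7.0, n = 4: 7^4 / (3.5^4 + 7^4) = 2401/2551.0625
        assert egf_growth_factor(7.0, 3.5, 4) == pytest.approx(
            2401.0 / 2551.0625, abs=1e-9)
        assert egf_growth_factor(7.0, 3.5, 4) == pytest.approx(0.941176, abs=1e-6)

    def test_density_uncrowded(self):
        assert density_growth_factor(0.0, 125.0) == 1.0

    def test_density_midpoint(self):
        assert density_growth_factor(125.0, 125.0) == pytest.approx(0.5)

    def test_density_double_km(self):
        # P = 2 km: km^4 / (km^4 + 16 km^4) = 1/17
        assert density_growth_factor(250.0, 125.0, 4) == pytest.approx(
            1.0 / 17.0, abs=1e-12)

    def test_bounds_and_errors(self):
        rng = np.random.default_rng(0)
        for _ in range(200):
            e = egf_growth_factor(rng.uniform(0, 50), rng.uniform(0.1, 50))
            d = density_growth_factor(rng.uniform(-10, 500), 125.0)
            assert 0.0 <= e <= 1.0 and 0.0 <= d <= 1.0
        with pytest.raises(ValueError):
            egf_growth_factor(-1.0, 3.5)
        with pytest.raises(ValueError):
            egf_growth_factor(1.0, 0.0)


class TestPressure:
    def test_no_deviation(self):
        assert cell_pressure(25, 25.0, 2.0) == 0.0

    def test_overfilled_clamps(self):
        assert cell_pressure(30, 25.0, 2.0) == 0.0

    def test_linear_in_deficit(self):
        assert cell_pressure(25, 30.0, 2.0) == pytest.approx(10.0)


class TestGrowth:
    def _cell(self, ctype=BASAL, vol=25, tvol=25.0):
        cells = CellRegistry()
        cid = cells.new_cell(ctype, 0, target_volume=tvol)
        cells.vol[cid] = vol
        return cells, cid

    def test_full_stimulation_increment_is_delta(self):
        cells, cid = self._cell()
        p = GrowthParams()
        inc = apply_growth(cells, cid, egf_mean=1e6, params=p)
        assert inc == pytest.approx(p.delta["BASAL"], rel=1e-6)

    def test_zero_egf_increment_zero(self):
        cells, cid = self._cell()
        assert apply_growth(cells, cid, 0.0, GrowthParams()) == 0.0

    def test_nonproliferative_unchanged(self):
        cells, cid = self._cell(ctype=WING)
        assert apply_growth(cells, cid, 1e6, GrowthParams()) == 0.0
        assert cells.tvol[cid] == 25.0

    def test_eight_hour_doubling_calibration(self):
        """Saturating EGF, zero crowding: target volume crosses 50 voxels at
        MCS 80 +- 1 from a 25-voxel start (the 8 h optimal doubling)."""
        cells, cid = self._cell()
        p = GrowthParams()
        crossed = None
        for mcs in range(1, 200):
            cells.vol[cid] = int(round(cells.tvol[cid]))  # compliant tissue
            apply_growth(cells, cid, 1e6, p)
            if cells.tvol[cid] >= 50.0:
                crossed = mcs
                break
        assert crossed is not None and abs(crossed - 80) <= 1

    def test_zero_egf_never_grows(self):
        """With EGF clamped to zero, no proliferative target volume rises."""
        for ctype in (STEM, BASAL):
            cells, cid = self._cell(ctype=ctype)
            for _ in range(50):
                apply_growth(cells, cid, 0.0, GrowthParams())
            assert cells.tvol[cid] == 25.0


class TestDivision:
    def _rig(self, ctype, shape=(5, 10), at=(2, 2)):
        state = LatticeState.empty(20, 14)
        cells = CellRegistry()
        cid = place_cell(state, cells, ctype, at[0], at[0] + shape[0],
                         at[1], at[1] + shape[1])
        finalize(state, cells)
        return state, cells, cid

    def test_below_threshold_no_division(self):
        state, cells, cid = self._rig(BASAL, shape=(7, 7))
        assert cells.vol[cid] == 49
        rng = np.random.default_rng(0)
        assert maybe_divide(state, cells, cid, rng) is None

    def test_even_split_at_fifty(self):
        state, cells, cid = self._rig(STEM, shape=(5, 10))
        assert cells.vol[cid] == 50
        rng = np.random.default_rng(0)
        new = maybe_divide(state, cells, cid, rng)
        assert new is not None
        assert cells.vol[cid] == 25 and cells.vol[new] == 25
        assert cells.tvol[cid] == 25.0 and cells.tvol[new] == 25.0

    def test_stem_daughter_is_centripetal(self):
        """The new stem cell lies toward larger x (toward the cornea)."""
        state, cells, cid = self._rig(STEM, shape=(5, 10))
        new = maybe_divide(state, cells, cid, np.random.default_rng(0))
        assert (cells.sumx[new] / cells.vol[new]
                > cells.sumx[cid] / cells.vol[cid])

    @pytest.mark.parametrize("seed", range(6))
    def test_volume_conservation_random_shapes(self, seed):
        rng = np.random.default_rng(seed)
        state = LatticeState.empty(24, 18)
        cells = CellRegistry()
        cid = cells.new_cell(BASAL, 0)
        # random connected-ish blob of 50-60 voxels
        n = int(rng.integers(50, 61))
        y, x = 9, 12
        placed = set()
        while len(placed) < n:
            placed.add((y, x))
            y = min(16, max(1, y + int(rng.integers(-1, 2))))
            x = min(22, max(1, x + int(rng.integers(-1, 2))))
        for (yy, xx) in placed:
            state.spin[yy, xx] = cid
            state.tmap[yy, xx] = BASAL
        cells.recompute_from(state)
        parent_vol = cells.vol[cid]
        new = maybe_divide(state, cells, cid, rng)
        assert new is not None
        assert cells.vol[cid] + cells.vol[new] == parent_vol
        assert abs(cells.vol[cid] - cells.vol[new]) <= 1
        cells.check_consistency(state)


class TestDifferentiation:
    @pytest.mark.parametrize("ctype,neigh,area,expected", [
        (STEM, {BASAL, WING}, 9, BASAL),          # lost limbal contact
        (STEM, {LIMB, BASAL}, 9, None),           # anchored: stays stem
        (BASAL, {MEMB, BASAL}, 5, WING),          # at the omega boundary
        (BASAL, {MEMB, BASAL}, 6, None),          # just above it
        (BASAL, {MEMB, BASAL}, 0, WING),
        (WING, {TEAR, WING, SUPER}, 0, SUPER),    # apical, detached below
        (WING, {TEAR, BASAL}, 0, None),           # still touching basal
        (WING, {TEAR, MEMB}, 0, None),
        (WING, {TEAR, STEM}, 0, None),
        (WING, {WING, SUPER}, 0, None),           # no tear contact
        (SUPER, {TEAR}, 0, None),                 # terminal type
    ])
    def test_truth_table(self, ctype, neigh, area, expected):
        assert differentiate(ctype, neigh, area) == expected

    def test_no_dedifferentiation_possible(self):
        """No rule output ever moves backwards along the cascade."""
        order = {STEM: 0, BASAL: 1, WING: 2, SUPER: 3}
        rng = np.random.default_rng(1)
        all_types = [STEM, BASAL, WING, SUPER, TEAR, LIMB, MEMB]
        for _ in range(500):
            ct = [STEM, BASAL, WING, SUPER][int(rng.integers(4))]
            neigh = {t for t in all_types if rng.random() < 0.4}
            out = differentiate(ct, neigh, int(rng.integers(0, 12)))
            if out is not None:
                assert order[out] > order[ct]


class TestSloughing:
    def test_probability_value(self):
        assert SloughParams().p_per_mcs == pytest.approx(1.0 / 720.0)

    def test_no_tear_contact_never_sloughs(self):
        rng = np.random.default_rng(0)
        p = SloughParams()
        assert not any(maybe_slough(SUPER, {WING, SUPER}, p, rng)
                       for _ in range(5000))

    def test_only_superficial_sloughs(self):
        rng = np.random.default_rng(0)
        p = SloughParams()
        assert not any(maybe_slough(WING, {TEAR}, p, rng) for _ in range(5000))

    def test_geometric_lifetime_mean(self):
        """Always-exposed superficial cells live 720 MCS (3 days) on average,
        within 2% over 10^4 sampled lifetimes."""
        rng = np.random.default_rng(12345)
        p = SloughParams().p_per_mcs
        n = 10_000
        alive = np.arange(n)
        lifetimes = np.zeros(n, dtype=np.int64)
        t = 0
        while len(alive) and t < 40_000:
            t += 1
            u = rng.random(len(alive))
            died = u < p
            lifetimes[alive[died]] = t
            alive = alive[~died]
        lifetimes[lifetimes == 0] = t
        assert abs(lifetimes.mean() - 720.0) / 720.0 < 0.02

    def test_geometric_distribution_shape(self):
        """Binned lifetime histogram is consistent with a geometric law."""
        from scipy import stats
        rng = np.random.default_rng(7)
        p = SloughParams().p_per_mcs
        samples = rng.geometric(p, size=10_000)   # reference sampler
        # compare our hazard-simulated lifetimes against it
        sim = []
        for _ in range(2000):
            t = 0
            while True:
                t += 1
                if rng.random() < p:
                    break
            sim.append(t)
        ks = stats.ks_2samp(samples, np.array(sim))
        assert ks.pvalue > 0.01


class TestInjuryDeath:
    def test_below_threshold_lives(self):
        assert not injury_death(0.0, 1.0)

    def test_above_threshold_dies(self):
        assert injury_death(1.5, 1.0)

    def test_infinite_threshold_immortal(self):
        assert not injury_death(1e12, float("inf"))
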