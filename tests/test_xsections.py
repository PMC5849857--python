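"""Coefficient tables: interpolation, edges, branching, crossover, ranges."""
import numpy as np
import pytest

from lipdef.constants import SIGMA_THOMSON
from lipdef.materials import ELEMENTS, Material
from lipdef.xsections import (
    CrossoverNotFoundError,
    EnergyRangeError,
    KEdgeNotFoundError,
    branching,
    crossover_energy,
    csda_range,
    kedge_energy,
    klein_nishina_sigma,
    mu_en_over_rho,
    mu_over_rho,
    table_for,
)

ALL_SYMBOLS = ["H", "C", "O", "Cu", "I", "W"]


class TestTableInvariants:
    @pytest.mark.parametrize("sym", ALL_SYMBOLS)
    def test_components_bounded_by_total(self, sym):
        t = table_for(sym)
        assert np.all(t.pe >= 0)
        assert np.all(t.incoh >= 0)
        assert np.all(t.pair >= 0)
        # coherent makes up the (non-negative) remainder
        assert np.all(t.pe + t.incoh + t.pair <= t.mu_rho * (1 + 1e-9))

    @pytest.mark.parametrize("sym", ALL_SYMBOLS)
    def test_pair_zero_below_threshold(self, sym):
        t = table_for(sym)
        below = t.energies < 1.022
        assert np.all(t.pair[below] == 0)

    @pytest.mark.parametrize("sym", ALL_SYMBOLS)
    def test_absorbed_not_more_than_attenuated(self, sym):
        t = table_for(sym)
        assert np.all(t.mu_en_rho <= t.mu_rho * (1 + 1e-9))

    @pytest.mark.parametrize("sym", ALL_SYMBOLS)
    def test_grid_sorted_with_at_most_pairwise_duplicates(self, sym):
        e = table_for(sym).energies
        assert np.all(np.diff(e) >= 0)
        # no triplicated abscissae
        assert not np.any((e[:-2] == e[1:-1]) & (e[1:-1] == e[2:]))


class TestInterpolation:
    def test_reproduces_nodes_exactly_away_from_edges(self, water):
        t = table_for("O")
        e = t.energies
        # pick non-duplicated nodes
        mask = np.ones(len(e), bool)
        mask[:-1] &= e[:-1] != e[1:]
        mask[1:] &= e[1:] != e[:-1]
        ox = Material("o", 1.0, {ELEMENTS["O"]: 1.0})
        got = mu_over_rho(ox, e[mask])
        assert got == pytest.approx(t.mu_rho[mask], rel=1e-12)

    def test_between_nodes_within_bracketing_values(self):
        t = table_for("O")
        ox = Material("o", 1.0, {ELEMENTS["O"]: 1.0})
        for i in [5, 10, 20]:
            mid = np.sqrt(t.energies[i] * t.energies[i + 1])
            lo, hi = sorted([t.mu_rho[i], t.mu_rho[i + 1]])
            assert lo <= mu_over_rho(ox, mid) <= hi

    def test_range_error_outside_table(self, water):
        with pytest.raises(EnergyRangeError):
            mu_over_rho(water, 100.0)
        with pytest.raises(EnergyRangeError):
            mu_over_rho(water, 1e-5)

    def test_water_reference_values(self, water):
        # bundled-table oracle values at 1 MeV
        assert mu_over_rho(water, 1.0) == pytest.approx(0.0707, rel=0.01)
        assert mu_en_over_rho(water, 1.0) == pytest.approx(0.0309, rel=0.02)

    def test_monotone_decreasing_on_edge_free_interval(self, water):
        e = np.geomspace(0.05, 0.9, 40)
        v = mu_over_rho(water, e)
        assert np.all(np.diff(v) < 0)


class TestKEdge:
    def test_iodine_kedge_location_and_jump(self, lipiodol):
        e_k = kedge_energy(ELEMENTS["I"])
        assert e_k == pytest.approx(0.0332, abs=1e-6)
        below = mu_over_rho(lipiodol, e_k * 0.999)
        above = mu_over_rho(lipiodol, e_k * 1.001)
        assert above > 3 * below  # strong upward jump across the K edge
        # a query exactly at the edge resolves to the above-edge branch
        at = mu_over_rho(lipiodol, e_k)
        assert at > 3 * below

    @pytest.mark.parametrize("sym", ["H", "O"])
    def test_low_z_elements_have_no_edge_in_range(self, sym):
        with pytest.raises(KEdgeNotFoundError):
            kedge_energy(ELEMENTS[sym])


class TestBranching:
    def test_fractions_sum_to_one(self, water, lipiodol):
        for mat in (water, lipiodol):
            for e in (0.02, 0.1, 1.0, 8.0):
                b = branching(mat, e)
                assert b.p_pe + b.p_ce + b.p_pp == pytest.approx(1.0, abs=1e-12)

    def test_no_pair_below_threshold(self, water):
        assert branching(water, 1.0).p_pp == 0.0

    def test_water_channels_balanced_near_30_keV(self, water):
        b = branching(water, 0.03)
        assert b.p_pe == pytest.approx(b.p_ce, rel=0.35)


class TestCrossover:
    def test_water_crossover_near_30_keV(self, water):
        assert crossover_energy(water) == pytest.approx(0.03, abs=0.005)

    def test_crossover_monotone_in_iodine_fraction(self, water, lipiodol):
        iodine = Material("iodine", 4.93, {ELEMENTS["I"]: 1.0})
        e_w = crossover_energy(water)
        e_l = crossover_energy(lipiodol)
        e_i = crossover_energy(iodine)
        assert e_w < e_l < e_i

    def test_ordering_with_kedge(self, water, lipiodol):
        # water crossover < iodine K edge < Lipiodol crossover
        assert (
            crossover_energy(water)
            < kedge_energy(ELEMENTS["I"])
            < crossover_energy(lipiodol)
        )

    def test_pure_iodine_matches_element_table_boundary(self):
        # the 0.3 MeV boundary quoted for iodinated media in the element
        # compilations corresponds to elemental iodine
        iodine = Material("iodine", 4.93, {ELEMENTS["I"]: 1.0})
        assert round(crossover_energy(iodine), 1) == pytest.approx(0.3)

    def test_no_crossover_in_window_raises(self, water):
        # photoelectric dominates everywhere below 10 keV: no equality there
        with pytest.raises(CrossoverNotFoundError):
            crossover_energy(water, e_hi=0.01)


class TestCSDARange:
    def test_500_keV_in_water_is_about_2_mm(self, water):
        assert csda_range(water, 0.5) == pytest.approx(0.2, abs=0.05)

    def test_strictly_increasing_in_energy(self, water):
        e = np.geomspace(0.02, 15.0, 30)
        r = csda_range(water, e)
        assert np.all(np.diff(r) > 0)

    def test_shorter_in_lipiodol_than_water(self, water, lipiodol):
        assert csda_range(lipiodol, 0.5) < csda_range(water, 0.5)

    def test_range_error(self, water):
        with pytest.raises(EnergyRangeError):
            csda_range(water, 50.0)


class TestKleinNishina:
    def test_thomson_limit(self):
        assert klein_nishina_sigma(1e-6) == pytest.approx(SIGMA_THOMSON, rel=1e-4)

    def test_value_at_1_MeV(self):
        # closed-form evaluation
        assert klein_nishina_sigma(1.0) == pytest.approx(2.112e-25, rel=1e-3)

    def test_monotone_decreasing(self):
        e = np.geomspace(0.001, 20, 100)
        s = klein_nishina_sigma(e)
        assert np.all(np.diff(s) < 0)
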