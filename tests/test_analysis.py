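"""PDD, DEF and PEG statistics on synthetic and simulated grids."""
import numpy as np
import pytest

from lipdef.analysis import (
    DegenerateInputError,
    band_fraction,
    def_curve,
    pdd,
    peg,
)
from lipdef.beam import Spectrum
from lipdef.phantom import build_phantom
from lipdef.transport import DoseGrid, log_bin_edges


def _grid(values, with_lip=False, n_hist=1000):
    ph = build_phantom(with_lip)
    return DoseGrid(ph, np.asarray(values, dtype=float), n_hist)


def _uniform_grid(level=1.0, **kw):
    ph = build_phantom(False)
    return _grid(np.full(ph.dims, level), **kw)


class TestPDD:
    def test_uniform_grid_gives_flat_100(self):
        curve = pdd(_uniform_grid())
        assert curve.values == pytest.approx(np.full(100, 100.0))

    def test_max_is_exactly_100(self):
        ph = build_phantom(False)
        edep = np.random.default_rng(0).random(ph.dims) + 0.5
        curve = pdd(_grid(edep))
        assert curve.values.max() == 100.0

    def test_all_zero_grid_rejected(self):
        with pytest.raises(DegenerateInputError):
            pdd(_uniform_grid(0.0))


class TestDEFCurve:
    def test_identical_grids_give_zero(self):
        a, b = _uniform_grid(), _uniform_grid()
        curve = def_curve(a, b)
        assert curve.def_percent == pytest.approx(np.zeros(100), abs=1e-9)

    def test_scaled_layer_reports_percent_enhancement(self):
        base = _uniform_grid()
        ph = base.phantom
        boosted = np.full(ph.dims, 1.0)
        layer = 32  # contains depth 6.5 cm
        boosted[:, :, layer] *= 1.17
        curve = def_curve(_grid(boosted), base)
        assert curve.at_depth(6.5) == pytest.approx(17.0, abs=1e-9)
        assert curve.at_depth(2.0) == pytest.approx(0.0, abs=1e-9)

    def test_per_history_normalization(self):
        # same physical dose at different history counts
        a = _uniform_grid(2.0, n_hist=2000)
        b = _uniform_grid(1.0, n_hist=1000)
        assert def_curve(a, b).at_depth(6.5) == pytest.approx(0.0, abs=1e-9)

    def test_geometry_mismatch_rejected(self):
        from lipdef.phantom import VoxelPhantom

        ph = build_phantom(False)
        dims = (50, 50, 50)
        other = VoxelPhantom(
            ph.origin, 0.4, dims, np.zeros(dims, dtype=np.uint8), ph.materials
        )
        a = DoseGrid(ph, np.ones(ph.dims), 10)
        b = DoseGrid(other, np.ones(dims), 10)
        with pytest.raises(ValueError, match="geometry"):
            def_curve(a, b)


class TestPEG:
    def test_delta_spectrum_single_bin(self, lipiodol):
        edges = log_bin_edges()
        values = np.zeros(len(edges) - 1)
        values[40] = 123.0
        result = peg(Spectrum(edges, values), lipiodol)
        nz = np.nonzero(result.peg_total)[0]
        assert list(nz) == [40]
        assert result.peg_total[40] == pytest.approx(1.0)

    def test_rescaling_invariance(self, lipiodol):
        edges = log_bin_edges()
        rng = np.random.default_rng(3)
        values = rng.random(len(edges) - 1)
        r1 = peg(Spectrum(edges, values), lipiodol)
        r2 = peg(Spectrum(edges, values * 37.5), lipiodol)
        assert r1.peg_pe == pytest.approx(r2.peg_pe, rel=1e-12)

    def test_total_is_sum_of_channels(self, water):
        edges = log_bin_edges()
        values = np.linspace(0, 1, len(edges) - 1)
        r = peg(Spectrum(edges, values), water)
        assert r.peg_total == pytest.approx(r.peg_pe + r.peg_ce, rel=1e-12)

    @pytest.mark.parametrize("variant", ["muen", "ratio"])
    def test_compton_dominates_in_water_above_100_keV(self, water, variant):
        edges = log_bin_edges()
        values = np.ones(len(edges) - 1)
        r = peg(Spectrum(edges, values), water, variant)
        above = r.bin_centers > 0.1
        assert np.all(r.peg_ce[above] >= r.peg_pe[above])

    @pytest.mark.parametrize("variant", ["muen", "ratio"])
    def test_lipiodol_peg_exceeds_water_below_300_keV(
        self, water, lipiodol, variant
    ):
        # pre-normalization comparison on the same flat spectrum
        from lipdef.xsections import branching, mu_en_over_rho, mu_over_rho

        energies = np.geomspace(0.02, 0.29, 15)
        for e in energies:
            def raw_total(mat):
                b = branching(mat, e)
                w = mu_en_over_rho(mat, e)
                if variant == "ratio":
                    w = w / mu_over_rho(mat, e)
                return w * (b.p_pe + b.p_ce)

            assert raw_total(lipiodol) >= raw_total(water)

    def test_degenerate_spectrum_rejected(self, water):
        edges = log_bin_edges()
        with pytest.raises(DegenerateInputError):
            peg(Spectrum(edges, np.zeros(len(edges) - 1)), water)


class TestBandFraction:
    def test_full_range_is_one(self):
        s = Spectrum(np.linspace(0, 10, 11), np.arange(10, dtype=float))
        assert band_fraction(s, 0.0, 10.0) == pytest.approx(1.0)

    def test_disjoint_band_is_zero(self):
        s = Spectrum(np.linspace(0, 10, 11), np.ones(10))
        assert band_fraction(s, 15.0, 20.0) == 0.0

    def test_partial_bin_weighting(self):
        s = Spectrum(np.array([0.0, 1.0]), np.array([4.0]))
        assert band_fraction(s, 0.0, 0.25) == pytest.approx(0.25)

    def test_invalid_band_rejected(self):
        s = Spectrum(np.linspace(0, 1, 3), np.ones(2))
        with pytest.raises(ValueError):
            band_fraction(s, 0.5, 0.5)
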