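"""Transport engine verification: samplers, interactions, conservation."""
import numpy as np
import pytest
from scipy.integrate import quad

from lipdef._kernel import sample_compton_batch
from lipdef.beam import BeamSpec, PhotonState, Spectrum, generate_spectrum
from lipdef.constants import MEC2, PAIR_THRESHOLD
from lipdef.phantom import build_phantom
from lipdef.transport import (
    RunConfig,
    _iodine_k_probability,
    do_compton,
    do_pair,
    do_photoelectric,
    next_interaction,
    run_simulation,
)
from lipdef.xsections import mu_over_rho


def _kn_mean_scattered_fraction(E):
    """Independent oracle: numerical integration of the KN distribution."""
    a = E / MEC2

    def dsig(ep):
        cos_t = 1.0 + MEC2 / E - MEC2 / ep
        sin2 = 1.0 - cos_t**2
        return (ep / E) ** 2 * (ep / E + E / ep - sin2) * MEC2 / ep**2

    lo = E / (1 + 2 * a)
    num = quad(lambda ep: ep * dsig(ep), lo, E, limit=200)[0]
    den = quad(dsig, lo, E, limit=200)[0]
    return num / den / E


class TestComptonSampler:
    def test_kinematic_bounds(self):
        for e in (0.03, 0.3, 1.0, 6.0):
            ep, cos = sample_compton_batch(e, 20_000, 42)
            lo = e / (1 + 2 * e / MEC2)
            assert np.all(ep >= lo - 1e-12)
            assert np.all(ep <= e + 1e-12)
            assert np.all(np.abs(cos) <= 1.0)

    def test_mean_scattered_fraction_matches_kn_integral(self):
        n = 1_000_000
        for e in (0.1, 1.0, 6.0):
            ep, _ = sample_compton_batch(e, n, 7)
            frac = ep / e
            oracle = _kn_mean_scattered_fraction(e)
            se = frac.std() / np.sqrt(n)
            assert abs(frac.mean() - oracle) < 3 * se

    def test_thomson_limit_forward_backward_symmetry(self):
        # E -> 0: angular distribution symmetric about 90 degrees
        _, cos = sample_compton_batch(1e-4, 400_000, 11)
        fwd = (cos > 0).sum()
        bwd = (cos < 0).sum()
        assert fwd / bwd == pytest.approx(1.0, abs=0.02)


class TestSingleInteractions:
    def test_photoelectric_energy_balance(self, lipiodol, rng):
        for e in (0.02, 0.05, 0.2):
            st = PhotonState(np.zeros(3), np.array([0, 0, 1.0]), e)
            out = do_photoelectric(st, lipiodol, rng)
            fl = out["fluorescence"].energy if out["fluorescence"] else 0.0
            assert out["deposited_local"] + out["electron_energy"] + fl == pytest.approx(
                e, abs=1e-12
            )

    def test_no_k_fluorescence_below_edge(self, lipiodol, rng):
        st = PhotonState(np.zeros(3), np.array([0, 0, 1.0]), 0.020)
        for _ in range(200):
            assert do_photoelectric(st, lipiodol, rng)["fluorescence"] is None

    def test_fluorescence_fraction_matches_constants(self, lipiodol, rng):
        # oracle: omega_K x (iodine K-shell photoelectric share)
        from lipdef.constants import IODINE_OMEGA_K

        e = 0.05
        st = PhotonState(np.zeros(3), np.array([0, 0, 1.0]), e)
        n = 100_000
        hits = sum(
            1 for _ in range(n) if do_photoelectric(st, lipiodol, rng)["fluorescence"]
        )
        expected = IODINE_OMEGA_K * _iodine_k_probability(lipiodol, e)
        se = np.sqrt(expected * (1 - expected) / n)
        assert abs(hits / n - expected) < 4 * se

    def test_compton_scattered_state(self, rng):
        st = PhotonState(np.zeros(3), np.array([0, 0, 1.0]), 1.0)
        scattered, e_elec = do_compton(st, rng)
        assert scattered.energy + e_elec == pytest.approx(1.0, abs=1e-12)
        assert np.linalg.norm(scattered.direction) == pytest.approx(1.0, abs=1e-9)

    def test_pair_below_threshold_is_logic_error(self, rng):
        st = PhotonState(np.zeros(3), np.array([0, 0, 1.0]), 1.0)
        with pytest.raises(ValueError, match="threshold"):
            do_pair(st, rng)

    def test_pair_energy_balance_and_antiparallel_photons(self, rng):
        st = PhotonState(np.zeros(3), np.array([0, 0, 1.0]), 6.0)
        p1, p2, charged = do_pair(st, rng)
        assert p1.energy == p2.energy == pytest.approx(MEC2)
        assert charged == pytest.approx(6.0 - PAIR_THRESHOLD)
        assert p1.direction == pytest.approx(-p2.direction)


class TestNextInteraction:
    def test_mean_free_path_matches_majorant(self, rng):
        # free paths against the majorant are Exp(mu_maj): mean 1/mu_maj
        ph = build_phantom(False)
        majorant = 1.0
        st = PhotonState(np.array([0.0, 0.0, 0.0]), np.array([0, 0, 1.0]), 1.0)
        n = 3000
        sampled = np.array(
            [next_interaction(st, ph, majorant, rng)[0][2] for _ in range(n)]
        )
        se = sampled.std() / np.sqrt(n)
        assert abs(sampled.mean() - 1.0 / majorant) < 4 * se

    def test_majorant_equal_mu_gives_only_real_collisions(self, water, rng):
        ph = build_phantom(False)
        e = 1.0
        mu = mu_over_rho(water, e) * water.density
        st = PhotonState(np.array([0.0, 0.0, 0.0]), np.array([0, 0, 1.0]), e)
        kinds = set()
        for _ in range(300):
            pos, kind = next_interaction(st, ph, mu, rng)
            kinds.add(kind)
        assert "virtual" not in kinds
        assert "real" in kinds

    def test_escape_through_back_face(self, rng):
        ph = build_phantom(False)
        # negligible attenuation: huge sampled free path
        st = PhotonState(np.array([0.0, 0.0, 19.9]), np.array([0, 0, 1.0]), 1.0)
        seen_escape = False
        for _ in range(50):
            _, kind = next_interaction(st, ph, 0.05, rng)
            if kind == "escape":
                seen_escape = True
        assert seen_escape


def _tiny_run(with_lip=True, **kw):
    spec = BeamSpec(6, False)
    spectrum = generate_spectrum(spec)
    cfg = RunConfig(**{"n_histories": 20_000, "seed": 99, **kw})
    return run_simulation(build_phantom(with_lip), spec, spectrum, cfg)


class TestRunSimulation:
    def test_zero_history_run_is_all_zero(self):
        grid, tally = _tiny_run(n_histories=0)
        assert not np.any(grid.energy_deposited)
        assert tally.energy_emitted == 0.0

    def test_seeded_runs_bit_identical(self):
        g1, t1 = _tiny_run(n_histories=30_000, seed=5)
        g2, t2 = _tiny_run(n_histories=30_000, seed=5)
        assert np.array_equal(g1.energy_deposited, g2.energy_deposited)
        assert t1.energy_escaped == t2.energy_escaped

    def test_different_seeds_differ(self):
        g1, _ = _tiny_run(n_histories=30_000, seed=5)
        g2, _ = _tiny_run(n_histories=30_000, seed=6)
        assert not np.array_equal(g1.energy_deposited, g2.energy_deposited)

    def test_global_energy_conservation(self):
        _, tally = _tiny_run(n_histories=50_000)
        assert tally.conservation_error < 1e-6
        assert tally.energy_emitted > 0

    def test_dose_grid_finite_and_nonnegative(self):
        grid, _ = _tiny_run(n_histories=50_000)
        d = grid.dose_per_history()
        assert np.all(np.isfinite(d))
        assert np.all(d >= 0)

    def test_csda_line_mode_conserves_energy(self):
        _, tally = _tiny_run(n_histories=20_000, electron_mode="csda_line")
        assert tally.conservation_error < 1e-6

    def test_primaries_only_axial_attenuation(self, water):
        """First-collision density falls as exp(-mu z): analytic oracle."""
        e0 = 1.0
        spec = BeamSpec(6, False, field_size=0.5)
        edges = np.array([e0 - 1e-6, e0 + 1e-6])
        spectrum = Spectrum(edges, np.array([1.0]))
        ph = build_phantom(False)
        cfg = RunConfig(n_histories=400_000, seed=17, primaries_only=True)
        grid, _ = run_simulation(ph, spec, spectrum, cfg)
        prof = grid.energy_deposited.sum(axis=(0, 1))
        z = (np.arange(100) + 0.5) * 0.2
        sel = (z > 1.0) & (z < 15.0) & (prof > 200)
        slope = np.polyfit(z[sel], np.log(prof[sel]), 1)[0]
        mu = mu_over_rho(water, e0) * water.density
        assert slope == pytest.approx(-mu, rel=0.03)


def test_lipiodol_hardens_local_spectrum():
    """The Lipiodol layer shows K-fluorescence lines absent in water."""
    _, t_lip = _tiny_run(with_lip=True, n_histories=150_000)
    _, t_wat = _tiny_run(with_lip=False, n_histories=150_000)
    s_lip = t_lip.photon_spectrum
    s_wat = t_wat.photon_spectrum
    band = (s_lip.centers > 0.027) & (s_lip.centers < 0.034)
    frac_lip = s_lip.values[band].sum() / s_lip.values.sum()
    frac_wat = s_wat.values[band].sum() / s_wat.values.sum()
    assert frac_lip > 5 * frac_wat
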