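"""Analog Monte Carlo photon transport through the voxel phantom.

:func:`run_simulation` transports source photons sampled from a beam
spectrum with Woodcock delta-tracking, deposits secondary-electron energy
(kerma approximation by default), and accumulates

* a :class:`DoseGrid` of energy deposited per voxel, and
* a :class:`TallySurface` at a chosen depth: track-length photon fluence
  spectra and set-in-motion electron spectra over the Lipiodol footprint,
  with per-channel electron-generation counters.

Energy is strictly conserved: source energy = deposited + escaped, which is
checked after every run.  Sampling uses a counter-based per-history PRNG,
so results are bit-reproducible and independent of how the run is chunked;
:func:`run_paired` exploits this to produce history-correlated
with/without-Lipiodol runs for low-variance DEF estimates.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Optional

import numpy as np

from . import _kernel
from .beam import BeamSpec, PhotonState, Spectrum
from .constants import (
    IODINE_E_KALPHA,
    IODINE_E_KBETA,
    IODINE_K_EDGE,
    IODINE_K_SHARE,
    IODINE_OMEGA_K,
    IODINE_P_KALPHA,
    MEC2,
    PAIR_THRESHOLD,
)
from .materials import Material
from .phantom import OutsidePhantomError, VoxelPhantom, lipiodol_bounds, material_at
from .xsections import (
    _element_component,
    component_mu,
    csda_range,
    mu_over_rho,
)

# fine lookup grid shared by all kernel tables
_GRID_N = 4096
_GRID_EMIN = 0.01
_GRID_EMAX = 20.0

# analysis binnings: 100 log bins (resolves the K-edge region) and the
# 50-bin linear 0-20 MeV convention
N_LOG_BINS = 100
LOG_EMIN = 0.01
LOG_EMAX = 20.0
N_LIN_BINS = 50
LIN_EMAX = 20.0

TALLY_DEPTH = 6.5  # cm, centre of the Lipiodol cube
TALLY_HALF_XY = 1.5  # cm, Lipiodol footprint


@dataclass
class RunConfig:
    """Transport run parameters."""

    n_histories: int
    seed: int = 12345
    cutoff_energy: float = 0.01  # MeV, photons and electrons
    electron_mode: Literal["local", "csda_line"] = "local"
    primaries_only: bool = False
    tally_depth: float = TALLY_DEPTH

    def __post_init__(self) -> None:
        if self.n_histories < 0:
            raise ValueError("n_histories must be >= 0")
        if self.cutoff_energy < 0.001:
            raise ValueError("cutoff_energy must be >= 0.001 MeV")
        if self.electron_mode not in ("local", "csda_line"):
            raise ValueError(f"unknown electron_mode {self.electron_mode!r}")


@dataclass
class DoseGrid:
    """Per-voxel deposited energy (MeV) for a run."""

    phantom: VoxelPhantom
    energy_deposited: np.ndarray  # MeV, shape = phantom.dims
    n_histories: int

    def dose_per_history(self) -> np.ndarray:
        """Dose in MeV/g per source photon."""
        if self.n_histories == 0:
            return np.zeros_like(self.energy_deposited)
        return self.energy_deposited / self.phantom.voxel_mass_grid() / self.n_histories


@dataclass
class TallySurface:
    """Spectral tallies in the scoring layer at the tally depth."""

    depth: float
    photon_spectrum: Spectrum  # track-length fluence, log bins
    photon_spectrum_linear: Spectrum  # 50-bin 0-20 MeV convention
    electron_spectrum: Spectrum  # set-in-motion electron counts, log bins
    electron_spectrum_linear: Spectrum
    electron_counts: dict = field(default_factory=dict)
    energy_emitted: float = 0.0
    energy_deposited: float = 0.0
    energy_escaped: float = 0.0

    @property
    def conservation_error(self) -> float:
        """Relative energy-balance defect of the run."""
        if self.energy_emitted == 0:
            return 0.0
        return abs(
            self.energy_emitted - self.energy_deposited - self.energy_escaped
        ) / self.energy_emitted


def log_bin_edges() -> np.ndarray:
    return np.geomspace(LOG_EMIN, LOG_EMAX, N_LOG_BINS + 1)


def linear_bin_edges() -> np.ndarray:
    return np.linspace(0.0, LIN_EMAX, N_LIN_BINS + 1)


def _material_tables(phantom: VoxelPhantom):
    """Fine log-grid linear coefficients (1/cm) for every phantom material."""
    energies = np.geomspace(_GRID_EMIN, _GRID_EMAX, _GRID_N)
    n_mat = len(phantom.materials)
    t_tot = np.empty((n_mat, _GRID_N))
    t_pe = np.empty((n_mat, _GRID_N))
    t_inc = np.empty((n_mat, _GRID_N))
    t_pp = np.empty((n_mat, _GRID_N))
    t_iodk = np.zeros((n_mat, _GRID_N))
    t_csda = np.empty((n_mat, _GRID_N))
    for i, mat in enumerate(phantom.materials):
        rho = mat.density
        t_tot[i] = mu_over_rho(mat, energies) * rho
        t_pe[i] = component_mu(mat, energies, "pe") * rho
        t_inc[i] = component_mu(mat, energies, "incoh") * rho
        t_pp[i] = component_mu(mat, energies, "pair") * rho
        e_el = np.clip(energies, 0.01, 20.0)
        t_csda[i] = csda_range(mat, e_el)
        for el, w in mat.composition.items():
            if el.symbol == "I":
                pe_i = w * _element_component(el, energies, "pe") * rho
                with np.errstate(invalid="ignore", divide="ignore"):
                    share = np.where(t_pe[i] > 0, pe_i / t_pe[i], 0.0)
                t_iodk[i] = share * IODINE_K_SHARE
        # below the K edge there is no K-shell ionization
        t_iodk[i, energies < IODINE_K_EDGE] = 0.0
    return energies, t_tot, t_pe, t_inc, t_pp, t_iodk, t_csda


def run_simulation(
    phantom: VoxelPhantom,
    spec: BeamSpec,
    spectrum: Spectrum,
    config: RunConfig,
    chunk_size: int = 2_000_000,
    _tables=None,
    _region_box: Optional[np.ndarray] = None,
) -> tuple[DoseGrid, TallySurface]:
    """Transport ``config.n_histories`` source photons; see module docstring."""
    if _tables is None:
        _tables = _material_tables(phantom)
    energies, t_tot, t_pe, t_inc, t_pp, t_iodk, t_csda = _tables
    ln_e0 = np.log(_GRID_EMIN)
    inv_dln = (_GRID_N - 1) / (np.log(_GRID_EMAX) - np.log(_GRID_EMIN))

    ext = phantom.extent
    box = lipiodol_bounds(phantom) if _region_box is None else _region_box
    if box is None:
        box_on = 0
        box = np.array([[0.0, 0.0]] * 3)
        outside_mats = np.unique(phantom.material_map)
    else:
        box_on = 1
        mask = np.ones(phantom.dims, dtype=bool)
        o = np.asarray(phantom.origin)
        i0 = np.round((box[:, 0] - o) / phantom.voxel_size).astype(int)
        i1 = np.round((box[:, 1] - o) / phantom.voxel_size).astype(int)
        mask[i0[0]:i1[0], i0[1]:i1[1], i0[2]:i1[2]] = False
        outside_mats = np.unique(phantom.material_map[mask])
    maj_in = t_tot.max(axis=0)
    maj_out = t_tot[outside_mats].max(axis=0)

    sp_norm = spectrum.normalized("unit-sum")
    cdf = np.cumsum(sp_norm.values)
    cdf[-1] = 1.0
    bin_lo = sp_norm.bin_edges[:-1].astype(float)
    bin_hi = sp_norm.bin_edges[1:].astype(float)

    edep = np.zeros(phantom.dims)
    ph_log = np.zeros(N_LOG_BINS)
    ph_lin = np.zeros(N_LIN_BINS)
    el_log = np.zeros(N_LOG_BINS)
    el_lin = np.zeros(N_LIN_BINS)
    counters = np.zeros(3)
    accounting = np.zeros(2)

    tz0 = np.floor(config.tally_depth / phantom.voxel_size) * phantom.voxel_size
    tz1 = tz0 + phantom.voxel_size

    remaining = config.n_histories
    history_offset = 0
    while remaining > 0:
        n = min(chunk_size, remaining)
        _kernel.run_chunk(
            n,
            config.seed,
            history_offset,
            cdf,
            bin_lo,
            bin_hi,
            spec.field_size / 2.0,
            spec.ssd,
            phantom.material_map,
            ext[0, 0],
            ext[1, 0],
            ext[2, 0],
            phantom.voxel_size,
            box_on,
            box[0, 0],
            box[0, 1],
            box[1, 0],
            box[1, 1],
            box[2, 0],
            box[2, 1],
            ln_e0,
            inv_dln,
            t_tot,
            t_pe,
            t_inc,
            t_pp,
            t_iodk,
            maj_out,
            maj_in,
            t_csda,
            config.cutoff_energy,
            IODINE_K_EDGE,
            IODINE_OMEGA_K,
            IODINE_P_KALPHA,
            IODINE_E_KALPHA,
            IODINE_E_KBETA,
            0 if config.electron_mode == "local" else 1,
            1 if config.primaries_only else 0,
            -TALLY_HALF_XY,
            TALLY_HALF_XY,
            -TALLY_HALF_XY,
            TALLY_HALF_XY,
            tz0,
            tz1,
            np.log(LOG_EMIN),
            N_LOG_BINS / (np.log(LOG_EMAX) - np.log(LOG_EMIN)),
            N_LOG_BINS,
            LIN_EMAX,
            N_LIN_BINS,
            edep,
            ph_log,
            ph_lin,
            el_log,
            el_lin,
            counters,
            accounting,
        )
        remaining -= n
        history_offset += n

    grid = DoseGrid(phantom, edep, config.n_histories)
    tally = TallySurface(
        depth=config.tally_depth,
        photon_spectrum=Spectrum(log_bin_edges(), ph_log, "photon"),
        photon_spectrum_linear=Spectrum(linear_bin_edges(), ph_lin, "photon"),
        electron_spectrum=Spectrum(log_bin_edges(), el_log, "electron"),
        electron_spectrum_linear=Spectrum(linear_bin_edges(), el_lin, "electron"),
        electron_counts={
            "photoelectric": float(counters[0]),
            "compton": float(counters[1]),
            "pair": float(counters[2]),
        },
        energy_emitted=float(accounting[0]),
        energy_deposited=float(edep.sum()),
        energy_escaped=float(accounting[1]),
    )
    if tally.conservation_error > 1e-6:
        raise RuntimeError(
            f"energy conservation violated: defect {tally.conservation_error:.2e}"
        )
    return grid, tally


def run_paired(
    spec: BeamSpec,
    spectrum: Spectrum,
    config: RunConfig,
    chunk_size: int = 2_000_000,
):
    """Correlated with/without-Lipiodol runs for dose-enhancement ratios.

    Both runs share the same seed, coefficient tables and delta-tracking
    majorant regions (the Lipiodol bounding box is kept as a majorant
    region even in the all-water run), so the random-number streams of a
    history are identical until its path first differs inside the Lipiodol
    region.  Common-mode statistical noise then cancels in the DEF ratio.

    Returns ``(grid_with, tally_with, grid_without, tally_without)``.
    """
    from .phantom import build_phantom

    ph_with = build_phantom(True)
    ph_without = build_phantom(False)
    tables = _material_tables(ph_with)
    box = lipiodol_bounds(ph_with)
    g_w, t_w = run_simulation(
        ph_with, spec, spectrum, config, chunk_size, _tables=tables
    )
    g_o, t_o = run_simulation(
        ph_without, spec, spectrum, config, chunk_size,
        _tables=tables, _region_box=box,
    )
    return g_w, t_w, g_o, t_o


# --------------------------------------------------------------------------
# Single-interaction operations (Python mirrors of the kernel physics, used
# for unit-level verification and interactive work)
# --------------------------------------------------------------------------


def next_interaction(
    state: PhotonState,
    phantom: VoxelPhantom,
    majorant: float,
    rng: np.random.Generator,
):
    """Delta-tracking step: sample a tentative collision against a majorant.

    Returns ``(position, kind)`` with kind one of ``"real"``, ``"virtual"``
    or ``"escape"``.  The majorant must bound the local attenuation
    coefficient for every material in the phantom at the photon energy.
    """
    if majorant <= 0:
        raise ValueError("majorant must be positive")
    s = rng.exponential(1.0 / majorant)
    pos = state.position + s * state.direction
    try:
        mat = material_at(phantom, pos)
    except OutsidePhantomError:
        return pos, "escape"
    mu = mu_over_rho(mat, state.energy) * mat.density
    if mu > majorant * (1 + 1e-9):
        raise ValueError("majorant smaller than local attenuation coefficient")
    kind = "real" if rng.random() < mu / majorant else "virtual"
    return pos, kind


def _iodine_k_probability(material: Material, E: float) -> float:
    pe_tot = component_mu(material, E, "pe")
    if pe_tot <= 0 or E < IODINE_K_EDGE:
        return 0.0
    for el, w in material.composition.items():
        if el.symbol == "I":
            pe_i = w * _element_component(el, E, "pe")
            return pe_i / pe_tot * IODINE_K_SHARE
    return 0.0


def do_photoelectric(
    state: PhotonState, material: Material, rng: np.random.Generator
) -> dict:
    """Photoelectric absorption with iodine K-fluorescence emission.

    Returns a dict with the locally deposited energy, the photoelectron
    energy and an optional fluorescence :class:`PhotonState`; the three
    always sum to the photon energy exactly.
    """
    E = state.energy
    electron_energy = E
    local = 0.0
    fluorescence: Optional[PhotonState] = None
    if rng.random() < _iodine_k_probability(material, E):
        electron_energy = E - IODINE_K_EDGE
        fl_e = 0.0
        if rng.random() < IODINE_OMEGA_K:
            fl_e = (
                IODINE_E_KALPHA
                if rng.random() < IODINE_P_KALPHA
                else IODINE_E_KBETA
            )
            cost = 2 * rng.random() - 1
            phi = 2 * np.pi * rng.random()
            sint = np.sqrt(1 - cost**2)
            fluorescence = PhotonState(
                state.position.copy(),
                np.array([sint * np.cos(phi), sint * np.sin(phi), cost]),
                fl_e,
            )
        local = IODINE_K_EDGE - fl_e
    return {
        "deposited_local": local,
        "electron_energy": electron_energy,
        "fluorescence": fluorescence,
    }


def _kahn_compton(E: float, rng: np.random.Generator) -> tuple[float, float]:
    a = E / MEC2
    while True:
        r1, r2, r3 = rng.random(3)
        if r1 <= (1 + 2 * a) / (9 + 2 * a):
            x = 1 + 2 * a * r2
            if r3 <= 4 * (1 / x - 1 / x**2):
                break
        else:
            x = (1 + 2 * a) / (1 + 2 * a * r2)
            c = 1 - (x - 1) / a
            if r3 <= 0.5 * (c * c + 1 / x):
                break
    return E / x, float(np.clip(1 - (x - 1) / a, -1, 1))


def do_compton(
    state: PhotonState, rng: np.random.Generator
) -> tuple[PhotonState, float]:
    """Klein-Nishina Compton scatter: returns scattered photon and electron energy."""
    Ep, cost = _kahn_compton(state.energy, rng)
    phi = 2 * np.pi * rng.random()
    ux, uy, uz = state.direction
    nd = _kernel._rotate(ux, uy, uz, cost, phi)
    scattered = PhotonState(state.position.copy(), np.array(nd), Ep)
    return scattered, state.energy - Ep


def do_pair(
    state: PhotonState, rng: np.random.Generator
) -> tuple[PhotonState, PhotonState, float]:
    """Pair production: charged-pair energy plus two annihilation photons."""
    if state.energy <= PAIR_THRESHOLD:
        raise ValueError(
            f"pair production below threshold: E={state.energy} MeV"
        )
    cost = 2 * rng.random() - 1
    phi = 2 * np.pi * rng.random()
    sint = np.sqrt(1 - cost**2)
    d = np.array([sint * np.cos(phi), sint * np.sin(phi), cost])
    p1 = PhotonState(state.position.copy(), d, MEC2)
    p2 = PhotonState(state.position.copy(), -d, MEC2)
    return p1, p2, state.energy - PAIR_THRESHOLD
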