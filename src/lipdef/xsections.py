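"""Photon interaction-coefficient and electron-range data layer.

Per-element tables of mass attenuation (``mu_rho``), mass energy-absorption
(``mu_en_rho``) and per-interaction components (photoelectric, incoherent,
pair) are bundled as CSV package data on an energy grid with duplicated
abscissae at absorption edges.  Interpolation is log-log linear; a query
exactly at an edge resolves to the above-edge value.

Coherent (Rayleigh) scattering is retained inside ``mu_rho`` for attenuation
but excluded from the interaction branching, which considers only the
photoelectric effect, Compton scattering and pair production.
"""
from __future__ import annotations

import functools
from dataclasses import dataclass
from importlib import resources
from typing import Iterable

import numpy as np
from scipy.optimize import bisect

from .constants import MEC2, R_E, SIGMA_THOMSON
from .materials import Element, Material, mixture_value

_TINY = 1e-300


class EnergyRangeError(ValueError):
    """Requested energy lies outside the tabulated range."""


class KEdgeNotFoundError(LookupError):
    """The element has no tabulated absorption edge in range."""


class CrossoverNotFoundError(ValueError):
    """No photoelectric/Compton equality found in the search window."""


@dataclass(frozen=True)
class CoefficientTable:
    """Energy-gridded mass interaction coefficients for one element."""

    element_symbol: str
    energies: np.ndarray  # MeV, ascending, duplicated at edges
    mu_rho: np.ndarray  # cm^2/g
    mu_en_rho: np.ndarray
    pe: np.ndarray
    incoh: np.ndarray
    pair: np.ndarray

    @property
    def e_min(self) -> float:
        return float(self.energies[0])

    @property
    def e_max(self) -> float:
        return float(self.energies[-1])

    def edge_energies(self) -> np.ndarray:
        """Energies that appear twice in the grid (absorption edges)."""
        e = self.energies
        return np.unique(e[:-1][e[:-1] == e[1:]])


@dataclass(frozen=True)
class BranchingFractions:
    """Channel probabilities given that an interaction occurred."""

    p_pe: float
    p_ce: float
    p_pp: float


def _interp_loglog(E, xs: np.ndarray, ys: np.ndarray):
    """Log-log interpolation honouring duplicated edge abscissae.

    For a query exactly at a duplicated energy, ``searchsorted(side='right')``
    brackets the interval that starts at the above-edge node, so edges resolve
    upward.
    """
    e = np.asarray(E, dtype=float)
    if np.any(e < xs[0]) or np.any(e > xs[-1]):
        raise EnergyRangeError(
            f"energy outside table range [{xs[0]:g}, {xs[-1]:g}] MeV"
        )
    idx = np.clip(np.searchsorted(xs, e, side="right"), 1, len(xs) - 1)
    x0, x1 = xs[idx - 1], xs[idx]
    y0 = np.maximum(ys[idx - 1], _TINY)
    y1 = np.maximum(ys[idx], _TINY)
    with np.errstate(divide="ignore"):
        t = np.where(x1 > x0, np.log(e / x0) / np.log(x1 / x0), 0.0)
    out = np.exp((1.0 - t) * np.log(y0) + t * np.log(y1))
    out = np.where(out < 1e-250, 0.0, out)
    return float(out) if np.isscalar(E) else out


@functools.lru_cache(maxsize=None)
def table_for(symbol: str) -> CoefficientTable:
    """Load (and cache) the bundled coefficient table for an element."""
    ref = resources.files("lipdef").joinpath("data", f"{symbol.lower()}.csv")
    if not ref.is_file():
        raise KeyError(symbol)
    rows = []
    for line in ref.read_text().splitlines():
        if not line or line.startswith("#") or line.startswith("energy"):
            continue
        rows.append([float(v) for v in line.split(",")])
    arr = np.asarray(rows)
    return CoefficientTable(symbol, *(np.ascontiguousarray(arr[:, j]) for j in range(6)))


def _element_component(el: Element, E, column: str):
    return _interp_loglog(E, table_for(el.symbol).energies, getattr(table_for(el.symbol), column))


def mu_over_rho(material: Material, E) -> float:
    """Mass attenuation coefficient of the mixture, cm^2/g."""
    return mixture_value(material, lambda el: _element_component(el, E, "mu_rho"))


def mu_en_over_rho(material: Material, E) -> float:
    """Mass energy-absorption coefficient of the mixture, cm^2/g."""
    return mixture_value(material, lambda el: _element_component(el, E, "mu_en_rho"))


def component_mu(material: Material, E, component: str):
    """Per-interaction mass coefficient (``pe``, ``incoh`` or ``pair``)."""
    if component not in ("pe", "incoh", "pair"):
        raise ValueError(f"unknown component {component!r}")
    return mixture_value(material, lambda el: _element_component(el, E, component))


def branching(material: Material, E) -> BranchingFractions:
    """Photoelectric / Compton / pair probabilities given an interaction.

    Coherent scattering is excluded; the three fractions sum to one.
    """
    pe = component_mu(material, E, "pe")
    ce = component_mu(material, E, "incoh")
    pp = component_mu(material, E, "pair")
    tot = pe + ce + pp
    if tot <= 0:
        raise ValueError(f"no interaction components at E={E} MeV")
    return BranchingFractions(pe / tot, ce / tot, pp / tot)


def kedge_energy(element: Element) -> float:
    """K-edge energy (highest duplicated grid energy) of an element, MeV."""
    edges = table_for(element.symbol).edge_energies()
    if edges.size == 0:
        raise KEdgeNotFoundError(
            f"{element.symbol} has no absorption edge in the tabulated range"
        )
    return float(edges[-1])


def _highest_edge(material: Material) -> float:
    best = 0.0
    for el in material.composition:
        edges = table_for(el.symbol).edge_energies()
        if edges.size:
            best = max(best, float(edges[-1]))
    return best


def crossover_energy(material: Material, e_hi: float = 2.0) -> float:
    """Energy where the photoelectric and incoherent components are equal.

    Searches above the highest absorption edge of the mixture by scanning a
    log grid for a sign change of ``log(pe/incoh)`` and refining the root by
    bisection.
    """
    e_lo = max(1.0002 * _highest_edge(material), 0.002)

    def f(E: float) -> float:
        pe = component_mu(material, E, "pe")
        ce = component_mu(material, E, "incoh")
        if pe <= 0:
            return -50.0
        return float(np.log(pe / ce))

    grid = np.geomspace(e_lo, e_hi, 240)
    vals = np.array([f(e) for e in grid])
    sign_change = np.nonzero(np.sign(vals[:-1]) * np.sign(vals[1:]) < 0)[0]
    if sign_change.size == 0:
        raise CrossoverNotFoundError(
            f"no photoelectric/Compton crossover for {material.name} "
            f"in [{e_lo:g}, {e_hi:g}] MeV"
        )
    i = int(sign_change[0])
    return float(bisect(f, grid[i], grid[i + 1], xtol=1e-7))


@functools.lru_cache(maxsize=1)
def _csda_table() -> tuple[np.ndarray, np.ndarray]:
    ref = resources.files("lipdef").joinpath("data", "electron_csda.csv")
    rows = [
        [float(v) for v in line.split(",")]
        for line in ref.read_text().splitlines()
        if line and not line.startswith(("#", "energy"))
    ]
    arr = np.asarray(rows)
    return np.ascontiguousarray(arr[:, 0]), np.ascontiguousarray(arr[:, 1])


#: Z/A of water, reference for the CSDA mass-scaling rule
_WATER_Z_OVER_A = (2 * 1.008 / 18.015) * 1.0 / 1.008 + (15.999 / 18.015) * 8 / 15.999


def csda_range(material: Material, E) -> float:
    """CSDA range of an electron in the material, cm.

    The bundled water range (g/cm^2) is scaled by the Z/A ratio of the
    mixture relative to water (collision stopping power is proportional to
    the electron density per unit mass to first order) and divided by the
    mass density.
    """
    es, rs = _csda_table()
    e = np.asarray(E, dtype=float)
    if np.any(e < es[0]) or np.any(e > es[-1]):
        raise EnergyRangeError(
            f"electron energy outside table range [{es[0]:g}, {es[-1]:g}] MeV"
        )
    r_water = _interp_loglog(E, es, rs)
    return r_water * (_WATER_Z_OVER_A / material.z_over_a) / material.density


def klein_nishina_sigma(E) -> float:
    """Total Klein-Nishina cross section per electron, cm^2."""
    a = np.asarray(E, dtype=float) / MEC2
    a = np.where(a < 1e-9, 1e-9, a)
    small = a < 1e-4
    # Thomson expansion for small alpha avoids cancellation
    series = SIGMA_THOMSON * (1.0 - 2.0 * a + 5.2 * a**2)
    t1 = (1.0 + a) / a**2 * (2.0 * (1.0 + a) / (1.0 + 2.0 * a) - np.log1p(2.0 * a) / a)
    t2 = np.log1p(2.0 * a) / (2.0 * a)
    t3 = (1.0 + 3.0 * a) / (1.0 + 2.0 * a) ** 2
    full = 2.0 * np.pi * R_E**2 * (t1 + t2 - t3)
    out = np.where(small, series, full)
    return float(out) if np.isscalar(E) else out


def available_elements() -> Iterable[str]:
    """Symbols of the elements with bundled coefficient tables."""
    return sorted(
        p.name[:-4].upper() if len(p.name) == 5 else p.name[:-4].capitalize()
        for p in (resources.files("lipdef") / "data").iterdir()
        if p.name.endswith(".csv") and p.name != "electron_csda.csv"
    )
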