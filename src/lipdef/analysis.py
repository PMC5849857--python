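"""Derived dosimetric statistics: PDD, depth-resolved DEF and PEG scores.

* **PDD** -- central-axis percentage depth dose, normalized to 100 % at its
  maximum.
* **DEF** -- percent dose enhancement ``100 * (D_with/D_without - 1)`` per
  depth layer, with doses averaged over the Lipiodol footprint (the central
  15 x 15 voxel columns).
* **PEG** -- probability of electron generation: the spectral score that
  decomposes the electron-production propensity of a photon spectrum into
  photoelectric and Compton channels.  Per bin ``i`` with centre ``E_i`` and
  relative photon abundance ``n_i`` (unit-sum),

      PEG_PE,i = n_i * (mu_en/rho)(E_i) * p_pe(E_i)
      PEG_CE,i = n_i * (mu_en/rho)(E_i) * p_ce(E_i)
      PEG_Total,i = PEG_PE,i + PEG_CE,i

  and the three curves are jointly normalized so the maximum of the total
  is one.  A second variant replaces ``mu_en/rho`` by the dimensionless
  ratio ``mu_en/mu``; both orderings of the qualitative conclusions agree,
  and the variant is selectable.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np

from .beam import Spectrum
from .materials import Material
from .transport import DoseGrid, TALLY_HALF_XY
from .phantom import axis_voxel_xy
from .xsections import branching, mu_en_over_rho, mu_over_rho


class DegenerateInputError(ValueError):
    """The input carries no usable signal (e.g. an all-zero grid)."""


@dataclass
class PDDCurve:
    depths: np.ndarray  # cm, voxel-layer centres on the beam axis
    values: np.ndarray  # percent of maximum; max is exactly 100


@dataclass
class DEFCurve:
    depths: np.ndarray  # cm
    def_percent: np.ndarray  # percent enhancement (NaN where undefined)

    def at_depth(self, depth: float) -> float:
        """DEF of the layer whose half-open interval contains ``depth``."""
        dz = self.depths[1] - self.depths[0]
        i = int(np.floor((depth - (self.depths[0] - dz / 2)) / dz))
        if not 0 <= i < len(self.depths):
            raise ValueError(f"depth {depth} outside the curve")
        return float(self.def_percent[i])


@dataclass
class PEGResult:
    bin_centers: np.ndarray  # MeV
    peg_pe: np.ndarray
    peg_ce: np.ndarray
    peg_total: np.ndarray
    variant: str = "muen"

    @property
    def argmax_pe_energy(self) -> float:
        """Bin-centre energy of the photoelectric PEG maximum."""
        return float(self.bin_centers[int(np.argmax(self.peg_pe))])


def pdd(grid: DoseGrid) -> PDDCurve:
    """Central-axis depth dose (3x3 voxel column average), max -> 100 %."""
    ph = grid.phantom
    ix, iy = axis_voxel_xy(ph)
    dose = grid.dose_per_history()
    col = dose[ix - 1 : ix + 2, iy - 1 : iy + 2, :].mean(axis=(0, 1))
    if not np.any(col > 0):
        raise DegenerateInputError("axial dose is identically zero")
    depths = (np.arange(ph.dims[2]) + 0.5) * ph.voxel_size + ph.origin[2]
    return PDDCurve(depths, 100.0 * col / col.max())


def _footprint_mean(grid: DoseGrid) -> np.ndarray:
    """Layer-wise dose averaged over the central Lipiodol footprint."""
    ph = grid.phantom
    half = int(round(TALLY_HALF_XY / ph.voxel_size))
    ix, iy = axis_voxel_xy(ph)
    dose = grid.dose_per_history()
    return dose[ix - half : ix + half + 1, iy - half : iy + half + 1, :].mean(
        axis=(0, 1)
    )


def def_curve(grid_with: DoseGrid, grid_without: DoseGrid) -> DEFCurve:
    """Percent dose enhancement vs depth over the Lipiodol footprint."""
    if grid_with.phantom.dims != grid_without.phantom.dims:
        raise ValueError("dose grids have mismatched geometry")
    d_with = _footprint_mean(grid_with)
    d_without = _footprint_mean(grid_without)
    ph = grid_with.phantom
    depths = (np.arange(ph.dims[2]) + 0.5) * ph.voxel_size + ph.origin[2]
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(d_without > 0, d_with / d_without, np.nan)
    return DEFCurve(depths, 100.0 * (ratio - 1.0))


def peg(
    spectrum: Spectrum,
    material: Material,
    variant: Literal["muen", "ratio"] = "muen",
) -> PEGResult:
    """PEG spectral scores for a photon spectrum in a material."""
    if spectrum.values.sum() <= 0:
        raise DegenerateInputError("empty or all-zero spectrum")
    n = spectrum.values / spectrum.values.sum()
    centers = spectrum.centers
    ok = (n > 0) & (centers > 0)
    peg_pe = np.zeros_like(n)
    peg_ce = np.zeros_like(n)
    e_ok = np.clip(centers[ok], 0.001, 20.0)
    mu_en = mu_en_over_rho(material, e_ok)
    if variant == "ratio":
        weight = mu_en / mu_over_rho(material, e_ok)
    elif variant == "muen":
        weight = mu_en
    else:
        raise ValueError(f"unknown PEG variant {variant!r}")
    p_pe = np.array([branching(material, e).p_pe for e in e_ok])
    p_ce = np.array([branching(material, e).p_ce for e in e_ok])
    peg_pe[ok] = n[ok] * weight * p_pe
    peg_ce[ok] = n[ok] * weight * p_ce
    total = peg_pe + peg_ce
    scale = total.max()
    if scale <= 0:
        raise DegenerateInputError("PEG is identically zero")
    return PEGResult(centers, peg_pe / scale, peg_ce / scale, total / scale, variant)


def band_fraction(spectrum: Spectrum, lo: float, hi: float) -> float:
    """Fraction of total spectrum weight in the energy band ``[lo, hi)``.

    Bins partially covered by the band contribute proportionally to the
    covered width.
    """
    if lo >= hi:
        raise ValueError("band_fraction requires lo < hi")
    total = spectrum.values.sum()
    if total <= 0:
        raise DegenerateInputError("empty spectrum")
    e0, e1 = spectrum.bin_edges[:-1], spectrum.bin_edges[1:]
    overlap = np.clip(np.minimum(e1, hi) - np.maximum(e0, lo), 0.0, None)
    frac = overlap / (e1 - e0)
    return float((spectrum.values * frac).sum() / total)
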