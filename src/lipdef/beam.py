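"""Surrogate linac beam model: FF and FFF photon spectra and source sampling.

Vendor phase-space files for the TrueBeam head are proprietary, so the beam
is modelled parametrically: a Schiff-like thin-target bremsstrahlung shape
``n(E) ~ (E_max/E - 1)`` hardened by 2 mm of tungsten-equivalent inherent
filtration.  The flattened (FF) variant is additionally attenuated by a
copper-equivalent flattening filter (2.0 cm for 6 MV, 1.5 cm for 10 MV)
using the bundled attenuation tables; the unflattened (FFF) variant omits
it.  This reproduces the features that matter for the analysis: the FFF
spectrum is softer, with a surplus of photons below ~1.5 MeV, and 10 MV is
harder than 6 MV.

The source is an ideal point source; the field is defined at the phantom
surface (SSD plane) and photons are aimed at points drawn uniformly over
the field square, giving a divergent beam.  All outputs are per source
photon; no monitor-unit calibration is attempted.
"""
from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Literal

import numpy as np

from .constants import DENSITY_CU, DENSITY_W
from .materials import ELEMENTS
from .xsections import _element_component

#: copper-equivalent flattening-filter thickness (cm) per nominal MV
FLATTENING_FILTER_CM = {6: 2.0, 10: 1.5}
#: tungsten-equivalent inherent filtration (cm)
INHERENT_FILTRATION_CM = 0.2


@dataclass(frozen=True)
class BeamSpec:
    """Nominal accelerating potential, filtration flag and field geometry."""

    nominal_mv: int
    filtered: bool  # True = FF, False = FFF
    field_size: float = 5.0  # cm, side length at the surface
    ssd: float = 90.0  # cm

    def __post_init__(self) -> None:
        if self.nominal_mv not in (6, 10):
            raise ValueError(f"nominal_mv must be 6 or 10, got {self.nominal_mv}")
        if self.field_size <= 0 or self.ssd <= 0:
            raise ValueError("field_size and ssd must be positive")

    @property
    def label(self) -> str:
        return f"{self.nominal_mv}MV-{'FF' if self.filtered else 'FFF'}"


@dataclass
class Spectrum:
    """A binned photon or electron spectrum."""

    bin_edges: np.ndarray  # MeV, ascending, len = n_bins + 1
    values: np.ndarray  # counts or normalized fluence, >= 0
    kind: Literal["photon", "electron"] = "photon"
    normalization: Literal["none", "unit-sum", "max-one"] = "none"

    def __post_init__(self) -> None:
        self.bin_edges = np.asarray(self.bin_edges, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if len(self.values) != len(self.bin_edges) - 1:
            raise ValueError("values must have one entry per bin")
        if np.any(np.diff(self.bin_edges) <= 0):
            raise ValueError("bin edges must be strictly ascending")
        if np.any(self.values < 0):
            raise ValueError("spectrum values must be non-negative")

    @property
    def centers(self) -> np.ndarray:
        """Bin centers: geometric mean where both edges are positive."""
        lo, hi = self.bin_edges[:-1], self.bin_edges[1:]
        return np.where(lo > 0, np.sqrt(lo * hi), 0.5 * (lo + hi))

    def normalized(self, how: Literal["unit-sum", "max-one"]) -> "Spectrum":
        total = self.values.sum() if how == "unit-sum" else self.values.max()
        if total <= 0:
            raise ValueError("cannot normalize an all-zero spectrum")
        return Spectrum(self.bin_edges.copy(), self.values / total, self.kind, how)

    def mean_energy(self) -> float:
        w = self.values.sum()
        if w <= 0:
            raise ValueError("empty spectrum has no mean energy")
        return float((self.centers * self.values).sum() / w)

    def to_csv(self, path: str | Path) -> None:
        """Two-column CSV: bin upper edge (MeV), value."""
        with open(path, "w") as fh:
            fh.write(f"# {self.kind} spectrum, normalization={self.normalization}\n")
            fh.write(f"# first bin lower edge: {self.bin_edges[0]:.8g} MeV\n")
            fh.write("bin_upper_MeV,value\n")
            for hi, v in zip(self.bin_edges[1:], self.values):
                fh.write(f"{hi:.8g},{v:.8g}\n")

    @classmethod
    def from_csv(cls, path: str | Path, kind: str = "photon") -> "Spectrum":
        lower = 0.0
        uppers, values = [], []
        for line in Path(path).read_text().splitlines():
            if line.startswith("# first bin lower edge:"):
                lower = float(line.split(":")[1].split()[0])
            if not line or line.startswith(("#", "bin_upper")):
                continue
            a, b = line.split(",")
            uppers.append(float(a))
            values.append(float(b))
        edges = np.concatenate([[lower], uppers])
        return cls(edges, np.asarray(values), kind=kind)


@dataclass
class PhotonState:
    """A photon in flight: position (cm), unit direction, energy (MeV)."""

    position: np.ndarray
    direction: np.ndarray
    energy: float
    weight: float = 1.0

    def __post_init__(self) -> None:
        self.position = np.asarray(self.position, dtype=float)
        self.direction = np.asarray(self.direction, dtype=float)
        norm = float(np.linalg.norm(self.direction))
        if abs(norm - 1.0) > 1e-9:
            raise ValueError(f"direction must be a unit vector, |d|={norm}")
        if self.energy <= 0 or self.weight <= 0:
            raise ValueError("energy and weight must be positive")


def generate_spectrum(spec: BeamSpec, n_bins: int = 150) -> Spectrum:
    """Surrogate bremsstrahlung spectrum for the beam, unit-sum normalized."""
    e_max = float(spec.nominal_mv)
    edges = np.linspace(0.05, e_max, n_bins + 1)
    e = 0.5 * (edges[:-1] + edges[1:])
    shape = e_max / e - 1.0

    w_tab = lambda E: _element_component(ELEMENTS["W"], E, "mu_rho")
    trans = np.exp(-w_tab(e) * DENSITY_W * INHERENT_FILTRATION_CM)
    if spec.filtered:
        cu_tab = lambda E: _element_component(ELEMENTS["Cu"], E, "mu_rho")
        t_cu = FLATTENING_FILTER_CM[spec.nominal_mv]
        trans = trans * np.exp(-cu_tab(e) * DENSITY_CU * t_cu)
    values = shape * trans
    return Spectrum(edges, values / values.sum(), "photon", "unit-sum")


def _cdf(spectrum: Spectrum) -> np.ndarray:
    w = spectrum.values / spectrum.values.sum()
    return np.cumsum(w)


def sample_primaries(
    spec: BeamSpec, spectrum: Spectrum, n: int, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized source sampling: positions, directions, energies.

    Photons start at the point source ``(0, 0, -ssd)`` (the phantom surface
    is z = 0, depth increases with z) and are aimed at points uniform over
    the field square on the surface plane; energies are drawn from the
    spectrum with uniform sampling within the chosen bin.
    """
    cdf = _cdf(spectrum)
    j = np.searchsorted(cdf, rng.random(n), side="right")
    lo = spectrum.bin_edges[j]
    hi = spectrum.bin_edges[j + 1]
    energies = lo + rng.random(n) * (hi - lo)

    half = spec.field_size / 2.0
    tx = rng.uniform(-half, half, n)
    ty = rng.uniform(-half, half, n)
    d = np.stack([tx, ty, np.full(n, spec.ssd)], axis=1)
    d /= np.linalg.norm(d, axis=1, keepdims=True)
    pos = np.zeros((n, 3))
    pos[:, 2] = -spec.ssd
    return pos, d, energies


def sample_primary(
    spec: BeamSpec, spectrum: Spectrum, rng: np.random.Generator
) -> PhotonState:
    """Draw a single source photon (see :func:`sample_primaries`)."""
    pos, d, e = sample_primaries(spec, spectrum, 1, rng)
    return PhotonState(pos[0], d[0], float(e[0]))
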