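"""Material definitions: elemental compositions, densities, mixture rule.

The two materials of interest are water (the phantom medium) and Lipiodol,
an ethiodized poppyseed-oil contrast agent carrying 480 mg of iodine per
millilitre at a bulk density of 1.28 g/cm^3, i.e. an iodine mass fraction of
0.480/1.28 = 0.375.  The non-iodine remainder is modelled as ethyl linoleate
(C20H36O2), the dominant fatty-acid ethyl ester of poppyseed oil; photon
coefficients of low-Z organics are insensitive to the exact ester at these
energies.

All coefficient lookups for compounds go through :func:`mixture_value`,
the mass-fraction-weighted additivity rule.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Dict

from .constants import ATOMIC_MASS, ATOMIC_NUMBER, DENSITY_LIPIODOL, DENSITY_WATER


class MissingElementDataError(KeyError):
    """A coefficient lookup was requested for an element without data."""


@dataclass(frozen=True)
class Element:
    """A chemical element: symbol, atomic number Z and atomic mass A (g/mol)."""

    symbol: str
    Z: int
    A: float

    def __post_init__(self) -> None:
        if self.Z < 1:
            raise ValueError(f"Z must be >= 1, got {self.Z}")
        if self.A <= 0:
            raise ValueError(f"A must be > 0, got {self.A}")


#: registry of the elements bundled with the package
ELEMENTS: Dict[str, Element] = {
    sym: Element(sym, ATOMIC_NUMBER[sym], ATOMIC_MASS[sym]) for sym in ATOMIC_MASS
}

H, C, O, I = ELEMENTS["H"], ELEMENTS["C"], ELEMENTS["O"], ELEMENTS["I"]


@dataclass(frozen=True)
class Material:
    """A mixture defined by mass density and element mass fractions."""

    name: str
    density: float  # g/cm^3
    composition: Dict[Element, float] = field(hash=False)

    def __post_init__(self) -> None:
        if self.density <= 0:
            raise ValueError(f"density must be > 0, got {self.density}")
        total = 0.0
        for el, w in self.composition.items():
            if not 0.0 <= w <= 1.0:
                raise ValueError(f"mass fraction of {el.symbol} out of [0,1]: {w}")
            total += w
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"mass fractions must sum to 1, got {total!r}")

    @property
    def z_over_a(self) -> float:
        """Mean Z/A of the mixture (electrons per atomic mass unit)."""
        return sum(w * el.Z / el.A for el, w in self.composition.items())


def make_water() -> Material:
    """Liquid water at 1.0 g/cm^3 with mass fractions from atomic masses."""
    m_h2o = 2 * H.A + O.A
    return Material(
        "water", DENSITY_WATER, {H: 2 * H.A / m_h2o, O: O.A / m_h2o}
    )


def make_lipiodol() -> Material:
    """Lipiodol: 0.480 g iodine per 1.28 g, remainder ethyl linoleate."""
    w_i = 0.480 / 1.28
    # C20H36O2 stoichiometric mass split of the organic remainder
    m_c, m_h, m_o = 20 * C.A, 36 * H.A, 2 * O.A
    m_ester = m_c + m_h + m_o
    rest = 1.0 - w_i
    return Material(
        "lipiodol",
        DENSITY_LIPIODOL,
        {
            I: w_i,
            C: rest * m_c / m_ester,
            H: rest * m_h / m_ester,
            O: rest * m_o / m_ester,
        },
    )


def mixture_value(material: Material, per_element_fn: Callable[[Element], float]) -> float:
    """Mass-fraction-weighted sum of a per-element coefficient.

    Raises :class:`MissingElementDataError` if ``per_element_fn`` fails for a
    constituent.
    """
    total = 0.0
    for el, w in material.composition.items():
        try:
            total += w * per_element_fn(el)
        except (KeyError, FileNotFoundError) as exc:
            raise MissingElementDataError(
                f"no coefficient data for element {el.symbol}"
            ) from exc
    return total


def save_material(material: Material, path: str | Path) -> None:
    """Write a material to a plain-text composition file."""
    lines = [f"name {material.name}", f"density {material.density!r}"]
    for el, w in sorted(material.composition.items(), key=lambda kv: kv[0].Z):
        lines.append(f"{el.symbol} {w!r}")
    Path(path).write_text("\n".join(lines) + "\n")


def load_material(path: str | Path) -> Material:
    """Read a material from the plain-text composition format."""
    name, density = None, None
    comp: Dict[Element, float] = {}
    for raw in Path(path).read_text().splitlines():
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        key, value = line.split(None, 1)
        if key == "name":
            name = value.strip()
        elif key == "density":
            density = float(value)
        else:
            if key not in ELEMENTS:
                raise MissingElementDataError(f"unknown element symbol {key!r}")
            comp[ELEMENTS[key]] = float(value)
    if name is None or density is None:
        raise ValueError(f"material file {path} lacks a name or density line")
    return Material(name, density, comp)
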