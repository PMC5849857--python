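"""Voxelized virtual inhomogeneity phantom.

A 20x20x20 cm^3 water cube with 0.2 cm isotropic voxels (100^3), optionally
containing a 3x3x3 cm^3 Lipiodol cube whose proximal face is at 5.0 cm depth,
centred on the beam axis.  Depth z increases along the beam axis from the
irradiated surface at z = 0; the lateral origin is chosen so that the beam
axis passes through the centre of a voxel column and the Lipiodol faces lie
exactly on voxel boundaries.  Voxel intervals are half-open ``[low, high)``.
"""
from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import List, Tuple

import numpy as np

from .materials import Material, make_lipiodol, make_water

VOXEL_SIZE = 0.2  # cm
PHANTOM_SIDE = 20.0  # cm
LIPIODOL_SIDE = 3.0  # cm
LIPIODOL_DEPTH = 5.0  # cm, proximal face
N_VOX = int(round(PHANTOM_SIDE / VOXEL_SIZE))


class OutsidePhantomError(ValueError):
    """A position lies outside the phantom; the photon escapes the geometry."""


@dataclass
class VoxelPhantom:
    """Voxel grid with a per-voxel material index."""

    origin: Tuple[float, float, float]  # corner of voxel (0,0,0), cm
    voxel_size: float
    dims: Tuple[int, int, int]
    material_map: np.ndarray  # uint8 [nx, ny, nz]
    materials: List[Material]

    def __post_init__(self) -> None:
        if any(d <= 0 for d in self.dims):
            raise ValueError("dims must be positive")
        if self.material_map.shape != self.dims:
            raise ValueError("material_map shape must equal dims")
        if self.material_map.max(initial=0) >= len(self.materials):
            raise ValueError("material index out of range")

    @property
    def extent(self) -> np.ndarray:
        """(3, 2) array of low/high coordinates per axis."""
        o = np.asarray(self.origin)
        hi = o + np.asarray(self.dims) * self.voxel_size
        return np.stack([o, hi], axis=1)

    def voxel_index(self, position) -> Tuple[int, int, int]:
        """Indices of the enclosing voxel, half-open convention."""
        p = np.asarray(position, dtype=float)
        rel = (p - np.asarray(self.origin)) / self.voxel_size
        idx = np.floor(rel).astype(int)
        if np.any(idx < 0) or np.any(idx >= np.asarray(self.dims)):
            raise OutsidePhantomError(f"position {tuple(p)} outside phantom")
        return int(idx[0]), int(idx[1]), int(idx[2])

    def voxel_volume(self) -> float:
        return self.voxel_size**3

    def mass(self) -> float:
        """Total phantom mass, g."""
        dens = np.array([m.density for m in self.materials])
        return float(dens[self.material_map].sum() * self.voxel_volume())

    def voxel_mass_grid(self) -> np.ndarray:
        dens = np.array([m.density for m in self.materials])
        return dens[self.material_map] * self.voxel_volume()


def axis_voxel_xy(phantom: VoxelPhantom) -> Tuple[int, int]:
    """Lateral indices of the voxel column containing the beam axis."""
    ox, oy, _ = phantom.origin
    return (
        int(np.floor(-ox / phantom.voxel_size)),
        int(np.floor(-oy / phantom.voxel_size)),
    )


def build_phantom(with_lipiodol: bool) -> VoxelPhantom:
    """The standard virtual phantom, with or without the Lipiodol cube."""
    water = make_water()
    materials = [water]
    # lateral origin offset by half a voxel so the axis is a voxel centre
    # and +-1.5 cm are voxel boundaries
    origin = (-PHANTOM_SIDE / 2 - VOXEL_SIZE / 2, -PHANTOM_SIDE / 2 - VOXEL_SIZE / 2, 0.0)
    mat_map = np.zeros((N_VOX, N_VOX, N_VOX), dtype=np.uint8)
    if with_lipiodol:
        materials.append(make_lipiodol())
        half = LIPIODOL_SIDE / 2
        ix0 = int(round((-half - origin[0]) / VOXEL_SIZE))
        ix1 = int(round((half - origin[0]) / VOXEL_SIZE))
        iz0 = int(round(LIPIODOL_DEPTH / VOXEL_SIZE))
        iz1 = int(round((LIPIODOL_DEPTH + LIPIODOL_SIDE) / VOXEL_SIZE))
        mat_map[ix0:ix1, ix0:ix1, iz0:iz1] = 1
    return VoxelPhantom(origin, VOXEL_SIZE, (N_VOX, N_VOX, N_VOX), mat_map, materials)


def lipiodol_bounds(phantom: VoxelPhantom) -> np.ndarray | None:
    """Axis-aligned bounding box of the Lipiodol region, or None."""
    if len(phantom.materials) < 2:
        return None
    idx = np.argwhere(phantom.material_map > 0)
    if idx.size == 0:
        return None
    o = np.asarray(phantom.origin)
    lo = o + idx.min(axis=0) * phantom.voxel_size
    hi = o + (idx.max(axis=0) + 1) * phantom.voxel_size
    return np.stack([lo, hi], axis=1)


def material_at(phantom: VoxelPhantom, position) -> Material:
    """Material of the voxel enclosing ``position`` (raises outside)."""
    i, j, k = phantom.voxel_index(position)
    return phantom.materials[phantom.material_map[i, j, k]]


def save_phantom(phantom: VoxelPhantom, path: str | Path) -> None:
    """Dump as a JSON header line followed by one row of indices per line."""
    header = {
        "origin": list(phantom.origin),
        "voxel_size": phantom.voxel_size,
        "dims": list(phantom.dims),
        "materials": [
            {
                "name": m.name,
                "density": m.density,
                "composition": {el.symbol: w for el, w in m.composition.items()},
            }
            for m in phantom.materials
        ],
    }
    with open(path, "w") as fh:
        fh.write(json.dumps(header) + "\n")
        flat = phantom.material_map.reshape(phantom.dims[0], -1)
        for row in flat:
            fh.write("".join(map(str, row)) + "\n")


def load_phantom(path: str | Path) -> VoxelPhantom:
    from .materials import ELEMENTS

    with open(path) as fh:
        header = json.loads(fh.readline())
        dims = tuple(header["dims"])
        rows = [np.frombuffer(line.strip().encode(), dtype=np.uint8) - ord("0")
                for line in fh]
    mat_map = np.vstack(rows).reshape(dims).astype(np.uint8)
    materials = [
        Material(
            m["name"],
            m["density"],
            {ELEMENTS[s]: w for s, w in m["composition"].items()},
        )
        for m in header["materials"]
    ]
    return VoxelPhantom(
        tuple(header["origin"]), header["voxel_size"], dims, mat_map, materials
    )
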