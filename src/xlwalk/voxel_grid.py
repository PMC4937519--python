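"""Voxelization of the solvent-excluded volume and lysine accessibility.

The structure is placed on a cubic grid (default 1 Å voxels) padded by at
least 4 voxels on every face.  A sphere of radius vdw(element) + 0.7 Å
(half a water molecule), rounded to the nearest voxel size, is expanded
around every atom except the lysine and N-terminal side chains; voxels
inside any sphere are marked occupied (value 1) and no surface path may
cross them.  A lysine (or chain N-terminus) is solvent accessible if a
similar probe sphere centred on its Nζ (Cα for N-termini, or as a fallback
when the side chain is missing) contains at least one zero-valued voxel;
those zero voxels seed the later surface path search.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np

from .structures_io import (
    DEFAULT_VDW,
    LYSINE_SIDE_CHAIN_ATOMS,
    ResidueKey,
    StructureModel,
    default_probe_increment,
)

__all__ = ["Grid", "ResidueAccess", "AccessibilityMap", "build_grid",
           "find_accessible_residues", "round_to_voxel"]


def round_to_voxel(radius: float, voxel_size: float) -> float:
    """Round a radius to the nearest multiple of the voxel size, ties upward.

    Rounding (rather than truncating) avoids marking borderline-exposed
    residues as buried through discretization blur.
    """
    return voxel_size * np.floor(radius / voxel_size + 0.5)


@dataclass
class Grid:
    """Voxelized occupancy volume: 1 = inside the expanded protein, 0 = solvent."""

    origin: np.ndarray           # Å, position of voxel (0,0,0) centre
    voxel_size: float            # Å
    occupancy: np.ndarray        # bool, shape (nx, ny, nz)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.occupancy.shape

    def voxel_index(self, position: np.ndarray) -> tuple[int, int, int]:
        """Nearest voxel to a Cartesian position; ties toward the lower index."""
        frac = (np.asarray(position, dtype=float) - self.origin) / self.voxel_size
        idx = np.ceil(frac - 0.5).astype(int)
        return tuple(int(i) for i in idx)

    def voxel_center(self, index) -> np.ndarray:
        return self.origin + np.asarray(index, dtype=float) * self.voxel_size

    def in_bounds(self, index) -> bool:
        return all(0 <= i < s for i, s in zip(index, self.shape))


@lru_cache(maxsize=64)
def _sphere_offsets(radius_voxels: int, strict: bool = False) -> np.ndarray:
    """Integer offsets of voxels whose centre lies within radius_voxels.

    The occupancy expansion uses the open ball (``strict``): voxels exactly at
    the rounded radius stay solvent.  The accessibility probe uses the closed
    ball.  The asymmetry keeps the probe sphere from being sealed by its own
    centre atom's excluded volume when the probe and occupancy radii round to
    the same voxel count (the Cα-fallback case).
    """
    r = radius_voxels
    axis = np.arange(-r, r + 1)
    dx, dy, dz = np.meshgrid(axis, axis, axis, indexing="ij")
    d2 = dx * dx + dy * dy + dz * dz
    inside = d2 < r * r if strict else d2 <= r * r
    return np.stack([dx[inside], dy[inside], dz[inside]], axis=1)


def _excluded_from_expansion(structure: StructureModel) -> set[int]:
    """Serials of atoms left out of the occupancy expansion: lysine side-chain
    atoms (CB..NZ) and all side-chain atoms of each chain's N-terminal
    residue, so the crosslinker's own attachment point cannot self-block."""
    excluded: set[int] = set()
    n_termini = {structure.n_terminus(c) for c in structure.chains}
    for atom in structure.atoms:
        key = (atom.chain, atom.residue_number)
        if atom.residue_name == "LYS" and atom.name in LYSINE_SIDE_CHAIN_ATOMS:
            excluded.add(atom.serial)
        elif key in n_termini and atom.name not in ("N", "CA", "C", "O", "OXT"):
            excluded.add(atom.serial)
    return excluded


def build_grid(structure: StructureModel, voxel_size: float = 1.0,
               vdw: dict[str, float] | None = None,
               probe_increment: float | None = None) -> Grid:
    """Voxelize a structure's solvent-excluded volume.

    Every voxel within ``round_to_voxel(vdw(element) + probe_increment)`` of a
    non-excluded atom's grid point is marked occupied.  Grid bounds are the
    atom bounding box plus padding of at least 4 voxels per face (more when a
    rounded sphere radius would otherwise clip the boundary).
    """
    if len(structure) == 0:
        raise ValueError("cannot build a grid from an empty structure")
    if voxel_size <= 0:
        raise ValueError("voxel_size must be positive")
    vdw = DEFAULT_VDW if vdw is None else vdw
    if probe_increment is None:
        probe_increment = default_probe_increment()

    coords = structure.coords()
    excluded = _excluded_from_expansion(structure)
    radii_vox = {}
    for atom in structure.atoms:
        if atom.serial in excluded:
            continue
        r = vdw.get(atom.element, vdw.get("C", 1.7)) + probe_increment
        radii_vox[atom.serial] = int(round_to_voxel(r, voxel_size) / voxel_size)

    max_r = max(radii_vox.values(), default=0)
    pad = max(4, max_r + 1)
    lo = coords.min(axis=0)
    hi = coords.max(axis=0)
    origin = lo - pad * voxel_size
    shape = np.ceil((hi - origin) / voxel_size).astype(int) + pad + 1
    occupancy = np.zeros(tuple(shape), dtype=bool)

    grid = Grid(origin=origin, voxel_size=voxel_size, occupancy=occupancy)
    nx, ny, nz = grid.shape
    for atom in structure.atoms:
        rv = radii_vox.get(atom.serial)
        if rv is None:
            continue
        centre = np.array(grid.voxel_index(atom.position))
        pts = centre + _sphere_offsets(rv, strict=True)
        ok = np.all((pts >= 0) & (pts < [nx, ny, nz]), axis=1)
        pts = pts[ok]
        occupancy[pts[:, 0], pts[:, 1], pts[:, 2]] = True
    return grid


@dataclass
class ResidueAccess:
    """Accessibility verdict for one lysine / N-terminal residue."""

    residue: ResidueKey
    accessible: bool
    start_voxels: list[tuple[int, int, int]] = field(default_factory=list)
    ca_position: np.ndarray | None = None
    probe_atom: str = "NZ"          # atom the probe sphere was centred on
    evaluable: bool = True


class AccessibilityMap(dict):
    """Mapping residue key → :class:`ResidueAccess` for all crosslink targets."""

    def accessible_residues(self) -> list[ResidueKey]:
        return sorted(k for k, v in self.items() if v.accessible)


def find_accessible_residues(grid: Grid, structure: StructureModel,
                             vdw: dict[str, float] | None = None,
                             probe_increment: float | None = None
                             ) -> AccessibilityMap:
    """Determine solvent accessibility of every lysine and chain N-terminus.

    The probe sphere has radius ``round_to_voxel(vdw(N) + probe_increment)``
    and is centred on the lysine Nζ (falling back to Cα when the side chain
    is missing) or on the Cα for N-terminal residues.  Zero-valued voxels
    inside the sphere are recorded as path start voxels; a residue with no
    such voxel is non-accessible.  Residues lacking both Nζ and Cα are
    reported unevaluable (and not accessible).
    """
    vdw = DEFAULT_VDW if vdw is None else vdw
    if probe_increment is None:
        probe_increment = default_probe_increment()
    r_vox = int(round_to_voxel(vdw.get("N", 1.55) + probe_increment,
                               grid.voxel_size) / grid.voxel_size)
    offsets = _sphere_offsets(r_vox)
    nx, ny, nz = grid.shape
    n_termini = {structure.n_terminus(c) for c in structure.chains}

    amap = AccessibilityMap()
    for key in structure.crosslink_targets():
        ca = structure.ca(key)
        if key in n_termini and structure.residue_name(key) != "LYS":
            centre_pos, probe_atom = ca, "CA"
        else:
            nzp = structure.nz(key)
            if nzp is not None:
                centre_pos, probe_atom = nzp, "NZ"
            else:
                centre_pos, probe_atom = ca, "CA"
        if centre_pos is None or ca is None:
            amap[key] = ResidueAccess(key, accessible=False, ca_position=ca,
                                      probe_atom=probe_atom, evaluable=False)
            continue
        centre = np.array(grid.voxel_index(centre_pos))
        pts = centre + offsets
        ok = np.all((pts >= 0) & (pts < [nx, ny, nz]), axis=1)
        pts = pts[ok]
        free = ~grid.occupancy[pts[:, 0], pts[:, 1], pts[:, 2]]
        starts = [tuple(int(c) for c in p) for p in pts[free]]
        amap[key] = ResidueAccess(key, accessible=bool(starts),
                                  start_voxels=starts, ca_position=ca,
                                  probe_atom=probe_atom)
    return amap
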