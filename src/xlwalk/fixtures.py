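"""Synthetic structures with known geometry, and an independent path oracle.

Everything here is generated programmatically so the full pipeline — grid
building, accessibility, surface path search, scoring and evaluation — can be
exercised without downloading real structures.  Residues are minimal
lysine-like constructions (backbone plus an extended CB–CG–CD–CE–NZ side
chain) rather than stereochemically exact amino acids; wall obstacles are
carbon lattices with 2 Å spacing so their occupancy is contiguous at 1 Å
voxels, and buried cases enclose the lysine Nζ in a dense carbon shell.

The shortest-path oracle (:func:`grid_oracle`, :func:`sasd_oracle`) runs
networkx Dijkstra over the same 26-neighbour metric and is implemented
independently of the production search so the two can cross-validate.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from .structures_io import Atom, ResidueKey, StructureModel
from .voxel_grid import AccessibilityMap, Grid

__all__ = ["FixtureSpec", "Fixture", "make_fixture", "lysine_residue",
           "alanine_residue", "grid_oracle", "sasd_oracle",
           "random_occupancy_grid"]

FIXTURE_KINDS = ("free_pair", "wall", "buried", "helix", "perturbed_ensemble")


@dataclass
class FixtureSpec:
    kind: str
    separation: float = 10.0        # Å between the two lysine Cα (pair kinds)
    wall_halfwidth: float = 12.0    # Å half-extent of the wall slab
    shell_radius: float = 1.8       # Å radius of the burying carbon shell
    n_residues: int = 10            # helix length
    n_models: int = 50              # ensemble size
    max_sigma: float = 15.0         # Å largest per-residue perturbation
    side_chains: bool = True        # False → Cα-only lysines (fallback probe)
    seed: int = 0

    def __post_init__(self):
        if self.kind not in FIXTURE_KINDS:
            raise ValueError(f"unknown fixture kind {self.kind!r}; "
                             f"choose from {FIXTURE_KINDS}")
        for name in ("separation", "wall_halfwidth", "shell_radius",
                     "max_sigma"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")


@dataclass
class Fixture:
    structure: StructureModel
    truth: dict
    models: list[StructureModel] = field(default_factory=list)


_SIDE_CHAIN = ("CB", "CG", "CD", "CE", "NZ")


def lysine_residue(chain: str, resnum: int, ca: np.ndarray,
                   direction: np.ndarray = (0.0, 0.0, 1.0),
                   serial_start: int = 1, side_chain: bool = True,
                   backbone: bool = True) -> list[Atom]:
    """A minimal lysine: backbone N/CA/C/O plus an extended side chain whose
    Nζ sits 5.5 Å from the Cα along ``direction``."""
    ca = np.asarray(ca, dtype=float)
    d = np.asarray(direction, dtype=float)
    d = d / np.linalg.norm(d)
    # a perpendicular for placing N/C either side of CA
    perp = np.array([1.0, 0.0, 0.0]) if abs(d[0]) < 0.9 else np.array([0.0, 1.0, 0.0])
    perp = perp - d * (perp @ d)
    perp /= np.linalg.norm(perp)
    atoms = []
    serial = serial_start

    def add(name, element, pos):
        nonlocal serial
        atoms.append(Atom(serial, name, element, chain, resnum, "LYS",
                          np.asarray(pos, dtype=float)))
        serial += 1

    if backbone:
        add("N", "N", ca + 1.46 * perp)
        add("CA", "C", ca)
        add("C", "C", ca - 1.52 * perp)
        add("O", "O", ca - 1.52 * perp - 1.23 * d)
    else:
        add("CA", "C", ca)
    if side_chain:
        for i, name in enumerate(_SIDE_CHAIN, start=1):
            element = "N" if name == "NZ" else "C"
            add(name, element, ca + (5.5 * i / len(_SIDE_CHAIN)) * d)
    return atoms


def alanine_residue(chain: str, resnum: int, ca: np.ndarray,
                    direction: np.ndarray = (0.0, 0.0, 1.0),
                    serial_start: int = 1) -> list[Atom]:
    ca = np.asarray(ca, dtype=float)
    d = np.asarray(direction, dtype=float)
    d = d / np.linalg.norm(d)
    perp = np.array([1.0, 0.0, 0.0]) if abs(d[0]) < 0.9 else np.array([0.0, 1.0, 0.0])
    perp = perp - d * (perp @ d)
    perp /= np.linalg.norm(perp)
    names = [("N", "N", ca + 1.46 * perp), ("CA", "C", ca),
             ("C", "C", ca - 1.52 * perp),
             ("O", "O", ca - 1.52 * perp - 1.23 * d), ("CB", "C", ca + 1.53 * d)]
    return [Atom(serial_start + i, n, e, chain, resnum, "ALA", p)
            for i, (n, e, p) in enumerate(names)]


def _carbon(serial: int, chain: str, resnum: int, pos) -> Atom:
    return Atom(serial, "C", "C", chain, resnum, "OBS",
                np.asarray(pos, dtype=float))


def _fibonacci_sphere(n: int) -> np.ndarray:
    i = np.arange(n)
    phi = np.pi * (3.0 - np.sqrt(5.0))
    y = 1.0 - 2.0 * (i + 0.5) / n
    r = np.sqrt(1.0 - y * y)
    return np.stack([r * np.cos(phi * i), y, r * np.sin(phi * i)], axis=1)


def make_fixture(spec: FixtureSpec) -> Fixture:
    """Generate a synthetic structure plus its ground-truth annotation.

    Ground truth is stated by construction (exact Euclidean separations,
    detour bounds, the identity of the buried residue, per-model perturbation
    magnitudes) so tests can verify it by independent computation.
    """
    if spec.kind == "free_pair":
        return _free_pair(spec)
    if spec.kind == "wall":
        return _wall(spec)
    if spec.kind == "buried":
        return _buried(spec)
    if spec.kind == "helix":
        return _helix(spec)
    if spec.kind == "perturbed_ensemble":
        return _perturbed_ensemble(spec)
    raise ValueError(spec.kind)


def _free_pair(spec: FixtureSpec) -> Fixture:
    sep = spec.separation
    atoms = lysine_residue("A", 1, (0.0, 0.0, 0.0), (0, 0, 1), 1,
                           side_chain=spec.side_chains,
                           backbone=spec.side_chains)
    atoms += lysine_residue("A", 2, (sep, 0.0, 0.0), (0, 0, 1),
                            len(atoms) + 1, side_chain=spec.side_chains,
                            backbone=spec.side_chains)
    truth = {"euclidean": sep,
             "pair": ((("A", 1)), ("A", 2))}
    return Fixture(StructureModel(atoms), truth)


def _wall(spec: FixtureSpec) -> Fixture:
    """Two Cα-only lysines separated by a planar carbon slab.

    The slab sits halfway between them, spans ``±wall_halfwidth`` in y and z
    except for being open beyond +y (the detour side), forcing any surface
    path to go around; the detour is at least twice the perpendicular
    distance from the straight line to the wall edge.
    """
    sep, w = spec.separation, spec.wall_halfwidth
    atoms = lysine_residue("A", 1, (0.0, 0.0, 0.0), (0, 0, 1), 1,
                           side_chain=False, backbone=False)
    atoms += lysine_residue("A", 2, (sep, 0.0, 0.0), (0, 0, 1),
                            len(atoms) + 1, side_chain=False, backbone=False)
    serial = len(atoms) + 1
    resnum = 100
    x0 = sep / 2.0
    ys = np.arange(-w, w + 1e-9, 2.0)
    zs = np.arange(-w, w + 1e-9, 2.0)
    # obstacles share chain A (high residue numbers) so they add no
    # N-terminal crosslink target of their own
    for y in ys:
        for z in zs:
            atoms.append(_carbon(serial, "A", resnum, (x0, y, z)))
            serial += 1
            resnum += 1
    # straight line blocked; path must clear the +y edge of the slab
    detour_lb = 2.0 * np.hypot(sep / 2.0, w) - sep
    truth = {"euclidean": sep, "detour_lower_bound_excess": detour_lb,
             "pair": (("A", 1), ("A", 2))}
    return Fixture(StructureModel(atoms), truth)


def _buried(spec: FixtureSpec) -> Fixture:
    """One lysine whose Nζ is enclosed by a dense carbon shell, plus a free
    partner lysine; the shell radius is small enough that every voxel of the
    Nζ probe sphere lies inside some shell atom's excluded volume."""
    atoms = lysine_residue("A", 1, (0.0, 0.0, 0.0), (0, 0, 1), 1)
    nz = np.array([0.0, 0.0, 5.5])
    serial = len(atoms) + 1
    shell = _fibonacci_sphere(80) * spec.shell_radius + nz
    resnum = 100
    for pos in shell:
        atoms.append(_carbon(serial, "A", resnum, pos))
        serial += 1
        resnum += 1
    atoms += lysine_residue("A", 2, (spec.separation + 8.0, 0.0, 0.0),
                            (0, 0, 1), serial)
    truth = {"buried_residue": ("A", 1), "accessible_residue": ("A", 2)}
    return Fixture(StructureModel(atoms), truth)


def _helix(spec: FixtureSpec) -> Fixture:
    """Ideal-ish alpha helix of alanines (2.3 Å radius, 1.5 Å rise, 100°)."""
    atoms = []
    for i in range(spec.n_residues):
        angle = np.deg2rad(100.0 * i)
        ca = np.array([2.3 * np.cos(angle), 2.3 * np.sin(angle), 1.5 * i])
        out = np.array([np.cos(angle), np.sin(angle), 0.0])
        atoms += alanine_residue("A", i + 1, ca, out, len(atoms) + 1)
    return Fixture(StructureModel(atoms), {"n_residues": spec.n_residues})


def _base_assembly(seed: int) -> StructureModel:
    """Compact reference 'protein': eight lysines on a 12 Å cube with an
    alanine core providing body that can bury side chains when perturbed."""
    rng = np.random.default_rng(seed)
    atoms = []
    corners = [np.array([x, y, z]) for x in (0.0, 12.0) for y in (0.0, 12.0)
               for z in (0.0, 12.0)]
    for i, corner in enumerate(corners, start=1):
        outward = corner - np.array([6.0, 6.0, 6.0])
        atoms += lysine_residue("A", i, corner, outward, len(atoms) + 1)
    # filler body near the centre
    for j in range(12):
        pos = np.array([6.0, 6.0, 6.0]) + rng.normal(0, 2.5, 3)
        atoms += alanine_residue("A", 20 + j, pos, (0, 0, 1), len(atoms) + 1)
    return StructureModel(atoms)


def _perturbed_ensemble(spec: FixtureSpec) -> Fixture:
    """Ensemble of models derived from the base assembly by displacing each
    residue rigidly with seeded Gaussian noise of increasing magnitude; the
    per-model sigma serves as a model-quality proxy."""
    rng = np.random.default_rng(spec.seed)
    base = _base_assembly(spec.seed)
    sigmas = np.linspace(0.0, spec.max_sigma, spec.n_models)
    models = []
    for sigma in sigmas:
        shifts: dict[ResidueKey, np.ndarray] = {}
        atoms = []
        for atom in base.atoms:
            key = (atom.chain, atom.residue_number)
            if key not in shifts:
                shifts[key] = rng.normal(0.0, sigma, 3) if sigma > 0 else np.zeros(3)
            atoms.append(Atom(atom.serial, atom.name, atom.element, atom.chain,
                              atom.residue_number, atom.residue_name,
                              atom.position + shifts[key]))
        models.append(StructureModel(atoms))
    truth = {"sigmas": sigmas.tolist()}
    return Fixture(base, truth, models=models)


# ---------------------------------------------------------------------------
# Independent shortest-path oracle (networkx Dijkstra)

_NEIGHBOURS_26 = [(i, j, k)
                  for i in (-1, 0, 1) for j in (-1, 0, 1) for k in (-1, 0, 1)
                  if (i, j, k) != (0, 0, 0)]
_NEIGHBOURS_6 = [(1, 0, 0), (-1, 0, 0), (0, 1, 0), (0, -1, 0),
                 (0, 0, 1), (0, 0, -1)]


def _oracle_graph(grid: Grid, connectivity: int = 26) -> nx.Graph:
    nbrs = _NEIGHBOURS_26 if connectivity == 26 else _NEIGHBOURS_6
    graph = nx.Graph()
    free = ~grid.occupancy
    nx_, ny_, nz_ = grid.shape
    for idx in zip(*np.nonzero(free)):
        graph.add_node(idx)
    for idx in list(graph.nodes):
        x, y, z = idx
        for di, dj, dk in nbrs:
            nb = (x + di, y + dj, z + dk)
            if (0 <= nb[0] < nx_ and 0 <= nb[1] < ny_ and 0 <= nb[2] < nz_
                    and free[nb]):
                graph.add_edge(idx, nb, weight=float(
                    np.sqrt(di * di + dj * dj + dk * dk)) * grid.voxel_size)
    return graph


def grid_oracle(grid: Grid, source: tuple[int, int, int],
                targets: list[tuple[int, int, int]],
                connectivity: int = 26) -> dict[tuple[int, int, int], float]:
    """Exact shortest-path lengths from a free source voxel to target voxels.

    Reference Dijkstra (networkx) over the same neighbour metric as the
    production search; unreachable targets map to infinity.  Intended for
    small grids (≲ 64³).
    """
    if grid.occupancy[source]:
        raise ValueError(f"source voxel {source} is occupied")
    graph = _oracle_graph(grid, connectivity)
    lengths = nx.single_source_dijkstra_path_length(graph, source,
                                                    weight="weight")
    return {t: lengths.get(t, float("inf")) for t in targets}


def sasd_oracle(grid: Grid, access: AccessibilityMap, pair,
                connectivity: int = 26) -> float:
    """Independent SASD for one residue pair: networkx Dijkstra with virtual
    endpoint nodes carrying the Cα–surface-voxel Euclidean connections."""
    a, b = pair
    graph = _oracle_graph(grid, connectivity)
    for label, res in (("SRC", a), ("DST", b)):
        acc = access[res]
        if not acc.accessible:
            return float("inf")
        graph.add_node(label)
        for voxel in acc.start_voxels:
            centre = grid.voxel_center(voxel)
            graph.add_edge(label, voxel,
                           weight=float(np.linalg.norm(centre - acc.ca_position)))
    try:
        return float(nx.dijkstra_path_length(graph, "SRC", "DST",
                                             weight="weight"))
    except nx.NetworkXNoPath:
        return float("inf")


def random_occupancy_grid(shape=(20, 20, 20), fill: float = 0.3,
                          voxel_size: float = 1.0, seed: int = 0) -> Grid:
    """Random occupancy volume for randomized search cross-checks."""
    rng = np.random.default_rng(seed)
    occ = rng.random(shape) < fill
    return Grid(origin=np.zeros(3), voxel_size=voxel_size, occupancy=occ)
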