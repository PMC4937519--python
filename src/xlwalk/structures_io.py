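"""Structure and crosslink I/O.

Reads PDB-format structures (via gemmi), validates crosslink tables against a
structure using the curation rules applied to literature crosslink databases
(remove self-links, non-lysine/non-N-terminal endpoints, duplicates, records
whose residues are missing from the structure), and fits the normal
distribution of crosslinked-lysine surface distances used by the matched
crosslink score.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import gemmi
import numpy as np
import pandas as pd

__all__ = [
    "Atom",
    "StructureModel",
    "CrosslinkRecord",
    "CrosslinkDataset",
    "NormalParams",
    "DEFAULT_VDW",
    "WATER_VDW",
    "default_probe_increment",
    "max_physical_length",
    "parse_structure",
    "read_structure",
    "write_structure",
    "read_crosslink_csv",
    "curate_crosslinks",
    "fit_sasd_distribution",
]

#: Van der Waals radii in Å (Bondi 1964 set, the standard element radii used
#: for solvent-excluded-volume construction).
DEFAULT_VDW: dict[str, float] = {
    "H": 1.20,
    "C": 1.70,
    "N": 1.55,
    "O": 1.52,
    "S": 1.80,
    "P": 1.80,
    "F": 1.47,
    "CL": 1.75,
    "BR": 1.85,
    "I": 1.98,
    "FE": 2.00,
    "ZN": 1.39,
    "MG": 1.73,
    "CA": 2.00,
    "SE": 1.90,
}

#: Van der Waals diameter of a water molecule in Å.
WATER_VDW = 1.4

#: Length of a fully extended lysine side chain, Cα to Nζ, in Å.
LYSINE_SIDE_CHAIN_LENGTH = 5.5

#: Linker arm length of the BS3 / DSS crosslinkers in Å.
BS3_LINKER_LENGTH = 11.4

LYSINE_SIDE_CHAIN_ATOMS = frozenset({"CB", "CG", "CD", "CE", "NZ"})
BACKBONE_ATOMS = frozenset({"N", "CA", "C", "O", "OXT"})
WATER_RESIDUES = frozenset({"HOH", "WAT", "DOD"})


def default_probe_increment() -> float:
    """Radius increment added to each atom's VdW radius when marking the
    solvent-excluded volume: half the VdW radius of a water molecule."""
    return WATER_VDW / 2.0


def max_physical_length(linker_length: float = BS3_LINKER_LENGTH,
                        side_chain_length: float = LYSINE_SIDE_CHAIN_LENGTH) -> float:
    """Maximum physical Cα–Cα span of a lysine–lysine crosslink.

    The linker bridges the two Nζ atoms, so measured from the backbone the
    crosslink can reach the linker length plus one extended side chain at
    each end.
    """
    return linker_length + 2.0 * side_chain_length


@dataclass(frozen=True)
class Atom:
    serial: int
    name: str
    element: str
    chain: str
    residue_number: int
    residue_name: str
    position: np.ndarray
    occupancy: float = 1.0
    altloc: str = ""

    def __post_init__(self):
        pos = np.asarray(self.position, dtype=float)
        if pos.shape != (3,) or not np.all(np.isfinite(pos)):
            raise ValueError(f"atom {self.name}: position must be a finite 3-vector")
        object.__setattr__(self, "position", pos)


ResidueKey = tuple[str, int]


class StructureModel:
    """Parsed atomic structure with chain/residue/atom lookups.

    The residues of interest for crosslinking are lysines and each chain's
    N-terminal residue; helpers expose their Cα and Nζ coordinates.
    """

    def __init__(self, atoms: Sequence[Atom]):
        self.atoms: list[Atom] = list(atoms)
        self._by_residue: dict[ResidueKey, dict[str, Atom]] = {}
        self._residue_names: dict[ResidueKey, str] = {}
        self._chain_order: list[str] = []
        for atom in self.atoms:
            key = (atom.chain, atom.residue_number)
            res = self._by_residue.setdefault(key, {})
            if atom.name in res:
                raise ValueError(
                    f"duplicate atom {atom.name} in {atom.chain}/{atom.residue_number}"
                )
            res[atom.name] = atom
            self._residue_names.setdefault(key, atom.residue_name)
            if atom.chain not in self._chain_order:
                self._chain_order.append(atom.chain)

    # -- basic lookups ----------------------------------------------------

    @property
    def chains(self) -> list[str]:
        return list(self._chain_order)

    def residues(self, chain: str | None = None) -> list[ResidueKey]:
        keys = list(self._by_residue)
        if chain is not None:
            keys = [k for k in keys if k[0] == chain]
        return keys

    def residue_name(self, key: ResidueKey) -> str | None:
        return self._residue_names.get(key)

    def has_residue(self, key: ResidueKey) -> bool:
        return key in self._by_residue

    def atom(self, key: ResidueKey, name: str) -> Atom | None:
        return self._by_residue.get(key, {}).get(name)

    def coords(self) -> np.ndarray:
        return np.array([a.position for a in self.atoms], dtype=float)

    # -- crosslink targets -------------------------------------------------

    def n_terminus(self, chain: str) -> ResidueKey:
        """First (lowest-numbered) residue of a chain."""
        numbers = [k[1] for k in self._by_residue if k[0] == chain]
        if not numbers:
            raise KeyError(f"chain {chain!r} not in structure")
        return (chain, min(numbers))

    def lysines(self) -> list[ResidueKey]:
        return sorted(k for k, n in self._residue_names.items() if n == "LYS")

    def crosslink_targets(self) -> list[ResidueKey]:
        """Lysines plus each chain's N-terminal residue, deduplicated."""
        targets = set(self.lysines())
        for chain in self.chains:
            targets.add(self.n_terminus(chain))
        return sorted(targets)

    def is_target(self, key: ResidueKey) -> bool:
        if self._residue_names.get(key) == "LYS":
            return True
        return key[0] in self._chain_order and key == self.n_terminus(key[0])

    def ca(self, key: ResidueKey) -> np.ndarray | None:
        atom = self.atom(key, "CA")
        return None if atom is None else atom.position

    def nz(self, key: ResidueKey) -> np.ndarray | None:
        atom = self.atom(key, "NZ")
        return None if atom is None else atom.position

    def __len__(self) -> int:
        return len(self.atoms)

    def __repr__(self) -> str:
        return (f"StructureModel({len(self.atoms)} atoms, "
                f"{len(self._by_residue)} residues, chains {self.chains})")


def _resolve_altlocs(atoms: list[Atom]) -> list[Atom]:
    # keep highest occupancy; ties resolved toward altloc 'A' (lexicographic)
    best: dict[tuple, Atom] = {}
    order: list[tuple] = []
    for atom in atoms:
        key = (atom.chain, atom.residue_number, atom.name)
        if key not in best:
            best[key] = atom
            order.append(key)
        else:
            cur = best[key]
            if (atom.occupancy, _altloc_rank(atom.altloc)) > (
                    cur.occupancy, _altloc_rank(cur.altloc)):
                best[key] = atom
    return [best[k] for k in order]


def _altloc_rank(altloc: str) -> float:
    # 'A' wins ties, then 'B', ...; blank sorts last among equals
    if not altloc:
        return 0.0
    return 1.0 / (ord(altloc[0]) - ord("A") + 1.0)


def parse_structure(pdb_text: str, *, include_hydrogens: bool = False,
                    include_het: bool = False) -> StructureModel:
    """Parse PDB-format text into a :class:`StructureModel`.

    Altloc duplicates are collapsed to the highest-occupancy location
    (ties → 'A').  Hydrogens are dropped unless requested.  Waters are always
    excluded; other HETATM groups are excluded unless ``include_het`` is set
    (they then act as path obstacles only).
    """
    if not pdb_text.strip():
        raise ValueError("empty PDB input: no ATOM records")
    try:
        structure = gemmi.read_pdb_string(pdb_text)
    except (RuntimeError, ValueError) as exc:
        raise ValueError(f"PDB parse error: {exc}") from exc
    structure.setup_entities()
    atoms: list[Atom] = []
    serial = 0
    model = structure[0]
    for chain in model:
        for residue in chain:
            if residue.name in WATER_RESIDUES:
                continue
            is_het = residue.het_flag == "H"
            if is_het and not include_het:
                continue
            for at in residue:
                element = at.element.name.upper()
                if element == "H" and not include_hydrogens:
                    continue
                serial += 1
                atoms.append(Atom(
                    serial=serial,
                    name=at.name,
                    element=element or _element_from_name(at.name),
                    chain=chain.name,
                    residue_number=residue.seqid.num,
                    residue_name=residue.name,
                    position=np.array([at.pos.x, at.pos.y, at.pos.z]),
                    occupancy=float(at.occ),
                    altloc=at.altloc or "",
                ))
    if not atoms:
        raise ValueError("PDB input contains no usable ATOM records")
    return StructureModel(_resolve_altlocs(atoms))


def _element_from_name(name: str) -> str:
    stripped = name.strip().lstrip("0123456789")
    return stripped[:1].upper() if stripped else "C"


def read_structure(path, **kwargs) -> StructureModel:
    with open(path) as fh:
        return parse_structure(fh.read(), **kwargs)


def write_structure(model: StructureModel, path=None) -> str:
    """Serialize a :class:`StructureModel` to PDB-format text (and optionally
    write it to ``path``)."""
    st = gemmi.Structure()
    st.add_model(gemmi.Model("1"))
    gm = st[0]
    chain_map: dict[str, gemmi.Chain] = {}
    for atom in model.atoms:
        if atom.chain not in chain_map:
            gm.add_chain(gemmi.Chain(atom.chain))
            chain_map[atom.chain] = gm[len(chain_map)]
        chain = chain_map[atom.chain]
        res = None
        if len(chain) > 0 and chain[len(chain) - 1].seqid.num == atom.residue_number:
            res = chain[len(chain) - 1]
        if res is None:
            res = gemmi.Residue()
            res.name = atom.residue_name
            res.seqid = gemmi.SeqId(atom.residue_number, " ")
            chain.add_residue(res)
            res = chain[len(chain) - 1]
        ga = gemmi.Atom()
        ga.name = atom.name
        ga.element = gemmi.Element(atom.element.capitalize())
        ga.pos = gemmi.Position(*atom.position)
        ga.occ = atom.occupancy
        res.add_atom(ga)
    st.setup_entities()
    text = st.make_pdb_string()
    if path is not None:
        with open(path, "w") as fh:
            fh.write(text)
    return text


# ---------------------------------------------------------------------------
# Crosslink records


@dataclass(frozen=True)
class CrosslinkRecord:
    """One unordered crosslinked residue pair, canonicalized so that
    ``(chain_a, residue_a) <= (chain_b, residue_b)``."""

    chain_a: str
    residue_a: int
    chain_b: str
    residue_b: int
    linker_length: float = BS3_LINKER_LENGTH

    def __post_init__(self):
        a = (self.chain_a, self.residue_a)
        b = (self.chain_b, self.residue_b)
        if a == b:
            # represented, caught later by curation; keep canonical anyway
            pass
        if b < a:
            object.__setattr__(self, "chain_a", b[0])
            object.__setattr__(self, "residue_a", b[1])
            object.__setattr__(self, "chain_b", a[0])
            object.__setattr__(self, "residue_b", a[1])

    @property
    def a(self) -> ResidueKey:
        return (self.chain_a, self.residue_a)

    @property
    def b(self) -> ResidueKey:
        return (self.chain_b, self.residue_b)

    @property
    def pair(self) -> tuple[ResidueKey, ResidueKey]:
        return (self.a, self.b)

    @property
    def link_type(self) -> str:
        return "intra" if self.chain_a == self.chain_b else "inter"

    def is_self_link(self) -> bool:
        return self.a == self.b


@dataclass
class CrosslinkDataset:
    """A validated set of crosslink records with a provenance tag."""

    records: list[CrosslinkRecord] = field(default_factory=list)
    provenance: str = "experimental"  # experimental | theoretical | bootstrap

    def pairs(self) -> list[tuple[ResidueKey, ResidueKey]]:
        return [r.pair for r in self.records]

    def subset(self, indices: Iterable[int], provenance: str = "bootstrap"
               ) -> "CrosslinkDataset":
        recs = [self.records[i] for i in indices]
        return CrosslinkDataset(recs, provenance)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)


def read_crosslink_csv(path_or_buffer) -> list[CrosslinkRecord]:
    """Read crosslinks from CSV with header ``chain_a,res_a,chain_b,res_b[,linker]``."""
    df = pd.read_csv(path_or_buffer, dtype={"chain_a": str, "chain_b": str})
    required = {"chain_a", "res_a", "chain_b", "res_b"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"crosslink CSV missing columns: {sorted(missing)}")
    records = []
    for row in df.itertuples(index=False):
        linker = getattr(row, "linker", BS3_LINKER_LENGTH)
        if linker is None or (isinstance(linker, float) and np.isnan(linker)):
            linker = BS3_LINKER_LENGTH
        records.append(CrosslinkRecord(
            str(row.chain_a), int(row.res_a), str(row.chain_b), int(row.res_b),
            float(linker)))
    return records


def write_crosslink_csv(records: Iterable[CrosslinkRecord], path) -> None:
    df = pd.DataFrame(
        [(r.chain_a, r.residue_a, r.chain_b, r.residue_b, r.linker_length)
         for r in records],
        columns=["chain_a", "res_a", "chain_b", "res_b", "linker"])
    df.to_csv(path, index=False)


CURATION_RULES = ("missing_residue", "self_link", "non_lysine", "duplicate",
                  "domain_filter")


def curate_crosslinks(
    records: Iterable[CrosslinkRecord],
    structure: StructureModel,
    domain_filter: Mapping[str, tuple[int, int]] | None = None,
    provenance: str = "experimental",
) -> tuple[CrosslinkDataset, dict[str, int]]:
    """Apply the crosslink-database curation rules against a structure.

    Removes, in order: records whose residues are absent from the structure;
    self-links; records with an endpoint that is neither a lysine nor its
    chain's N-terminal residue; duplicate unordered pairs; and, when
    ``domain_filter`` maps chains to residue ranges, pairs that cross a
    domain boundary (either endpoint outside its chain's range).

    Returns the surviving dataset and a per-rule removal count.
    """
    removed = {rule: 0 for rule in CURATION_RULES}
    kept: list[CrosslinkRecord] = []
    seen: set[tuple[ResidueKey, ResidueKey]] = set()
    for rec in records:
        if not (structure.has_residue(rec.a) and structure.has_residue(rec.b)):
            removed["missing_residue"] += 1
            continue
        if rec.is_self_link():
            removed["self_link"] += 1
            continue
        if not (structure.is_target(rec.a) and structure.is_target(rec.b)):
            removed["non_lysine"] += 1
            continue
        if rec.pair in seen:
            removed["duplicate"] += 1
            continue
        if domain_filter is not None and not _within_domain(rec, domain_filter):
            removed["domain_filter"] += 1
            continue
        seen.add(rec.pair)
        kept.append(rec)
    return CrosslinkDataset(kept, provenance), removed


def _within_domain(rec: CrosslinkRecord,
                   domain_filter: Mapping[str, tuple[int, int]]) -> bool:
    for chain, resnum in (rec.a, rec.b):
        if chain not in domain_filter:
            return False
        lo, hi = domain_filter[chain]
        if not lo <= resnum <= hi:
            return False
    return True


# ---------------------------------------------------------------------------
# Distance-distribution fitting


@dataclass(frozen=True)
class NormalParams:
    """Normal distribution fitted to crosslink surface distances ≤ fit_cutoff."""

    mu: float
    sigma: float
    fit_cutoff: float = 33.0
    n_fit: int = 0

    def __post_init__(self):
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")


def fit_sasd_distribution(sasd_values: Iterable[float],
                          fit_cutoff: float = 33.0) -> NormalParams:
    """Fit mean and sample standard deviation of distances ≤ ``fit_cutoff``.

    Distances above the cutoff are excluded before fitting, mirroring how the
    scoring distribution is derived from a curated crosslink database.
    """
    values = np.asarray([v for v in sasd_values if np.isfinite(v)], dtype=float)
    used = values[values <= fit_cutoff]
    if used.size < 2:
        raise ValueError(
            f"need at least 2 distances <= {fit_cutoff} to fit (got {used.size})")
    mu = float(np.mean(used))
    sigma = float(np.std(used, ddof=1))
    if sigma == 0.0:
        raise ValueError("degenerate fit: all retained distances are equal")
    return NormalParams(mu=mu, sigma=sigma, fit_cutoff=fit_cutoff, n_fit=int(used.size))
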