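"""Reading PDB-format crystal structures into a uniform in-memory model.

The model keeps every alternate-location conformer as its own
:class:`AtomRecord` (altloc groups matter for occupancy-weighted
temperature factors), preserves chain order as found in the file (the
"first molecule in the asymmetric unit" convention depends on it), and
separates polymer chains from heteroatom groups such as nucleotides,
ions and waters.

Only the first MODEL of a file is retained and hydrogens are dropped:
the corpus this package targets consists of X-ray structures where
neither multiple models nor hydrogen positions carry information.
"""

from __future__ import annotations

import logging
import urllib.request
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Optional, Sequence

import gemmi
import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "AtomRecord",
    "ResidueId",
    "Residue",
    "Chain",
    "HetGroup",
    "StructureModel",
    "read_structure",
    "effective_b",
    "select_atom",
    "fetch_pdb",
    "WATER_CODES",
]

#: Residue names treated as water when partitioning het groups.
WATER_CODES = frozenset({"HOH", "WAT", "DOD", "H2O"})


@dataclass(frozen=True)
class AtomRecord:
    """One crystallographic atom (one altloc conformer)."""

    serial: int
    atom_name: str
    altloc: str  # single char, "" when no alternate locations
    residue_name: str
    chain_id: str
    residue_seq: int
    insertion_code: str
    position: np.ndarray  # shape (3,), Angstrom
    occupancy: float
    b_factor: float  # Angstrom^2
    element: str

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "position", np.asarray(self.position, dtype=float)
        )
        if not np.all(np.isfinite(self.position)):
            raise ValueError(f"non-finite coordinates for atom {self.serial}")
        if not 0.0 <= self.occupancy <= 1.0:
            raise ValueError(
                f"occupancy {self.occupancy} outside [0, 1] for atom {self.serial}"
            )
        if self.b_factor < 0:
            # Negative B-factors occur in malformed files; keep the atom so
            # the outlier filter can see it, but make the anomaly visible.
            logger.warning(
                "negative B-factor %.2f on atom serial %d (%s %s%d)",
                self.b_factor,
                self.serial,
                self.atom_name,
                self.chain_id,
                self.residue_seq,
            )


@dataclass(frozen=True, order=True)
class ResidueId:
    """Position of a residue within a structure; orderable within a chain."""

    chain_id: str
    residue_seq: int
    insertion_code: str = ""


@dataclass
class Residue:
    rid: ResidueId
    name: str
    atoms: list[AtomRecord] = field(default_factory=list)

    def atoms_named(self, atom_name: str) -> list[AtomRecord]:
        """All conformers of one atom identity (possibly several altlocs)."""
        return [a for a in self.atoms if a.atom_name == atom_name]


@dataclass
class Chain:
    chain_id: str
    residues: list[Residue] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.residues)

    def __iter__(self) -> Iterator[Residue]:
        return iter(self.residues)

    def residue(self, residue_seq: int, insertion_code: str = "") -> Optional[Residue]:
        for res in self.residues:
            if (
                res.rid.residue_seq == residue_seq
                and res.rid.insertion_code == insertion_code
            ):
                return res
        return None


@dataclass
class HetGroup:
    het_code: str
    rid: ResidueId
    atoms: list[AtomRecord] = field(default_factory=list)

    @property
    def is_water(self) -> bool:
        return self.het_code in WATER_CODES


@dataclass
class StructureModel:
    """One crystal structure: ordered polymer chains plus het groups."""

    structure_id: str
    polymer_chains: list[Chain] = field(default_factory=list)
    het_groups: list[HetGroup] = field(default_factory=list)
    model_number: int = 1

    def chain(self, chain_id: str) -> Optional[Chain]:
        for ch in self.polymer_chains:
            if ch.chain_id == chain_id:
                return ch
        return None

    @property
    def ligands(self) -> list[HetGroup]:
        """Het groups that are not water."""
        return [h for h in self.het_groups if not h.is_water]

    @property
    def waters(self) -> list[HetGroup]:
        return [h for h in self.het_groups if h.is_water]


def _validate_pdb_columns(path: Path) -> None:
    """Fail early, naming the offending line, when occupancy/B are absent.

    gemmi silently defaults missing trailing columns; the analysis is
    meaningless without them, so the contract is a hard error.
    """
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if line.startswith("ENDMDL"):
                break
            if not (line.startswith("ATOM") or line.startswith("HETATM")):
                continue
            if len(line.rstrip("\n")) < 66 or not line[54:60].strip() or not line[60:66].strip():
                raise ValueError(
                    f"{path}: line {lineno} lacks occupancy/B-factor columns: "
                    f"{line.rstrip()!r}"
                )


def read_structure(path: str | Path, structure_id: Optional[str] = None) -> StructureModel:
    """Parse a PDB file into a :class:`StructureModel` (first model only).

    ATOM records populate polymer chains; HETATM records become het
    groups keyed by their three-letter code. Altloc conformers are kept
    as distinct :class:`AtomRecord` objects sharing the same
    ``(atom_name, ResidueId)``. Hydrogens/deuteriums are skipped.

    Raises
    ------
    FileNotFoundError
        If the file does not exist.
    ValueError
        If the file contains no ATOM records or an ATOM/HETATM line
        lacks occupancy or B-factor columns.
    """
    path = Path(path)
    if not path.is_file():
        raise FileNotFoundError(path)
    _validate_pdb_columns(path)

    st = gemmi.read_structure(str(path), format=gemmi.CoorFormat.Detect)
    if len(st) == 0:
        raise ValueError(f"{path}: no models found")
    model = st[0]

    sid = structure_id or (st.name.strip() or path.stem).upper()
    out = StructureModel(structure_id=sid, model_number=1)
    chains_by_id: dict[str, Chain] = {}
    n_atom_records = 0

    for g_chain in model:
        for g_res in g_chain:
            is_het = g_res.het_flag == "H"
            rid = ResidueId(
                chain_id=g_chain.name,
                residue_seq=g_res.seqid.num,
                insertion_code=(g_res.seqid.icode or "").strip(),
            )
            records = []
            for g_atom in g_res:
                if g_atom.element.is_hydrogen:
                    continue
                records.append(
                    AtomRecord(
                        serial=g_atom.serial,
                        atom_name=g_atom.name,
                        altloc=(g_atom.altloc or "").replace("\x00", "").strip(),
                        residue_name=g_res.name,
                        chain_id=g_chain.name,
                        residue_seq=rid.residue_seq,
                        insertion_code=rid.insertion_code,
                        position=np.array(
                            [g_atom.pos.x, g_atom.pos.y, g_atom.pos.z]
                        ),
                        occupancy=float(g_atom.occ),
                        b_factor=float(g_atom.b_iso),
                        element=g_atom.element.name,
                    )
                )
            if not records:
                continue
            if is_het:
                out.het_groups.append(
                    HetGroup(het_code=g_res.name, rid=rid, atoms=records)
                )
            else:
                n_atom_records += len(records)
                chain = chains_by_id.get(g_chain.name)
                if chain is None:
                    chain = Chain(chain_id=g_chain.name)
                    chains_by_id[g_chain.name] = chain
                    out.polymer_chains.append(chain)
                chain.residues.append(Residue(rid=rid, name=g_res.name, atoms=records))

    if n_atom_records == 0:
        raise ValueError(f"{path}: no ATOM records")
    return out


def effective_b(atoms: Sequence[AtomRecord] | Iterable[AtomRecord]) -> float:
    """Occupancy-weighted B-factor of one atom identity, Σ_I π_I · B(i, I).

    The sum runs over all altloc conformers ``I`` of the atom with
    occupancies ``π_I``. When occupancies do not sum to 1 (partial
    disorder) the weighted sum is used exactly as given — no
    renormalization — and a warning is logged.
    """
    atoms = list(atoms)
    if not atoms:
        raise ValueError("effective_b requires at least one conformer")
    total_occ = sum(a.occupancy for a in atoms)
    if len(atoms) > 1 and abs(total_occ - 1.0) > 1e-3:
        logger.warning(
            "altloc occupancies sum to %.3f (not 1) for atom %s %s%d; "
            "using the weighted sum as given",
            total_occ,
            atoms[0].atom_name,
            atoms[0].chain_id,
            atoms[0].residue_seq,
        )
    return float(sum(a.occupancy * a.b_factor for a in atoms))


def select_atom(
    model: StructureModel,
    chain_id: str,
    residue_seq: int,
    atom_name: str,
    insertion_code: str = "",
) -> Optional[AtomRecord]:
    """Pick one conformer of one atom, or ``None`` when unresolved.

    Among altloc conformers the highest-occupancy one wins; ties break
    alphabetically on the altloc character (matching common molecular
    viewer defaults). A missing residue or atom is a value, not an
    error: unresolved residues are ordinary in crystal structures and
    downstream statistics treat them as missing data.
    """
    chain = model.chain(chain_id)
    if chain is None:
        return None
    res = chain.residue(residue_seq, insertion_code)
    if res is None:
        return None
    conformers = res.atoms_named(atom_name)
    if not conformers:
        return None
    best = min(conformers, key=lambda a: (-a.occupancy, a.altloc))
    if len(conformers) > 1:
        logger.info(
            "altloc pick %s (occ %.2f) for %s %s%d among %d conformers",
            best.altloc or "-",
            best.occupancy,
            atom_name,
            chain_id,
            residue_seq,
        )
    return best


def fetch_pdb(pdb_id: str, cache_dir: str | Path) -> Path:
    """Download one entry from the RCSB PDB into ``cache_dir``.

    Network access is always explicit: nothing in the package calls
    this implicitly. Returns the cached path; a file already in the
    cache is not re-downloaded.
    """
    pdb_id = pdb_id.lower()
    cache_dir = Path(cache_dir)
    cache_dir.mkdir(parents=True, exist_ok=True)
    dest = cache_dir / f"{pdb_id}.pdb"
    if dest.is_file():
        return dest
    url = f"https://files.rcsb.org/download/{pdb_id}.pdb"
    logger.info("fetching %s -> %s", url, dest)
    with urllib.request.urlopen(url) as resp:
        dest.write_bytes(resp.read())
    return dest
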