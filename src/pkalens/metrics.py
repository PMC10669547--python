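"""Distance-triplet conformational metrics for the kinase catalytic domain.

Each metric is a named triplet of probe atoms (default Cα) whose three
pairwise distances summarise one aspect of the domain's conformation:
inter-lobe opening/closing, regulatory-spine assembly around the DFG
phenylalanine, C-tail tethering, G-loop orientation relative to the
catalytic spine, and N-lobe core geometry. Residue numbers follow PKA
catalytic-subunit conventional numbering; a per-structure integer
offset accommodates files numbered differently.

Missingness is data: a probe residue unresolved in the crystal yields a
missing distance, the record is still emitted, and downstream summaries
drop missing values per distance pair (so sample sizes may differ
between the three columns of one metric).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .structure_io import StructureModel, select_atom

logger = logging.getLogger(__name__)

__all__ = [
    "DistanceTriplet",
    "DistanceRecord",
    "builtin_triplets",
    "get_triplet",
    "euclidean",
    "measure",
    "measure_corpus",
    "records_to_frame",
]

Probe = tuple[int, str]


@dataclass(frozen=True)
class DistanceTriplet:
    """Three probe atoms, each a (residue_seq, atom_name) pair."""

    name: str
    probes: tuple[Probe, Probe, Probe]

    def __post_init__(self) -> None:
        if len(set(self.probes)) != 3:
            raise ValueError(f"triplet {self.name}: probes must be distinct")

    def pair_labels(self) -> tuple[str, str, str]:
        """Labels for (d12, d13, d23), e.g. ``('51CA-87CA', ...)``."""

        def lab(p: Probe) -> str:
            return f"{p[0]}{p[1]}"

        (a, b, c) = self.probes
        return (f"{lab(a)}-{lab(b)}", f"{lab(a)}-{lab(c)}", f"{lab(b)}-{lab(c)}")


# The six built-in metrics. Probe atoms are Cα except the DFG
# phenylalanine, where the ring tip Cζ tracks the side-chain flip that
# distinguishes DFG-in from DFG-out/inter.
_BUILTINS = (
    # G-loop (T51) and αC (H87) on the N-lobe vs the immobile αF helix
    # (A223): inter-lobe opening/closing.
    DistanceTriplet("lobe_closure", ((51, "CA"), (87, "CA"), (223, "CA"))),
    # Historical variant anchored at S53; sensitive to G-loop tip
    # inversions, kept for comparison.
    DistanceTriplet("lobe_closure_s53", ((53, "CA"), (87, "CA"), (223, "CA"))),
    # R-spine assembly: β3 lysine, DFG phenylalanine ring tip, αC+4
    # leucine.
    DistanceTriplet("dfg_spine", ((72, "CA"), (185, "CZ"), (95, "CA"))),
    # C-tail tethering: FDDY-motif D328 vs G-loop G52 and C-spine E127.
    DistanceTriplet("ctail_gloop", ((328, "CA"), (52, "CA"), (127, "CA"))),
    # G-loop tip F54 vs αE-helix F154 and C-spine L173.
    DistanceTriplet("cspine_gloop", ((54, "CA"), (154, "CA"), (173, "CA"))),
    # N-lobe core: shield residue V104, αB K81, β4-β5 loop N113.
    DistanceTriplet("nlobe_core", ((104, "CA"), (81, "CA"), (113, "CA"))),
)


def builtin_triplets() -> tuple[DistanceTriplet, ...]:
    """The six built-in named distance triplets."""
    return _BUILTINS


def get_triplet(name: str) -> DistanceTriplet:
    for t in _BUILTINS:
        if t.name == name:
            return t
    raise KeyError(f"unknown triplet {name!r}; known: {[t.name for t in _BUILTINS]}")


@dataclass(frozen=True)
class DistanceRecord:
    """Measured pairwise distances of one triplet on one chain.

    ``d12``, ``d13``, ``d23`` follow the probe order of the triplet;
    each may be ``None`` when a probe atom is unresolved.
    """

    structure_id: str
    chain_id: str
    triplet_name: str
    d12: Optional[float]
    d13: Optional[float]
    d23: Optional[float]
    state: Optional[str] = None

    def distances(self) -> tuple[Optional[float], Optional[float], Optional[float]]:
        return (self.d12, self.d13, self.d23)

    def is_complete(self) -> bool:
        return None not in self.distances()


def euclidean(a: Sequence[float] | np.ndarray, b: Sequence[float] | np.ndarray) -> float:
    """Euclidean distance between two points in Å."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if not (np.all(np.isfinite(a)) and np.all(np.isfinite(b))):
        raise ValueError("non-finite coordinates")
    return float(np.linalg.norm(a - b))


def measure(
    model: StructureModel,
    chain_id: str,
    triplet: DistanceTriplet,
    numbering_offset: int = 0,
    state: Optional[str] = None,
) -> DistanceRecord:
    """Measure one triplet on one chain.

    ``numbering_offset`` is added to the triplet's residue numbers
    before lookup, for files whose author numbering differs from PKA
    convention. A missing probe leaves the affected distances missing;
    the record is emitted regardless.
    """
    atoms = []
    for res_seq, atom_name in triplet.probes:
        atom = select_atom(model, chain_id, res_seq + numbering_offset, atom_name)
        if atom is None:
            logger.info(
                "%s chain %s: probe %d %s unresolved (%s)",
                model.structure_id, chain_id, res_seq, atom_name, triplet.name,
            )
        atoms.append(atom)

    def dist(i: int, j: int) -> Optional[float]:
        if atoms[i] is None or atoms[j] is None:
            return None
        return euclidean(atoms[i].position, atoms[j].position)

    return DistanceRecord(
        structure_id=model.structure_id,
        chain_id=chain_id,
        triplet_name=triplet.name,
        d12=dist(0, 1),
        d13=dist(0, 2),
        d23=dist(1, 2),
        state=state,
    )


def measure_corpus(
    models: Iterable[StructureModel],
    triplets: Sequence[DistanceTriplet] | None = None,
    states: dict[str, str] | None = None,
    all_chains: bool = True,
    numbering_offset: int = 0,
) -> list[DistanceRecord]:
    """Measure triplets on every chain of every structure.

    Multiple kinase copies in one asymmetric unit enter the dataset as
    individual entries (one record per chain per triplet). Chains with
    no Cα atoms at all (pure-ligand "chains") are skipped with a
    warning. ``states`` maps structure_id to a state label attached to
    each record. Output order is (structure_id, chain_id, triplet name).
    """
    if triplets is None:
        triplets = builtin_triplets()
    records: list[DistanceRecord] = []
    for model in models:
        state = states.get(model.structure_id) if states else None
        chains = model.polymer_chains if all_chains else model.polymer_chains[:1]
        for chain in chains:
            has_ca = any(res.atoms_named("CA") for res in chain)
            if not has_ca:
                logger.warning(
                    "%s chain %s has no CA atoms; skipped",
                    model.structure_id, chain.chain_id,
                )
                continue
            for triplet in triplets:
                records.append(
                    measure(model, chain.chain_id, triplet, numbering_offset, state)
                )
    records.sort(key=lambda r: (r.structure_id, r.chain_id, r.triplet_name))
    return records


def records_to_frame(records: Iterable[DistanceRecord]) -> pd.DataFrame:
    """Tidy long-form table: one row per (record, distance pair).

    Columns: structure_id, chain_id, state, triplet, pair,
    distance_angstrom (NaN for missing).
    """
    rows = []
    for rec in records:
        labels = get_triplet(rec.triplet_name).pair_labels() if any(
            t.name == rec.triplet_name for t in _BUILTINS
        ) else ("d12", "d13", "d23")
        for label, value in zip(labels, rec.distances()):
            rows.append(
                {
                    "structure_id": rec.structure_id,
                    "chain_id": rec.chain_id,
                    "state": rec.state,
                    "triplet": rec.triplet_name,
                    "pair": label,
                    "distance_angstrom": np.nan if value is None else value,
                }
            )
    return pd.DataFrame(
        rows,
        columns=[
            "structure_id", "chain_id", "state", "triplet", "pair", "distance_angstrom",
        ],
    )
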