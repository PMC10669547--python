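"""End-to-end orchestration over a directory of structures.

Thin convenience layer tying the stages together: read a corpus,
classify states, measure the distance triplets, build B′ profiles and
assemble report tables. The CLI wraps these functions; library users
can call them directly.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .bprime import BPrimeProfile, Selection, normalize_chain
from .ensemble import summarize
from .metrics import DistanceRecord, DistanceTriplet, builtin_triplets, measure, measure_corpus
from .states import LigandDictionary, classify
from .structure_io import StructureModel, read_structure

logger = logging.getLogger(__name__)

__all__ = [
    "load_corpus",
    "classify_corpus",
    "corpus_distances",
    "corpus_profiles",
    "summary_tables",
    "structure_grid",
    "paint_values_as_b",
]


def load_corpus(paths: Iterable[str | Path]) -> list[StructureModel]:
    """Read many PDB files; structure_id = upper-cased file stem."""
    models = []
    for p in sorted(Path(p) for p in paths):
        models.append(read_structure(p, structure_id=p.stem.upper()))
    return models


def classify_corpus(
    models: Sequence[StructureModel],
    lig_dict: Optional[LigandDictionary] = None,
) -> dict[str, str]:
    """State label per structure_id."""
    return {m.structure_id: classify(m, lig_dict) for m in models}


def corpus_distances(
    models: Sequence[StructureModel],
    states: Optional[dict[str, str]] = None,
    triplets: Optional[Sequence[DistanceTriplet]] = None,
) -> list[DistanceRecord]:
    """All-chain distance records for the whole corpus."""
    return measure_corpus(models, triplets=triplets, states=states)


def corpus_profiles(
    models: Sequence[StructureModel],
    selection: Selection = "backbone",
    first_chain_only: bool = True,
) -> list[BPrimeProfile]:
    """B′ profiles across the corpus.

    ``first_chain_only`` keeps one molecule per structure (the first
    chain by file order), the convention used for profile-level
    statistics and PCA. Chains that cannot be normalized (degenerate B
    columns) are skipped with a warning.
    """
    profiles = []
    for model in models:
        chains = model.polymer_chains[:1] if first_chain_only else model.polymer_chains
        for chain in chains:
            # short bound peptides are not kinase molecules
            if len(chain) <= 30:
                continue
            try:
                profiles.append(normalize_chain(model, chain.chain_id, selection))
            except ValueError as exc:
                logger.warning("skipping %s:%s: %s", model.structure_id, chain.chain_id, exc)
    return profiles


def summary_tables(records: Sequence[DistanceRecord]) -> dict[str, pd.DataFrame]:
    """One wide summary table per triplet (states as row blocks)."""
    full = summarize(records)
    out = {}
    for triplet in sorted({r.triplet_name for r in records}):
        try:
            block = full.xs(triplet, level="triplet")
        except KeyError:
            continue
        out[triplet] = block
    return out


def structure_grid(
    models: Sequence[StructureModel],
    chains: Optional[dict[str, str]] = None,
    triplets: Optional[Sequence[DistanceTriplet]] = None,
    decimals: int = 1,
) -> pd.DataFrame:
    """Per-structure grid of every pairwise distance (rows) by structure/chain.

    ``chains`` optionally restricts each structure_id to one chain;
    otherwise all chains appear as separate columns. Values are
    rounded to ``decimals`` for reporting; missing probes show as NaN.
    """
    if triplets is None:
        triplets = builtin_triplets()
    columns = {}
    for model in models:
        chain_ids = (
            [chains[model.structure_id]]
            if chains and model.structure_id in chains
            else [c.chain_id for c in model.polymer_chains]
        )
        for chain_id in chain_ids:
            col = {}
            for triplet in triplets:
                rec = measure(model, chain_id, triplet)
                for label, value in zip(triplet.pair_labels(), rec.distances()):
                    col[(triplet.name, label)] = (
                        float("nan") if value is None else round(value, decimals)
                    )
            columns[(model.structure_id, chain_id)] = col
    grid = pd.DataFrame(columns)
    grid.index = pd.MultiIndex.from_tuples(grid.index, names=["triplet", "pair"])
    grid.columns = pd.MultiIndex.from_tuples(grid.columns, names=["structure", "chain"])
    return grid


def paint_values_as_b(
    model: StructureModel,
    chain_id: str,
    values: dict[int, float],
    out_path: str | Path,
    scale: float = 100.0,
    missing: float = 0.0,
) -> Path:
    """Write one chain as a PDB with the B column replaced by per-residue values.

    The standard trick for putty/colour rendering of per-residue
    quantities (B' means, PCA loadings) in molecular viewers: every
    atom of a residue carries ``scale * value`` in the B-factor field.
    Residues absent from ``values`` (keys are residue_seq) get
    ``missing``. Occupancy is set to 1.00.
    """
    chain = model.chain(chain_id)
    if chain is None:
        raise ValueError(f"{model.structure_id}: no chain {chain_id!r}")
    out_path = Path(out_path)
    lines = []
    serial = 1
    for res in chain:
        val = values.get(res.rid.residue_seq)
        painted = missing if val is None else scale * val
        for atom in res.atoms:
            name_field = f" {atom.atom_name:<3s}" if len(atom.atom_name) < 4 else atom.atom_name
            lines.append(
                f"ATOM  {serial:5d} {name_field}{atom.altloc or ' '}"
                f"{res.name:>3s} {chain_id}{res.rid.residue_seq:4d}    "
                f"{atom.position[0]:8.3f}{atom.position[1]:8.3f}{atom.position[2]:8.3f}"
                f"{1.00:6.2f}{np.clip(painted, -9.99, 999.99):6.2f}"
                f"          {atom.element:>2s}\n"
            )
            serial += 1
    lines.append("END\n")
    out_path.write_text("".join(lines))
    return out_path
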