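"""Shared fixtures: in-memory model builders and synthetic corpora.

All structural fixtures are generated programmatically; nothing is
read from checked-in data files.
"""

from __future__ import annotations

import numpy as np
import pytest

from pkalens.bprime import BPrimeProfile, NormalizationReport
from pkalens.structure_io import (
    AtomRecord,
    Chain,
    HetGroup,
    Residue,
    ResidueId,
    StructureModel,
)
from pkalens.synthetic import generate_corpus
from pkalens import pipeline


def build_model(
    structure_id: str,
    chains: dict[str, list[tuple[int, str, list[tuple[str, str, tuple, float, float, str]]]]],
    het: list[tuple[str, str, int]] | None = None,
) -> StructureModel:
    """Assemble a StructureModel directly in memory.

    ``chains`` maps chain_id to residues, each
    ``(residue_seq, residue_name, atoms)`` with atoms
    ``(atom_name, element, position, occupancy, b_factor, altloc)``.
    ``het`` lists (het_code, chain_id, residue_seq) one-atom groups.
    """
    serial = 1
    model = StructureModel(structure_id=structure_id)
    for chain_id, residues in chains.items():
        chain = Chain(chain_id=chain_id)
        for res_seq, res_name, atoms in residues:
            rid = ResidueId(chain_id=chain_id, residue_seq=res_seq)
            res = Residue(rid=rid, name=res_name)
            for atom_name, element, pos, occ, b, altloc in atoms:
                res.atoms.append(
                    AtomRecord(
                        serial=serial, atom_name=atom_name, altloc=altloc,
                        residue_name=res_name, chain_id=chain_id,
                        residue_seq=res_seq, insertion_code="",
                        position=np.asarray(pos, dtype=float),
                        occupancy=occ, b_factor=b, element=element,
                    )
                )
                serial += 1
            chain.residues.append(res)
        model.polymer_chains.append(chain)
    for het_code, chain_id, res_seq in het or []:
        rid = ResidueId(chain_id=chain_id, residue_seq=res_seq)
        model.het_groups.append(
            HetGroup(
                het_code=het_code, rid=rid,
                atoms=[
                    AtomRecord(
                        serial=serial, atom_name="C1", altloc="",
                        residue_name=het_code, chain_id=chain_id,
                        residue_seq=res_seq, insertion_code="",
                        position=np.zeros(3), occupancy=1.0, b_factor=20.0,
                        element="C",
                    )
                ],
            )
        )
        serial += 1
    return model


def make_profiles(
    matrix: np.ndarray,
    structure_ids: list[str] | None = None,
    residue_seqs: list[int] | None = None,
) -> list[BPrimeProfile]:
    """Wrap a (structures x residues) array as B' profiles."""
    n, p = matrix.shape
    sids = structure_ids or [f"S{i:03d}" for i in range(n)]
    seqs = residue_seqs or list(range(40, 40 + p))
    dummy = NormalizationReport(
        median_b=0.0, mad=0.0, mean_b=0.0, sd_b=1.0,
        excluded_atoms=frozenset(), n_included=p,
    )
    profiles = []
    for i, sid in enumerate(sids):
        values = {
            ResidueId(chain_id="A", residue_seq=s): float(matrix[i, j])
            for j, s in enumerate(seqs)
        }
        profiles.append(
            BPrimeProfile(
                structure_id=sid, chain_id="A", selection="backbone",
                values=values, residue_names={}, report=dummy,
            )
        )
    return profiles


@pytest.fixture(scope="session")
def small_corpus(tmp_path_factory):
    """A 22-structure synthetic corpus with default planted effects."""
    out = tmp_path_factory.mktemp("small_corpus")
    manifest = generate_corpus(
        out,
        per_state_counts={"substrate_product": 6, "inhibitor": 8, "apo": 5, "peptide": 3},
        seed=11,
    )
    models = pipeline.load_corpus(out.glob("*.pdb"))
    truth = {s["structure_id"]: s["state"] for s in manifest["structures"]}
    return {"dir": out, "manifest": manifest, "models": models, "truth": truth}


@pytest.fixture(scope="session")
def study_corpus(tmp_path_factory):
    """The full 115-structure corpus at the default study composition."""
    out = tmp_path_factory.mktemp("study_corpus")
    manifest = generate_corpus(out, seed=20230)
    models = pipeline.load_corpus(out.glob("*.pdb"))
    truth = {s["structure_id"]: s["state"] for s in manifest["structures"]}
    return {"dir": out, "manifest": manifest, "models": models, "truth": truth}
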