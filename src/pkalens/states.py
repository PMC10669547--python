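"""Catalytic-state classification of kinase structures from active-site contents.

A PKA catalytic-subunit structure is assigned exactly one of four
ligand-defined catalytic-cycle states:

``substrate_product``
    ATP or ADP bound (with or without a substrate peptide).
``inhibitor``
    A non-hydrolysable nucleotide analogue (AMP-PNP) or a Type-I
    ATP-competitive inhibitor bound, with or without a peptide.
``peptide``
    No small molecule in the active site but a short peptide chain
    present (e.g. PKI fragments or substrate peptides).
``apo``
    Neither small molecule nor peptide.

The priority order substrate_product > inhibitor > peptide > apo is
total: nucleotide identity wins over peptide presence. Classification is
by ligand identity only — no geometric active-site occupancy check is
performed, mirroring how such corpora are conventionally curated.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

from .structure_io import StructureModel

__all__ = [
    "STATES",
    "LigandDictionary",
    "UnclassifiableStructureError",
    "classify",
]

STATES = ("substrate_product", "inhibitor", "apo", "peptide")

# Modified residues and crystallization additives that say nothing about
# the catalytic state. Phospho-residues (TPO/SEP/PTR) are covalent parts
# of the kinase chain that many files write as HETATM records.
_DEFAULT_IGNORE = frozenset(
    {
        "HOH", "WAT", "DOD", "H2O",          # waters
        "MG", "MN", "NA", "CL", "K", "ZN", "CA", "IOD", "BR",  # ions
        "SO4", "PO4", "ACT", "GOL", "EDO", "DMS", "PEG", "PGE",
        "MPD", "TRS", "FMT", "NO3", "MES", "EPE",  # cryo/buffer additives
        "TPO", "SEP", "PTR", "CME", "OCS", "MSE", "KCX", "LLP",  # modified residues
        "MYR",  # N-terminal myristoylation of the kinase chain
    }
)

# Type-I inhibitors seen in PKA catalytic-subunit entries; the list is a
# seed, not a registry — unknown codes raise, forcing explicit curation.
_DEFAULT_INHIBITORS = frozenset({"ANP", "STU", "ADN"})


@dataclass(frozen=True)
class LigandDictionary:
    """Het-code sets that drive state assignment.

    ``sp_codes`` mark the substrate/product state, ``inhibitor_codes``
    the inhibitor state, and ``ignore_codes`` are invisible to the
    classifier. ``peptide_max_length`` separates short bound peptides
    from the ~350-residue kinase chain; for this corpus any threshold
    between ~30 and ~300 gives the same answer.
    """

    sp_codes: frozenset[str] = frozenset({"ATP", "ADP"})
    inhibitor_codes: frozenset[str] = _DEFAULT_INHIBITORS
    ignore_codes: frozenset[str] = _DEFAULT_IGNORE
    peptide_max_length: int = 30

    def __post_init__(self) -> None:
        object.__setattr__(self, "sp_codes", frozenset(self.sp_codes))
        object.__setattr__(self, "inhibitor_codes", frozenset(self.inhibitor_codes))
        object.__setattr__(self, "ignore_codes", frozenset(self.ignore_codes))
        if self.sp_codes & self.inhibitor_codes:
            raise ValueError(
                "sp_codes and inhibitor_codes overlap: "
                f"{sorted(self.sp_codes & self.inhibitor_codes)}"
            )

    @classmethod
    def from_json(cls, path: str | Path) -> "LigandDictionary":
        """Load a dictionary from a JSON config.

        Recognised keys: ``sp_codes``, ``inhibitor_codes``,
        ``ignore_codes`` (lists of het codes), ``peptide_max_length``.
        Absent keys keep their defaults; ``extra_inhibitor_codes`` and
        ``extra_ignore_codes`` extend rather than replace.
        """
        data = json.loads(Path(path).read_text())
        kwargs: dict = {}
        for key in ("sp_codes", "inhibitor_codes", "ignore_codes"):
            if key in data:
                kwargs[key] = frozenset(data[key])
        if "peptide_max_length" in data:
            kwargs["peptide_max_length"] = int(data["peptide_max_length"])
        base = cls(**kwargs)
        if "extra_inhibitor_codes" in data:
            base = LigandDictionary(
                sp_codes=base.sp_codes,
                inhibitor_codes=base.inhibitor_codes | frozenset(data["extra_inhibitor_codes"]),
                ignore_codes=base.ignore_codes,
                peptide_max_length=base.peptide_max_length,
            )
        if "extra_ignore_codes" in data:
            base = LigandDictionary(
                sp_codes=base.sp_codes,
                inhibitor_codes=base.inhibitor_codes,
                ignore_codes=base.ignore_codes | frozenset(data["extra_ignore_codes"]),
                peptide_max_length=base.peptide_max_length,
            )
        return base


class UnclassifiableStructureError(ValueError):
    """A het code is in neither the state dictionaries nor the ignore list."""

    def __init__(self, structure_id: str, codes: set[str]):
        self.structure_id = structure_id
        self.codes = sorted(codes)
        super().__init__(
            f"structure {structure_id}: unrecognised het code(s) {self.codes}; "
            "extend the LigandDictionary (inhibitor_codes / ignore_codes) "
            "to classify this structure"
        )


def classify(model: StructureModel, lig_dict: LigandDictionary | None = None) -> str:
    """Assign one catalytic-cycle state label to a structure.

    Unknown het codes raise :class:`UnclassifiableStructureError` rather
    than being guessed into a state — the dictionary must be extended
    explicitly. The result is invariant to chain order and to waters,
    ions and other ignored groups.
    """
    if lig_dict is None:
        lig_dict = LigandDictionary()
    if not model.polymer_chains:
        raise ValueError(f"structure {model.structure_id} has no polymer chains")

    het_codes = {h.het_code for h in model.het_groups}
    unknown = het_codes - lig_dict.sp_codes - lig_dict.inhibitor_codes - lig_dict.ignore_codes
    if unknown:
        raise UnclassifiableStructureError(model.structure_id, unknown)

    if het_codes & lig_dict.sp_codes:
        return "substrate_product"
    if het_codes & lig_dict.inhibitor_codes:
        return "inhibitor"
    if any(len(ch) <= lig_dict.peptide_max_length for ch in model.polymer_chains):
        return "peptide"
    return "apo"
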