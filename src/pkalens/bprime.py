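"""Normalized temperature factors (B′) for one chain.

Raw crystallographic B-factors are not comparable across structures:
they absorb resolution, refinement protocol and lattice order. The B′
normalization makes per-residue flexibility profiles comparable by

1. collapsing altloc conformers to an occupancy-weighted effective
   B-factor per atom, ``B_i = Σ_I π_I B(i,I)``;
2. excluding outlier atoms by the modified z-score
   ``M(i) = 0.6745 |B_i − B~| / MAD`` with cutoff 3.5 (single pass);
3. z-scoring the surviving atoms, ``B′(a) = (B_a − B̄) / σ``;
4. aggregating atoms to residues by an atomic-mass-weighted mean,
   ``B′(i) = Σ_a M_a B′(a) / Σ_a M_a``.

Each chain is normalized independently (one molecule = one profile),
and each atom selection (all heavy atoms, backbone N/CA/C/O, or Cα
only) is self-contained: its median, MAD, mean and standard deviation
are computed over that selection alone.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Literal, Sequence

import gemmi
import numpy as np

from .structure_io import ResidueId, StructureModel, effective_b

logger = logging.getLogger(__name__)

__all__ = [
    "NormalizationReport",
    "BPrimeProfile",
    "modified_zscores",
    "exclude_outliers",
    "normalize_chain",
    "BACKBONE_ATOMS",
]

Selection = Literal["all_atom", "backbone", "calpha"]

BACKBONE_ATOMS = ("N", "CA", "C", "O")

#: Consistency constant relating MAD to σ for Gaussian data.
MZ_CONSISTENCY = 0.6745

#: Default modified-z cutoff for outlier exclusion.
MZ_CUTOFF = 3.5


@dataclass(frozen=True)
class NormalizationReport:
    """Chain-level statistics behind one B′ profile.

    ``median_b``/``mad`` drive the outlier filter; ``mean_b``/``sd_b``
    are computed on the post-exclusion survivors and define the
    z-scoring. ``excluded_atoms`` holds (ResidueId, atom_name) pairs.
    ``sd_convention`` records that σ is the sample standard deviation
    (n−1 denominator).
    """

    median_b: float
    mad: float
    mean_b: float
    sd_b: float
    excluded_atoms: frozenset[tuple[ResidueId, str]]
    n_included: int
    mad_method: str = "absolute"
    sd_convention: str = "sample"


@dataclass
class BPrimeProfile:
    """Per-residue normalized B-factors for one chain."""

    structure_id: str
    chain_id: str
    selection: Selection
    values: dict[ResidueId, float]
    residue_names: dict[ResidueId, str]
    report: NormalizationReport

    def as_series(self):
        import pandas as pd

        idx = sorted(self.values)
        return pd.Series(
            [self.values[k] for k in idx],
            index=[(k.residue_seq, k.insertion_code) for k in idx],
            name=f"{self.structure_id}:{self.chain_id}",
        )


def modified_zscores(
    b_values: Sequence[float] | np.ndarray,
    method: Literal["absolute", "squared"] = "absolute",
) -> np.ndarray:
    """Median-based modified z-scores M(i) of a B-factor sample.

    ``M(i) = 0.6745 · |B_i − B~| / MAD`` with ``B~`` the median and
    ``MAD`` the median absolute deviation (default). The ``squared``
    variant uses the median of squared deviations as the denominator
    instead; it is provided for comparison but pairs oddly with the
    0.6745 consistency constant and is not the default. When MAD is 0
    (constant or near-constant data) all scores are 0 and nothing can
    be flagged.
    """
    b = np.asarray(b_values, dtype=float)
    if b.size == 0:
        raise ValueError("modified_zscores requires at least one value")
    med = np.median(b)
    dev = np.abs(b - med)
    if method == "absolute":
        mad = np.median(dev)
    elif method == "squared":
        mad = np.median(dev**2)
    else:
        raise ValueError(f"unknown MAD method {method!r}")
    if mad == 0:
        return np.zeros_like(b)
    return MZ_CONSISTENCY * dev / mad


def exclude_outliers(
    b_values: Sequence[float] | np.ndarray,
    cutoff: float = MZ_CUTOFF,
    method: Literal["absolute", "squared"] = "absolute",
) -> tuple[np.ndarray, float, float, float, float]:
    """Single-pass modified-z outlier exclusion.

    Returns ``(included_mask, median, mad, mean, sd)`` where mean and
    sample standard deviation are computed over the survivors only.
    The filter is deliberately one-pass: exclusion is not iterated.
    """
    b = np.asarray(b_values, dtype=float)
    if b.size < 2:
        raise ValueError("outlier exclusion requires at least two values")
    med = float(np.median(b))
    dev = np.abs(b - med)
    mad = float(np.median(dev if method == "absolute" else dev**2))
    scores = modified_zscores(b, method=method)
    included = scores <= cutoff
    if not included.any():  # unreachable: the median always scores 0
        raise RuntimeError("outlier filter excluded every atom")
    survivors = b[included]
    mean = float(survivors.mean())
    sd = float(survivors.std(ddof=1)) if survivors.size > 1 else 0.0
    return included, med, mad, mean, sd


# standard atomic weights (IUPAC abridged) for the elements that occur
# in protein heavy atoms; anything else falls back to gemmi's table
_ATOMIC_WEIGHTS = {
    "C": 12.011, "N": 14.007, "O": 15.999, "S": 32.06,
    "P": 30.974, "SE": 78.971,
}


def _atomic_mass(element: str) -> float:
    try:
        return _ATOMIC_WEIGHTS[element.upper()]
    except KeyError:
        return float(gemmi.Element(element).weight)


def normalize_chain(
    model: StructureModel,
    chain_id: str,
    selection: Selection = "backbone",
    cutoff: float = MZ_CUTOFF,
    mad_method: Literal["absolute", "squared"] = "absolute",
) -> BPrimeProfile:
    """Compute the B′ profile of one chain.

    Pipeline: occupancy-weighted effective B per atom identity →
    restrict to the atom selection → modified-z outlier exclusion over
    the chain's selected atoms → atom-level z-score → mass-weighted
    per-residue mean over the residue's included atoms. Residues whose
    selected atoms are all excluded or unresolved get no value.

    Raises
    ------
    ValueError
        If the chain is missing, has fewer than two selected atoms, or
        the post-exclusion standard deviation is zero (degenerate
        chain; z-scores undefined).
    """
    chain = model.chain(chain_id)
    if chain is None:
        raise ValueError(f"{model.structure_id}: no chain {chain_id!r}")

    # One entry per atom identity; altloc conformers collapse here.
    entries: list[tuple[ResidueId, str, float, float]] = []  # rid, name, eff_b, mass
    res_names: dict[ResidueId, str] = {}
    for res in chain:
        res_names[res.rid] = res.name
        groups: dict[str, list] = {}
        for atom in res.atoms:
            if selection == "calpha" and atom.atom_name != "CA":
                continue
            if selection == "backbone" and atom.atom_name not in BACKBONE_ATOMS:
                continue
            groups.setdefault(atom.atom_name, []).append(atom)
        for atom_name, conformers in groups.items():
            entries.append(
                (
                    res.rid,
                    atom_name,
                    effective_b(conformers),
                    _atomic_mass(conformers[0].element),
                )
            )

    if len(entries) < 2:
        raise ValueError(
            f"{model.structure_id} chain {chain_id}: fewer than 2 atoms in "
            f"selection {selection!r}"
        )

    b = np.array([e[2] for e in entries])
    included, med, mad, mean, sd = exclude_outliers(b, cutoff=cutoff, method=mad_method)
    if sd == 0:
        raise ValueError(
            f"{model.structure_id} chain {chain_id}: zero B-factor variance "
            "after exclusion; profile undefined"
        )
    excluded = frozenset(
        (e[0], e[1]) for e, keep in zip(entries, included) if not keep
    )
    for rid, name in sorted(excluded, key=lambda x: (x[0], x[1])):
        logger.info(
            "%s chain %s: excluded outlier atom %s %d%s",
            model.structure_id, chain_id, name, rid.residue_seq, rid.insertion_code,
        )

    b_prime = (b - mean) / sd
    values: dict[ResidueId, float] = {}
    by_res: dict[ResidueId, list[tuple[float, float]]] = {}
    for (rid, _name, _eb, mass), keep, bp in zip(entries, included, b_prime):
        if keep:
            by_res.setdefault(rid, []).append((mass, bp))
    for rid, pairs in by_res.items():
        total_mass = sum(m for m, _ in pairs)
        values[rid] = sum(m * bp for m, bp in pairs) / total_mass

    report = NormalizationReport(
        median_b=med,
        mad=mad,
        mean_b=mean,
        sd_b=sd,
        excluded_atoms=excluded,
        n_included=int(included.sum()),
        mad_method=mad_method,
    )
    return BPrimeProfile(
        structure_id=model.structure_id,
        chain_id=chain_id,
        selection=selection,
        values=values,
        residue_names=res_names,
        report=report,
    )
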