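"""Synthetic kinase-like PDB fixtures with fully known ground truth.

The generator writes wwPDB-v3.3 fixed-width PDB files that look like a
PKA catalytic subunit to any parser — a ~310-residue chain numbered
40–350 with backbone atoms, state-specific active-site het groups
(ATP/ADP/AMP-PNP), optional short peptide chains, waters and ions,
altloc conformers with occupancies, and a configurable B-factor field —
while every quantity the analysis pipeline measures is planted and
recorded in a JSON-able manifest: marker-residue coordinates and all
their pairwise distances, the state label, per-region B-factor means,
injected outlier atoms and altloc effective B-factors.

The marker residues are the probe residues of the built-in distance
triplets (51, 52, 53, 54, 72, 81, 87, 95, 104, 113, 127, 154, 173,
185, 223, 328). Their default positions reproduce the within-triplet
distance geometry typical of nucleotide-bound PKA; non-marker residues
follow an ideal helix trace whose geometry carries no signal. This is
a measurement fixture, not a physical model of the kinase.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

__all__ = [
    "MARKER_RESIDUES",
    "DEFAULT_MARKER_POSITIONS",
    "AltlocSpec",
    "SyntheticSpec",
    "generate",
    "generate_corpus",
    "DEFAULT_STATE_COUNTS",
    "DEFAULT_DISPLACEMENT_RULES",
    "DEFAULT_B_REGION_RULES",
]

#: residue_seq -> 3-letter residue name for each probe residue.
MARKER_RESIDUES = {
    51: "THR", 52: "GLY", 53: "SER", 54: "PHE",
    72: "LYS", 81: "LYS", 87: "HIS", 95: "LEU",
    104: "VAL", 113: "ASN", 127: "GLU", 154: "PHE",
    173: "LEU", 185: "PHE", 223: "ALA", 328: "ASP",
}

# Cα positions (CZ for residue 185) chosen so each built-in triplet
# reproduces distances typical of the nucleotide-bound kinase; the five
# triplet neighbourhoods are spatially separated so planted
# displacements never couple across metrics.
DEFAULT_MARKER_POSITIONS: dict[int, np.ndarray] = {
    51: np.array([19.700, 0.000, 0.000]),
    52: np.array([5.485, 12.226, 60.000]),
    53: np.array([2.171, 19.379, 0.000]),
    54: np.array([0.000, 60.000, 0.000]),
    72: np.array([60.000, 0.000, 0.000]),
    81: np.array([87.200, 60.000, 0.000]),
    87: np.array([14.091, 13.480, 0.000]),
    95: np.array([71.417, 5.090, 0.000]),
    104: np.array([60.000, 60.000, 0.000]),
    113: np.array([81.468, 75.366, 0.000]),
    127: np.array([9.600, 0.000, 60.000]),
    154: np.array([19.079, 76.000, 0.000]),
    173: np.array([19.000, 60.000, 0.000]),
    185: np.array([74.400, 0.000, 0.000]),
    223: np.array([0.000, 0.000, 0.000]),
    328: np.array([0.000, 0.000, 60.000]),
}

_STATE_LIGAND = {
    "substrate_product": "ATP",
    "inhibitor": "ANP",
    "peptide": None,
    "apo": None,
}

# Minimal heavy-atom subsets for the nucleotide het groups; enough for
# realistic-looking HETATM records, irrelevant to any measurement.
_LIGAND_ATOMS = {
    "ATP": [("PG", "P"), ("PB", "P"), ("PA", "P"), ("O5'", "O"),
            ("C5'", "C"), ("C4'", "C"), ("C1'", "C"), ("N9", "N"), ("C8", "C")],
    "ADP": [("PB", "P"), ("PA", "P"), ("O5'", "O"), ("C5'", "C"),
            ("C4'", "C"), ("C1'", "C"), ("N9", "N"), ("C8", "C")],
    "ANP": [("PG", "P"), ("N3B", "N"), ("PB", "P"), ("PA", "P"), ("O5'", "O"),
            ("C5'", "C"), ("C1'", "C"), ("N9", "N"), ("C8", "C")],
}

_PEPTIDE_NAMES = ["GLY", "ALA", "SER", "THR", "ARG"]


@dataclass(frozen=True)
class AltlocSpec:
    """Emit an atom as several conformers: [(occupancy, b_factor), ...]."""

    residue_seq: int
    atom_name: str
    conformers: tuple[tuple[float, float], ...]

    def effective_b(self) -> float:
        return float(sum(occ * b for occ, b in self.conformers))


@dataclass(frozen=True)
class SyntheticSpec:
    """Full recipe for one synthetic structure.

    ``b_region_means`` maps inclusive residue ranges to a mean raw
    B-factor (Å²); residues outside every range use ``base_b``. Noise
    is Gaussian truncated at 0 (B-factors are non-negative).
    ``marker_shifts`` are exact displacement vectors added to marker
    positions (how planted state effects are injected);
    ``position_jitter_sd`` adds per-coordinate Gaussian jitter to the
    marker atoms to emulate between-structure conformational noise.
    """

    structure_id: str = "SYN001"
    state: str = "apo"
    n_chains: int = 1
    residue_first: int = 40
    residue_last: int = 350
    marker_positions: dict[int, np.ndarray] = field(
        default_factory=lambda: dict(DEFAULT_MARKER_POSITIONS)
    )
    marker_shifts: dict[int, np.ndarray] = field(default_factory=dict)
    position_jitter_sd: float = 0.0
    base_b: float = 20.0
    b_region_means: dict[tuple[int, int], float] = field(default_factory=dict)
    b_noise_sd: float = 4.0
    outliers: tuple[tuple[int, str, float], ...] = ()  # (residue_seq, atom_name, B)
    altlocs: tuple[AltlocSpec, ...] = ()
    peptide_length: int = 0  # 0 = no peptide chain
    include_waters: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.state not in _STATE_LIGAND:
            raise ValueError(f"unknown state {self.state!r}")
        pos = {k: np.asarray(v, dtype=float) for k, v in self.marker_positions.items()}
        keys = sorted(pos)
        for i, a in enumerate(keys):
            for b in keys[i + 1:]:
                if np.linalg.norm(pos[a] - pos[b]) < 1e-6:
                    raise ValueError(f"marker collision: residues {a} and {b}")
        object.__setattr__(self, "marker_positions", pos)
        object.__setattr__(
            self,
            "marker_shifts",
            {k: np.asarray(v, dtype=float) for k, v in self.marker_shifts.items()},
        )


def _fmt_atom(
    serial: int, name: str, altloc: str, resname: str, chain: str, resseq: int,
    pos: np.ndarray, occ: float, b: float, element: str, het: bool = False,
) -> str:
    record = "HETATM" if het else "ATOM  "
    if len(name) < 4:
        name_field = f" {name:<3s}"
    else:
        name_field = name
    return (
        f"{record}{serial:5d} {name_field}{altloc or ' '}{resname:>3s} {chain}"
        f"{resseq:4d}    {pos[0]:8.3f}{pos[1]:8.3f}{pos[2]:8.3f}"
        f"{occ:6.2f}{b:6.2f}          {element:>2s}\n"
    )


def _backbone_offsets() -> dict[str, np.ndarray]:
    # Rigid local frame around each Cα; bond-length-scaled so files look
    # plausible to geometry-aware parsers.
    return {
        "N": np.array([-1.458, 0.0, 0.0]),
        "CA": np.zeros(3),
        "C": np.array([1.525, 0.0, 0.0]),
        "O": np.array([1.525, 1.231, 0.0]),
    }


def _helix_trace(n: int, origin: np.ndarray) -> np.ndarray:
    """Ideal-helix Cα trace: 1.5 Å rise, 2.3 Å radius, 100°/residue."""
    k = np.arange(n)
    theta = np.deg2rad(100.0) * k
    return origin + np.stack(
        [2.3 * np.cos(theta), 2.3 * np.sin(theta), 1.5 * k], axis=1
    )


def generate(spec: SyntheticSpec, out_path: str | Path) -> dict:
    """Write one synthetic PDB file; return its ground-truth manifest.

    The same spec (same seed) always produces byte-identical output.
    The manifest records, per chain, the marker coordinates exactly as
    written (3-decimal precision) and every pairwise marker distance
    computed from those written coordinates, plus the state label,
    ligand content, B-field recipe, injected outliers and altloc
    effective B-factors.
    """
    out_path = Path(out_path)
    rng = np.random.default_rng(spec.seed)
    offsets = _backbone_offsets()
    residues = list(range(spec.residue_first, spec.residue_last + 1))
    filler = _helix_trace(len(residues), np.array([150.0, 150.0, -50.0]))

    region_mean = {}
    for (lo, hi), mean in spec.b_region_means.items():
        for r in range(lo, hi + 1):
            region_mean[r] = mean

    def draw_b(res_seq: int) -> float:
        mean = region_mean.get(res_seq, spec.base_b)
        return max(0.01, float(mean + rng.normal(0.0, spec.b_noise_sd)))

    altloc_by_key = {(al.residue_seq, al.atom_name): al for al in spec.altlocs}
    outlier_by_key = {(r, a): b for r, a, b in spec.outliers}

    lines: list[str] = [f"REMARK 250 SYNTHETIC KINASE FIXTURE {spec.structure_id}\n"]
    serial = 1
    chain_ids = [chr(ord("A") + i) for i in range(spec.n_chains)]
    manifest_chains: dict[str, dict] = {}
    altloc_truth: list[dict] = []
    outlier_truth: list[dict] = []

    for ci, chain_id in enumerate(chain_ids):
        chain_offset = np.array([0.0, 0.0, 400.0 * ci])
        marker_written: dict[int, np.ndarray] = {}
        for ri, res_seq in enumerate(residues):
            resname = MARKER_RESIDUES.get(res_seq, "ALA")
            if res_seq in spec.marker_positions:
                ca = spec.marker_positions[res_seq].copy()
                ca += spec.marker_shifts.get(res_seq, 0.0)
                if spec.position_jitter_sd > 0:
                    ca = ca + rng.normal(0.0, spec.position_jitter_sd, 3)
            else:
                ca = filler[ri]
            ca = ca + chain_offset
            if res_seq == 185:
                # the probe atom for the DFG phenylalanine is the ring
                # tip CZ: put it exactly at the marker point and hang
                # the backbone off it
                atom_plan = [(name, name[0], ca + np.array([0.0, 4.2, 0.0]) + off)
                             for name, off in offsets.items()]
                atom_plan.append(("CZ", "C", ca.copy()))
            else:
                atom_plan = [(name, name[0], ca + off) for name, off in offsets.items()]
            for name, element, pos in atom_plan:
                key = (res_seq, name)
                probe_name = "CZ" if res_seq == 185 else "CA"
                if name == probe_name and res_seq in spec.marker_positions:
                    marker_written[res_seq] = np.round(pos, 3)
                if key in altloc_by_key and ci == 0:
                    al = altloc_by_key[key]
                    for j, (occ, b_val) in enumerate(al.conformers):
                        shift = np.array([0.25 * j, 0.0, 0.0])
                        lines.append(
                            _fmt_atom(serial, name, chr(ord("A") + j), resname,
                                      chain_id, res_seq, pos + shift, occ, b_val, element)
                        )
                        serial += 1
                    altloc_truth.append(
                        {"chain_id": chain_id, "residue_seq": res_seq,
                         "atom_name": name, "effective_b": al.effective_b()}
                    )
                    continue
                if key in outlier_by_key and ci == 0:
                    b_val = outlier_by_key[key]
                    outlier_truth.append(
                        {"chain_id": chain_id, "residue_seq": res_seq,
                         "atom_name": name, "b_factor": b_val}
                    )
                else:
                    b_val = draw_b(res_seq)
                lines.append(
                    _fmt_atom(serial, name, "", resname, chain_id, res_seq,
                              pos, 1.00, b_val, element)
                )
                serial += 1
        lines.append(f"TER   {serial:5d}      {MARKER_RESIDUES.get(residues[-1], 'ALA'):>3s} "
                     f"{chain_id}{residues[-1]:4d}\n")
        serial += 1

        # marker truth uses written (rounded) coordinates
        dists = {}
        keys = sorted(marker_written)
        # 185 truth is the CZ probe; everything else CA
        for i, a in enumerate(keys):
            for b in keys[i + 1:]:
                dists[f"{a}-{b}"] = float(
                    np.linalg.norm(marker_written[a] - marker_written[b])
                )
        manifest_chains[chain_id] = {
            "marker_coords": {str(k): [float(x) for x in v] for k, v in marker_written.items()},
            "marker_distances": dists,
        }

    # peptide chain (short polymer, no het identity)
    if spec.peptide_length > 0:
        pep_chain = chr(ord("A") + spec.n_chains)
        trace = _helix_trace(spec.peptide_length, np.array([-80.0, -80.0, 0.0]))
        for i in range(spec.peptide_length):
            resname = _PEPTIDE_NAMES[i % len(_PEPTIDE_NAMES)]
            for name, off in offsets.items():
                lines.append(
                    _fmt_atom(serial, name, "", resname, pep_chain, i + 1,
                              trace[i] + off, 1.00, draw_b(-1), name[0])
                )
                serial += 1
        lines.append(f"TER   {serial:5d}      {_PEPTIDE_NAMES[(spec.peptide_length - 1) % len(_PEPTIDE_NAMES)]:>3s} "
                     f"{pep_chain}{spec.peptide_length:4d}\n")
        serial += 1

    het_code = _STATE_LIGAND[spec.state]
    if het_code is not None:
        anchor = np.array([12.0, 6.0, 4.0])  # active-site cleft region
        for j, (name, element) in enumerate(_LIGAND_ATOMS[het_code]):
            pos = anchor + np.array([1.4 * j, 0.3 * (j % 3), 0.2 * j])
            lines.append(
                _fmt_atom(serial, name, "", het_code, "X", 401 + 0,
                          pos, 1.00, draw_b(-1), element, het=True)
            )
            serial += 1
        lines.append(_fmt_atom(serial, "MG", "", "MG", "X", 402,
                               anchor + np.array([-2.0, 1.0, 0.5]), 1.00,
                               draw_b(-1), "MG", het=True))
        serial += 1
    if spec.include_waters:
        for j in range(3):
            lines.append(
                _fmt_atom(serial, "O", "", "HOH", "W", 501 + j,
                          np.array([30.0 + 5 * j, 30.0, 30.0]), 1.00,
                          draw_b(-1), "O", het=True)
            )
            serial += 1
    lines.append("END\n")
    out_path.write_text("".join(lines))

    return {
        "structure_id": spec.structure_id,
        "path": str(out_path),
        "state": spec.state,
        "ligand": het_code,
        "n_chains": spec.n_chains,
        "peptide_length": spec.peptide_length,
        "chains": manifest_chains,
        "base_b": spec.base_b,
        "b_region_means": {f"{lo}-{hi}": m for (lo, hi), m in spec.b_region_means.items()},
        "b_noise_sd": spec.b_noise_sd,
        "outliers": outlier_truth,
        "altlocs": altloc_truth,
        "seed": spec.seed,
    }


#: Corpus composition of the analyzed PKA ensemble.
DEFAULT_STATE_COUNTS = {
    "substrate_product": 37,
    "inhibitor": 60,
    "apo": 15,
    "peptide": 3,
}

#: Planted conformational effect: in apo structures the G-loop probe
#: T51 moves 4 Å away from the αF anchor A223 (lobe opening).
DEFAULT_DISPLACEMENT_RULES: dict[str, tuple[tuple[int, int, float], ...]] = {
    "apo": ((51, 223, 4.0),),
}

#: Planted flexibility effect: apo structures carry an elevated raw-B
#: band over the αD-helix region (residues 120-139).
DEFAULT_B_REGION_RULES: dict[str, dict[tuple[int, int], float]] = {
    "apo": {(120, 139): 32.0},
}


def generate_corpus(
    out_dir: str | Path,
    per_state_counts: Optional[dict[str, int]] = None,
    displacement_rules: Optional[dict[str, Sequence[tuple[int, int, float]]]] = None,
    b_region_rules: Optional[dict[str, dict[tuple[int, int], float]]] = None,
    position_jitter_sd: float = 0.35,
    base_spec: Optional[SyntheticSpec] = None,
    seed: int = 0,
) -> dict:
    """Generate a corpus of synthetic structures plus a corpus manifest.

    Defaults emulate the analyzed PKA ensemble: 37 substrate/product,
    60 inhibitor, 15 apo and 3 peptide structures (115 total); apo
    structures carry a +4 Å T51→A223 displacement (lobe opening) and an
    elevated raw-B band over the αD region; every structure gets
    0.35 Å/coordinate marker jitter (≈0.5 Å distance noise, matching
    the within-state spread of the real tables), two injected
    high-B outlier atoms and one two-conformer altloc group. A minority
    of structures carry two kinase copies in the asymmetric unit, and
    substrate/product structures alternate with/without a bound
    peptide.

    Returns the corpus manifest (also written to
    ``out_dir/corpus_manifest.json``): per-structure ground truth plus
    the displacement and B-region rules actually applied.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    counts = dict(DEFAULT_STATE_COUNTS if per_state_counts is None else per_state_counts)
    disp = dict(DEFAULT_DISPLACEMENT_RULES if displacement_rules is None else displacement_rules)
    b_rules = dict(DEFAULT_B_REGION_RULES if b_region_rules is None else b_region_rules)
    base = base_spec or SyntheticSpec()
    rng = np.random.default_rng(seed)

    structures = []
    prefix = {"substrate_product": "SPR", "inhibitor": "INH", "apo": "APO", "peptide": "PEP"}
    for state in ("substrate_product", "inhibitor", "apo", "peptide"):
        for i in range(counts.get(state, 0)):
            sid = f"{prefix[state]}{i + 1:03d}"
            shifts: dict[int, np.ndarray] = {}
            planted = []
            for res_move, res_ref, delta in disp.get(state, ()):
                direction = base.marker_positions[res_move] - base.marker_positions[res_ref]
                direction = direction / np.linalg.norm(direction)
                shifts[res_move] = shifts.get(res_move, np.zeros(3)) + delta * direction
                planted.append({"move": res_move, "away_from": res_ref, "delta": delta})

            # two high-B outlier atoms and one altloc group per structure
            out_res = rng.choice(np.arange(base.residue_first + 5, base.residue_last - 5),
                                 size=2, replace=False)
            outliers = tuple((int(r), "O", 150.0 + float(rng.uniform(0, 30))) for r in out_res)
            al_res = int(rng.choice(np.arange(base.residue_first + 5, base.residue_last - 5)))
            altlocs = (AltlocSpec(al_res, "CA", ((0.6, 18.0), (0.4, 26.0))),)

            n_chains = 2 if (i % 5 == 4) else 1
            peptide_len = 0
            if state == "peptide":
                peptide_len = 20
            elif state == "substrate_product" and i % 2 == 0:
                peptide_len = 20
            elif state == "inhibitor" and i % 4 == 0:
                # inhibitor-bound entries may also carry a peptide;
                # nucleotide identity still decides the state
                peptide_len = 20

            spec = replace(
                base,
                structure_id=sid,
                state=state,
                n_chains=n_chains,
                marker_shifts=shifts,
                position_jitter_sd=position_jitter_sd,
                b_region_means=dict(b_rules.get(state, {})),
                outliers=outliers,
                altlocs=altlocs,
                peptide_length=peptide_len,
                seed=int(rng.integers(0, 2**31 - 1)),
            )
            manifest = generate(spec, out_dir / f"{sid}.pdb")
            manifest["planted_displacements"] = planted
            structures.append(manifest)

    corpus = {
        "n_structures": len(structures),
        "per_state_counts": {s: counts.get(s, 0) for s in prefix},
        "displacement_rules": {
            s: [list(r) for r in rules] for s, rules in disp.items()
        },
        "b_region_rules": {
            s: {f"{lo}-{hi}": m for (lo, hi), m in rules.items()}
            for s, rules in b_rules.items()
        },
        "position_jitter_sd": position_jitter_sd,
        "seed": seed,
        "structures": structures,
    }
    (out_dir / "corpus_manifest.json").write_text(json.dumps(corpus, indent=1))
    return corpus
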