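# Methods

`pkalens` analyses ensembles of protein kinase A (PKA) catalytic-subunit
crystal structures for ligand-dependent conformational and flexibility
signal. This note records the models, the defaults and the numerical
choices, and what the synthetic fixtures do and do not establish.

## Catalytic-state model

Each structure is assigned exactly one of four states from its
active-site contents:

| state | definition |
|---|---|
| `substrate_product` | ATP or ADP bound, with or without a substrate peptide |
| `inhibitor` | AMP-PNP (het code ANP) or a Type-I ATP-competitive inhibitor, with or without a peptide |
| `peptide` | no small molecule, but a short peptide chain present |
| `apo` | neither small molecule nor peptide |

The priority order `substrate_product > inhibitor > peptide > apo` is
total: nucleotide identity always wins over peptide presence, so an
inhibitor-plus-peptide complex is `inhibitor`. Classification is by
ligand identity only; no geometric check that the ligand occupies the
ATP pocket is performed. This mirrors how such corpora are curated by
hand and keeps the classifier deterministic and auditable. The het-code
dictionary is deliberately conservative: a code that is neither a
state-defining ligand nor on the ignore list (waters, ions, cryo
additives, covalently modified residues such as TPO/SEP) raises an
error naming the code instead of guessing. The shipped Type-I seed list
(ANP, STU, ADN) is a starting point, not a registry; real corpora need
per-project extension via a JSON config.

Peptides are detected as polymer chains of at most 30 residues
(default). PKI fragments and substrate peptides are ~20 residues while
the kinase chain is ~350, so any threshold in between gives the same
answer for this corpus.

## Distance triplets

Conformation is summarised by the three pairwise Cα–Cα distances of
named residue triplets (PKA conventional numbering; one atom — the DFG
phenylalanine probe — uses the ring-tip Cζ):

- `lobe_closure` T51/H87/A223 — G-loop and αC versus the immobile αF
  helix; inter-lobe opening and closing. T51 is preferred over the
  historical S53 anchor because G-loop tip inversions in some
  inhibitor-bound structures contaminate the S53 signal;
  `lobe_closure_s53` is kept for comparison.
- `dfg_spine` K72(Cα)/F185(Cζ)/L95(Cα) — regulatory-spine assembly and
  the DFG-in/out/inter distinction.
- `ctail_gloop` D328/G52/E127 — tethering of the C-tail FDDY motif over
  the adenine pocket.
- `cspine_gloop` F54/F154/L173 — G-loop orientation relative to the
  catalytic spine and αE helix.
- `nlobe_core` V104/K81/N113 — N-lobe core geometry.

Altloc conformers resolve to the highest-occupancy one (ties break
alphabetically). A probe residue unresolved in the crystal yields a
missing distance; the record is still emitted and each summary cell
drops missing values independently, so the three pairs of one metric
may have different N within a state — as happens in real apo blocks
where the C-tail is disordered. Every kinase copy in a multi-copy
asymmetric unit contributes its own record.

Report output rounds to 0.1 Å, matching the precision crystallographic
distance tables are conventionally printed at; internal values keep
full precision.

## B′ normalization

Raw B-factors absorb resolution, refinement protocol and lattice
order, so chains are normalized independently:

1. **Occupancy weighting.** For an atom with altloc conformers,
   `B_i = Σ_I π_I B(i,I)`. If occupancies do not sum to 1 the sum is
   used as given (partial disorder is information, not an error) and a
   warning is logged.
2. **Outlier exclusion.** Modified z-scores
   `M(i) = 0.6745 |B_i − B~| / MAD` with `B~` the median and MAD the
   median absolute deviation; atoms with `M(i) > 3.5` are excluded in a
   single pass (no iteration). When MAD = 0 nothing is excluded.
   The MAD is the standard absolute-deviation form, which is what the
   0.6745 Gaussian consistency constant belongs to; a squared-deviation
   variant is available behind a flag for comparison.
3. **z-scoring.** `B′(a) = (B_a − B̄)/σ` with mean and sample standard
   deviation (n−1) over the surviving atoms. σ is recorded in the
   profile's report; at chain scale (≥ several hundred atoms) the
   sample/population distinction is negligible.
4. **Residue aggregation.** `B′(i) = Σ_a M_a B′(a) / Σ_a M_a` over the
   residue's selected, non-excluded atoms, with `M_a` the standard
   atomic weight — so a residue's value is the mass-weighted mean of
   its atoms and the weights sum to one. Residues whose selected atoms
   are all excluded or unresolved are reported missing, never imputed.

Three atom selections are supported — all heavy atoms, backbone
(N, CA, C, O) and Cα-only — and each is self-contained: median, MAD,
mean and σ are computed over the selection in use, so a backbone
profile does not depend on side-chain atoms. A consequence of the
sample-σ convention is that when every backbone atom of each residue
carries the same B, the Cα and backbone profiles agree exactly in
their unscaled deviations and differ only by the (finite-sample) σ
ratio of the two selections, which vanishes with chain length.

Hydrogens are ignored throughout; negative B-factors are flagged on
parse but left to the outlier filter rather than dropped.

## Ensemble statistics

- **Summary tables** per (state, triplet, pair): mean, median, sample
  SD (defined as 0 for a single value), N, min, quartiles, max.
  Quartiles use linear interpolation between order statistics; other
  conventions move q1/q3 by ≲0.1 Å at these sample sizes.
- **State bands**: per-residue mean B′ over the structures resolving
  that residue, with a 95% percentile bootstrap over structures
  (1000 resamples, seeded, bit-reproducible). The CI is over
  structures, not residues — the only reading that yields a
  per-residue band. Residues in fewer than two profiles keep their
  mean but get no CI.
- **PCA** of B′ profiles: one profile per structure (first molecule by
  chain order — the convention for multi-copy asymmetric units),
  columns restricted to the intersection of resolved residues across
  all profiles (imputation would fabricate flexibility signal),
  mean-centered but not variance-scaled since B′ is already z-scored.
  Loadings are orthonormal and reported up to sign; loading vectors
  can be exported as a PDB with the B column overwritten for putty
  rendering.
- **KDE** of distance distributions: Gaussian kernel, Scott's-rule
  bandwidth, deterministic given the data. Requires two distinct
  values.
- **Mutant placement** is purely descriptive: a structure's distance is
  reported against each state's density and the state whose density
  peak (argmax on a 2048-point grid spanning the data ± 6 kernel SDs)
  lies nearest. No significance statement is attached; with ~100
  structures per corpus none would be honest.

## Synthetic fixtures

The generator writes wwPDB v3.3 fixed-width PDB files whose every
measurable quantity is planted and recorded in a manifest: marker
coordinates as written (3-decimal precision) and all pairwise marker
distances, state-defining ligands and peptide chains, per-region raw-B
means with truncated-Gaussian noise (B ≥ 0), injected outlier atoms,
and altloc groups with known occupancies. Marker residues are the 16
probe residues of the built-in triplets, placed so each triplet
reproduces distances typical of nucleotide-bound PKA; the five triplet
neighbourhoods are spatially separated so planted displacements never
couple across metrics. Non-marker residues follow an ideal helix trace
whose geometry carries no signal.

The default corpus emulates the analysed PKA ensemble's composition —
37 substrate/product, 60 inhibitor, 15 apo, 3 peptide (115 structures)
— with: a +4 Å apo displacement of T51 away from A223 (lobe opening);
an elevated apo raw-B band over residues 120–139 (the αD-helix
region); 0.35 Å per-coordinate marker jitter, giving ≈0.5 Å distance
noise comparable to the within-state spread of real nucleotide-bound
ensembles; one two-conformer altloc group and two ~150 Å² outlier
atoms per structure; a two-copy asymmetric unit in every fifth
structure; and peptide chains on alternating substrate/product and
every fourth inhibitor entry.

What passing on these fixtures shows: the measurement, normalization
and aggregation machinery is algebraically correct and recovers
planted effects of realistic size under realistic noise. What it does
not show: robustness to the pathologies of real crystallography —
lattice-contact B-factor artefacts, resolution heterogeneity,
mis-numbered author chains, non-standard ligand codes — which is why
the classifier refuses unknown codes and the readers flag rather than
repair anomalies.

## Problem sizes and determinism

Tests and the acceptance script run the full 115-structure corpus
(~1 s to generate, ~4 s to read and analyse), 1000-atom outlier
Monte-Carlo samples, 20 PCA replicates at 30 structures × 100
residues, and 1000-resample bootstraps — sizes at which every planted
effect is comfortably resolvable while a complete run stays in the
tens of seconds. All stochastic steps (generator noise, bootstrap,
replicate seeds) derive from explicit integer seeds; identical seeds
reproduce outputs byte-for-byte.

## Known limitations

- No dihedral-based DFG-in/out classification and no interlobe
  rotation-angle analysis; distances only.
- No TLS/anisotropic decomposition or resolution-dependent correction
  of B-factors; z-scoring is the only inter-structure harmonization.
- Residue numbering is assumed to follow PKA convention (true for the
  targeted corpus); a per-structure integer offset is the only
  renumbering mechanism.
- The bundled inhibitor het-code list is minimal by design.
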