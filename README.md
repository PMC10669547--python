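# pkalens

Conformational-state and flexibility analysis of protein kinase A (PKA)
crystal-structure ensembles.

Protein kinases cycle through ligand-dependent conformations — lobe
opening and closing, regulatory-spine (R-spine) assembly around the DFG
motif, glycine-rich-loop (G-loop) rearrangement — that are visible
across the hundreds of PKA catalytic-subunit entries in the PDB.
`pkalens` turns a directory of PDB files into quantitative ensemble
statistics for structural biologists studying kinase regulation:

- **State assignment** — each structure is classified as
  `substrate_product` (ATP/ADP), `inhibitor` (AMP-PNP or Type-I
  inhibitors), `peptide` or `apo` from its active-site contents, with
  priority substrate_product > inhibitor > peptide > apo.
- **Distance triplets** — named Cα metrics, three pairwise distances
  each: `lobe_closure` (T51/H87/A223), `dfg_spine` (K72/F185-Cζ/L95),
  `ctail_gloop` (D328/G52/E127), `cspine_gloop` (F54/F154/L173),
  `nlobe_core` (V104/K81/N113), plus the historical S53 lobe metric.
  Every kinase copy in the asymmetric unit is measured.
- **B′ profiles** — raw B-factors are made comparable across
  structures: occupancy weighting `B_i = Σ_I π_I B(i,I)`, modified
  z-score outlier exclusion (`M(i) = 0.6745·|B_i − B~|/MAD > 3.5`),
  z-scoring `B′ = (B − B̄)/σ`, and atomic-mass-weighted per-residue
  aggregation `B′(i) = Σ M_a B′(a) / Σ M_a`.
- **Ensemble statistics** — per-state summary tables, per-residue mean
  B′ with seeded bootstrap 95% CIs, PCA of B′ profiles (first molecule
  per structure, intersection of resolved residues), Gaussian KDEs of
  distance distributions, and density-based placement of mutant
  structures against the per-state distributions.
- **Synthetic fixtures** — a generator that writes kinase-like PDB
  files with fully known geometry, ligands, altlocs and B-factor
  structure, so every stage is testable offline against a ground-truth
  manifest.

## Worked example

```bash
python examples/02_distance_triplets.py
```

builds a 24-structure synthetic corpus (planted +4 Å apo lobe
opening, 0.35 Å coordinate noise), classifies it, measures the
`lobe_closure` triplet and summarizes the T51–A223 distance per state:

```
                   average  std_dev    n  min_value  max_value
state
apo                  23.66     0.58  7.0      22.76      24.40
inhibitor            19.77     0.57  9.0      19.18      20.88
peptide              19.50     0.38  2.0      19.24      19.77
substrate_product    19.47     0.36  9.0      18.93      19.93

apo - substrate/product mean T51-A223 distance: +4.18 A
```

Ligand-free (apo) structures sit ~4 Å more open between the G-loop and
the αF helix than nucleotide-bound ones — the planted effect,
recovered within the configured noise. The other examples cover
state classification (`01`), single-chain B′ normalization with
outlier exclusion (`03`), and state bands, PCA and KDE mutant
placement (`04`); each prints the numbers it computes and what they
mean.

The same stages are available as subcommands of the `pkalens` console
script (`synth`, `classify`, `measure`, `bprime`, `profile`, `pca`,
`report`, `fetch`); run `pkalens --help`. Fetching real entries from
the RCSB PDB is always explicit (`pkalens fetch 1ATP 4DFY ...`) and
never triggered by tests.

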