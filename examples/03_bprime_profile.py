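"""Normalize one chain's B-factors into a B' flexibility profile.

Shows the full normalization chain on a single synthetic structure:
occupancy-weighted effective B per atom, modified-z outlier exclusion
(the generator plants two ~150 A^2 atoms), z-scoring, and
mass-weighted per-residue aggregation. A planted high-B band over
residues 120-139 (the aD-helix region) stands out in the profile.
"""

from pathlib import Path
from tempfile import mkdtemp

import numpy as np

from pkalens import normalize_chain, read_structure
from pkalens.synthetic import SyntheticSpec, generate

out = Path(mkdtemp(prefix="pkalens_demo_")) / "demo.pdb"
spec = SyntheticSpec(
    structure_id="DEMO", state="apo",
    b_region_means={(120, 139): 32.0}, base_b=20.0, b_noise_sd=4.0,
    outliers=((200, "O", 150.0), (260, "O", 160.0)),
    seed=3,
)
manifest = generate(spec, out)

model = read_structure(out, structure_id="DEMO")
profile = normalize_chain(model, "A", selection="backbone")
rep = profile.report

print(f"chain A backbone atoms: median B = {rep.median_b:.2f} A^2, MAD = {rep.mad:.2f} A^2")
print(f"post-exclusion mean = {rep.mean_b:.2f} A^2, sd = {rep.sd_b:.2f} A^2, "
      f"{rep.n_included} atoms kept")
print("excluded atoms:",
      sorted((r.residue_seq, n) for r, n in rep.excluded_atoms))
band = [v for r, v in profile.values.items() if 120 <= r.residue_seq <= 139]
rest = [v for r, v in profile.values.items() if not 120 <= r.residue_seq <= 139]
print(f"mean B' in planted 120-139 band: {np.mean(band):+.2f} "
      f"vs elsewhere: {np.mean(rest):+.2f}")
# The two injected ~150 A^2 atoms are caught by the M > 3.5 modified
# z-score filter; the planted band shows up as elevated dimensionless
# B' (flexibility in units of chain-level standard deviations).
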