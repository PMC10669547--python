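"""Measure the conformational distance triplets and summarize per state.

The apo structures in the default synthetic corpus carry a planted
+4 A displacement of the G-loop probe T51 away from the aF-helix
anchor A223, emulating lobe opening in ligand-free kinase structures.
The per-state summary of the T51-A223 distance recovers that shift.
"""

from pathlib import Path
from tempfile import mkdtemp

from pkalens import pipeline, summarize
from pkalens.metrics import get_triplet
from pkalens.synthetic import generate_corpus

out_dir = Path(mkdtemp(prefix="pkalens_demo_"))
generate_corpus(
    out_dir,
    per_state_counts={"substrate_product": 8, "inhibitor": 8, "apo": 6, "peptide": 2},
    seed=7,
)
models = pipeline.load_corpus(out_dir.glob("*.pdb"))
states = pipeline.classify_corpus(models)
records = pipeline.corpus_distances(models, states, [get_triplet("lobe_closure")])

table = summarize(records)
col = table.xs(("lobe_closure", "51CA-223CA"), level=["triplet", "pair"])
print(col[["average", "std_dev", "n", "min_value", "max_value"]].round(2))
shift = col.loc["apo", "average"] - col.loc["substrate_product", "average"]
print(f"\napo - substrate/product mean T51-A223 distance: {shift:+.2f} A")
# ~+4 A: ligand-free structures sit in the open lobe conformation;
# the residual deviation from 4.0 reflects the configured 0.35 A
# per-coordinate conformational jitter.
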