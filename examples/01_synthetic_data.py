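"""Generate a synthetic study: single cells, bulk cohort, cell lines.

The generator plants a strong CAF mesenchymal program, a weaker partial-EMT
program in a subset of cancer cells, shared genes expressed by both, CNA
blocks in cancer cells, and a bulk cohort whose CAF and pEMT fractions vary
nearly independently across tumours.
"""

import numpy as np

import emtdecouple as ed
from emtdecouple.sc import genes_detected

config = ed.SyntheticConfig(seed=0)
matrix, meta, positions, truth = ed.generate_sc_dataset(config)
bulk = ed.generate_bulk_cohort(config, truth)
lines = ed.generate_cellline_profiles(config, truth)

gd = genes_detected(matrix)
print(f"single cells: {matrix.shape[0]} genes x {matrix.shape[1]} cells")
print("cell types:", meta["cell_type"].value_counts().to_dict())
print(f"genes detected span: {gd.min()}-{gd.max()} "
      f"({gd.max() / gd.min():.1f}-fold)")
print(f"planted programs: {len(truth.pemt_genes)} pEMT, "
      f"{len(truth.caf_genes)} CAF, {len(truth.shared_genes)} shared genes")
print(f"bulk cohort: {bulk.expression.shape[1]} tumours, "
      f"purity {bulk.purity.min():.2f}-{bulk.purity.max():.2f}")
r = np.corrcoef(truth.caf_fraction, truth.pemt_fraction)[0, 1]
print(f"CAF-vs-pEMT fraction correlation: {r:+.3f} "
      "(limited by design, so co-expression can separate the programs)")
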