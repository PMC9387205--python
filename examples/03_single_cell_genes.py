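"""Color genes by their expression pattern across cells.

A synthetic sparse count matrix contains three gene modules (genes in a
module are expressed in the same subset of cells).  The single-cell track
depth-normalises and log-transforms the counts, reduces them (uncentered
SVD + UMAP with 50 neighbors) and colors each *gene*; module-mates end up
with similar colors, ready to paint nodes in a network viewer.
"""

from chromacloud import FitConfig, fit_and_encode, reduce_single_cell
from chromacloud.synthetic import sc_counts

counts, modules = sc_counts(n_genes=60, n_cells=90, seed=3)
dense = counts.dense()
print(f"counts: {counts.shape[0]} genes x {counts.shape[1]} cells, "
      f"{100 * (dense == 0).mean():.0f}% zeros")

cloud = reduce_single_cell(counts, seed=3)
table, _ = fit_and_encode(cloud, config=FitConfig(n_starts=10, seed=3))

for k in range(3):
    hexes = [h for h, m in zip(table.hex, modules == k) if m]
    print(f"module {k}: {hexes[:5]} ...")
print("\nEach line is one gene module: colors agree within a module because")
print("those genes share an expression pattern across the cells.")
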