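"""Color the rows of a high-dimensional matrix.

A 50-dimensional matrix with three planted clusters is reduced to 3D
(PCA, then UMAP), fitted into CIELAB, and summarised per cluster: mean
within-cluster color distance should be far below the between-cluster one,
i.e. rows with similar profiles receive similar colors.
"""

import numpy as np

from chromacloud import FitConfig, fit_and_encode, reduce_highdim
from chromacloud.synthetic import highdim_clusters

matrix, labels = highdim_clusters(n=90, seed=2)
cloud = reduce_highdim(matrix, seed=2)
table, _ = fit_and_encode(cloud, config=FitConfig(n_starts=10, seed=2))

for k in range(3):
    mask = labels == k
    hexes = [h for h, m in zip(table.hex, mask) if m]
    print(f"cluster {k}: {mask.sum()} rows, e.g. {hexes[:4]}")

lab = table.lab
d = np.linalg.norm(lab[:, None] - lab[None, :], axis=2)
same = labels[:, None] == labels[None, :]
iu = np.triu_indices(len(labels), 1)
print(f"\nmean color distance within clusters : {d[iu][same[iu]].mean():6.2f}")
print(f"mean color distance between clusters: {d[iu][~same[iu]].mean():6.2f}")
print("(small within vs large between = the encoding kept the structure)")
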