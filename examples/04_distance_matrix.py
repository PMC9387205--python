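"""Color entities given only a precomputed distance matrix.

Three tight cliques (within-distance 0.1, between-distance 10) are
embedded straight from the matrix (UMAP, precomputed metric) and colored.
Useful when the natural input is a tree or profile distance, not a
feature matrix.
"""

from chromacloud import FitConfig, fit_and_encode, reduce_distance
from chromacloud.synthetic import cliques_dist

dist, cliques = cliques_dist(n=45, seed=4)
cloud = reduce_distance(dist, seed=4)
table, _ = fit_and_encode(cloud, config=FitConfig(n_starts=10, seed=4))

for k in range(3):
    hexes = [h for h, m in zip(table.hex, cliques == k) if m]
    print(f"clique {k}: {hexes[:5]}")
print("\nMembers of a clique share nearly one color; cliques differ strongly.")
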