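"""Color a small 3D point cloud directly (no dimensionality reduction).

Builds three well-separated Gaussian clusters in 3D, fits them into the
displayable part of CIELAB, and prints one hex color per point.  Points in
the same cluster come out in visibly similar colors because the fit is a
similarity transform: CIELAB distance stays proportional to 3D distance.
"""

import numpy as np

from chromacloud import FitConfig, fit_and_encode
from chromacloud.synthetic import clusters3d

cloud, labels = clusters3d(n=30, seed=1)
table, result = fit_and_encode(cloud, config=FitConfig(n_starts=10, seed=1))

print(f"best objective {result.objective:.2f} at scale {result.best.scale:.1f}")
print("name      cluster  L*      a*      b*      hex")
for name, lab, (L, a, b), h in zip(table.names, labels, table.lab, table.hex):
    print(f"{name}  {lab}        {L:6.1f}  {a:6.1f}  {b:6.1f}  {h}")

# distances between colors mirror distances between points exactly
d_in = np.linalg.norm(cloud.coords[0] - cloud.coords[1])
d_out = np.linalg.norm(table.lab[0] - table.lab[1])
print(f"\npoint distance {d_in:.3f} -> color distance {d_out:.2f} "
      f"(ratio = fitted scale / cloud radius = {d_out / d_in:.2f})")
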