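"""Save a fitted transform and reapply it to new data points.

The fit records the cloud normalisation and the optimal similarity
transform as JSON, so new points expressed in the same coordinate frame
can be colored later without re-optimising — their colors are directly
comparable to the original ones.
"""

import numpy as np

from chromacloud import FitConfig, FitResult, PointCloud3, encode, fit_cloud
from chromacloud.synthetic import clusters3d

cloud, _ = clusters3d(n=30, seed=5)
result = fit_cloud(cloud, config=FitConfig(n_starts=10, seed=5))
text = result.to_json()  # or result.to_json("fit.json")
print(f"saved fit: objective {result.objective:.2f}, "
      f"{len(result.alternatives)} ranked alternatives")

# ... later, possibly in another process ...
reloaded = FitResult.from_json(text)
new_points = PointCloud3(["new_a", "new_b"], cloud.coords[:2] + 0.05)
new_table = encode(new_points, reloaded)
orig_table = encode(cloud, reloaded)
for i, (name, h) in enumerate(zip(new_table.names, new_table.hex)):
    print(f"{name}: {h}   (neighbor {cloud.names[i]}: {orig_table.hex[i]})")
print("Each new point sits 0.05 away from an original, so its color is "
      "near-identical to that original's color.")
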