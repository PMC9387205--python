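# chromacloud

Encode high-dimensional data as colors that you can put anywhere — on
network nodes, map markers, tree leaves — so that **similar profiles get
similar colors**.

Large biological datasets (single-cell expression, microbiome profiles,
any entities × features matrix) are usually visualized by scatter plots of
a 2D embedding, which occupies the spatial axes.  Encoding each entity as
a *color* instead frees those axes: gene colors can be painted onto a
protein-interaction network, sample colors onto sampling locations.  For
the colors to be meaningful, perceptual color difference must track
profile distance.  `chromacloud` achieves this in two steps:

1. **Reduce** the data to a 3D point cloud (human color perception is
   three-dimensional).  Tracks: dense matrices (PCA → UMAP), sparse
   single-cell counts (log-normalisation → uncentered SVD → UMAP, coloring
   the genes), precomputed distance matrices (UMAP on the metric), or data
   that is already 3D.
2. **Fit** the cloud into the displayable part of CIELAB — the image of
   the sRGB cube, within which Euclidean distance approximates perceptual
   difference.  A multi-start Nelder–Mead search over a 7-parameter
   similarity transform (translation **t**, rotations θ about the
   L\*, a\*, b\* axes, uniform scale s) maximises

       size(T(hull)) − λ · mean overshoot(T(hull)),

   the axis-weighted extent of the transformed convex hull minus a penalty
   for hull vertices protruding past the gamut boundary.  Because the
   transform is a similarity, output color distances are an *exact*
   positive multiple of input distances.

Every entity then gets an (L\*, a\*, b\*) triple and an sRGB hex string.

## Worked example

```python
from chromacloud import FitConfig, fit_and_encode
from chromacloud.synthetic import clusters3d

cloud, labels = clusters3d(n=30, seed=1)        # 3 planted clusters in 3D
table, result = fit_and_encode(cloud, config=FitConfig(n_starts=10, seed=1))
print(f"best objective {result.objective:.2f} at scale {result.best.scale:.1f}")
for name, (L, a, b), h in list(zip(table.names, table.lab, table.hex))[:3]:
    print(f"{name}  L*={L:5.1f} a*={a:6.1f} b*={b:6.1f}  {h}")
```

prints

```
best objective 108.79 at scale 90.6
pt0000  L*= 53.9 a*=  48.0 b*=  41.2  #D7593C
pt0001  L*= 53.9 a*=  49.5 b*=  57.7  #DB5618
pt0002  L*= 53.4 a*=  51.6 b*=  49.6  #DB532B
```

The objective is the mean Lab-axis extent of the fitted cloud (~109 Lab
units here — the cloud fills most of the gamut); `scale` is the factor by
which normalised input distances are multiplied to become color
distances.  The three points shown are cluster-mates, so their red-orange
hex colors nearly coincide, while the other two clusters come out
blue-violet and green (run `python examples/01_color_a_3d_cloud.py` for
the full table).  The `examples/` directory has one script per track,
plus saving a fit and reapplying it to new data.

Command-line equivalents:

```bash
chromacloud fixture clusters3d -n 30 --seed 1 -o demo.csv
chromacloud direct3d demo.csv -o colors.tsv --seed 1 --save-fit fit.json
chromacloud highdim matrix.csv -o colors.tsv --weights 2,1,1
chromacloud single-cell counts.mtx -o colors.tsv --transpose
chromacloud distmatrix dist.csv -o colors.tsv
```

The output TSV has columns `name, L, a, b, hex` and feeds node-color
imports in network tools directly.

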