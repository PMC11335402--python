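"""Fit a PCA morphospace to a synthetic jaw population and grid it.

Generates 60 jaw outlines varying in robustness, curvature and joint
position, runs EFA + PCA, and reconstructs a 25 x 20 theoretical grid
(padded by 20% of the PC1 range on every side).  Cells whose reconstructed
outline self-intersects are "impossible morphospace": shapes the linear
coefficient space describes but no planar jaw can realize.
"""

import numpy as np

import jawscape as jw

pop = jw.generate_population(60, seed=42, K=600)
vectors = np.array(
    [jw.efa_normalize(jw.efa_forward(loop, 40)).to_vector() for loop, _ in pop]
)
ms = jw.fit_pca(vectors, shape_ids=[loop.source_id for loop, _ in pop])
print("variance explained (%):", np.round(ms.var_explained[:5], 2))
print("PC1+PC2 capture", round(float(ms.var_explained[:2].sum()), 1),
      "% of shape variation -> a 2D grid is a fair summary of the space")

grid = jw.sample_grid(ms, nx=25, ny=20, extension_frac=0.20, K=600)
n_bad = int((~grid.valid).sum())
print(f"theoretical grid: {grid.n_cells} shapes, {n_bad} impossible "
      f"({100 * n_bad / grid.n_cells:.0f}% of cells self-intersect)")
print("PC1 span:", np.round([grid.pc1_values[0], grid.pc1_values[-1]], 3),
      " PC2 span:", np.round([grid.pc2_values[0], grid.pc2_values[-1]], 3))
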