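"""Train a K-SVD patch dictionary and sparse-code patches with OMP.

The low-pass fusion rule runs on exactly these primitives: 8x8 patches are
coded as sparse combinations of learned atoms, and per patch the code with
the larger l1 norm wins.
"""

import numpy as np

from ffoafuse import extract_patches, ksvd_train, l1_max_select, make_vessel_phantom, omp_encode

image = make_vessel_phantom(160, 160, n_vessels=10, seed=2, texture_amplitude=0.03)
grid = extract_patches(image, patch_size=8, step=3)
print(f"{grid.n_patches} patches of 8x8 extracted (stride 3)")

dictionary = ksvd_train(grid.patches, n_atoms=96, max_nonzeros=8, n_iterations=6, seed=0)
errs = dictionary.metadata["errors"]
print("mean coding residual per K-SVD iteration:",
      " ".join(f"{e:.4f}" for e in errs))

codes = omp_encode(grid.patches[:, :500], dictionary, tolerance=0.01, max_nonzeros=8)
nnz = (codes.coefficients != 0).sum(axis=0)
print(f"OMP on 500 patches: mean nonzeros {nnz.mean():.2f}, "
      f"max residual {codes.residual_norms.max():.4f} (tolerance 0.01, cap 8)")

winner = l1_max_select(codes.coefficients[:, 0], codes.coefficients[:, 1])
print(f"l1-max rule between patches 0 and 1 keeps the code with "
      f"l1 norm {np.abs(winner).sum():.3f}")
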