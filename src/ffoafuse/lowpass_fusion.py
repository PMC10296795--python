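"""Sparse-representation fusion of the two NSCT low-pass subbands.

The low-pass bands carry the energy (brightness/contrast) of the source
images.  Both are cut into the same sliding-window patch grid, each patch is
OMP-coded over a shared redundant dictionary, and for every grid position
the code with the larger l1 norm wins (the "l1-max" rule); the winning codes
are decoded through the dictionary and the blocks pasted back, averaging
overlapping pixels.
"""

from __future__ import annotations

import numpy as np

from .dictionary import Dictionary, extract_patches, omp_encode, reassemble_patches
from .exceptions import DimensionError

__all__ = ["l1_max_select", "fuse_lowpass"]


def l1_max_select(vA: np.ndarray, vB: np.ndarray) -> np.ndarray:
    """Return ``vA`` if its l1 norm is strictly larger, else ``vB`` (ties -> B)."""
    vA = np.asarray(vA, dtype=float)
    vB = np.asarray(vB, dtype=float)
    if vA.shape != vB.shape:
        raise DimensionError(f"coefficient shapes differ: {vA.shape} vs {vB.shape}")
    return vA if np.abs(vA).sum() > np.abs(vB).sum() else vB


def fuse_lowpass(
    LA: np.ndarray,
    LB: np.ndarray,
    dictionary: Dictionary,
    step: int = 1,
    tolerance: float = 0.01,
    max_nonzeros: int = 8,
    patch_size: int = 8,
    return_choice: bool = False,
):
    """Fuse two low-pass subbands by per-patch l1-max selection of sparse codes.

    Parameters
    ----------
    LA, LB : 2-D arrays of identical shape
    dictionary : Dictionary
        Shared patch dictionary (atom length must equal ``patch_size**2``).
    step : int
        Sliding-window stride (lambda); 1 gives maximum overlap.
    tolerance, max_nonzeros :
        OMP stopping parameters.
    return_choice : bool
        Also return the boolean per-patch array (True where A's code won).
    """
    LA = np.asarray(LA, dtype=float)
    LB = np.asarray(LB, dtype=float)
    if LA.shape != LB.shape:
        raise DimensionError(f"low-pass shapes differ: {LA.shape} vs {LB.shape}")
    if dictionary.atom_length != patch_size * patch_size:
        raise DimensionError(
            f"dictionary atom length {dictionary.atom_length} does not match "
            f"patch size {patch_size}x{patch_size}"
        )
    gridA = extract_patches(LA, patch_size, step)
    gridB = extract_patches(LB, patch_size, step)
    codesA = omp_encode(gridA.patches, dictionary, tolerance, max_nonzeros)
    codesB = omp_encode(gridB.patches, dictionary, tolerance, max_nonzeros)
    a_wins = codesA.l1_norms() > codesB.l1_norms()  # ties -> B, as in the l1-max rule
    fused_codes = np.where(a_wins[None, :], codesA.coefficients, codesB.coefficients)
    decoded = dictionary.atoms @ fused_codes
    fused = reassemble_patches(decoded, gridA.positions, patch_size, LA.shape)
    if return_choice:
        return fused, a_wins
    return fused
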