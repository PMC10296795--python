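"""Information-theoretic fusion quality metrics: Q^MI, Q^TE, Q^NCIE.

All three score how much of the two source images' information survives in
the fused image; larger is better.  Intensities in [0, 1] are quantised to
``n_bins`` grey levels and all probabilities come from unsmoothed joint
histograms.

* Q^MI: normalised mutual information,
  ``2 * [I(A;F)/(H(A)+H(F)) + I(B;F)/(H(B)+H(F))]`` — equals 2 when
  F = A = B.
* Q^TE: the same construction with Tsallis (order-q) divergence and
  entropies; as q -> 1 it converges to Q^MI.
* Q^NCIE: nonlinear correlation information entropy — the eigenvalue
  entropy of the 3x3 matrix of pairwise nonlinear correlation coefficients,
  each computed from rank-transformed pixels placed into equal-frequency
  bins; equals 1 for three identical images.
"""

from __future__ import annotations

import warnings

import numpy as np

from .exceptions import ConfigurationError, DimensionError

__all__ = ["q_mi", "q_te", "q_ncie"]


def _quantize(img: np.ndarray, n_bins: int) -> np.ndarray:
    img = np.asarray(img, dtype=float)
    return np.clip(np.floor(img * n_bins), 0, n_bins - 1).astype(np.intp)


def _check_triple(A, B, F):
    A, B, F = (np.asarray(x, dtype=float) for x in (A, B, F))
    if not (A.shape == B.shape == F.shape):
        raise DimensionError(f"shapes differ: {A.shape}, {B.shape}, {F.shape}")
    return A, B, F


def _joint_hist(x: np.ndarray, y: np.ndarray, n_bins: int) -> np.ndarray:
    idx = x.ravel() * n_bins + y.ravel()
    counts = np.bincount(idx, minlength=n_bins * n_bins)
    return (counts / counts.sum()).reshape(n_bins, n_bins)


def _entropy(p: np.ndarray) -> float:
    p = p[p > 0]
    return float(-(p * np.log(p)).sum())


def _nmi_term(x: np.ndarray, f: np.ndarray, n_bins: int) -> float:
    pxy = _joint_hist(x, f, n_bins)
    hx = _entropy(pxy.sum(axis=1))
    hf = _entropy(pxy.sum(axis=0))
    if hx + hf == 0.0:
        warnings.warn("constant image: zero-entropy term contributes 0", stacklevel=3)
        return 0.0
    mi = hx + hf - _entropy(pxy)
    return mi / (hx + hf)


def q_mi(A, B, F, n_bins: int = 256) -> float:
    """Normalised mutual information between the sources and the fused image."""
    A, B, F = _check_triple(A, B, F)
    qa, qb, qf = (_quantize(x, n_bins) for x in (A, B, F))
    return 2.0 * (_nmi_term(qa, qf, n_bins) + _nmi_term(qb, qf, n_bins))


def _tsallis_entropy(p: np.ndarray, q: float) -> float:
    return float((1.0 - (p[p > 0] ** q).sum()) / (q - 1.0))


def _tsallis_term(x: np.ndarray, f: np.ndarray, q: float, n_bins: int) -> float:
    pxy = _joint_hist(x, f, n_bins)
    px = pxy.sum(axis=1)
    pf = pxy.sum(axis=0)
    hx = _tsallis_entropy(px, q)
    hf = _tsallis_entropy(pf, q)
    if hx + hf == 0.0:
        warnings.warn("constant image: zero-entropy term contributes 0", stacklevel=3)
        return 0.0
    # Tsallis divergence between the joint and the product of marginals
    prod = np.outer(px, pf)
    nz = pxy > 0
    div = ((pxy[nz] ** q) * (prod[nz] ** (1.0 - q))).sum()
    div = (div - 1.0) / (q - 1.0)
    return div / (hx + hf)


def q_te(A, B, F, q_param: float = 1.85, n_bins: int = 256) -> float:
    """Tsallis-divergence analogue of Q^MI (order ``q_param`` != 1)."""
    if q_param == 1.0:
        raise ConfigurationError("q_param must differ from 1 (use q_mi for the limit)")
    A, B, F = _check_triple(A, B, F)
    qa, qb, qf = (_quantize(x, n_bins) for x in (A, B, F))
    return 2.0 * (
        _tsallis_term(qa, qf, q_param, n_bins) + _tsallis_term(qb, qf, q_param, n_bins)
    )


def _rank_bins(x: np.ndarray, n_bins: int) -> np.ndarray:
    """Equal-frequency binning of pixel ranks (stable sort, ties in raster order)."""
    flat = x.ravel()
    order = np.argsort(flat, kind="stable")
    ranks = np.empty_like(order)
    ranks[order] = np.arange(flat.size)
    return (ranks * n_bins) // flat.size


def _ncc(bx: np.ndarray, by: np.ndarray, n_bins: int) -> float:
    """Nonlinear correlation coefficient: H_b(X) + H_b(Y) - H_b(X, Y), log base b."""
    pxy = _joint_hist(bx, by, n_bins)
    logb = np.log(n_bins)
    hx = _entropy(pxy.sum(axis=1)) / logb
    hy = _entropy(pxy.sum(axis=0)) / logb
    hxy = _entropy(pxy) / logb
    return hx + hy - hxy


def q_ncie(A, B, F, n_bins: int = 256) -> float:
    """Nonlinear correlation information entropy of the (A, B, F) triple.

    Builds the symmetric 3x3 matrix R of pairwise nonlinear correlation
    coefficients (unit diagonal) and returns
    ``1 + sum_i (lam_i / 3) * log_b(lam_i / 3)`` over its eigenvalues, with
    log base ``b = n_bins``.  Lies in [0, 1]; 1 iff the three images are
    perfectly dependent.  The "equals 1 exactly for identical images"
    property requires the pixel count to be divisible by ``n_bins`` (equal
    rank-bin occupancy).
    """
    A, B, F = _check_triple(A, B, F)
    bins = [_rank_bins(x, n_bins) for x in (A, B, F)]
    R = np.eye(3)
    for i in range(3):
        for j in range(i + 1, 3):
            R[i, j] = R[j, i] = _ncc(bins[i], bins[j], n_bins)
    lam = np.clip(np.linalg.eigvalsh(R), 0.0, None)
    frac = lam / 3.0
    nz = frac > 0
    return float(1.0 + (frac[nz] * np.log(frac[nz]) / np.log(n_bins)).sum())
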